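"""Pipeline configuration: every tunable stage parameter with its default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Stage parameters for the feature-extraction chain.

    Defaults follow the published processing chain: trim 10% of each end,
    0.2 Hz zero-phase high-pass detrend, a 2-12 Hz physiological search band,
    and a +/-2 Hz zero-phase band-pass around the autocorrelation frequency.
    """

    trim_fraction: float = 0.10
    detrend_cutoff: float = 0.2  # Hz
    detrend_order: int = 3
    band: tuple[float, float] = (2.0, 12.0)  # Hz, f_ac and fc search band
    autocorr_peak_rule: str = "highest"  # or "first" local maximum
    bp_half_width: float = 2.0  # Hz
    bp_order: int = 8  # per band-pass half
    peak_min_prom_frac: float = 0.1  # fraction of the interdecile range
    spcr_narrow: float = 0.5  # Hz
    spcr_wide: float = 2.0  # Hz

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        self.band = tuple(float(b) for b in self.band)  # type: ignore[assignment]
        if len(self.band) != 2 or self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if self.spcr_narrow >= self.spcr_wide:
            raise ValueError("spcr_narrow must be < spcr_wide")
        if self.autocorr_peak_rule not in ("highest", "first"):
            raise ValueError("autocorr_peak_rule must be 'highest' or 'first'")
        if self.detrend_cutoff <= 0 or self.bp_half_width <= 0:
            raise ValueError("cutoffs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (plain key: value) file; unknown keys rejected."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a key-value mapping")
        return cls.from_dict(data)
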