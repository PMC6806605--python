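"""Reading, validating and writing TremorSense-style gyroscope CSV recordings.

A recording is a plain CSV with four columns ``timestamp,x,y,z``: a timestamp
and the angular velocity (deg/s) about the three sensor axes.  The acquisition
app logs millisecond timestamps; analysis uses seconds relative to the first
sample, so the reader normalizes either encoding.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Widest angular-velocity range of the target gyroscope, deg/s.  A sample
#: beyond this indicates a unit error (e.g. raw counts), not tremor.
MAX_ANGULAR_VELOCITY = 2000.0

#: Column order of a feature table, mirroring the cohort summary tables.
FEATURE_COLUMNS = [
    "peak_frequency",
    "amplitude_mean",
    "amplitude_std",
    "amplitude_iqr",
    "regularity_mean",
    "regularity_std",
    "regularity_iqr",
    "icvf_mean",
    "icvf_std",
    "icvf_iqr",
    "spcr",
    "f_ac",
    "pc1_evr",
]

FEATURE_TABLE_COLUMNS = ["patient_id", "group"] + FEATURE_COLUMNS


class RecordingError(ValueError):
    """Raised when a recording file or array fails validation."""


@dataclass
class GyroRecording:
    """Timestamped triaxial angular-velocity samples plus metadata.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing, relative to the first
        sample (``timestamps[0] == 0`` after normalization).
    omega
        ``(n, 3)`` array of angular velocity about x, y, z in deg/s.
    patient_id
        Opaque identifier carried through to feature tables.
    nominal_rate
        Sampling rate in Hz; inferred as ``1 / median(dt)`` when not given.
    """

    timestamps: np.ndarray
    omega: np.ndarray
    patient_id: str = ""
    nominal_rate: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[1] != 3:
            raise RecordingError("omega must be an (n, 3) array")
        n = len(self.timestamps)
        if n != self.omega.shape[0]:
            raise RecordingError(
                f"length mismatch: {n} timestamps vs {self.omega.shape[0]} samples"
            )
        if n < 2:
            raise RecordingError("recording must contain at least 2 samples")
        if not np.all(np.isfinite(self.timestamps)) or not np.all(
            np.isfinite(self.omega)
        ):
            raise RecordingError("recording contains non-finite values")
        if np.any(np.diff(self.timestamps) <= 0):
            raise RecordingError("timestamps must be strictly increasing")
        if np.any(np.abs(self.omega) > MAX_ANGULAR_VELOCITY):
            raise RecordingError(
                f"|angular velocity| exceeds {MAX_ANGULAR_VELOCITY} deg/s; "
                "check input units"
            )
        if np.isnan(self.nominal_rate):
            self.nominal_rate = 1.0 / float(np.median(np.diff(self.timestamps)))

    # Convenience channel views -------------------------------------------
    @property
    def omega_x(self) -> np.ndarray:
        return self.omega[:, 0]

    @property
    def omega_y(self) -> np.ndarray:
        return self.omega[:, 1]

    @property
    def omega_z(self) -> np.ndarray:
        return self.omega[:, 2]

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])


def _normalize_timestamps(t: np.ndarray, timestamp_unit: str) -> np.ndarray:
    """Convert raw timestamps to seconds relative to the first sample.

    Auto-detection: acquisition apps log epoch/relative milliseconds, so a
    median spacing above 1 implies milliseconds; analysis-grade files use
    seconds with spacings well below 1 s.
    """
    t = np.asarray(t, dtype=float)
    t = t - t[0]
    if timestamp_unit == "auto":
        dt = np.diff(t)
        if len(dt) and np.median(dt) > 1.0:
            timestamp_unit = "ms"
        else:
            timestamp_unit = "s"
    if timestamp_unit == "ms":
        t = t / 1000.0
    elif timestamp_unit != "s":
        raise ValueError(f"unknown timestamp unit: {timestamp_unit!r}")
    return t


def read_recording(
    path: str | Path,
    unit: str = "deg/s",
    timestamp_unit: str = "auto",
    patient_id: str | None = None,
) -> GyroRecording:
    """Read a 4-column gyroscope CSV into a :class:`GyroRecording`.

    Parameters
    ----------
    path
        CSV file with columns ``timestamp,x,y,z``.  A header row is detected
        automatically (first row non-numeric).
    unit
        Angular-velocity unit of the file, ``"deg/s"`` or ``"rad/s"``;
        rad/s values are converted to deg/s.
    timestamp_unit
        ``"s"``, ``"ms"`` or ``"auto"`` (median spacing > 1 implies ms).
    patient_id
        Override for the recording identifier; defaults to the file stem.
    """
    path = Path(path)
    if unit not in ("deg/s", "rad/s"):
        raise ValueError(f"unsupported unit: {unit!r}")
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, raw in enumerate(reader, start=1):
            if not raw or all(not cell.strip() for cell in raw):
                continue
            if len(raw) < 4:
                raise RecordingError(
                    f"{path.name}:{lineno}: expected 4 columns, got {len(raw)}"
                )
            try:
                vals = [float(cell) for cell in raw[:4]]
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header row
                raise RecordingError(
                    f"{path.name}:{lineno}: malformed row {raw[:4]!r}"
                ) from None
            rows.append(vals)
    if len(rows) < 2:
        raise RecordingError(f"{path.name}: fewer than 2 data rows")
    data = np.asarray(rows, dtype=float)
    t = _normalize_timestamps(data[:, 0], timestamp_unit)
    omega = data[:, 1:4]
    if unit == "rad/s":
        omega = np.degrees(omega)
    if np.any(np.diff(t) <= 0):
        raise RecordingError(f"{path.name}: timestamps are not strictly increasing")
    return GyroRecording(
        timestamps=t,
        omega=omega,
        patient_id=patient_id if patient_id is not None else path.stem,
    )


def write_recording(rec: GyroRecording, path: str | Path) -> None:
    """Write a recording as a ``timestamp,x,y,z`` CSV at full float precision.

    Round-trip stable: ``read_recording(write_recording(rec))`` reproduces the
    channels to better than 1e-9 deg/s.
    """
    if len(rec) == 0:
        raise RecordingError("refusing to write an empty recording")
    path = Path(path)
    buf = _io.StringIO()
    buf.write("timestamp,x,y,z\n")
    for t, (x, y, z) in zip(rec.timestamps, rec.omega):
        buf.write(f"{t:.17g},{x:.17g},{y:.17g},{z:.17g}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def resample_uniform(rec: GyroRecording, tol: float = 0.01) -> GyroRecording:
    """Return the recording on a uniform time grid at the median sample period.

    If the relative timestamp jitter ``max|dt - median(dt)| / median(dt)``
    exceeds ``tol``, all three axes are cubic-spline interpolated onto the
    uniform grid (linear interpolation at tremor frequencies would distort
    amplitudes by several percent at this sampling rate); otherwise the
    samples are kept and only the timestamps are regularized.  Idempotent.
    """
    dt = np.diff(rec.timestamps)
    med = float(np.median(dt))
    n = len(rec)
    grid = rec.timestamps[0] + med * np.arange(n)
    # keep the grid inside the observed span so interpolation never extrapolates
    grid = grid[grid <= rec.timestamps[-1] + med * 1e-9]
    if np.max(np.abs(dt - med)) / med <= tol:
        return replace(
            rec,
            timestamps=rec.timestamps[0] + med * np.arange(n),
            omega=rec.omega.copy(),
            nominal_rate=1.0 / med,
        )
    from scipy.interpolate import CubicSpline

    spline = CubicSpline(rec.timestamps, rec.omega, axis=0)
    omega = spline(grid)
    return replace(rec, timestamps=grid, omega=omega, nominal_rate=1.0 / med)


# Feature tables -----------------------------------------------------------


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a feature table against the expected schema.

    One row per recording; ``patient_id`` unique within each group.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    dup = table.duplicated(subset=["patient_id", "group"])
    if dup.any():
        ids = table.loc[dup, "patient_id"].tolist()
        raise ValueError(f"duplicated patient_id within a group: {ids}")
    return table[FEATURE_TABLE_COLUMNS]


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV."""
    return validate_feature_table(pd.read_csv(path))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated feature table as CSV."""
    validate_feature_table(table).to_csv(path, index=False)
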