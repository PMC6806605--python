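"""Cohort-level statistics: group comparison tables and ROC discrimination.

The ROC machinery is deliberately self-contained (thresholds at midpoints of
consecutive unique scores, trapezoid AUC): the trapezoid AUC then equals the
tie-adjusted pairwise-comparison probability (Mann-Whitney U / n1*n2)
exactly, which the test suite checks against an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io import FEATURE_COLUMNS


class CohortError(ValueError):
    pass


@dataclass
class GroupComparison:
    """Per-feature group means/SDs and two-sided p-values."""

    table: pd.DataFrame  # index: feature; columns mean_a sd_a mean_b sd_b p_value
    test_name: str
    n_a: int
    n_b: int


@dataclass
class RocResult:
    """ROC curve with AUC, optional bootstrap CI, and an operating point."""

    thresholds: np.ndarray  # descending; +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: object = 1
    auc_ci: tuple[float, float] | None = None
    optimal: tuple[float, float, float] | None = None  # threshold, sens, spec
    flipped: bool = False  # True when the score direction was inverted

    def youden(self) -> np.ndarray:
        """J = sensitivity - (1 - specificity) at every threshold."""
        return self.sensitivity + self.specificity - 1.0


#: Row order of the comparison table, matching the published feature tables.
TABLE_ORDER = [c for c in FEATURE_COLUMNS if c not in ("f_ac", "pc1_evr")]


def compare_groups(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    test: str = "welch_t",
    features: list[str] | None = None,
) -> GroupComparison:
    """Per-feature mean +/- SD for each group with a two-sided p-value.

    ``welch_t`` (unequal-variance t-test, the default) or ``mann_whitney``
    (mid-rank ties).  Raw p-values, no multiplicity correction.
    """
    features = features or TABLE_ORDER
    for tbl, label in ((tableA, "A"), (tableB, "B")):
        missing = [f for f in features if f not in tbl.columns]
        if missing:
            raise CohortError(f"group {label} table missing columns: {missing}")
        if len(tbl) < 2:
            raise CohortError(f"group {label} needs at least 2 rows")
    rows = []
    for feat in features:
        a = np.asarray(tableA[feat], dtype=float)
        b = np.asarray(tableB[feat], dtype=float)
        if test not in ("welch_t", "mann_whitney"):
            raise CohortError(f"unknown test: {test!r}")
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical samples: the null is true by construction
        elif test == "welch_t":
            p = float(spstats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(spstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "feature": feat,
                "mean_a": float(np.mean(a)),
                "sd_a": float(np.std(a, ddof=1)),
                "mean_b": float(np.mean(b)),
                "sd_b": float(np.std(b, ddof=1)),
                "p_value": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    return GroupComparison(
        table=table, test_name=test, n_a=len(tableA), n_b=len(tableB)
    )


def roc_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_label: object = 1,
) -> RocResult:
    """ROC curve treating ``score >= threshold`` as a positive prediction.

    Thresholds sit at midpoints between consecutive sorted unique scores,
    bracketed by +/-inf so the curve spans (0,0) to (1,1).  AUC is the
    trapezoid integral of sensitivity over 1 - specificity, which equals the
    tie-adjusted probability that a random positive outscores a random
    negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise CohortError("scores and labels must have the same shape")
    if not np.all(np.isfinite(scores)):
        raise CohortError("scores must be finite")
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise CohortError("both classes must be present")
    u = np.unique(scores)
    mids = (u[1:] + u[:-1]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    # predicted positive: score >= threshold
    sens = np.array([np.mean(pos >= th) for th in thresholds])
    spec = np.array([np.mean(neg < th) for th in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_label=positive_label,
    )


def optimal_threshold(roc: RocResult) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity - (1 - specificity).

    Ties are broken toward the lower threshold.  A degenerate curve (all
    scores identical, J = 0 everywhere) returns the -inf endpoint with a
    warning.
    """
    j = roc.youden()
    best = int(np.argmax(j + 0.0))  # first occurrence = highest threshold
    # ties toward the LOWER threshold: scan for the last index attaining max J
    jmax = j[best]
    best = int(np.max(np.flatnonzero(np.isclose(j, jmax, rtol=0, atol=1e-12))))
    if np.isclose(jmax, 0.0, atol=1e-12):
        warnings.warn(
            "degenerate ROC curve: no threshold separates the classes",
            stacklevel=2,
        )
    point = (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )
    roc.optimal = point
    return point


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via mid-ranks; fast path used by the bootstrap."""
    ranks = spstats.rankdata(np.concatenate([pos, neg]))
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auc_confidence_interval(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    positive_label: object = 1,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Resamples within each class so both remain represented; deterministic
    given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) < 5 or len(neg) < 5:
        raise CohortError(
            "each class needs >= 5 subjects for a bootstrap CI; "
            "use exact methods for smaller samples"
        )
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        aucs[b] = _auc_rank(
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def discriminate(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    feature: str,
    positive: str = "B",
    n_boot: int = 2000,
    seed: int = 0,
    auto_flip: bool = True,
) -> RocResult:
    """Full single-feature discrimination: ROC + optimal point + AUC CI.

    Group B is the positive class by default.  When ``auto_flip`` is set and
    the raw AUC is below 0.5, the score sign is inverted (and reported via
    ``flipped``) so the curve reads in the conventional direction.
    """
    if feature not in tableA.columns or feature not in tableB.columns:
        raise CohortError(f"feature {feature!r} absent from a group table")
    scores = np.concatenate(
        [np.asarray(tableA[feature], float), np.asarray(tableB[feature], float)]
    )
    labels = np.concatenate([np.zeros(len(tableA)), np.ones(len(tableB))])
    pos_label = 1.0 if positive == "B" else 0.0
    roc = roc_curve(scores, labels, positive_label=pos_label)
    flipped = False
    if auto_flip and roc.auc < 0.5:
        scores = -scores
        roc = roc_curve(scores, labels, positive_label=pos_label)
        flipped = True
    roc.flipped = flipped
    optimal_threshold(roc)
    roc.auc_ci = auc_confidence_interval(
        scores, labels, n_boot=n_boot, seed=seed, positive_label=pos_label
    )
    return roc
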