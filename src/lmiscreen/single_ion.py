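"""Single-ion threshold screening.

For one ion the classifier is a threshold on the log10 peak area.  The
threshold is searched on a fixed grid of increment 0.01 spanning the pooled
data range (bounds rounded outward), under both orientations:

* ``positive_high`` — a sample is called positive iff its score is strictly
  greater than the threshold;
* ``positive_low`` — strictly less than.

The optimum maximizes sensitivity + specificity (the Youden-style sum).  When
several grid thresholds attain the optimum they are averaged; when the optimum
is perfect (sensitivity = specificity = 1) the width of the optimal-threshold
set — max minus min — is reported as the *gap*, a margin of separation.
Reported sensitivity and specificity are the confusion re-evaluated at the
averaged threshold.

Ions are ranked by the sum, then gap, then Fisher's discriminant ratio
(mean difference squared over summed class variances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peak_table import CohortManifest, Comparison, IonID, PeakTable

__all__ = [
    "POSITIVE_HIGH",
    "POSITIVE_LOW",
    "ThresholdSearchResult",
    "confusion_stats",
    "threshold_search",
    "fisher_discriminant_ratio",
    "rank_single_ions",
]

POSITIVE_HIGH = "positive_high"
POSITIVE_LOW = "positive_low"

# Refuse to materialize absurd grids (e.g. raw-scale areas passed by mistake).
_MAX_GRID = 5_000_000


def floor_grid_index(v: float, inc: float) -> int:
    """Largest integer k with k*inc <= v, under float arithmetic."""
    k = int(math.floor(v / inc))
    while k * inc > v:
        k -= 1
    while (k + 1) * inc <= v:
        k += 1
    return k


def ceil_grid_index(v: float, inc: float) -> int:
    """Smallest integer k with k*inc >= v, under float arithmetic."""
    k = int(math.ceil(v / inc))
    while k * inc < v:
        k += 1
    while (k - 1) * inc >= v:
        k -= 1
    return k


@dataclass
class ThresholdSearchResult:
    """Outcome of the grid threshold search for one score vector."""

    orientation: str
    best_threshold: float
    tie_set_min: float
    tie_set_max: float
    gap: float | None
    sensitivity: float
    specificity: float
    fisher_ratio: float | None = None
    ion: IonID | None = None

    @property
    def youden_sum(self) -> float:
        return self.sensitivity + self.specificity

    @property
    def perfect(self) -> bool:
        return self.gap is not None


def confusion_stats(
    values: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    orientation: str = POSITIVE_HIGH,
) -> tuple[float, float, int, int]:
    """Sensitivity, specificity and error counts of a threshold classifier.

    Under ``positive_high`` a sample is called positive iff score > threshold
    (strictly); under ``positive_low`` iff score < threshold.  Returns
    ``(sensitivity, specificity, n_false_negative, n_false_positive)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    if orientation == POSITIVE_HIGH:
        called = values > threshold
    elif orientation == POSITIVE_LOW:
        called = values < threshold
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    fn = n_pos - tp
    tn = n_neg - fp
    return tp / n_pos, tn / n_neg, fn, fp


def _grid_search_one_orientation(
    pos_sorted: np.ndarray,
    neg_sorted: np.ndarray,
    thresholds: np.ndarray,
    orientation: str,
) -> np.ndarray:
    """Integer-valued n_pos*n_neg*(sensitivity+specificity) for each grid point."""
    n_pos = pos_sorted.size
    n_neg = neg_sorted.size
    if orientation == POSITIVE_HIGH:
        pos_le = np.searchsorted(pos_sorted, thresholds, side="right")
        neg_le = np.searchsorted(neg_sorted, thresholds, side="right")
        return (n_pos - pos_le) * n_neg + neg_le * n_pos
    pos_lt = np.searchsorted(pos_sorted, thresholds, side="left")
    neg_lt = np.searchsorted(neg_sorted, thresholds, side="left")
    return pos_lt * n_neg + (n_neg - neg_lt) * n_pos


def threshold_search(
    values: np.ndarray,
    labels: np.ndarray,
    increment: float = 0.01,
) -> ThresholdSearchResult:
    """Exhaustive grid threshold search maximizing sensitivity + specificity.

    Every grid threshold ``k * increment`` between the pooled minimum and
    maximum (bounds rounded outward to the grid) is evaluated under both
    orientations.  The returned threshold is the arithmetic mean of all grid
    thresholds attaining the optimum; ties between orientations resolve to
    ``positive_high``.  The gap (tie-set width) is populated iff the optimum
    is perfect discrimination.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be represented")
    k_lo = floor_grid_index(float(min(pos[0], neg[0])), increment)
    k_hi = ceil_grid_index(float(max(pos[-1], neg[-1])), increment)
    if k_hi - k_lo + 1 > _MAX_GRID:
        raise ValueError(
            f"grid of {k_hi - k_lo + 1} thresholds at increment {increment}; "
            "scores look unscaled (is the table log10?)"
        )
    ks = np.arange(k_lo, k_hi + 1, dtype=np.int64)
    thresholds = ks * increment
    scores = {
        o: _grid_search_one_orientation(pos, neg, thresholds, o)
        for o in (POSITIVE_HIGH, POSITIVE_LOW)
    }
    best = {o: int(s.max()) for o, s in scores.items()}
    orientation = (
        POSITIVE_HIGH if best[POSITIVE_HIGH] >= best[POSITIVE_LOW] else POSITIVE_LOW
    )
    opt = ks[scores[orientation] == best[orientation]]
    # Integer-exact mean of the optimal grid indices, then back to score units.
    best_threshold = (int(opt.sum()) / opt.size) * increment
    tie_min = float(opt[0] * increment)
    tie_max = float(opt[-1] * increment)
    sens, spec, _, _ = confusion_stats(values, labels, best_threshold, orientation)
    perfect = best[orientation] == 2 * pos.size * neg.size
    gap = tie_max - tie_min if perfect else None
    fisher = None
    if pos.size >= 2 and neg.size >= 2:
        fisher = fisher_discriminant_ratio(pos, neg)
    return ThresholdSearchResult(
        orientation=orientation,
        best_threshold=best_threshold,
        tie_set_min=tie_min,
        tie_set_max=tie_max,
        gap=gap,
        sensitivity=sens,
        specificity=spec,
        fisher_ratio=fisher,
    )


def fisher_discriminant_ratio(pos_values, neg_values) -> float:
    """(mean_pos - mean_neg)^2 / (var_pos + var_neg), sample (n-1) variances.

    Returns 0.0 when the class means are equal.  Zero combined variance with
    distinct means yields ``inf`` (degenerate, perfectly separated point
    masses).
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two values per class")
    diff = pos.mean() - neg.mean()
    if diff == 0.0:
        return 0.0
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    if denom == 0.0:
        return math.inf
    return float(diff * diff / denom)


def rank_single_ions(
    table: PeakTable,
    manifest: CohortManifest,
    comparison: Comparison,
    increment: float = 0.01,
    perfect_only: bool = False,
) -> list[ThresholdSearchResult]:
    """Threshold-search every ion of a log10 table and rank the results.

    Sort order: sensitivity + specificity descending, then gap descending
    (ions without a gap last), then Fisher ratio descending, then (m/z, RT)
    ascending — a total order, for reproducible output.  ``perfect_only``
    restricts the result to ions achieving perfect discrimination.
    """
    if table.scale != "log10":
        raise ValueError("single-ion screening runs on the log10 table")
    pos_idx, neg_idx = manifest.class_labels(table, comparison)
    cols = np.concatenate([pos_idx, neg_idx])
    labels = np.zeros(cols.size, dtype=bool)
    labels[: pos_idx.size] = True
    results: list[ThresholdSearchResult] = []
    for i, ion in enumerate(table.ions):
        res = threshold_search(table.areas[i, cols], labels, increment)
        res.ion = ion
        results.append(res)

    def sort_key(r: ThresholdSearchResult):
        gap = r.gap if r.gap is not None else -math.inf
        fisher = r.fisher_ratio if r.fisher_ratio is not None else -math.inf
        return (-(r.sensitivity + r.specificity), -gap, -fisher, r.ion.mz, r.ion.rt)

    results.sort(key=sort_key)
    if perfect_only:
        results = [r for r in results if r.perfect]
    return results
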