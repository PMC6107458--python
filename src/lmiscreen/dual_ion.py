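"""Dual-ion (pair) screening.

A pair score combines two ions into one per-sample discriminant:

* ``ratio_of_logs`` — log10(area_a) / log10(area_b);
* ``log_of_ratio``  — log10(area_a) - log10(area_b) = log10(area_a / area_b),
  the *difference* method.

Pairs are ordered: each unordered combination is examined twice, once with
each ion as the numerator (minuend).  Every ordered pair gets the same grid
threshold search as a single ion; pairs whose best threshold achieves both
sensitivity and specificity at or above the selection floor (default 0.90)
are reported.

The difference method is invariant under per-sample rescaling (total-area
normalization) on all-positive tables and antisymmetric under swapping the
two ions; the ratio method is neither, and is undefined for samples whose
denominator log-area is 0 (raw area 1, or 0 mapped to 1 by the zero rule).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import _sweep
from .peak_table import CohortManifest, Comparison, IonID, PeakTable
from .single_ion import POSITIVE_HIGH, POSITIVE_LOW

__all__ = [
    "RATIO_OF_LOGS",
    "LOG_OF_RATIO",
    "PairResult",
    "PairScreen",
    "UndefinedRatioError",
    "pair_scores",
    "enumerate_ordered_pairs",
    "screen_pairs",
]

logger = logging.getLogger(__name__)

RATIO_OF_LOGS = "ratio_of_logs"
LOG_OF_RATIO = "log_of_ratio"

_METHOD_ALIASES = {
    RATIO_OF_LOGS: RATIO_OF_LOGS,
    LOG_OF_RATIO: LOG_OF_RATIO,
    "ratio": RATIO_OF_LOGS,
    "difference": LOG_OF_RATIO,
}

_ORIENT_NAMES = {_sweep.ORIENT_HIGH: POSITIVE_HIGH, _sweep.ORIENT_LOW: POSITIVE_LOW}


class UndefinedRatioError(ValueError):
    """Raised when a ratio-of-logs score divides by a log-area of zero."""


@dataclass(frozen=True)
class PairResult:
    """One ordered pair passing the screen.

    ``numerator_or_minuend`` is the ion whose log-area enters the score
    positively; for the ratio method it is the numerator, for the difference
    method the minuend.
    """

    numerator_or_minuend: IonID
    denominator_or_subtrahend: IonID
    method: str
    threshold: float
    sensitivity: float
    specificity: float
    orientation: str

    @property
    def youden_sum(self) -> float:
        return self.sensitivity + self.specificity


@dataclass
class PairScreen:
    """Screen output: selected pairs plus bookkeeping counters."""

    pairs: list[PairResult]
    n_ions: int
    n_pairs_enumerated: int
    n_pairs_skipped: int
    method: str
    comparison: str = ""

    def __iter__(self) -> Iterator[PairResult]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def canonical_method(method: str) -> str:
    try:
        return _METHOD_ALIASES[method]
    except KeyError:
        raise ValueError(
            f"unknown pair-score method {method!r}; "
            f"expected one of {sorted(_METHOD_ALIASES)}"
        ) from None


def pair_scores(
    table: PeakTable,
    ion_a: IonID,
    ion_b: IonID,
    method: str,
) -> np.ndarray:
    """Per-sample pair scores for ordered pair (ion_a, ion_b) on a log10 table.

    Raises :class:`UndefinedRatioError` if the ratio method meets a sample
    whose denominator log-area is exactly 0.
    """
    if table.scale != "log10":
        raise ValueError("pair scores are defined on the log10 table")
    method = canonical_method(method)
    la = table.areas[table.ion_index(ion_a)]
    lb = table.areas[table.ion_index(ion_b)]
    if method == LOG_OF_RATIO:
        return la - lb
    zero = lb == 0.0
    if np.any(zero):
        bad = [table.samples[k] for k in np.flatnonzero(zero)[:5]]
        raise UndefinedRatioError(
            f"ratio_of_logs undefined for pair ({ion_a}, {ion_b}): denominator "
            f"log-area is 0 in sample(s) {bad}"
        )
    return la / lb


def enumerate_ordered_pairs(ions: Sequence[IonID]) -> Iterator[tuple[IonID, IonID]]:
    """Stream all N*(N-1) ordered pairs, lexicographic by (m/z, RT) of the
    first then the second ion.  Never materializes the pair list."""
    if len(ions) < 2:
        raise ValueError("need at least two ions to form pairs")
    return itertools.permutations(sorted(ions), 2)


def screen_pairs(
    table: PeakTable,
    manifest: CohortManifest,
    comparison: Comparison,
    method: str = LOG_OF_RATIO,
    min_sensitivity: float = 0.90,
    min_specificity: float = 0.90,
    increment: float = 0.01,
    zero_policy: str = "skip",
    chunk_slots: int = 262_144,
) -> PairScreen:
    """Exhaustive ordered-pair screen.

    Every ordered pair of ions is scored, threshold-searched (identical
    semantics to :func:`lmiscreen.single_ion.threshold_search`) and kept iff
    sensitivity >= ``min_sensitivity`` and specificity >= ``min_specificity``
    at the tie-averaged threshold.  Results are streamed in fixed-size chunks
    of at most ``chunk_slots`` pairs; only passing pairs are retained.

    ``zero_policy`` governs ratio scores with a zero denominator log-area:
    ``"skip"`` drops (and counts) the ordered pair, ``"drop_sample"`` drops
    the offending samples from that pair's score vector.
    """
    if table.scale != "log10":
        raise ValueError("pair screening runs on the log10 table")
    if increment <= 0:
        raise ValueError("increment must be positive")
    method = canonical_method(method)
    method_code = (
        _sweep.METHOD_RATIO if method == RATIO_OF_LOGS else _sweep.METHOD_DIFFERENCE
    )
    try:
        policy_code = {"skip": _sweep.POLICY_SKIP_PAIR,
                       "drop_sample": _sweep.POLICY_DROP_SAMPLE}[zero_policy]
    except KeyError:
        raise ValueError(f"unknown zero_policy {zero_policy!r}") from None

    pos_idx, neg_idx = manifest.class_labels(table, comparison)
    # Deterministic pair order: rows sorted lexicographically by (mz, rt).
    order = sorted(range(table.n_ions), key=lambda k: table.ions[k])
    ions_sorted = [table.ions[k] for k in order]
    log_areas = np.ascontiguousarray(table.areas[order])

    n = table.n_ions
    if n < 2:
        raise ValueError("need at least two ions to form pairs")
    rows_per_chunk = max(1, chunk_slots // n)
    selected: list[PairResult] = []
    n_skipped = 0
    n_evaluated = 0

    status = np.empty(rows_per_chunk * n, dtype=np.int8)
    orient = np.empty(rows_per_chunk * n, dtype=np.int8)
    thr = np.empty(rows_per_chunk * n, dtype=np.float64)
    sens = np.empty(rows_per_chunk * n, dtype=np.float64)
    spec = np.empty(rows_per_chunk * n, dtype=np.float64)

    for i0 in range(0, n, rows_per_chunk):
        i1 = min(i0 + rows_per_chunk, n)
        m = (i1 - i0) * n
        _sweep.screen_chunk(
            log_areas, pos_idx, neg_idx, i0, i1, method_code, policy_code,
            float(increment), status[:m], orient[:m], thr[:m], sens[:m], spec[:m],
        )
        ok = status[:m] == _sweep.STATUS_OK
        n_skipped += int(np.sum(status[:m] == _sweep.STATUS_SKIPPED))
        n_evaluated += int(np.sum(ok))
        passing = ok & (sens[:m] >= min_sensitivity) & (spec[:m] >= min_specificity)
        for slot in np.flatnonzero(passing):
            i = i0 + slot // n
            j = slot % n
            selected.append(
                PairResult(
                    numerator_or_minuend=ions_sorted[i],
                    denominator_or_subtrahend=ions_sorted[j],
                    method=method,
                    threshold=float(thr[slot]),
                    sensitivity=float(sens[slot]),
                    specificity=float(spec[slot]),
                    orientation=_ORIENT_NAMES[int(orient[slot])],
                )
            )
        logger.debug(
            "pair screen %s: rows %d-%d done, %d selected so far",
            comparison.name, i0, i1 - 1, len(selected),
        )

    selected.sort(
        key=lambda r: (
            -(r.sensitivity + r.specificity),
            r.numerator_or_minuend,
            r.denominator_or_subtrahend,
        )
    )
    logger.info(
        "pair screen %s (%s): %d ions, %d ordered pairs, %d skipped, %d selected",
        comparison.name, method, n, n * (n - 1), n_skipped, len(selected),
    )
    return PairScreen(
        pairs=selected,
        n_ions=n,
        n_pairs_enumerated=n * (n - 1),
        n_pairs_skipped=n_skipped,
        method=method,
        comparison=comparison.name,
    )
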