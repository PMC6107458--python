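"""Two-group comparisons with a normality-gated test choice.

For a selected ion, the two groups' log10 areas are each checked with the
Shapiro-Wilk test; if both groups look normal (p > alpha) the difference in
means is tested with Welch's independent-samples t test, otherwise with the
Mann-Whitney U test.  All tests are two-sided.  A zero-range group fails the
normality gate outright (the Shapiro-Wilk statistic is undefined there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .peak_table import CohortManifest, IonID, PeakTable

__all__ = ["GroupComparisonResult", "compare_groups"]

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"


@dataclass
class GroupComparisonResult:
    ion: IonID
    groups: tuple[str, str]
    normality_p: tuple[float | None, float | None]
    test_used: str
    statistic: float
    p_value: float


def _normality_p(values: np.ndarray) -> float | None:
    """Shapiro-Wilk p-value, or None when undefined (zero range)."""
    if np.ptp(values) == 0.0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def compare_groups(
    table: PeakTable,
    manifest: CohortManifest,
    ion: IonID,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparisonResult:
    """Compare one ion's log10 areas between two groups.

    Requires at least 3 samples per group (the Shapiro-Wilk minimum).  The t
    branch defaults to Welch's unequal-variance form; pass ``equal_var=True``
    for the pooled-variance t test.
    """
    if table.scale != "log10":
        raise ValueError("group comparisons run on the log10 table")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    row = table.areas[table.ion_index(ion)]
    cols_a = table.sample_indices(manifest.members([group_a]))
    cols_b = table.sample_indices(manifest.members([group_b]))
    a = row[cols_a]
    b = row[cols_b]
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"need >= 3 samples per group (got {a.size} {group_a!r}, "
            f"{b.size} {group_b!r})"
        )
    p_a = _normality_p(a)
    p_b = _normality_p(b)
    normal = (p_a is not None and p_a > alpha) and (p_b is not None and p_b > alpha)
    if normal:
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            raise ValueError("both groups have zero variance; t test degenerate")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = T_TEST
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = MANN_WHITNEY
    p_value = float(res.pvalue)
    if np.isnan(p_value) and np.ptp(np.concatenate([a, b])) == 0.0:
        # all observations identical: no evidence of any difference
        p_value = 1.0
    return GroupComparisonResult(
        ion=IonID(*ion),
        groups=(group_a, group_b),
        normality_p=(p_a, p_b),
        test_used=test,
        statistic=float(res.statistic),
        p_value=p_value,
    )
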