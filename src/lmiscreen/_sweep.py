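"""Jit-compiled sort-based sweep for pair screening.

The exhaustive dual-ion screen evaluates N*(N-1) ordered pairs; materializing
a threshold grid per pair is wasteful because sensitivity and specificity are
step functions that only change at data values.  The sweep walks the sorted
scores and aggregates, per run of grid thresholds between consecutive distinct
values, the same integer objective the grid evaluation computes —
n_pos*n_neg*(sensitivity+specificity) — so its result is *identical* to the
exhaustive grid search in :mod:`lmiscreen.single_ion` (proven by test).

Thresholds are the floats ``k * increment``; boundary indices are computed
with the same compare-and-adjust arithmetic as the pure-Python helpers so the
two routes agree bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ORIENT_HIGH = 0
ORIENT_LOW = 1

STATUS_OK = 0
STATUS_SKIPPED = 1
STATUS_SELF = 2

METHOD_RATIO = 0
METHOD_DIFFERENCE = 1

POLICY_SKIP_PAIR = 0
POLICY_DROP_SAMPLE = 1


@njit(cache=True)
def _floor_k(v, inc):
    k = int(math.floor(v / inc))
    while k * inc > v:
        k -= 1
    while (k + 1) * inc <= v:
        k += 1
    return k


@njit(cache=True)
def _ceil_k(v, inc):
    k = int(math.ceil(v / inc))
    while k * inc < v:
        k += 1
    while (k - 1) * inc >= v:
        k -= 1
    return k


@njit(cache=True)
def _sweep_high(pos, neg, inc):
    """Optimal grid thresholds under 'called positive iff score > t'.

    Returns (best_score, tie_count, tie_index_sum, tie_index_min,
    tie_index_max) where best_score = n_pos*n_neg*(sens+spec) as an integer
    and the tie statistics range over every grid index attaining it.
    """
    n_pos = pos.shape[0]
    n_neg = neg.shape[0]
    ps = np.sort(pos)
    ns = np.sort(neg)
    vmin = ps[0] if ps[0] < ns[0] else ns[0]
    vmax = ps[-1] if ps[-1] > ns[-1] else ns[-1]
    k_lo = _floor_k(vmin, inc)
    k_hi = _ceil_k(vmax, inc)

    best = np.int64(-1)
    cnt = np.int64(0)
    ksum = np.int64(0)
    kmin = np.int64(0)
    kmax = np.int64(0)

    ip = 0  # positives consumed (<= current value)
    iq = 0  # negatives consumed
    seg_lo = np.int64(k_lo)
    while True:
        has_next = ip < n_pos or iq < n_neg
        if has_next:
            if ip < n_pos and (iq >= n_neg or ps[ip] <= ns[iq]):
                v_next = ps[ip]
            else:
                v_next = ns[iq]
            seg_hi = np.int64(_ceil_k(v_next, inc) - 1)
        else:
            seg_hi = np.int64(k_hi)
        lo = seg_lo if seg_lo > k_lo else np.int64(k_lo)
        hi = seg_hi if seg_hi < k_hi else np.int64(k_hi)
        if lo <= hi:
            score = np.int64(n_pos - ip) * n_neg + np.int64(iq) * n_pos
            if score > best:
                best = score
                cnt = np.int64(0)
                ksum = np.int64(0)
                kmin = lo
                kmax = hi
            if score == best:
                m = hi - lo + 1
                cnt += m
                ksum += (lo + hi) * m // 2
                if lo < kmin:
                    kmin = lo
                if hi > kmax:
                    kmax = hi
        if not has_next:
            break
        while ip < n_pos and ps[ip] == v_next:
            ip += 1
        while iq < n_neg and ns[iq] == v_next:
            iq += 1
        seg_lo = np.int64(_ceil_k(v_next, inc))
    return best, cnt, ksum, kmin, kmax


@njit(cache=True)
def _search_both_orientations(pos, neg, inc):
    """Full threshold search: both orientations, tie-averaged threshold,
    confusion re-evaluated at that threshold.

    Returns (orientation, threshold, sensitivity, specificity, best_score).
    """
    n_pos = pos.shape[0]
    n_neg = neg.shape[0]
    bh, ch, sh, _, _ = _sweep_high(pos, neg, inc)
    bl, cl, sl, _, _ = _sweep_high(-pos, -neg, inc)
    if bh >= bl:
        orient = ORIENT_HIGH
        thr = (sh / ch) * inc
        best = bh
    else:
        orient = ORIENT_LOW
        thr = -((sl / cl) * inc)
        best = bl
    tp = 0
    tn = 0
    if orient == ORIENT_HIGH:
        for k in range(n_pos):
            if pos[k] > thr:
                tp += 1
        for k in range(n_neg):
            if not (neg[k] > thr):
                tn += 1
    else:
        for k in range(n_pos):
            if pos[k] < thr:
                tp += 1
        for k in range(n_neg):
            if not (neg[k] < thr):
                tn += 1
    return orient, thr, tp / n_pos, tn / n_neg, best


@njit(cache=True)
def screen_chunk(
    log_areas,
    pos_cols,
    neg_cols,
    i0,
    i1,
    method,
    zero_policy,
    inc,
    out_status,
    out_orient,
    out_thr,
    out_sens,
    out_spec,
):
    """Screen every ordered pair (i, j), i in [i0, i1), j != i.

    Row i is the numerator (or minuend), row j the denominator (or
    subtrahend).  Output slot for (i, j) is ``(i - i0) * n_ions + j``.
    """
    n_ions = log_areas.shape[0]
    n_pos = pos_cols.shape[0]
    n_neg = neg_cols.shape[0]
    pos = np.empty(n_pos, dtype=np.float64)
    neg = np.empty(n_neg, dtype=np.float64)
    for i in range(i0, i1):
        for j in range(n_ions):
            slot = (i - i0) * n_ions + j
            if j == i:
                out_status[slot] = STATUS_SELF
                continue
            ok = True
            np_eff = 0
            nn_eff = 0
            if method == METHOD_RATIO:
                for s in range(n_pos):
                    lb = log_areas[j, pos_cols[s]]
                    if lb == 0.0:
                        if zero_policy == POLICY_SKIP_PAIR:
                            ok = False
                            break
                    else:
                        pos[np_eff] = log_areas[i, pos_cols[s]] / lb
                        np_eff += 1
                if ok:
                    for s in range(n_neg):
                        lb = log_areas[j, neg_cols[s]]
                        if lb == 0.0:
                            if zero_policy == POLICY_SKIP_PAIR:
                                ok = False
                                break
                        else:
                            neg[nn_eff] = log_areas[i, neg_cols[s]] / lb
                            nn_eff += 1
            else:
                for s in range(n_pos):
                    pos[s] = log_areas[i, pos_cols[s]] - log_areas[j, pos_cols[s]]
                for s in range(n_neg):
                    neg[s] = log_areas[i, neg_cols[s]] - log_areas[j, neg_cols[s]]
                np_eff = n_pos
                nn_eff = n_neg
            if (not ok) or np_eff == 0 or nn_eff == 0:
                out_status[slot] = STATUS_SKIPPED
                continue
            orient, thr, sens, spec, _ = _search_both_orientations(
                pos[:np_eff], neg[:nn_eff], inc
            )
            out_status[slot] = STATUS_OK
            out_orient[slot] = orient
            out_thr[slot] = thr
            out_sens[slot] = sens
            out_spec[slot] = spec
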