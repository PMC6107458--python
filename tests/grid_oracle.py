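"""Brute-force reference semantics for the grid threshold search.

Every grid threshold between the rounded-out data bounds is evaluated with
explicit Python loops, under both orientations; ties on the integer-valued
objective n_pos*n_neg*(sensitivity+specificity) are collected and averaged.
Deliberately naive: this is the definition the fast implementations must
match exactly.
"""

import math


def _floor_k(v, inc):
    k = int(math.floor(v / inc))
    while k * inc > v:
        k -= 1
    while (k + 1) * inc <= v:
        k += 1
    return k


def _ceil_k(v, inc):
    k = int(math.ceil(v / inc))
    while k * inc < v:
        k += 1
    while (k - 1) * inc >= v:
        k -= 1
    return k


def _confusion(values, labels, t, high):
    tp = tn = n_pos = n_neg = 0
    for v, lab in zip(values, labels):
        called = v > t if high else v < t
        if lab:
            n_pos += 1
            tp += called
        else:
            n_neg += 1
            tn += not called
    return tp, tn, n_pos, n_neg


def brute_threshold_search(values, labels, inc=0.01):
    values = [float(v) for v in values]
    labels = [bool(l) for l in labels]
    k_lo = _floor_k(min(values), inc)
    k_hi = _ceil_k(max(values), inc)
    per_orientation = {}
    for name, high in (("positive_high", True), ("positive_low", False)):
        best = -1
        opt_ks = []
        for k in range(k_lo, k_hi + 1):
            tp, tn, n_pos, n_neg = _confusion(values, labels, k * inc, high)
            score = tp * n_neg + tn * n_pos
            if score > best:
                best = score
                opt_ks = [k]
            elif score == best:
                opt_ks.append(k)
        per_orientation[name] = (best, opt_ks)
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    bh, _ = per_orientation["positive_high"]
    bl, _ = per_orientation["positive_low"]
    orientation = "positive_high" if bh >= bl else "positive_low"
    best, opt_ks = per_orientation[orientation]
    threshold = (sum(opt_ks) / len(opt_ks)) * inc
    tp, tn, _, _ = _confusion(values, labels, threshold, orientation == "positive_high")
    return {
        "orientation": orientation,
        "best_threshold": threshold,
        "tie_set_min": opt_ks[0] * inc,
        "tie_set_max": opt_ks[-1] * inc,
        "perfect": best == 2 * n_pos * n_neg,
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
    }
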