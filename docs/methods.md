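# Methods

## Data model

A peak table is an ions × samples matrix of non-negative integrated peak
areas; each ion is identified by the (m/z, RT) pair — m/z alone is not unique
(isobaric features elute at different times). Sample identity is carried by
name, so manifest joins never depend on column order. Tables carry a scale
marker (`raw` or `log10`) in the file header so the two cannot be confused.

All screening statistics are computed on log10 areas. An area of exactly 0
(a peak absent in one sample) is set to 1 before the logarithm, mapping it to
0.0. The substitution is literal: only exact zeros are replaced. Synthetic
areas in (0, 1) — which integrated real areas essentially never are — pass
through log10 and become negative; this is deliberate, so the zero rule never
silently clips small values.

Total-area-sums normalization is defined on the raw scale (it equalizes
*total peak areas*, a raw-scale notion) and is applied before the log
transform. The common total is chosen as the **mean** of the original sample
totals — the target is arbitrary up to a global constant, and the mean
preserves the table's overall magnitude. A sample with zero total area is an
error, not a silent skip.

## Threshold search

For a per-sample score vector with binary class labels, every threshold
`t = k · increment` (default increment 0.01) between the pooled minimum and
maximum, bounds rounded outward to the grid, is evaluated under both
orientations — positive called iff score **strictly** above `t`, or strictly
below. The objective is sensitivity + specificity, maximized as the exact
integer `TP·n_neg + TN·n_pos`, which makes tie detection exact rather than
float-fuzzy.

Conventions where a choice had to be made:

* **Strict comparator.** With `>` (resp. `<`), the lower grid endpoint is
  usable and the perfect-separation threshold set is a half-open interval.
  Centralized so it could be flipped.
* **Tie averaging.** The reported threshold is the arithmetic mean of *all*
  optimal grid thresholds, computed as the integer mean of grid indices times
  the increment (exact, order-independent).
* **Reported performance** is the confusion re-evaluated at that averaged
  threshold. This makes every reported (threshold, sensitivity, specificity)
  triple self-consistent and independently checkable; when the optimal set is
  non-contiguous with unequal sensitivity/specificity splits, the re-evaluated
  sum can fall below the grid optimum — an inherent consequence of averaging
  tied thresholds.
* **Orientation ties** resolve to `positive_high`. Consequence: for an
  antisymmetric pair score whose two orientations tie, the two orderings of
  the pair both report `positive_high` and are not mirror images; otherwise
  reversing an ordered difference-method pair flips the orientation, negates
  the threshold and preserves the performance exactly (tested).
* **Separation gap.** Only when the optimum is perfect (J = 2) is the width
  of the optimal-threshold set reported; it is the margin between the classes
  measured on the grid.

Grid bounds are computed with compare-and-adjust float arithmetic (largest
`k` with `k·inc ≤ min`, smallest with `k·inc ≥ max`) so the vectorized
search, the jit sweep and the brute-force test oracle agree bit-for-bit.

The single-ion ranking orders by J, then gap (descending, absent last), then
Fisher's discriminant ratio, then (m/z, RT) — a total order, so output is
reproducible. Fisher's ratio uses the standard two-class form
(m₁ − m₂)²/(s₁² + s₂²) with n−1 variances; equal means give 0, zero combined
variance with distinct means gives `inf` (degenerate point masses).

## Pair screening

Both orderings of every combination are screened (N·(N−1) ordered pairs) —
the two score definitions:

* `ratio_of_logs`: log a / log b. Undefined when the denominator log-area is
  0 (raw area 1, or 0 mapped through the zero rule). Default policy skips and
  counts the ordered pair — dropping samples silently would change n
  invisibly; `drop_sample` is available as an explicit alternative.
* `log_of_ratio` (difference): log a − log b. Antisymmetric under ordering
  swap, and invariant under per-sample rescaling on positive tables, since
  log(s·a) − log(s·b) = log a − log b — so total-area normalization cannot
  change a difference-method screen (verified numerically to ~1e-15).

Selection keeps pairs with sensitivity ≥ 0.90 **and** specificity ≥ 0.90 —
reading "combined sensitivity/specificity > 90%" as both-at-least, the
reading consistent with all tabulated pair performances; both floors are
configurable.

The per-pair search is a sort-based sweep (numba-jitted): sensitivity and
specificity are step functions changing only at data values, so the sweep
aggregates runs of grid indices between consecutive distinct values instead
of materializing the grid. It computes the identical integer objective and
identical tie statistics, and the suite proves it equal to the naive
double-loop + exhaustive grid search on full small instances. Screening is
chunked (≤ ~256k pair slots in flight) so memory stays fixed at full scale;
at the emulated full scale (6724 ions) the ~45.2M ordered pairs are streamed,
never materialized.

## Group statistics

For a selected ion and two groups, each group's log areas pass a
Shapiro–Wilk test; if both give p > α (default 0.05) the means are compared
with Welch's t test (the safer default absent an equal-variance argument; a
flag restores the pooled form), otherwise with the Mann–Whitney U test. Tests
are two-sided. A zero-range group fails the gate outright — the Shapiro–Wilk
statistic is undefined for constant data — which routes degenerate inputs to
the rank test, where two identical constant groups give p = 1. Under a
normal null the gated procedure rejects at ≈ α (calibrated by simulation at
1000 runs); no multiple-testing correction is applied anywhere in the screen,
which is an exploratory ranking, not an inference procedure.

## Synthetic cohorts

The generator emulates what the analysis assumes about real serum peak
tables, not their chemistry:

* log10 areas normal around `baseline_mean` 4.0 with `null_sd` 0.5, putting
  areas mostly in the 10^2.5 to 10^5.5 range of integrated LC-MS features (raw areas
  log-normal, matching the heavy right skew of real intensities);
* default group sizes PC 51, BTC 39, control 100, CRC 100, OVC 30, plus
  high-risk groups PC_HRG 21 and BTC_HRG 25, and a default table of 6724
  null ions — the emulated study's scale;
* planted singles shift the positive-group mean by δ with residual sd σ;
* planted pairs share a per-sample latent log-scale u ~ N(0, τ²); each
  member ion has spread √(τ² + σ²), so with τ ≫ σ neither separates alone,
  while the difference score cancels u and separates at δ/(√2 σ) residual
  sds — the construction that makes pair-only markers exist;
* dropout zeroes each raw area independently with probability 0.05 by
  default (unstated in the emulated design, but zeros must occur for the
  0 → 1 rule to matter); dropout is intensity-independent — the simplest
  mechanism that exercises the rule. Intensity-dependent dropout, RT/mz
  structure, isotopes and adducts are deliberately not modelled, so passing
  tests demonstrate algorithmic correctness on the assumed statistical
  structure, not robustness to real acquisition artifacts.

Generation is a pure function of the seed. A registry of planted markers is
returned so recovery is scored against ground truth rather than re-derived.

The recovery benchmark (`recovery_benchmark_config`) fixes the conditions
used by the acceptance checks: 50 vs 50 samples, 500 null ions, three
planted singles at δ/σ = 10 (δ = 1, σ = 0.1) and one planted pair with
δ = 2, τ = 1, σ = 0.1 (pair separation ≈ 14 residual sds, member-ion shift
only 2 overall sds), no dropout. At these sizes a null ion separates
perfectly with probability ≈ 1/C(100, 50) — never in practice — so the
perfect-discrimination filter should return exactly the planted singles,
while pairs of a planted member with a null can reach the 0.90 floors
occasionally (overfit thresholds at n = 100); recovery is therefore scored
as membership of the planted markers, not exclusivity of the pair list.

## Pipeline

`run_pipeline` chains load → (optional) normalize → log transform → per
comparison: single-ion screen, pair screens, gated statistics for the top
(perfect, else best-ranked) ions against each group pair — and writes TSV
tables mirroring the screening-report layouts plus a JSON run manifest with
config echo, versions and bookkeeping (ions screened; ordered pairs
enumerated = N·(N−1); skipped; selected). Percentages are printed to two
decimals, half-up. Result tables contain no timestamps and rerun
byte-identical; a stage failure leaves an `INCOMPLETE` marker naming the
failed stage.

## Problem sizes used in the checks

Oracle equivalence uses 200 random instances of 4–40 samples (a third
snapped to the 0.01 grid to force exact ties); recovery uses 20 benchmark
cohorts (505 ions × 100 samples; ~254k ordered pairs each); the type-I
calibration uses 1000 null cohorts of 50 + 50; the enumeration check counts
the full 6724-ion ordered-pair stream. Together they run in about a minute
on one core.

## Known limitations

* The 0.01 grid is a convention, not an optimum: structure finer than the
  increment (distinct values closer than 0.01) may be unsplittable on the
  grid, so the grid optimum can be below the continuous-threshold optimum.
* Tie-averaged thresholds can sit below the grid optimum's performance on
  non-contiguous tie sets (see above).
* The screen reports apparent (resubstitution) performance; with ~45M
  candidate pairs the selection is heavily overfit by construction and must
  be validated on independent samples.
* `ratio_of_logs` is scale-sensitive (normalization changes it) and
  ill-conditioned near zero denominator logs; the difference method is the
  numerically robust of the two.
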