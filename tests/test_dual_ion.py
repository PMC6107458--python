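import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lmiscreen as lm
from conftest import random_log_table


def naive_screen(table, manifest, comparison, method, zero_policy="skip"):
    """Reference pair screen: explicit double loop + the single-ion search."""
    pos_idx, neg_idx = manifest.class_labels(table, comparison)
    results = {}
    skipped = 0
    for ion_a, ion_b in lm.enumerate_ordered_pairs(table.ions):
        try:
            scores = lm.pair_scores(table, ion_a, ion_b, method)
        except lm.UndefinedRatioError:
            if zero_policy == "skip":
                skipped += 1
                continue
            la = table.areas[table.ion_index(ion_a)]
            lb = table.areas[table.ion_index(ion_b)]
            keep = lb != 0.0
            scores = np.where(keep, la / np.where(keep, lb, 1.0), np.nan)
        cols = np.concatenate([pos_idx, neg_idx])
        labels = np.zeros(cols.size, bool)
        labels[: pos_idx.size] = True
        vals = scores[cols]
        ok = np.isfinite(vals)
        if (~ok).any():
            vals, labels = vals[ok], labels[ok]
            if labels.sum() == 0 or (~labels).sum() == 0:
                skipped += 1
                continue
        res = lm.threshold_search(vals, labels)
        results[(ion_a, ion_b)] = res
    return results, skipped


class TestPairScores:
    @pytest.fixture
    def log_table(self):
        raw = lm.PeakTable(
            [lm.IonID(100, 1), lm.IonID(200, 2)],
            ["a", "b"],
            np.array([[1000.0, 10.0], [100.0, 100.0]]),
        )
        return lm.log_transform(raw)

    def test_logarithm_identities(self, log_table):
        a, b = log_table.ions
        ratio = lm.pair_scores(log_table, a, b, "ratio_of_logs")
        diff = lm.pair_scores(log_table, a, b, "log_of_ratio")
        assert ratio[0] == pytest.approx(3 / 2)
        assert diff[0] == pytest.approx(1.0)
        assert diff[1] == pytest.approx(-1.0)

    def test_method_aliases(self, log_table):
        a, b = log_table.ions
        assert np.array_equal(
            lm.pair_scores(log_table, a, b, "difference"),
            lm.pair_scores(log_table, a, b, "log_of_ratio"),
        )

    @given(st.integers(0, 2**32 - 1))
    def test_difference_antisymmetric_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        table = random_log_table(rng, 4, 6)
        for a, b in itertools.permutations(table.ions, 2):
            fwd = lm.pair_scores(table, a, b, "log_of_ratio")
            rev = lm.pair_scores(table, b, a, "log_of_ratio")
            assert np.array_equal(fwd, -rev)

    def test_zero_denominator_log_flagged(self):
        raw = lm.PeakTable(
            [lm.IonID(100, 1), lm.IonID(200, 2)],
            ["a", "b"],
            np.array([[1000.0, 10.0], [1.0, 100.0]]),  # area 1 -> log 0
        )
        logt = lm.log_transform(raw)
        with pytest.raises(lm.UndefinedRatioError, match="denominator"):
            lm.pair_scores(logt, logt.ions[0], logt.ions[1], "ratio_of_logs")
        # the same pair is fine under the difference method
        lm.pair_scores(logt, logt.ions[0], logt.ions[1], "log_of_ratio")

    def test_requires_log_table(self, tiny_table):
        with pytest.raises(ValueError, match="log10"):
            lm.pair_scores(tiny_table, *tiny_table.ions, "difference")


class TestEnumerateOrderedPairs:
    def test_counts(self):
        ions3 = [lm.IonID(100 + k, k) for k in range(3)]
        assert len(list(lm.enumerate_ordered_pairs(ions3))) == 6
        a, b = lm.IonID(100, 1), lm.IonID(200, 2)
        assert list(lm.enumerate_ordered_pairs([b, a])) == [(a, b), (b, a)]

    def test_lexicographic_order(self):
        ions = [lm.IonID(200, 1), lm.IonID(100, 2), lm.IonID(100, 1)]
        first = next(iter(lm.enumerate_ordered_pairs(ions)))
        assert first == (lm.IonID(100, 1), lm.IonID(100, 2))

    def test_too_few_ions(self):
        with pytest.raises(ValueError, match="two ions"):
            lm.enumerate_ordered_pairs([lm.IonID(100, 1)])


class TestScreenPairs:
    @pytest.fixture
    def cohort(self):
        # dropout exercises log-0 denominators in the ratio screen
        config = lm.SyntheticConfig(
            group_sizes={"PC": 15, "control": 15},
            n_null_ions=8,
            planted_pairs=[lm.PlantedPair({"PC"}, delta=2.0, tau=1.0, sigma=0.1)],
            dropout_rate=0.1,
            seed=3,
        )
        table, manifest, truth = lm.generate_cohort(config)
        return lm.log_transform(table), manifest, truth

    @pytest.fixture
    def clean_cohort(self):
        # no dropout: the planted pair separates perfectly
        config = lm.SyntheticConfig(
            group_sizes={"PC": 15, "control": 15},
            n_null_ions=8,
            planted_pairs=[lm.PlantedPair({"PC"}, delta=2.0, tau=1.0, sigma=0.1)],
            dropout_rate=0.0,
            seed=3,
        )
        table, manifest, truth = lm.generate_cohort(config)
        return lm.log_transform(table), manifest, truth

    @pytest.mark.parametrize("method", ["log_of_ratio", "ratio_of_logs"])
    def test_matches_naive_double_loop(self, cohort, method):
        """The chunked jit sweep equals the naive loop + grid search exactly."""
        logt, manifest, _ = cohort
        comparison = lm.Comparison({"PC"}, {"control"})
        screen = lm.screen_pairs(
            logt, manifest, comparison, method,
            min_sensitivity=0.0, min_specificity=0.0,
        )
        ref, ref_skipped = naive_screen(logt, manifest, comparison, method)
        assert screen.n_pairs_skipped == ref_skipped
        assert len(screen) == len(ref)
        for pr in screen:
            res = ref[(pr.numerator_or_minuend, pr.denominator_or_subtrahend)]
            assert pr.orientation == res.orientation
            assert pr.threshold == res.best_threshold
            assert pr.sensitivity == res.sensitivity
            assert pr.specificity == res.specificity

    def test_drop_sample_policy_matches_naive(self, cohort):
        logt, manifest, _ = cohort
        comparison = lm.Comparison({"PC"}, {"control"})
        screen = lm.screen_pairs(
            logt, manifest, comparison, "ratio_of_logs",
            min_sensitivity=0.0, min_specificity=0.0, zero_policy="drop_sample",
        )
        ref, ref_skipped = naive_screen(
            logt, manifest, comparison, "ratio_of_logs", zero_policy="drop_sample"
        )
        assert screen.n_pairs_skipped == ref_skipped
        for pr in screen:
            res = ref[(pr.numerator_or_minuend, pr.denominator_or_subtrahend)]
            assert pr.threshold == res.best_threshold
            assert (pr.sensitivity, pr.specificity) == (
                res.sensitivity, res.specificity,
            )

    def test_reversed_pair_symmetry_for_difference(self, cohort):
        logt, manifest, _ = cohort
        screen = lm.screen_pairs(
            logt, manifest, lm.Comparison({"PC"}, {"control"}), "log_of_ratio",
            min_sensitivity=0.0, min_specificity=0.0,
        )
        by_pair = {
            (p.numerator_or_minuend, p.denominator_or_subtrahend): p for p in screen
        }
        flip = {"positive_high": "positive_low", "positive_low": "positive_high"}
        n_mirrored = 0
        for (a, b), p in by_pair.items():
            q = by_pair[(b, a)]
            if q.orientation == p.orientation:
                # both orientations tied on the optimum for this pair; each
                # ordering then resolves the tie to positive_high and the two
                # results are not mirrors of one another
                continue
            n_mirrored += 1
            assert q.orientation == flip[p.orientation]
            assert q.sensitivity == p.sensitivity
            assert q.specificity == p.specificity
            assert q.threshold == pytest.approx(-p.threshold, abs=1e-12)
        assert n_mirrored >= len(by_pair) // 2

    def test_selected_pairs_reproduce_reported_confusion(self, clean_cohort):
        logt, manifest, truth = clean_cohort
        comparison = lm.Comparison({"PC"}, {"control"})
        pos_idx, neg_idx = manifest.class_labels(logt, comparison)
        cols = np.concatenate([pos_idx, neg_idx])
        labels = np.zeros(cols.size, bool)
        labels[: pos_idx.size] = True
        screen = lm.screen_pairs(logt, manifest, comparison, "log_of_ratio")
        assert len(screen) > 0
        for pr in screen:
            scores = lm.pair_scores(
                logt, pr.numerator_or_minuend, pr.denominator_or_subtrahend,
                "log_of_ratio",
            )[cols]
            sens, spec, _, _ = lm.confusion_stats(
                scores, labels, pr.threshold, pr.orientation
            )
            assert (sens, spec) == (pr.sensitivity, pr.specificity)

    def test_planted_pair_selected_in_correct_orientation(self, clean_cohort):
        logt, manifest, truth = clean_cohort
        screen = lm.screen_pairs(
            logt, manifest, lm.Comparison({"PC"}, {"control"}), "log_of_ratio"
        )
        minuend, subtrahend = truth.pairs[0]
        match = [
            p for p in screen
            if p.numerator_or_minuend == minuend
            and p.denominator_or_subtrahend == subtrahend
        ]
        assert len(match) == 1
        assert match[0].orientation == "positive_high"

    def test_impossible_criterion_empty(self, cohort):
        logt, manifest, _ = cohort
        screen = lm.screen_pairs(
            logt, manifest, lm.Comparison({"PC"}, {"control"}), "log_of_ratio",
            min_sensitivity=1.01, min_specificity=1.01,
        )
        assert len(screen) == 0
        assert screen.n_pairs_enumerated == logt.n_ions * (logt.n_ions - 1)

    def test_difference_screen_invariant_under_normalization(self):
        rng = np.random.default_rng(9)
        ions = [lm.IonID(100 + k, 1 + k) for k in range(6)]
        samples = [f"s{j}" for j in range(20)]
        raw = lm.PeakTable(
            ions, samples, rng.uniform(10.0, 1e5, size=(6, 20)), scale="raw"
        )
        logged = lm.log_transform(raw)
        logged_norm = lm.log_transform(lm.normalize_total_area(raw))
        for a, b in itertools.permutations(ions, 2):
            s0 = lm.pair_scores(logged, a, b, "log_of_ratio")
            s1 = lm.pair_scores(logged_norm, a, b, "log_of_ratio")
            np.testing.assert_allclose(s1, s0, atol=1e-9)

    def test_requires_log_scale(self, cohort, tiny_table, two_group_manifest):
        with pytest.raises(ValueError, match="log10"):
            lm.screen_pairs(
                tiny_table, two_group_manifest, lm.Comparison({"PC"}, {"control"})
            )
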