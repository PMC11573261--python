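"""Path-probability p-value: regions, combinatorics, FDR, calibration, scan."""

import math
from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from giftmap.encoding import MicrostateVector, genetic_path
from giftmap.significance import (
    bh_adjust,
    bh_adjust_log,
    calibrate_thresholds,
    p_gift_raw,
    partition_regions,
    scan_microstates,
)


def _path_from_values(vals):
    ms = MicrostateVector("s", np.array(vals, np.int8), np.zeros(len(vals), bool))
    return genetic_path(ms, np.arange(len(vals))), ms


class TestPartitionRegions:
    def test_max_then_min(self):
        path, _ = _path_from_values([1, 1, -1, -1])  # delta = [1, 2, 1, 0]
        assert partition_regions(path) == (2, 4, (2, 2, 0))

    def test_min_then_max_sorted_left_to_right(self):
        path, _ = _path_from_values([-1, -1, 1, 1])  # delta = [-1, -2, -1, 0]
        assert partition_regions(path) == (2, 4, (2, 2, 0))

    def test_flat_path_degenerates_to_first_position(self):
        path, _ = _path_from_values([0, 0, 0, 0, 0])
        i1, i2, widths = partition_regions(path)
        assert (i1, i2) == (1, 5)
        assert widths == (1, 4, 0)

    def test_widths_always_sum_to_n(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.choice([-1, 0, 1], size=rng.integers(1, 40))
            path, _ = _path_from_values(vals)
            _, _, widths = partition_regions(path)
            assert sum(widths) == len(vals)


def exhaustive_region_probability(vals, i1, i2):
    """Oracle: exact fraction of arrangements of the same multiset whose
    region composition (at the fixed boundaries i1, i2) matches that of
    ``vals``, by explicit enumeration."""
    vals = tuple(vals)

    def signature(arr):
        return tuple(
            (seg.count(1), seg.count(0), seg.count(-1))
            for seg in (arr[:i1], arr[i1:i2], arr[i2:])
        )
    target = signature(vals)
    arrangements = sorted(set(permutations(vals)))
    hits = sum(signature(a) == target for a in arrangements)
    return Fraction(hits, len(arrangements))


class TestPGiftRaw:
    def test_hand_case_one_sixth(self):
        # [+1, +1, -1, -1]: regions (2, 2, 0), each region single-typed;
        # exactly 1 of the 6 arrangements shares this composition.
        path, ms = _path_from_values([1, 1, -1, -1])
        res = p_gift_raw(path, ms)
        assert res.p_raw == pytest.approx(1 / 6, abs=1e-12)
        assert exhaustive_region_probability([1, 1, -1, -1], 2, 4) == Fraction(1, 6)

    @pytest.mark.parametrize("vals", [[1, 1, 1], [0, 0], [-1]])
    def test_single_microstate_type_gives_p_one(self, vals):
        path, ms = _path_from_values(vals)
        assert p_gift_raw(path, ms).p_raw == 1.0

    def test_region_counts_partition_the_totals(self):
        rng = np.random.default_rng(11)
        vals = rng.choice([-1, 0, 1], size=50)
        path, ms = _path_from_values(vals)
        res = p_gift_raw(path, ms)
        assert res.region_counts.sum(axis=1).tolist() == list(ms.counts)
        assert sum(res.region_widths) == 50
        assert 0 < res.p_raw <= 1

    def test_matches_enumeration_oracle_on_random_small_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            vals = rng.choice([-1, 0, 1], size=rng.integers(2, 9))
            path, ms = _path_from_values(vals)
            res = p_gift_raw(path, ms)
            oracle = exhaustive_region_probability(vals, res.i_ext1, res.i_ext2)
            assert res.p_raw == pytest.approx(float(oracle), rel=1e-12)

    def test_log10_npath0_exact_for_small_n_and_finite_for_huge_n(self):
        counts = (6, 7, 7)
        vals = [1] * 6 + [0] * 7 + [-1] * 7
        path, ms = _path_from_values(vals)
        res = p_gift_raw(path, ms)
        exact = math.factorial(20) // (
            math.factorial(6) * math.factorial(7) * math.factorial(7)
        )
        assert res.log10_npath0 == pytest.approx(math.log10(exact), rel=1e-12)
        big = MicrostateVector(
            "big",
            np.tile(np.array([1, 0, -1], np.int8), 3400)[:10000],
            np.zeros(10000, bool),
        )
        big_res = p_gift_raw(genetic_path(big, np.arange(10000)), big)
        assert np.isfinite(big_res.log10_npath0)
        assert big_res.log10_npath0 > 4000  # ~N log10(3) for balanced counts


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_test_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_monotone_and_never_decreases(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= -1e-15)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_rejects_values_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_log_space_variant_agrees_with_statsmodels(self, p):
        p = np.asarray(p)
        expected = multipletests(p, method="fdr_bh")[1]
        got = np.exp(bh_adjust_log(np.log(p)))
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_log_space_variant_survives_extreme_underflow(self):
        logs = np.array([-2000.0, -1500.0, -3.0])
        adj = bh_adjust_log(logs)
        assert np.all(adj <= 0)
        assert adj[0] == pytest.approx(-2000.0 + np.log(3), abs=1e-9)


class TestCalibration:
    def test_alpha_one_returns_pooled_minimum(self):
        cal = calibrate_thresholds([(5, 5, 5)], k=200, alphas=(1.0,), seed=0)
        # reproduce the pooled sample to compare against its minimum
        cal2 = calibrate_thresholds([(5, 5, 5)], k=200, alphas=(1.0, 0.5), seed=0)
        assert cal.thresholds[1.0] == cal2.thresholds[1.0]
        assert cal.thresholds[1.0] <= cal2.thresholds[0.5]

    def test_reproducible_and_seed_sensitive(self):
        comps = [(25, 125, 415)]
        a = calibrate_thresholds(comps, k=300, seed=5)
        b = calibrate_thresholds(comps, k=300, seed=5)
        c = calibrate_thresholds(comps, k=300, seed=6)
        assert a.thresholds == b.thresholds
        assert a.thresholds != c.thresholds

    def test_disjoint_seeds_agree_within_monte_carlo_tolerance(self):
        comps = [(25, 225, 315)]
        a = calibrate_thresholds(comps, k=1000, seed=1)
        b = calibrate_thresholds(comps, k=1000, seed=2)
        for alpha in (0.05, 0.01):
            assert a.thresholds[alpha] == pytest.approx(
                b.thresholds[alpha], rel=0.08
            )

    def test_per_composition_report_covers_all_levels(self):
        comps = [(5, 5, 5), (2, 10, 3)]
        cal = calibrate_thresholds(comps, k=100, seed=0, alphas=(0.05, 0.01))
        assert len(cal.per_composition) == 4
        assert set(cal.per_composition["alpha"]) == {0.05, 0.01}
        assert cal.stability(0.05) >= 0


class TestScan:
    def test_single_snp_adjusted_equals_raw(self):
        rng = np.random.default_rng(0)
        ms = MicrostateVector("x", rng.choice([-1, 0, 1], 30), np.zeros(30, bool))
        results, _ = scan_microstates([ms], rng.normal(size=30))
        assert results[0].p_adj == pytest.approx(results[0].p_raw, rel=1e-12)

    def test_missing_genotypes_drop_individual_for_that_snp_only(self):
        rng = np.random.default_rng(1)
        full = MicrostateVector("full", rng.choice([-1, 0, 1], 40), np.zeros(40, bool))
        miss_mask = np.zeros(40, bool)
        miss_mask[[3, 17]] = True
        holey = MicrostateVector("holey", full.values.copy(), miss_mask)
        results, paths = scan_microstates([full, holey], rng.normal(size=40))
        assert paths["full"].n == 40
        assert paths["holey"].n == 38
        assert paths["holey"].theta[-1] == holey.delta_n

    def test_flat_snp_scores_one_not_error(self):
        rng = np.random.default_rng(2)
        flat = MicrostateVector("flat", np.zeros(20, np.int8), np.zeros(20, bool))
        other = MicrostateVector("o", rng.choice([-1, 0, 1], 20), np.zeros(20, bool))
        results, _ = scan_microstates([flat, other], rng.normal(size=20))
        assert results[0].p_raw == 1.0

    def test_cohort_size_mismatch_rejected(self):
        ms = MicrostateVector("x", np.array([1, -1]), np.zeros(2, bool))
        with pytest.raises(ValueError, match="mismatch"):
            scan_microstates([ms], [0.1, 0.2, 0.3])

    def test_null_neglog10_distribution_roughly_frequency_independent(self):
        """Null -log10 p^GIFT medians vary little across compositions."""
        rng = np.random.default_rng(8)
        res = rng.normal(size=565)
        medians = []
        for counts in [(25, 125, 415), (25, 325, 215), (150, 250, 165)]:
            vals = np.repeat(np.array([1, 0, -1], np.int8), counts)
            snps = []
            for j in range(40):
                v = rng.permutation(vals)
                snps.append(MicrostateVector(f"s{j}", v, np.zeros(565, bool)))
            results, _ = scan_microstates(snps, res)
            medians.append(np.median([r.neglog10_p_raw for r in results]))
        assert (max(medians) - min(medians)) / np.mean(medians) < 0.35
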