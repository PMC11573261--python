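"""Fixed-effect residuals, genotype QC filters, LD pruning, Bonferroni."""

import numpy as np
import pandas as pd
import pytest

from giftmap.qc import (
    bonferroni_threshold,
    fixed_effect_residuals,
    ld_prune,
    ld_prune_count,
    qc_filters,
)


class TestFixedEffectResiduals:
    def test_intercept_only_centers_values(self):
        vals = pd.Series([1.0, 2.0, 6.0], index=list("abc"))
        res = fixed_effect_residuals(vals)
        np.testing.assert_allclose(res, vals - 3.0)

    def test_log_then_center(self):
        e = np.e
        vals = pd.Series([e, e**2, e**3])
        res = fixed_effect_residuals(vals, log_transform=True)
        np.testing.assert_allclose(res, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_one_factor_gives_within_group_centering(self):
        vals = pd.Series([1.0, 3.0, 10.0, 14.0])
        cov = pd.DataFrame({"farm": ["A", "A", "B", "B"]})
        res = fixed_effect_residuals(vals, cov)
        np.testing.assert_allclose(res, [-1.0, 1.0, -2.0, 2.0], atol=1e-10)

    def test_two_factor_additive_model_residuals_sum_to_zero(self, rng):
        n = 120
        cov = pd.DataFrame(
            {
                "farm": rng.choice(list("ABCDEFGHIJK"), n),
                "sex": rng.choice(["M", "F"], n),
            }
        )
        vals = pd.Series(rng.normal(50, 5, n))
        res = fixed_effect_residuals(vals, cov)
        assert abs(res.sum()) < 1e-8
        # residuals sum to zero within every fitted level
        for level in "ABCDEFGHIJK":
            assert abs(res[cov["farm"].to_numpy() == level].sum()) < 1e-8

    def test_invariant_to_covariate_relabeling(self, rng):
        n = 60
        farm = rng.choice(["x", "y", "z"], n)
        vals = pd.Series(rng.normal(size=n))
        res1 = fixed_effect_residuals(vals, pd.DataFrame({"farm": farm}))
        relabeled = pd.Series(farm).map({"x": "3", "y": "1", "z": "2"}).to_numpy()
        res2 = fixed_effect_residuals(vals, pd.DataFrame({"farm": relabeled}))
        np.testing.assert_allclose(res1, res2, atol=1e-10)

    def test_single_level_covariate_dropped_with_warning(self):
        vals = pd.Series([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="single level"):
            res = fixed_effect_residuals(vals, pd.DataFrame({"farm": ["A"] * 3}))
        np.testing.assert_allclose(res, vals - 2.0)

    def test_nonpositive_values_dropped_under_log(self):
        vals = pd.Series([1.0, -2.0, np.e])
        with pytest.warns(UserWarning, match="non-positive"):
            res = fixed_effect_residuals(vals, log_transform=True)
        assert len(res) == 2


def _geno_from_counts(n_plus, n_zero, n_minus, n_missing=0):
    col = np.concatenate(
        [
            np.ones(n_plus),
            np.zeros(n_zero),
            -np.ones(n_minus),
            np.full(n_missing, np.nan),
        ]
    )
    return col


class TestQcFilters:
    def test_exact_hwe_proportions_retained(self):
        # genotype counts 64/32/4 out of 100: allele freq 0.8, chi-square = 0
        frame = pd.DataFrame({"snp": _geno_from_counts(64, 32, 4)})
        kept, report = qc_filters(frame)
        assert list(kept.columns) == ["snp"]
        row = report.iloc[0]
        assert row["maf"] == pytest.approx(0.2)
        assert row["hwe_p"] == pytest.approx(1.0)

    def test_low_maf_removed(self):
        frame = pd.DataFrame(
            {
                "rare": _geno_from_counts(0, 2, 98),
                "ok": _geno_from_counts(30, 50, 20),
            }
        )
        kept, report = qc_filters(frame)
        assert "rare" not in kept.columns
        assert report.set_index("snp_id").loc["rare", "reason"] == "MAF"

    def test_excess_missingness_removed(self):
        frame = pd.DataFrame(
            {
                "holey": _geno_from_counts(30, 40, 15, n_missing=15),
                "ok": _geno_from_counts(32, 48, 20),
            }
        )
        kept, report = qc_filters(frame)
        assert "holey" not in kept.columns
        assert report.set_index("snp_id").loc["holey", "reason"] == "call rate"

    def test_hwe_violation_removed(self):
        # no heterozygotes at intermediate frequency: gross HWE violation
        frame = pd.DataFrame(
            {
                "hwe": _geno_from_counts(50, 0, 50),
                "ok": _geno_from_counts(25, 50, 25),
            }
        )
        kept, report = qc_filters(frame)
        assert "hwe" not in kept.columns
        assert report.set_index("snp_id").loc["hwe", "reason"] == "HWE"

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0], size=(200, 30)),
            columns=[f"s{j}" for j in range(30)],
        )
        once, _ = qc_filters(frame)
        twice, _ = qc_filters(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_removed_raises_with_advice(self):
        frame = pd.DataFrame({"rare": _geno_from_counts(0, 1, 99)})
        with pytest.raises(ValueError, match="relaxing"):
            qc_filters(frame)


class TestLdPrune:
    def test_perfectly_correlated_pair_collapses_to_one(self, rng):
        a = rng.choice([-1.0, 0.0, 1.0], 100)
        frame = pd.DataFrame({"a": a, "b": a, "c": -a})
        assert ld_prune_count(frame) == 1
        assert ld_prune(frame) == ["a"]

    def test_independent_snps_all_kept(self, rng):
        frame = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0], size=(3000, 20)),
            columns=[f"s{j}" for j in range(20)],
        )
        # expected r^2 ~ 1/n = 3e-4, far below the 0.1 threshold
        assert ld_prune_count(frame) == 20

    def test_single_snp(self, rng):
        frame = pd.DataFrame({"only": rng.choice([-1.0, 0.0, 1.0], 50)})
        assert ld_prune_count(frame) == 1

    def test_pruning_respects_chromosome_boundaries(self, rng):
        a = rng.choice([-1.0, 0.0, 1.0], 100)
        frame = pd.DataFrame({"a": a, "b": a})
        chroms = pd.Series({"a": "1", "b": "2"})
        assert ld_prune_count(frame, chromosomes=chroms) == 2

    def test_deterministic_and_never_grows(self, rng):
        frame = pd.DataFrame(
            rng.choice([-1.0, 0.0, 1.0], size=(80, 10)),
            columns=[f"s{j}" for j in range(10)],
        )
        frame["dup"] = frame["s0"]
        kept1 = ld_prune(frame)
        kept2 = ld_prune(frame)
        assert kept1 == kept2
        assert len(kept1) <= frame.shape[1]


@pytest.mark.parametrize(
    "n,alpha,expected",
    [
        (10433, 0.01, 6.0184),
        (10433, 0.05, 5.3194),
        (624, 0.05, 4.0962),
        (624, 0.01, 4.7952),
        (1, 1.0, 0.0),
    ],
)
def test_bonferroni_threshold(n, alpha, expected):
    assert bonferroni_threshold(n, alpha) == pytest.approx(expected, abs=5e-5)


def test_bonferroni_threshold_validates_inputs():
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 0.0)
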