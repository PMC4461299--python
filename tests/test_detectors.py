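"""Worked examples and reductions for the six detectors."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_expression
from degbench.datatypes import ConfigurationError, InputError
from degbench.detectors import (
    MethodParams,
    detect,
    detect_ba,
    detect_limma,
    detect_mw,
    detect_rp,
    detect_sam,
    detect_tt,
    fold_change,
    relative_difference,
)
from degbench.detectors.moderated_t import _trigamma_inverse, estimate_prior
from scipy import special


class TestMethodParams:
    def test_table_defaults(self):
        assert MethodParams("TT").alpha == 0.01
        assert MethodParams("MW").alpha == 0.05
        assert MethodParams("BA").alpha == 0.02
        assert MethodParams("RP").alpha == 0.01
        assert MethodParams("LIMMA").alpha == 0.05
        sam = MethodParams("SAM")
        assert sam.fold_change_threshold == 2.0
        assert sam.n_permutations == 200
        assert MethodParams("RP").n_permutations == 100

    @pytest.mark.parametrize(
        "bad",
        [dict(alpha=0.0), dict(alpha=1.0), dict(fold_change_threshold=0.5),
         dict(n_permutations=3), dict(fc_scale="log10")],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            MethodParams("TT", **bad)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            MethodParams("ANOVA")


class TestFoldChange:
    def test_identity_and_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(3, 5))
        expr = make_expression(base, np.vstack([base[0], base[1] + 5, base[2]]))
        fc = fold_change(expr)
        assert fc.iloc[0] == pytest.approx(0.0)
        assert fc.iloc[1] == pytest.approx(5.0)

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(1)
        ctrl, treat = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        fc = fold_change(make_expression(ctrl, treat))
        fc_neg = fold_change(make_expression(-ctrl, -treat))
        np.testing.assert_allclose(fc_neg.to_numpy(), -fc.to_numpy())

    def test_empty_group_is_an_input_error(self):
        with pytest.raises(InputError):
            fold_change(make_expression(np.zeros((3, 2)), np.zeros((3, 0))))


class TestTT:
    def test_constant_identical_groups_not_detected(self):
        expr = make_expression(np.full((5, 4), 3.0), np.full((5, 4), 3.0))
        res = detect_tt(expr, MethodParams("TT"))
        assert not res.table["detected"].any()
        assert (res.table["p_value"] == 1.0).all()

    def test_identical_samples_give_t0_p1(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        res = detect_tt(make_expression(vals, vals), MethodParams("TT"))
        assert res.table["statistic"].iloc[0] == pytest.approx(0.0)
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(2)
        ctrl, treat = rng.normal(size=(20, 6)), rng.normal(size=(20, 6))
        res = detect_tt(make_expression(ctrl, treat), MethodParams("TT"))
        t, p = stats.ttest_ind(treat, ctrl, axis=1, equal_var=False)
        np.testing.assert_allclose(res.table["statistic"], t)
        np.testing.assert_allclose(res.table["p_value"], p)

    def test_pooled_flag(self):
        rng = np.random.default_rng(3)
        ctrl, treat = rng.normal(size=(5, 4)), rng.normal(size=(5, 7))
        res = detect_tt(make_expression(ctrl, treat),
                        MethodParams("TT", welch=False))
        t, _ = stats.ttest_ind(treat, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["statistic"], t)


class TestMW:
    def test_complete_separation_exact_p(self):
        """Two-sided exact p for 10 vs 10 fully separated = 2 / C(20,10)."""
        from math import comb

        ctrl = np.arange(10.0)[None, :]
        treat = np.arange(100.0, 110.0)[None, :]
        # groups of 10 exceed the exact-path cutoff; check via scipy exact
        p_exact = stats.mannwhitneyu(
            treat[0], ctrl[0], alternative="two-sided", method="exact"
        ).pvalue
        assert p_exact == pytest.approx(2 / comb(20, 10))
        res = detect_mw(make_expression(ctrl, treat), MethodParams("MW"))
        assert res.table["detected"].iloc[0]
        # at 10 per group the detector is on its normal-approximation path,
        # which agrees with the enumerated tail to the approximation's order
        assert res.table["p_value"].iloc[0] < 1e-3

    def test_identical_groups_not_detected(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0]])
        res = detect_mw(make_expression(vals, vals), MethodParams("MW"))
        assert not res.table["detected"].iloc[0]

    def test_all_tied_gene_gets_p1(self):
        expr = make_expression(np.full((2, 5), 7.0), np.full((2, 5), 7.0))
        res = detect_mw(expr, MethodParams("MW"))
        assert (res.table["p_value"] == 1.0).all()


class TestBA:
    def test_zero_spread_detects_nothing(self):
        expr = make_expression(np.zeros((5, 3)), np.ones((5, 3)))
        res = detect_ba(expr, MethodParams("BA"))  # every d_g = 1
        assert not res.table["detected"].any()

    def test_single_outlier_gene_flagged(self):
        """One gene shifted +5 against noise sd 0.1: z ~ 50, only it flagged."""
        rng = np.random.default_rng(5)
        g = 2000
        ctrl = rng.normal(0, 0.1, size=(g, 4))
        treat = rng.normal(0, 0.1, size=(g, 4))
        treat[0] += 5.0
        res = detect_ba(make_expression(ctrl, treat), MethodParams("BA"))
        assert res.table["detected"].iloc[0]
        assert res.table["direction"].iloc[0] == "up"
        assert res.table["detected"].sum() <= 1 + int(0.03 * g)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        ctrl, treat = rng.normal(size=(50, 4)), rng.normal(size=(50, 4))
        r1 = detect_ba(make_expression(ctrl, treat), MethodParams("BA"))
        r2 = detect_ba(make_expression(ctrl + 7, treat + 7), MethodParams("BA"))
        assert (r1.table["detected"] == r2.table["detected"]).all()

    def test_needs_three_genes(self):
        with pytest.raises(InputError):
            detect_ba(make_expression(np.zeros((2, 3)), np.ones((2, 3))),
                      MethodParams("BA"))


class TestSAM:
    def test_s0_zero_reduces_to_pooled_t(self):
        rng = np.random.default_rng(7)
        ctrl, treat = rng.normal(size=(40, 5)), rng.normal(size=(40, 5))
        d, _ = relative_difference(treat, ctrl, s0=0.0)
        t, _ = stats.ttest_ind(treat, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(d, t)

    def test_large_shift_detected_on_preset_background(self):
        """A +5-sigma gene among nulls passes both the q and fc filters."""
        rng = np.random.default_rng(8)
        g = 400
        ctrl = rng.normal(10, 1.3, size=(g, 10))
        treat = rng.normal(10, 1.3, size=(g, 10))
        treat[0] += 5 * 1.3
        res = detect_sam(make_expression(ctrl, treat),
                         MethodParams("SAM", seed=8))
        assert res.table["detected"].iloc[0]
        assert res.table["direction"].iloc[0] == "up"

    def test_small_sample_enumerates_all_label_assignments(self):
        rng = np.random.default_rng(9)
        ctrl, treat = rng.normal(size=(30, 2)), rng.normal(size=(30, 2))
        res = detect_sam(make_expression(ctrl, treat),
                         MethodParams("SAM", n_permutations=50))
        # C(4,2)=6 distinct assignments; p-values respect the pooled floor
        assert res.table["p_value"].min() >= 1 / (30 * 6 + 1)

    def test_fold_change_filter_blocks_sub_threshold_shifts(self):
        """Tiny but consistent shifts fail |fc| >= 1 even if significant."""
        rng = np.random.default_rng(10)
        g = 300
        ctrl = rng.normal(10, 0.05, size=(g, 10))
        treat = rng.normal(10, 0.05, size=(g, 10))
        treat[0] += 0.5  # 10 sigma but below the log2 threshold of 1
        res = detect_sam(make_expression(ctrl, treat),
                         MethodParams("SAM", seed=1))
        assert not res.table["detected"].iloc[0]


class TestRP:
    def test_always_top_gene_has_rank_product_one(self):
        rng = np.random.default_rng(11)
        ctrl = rng.normal(0, 0.1, size=(20, 3))
        treat = rng.normal(0, 0.1, size=(20, 3))
        treat[0] += 100  # rank 1 in every pairwise comparison
        res = detect_rp(make_expression(ctrl, treat),
                        MethodParams("RP", seed=11))
        assert res.table["rp_up"].iloc[0] == pytest.approx(1.0)
        assert res.table["detected"].iloc[0]
        assert res.table["direction"].iloc[0] == "up"

    def test_null_probability_of_perfect_rank_product(self):
        """Under independent uniform ranks, P(RP = 1) = (1/G)^K."""
        rng = np.random.default_rng(12)
        g, k, n_draws = 5, 2, 20000
        hits = 0
        for _ in range(n_draws):
            ranks = np.stack([rng.permutation(g) + 1 for _ in range(k)])
            hits += (ranks[:, 0] == 1).all()
        p_hat = hits / n_draws
        p_true = (1 / g) ** k
        se = np.sqrt(p_true * (1 - p_true) / n_draws)
        assert abs(p_hat - p_true) < 4 * se

    def test_single_sample_per_group_allowed(self):
        ctrl = np.arange(10.0)[:, None]
        treat = ctrl + np.linspace(0, 5, 10)[:, None]
        res = detect_rp(make_expression(ctrl, treat),
                        MethodParams("RP", seed=1))
        assert len(res.table) == 10

    def test_zero_genes_is_an_input_error(self):
        with pytest.raises(InputError):
            detect_rp(make_expression(np.zeros((0, 2)), np.zeros((0, 2))),
                      MethodParams("RP"))


class TestLIMMA:
    def test_equal_variances_reduce_to_pooled_t(self):
        """With all gene variances equal the moderated t is the pooled t."""
        rng = np.random.default_rng(13)
        base = rng.normal(size=(60, 5))
        # force identical residual variance per gene by rescaling rows
        def normalize(x):
            centred = x - x.mean(axis=1, keepdims=True)
            rss = (centred**2).sum(axis=1, keepdims=True)
            return centred / np.sqrt(rss)

        ctrl = normalize(rng.normal(size=(60, 5)))
        treat = normalize(base) + rng.normal(size=(60, 1))
        res = detect_limma(make_expression(ctrl, treat), MethodParams("LIMMA"))
        t, _ = stats.ttest_ind(treat, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["statistic"], t, rtol=1e-6)

    def test_infinite_prior_df_pools_all_variances(self):
        rng = np.random.default_rng(14)
        ctrl, treat = rng.normal(size=(100, 4)), rng.normal(size=(100, 4))
        s2 = np.full(100, 2.0)
        d0, s0_sq = estimate_prior(s2, df=6)
        assert np.isinf(d0)
        assert s0_sq == pytest.approx(2.0)

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.01, 0.5, 3.0, 50.0):
            y = special.polygamma(1, x)
            assert _trigamma_inverse(y) == pytest.approx(x, rel=1e-5)

    def test_prior_estimate_recovers_simulated_hyperparameters(self):
        """Moment matching on a large chi-square ensemble finds (d0, s0^2)."""
        rng = np.random.default_rng(15)
        d0_true, s0_sq_true, df = 8.0, 1.5, 18
        # s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_df / df; sigma_g^2 from the prior
        sigma2 = d0_true * s0_sq_true / rng.chisquare(d0_true, size=20000)
        s2 = sigma2 * rng.chisquare(df, size=20000) / df
        d0_hat, s0_sq_hat = estimate_prior(s2, df)
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s0_sq_hat == pytest.approx(s0_sq_true, rel=0.05)


class TestCommonInterface:
    @pytest.mark.parametrize("method", ["SAM", "RP", "BA", "MW", "TT", "LIMMA"])
    def test_one_record_per_gene_and_detected_implies_significant(
        self, method, dataset1
    ):
        expr, _ = dataset1
        params = MethodParams(method, seed=3)
        res = detect(expr, params)
        assert len(res.table) == 2000
        assert list(res.table.index) == list(expr.gene_ids)
        det = res.table[res.table["detected"]]
        assert (det["direction"] != "none").all()
        has_p = res.table["p_value"].notna()
        if method == "SAM":
            assert (det["q_value"] <= params.alpha).all()
        elif has_p.all():
            assert (det["p_value"] < params.alpha).all()
        p = res.table.loc[has_p, "p_value"]
        assert ((p > 0) & (p <= 1)).all()

    @pytest.mark.parametrize("method", ["SAM", "RP"])
    def test_same_seed_reproduces_permutation_results(self, method, dataset1):
        expr, _ = dataset1
        r1 = detect(expr, MethodParams(method, seed=5))
        r2 = detect(expr, MethodParams(method, seed=5))
        assert r1.table.equals(r2.table)
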