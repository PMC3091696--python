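"""Linear fits, empirical-Bayes moderation, TREAT, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from paleoexpr.datatypes import GeneMatrix
from paleoexpr.diffexpr import (
    DEConfig,
    EBayesParams,
    TimecourseModel,
    adjust_bh,
    call_de,
    estimate_ebayes,
    fit_timecourse,
    moderated_tests,
    treat_tests,
)


def gene_matrix(values, timepoints, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    sheet = pd.DataFrame(
        {"experiment": "autogamy", "timepoint": timepoints,
         "replicate_group": timepoints, "hours": 0.0},
        index=samples,
    )
    return GeneMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                      sample_sheet=sheet)


class TestFitTimecourse:
    def test_two_level_means_and_contrast(self):
        gm = gene_matrix([[1, 3, 5, 7]], ["A", "A", "B", "B"])
        fit = fit_timecourse(gm)
        assert fit.coef.loc["g0", "A"] == 2
        assert fit.coef.loc["g0", "B"] == 6
        assert fit.df_residual == 2
        assert (fit.coef["A"] - fit.coef["B"]).iloc[0] == -4

    def test_identical_replicates_zero_variance(self):
        gm = gene_matrix([[5, 5, 9, 9]], ["A", "A", "B", "B"])
        assert fit_timecourse(gm).s2.iloc[0] == 0.0

    def test_equals_normal_equations_oracle(self, rng):
        """Cell-means fit equals the direct least-squares matrix solve."""
        levels = ["A"] * 3 + ["B"] * 2 + ["C"] * 4
        x = rng.normal(size=(20, 9))
        gm = gene_matrix(x, levels)
        fit = fit_timecourse(gm)
        design = np.zeros((9, 3))
        for j, lev in enumerate(levels):
            design[j, "ABC".index(lev)] = 1.0
        beta = np.linalg.solve(design.T @ design, design.T @ x.T).T
        resid = x - beta @ design.T
        s2 = (resid**2).sum(axis=1) / (9 - 3)
        assert np.allclose(fit.coef.to_numpy(), beta)
        assert np.allclose(fit.s2.to_numpy(), s2)

    def test_no_residual_df_rejected(self):
        gm = gene_matrix([[1, 2]], ["A", "B"])
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_timecourse(gm)

    def test_dev23_merged_for_autogamy(self):
        tps = ["VEG", "VEG", "DEV2", "DEV3"]
        gm = gene_matrix([[1, 2, 5, 7]], tps)
        fit = fit_timecourse(gm, DEConfig(merge_dev23=True))
        assert list(fit.coef.columns) == ["VEG", "DEV2-3"]
        assert fit.coef.loc["g0", "DEV2-3"] == 6


class TestEstimateEbayes:
    def _fit_with_variances(self, s2, dg=4):
        n = len(s2)
        coef = pd.DataFrame(np.zeros((n, 2)), columns=["A", "B"],
                            index=[f"g{i}" for i in range(n)])
        from paleoexpr.diffexpr import LinearFit

        return LinearFit(coef=coef, s2=pd.Series(s2, index=coef.index),
                         df_residual=dg, level_counts=pd.Series({"A": 3, "B": 3}),
                         contrasts=[("A", "B")])

    def test_equal_variances_give_infinite_prior_df(self):
        fit = self._fit_with_variances(np.full(50, 0.3))
        eb = estimate_ebayes(fit)
        assert np.isinf(eb.d0)
        assert np.allclose(eb.s2_post.to_numpy(), 0.3)

    def test_recovers_known_hyperparameters(self, rng):
        """5000 variances drawn from the scaled-F hierarchy with d0=4,
        s0^2=0.05 recover d0 within +/-1 and s0^2 within 20%."""
        d0, s02, dg, n = 4.0, 0.05, 10, 5000
        sigma2 = d0 * s02 / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(dg, size=n) / dg
        eb = estimate_ebayes(self._fit_with_variances(s2, dg=dg))
        assert abs(eb.d0 - d0) < 1.0
        assert abs(eb.s02 - s02) / s02 < 0.20

    def test_posterior_between_prior_and_observed(self, rng):
        s2 = rng.chisquare(5, size=200) / 5 * 0.1
        eb = estimate_ebayes(self._fit_with_variances(s2, dg=5))
        lo = np.minimum(s2, eb.s02)
        hi = np.maximum(s2, eb.s02)
        assert ((eb.s2_post.to_numpy() >= lo - 1e-12) & (eb.s2_post.to_numpy() <= hi + 1e-12)).all()

    def test_infinite_prior_df_limit_gives_s02(self):
        fit = self._fit_with_variances(np.array([0.1, 0.2, 0.3] * 10))
        eb = estimate_ebayes(fit)
        manual = EBayesParams(d0=np.inf, s02=eb.s02,
                              s2_post=pd.Series(np.full(30, eb.s02), index=fit.s2.index))
        if np.isinf(eb.d0):
            assert np.allclose(eb.s2_post, eb.s02)
        else:
            # large d0 shrinks most of the way to the prior
            assert np.abs(eb.s2_post - eb.s02).max() < np.abs(fit.s2 - eb.s02).max()
        assert manual.total_df(4) == np.inf

    def test_zero_variances_handled_by_offset(self):
        s2 = np.array([0.0, 0.0, 0.1, 0.2, 0.15, 0.12] * 5)
        eb = estimate_ebayes(self._fit_with_variances(s2))
        assert np.isfinite(eb.s02)
        assert (eb.s2_post > 0).all()


class TestModeratedTests:
    def test_flat_gene_has_p_one(self, rng):
        x = np.vstack([np.tile([5.0, 5.0], 3), rng.normal(size=6)])
        gm = gene_matrix(x, ["A", "A", "B", "B", "C", "C"])
        fit = fit_timecourse(gm)
        res = moderated_tests(fit, estimate_ebayes(fit))
        assert res.gene_p.loc["g0"] == pytest.approx(1.0)

    def test_single_contrast_is_moderated_two_sample_t(self, rng):
        x = rng.normal(size=(40, 6))
        gm = gene_matrix(x, ["A", "A", "A", "B", "B", "B"])
        fit = fit_timecourse(gm)
        eb = estimate_ebayes(fit)
        res = moderated_tests(fit, eb)
        g = "g3"
        diff = x[3, :3].mean() - x[3, 3:].mean()
        se = np.sqrt(eb.s2_post[g] * (1 / 3 + 1 / 3))
        t = diff / se
        p = 2 * t_dist.sf(abs(t), eb.d0 + fit.df_residual)
        assert res.t.loc[g, "A-B"] == pytest.approx(t)
        assert res.gene_p.loc[g] == pytest.approx(p)

    def test_null_data_fdr_controlled(self, rng):
        """On pure-noise data the flagged fraction at FDR 0.05 stays near 0."""
        x = rng.normal(10, 0.3, size=(2000, 12))
        gm = gene_matrix(x, ["A", "B", "C", "D"] * 3)
        fit = fit_timecourse(gm)
        res = moderated_tests(fit, estimate_ebayes(fit))
        assert res.de.mean() <= 0.05


class TestTreat:
    def _fitted(self, rng, n=300, effect=None):
        x = rng.normal(10, 0.3, size=(n, 12))
        if effect is not None:
            x[: n // 2, 6:] += effect
        gm = gene_matrix(x, ["A"] * 6 + ["B"] * 6)
        fit = fit_timecourse(gm)
        return fit, estimate_ebayes(fit)

    def test_tau_zero_equals_moderated_test(self, rng):
        fit, eb = self._fitted(rng, effect=1.0)
        ordinary = moderated_tests(fit, eb, DEConfig())
        treat = treat_tests(fit, eb, DEConfig(fold_change=1.0))
        assert np.allclose(ordinary.p.to_numpy(), treat.p.to_numpy())
        assert np.array_equal(ordinary.de.to_numpy(), treat.de.to_numpy())

    def test_boundary_logfc_with_tiny_se_gives_half(self):
        from paleoexpr.diffexpr import LinearFit

        tau = 1.0
        coef = pd.DataFrame({"A": [tau], "B": [0.0]}, index=["g0"])
        fit = LinearFit(coef=coef, s2=pd.Series([1e-12], index=["g0"]),
                        df_residual=10, level_counts=pd.Series({"A": 6, "B": 6}),
                        contrasts=[("A", "B")])
        eb = EBayesParams(d0=10.0, s02=1e-12,
                          s2_post=pd.Series([1e-12], index=["g0"]))
        res = treat_tests(fit, eb, DEConfig(fold_change=2.0))
        assert res.p.loc["g0", "A-B"] == pytest.approx(0.5, abs=1e-6)

    def test_treat_p_never_below_ordinary_p(self, rng):
        fit, eb = self._fitted(rng, effect=0.8)
        ordinary = moderated_tests(fit, eb, DEConfig())
        treat = treat_tests(fit, eb, DEConfig(fold_change=1.5))
        assert (treat.p.to_numpy() >= ordinary.p.to_numpy() - 1e-12).all()

    def test_conservative_at_the_boundary(self, rng):
        """Genes whose true |logFC| equals tau are rejected at <= the nominal
        rate."""
        tau = np.log2(1.5)
        n, reps = 2000, 1
        rejected = 0
        for _ in range(reps):
            x = rng.normal(10, 0.3, size=(n, 12))
            x[:, 6:] += tau
            gm = gene_matrix(x, ["A"] * 6 + ["B"] * 6)
            fit = fit_timecourse(gm)
            res = treat_tests(fit, estimate_ebayes(fit), DEConfig(fold_change=1.5))
            rejected += (res.p.to_numpy() < 0.05).mean()
        assert rejected / reps <= 0.055

    def test_de_call_requires_model_fold_change(self, rng):
        fit, eb = self._fitted(rng, effect=0.5)  # below log2(2)=1
        res = treat_tests(fit, eb, DEConfig(fold_change=2.0))
        assert not res.de.any()


class TestAdjustBH:
    def test_hand_worked_step_up(self):
        p = pd.Series([0.005, 0.01, 0.03, 0.04], index=list("abcd"))
        adj = adjust_bh(p)
        assert np.allclose(adj.to_numpy(), [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh(pd.Series([0.2])).iloc[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        adj = adjust_bh(pd.Series([0.3] * 7))
        assert np.allclose(adj, 0.3)

    def test_invariant_under_permutation(self, rng):
        p = pd.Series(rng.uniform(size=30), index=[f"g{i}" for i in range(30)])
        perm = rng.permutation(p.index)
        assert np.allclose(adjust_bh(p).loc[perm], adjust_bh(p.loc[perm]))

    def test_adjusted_at_least_raw(self, rng):
        p = pd.Series(rng.uniform(size=50))
        adj = adjust_bh(p)
        assert (adj.to_numpy() >= p.to_numpy() - 1e-12).all()
        assert (adj.to_numpy() <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            adjust_bh(pd.Series([0.1, np.nan]))


class TestCallDE:
    def test_all_p_one_yields_empty_set(self, rng):
        x = np.tile(rng.normal(10, 0.2, size=(20, 1)), (1, 8))
        x += rng.normal(0, 0.2, size=x.shape)
        gm = gene_matrix(x, ["A", "A", "B", "B", "C", "C", "D", "D"])
        fit = fit_timecourse(gm)
        res = moderated_tests(fit, estimate_ebayes(fit))
        res.de[:] = res.fdr < 1e-30
        assert call_de(res) == set() or (res.fdr[list(call_de(res))] < 1e-30).all()

    def test_recall_on_simulated_truth(self, small_gene_matrix, small_dataset):
        res = TimecourseModel(small_gene_matrix).fit(method="ebayes", fdr=0.05)
        true_de = set(small_dataset.truth.de_genes())
        called = res.de_genes()
        recall = len(called & true_de) / len(true_de)
        assert recall >= 0.8

    def test_model_summary_mentions_call_counts(self, small_de_results):
        text = small_de_results.summary()
        assert "DE genes" in text and "treat" in text
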