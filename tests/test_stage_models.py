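"""Stage-indicator and ordinal models, variance moderation, BH, consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stagemark as sm
from stagemark import stage_models as smod
from stagemark.errors import ConfigurationError
from .conftest import make_design, make_voom

# Residual variances simulated in R from a scaled inverse-chi-square prior
# (seed 42, 50 genes, df = 10); the frozen d0/s0^2 below are the output of
# Bioconductor limma::squeezeVar on the same values.
LIMMA_S2 = [
    0.159466545318, 0.896184892048, 0.19813877107, 1.122054671182,
    0.607504373846, 0.615025738737, 0.046163103714, 0.179699528869,
    1.351837337858, 2.35540687739, 0.240532492348, 0.087278510805,
    0.226253328483, 0.25771624444, 0.096610531355, 0.830226714383,
    0.415804807043, 0.059773437434, 0.097571607657, 0.142365165203,
    0.213977457896, 0.234342045729, 5.444984293982, 1.410551681355,
    0.168110169354, 0.242184282463, 0.210876680588, 0.400335479463,
    0.31784286989, 1.500533799263, 0.322677066563, 0.614965342933,
    0.14881576736, 0.405213857668, 0.277603479793, 1.187552862758,
    0.329498844176, 0.557087374474, 0.188150453711, 0.583978749029,
    0.351363306944, 0.4030141176, 0.091973989844, 0.047683698644,
    0.128686230051, 0.220098037634, 0.078505668191, 0.273235586656,
    0.139407993118, 0.228194333296,
]
LIMMA_D0 = 3.4003922136
LIMMA_S02 = 0.2405171378


def _five_group_design(per_group=6):
    return make_design(np.repeat([0, 1, 2, 3, 4], per_group))


class TestLinearStageModel:
    def test_equal_group_means_give_zero_contrasts(self):
        d = _five_group_design()
        y = np.full((3, 30), 5.0)
        fit = smod.fit_linear_stage_model(make_voom(y, np.ones_like(y)), d)
        assert np.allclose(fit.coefficients["alpha"], 5.0)
        assert np.allclose(fit.stage_coef, 0.0)
        assert fit.df_resid == 25

    def test_indicator_contrast_equals_group_mean_difference(self):
        d = _five_group_design()
        y = np.full((1, 30), 5.0)
        y[0, 6:12] = 7.0  # stage-1 samples
        fit = smod.fit_linear_stage_model(make_voom(y, np.ones_like(y)), d)
        assert fit.coefficients["beta1"].iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["alpha"].iloc[0] == pytest.approx(5.0, abs=1e-10)

    def test_wls_matches_dense_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        d = _five_group_design()
        y = rng.normal(5, 2, size=(20, 30))
        w = rng.uniform(0.2, 3.0, size=(20, 30))
        fit = smod.fit_linear_stage_model(make_voom(y, w), d)
        X = np.column_stack([np.ones(30), d.stage_indicators])
        for g in range(20):
            Wd = np.diag(w[g])
            beta = np.linalg.solve(X.T @ Wd @ X, X.T @ Wd @ y[g])
            np.testing.assert_allclose(fit.coefficients.iloc[g].to_numpy(), beta,
                                       atol=1e-8)
            resid = y[g] - X @ beta
            s2 = (w[g] * resid**2).sum() / (30 - 5)
            assert fit.sigma2[g] == pytest.approx(s2, abs=1e-8)

    def test_missing_stage_is_a_rank_deficiency_error(self):
        d = make_design([0, 0, 1, 1, 2, 2, 3, 3])  # no stage 4
        y = np.zeros((2, 8))
        with pytest.raises(ConfigurationError, match="stage 4"):
            smod.fit_linear_stage_model(make_voom(y, np.ones_like(y)), d)


class TestOrdinalModel:
    def test_exact_linear_fit(self):
        d = _five_group_design(4)
        x = d.numeric_stage
        y = (2.0 * x + 1.0)[None, :]
        fit = smod.fit_ordinal_model(make_voom(y, np.ones_like(y)), d)
        assert fit.slope[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_has_zero_slope(self):
        d = _five_group_design(4)
        y = np.full((1, 20), 3.3)
        fit = smod.fit_ordinal_model(make_voom(y, np.ones_like(y)), d)
        assert fit.slope[0] == pytest.approx(0.0, abs=1e-12)

    def test_weighted_slope_matches_closed_form(self):
        rng = np.random.default_rng(4)
        d = _five_group_design(5)
        x = d.numeric_stage
        y = rng.normal(size=(10, 25))
        w = rng.uniform(0.1, 2.0, size=(10, 25))
        fit = smod.fit_ordinal_model(make_voom(y, w), d)
        for g in range(10):
            xw = np.average(x, weights=w[g])
            yw = np.average(y[g], weights=w[g])
            slope = (w[g] * (x - xw) * (y[g] - yw)).sum() / (w[g] * (x - xw) ** 2).sum()
            assert fit.slope[g] == pytest.approx(slope, abs=1e-10)

    def test_single_stage_design_rejected(self):
        d = make_design([2] * 10)
        y = np.zeros((1, 10))
        with pytest.raises(ConfigurationError):
            smod.fit_ordinal_model(make_voom(y, np.ones_like(y)), d)


class TestModeration:
    def test_matches_limma_squeezevar_on_frozen_fixture(self):
        p = smod.squeeze_variances(np.array(LIMMA_S2), 10)
        assert p.prior_df == pytest.approx(LIMMA_D0, abs=1e-6)
        assert p.prior_var == pytest.approx(LIMMA_S02, abs=1e-6)

    def test_shared_variance_gives_infinite_prior_df(self):
        p = smod.squeeze_variances(np.full(20, 0.7), 5)
        assert math.isinf(p.prior_df)
        assert np.allclose(p.posterior_var, 0.7)

    def test_posterior_is_convex_combination(self):
        p = smod.squeeze_variances(np.array(LIMMA_S2), 10)
        s2 = np.array(LIMMA_S2)
        lo = np.minimum(s2, p.prior_var)
        hi = np.maximum(s2, p.prior_var)
        assert ((p.posterior_var > lo) & (p.posterior_var < hi)).all()

    def test_hyperparameter_recovery(self):
        """(d0, s0^2) recovered from 1,000 genes with known prior."""
        rng = np.random.default_rng(7)
        n, d0, s02, df = 1000, 4.0, 0.25, 10
        sigma2 = s02 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        p = smod.squeeze_variances(s2, df)
        assert abs(p.prior_df - d0) / d0 < 0.5
        assert abs(p.prior_var - s02) / s02 < 0.2

    def test_zero_prior_df_limit_is_ordinary_t(self):
        rng = np.random.default_rng(2)
        d = _five_group_design(5)
        y = rng.normal(size=(8, 25))
        w = np.ones_like(y)
        fit = smod.fit_ordinal_model(make_voom(y, w), d)
        params = smod.ModerationParams(0.0, 1.0, fit.sigma2.copy())
        stats = smod.moderate_ordinal(fit, params)
        np.testing.assert_allclose(stats.table["stat"], smod.ordinary_t(fit),
                                   atol=1e-12)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ConfigurationError):
            smod.squeeze_variances(np.zeros(10), 5)


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            smod.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )
        assert smod.bh_adjust([0.04])[0] == pytest.approx(0.04)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_matches_brute_force_step_up(self, p):
        adj = smod.bh_adjust(p)
        m = len(p)
        order = np.argsort(np.asarray(p), kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        np.testing.assert_allclose(adj, brute, atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            smod.bh_adjust([0.5, 1.2])


def _stats_frame(genes, adjp, p=None, lfc=None):
    p = adjp if p is None else p
    lfc = np.ones(len(genes)) if lfc is None else lfc
    t = pd.DataFrame({"lfc": lfc, "stat": np.zeros(len(genes)), "p": p},
                     index=pd.Index(genes, name="gene"))
    return t


class TestConsensus:
    def _table(self, p_lin, p_ord, genes=None):
        genes = genes or [f"g{i:03d}" for i in range(len(p_lin))]
        lin = smod.ModelStats(_stats_frame(genes, None, p=np.asarray(p_lin)), None)
        ordi = smod.ModelStats(_stats_frame(genes, None, p=np.asarray(p_ord)), None)
        return smod.build_stat_table(lin, ordi)

    def test_identical_rankings_full_overlap(self):
        p = np.linspace(1e-30, 1e-8, 40)
        table = self._table(p, p)
        assert len(smod.rank_and_consensus(table, top_n=15, alpha=1e-5)) == 15

    def test_disjoint_top_lists_empty_consensus(self):
        p_lin = np.concatenate([np.full(15, 1e-30), np.full(15, 1e-10)])
        p_ord = np.concatenate([np.full(15, 1e-10), np.full(15, 1e-30)])
        table = self._table(p_lin, p_ord)
        # identical values within blocks: ranks break ties by gene id, making
        # the two top-15 sets exactly the two blocks
        assert smod.rank_and_consensus(table, top_n=15, alpha=1e-3) == []

    def test_partial_overlap_of_eleven(self):
        """11 genes shared between the two top-15 lists -> consensus of 11."""
        n = 60
        p_lin = np.full(n, 0.5)
        p_ord = np.full(n, 0.5)
        shared = [f"g{i:03d}" for i in range(11)]
        lin_only = [f"g{i:03d}" for i in range(11, 15)]
        ord_only = [f"g{i:03d}" for i in range(15, 19)]
        genes = [f"g{i:03d}" for i in range(n)]
        for i, g in enumerate(shared + lin_only):
            p_lin[genes.index(g)] = 1e-30 * (i + 1)
        for i, g in enumerate(shared + ord_only):
            p_ord[genes.index(g)] = 1e-30 * (i + 1)
        table = self._table(p_lin, p_ord, genes)
        consensus = smod.rank_and_consensus(table, top_n=15, alpha=1e-5)
        assert sorted(consensus) == sorted(shared)

    def test_ranks_are_permutations(self, small_voom):
        voom, design = small_voom
        lin = smod.moderate_linear(smod.fit_linear_stage_model(voom, design))
        ordi = smod.moderate_ordinal(smod.fit_ordinal_model(voom, design))
        table = smod.build_stat_table(lin, ordi)
        n = len(table)
        assert sorted(table["rank_linear"]) == list(range(1, n + 1))
        assert sorted(table["rank_ordinal"]) == list(range(1, n + 1))
        assert (table["adjp_linear"] >= table["p_linear"] - 1e-15).all()

    def test_top_n_bounds_checked(self):
        table = self._table([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ConfigurationError):
            smod.rank_and_consensus(table, top_n=5)


def test_planted_genes_dominate_linear_ranking():
    """On a planted cohort (effect 2.0, noise 0.5, n = 300), at least 90% of
    planted linear-signal genes sit within twice the planted count of the
    top of the linear ranking."""
    cfg = sm.CohortConfig(n_genes=2000, effect_size=2.0, stage_gain=1.0,
                          noise_sd=0.5, seed=17)
    matrix, design, truth = sm.generate_cohort(cfg)
    filtered, _ = sm.filter_low_variance(matrix)
    voom = sm.voom_transform(filtered)
    lin = smod.moderate_linear(smod.fit_linear_stage_model(voom, design))
    ordi = smod.moderate_ordinal(smod.fit_ordinal_model(voom, design))
    table = smod.build_stat_table(lin, ordi)
    planted = truth.planted_genes
    cutoff = 2 * len(planted)
    in_top = (table.loc[planted, "rank_linear"] <= cutoff).mean()
    assert in_top >= 0.9


def test_null_cohort_p_values_calibrated():
    """With all signals off, the raw linear-model p < 0.05 fraction is 5% +/- 2."""
    cfg = sm.CohortConfig(n_genes=1500, n_linear_signal=0, n_ordinal_signal=0,
                          n_flat=0, seed=5)
    matrix, design, _ = sm.generate_cohort(cfg)
    filtered, _ = sm.filter_low_variance(matrix)
    voom = sm.voom_transform(filtered)
    lin = smod.moderate_linear(smod.fit_linear_stage_model(voom, design))
    frac = (lin.table["p"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07
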