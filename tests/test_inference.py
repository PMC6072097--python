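"""Marginal-mean effect tests and decompositions."""

import numpy as np
import pytest
import scipy.optimize
import scipy.stats
from scipy.special import expit as sp_expit, logit as sp_logit
from scipy.stats import beta as beta_dist

from mtpbeta import (
    FitConfig, SimDesign, TwoPartDataset, bonferroni_adjust,
    comparison_tests, ctp_binary_effect, ctp_continuous_effect, fit_ctp,
    fit_mtp, gen_two_part_beta, lrt_ctp_effect, lrt_mtp_effect, mtp_effect,
)


def _logit_marginal_mean(x, alpha, beta):
    """logit(p(x) mu(x)) for the conventional model (effect-defining map)."""
    p = sp_expit(x @ alpha)
    mu = sp_expit(x @ beta)
    return sp_logit(p * mu)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

class TestLRT:
    def test_statistics_nonnegative_and_nested(self, ref_data, config):
        m = lrt_mtp_effect(ref_data, 1, config)
        c = lrt_ctp_effect(ref_data, 1, config)
        assert m.statistic >= 0 and c.statistic >= 0
        assert m.df == 1 and c.df == 2
        # the 2-df CTP restriction nests the single-equation one
        joint = lrt_mtp_effect(ref_data, 1, config, joint=True)
        assert joint.df == 2
        assert joint.statistic >= m.statistic - 1e-8

    def test_mtp_statistic_against_independent_optimizer(self):
        """Brute-force Nelder-Mead refits reproduce the LRT statistic."""
        data = gen_two_part_beta(SimDesign(n=120, n_reps=1, seed=17))
        res = lrt_mtp_effect(data, 1)

        y, X = data.y, data.X
        pos = y > 0

        def negll(theta, with_gamma1):
            a = theta[:2]
            g = np.array([theta[2], theta[3] if with_gamma1 else 0.0])
            phi = np.exp(theta[-1])
            lp_a, lp_g = X @ a, X @ g
            p = sp_expit(lp_a)
            mu = sp_expit(lp_g) / p
            if np.any(mu[pos] >= 1):
                return 1e10
            ll = np.sum(np.log1p(-p[~pos]))
            ll += np.sum(np.log(p[pos]) + beta_dist.logpdf(
                y[pos], mu[pos] * phi, (1 - mu[pos]) * phi))
            return -ll

        def best(with_gamma1):
            vals = []
            for s in range(6):
                rng = np.random.default_rng(s)
                x0 = np.array([1.5, 1.0, -2.5, 1.0, 0.0])
                x0 = x0 + 0.3 * rng.standard_normal(5)
                for _ in range(3):  # grid-refined restarts
                    out = scipy.optimize.minimize(
                        negll, x0, args=(with_gamma1,), method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12,
                                 "maxiter": 20000})
                    x0 = out.x
                vals.append(out.fun)
            return -min(vals)

        stat = 2.0 * (best(True) - best(False))
        assert res.statistic == pytest.approx(stat, abs=1e-4)

    def test_requires_non_intercept_covariate(self, ref_data):
        with pytest.raises(IndexError):
            lrt_mtp_effect(ref_data, 0)
        with pytest.raises(IndexError):
            lrt_ctp_effect(ref_data, 0)

    def test_pvalues_uniform_under_true_null(self):
        """MTP LRT p-values are ~U(0,1) at gamma1=0 (KS at 1% level)."""
        design = SimDesign(n=200, n_reps=500, alpha=(1.5, 1.0),
                           gamma=(-2.5, 0.0), seed=404)
        from mtpbeta.simulation import _replicate_rngs, generate
        pvals = []
        for rng in _replicate_rngs(design):
            data = generate(design, rng)
            pvals.append(lrt_mtp_effect(data, 1).p_value)
        stat = scipy.stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# conventional-model effect decompositions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ctp_fit():
    data = gen_two_part_beta(SimDesign(n=800, n_reps=1, seed=31))
    fit = fit_ctp(data)
    assert fit.converged
    return fit


class TestCTPContinuousEffect:
    def test_matches_numerical_derivative_of_logit_mean(self, ctp_fit):
        """Analytic c1*alpha_j + c2*beta_j equals d/dx logit(p mu)."""
        alpha, beta = ctp_fit.params.alpha, ctp_fit.params.beta
        for xval in (0.0, 0.3, 1.0):
            x = np.array([1.0, xval])
            eff = ctp_continuous_effect(ctp_fit, x, 1)
            h = 1e-5
            xp, xm = x.copy(), x.copy()
            xp[1] += h
            xm[1] -= h
            num = (_logit_marginal_mean(xp, alpha, beta)
                   - _logit_marginal_mean(xm, alpha, beta)) / (2 * h)
            assert eff.estimate == pytest.approx(num, abs=1e-6)
            c1, c2 = eff.decomposition["c1"], eff.decomposition["c2"]
            assert 0 < c1 <= 1 and 0 < c2 <= 1 and c1 + c2 >= 1

    def test_grid_of_parameters(self, ctp_fit):
        """Identity c1 a_j + c2 b_j = d/dx logit(p mu) across a grid."""
        x = np.array([1.0, 0.5])
        for aj in (-1.0, 0.0, 0.8):
            for bj in (-0.5, 0.0, 1.2):
                alpha = np.array([0.7, aj])
                beta = np.array([-1.1, bj])
                p = sp_expit(x @ alpha)
                mu = sp_expit(x @ beta)
                c1 = (1 - p) / (1 - p * mu)
                c2 = (1 - mu) / (1 - p * mu)
                h = 1e-5
                xp, xm = x.copy(), x.copy()
                xp[1] += h
                xm[1] -= h
                num = (_logit_marginal_mean(xp, alpha, beta)
                       - _logit_marginal_mean(xm, alpha, beta)) / (2 * h)
                assert c1 * aj + c2 * bj == pytest.approx(num, abs=1e-6)

    def test_null_effect_is_zero_and_se_positive(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.uniform(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        p = sp_expit(1.0 + 0 * x)
        y = np.zeros(n)
        pres = rng.random(n) < p
        y[pres] = rng.beta(0.5, 2.0, pres.sum()).clip(1e-9, 1 - 1e-9)
        fit = fit_ctp(TwoPartDataset(y, X))
        eff = ctp_continuous_effect(fit, np.array([1.0, 0.5]), 1)
        # truth has alpha1 = beta1 = 0; estimate should be near 0
        assert abs(eff.estimate) < 4 * eff.se
        assert eff.se > 0

    def test_intercept_index_rejected(self, ctp_fit):
        with pytest.raises(IndexError):
            ctp_continuous_effect(ctp_fit, np.array([1.0, 0.5]), 0)

    def test_certain_presence_limit_collapses_to_beta(self):
        # with p -> 1, the marginal effect reduces to beta_j
        x = np.array([1.0, 0.5])
        alpha = np.array([40.0, 0.7])
        beta = np.array([-1.0, 0.9])
        p = sp_expit(x @ alpha)
        mu = sp_expit(x @ beta)
        c1 = (1 - p) / (1 - p * mu)
        c2 = (1 - mu) / (1 - p * mu)
        assert c1 == pytest.approx(0.0, abs=1e-15)
        assert c1 * alpha[1] + c2 * beta[1] == pytest.approx(
            beta[1] * (1 - mu) / (1 - mu), rel=1e-10)


class TestCTPBinaryEffect:
    def test_decomposition_equals_direct_logit_difference(self, ctp_fit):
        eff = ctp_binary_effect(ctp_fit, np.array([1.0, 0.0]), 1)
        d = eff.decomposition
        assert eff.estimate == pytest.approx(d["direct"], abs=1e-10)
        assert eff.estimate - (d["alpha_k"] + d["beta_k"]) == pytest.approx(
            d["b1"] + d["b2"] + d["b3"], abs=1e-12)

    def test_identity_across_parameter_grid(self):
        """b-decomposition = direct logit difference, many parameters."""
        x = np.array([1.0, 0.0])
        for a0, ak in [(-0.5, 0.4), (1.2, -1.0), (0.3, 2.0)]:
            for b0, bk in [(-2.0, 0.7), (-0.4, -0.9)]:
                la0, la1 = a0, a0 + ak
                lb0, lb1 = b0, b0 + bk
                p0, p1 = sp_expit(la0), sp_expit(la1)
                m0, m1 = sp_expit(lb0), sp_expit(lb1)
                b1 = np.log((1 + np.exp(la0)) / (1 + np.exp(la1)))
                b2 = np.log((1 + np.exp(lb0)) / (1 + np.exp(lb1)))
                b3 = np.log((1 - p0 * m0) / (1 - p1 * m1))
                direct = sp_logit(p1 * m1) - sp_logit(p0 * m0)
                assert ak + bk + b1 + b2 + b3 == pytest.approx(
                    direct, abs=1e-10)

    def test_opposite_signs_cancel_marginal_effect(self):
        """alpha_k, beta_k chosen so the marginal means coincide."""
        a0, b0 = 0.8, -1.5
        ak = 1.0
        # choose bk so p1*mu1 = p0*mu0 (nonzero coefficients, zero effect)
        target = sp_expit(a0) * sp_expit(b0)
        mu1 = target / sp_expit(a0 + ak)
        bk = sp_logit(mu1) - b0
        assert ak > 0 > bk
        direct = (sp_logit(sp_expit(a0 + ak) * sp_expit(b0 + bk))
                  - sp_logit(sp_expit(a0) * sp_expit(b0)))
        assert direct == pytest.approx(0.0, abs=1e-12)

    def test_non_binary_column_flagged(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.uniform(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        y = np.zeros(n)
        pres = rng.random(n) < 0.8
        y[pres] = rng.beta(0.5, 2.0, pres.sum()).clip(1e-9, 1 - 1e-9)
        fit = fit_ctp(TwoPartDataset(y, X))
        with pytest.raises(ValueError, match="binary"):
            ctp_binary_effect(fit, np.array([1.0, 0.0]), 1)


class TestMTPEffect:
    def test_estimate_is_fitted_coefficient(self, ref_data):
        fit = fit_mtp(ref_data)
        eff = mtp_effect(fit, 1)
        assert eff.estimate == fit.params.gamma[1]
        assert eff.ci_lower < eff.estimate < eff.ci_upper
        assert eff.ci_upper - eff.estimate == pytest.approx(
            1.959964 * eff.se, rel=1e-12)

    def test_equals_numerical_derivative_of_model_mean(self, ref_data):
        """gamma_j is exactly d/dx_j logit of the implied marginal mean."""
        fit = fit_mtp(ref_data)
        g = fit.params.gamma
        x = np.array([1.0, 0.4])
        h = 1e-6
        num = (sp_logit(sp_expit((x[0]) * g[0] + (x[1] + h) * g[1]))
               - sp_logit(sp_expit(x[0] * g[0] + (x[1] - h) * g[1]))) / (2 * h)
        assert mtp_effect(fit, 1).estimate == pytest.approx(num, rel=1e-6)


# ---------------------------------------------------------------------------
# comparison tests and Bonferroni
# ---------------------------------------------------------------------------

class TestComparisonTests:
    def test_identical_groups_t_p_is_one(self):
        y = np.tile([0.0, 0.1, 0.2, 0.3], 2)
        g = np.repeat([0.0, 1.0], 4)
        data = TwoPartDataset(y, np.column_stack([np.ones(8), g]))
        t, w = comparison_tests(data, 1)
        assert t.p_value == pytest.approx(1.0)

    def test_textbook_t_statistic(self):
        # hand-computed pooled t for two samples of 4
        y0 = np.array([0.10, 0.20, 0.30, 0.40])
        y1 = np.array([0.30, 0.40, 0.50, 0.60])
        sp2 = (np.var(y0, ddof=1) * 3 + np.var(y1, ddof=1) * 3) / 6
        t_manual = (y1.mean() - y0.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        data = TwoPartDataset(np.concatenate([y0, y1]),
                              np.column_stack([np.ones(8),
                                               np.repeat([0.0, 1.0], 4)]))
        t, _ = comparison_tests(data, 1)
        assert t.statistic == pytest.approx(t_manual, rel=1e-12)
        assert t.df == 6

    def test_small_group_rejected(self):
        data = TwoPartDataset(np.array([0.1, 0.2, 0.3]),
                              np.column_stack([np.ones(3),
                                               np.array([0.0, 1.0, 1.0])]))
        with pytest.raises(ValueError, match="at least 2"):
            comparison_tests(data, 1)

    def test_non_binary_group_rejected(self, ref_data):
        d = TwoPartDataset(ref_data.y,
                           np.column_stack([np.ones(ref_data.n),
                                            np.linspace(0, 2, ref_data.n)]))
        with pytest.raises(ValueError, match="binary"):
            comparison_tests(d, 1)


class TestBonferroni:
    def test_definition_and_cap(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.5]),
                                   [0.02, 1.0])
        np.testing.assert_allclose(bonferroni_adjust([1.0, 1.0, 1.0]),
                                   [1.0, 1.0, 1.0])

    def test_threshold_equivalence_at_m_131(self):
        p = 0.05 / 131
        adj = bonferroni_adjust(np.full(131, p))
        assert adj[0] == pytest.approx(0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.2, 1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])

    def test_order_preserving(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        adj = bonferroni_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= 0)
        assert np.all(adj >= p)
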