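"""Tests and effect measures on the marginal mean of relative abundance.

The scientific question is always "does the covariate shift the overall
(unconditional) mean abundance E[Y]?".  Under the marginalized model
that is exactly H0: gamma_j = 0, a 1-df likelihood-ratio test.  Under
the conventional model the marginal mean is p(x) * mu(x), a nonlinear
mix of both submodels, so the usual joint test H0: alpha_j = beta_j = 0
(2 df) targets a *different* null — covariates that act on presence but
leave the marginal mean unchanged make it anti-conservative.

The conventional-model effect of covariate j on logit E[Y] is still
computable: for a continuous covariate it is c1*alpha_j + c2*beta_j
with

    c1 = (1 - p) / (1 - p*mu),    c2 = (1 - mu) / (1 - p*mu),

and for a binary covariate the exact logit difference decomposes as
alpha_k + beta_k + b1 + b2 + b3 (log-partition corrections).  Standard
errors come from the delta method over the full joint covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .estimation import FitConfig, ModelFit, fit_ctp, fit_mtp
from .model import TwoPartDataset
from scipy.special import expit as _expit

__all__ = [
    "TestResult", "EffectResult",
    "lrt_mtp_effect", "lrt_ctp_effect", "ctp_continuous_effect",
    "ctp_binary_effect", "mtp_effect", "comparison_tests",
    "bonferroni_adjust",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class TestResult:
    method: str
    statistic: float
    df: int | None
    p_value: float
    adjusted_p: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value:
            raise ValueError("adjusted p must be >= raw p")


@dataclass
class EffectResult:
    """A covariate effect on logit of the marginal mean E[Y]."""

    scale: str
    estimate: float
    se: float
    decomposition: dict[str, float]
    ci_lower: float = np.nan
    ci_upper: float = np.nan


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def _drop_col(X: np.ndarray, j: int) -> np.ndarray:
    return np.delete(X, j, axis=1)


def _check_lrt_fits(full: ModelFit, null: ModelFit, label: str) -> None:
    if not (full.converged and null.converged):
        raise RuntimeError(
            f"{label}: non-converged fit "
            f"(full: rel_grad={full.rel_gradient:.3g} conv={full.converged}; "
            f"null: rel_grad={null.rel_gradient:.3g} conv={null.converged})"
        )


def lrt_mtp_effect(data: TwoPartDataset, covariate_index: int,
                   config: FitConfig | None = None,
                   joint: bool = False) -> TestResult:
    """LRT of no covariate effect on the marginal mean under the MTP model.

    The default null removes the covariate from the gamma-equation only
    (H0: gamma_j = 0, 1 df) — presence may still depend on it.  With
    ``joint=True`` the covariate is removed from both equations
    (H0: alpha_j = gamma_j = 0, 2 df), a stricter, non-default null.
    """
    j = int(covariate_index)
    if not 1 <= j < data.n_covariates:
        raise IndexError("covariate_index must name a non-intercept column")
    config = config or FitConfig()
    full = fit_mtp(data, config)
    Xr = _drop_col(data.X, j)
    if joint:
        null = fit_mtp(data, config, alpha_X=Xr, gamma_X=Xr)
        df = 2
    else:
        null = fit_mtp(data, config, gamma_X=Xr)
        df = 1
    _check_lrt_fits(full, null, "LRT-MTP")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(scipy.stats.chi2.sf(stat, df))
    return TestResult("LRT-MTP", stat, df, p,
                      detail={"loglik_full": full.loglik,
                              "loglik_null": null.loglik,
                              "full_fit": full, "null_fit": null})


def lrt_ctp_effect(data: TwoPartDataset, covariate_index: int,
                   config: FitConfig | None = None) -> TestResult:
    """LRT of H0: alpha_j = beta_j = 0 under the conventional model (2 df).

    This is the conventional-model surrogate for "no effect on the
    marginal mean"; it is not equivalent to that hypothesis and fails to
    control its type-I error when the covariate acts on presence alone.
    """
    j = int(covariate_index)
    if not 1 <= j < data.n_covariates:
        raise IndexError("covariate_index must name a non-intercept column")
    config = config or FitConfig()
    full = fit_ctp(data, config)
    Xr = _drop_col(data.X, j)
    null = fit_ctp(data, config, alpha_X=Xr, beta_X=Xr)
    _check_lrt_fits(full, null, "LRT-CTP")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(scipy.stats.chi2.sf(stat, 2))
    return TestResult("LRT-CTP", stat, 2, p,
                      detail={"loglik_full": full.loglik,
                              "loglik_null": null.loglik,
                              "full_fit": full, "null_fit": null})


# ---------------------------------------------------------------------------
# effect measures
# ---------------------------------------------------------------------------

def _delta_se(fit: ModelFit, est_fn) -> float:
    """Delta-method SE of est_fn(natural coefficient vector) via fit.vcov."""
    theta = fit.estimates()
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        h = 1e-6 * max(abs(theta[i]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grad[i] = (est_fn(tp) - est_fn(tm)) / (2.0 * h)
    var = float(grad @ fit.vcov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def ctp_continuous_effect(fit: ModelFit, x_row: np.ndarray,
                          j: int) -> EffectResult:
    """d logit(E[Y]) / dx_j under the CTP fit, evaluated at x_row.

    Returns the c1*alpha_j + c2*beta_j form with the weights reported in
    the decomposition; the SE is a delta-method SE over the full joint
    coefficient vector (the weights depend on every coefficient through
    p(x) and mu(x)).
    """
    if fit.model_kind != "CTP":
        raise ValueError("ctp_continuous_effect needs a CTP fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    j = int(j)
    ka = fit.alpha_X.shape[1]
    if not 1 <= j < ka:
        raise IndexError("j must name a non-intercept column")
    x = np.asarray(x_row, dtype=float)

    def eval_effect(theta):
        a, b = theta[:ka], theta[ka:-1]
        p = _expit(x @ a)
        mu = _expit(x @ b)
        c1 = (1.0 - p) / (1.0 - p * mu)
        c2 = (1.0 - mu) / (1.0 - p * mu)
        return c1 * a[j] + c2 * b[j]

    theta = fit.estimates()
    a, b = theta[:ka], theta[ka:-1]
    p = float(_expit(x @ a))
    mu = float(_expit(x @ b))
    c1 = (1.0 - p) / (1.0 - p * mu)
    c2 = (1.0 - mu) / (1.0 - p * mu)
    est = c1 * a[j] + c2 * b[j]
    se = _delta_se(fit, eval_effect)
    return EffectResult(
        scale="logit-marginal-mean", estimate=float(est), se=se,
        decomposition={"c1": float(c1), "c2": float(c2),
                       "alpha_j": float(a[j]), "beta_j": float(b[j])},
        ci_lower=float(est - Z_95 * se), ci_upper=float(est + Z_95 * se),
    )


def _softplus(z: float) -> float:
    return float(np.logaddexp(0.0, z))


def ctp_binary_effect(fit: ModelFit, x_row: np.ndarray, k: int) -> EffectResult:
    """logit E[Y | x_k=1] - logit E[Y | x_k=0] under the CTP fit.

    Decomposes exactly as alpha_k + beta_k + b1 + b2 + b3 where the
    b-terms are log-partition corrections evaluated at the remaining
    covariates of x_row; the direct logit difference is recomputed and
    must agree with the decomposition to 1e-10.
    """
    if fit.model_kind != "CTP":
        raise ValueError("ctp_binary_effect needs a CTP fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    k = int(k)
    ka = fit.alpha_X.shape[1]
    if not 1 <= k < ka:
        raise IndexError("k must name a non-intercept column")
    col = fit.data.X[:, k]
    if not np.all(np.isin(col, (0.0, 1.0))):
        raise ValueError(f"design column {k} is not binary 0/1")
    x = np.asarray(x_row, dtype=float)

    def pieces(theta):
        a, b = theta[:ka], theta[ka:-1]
        x0 = x.copy()
        x0[k] = 0.0
        la0, lb0 = float(x0 @ a), float(x0 @ b)
        la1, lb1 = la0 + a[k], lb0 + b[k]
        p0, p1 = _expit(la0), _expit(la1)
        m0, m1 = _expit(lb0), _expit(lb1)
        b1 = _softplus(la0) - _softplus(la1)
        b2 = _softplus(lb0) - _softplus(lb1)
        b3 = float(np.log((1.0 - p0 * m0) / (1.0 - p1 * m1)))
        direct = float(np.log(p1 * m1 / (1.0 - p1 * m1))
                       - np.log(p0 * m0 / (1.0 - p0 * m0)))
        return a[k], b[k], b1, b2, b3, direct

    theta = fit.estimates()
    ak, bk, b1, b2, b3, direct = pieces(theta)
    est = ak + bk + b1 + b2 + b3

    def eval_effect(th):
        a_, b_, b1_, b2_, b3_, _ = pieces(th)
        return a_ + b_ + b1_ + b2_ + b3_

    se = _delta_se(fit, eval_effect)
    return EffectResult(
        scale="logit-marginal-mean", estimate=float(est), se=se,
        decomposition={"alpha_k": float(ak), "beta_k": float(bk),
                       "b1": float(b1), "b2": float(b2), "b3": float(b3),
                       "direct": float(direct)},
        ci_lower=float(est - Z_95 * se), ci_upper=float(est + Z_95 * se),
    )


def mtp_effect(fit: ModelFit, j: int) -> EffectResult:
    """Marginal-mean effect under the MTP fit: the coefficient gamma_j."""
    if fit.model_kind != "MTP":
        raise ValueError("mtp_effect needs an MTP fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    idx = fit.param_index("gamma", int(j))
    est = float(fit.estimates()[idx])
    se = float(np.sqrt(fit.vcov[idx, idx]))
    return EffectResult(
        scale="logit-marginal-mean", estimate=est, se=se,
        decomposition={"gamma_j": est},
        ci_lower=est - Z_95 * se, ci_upper=est + Z_95 * se,
    )


# ---------------------------------------------------------------------------
# comparison tests and multiplicity
# ---------------------------------------------------------------------------

def comparison_tests(data: TwoPartDataset,
                     group_index: int) -> tuple[TestResult, TestResult]:
    """Pooled-variance two-sample t-test and Wilcoxon rank-sum test.

    Both compare the raw outcomes (zeros included) between the two
    levels of a binary design column.  The Wilcoxon test uses the exact
    null distribution for small untied samples and the tie-corrected,
    continuity-corrected normal approximation otherwise.
    """
    g = data.X[:, int(group_index)]
    if not np.all(np.isin(g, (0.0, 1.0))):
        raise ValueError("group column must be binary 0/1")
    y0, y1 = data.y[g == 0.0], data.y[g == 1.0]
    if y0.size < 2 or y1.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t_stat, t_p = scipy.stats.ttest_ind(y1, y0, equal_var=True)
    method = "exact" if (y0.size + y1.size) <= 50 else "asymptotic"
    if np.unique(data.y).size < data.n:   # ties (zeros guarantee them)
        method = "asymptotic"
    w_stat, w_p = scipy.stats.mannwhitneyu(
        y1, y0, alternative="two-sided", method=method, use_continuity=True,
    )
    t = TestResult("T-test", float(t_stat), int(y0.size + y1.size - 2),
                   float(t_p))
    w = TestResult("Wilcoxon", float(w_stat), None, float(w_p))
    return t, w


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)
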