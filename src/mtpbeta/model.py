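"""Core two-part Beta regression machinery.

Relative abundances are semicontinuous: a point mass at exactly zero
(the taxon is absent or undersampled) mixed with a right-skewed
continuous distribution on (0, 1).  Both models here share Part I, a
logistic regression for the presence probability

    logit(p_i) = x_i' alpha,

and a Beta distribution in mean-dispersion form for the positive part,
``Beta(mu * phi, (1 - mu) * phi)`` so that the conditional mean is
``mu`` and larger ``phi`` means lower variance.

They differ in what Part II's linear predictor targets:

* conventional two-part (CTP):   logit(mu_i) = x_i' beta
  (mu_i = E[Y_i | Y_i > 0], a *conditional* mean), and
* marginalized two-part (MTP):   logit(nu_i) = x_i' gamma
  (nu_i = E[Y_i] = p_i * mu_i, the *marginal* mean, so gamma has an
  unconditional population-level interpretation).

The MTP likelihood is the CTP likelihood reparameterized through
mu_i = nu_i / p_i; that ratio must stay below 1, which the likelihood
enforces by returning -inf outside the admissible region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit as _expit, log_expit, gammaln, digamma

__all__ = [
    "TwoPartDataset",
    "CTPParams",
    "MTPParams",
    "expit",
    "beta_log_density",
    "ctp_log_likelihood",
    "mtp_conditional_mean",
    "mtp_log_likelihood",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPartDataset:
    """Outcome vector in [0, 1) with its design matrix.

    Zeros are detected by exact equality ``y == 0``; rounding tiny
    positive abundances down to zero is the caller's responsibility.
    Values at or above 1 are outside the support and rejected.
    """

    y: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if X.ndim != 2:
            raise ValueError("X must be a matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in y or X")
        if np.any(y < 0) or np.any(y >= 1):
            bad = np.where((y < 0) | (y >= 1))[0]
            raise ValueError(
                f"outcomes must lie in [0, 1); offending indices: {bad[:10]}"
            )
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        names = tuple(self.covariate_names)
        if not names:
            names = ("intercept",) + tuple(
                f"x{j}" for j in range(1, X.shape[1])
            )
        if len(names) != X.shape[1]:
            raise ValueError("covariate_names length must match X columns")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        """Number of design columns including the intercept."""
        return self.X.shape[1]

    @property
    def positive_mask(self) -> np.ndarray:
        return self.y > 0

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.y == 0))


def _check_coef(vec: Sequence[float], name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(vec, dtype=float))
    if v.ndim != 1 or not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be a finite vector")
    return v


@dataclass(frozen=True)
class CTPParams:
    """Conventional two-part parameters (alpha, beta, phi).

    ``alpha`` drives presence, ``beta`` the conditional mean of the
    positive part (both on the logit scale), ``phi`` > 0 the Beta
    dispersion.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        a = _check_coef(self.alpha, "alpha")
        b = _check_coef(self.beta, "beta")
        if a.shape != b.shape:
            raise ValueError("alpha and beta must have the same length")
        if not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError("phi must be a positive finite scalar")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "phi", float(self.phi))


@dataclass(frozen=True)
class MTPParams:
    """Marginalized two-part parameters (alpha, gamma, phi).

    ``gamma`` models the logit of the marginal mean nu = E[Y].  The
    implied conditional mean mu = nu / p must stay below 1, which holds
    iff x'gamma < x'alpha for every design row; that is a property of
    (params, data) jointly, checked where the likelihood is evaluated.
    """

    alpha: np.ndarray
    gamma: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        a = _check_coef(self.alpha, "alpha")
        g = _check_coef(self.gamma, "gamma")
        if not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError("phi must be a positive finite scalar")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "phi", float(self.phi))


# ---------------------------------------------------------------------------
# links and densities
# ---------------------------------------------------------------------------

def expit(z):
    """Inverse logit 1 / (1 + exp(-z)), stable over the full float range."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("expit requires finite input")
    out = _expit(z)
    return float(out) if out.ndim == 0 else out


def beta_log_density(y, mu, phi):
    """Log-density of Beta(mu*phi, (1-mu)*phi) at y.

    This is the mean-dispersion parameterization: E[Y] = mu,
    Var[Y] = mu(1-mu)/(1+phi).  Computed on the log scale via
    log-gamma so large phi does not overflow.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = float(phi)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly in (0, 1); zeros belong to Part I")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    if not phi > 0:
        raise ValueError("phi must be positive")
    out = (
        gammaln(phi)
        - gammaln(mu * phi)
        - gammaln((1.0 - mu) * phi)
        + (mu * phi - 1.0) * np.log(y)
        + ((1.0 - mu) * phi - 1.0) * np.log1p(-y)
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# log-likelihoods (public, parameter-object API)
# ---------------------------------------------------------------------------

def ctp_log_likelihood(params: CTPParams, data: TwoPartDataset) -> float:
    """Log-likelihood of the conventional two-part Beta model.

    sum_i [ 1(y_i=0) log(1-p_i) + 1(y_i>0) (log p_i + log Beta density) ]
    with p_i = expit(x_i'alpha) and mu_i = expit(x_i'beta).
    """
    if params.alpha.shape[0] != data.X.shape[1]:
        raise ValueError("parameter dimension does not match design matrix")
    return _ctp_loglik(params.alpha, params.beta, params.phi, data.y, data.X, data.X)


def mtp_conditional_mean(alpha_lp, gamma_lp):
    """Conditional mean mu = nu / p implied by the MTP linear predictors.

    Returns (1 + exp(-alpha_lp)) / (1 + exp(-gamma_lp)); values >= 1
    signal that the marginal mean exceeds the presence probability,
    which the likelihood maps to -inf rather than raising.
    """
    alpha_lp = np.asarray(alpha_lp, dtype=float)
    gamma_lp = np.asarray(gamma_lp, dtype=float)
    # exp(log nu - log p) keeps precision when both predictors are large
    out = np.exp(log_expit(gamma_lp) - log_expit(alpha_lp))
    return float(out) if out.ndim == 0 else out


def mtp_log_likelihood(params: MTPParams, data: TwoPartDataset) -> float:
    """Log-likelihood of the marginalized two-part Beta model.

    Equals the CTP likelihood at the induced conditional means
    mu_i = expit(x_i'gamma) / expit(x_i'alpha); returns -inf (a value,
    not an exception) when any positive outcome has mu_i >= 1 so that
    unconstrained optimizers can retreat.
    """
    if params.alpha.shape[0] != data.X.shape[1]:
        raise ValueError("parameter dimension does not match design matrix")
    if params.gamma.shape[0] != data.X.shape[1]:
        raise ValueError("parameter dimension does not match design matrix")
    return _mtp_loglik(params.alpha, params.gamma, params.phi, data.y, data.X, data.X)


# ---------------------------------------------------------------------------
# internal vectorized kernels (separate alpha/gamma designs for null fits)
# ---------------------------------------------------------------------------

def _ctp_loglik(alpha, beta, phi, y, Xa, Xb) -> float:
    pos = y > 0
    a = Xa @ alpha
    ll = float(np.sum(log_expit(-a[~pos])))  # log(1 - p) on zero rows
    if np.any(pos):
        mu = _expit(Xb[pos] @ beta)
        ll += float(np.sum(log_expit(a[pos])))
        ll += float(np.sum(beta_log_density(y[pos], mu, phi)))
    return ll


def _mtp_mu_pos(alpha, gamma, y, Xa, Xg):
    """log mu on positive rows; mu >= 1 shows up as log mu >= 0."""
    pos = y > 0
    return log_expit(Xg[pos] @ gamma) - log_expit(Xa[pos] @ alpha)


def _mtp_loglik(alpha, gamma, phi, y, Xa, Xg) -> float:
    pos = y > 0
    a = Xa @ alpha
    ll = float(np.sum(log_expit(-a[~pos])))
    if np.any(pos):
        log_mu = _mtp_mu_pos(alpha, gamma, y, Xa, Xg)
        mu = np.exp(log_mu)
        # exp can round to exactly 1 (or underflow to 0) inside the
        # feasible region; both leave the Beta support
        if np.any(log_mu >= 0.0) or np.any(mu >= 1.0) or np.any(mu <= 0.0):
            return -np.inf
        ll += float(np.sum(log_expit(a[pos])))
        ll += float(np.sum(beta_log_density(y[pos], mu, phi)))
    return ll


def _beta_part_score_mu(y, mu, phi):
    """d/dmu of the Beta log-density (used by both gradients)."""
    return phi * (
        np.log(y) - np.log1p(-y) - digamma(mu * phi) + digamma((1.0 - mu) * phi)
    )


def _beta_part_score_phi(y, mu, phi):
    """d/dphi of the Beta log-density."""
    return (
        digamma(phi)
        - mu * digamma(mu * phi)
        - (1.0 - mu) * digamma((1.0 - mu) * phi)
        + mu * np.log(y)
        + (1.0 - mu) * np.log1p(-y)
    )


def _ctp_loglik_grad(alpha, beta, phi, y, Xa, Xb):
    """(loglik, grad) wrt (alpha, beta, log phi)."""
    pos = y > 0
    a = Xa @ alpha
    p = _expit(a)
    ll = float(np.sum(log_expit(-a[~pos])))
    ga = np.zeros_like(alpha)
    gb = np.zeros_like(beta)
    gphi = 0.0
    ga += -Xa[~pos].T @ p[~pos]
    if np.any(pos):
        mu = _expit(Xb[pos] @ beta)
        ll += float(np.sum(log_expit(a[pos])))
        ll += float(np.sum(beta_log_density(y[pos], mu, phi)))
        ga += Xa[pos].T @ (1.0 - p[pos])
        d_mu = _beta_part_score_mu(y[pos], mu, phi)
        gb += Xb[pos].T @ (d_mu * mu * (1.0 - mu))
        gphi = float(np.sum(_beta_part_score_phi(y[pos], mu, phi))) * phi
    return ll, np.concatenate([ga, gb, [gphi]])


def _mtp_loglik_grad(alpha, gamma, phi, y, Xa, Xg):
    """(loglik, grad) wrt (alpha, gamma, log phi); (-inf, zeros) off-support."""
    pos = y > 0
    a = Xa @ alpha
    p = _expit(a)
    ga = np.zeros_like(alpha)
    gg = np.zeros_like(gamma)
    ll = float(np.sum(log_expit(-a[~pos])))
    ga += -Xa[~pos].T @ p[~pos]
    gphi = 0.0
    if np.any(pos):
        log_mu = _mtp_mu_pos(alpha, gamma, y, Xa, Xg)
        mu = np.exp(log_mu)
        if np.any(log_mu >= 0.0) or np.any(mu >= 1.0) or np.any(mu <= 0.0):
            return -np.inf, np.zeros(alpha.size + gamma.size + 1)
        nu = _expit(Xg[pos] @ gamma)
        ll += float(np.sum(log_expit(a[pos])))
        ll += float(np.sum(beta_log_density(y[pos], mu, phi)))
        d_mu = _beta_part_score_mu(y[pos], mu, phi)
        # dmu/d(alpha lp) = -mu (1-p);  dmu/d(gamma lp) = mu (1-nu)
        ga += Xa[pos].T @ ((1.0 - p[pos]) - d_mu * mu * (1.0 - p[pos]))
        gg += Xg[pos].T @ (d_mu * mu * (1.0 - nu))
        gphi = float(np.sum(_beta_part_score_phi(y[pos], mu, phi))) * phi
    return ll, np.concatenate([ga, gg, [gphi]])
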