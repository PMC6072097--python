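"""Maximum-likelihood fitting of the CTP and MTP models.

The fitting recipe mirrors standard practice for marginalized two-part
models: Part I starting values come from a logistic regression of the
presence indicator, Part II starting values from a Beta regression
(logit link, ML) on the positive outcomes; the joint likelihood is then
maximized by quasi-Newton iteration with analytic gradients, declared
converged when a relative-gradient criterion falls below
``rel_gradient_tol`` (default 1e-8).

Internally the dispersion is optimized as log(phi) so the search is
unconstrained; estimates and the covariance matrix are reported on the
natural scale (delta method for the phi row/column).

The CTP likelihood factorizes into the logistic part and the Beta part,
so its joint quasi-Newton fit must coincide with the two standalone
fits; the MTP likelihood couples alpha and gamma through the induced
conditional mean mu = nu/p and requires genuinely joint optimization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import scipy.optimize

from .model import (
    CTPParams,
    MTPParams,
    TwoPartDataset,
    _ctp_loglik_grad,
    _mtp_loglik_grad,
    _beta_part_score_mu,
    _beta_part_score_phi,
    beta_log_density,
)
from scipy.special import expit as _expit, log_expit, logit

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "ModelFit", "starting_values", "fit_ctp", "fit_mtp",
           "standard_errors"]

_EPS_CBRT = float(np.finfo(float).eps) ** (1.0 / 3.0)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.

    rel_gradient_tol: convergence threshold for
        max_j |g_j * theta_j| / max(|loglik|, 1), evaluated on the
        internal (alpha, beta-or-gamma, log phi) scale.
    fallback_starts: number of jittered restarts (multiplicative
        N(0, 0.1^2) noise on the starting values, deterministic seed)
        before the fit is flagged non-converged.
    """

    rel_gradient_tol: float = 1e-8
    max_iter: int = 500
    optimizer_name: str = "BFGS"
    fallback_starts: int = 5

    def __post_init__(self) -> None:
        if not self.rel_gradient_tol > 0:
            raise ValueError("rel_gradient_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.fallback_starts < 0:
            raise ValueError("fallback_starts must be >= 0")


@dataclass
class ModelFit:
    """Result of a CTP or MTP maximum-likelihood fit.

    ``vcov`` covers all coefficients on the natural scale in the order
    (alpha block, beta- or gamma-block, phi); ``theta_internal`` is the
    optimum on the internal scale (phi as log phi).
    """

    model_kind: Literal["CTP", "MTP"]
    params: CTPParams | MTPParams
    loglik: float
    vcov: np.ndarray
    converged: bool
    n_used: int
    gradient_norm: float
    rel_gradient: float
    param_names: tuple[str, ...]
    theta_internal: np.ndarray
    data: TwoPartDataset
    alpha_X: np.ndarray
    part2_X: np.ndarray
    n_restarts: int = 0
    vcov_pseudo_inverse: bool = False
    message: str = ""

    @property
    def n_params(self) -> int:
        return self.theta_internal.size

    def param_index(self, block: str, j: int) -> int:
        """Flat index of coefficient j of 'alpha', 'beta'/'gamma', or 'phi'."""
        ka = self.alpha_X.shape[1]
        kg = self.part2_X.shape[1]
        if block == "alpha":
            if not 0 <= j < ka:
                raise IndexError("alpha index out of range")
            return j
        if block in ("beta", "gamma"):
            if not 0 <= j < kg:
                raise IndexError(f"{block} index out of range")
            return ka + j
        if block == "phi":
            return ka + kg
        raise KeyError(block)

    def estimates(self) -> np.ndarray:
        """All coefficients on the natural scale, in vcov order."""
        th = self.theta_internal.copy()
        th[-1] = np.exp(th[-1])
        return th


# ---------------------------------------------------------------------------
# inner ML routines (logistic Newton; Beta regression by quasi-Newton)
# ---------------------------------------------------------------------------

def _fit_logistic(z: np.ndarray, X: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Newton-Raphson logistic MLE of a 0/1 response z on X."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = _expit(eta)
        g = X.T @ (z - p)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving keeps the iteration monotone
        t = 1.0
        ll = float(np.sum(z * log_expit(eta) + (1 - z) * log_expit(-eta)))
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = float(np.sum(z * log_expit(eta_c) + (1 - z) * log_expit(-eta_c)))
            if ll_c >= ll - 1e-12:
                beta = cand
                ll = ll_c
                break
            t *= 0.5
        if abs(ll - ll_old) < 1e-12 and np.max(np.abs(g)) < 1e-8:
            break
        ll_old = ll
    return beta


def _betareg_negloglik_grad(theta, y, X):
    k = X.shape[1]
    b, logphi = theta[:k], theta[k]
    phi = np.exp(logphi)
    mu = _expit(X @ b)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0) or not np.isfinite(phi) \
            or phi <= 0.0:
        return np.inf, np.zeros(k + 1)
    ll = float(np.sum(beta_log_density(y, mu, phi)))
    d_mu = _beta_part_score_mu(y, mu, phi)
    gb = X.T @ (d_mu * mu * (1.0 - mu))
    gphi = float(np.sum(_beta_part_score_phi(y, mu, phi))) * phi
    return -ll, -np.concatenate([gb, [gphi]])


def _fit_betareg(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Beta-regression MLE (logit link); returns (beta..., log phi)."""
    yc = np.clip(y, 1e-6, 1 - 1e-6)
    b0 = np.linalg.lstsq(X, logit(yc), rcond=None)[0]
    mu0 = _expit(X @ b0)
    resid_var = max(float(np.var(y - mu0)), 1e-8)
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 0.05, 1e4))
    theta0 = np.concatenate([b0, [np.log(phi0)]])
    res = scipy.optimize.minimize(
        _betareg_negloglik_grad, theta0, args=(y, X), jac=True,
        method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def starting_values(
    data: TwoPartDataset,
    model_kind: Literal["CTP", "MTP"],
    *,
    alpha_X: np.ndarray | None = None,
    part2_X: np.ndarray | None = None,
) -> np.ndarray:
    """Starting vector (alpha0..., part2 coefs..., log phi0).

    alpha0 is the logistic MLE of 1(y>0) on X; the Part II coefficients
    and phi0 are the Beta-regression MLE on the positive outcomes.  For
    the MTP model gamma0 := beta0, shifted down in the intercept by the
    minimal constant (+1e-3) whenever some observed row would violate
    the support constraint x'gamma < x'alpha.
    """
    Xa = data.X if alpha_X is None else np.asarray(alpha_X, float)
    Xg = data.X if part2_X is None else np.asarray(part2_X, float)
    pos = data.positive_mask
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("degenerate data: all outcomes are zero; "
                         "a two-part model needs positive outcomes")
    if n_pos == data.n:
        raise ValueError("degenerate data: all outcomes are positive; "
                         "the presence submodel is unidentifiable")
    alpha0 = _fit_logistic(pos.astype(float), Xa)
    beta_logphi = _fit_betareg(data.y[pos], Xg[pos])
    if model_kind == "CTP":
        return np.concatenate([alpha0, beta_logphi])
    if model_kind != "MTP":
        raise ValueError(f"unknown model_kind {model_kind!r}")
    gamma0 = beta_logphi[:-1].copy()
    slack = Xg @ gamma0 - Xa @ alpha0
    worst = float(np.max(slack))
    if worst >= 0.0:
        gamma0[0] -= worst + 1e-3
    return np.concatenate([alpha0, gamma0, [beta_logphi[-1]]])


# ---------------------------------------------------------------------------
# generic maximizer with relative-gradient convergence + Newton polish
# ---------------------------------------------------------------------------

def _rel_gradient(g: np.ndarray, theta: np.ndarray, ll: float) -> float:
    return float(np.max(np.abs(g * theta)) / max(abs(ll), 1.0))


def _fd_hessian(grad_fn: Callable[[np.ndarray], np.ndarray],
                theta: np.ndarray) -> np.ndarray:
    """Central finite differences of the gradient, step ~ eps^(1/3)."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        h = _EPS_CBRT * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp, gm = grad_fn(tp), grad_fn(tm)
        if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
            # boundary proximity: shrink the step
            h *= 1e-2
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            gp, gm = grad_fn(tp), grad_fn(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _maximize(fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
              theta0: np.ndarray, config: FitConfig):
    """Maximize; returns (theta, ll, grad, rel_grad, ok)."""

    def neg(theta):
        ll, g = fun_grad(theta)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        return -ll, -g

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.optimize.minimize(
            neg, theta0, jac=True, method="BFGS",
            options={"gtol": 1e-9, "maxiter": config.max_iter},
        )
    theta = res.x
    ll, g = fun_grad(theta)
    if not np.isfinite(ll):   # optimizer died in the infeasible region
        return theta0, *fun_grad(theta0), np.inf, False

    def grad_only(t):
        return fun_grad(t)[1]

    # Newton polish: quadratic convergence drives the relative gradient
    # below tol when BFGS stalls near the optimum.
    for _ in range(25):
        rel = _rel_gradient(g, theta, ll)
        if rel <= config.rel_gradient_tol and np.max(np.abs(g)) < 1e-5:
            break
        H = _fd_hessian(grad_only, theta)
        try:
            step = np.linalg.solve(H, -g)   # H is d2(loglik), negative definite
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        improved = False
        for _ in range(40):
            cand = theta + t * step
            ll_c, g_c = fun_grad(cand)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-13 * max(abs(ll), 1.0):
                theta, ll, g = cand, ll_c, g_c
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    rel = _rel_gradient(g, theta, ll)
    return theta, ll, g, rel, rel <= config.rel_gradient_tol


def _fit_common(model_kind, fun_grad, theta0, config, data, Xa, X2, names):
    theta, ll, g, rel, ok = _maximize(fun_grad, theta0, config)
    restarts = 0
    if not ok:
        rng = np.random.default_rng(20180723)   # deterministic jitter
        best = (theta, ll, g, rel, ok)
        for r in range(config.fallback_starts):
            restarts += 1
            jitter = 1.0 + 0.1 * rng.standard_normal(theta0.size)
            cand0 = theta0 * jitter + 0.01 * rng.standard_normal(theta0.size)
            out = _maximize(fun_grad, cand0, config)
            if out[4] or (out[1] > best[1] and np.isfinite(out[1])):
                best = out
                if out[4]:
                    break
        theta, ll, g, rel, ok = best
    if not ok:
        logger.warning("%s fit did not meet the relative-gradient criterion "
                       "(rel=%.3g) after %d restarts", model_kind, rel, restarts)

    def grad_only(t):
        return fun_grad(t)[1]

    H = _fd_hessian(grad_only, theta)
    neg_H = -H
    pseudo = False
    try:
        vcov_int = np.linalg.inv(neg_H)
        if np.any(np.diag(vcov_int) <= 0):
            raise np.linalg.LinAlgError("non-PSD curvature")
    except np.linalg.LinAlgError:
        warnings.warn(f"{model_kind} Hessian not positive definite at the "
                      "optimum; using pseudo-inverse covariance")
        vcov_int = np.linalg.pinv(neg_H)
        pseudo = True
    # natural scale: phi = exp(log phi), chain rule on the last row/col
    J = np.ones(theta.size)
    J[-1] = np.exp(theta[-1])
    vcov_nat = vcov_int * np.outer(J, J)

    # quasi-separation / boundary maximum: the relative-gradient
    # criterion is met on a flat likelihood but the MLE does not exist
    # in the interior; a coefficient SE this large carries no
    # information and the fit must not be reported as converged
    if ok and np.any(np.sqrt(np.abs(np.diag(vcov_nat))) > 100.0):
        ok = False
        logger.warning("%s fit flagged non-converged: likelihood maximum "
                       "at the parameter-space boundary (quasi-separation)",
                       model_kind)

    ka = Xa.shape[1]
    if model_kind == "CTP":
        params = CTPParams(theta[:ka], theta[ka:-1], float(np.exp(theta[-1])))
    else:
        params = MTPParams(theta[:ka], theta[ka:-1], float(np.exp(theta[-1])))
    return ModelFit(
        model_kind=model_kind, params=params, loglik=float(ll),
        vcov=vcov_nat, converged=bool(ok), n_used=data.n,
        gradient_norm=float(np.max(np.abs(g))), rel_gradient=float(rel),
        param_names=names, theta_internal=theta, data=data,
        alpha_X=Xa, part2_X=X2, n_restarts=restarts,
        vcov_pseudo_inverse=pseudo,
        message="" if ok else ("boundary maximum (quasi-separation)"
                               if rel <= config.rel_gradient_tol
                               else "relative-gradient criterion not met"),
    )


def _names(prefix2: str, names_a, names_2) -> tuple[str, ...]:
    return (tuple(f"alpha[{n}]" for n in names_a)
            + tuple(f"{prefix2}[{n}]" for n in names_2) + ("phi",))


def fit_ctp(data: TwoPartDataset, config: FitConfig | None = None, *,
            alpha_X: np.ndarray | None = None,
            beta_X: np.ndarray | None = None,
            alpha_names=None, beta_names=None) -> ModelFit:
    """Fit the conventional two-part Beta model by maximum likelihood.

    The likelihood factorizes, so the starting values (standalone
    logistic + Beta-regression MLEs) are already the joint optimum; the
    quasi-Newton pass certifies this against the relative-gradient
    criterion and supplies the joint Hessian-based covariance.
    """
    config = config or FitConfig()
    Xa = data.X if alpha_X is None else np.asarray(alpha_X, float)
    Xb = data.X if beta_X is None else np.asarray(beta_X, float)
    theta0 = starting_values(data, "CTP", alpha_X=Xa, part2_X=Xb)
    ka = Xa.shape[1]

    def fun_grad(theta):
        return _ctp_loglik_grad(theta[:ka], theta[ka:-1], np.exp(theta[-1]),
                                data.y, Xa, Xb)

    names = _names("beta",
                   alpha_names or data.covariate_names[:ka],
                   beta_names or data.covariate_names[:Xb.shape[1]])
    return _fit_common("CTP", fun_grad, theta0, config, data, Xa, Xb, names)


def fit_mtp(data: TwoPartDataset, config: FitConfig | None = None, *,
            alpha_X: np.ndarray | None = None,
            gamma_X: np.ndarray | None = None,
            alpha_names=None, gamma_names=None) -> ModelFit:
    """Fit the marginalized two-part Beta model by maximum likelihood.

    alpha and gamma are coupled through mu = nu/p, so the optimization
    is genuinely joint over (alpha, gamma, log phi); parameter regions
    where some positive outcome implies mu >= 1 carry -inf likelihood
    and the quasi-Newton line search retreats from them.
    """
    config = config or FitConfig()
    Xa = data.X if alpha_X is None else np.asarray(alpha_X, float)
    Xg = data.X if gamma_X is None else np.asarray(gamma_X, float)
    theta0 = starting_values(data, "MTP", alpha_X=Xa, part2_X=Xg)
    ka = Xa.shape[1]

    def fun_grad(theta):
        return _mtp_loglik_grad(theta[:ka], theta[ka:-1], np.exp(theta[-1]),
                                data.y, Xa, Xg)

    names = _names("gamma",
                   alpha_names or data.covariate_names[:ka],
                   gamma_names or data.covariate_names[:Xg.shape[1]])
    return _fit_common("MTP", fun_grad, theta0, config, data, Xa, Xg, names)


def standard_errors(fit: ModelFit) -> np.ndarray:
    """Natural-scale standard errors (phi via the log-scale delta method)."""
    if not fit.converged:
        raise ValueError("standard errors requested from a non-converged fit")
    return np.sqrt(np.diag(fit.vcov))
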