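"""Random-intercept linear mixed models with Satterthwaite F tests.

The stage/size ANCOVA workflow needs many maximum-likelihood fits of one
specific model family — a Gaussian response with fixed effects and a single
random intercept per individual:

    y = X beta + Z u + e,   u ~ N(0, sigma_u^2 I),  e ~ N(0, sigma_e^2 I)

Profiling beta and the residual variance out of the (restricted) likelihood
leaves a 1-D optimisation over the variance ratio
phi = sigma_u^2 / sigma_e^2, which makes a fit essentially instant and lets
the calibration suites run thousands of replicates.  Both REML (default)
and ML estimation are supported: with as few groups as a 25-animal cohort,
ML variance estimates are biased low and Wald F tests built on them are
anticonservative, so inference defaults to REML.  Denominator degrees of
freedom for Wald F tests use the Satterthwaite approximation: for a 1-df
contrast ``l``,

    nu = 2 * (l' C l)^2 / (g' A g)

with ``C = (X' V^-1 X)^-1``, ``g`` the gradient of ``l' C l`` with respect
to the variance components and ``A`` their asymptotic covariance (inverse
observed information of the profile log-likelihood).  Multi-df terms
combine per-eigenvector 1-df values in the usual way.

Boundary fits (sigma_u^2 -> 0) fall back to the ordinary regression with
residual degrees of freedom and are flagged on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptFit", "FTest", "fit_random_intercept", "wald_f"]

_PHI_TOL = 1e-8


@dataclass
class FTest:
    """A Wald F test of a group of fixed-effect coefficients."""

    term: str
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class RandomInterceptFit:
    """Fitted random-intercept model (REML or ML)."""

    beta: np.ndarray
    names: list[str]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int
    boundary: bool
    theta_cov: np.ndarray = field(repr=False, default=None)
    _context: tuple = field(repr=False, default=None)


class _Blocks:
    """Per-group sufficient statistics for the block-diagonal algebra."""

    def __init__(self, y: np.ndarray, x: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.x = x[order]
        g = groups[order]
        _, starts, counts = np.unique(g, return_index=True, return_counts=True)
        self.counts = counts.astype(float)
        self.n = y.size
        self.p = x.shape[1]
        self.k = counts.size
        # group sums of X and y
        idx = np.repeat(np.arange(self.k), counts)
        self.sx = np.zeros((self.k, self.p))
        np.add.at(self.sx, idx, self.x)
        self.sy = np.bincount(idx, weights=self.y, minlength=self.k)
        self.idx = idx
        self.xtx = self.x.T @ self.x
        self.xty = self.x.T @ self.y
        self.yty = float(self.y @ self.y)

    def gls(self, c: np.ndarray):
        """GLS pieces for V0^-1 = I - c_g * J_g per group (unit scale)."""
        xtvx = self.xtx - (self.sx * c[:, None]).T @ self.sx
        xtvy = self.xty - self.sx.T @ (c * self.sy)
        ytvy = self.yty - float(c @ self.sy ** 2)
        return xtvx, xtvy, ytvy


def _profile_ll(blocks: _Blocks, phi: float, reml: bool):
    """Profile log-likelihood at variance ratio phi; returns pieces."""
    c = phi / (1.0 + phi * blocks.counts)
    xtvx, xtvy, ytvy = blocks.gls(c)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - float(beta @ xtvy)          # r' V0^-1 r at the GLS beta
    rss = max(rss, 1e-300)
    n, p = blocks.n, blocks.p
    logdet = float(np.sum(np.log1p(phi * blocks.counts)))
    if reml:
        sigma_e2 = rss / (n - p)
        ll = -0.5 * ((n - p) * math.log(2.0 * math.pi * sigma_e2) + logdet
                     + float(np.linalg.slogdet(xtvx)[1]) + (n - p))
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * math.log(2.0 * math.pi * sigma_e2) + logdet + n)
    return ll, beta, sigma_e2, xtvx


def _loglik_theta(blocks: _Blocks, sigma_u2: float, sigma_e2: float,
                  reml: bool) -> float:
    """Log-likelihood at given variance components (beta profiled)."""
    phi = sigma_u2 / sigma_e2
    c = phi / (1.0 + phi * blocks.counts)
    xtvx, xtvy, ytvy = blocks.gls(c)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - float(beta @ xtvy)
    n = blocks.n
    logdet = n * math.log(sigma_e2) + float(np.sum(np.log1p(phi * blocks.counts)))
    ll = -0.5 * (n * math.log(2.0 * math.pi) + logdet + rss / sigma_e2)
    if reml:
        # restricted likelihood: penalise by the fixed-effects information
        ll -= 0.5 * (float(np.linalg.slogdet(xtvx)[1])
                     - blocks.p * math.log(sigma_e2))
    return ll


def _cov_beta_theta(blocks: _Blocks, sigma_u2: float, sigma_e2: float) -> np.ndarray:
    phi = sigma_u2 / sigma_e2
    c = phi / (1.0 + phi * blocks.counts)
    xtvx, _, _ = blocks.gls(c)
    return sigma_e2 * np.linalg.inv(xtvx)


def fit_random_intercept(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    method: str = "reml",
) -> RandomInterceptFit:
    """Fit ``y ~ X`` with a random intercept per group.

    ``groups`` may be any hashable labels; ``names`` are optional column
    names for the fixed effects.  ``method`` is ``"reml"`` (default; the
    calibrated choice for Wald F tests with few groups) or ``"ml"``.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown estimation method {method!r}")
    reml = method == "reml"
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if x.ndim != 2 or y.size != x.shape[0] or groups.size != y.size:
        raise ValueError("inconsistent shapes for y, X, groups")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("fixed-effects design is rank deficient")
    blocks = _Blocks(y, x, np.unique(groups, return_inverse=True)[1])

    def neg_ll(log_phi: float) -> float:
        return -_profile_ll(blocks, math.exp(log_phi), reml)[0]

    res = minimize_scalar(neg_ll, bounds=(-14.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    ll_opt = -res.fun
    ll0 = _profile_ll(blocks, 0.0, reml)[0]
    if ll0 >= ll_opt - 1e-10 or math.exp(res.x) < _PHI_TOL:
        phi, boundary = 0.0, True
        ll = ll0
    else:
        phi, boundary = math.exp(res.x), False
        ll = ll_opt
    _, beta, sigma_e2, xtvx = _profile_ll(blocks, phi, reml)
    sigma_u2 = phi * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(xtvx)

    theta_cov = None
    if not boundary:
        theta_cov = _theta_cov(blocks, sigma_u2, sigma_e2, reml)
    return RandomInterceptFit(
        beta=beta,
        names=names or [f"x{i}" for i in range(x.shape[1])],
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        loglik=ll,
        cov_beta=cov_beta,
        n_obs=blocks.n,
        n_groups=blocks.k,
        boundary=boundary,
        theta_cov=theta_cov,
        _context=(blocks,),
    )


def _theta_cov(blocks: _Blocks, sigma_u2: float, sigma_e2: float,
               reml: bool) -> np.ndarray:
    """Asymptotic covariance of (sigma_u^2, sigma_e^2) from the observed
    information of the profile log-likelihood (central differences)."""
    theta = np.array([sigma_u2, sigma_e2])
    h = np.maximum(1e-4 * theta, 1e-10)

    def ll(t):
        return _loglik_theta(blocks, max(t[0], 1e-12), max(t[1], 1e-12), reml)

    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            hess[i, j] = hess[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    return cov


def _satterthwaite_1df(fit: RandomInterceptFit, l: np.ndarray) -> float:
    """Satterthwaite denominator df for the 1-df contrast ``l``."""
    if fit.boundary or fit.theta_cov is None:
        return float(fit.n_obs - fit.beta.size)
    (blocks,) = fit._context
    theta = np.array([fit.sigma_u2, fit.sigma_e2])
    h = np.maximum(1e-4 * theta, 1e-10)

    def var_l(t):
        cov = _cov_beta_theta(blocks, max(t[0], 1e-12), max(t[1], 1e-12))
        return float(l @ cov @ l)

    f0 = var_l(theta)
    grad = np.array([
        (var_l(theta + np.eye(2)[i] * h[i]) - var_l(theta - np.eye(2)[i] * h[i]))
        / (2.0 * h[i])
        for i in range(2)
    ])
    with np.errstate(over="ignore", invalid="ignore"):
        denom = float(grad @ fit.theta_cov @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return float(fit.n_obs - fit.beta.size)
    nu = 2.0 * f0 ** 2 / denom
    return float(min(max(nu, 1.0), fit.n_obs - fit.beta.size))


def wald_f(fit: RandomInterceptFit, l_mat: np.ndarray, term: str = "") -> FTest:
    """Wald F test of ``L beta = 0`` with Satterthwaite denominator df.

    Multi-row L is handled by the eigenvector decomposition of ``L C L'``:
    each orthonormalised 1-df contrast gets its own Satterthwaite df and
    the values are combined into a single denominator df.
    """
    l_mat = np.atleast_2d(np.asarray(l_mat, dtype=float))
    q = l_mat.shape[0]
    m = l_mat @ fit.cov_beta @ l_mat.T
    vals, vecs = np.linalg.eigh(m)
    keep = vals > max(vals.max(), 1e-300) * 1e-12
    vals, vecs = vals[keep], vecs[:, keep]
    q_eff = int(vals.size)
    lt = (vecs / np.sqrt(vals)).T @ l_mat     # orthonormalised contrasts
    t2 = (lt @ fit.beta) ** 2
    f_stat = float(np.sum(t2)) / q_eff

    nus = np.array([_satterthwaite_1df(fit, row) for row in lt])
    if q_eff == 1:
        df_den = float(nus[0])
    else:
        ok = nus > 2.0
        if not ok.any():
            df_den = float(fit.n_groups - fit.beta.size) if fit.n_groups > fit.beta.size \
                else float(fit.n_obs - fit.beta.size)
        else:
            e_sum = float(np.sum(nus[ok] / (nus[ok] - 2.0)))
            df_den = (2.0 * e_sum / (e_sum - q_eff)) if e_sum > q_eff else float(
                np.min(nus[ok]))
    df_den = max(df_den, 1.0)
    p = float(stats.f.sf(f_stat, q_eff, df_den))
    return FTest(term=term, f=f_stat, df_num=q_eff, df_den=df_den, p=p)
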