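"""Linear mixed models for node- and link-level landscape-genetic analyses.

Node-level responses (one value per population) are modelled with a landscape
-window random intercept.  Link-level responses (one value per population
pair) additionally carry the maximum-likelihood population-effects (MLPE)
correlation structure: residuals of two pairs that share exactly one
population are correlated with coefficient rho.  All models are estimated by
maximum likelihood (not REML) so that AICc values are comparable across
fixed-effect structures.

The covariance of the response is

    V = sigma2 * ( C(rho) + gamma * Z Z' )

where C(rho) = I + rho * S is the MLPE correlation (S_pq = 1 when pairs p and
q share one population; C = I at the node level), Z is the window-intercept
indicator and gamma = sigma2_w / sigma2.  beta is profiled by GLS and sigma2
in closed form; the remaining one or two variance parameters are optimised
numerically, which keeps every fit deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "FitResult", "box_cox_transform", "standardize", "fit_node_lmm",
    "fit_link_mlpe", "aicc", "lrt", "r2_marginal_conditional",
]


# ---- transforms ----------------------------------------------------------

def box_cox_transform(x: np.ndarray, grid: tuple[float, float, float] = (-3.0, 3.0, 0.05)
                      ) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with lambda chosen by profile likelihood on a grid.

    Non-positive inputs are first shifted by ``1 - min(x)``; the applied shift
    is returned.  Returns ``(y, lambda, shift)`` with y = (x^l - 1)/l, or
    ln(x) at l = 0.
    """
    x = np.asarray(x, dtype=float)
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
        x = x + shift
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    n = len(x)
    logx = np.log(x)
    best_lam, best_ll = 1.0, -np.inf
    for lam in lambdas:
        y = logx if abs(lam) < 1e-12 else (x ** lam - 1.0) / lam
        s2 = y.var()
        if s2 <= 0:
            continue
        ll = -0.5 * n * math.log(s2) + (lam - 1.0) * logx.sum()
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    lam = best_lam
    y = logx if abs(lam) < 1e-12 else (x ** lam - 1.0) / lam
    return y, lam, shift


def standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre and scale to mean 0, SD 1; errors on constant input."""
    x = np.asarray(x, dtype=float)
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - mu) / sd, mu, sd


# ---- fit result ----------------------------------------------------------

@dataclass
class FitResult:
    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    loglik: float
    sigma2: float                # residual variance
    sigma2_w: float              # window-intercept variance
    rho: float                   # MLPE correlation (0 at node level)
    n: int
    k_fixed: int                 # fixed effects incl. intercept
    k_var: int                   # variance parameters counted in AICc
    aicc: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    converged: bool = True
    fitted_fixed: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def k(self) -> int:
        return self.k_fixed + self.k_var

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "b": self.beta, "se": self.se, "p": self.pvalues,
        })


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; undefined (error) when n <= k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def lrt(full: FitResult, reduced: FitResult) -> float:
    """Likelihood-ratio test p-value of nested ML fits (chi2, df = Delta k)."""
    df = full.k - reduced.k
    dev = 2.0 * (full.loglik - reduced.loglik)
    if df < 0 or dev < -1e-6:
        raise ValueError("models are not nested (reduced fits better or has more df)")
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(max(dev, 0.0), df))


def r2_marginal_conditional(fit: FitResult) -> tuple[float, float]:
    """Variance explained by fixed effects alone / fixed plus window intercept."""
    var_f = float(np.var(fit.fitted_fixed))
    total = var_f + fit.sigma2_w + fit.sigma2
    return var_f / total, (var_f + fit.sigma2_w) / total


# ---- core ML machinery ---------------------------------------------------

def _profile_loglik(y: np.ndarray, X: np.ndarray, V0: np.ndarray):
    """GLS beta, profiled sigma2 and the ML log-likelihood given V0."""
    n = len(y)
    cf = linalg.cho_factor(V0, lower=True)
    Xi = linalg.cho_solve(cf, X)
    yi = linalg.cho_solve(cf, y)
    XtVX = X.T @ Xi
    beta = linalg.solve(XtVX, X.T @ yi, assume_a="pos")
    r = y - X @ beta
    ri = linalg.cho_solve(cf, r)
    sigma2 = float(r @ ri) / n
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return beta, sigma2, ll, XtVX


def _finish(y, X, names, V0, gamma, rho, k_var) -> FitResult:
    n, k = X.shape
    beta, sigma2, ll, XtVX = _profile_loglik(y, X, V0)
    cov_beta = sigma2 * linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    df = max(n - k, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    fit = FitResult(
        names=tuple(names), beta=beta, se=se, pvalues=pvals, loglik=ll,
        sigma2=sigma2, sigma2_w=sigma2 * gamma, rho=rho, n=n,
        k_fixed=k, k_var=k_var, fitted_fixed=X @ beta,
    )
    fit.aicc = aicc(ll, fit.k, n)
    fit.r2_marginal, fit.r2_conditional = r2_marginal_conditional(fit)
    return fit


def _window_indicator(windows: Sequence) -> np.ndarray:
    labels = pd.unique(np.asarray(windows))
    Z = np.zeros((len(windows), len(labels)))
    for j, lab in enumerate(labels):
        Z[np.asarray(windows) == lab, j] = 1.0
    return Z


def _check_X(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effects design")


def fit_node_lmm(y: np.ndarray, X: np.ndarray, windows: Sequence,
                 names: Sequence[str] | None = None,
                 fix_gamma: float | None = None) -> FitResult:
    """ML fit of y = X b + window intercept + residual.

    ``X`` must include the intercept column.  Coefficient p-values are Wald
    t-tests with n - k degrees of freedom.  ``fix_gamma`` pins the variance
    ratio sigma2_w / sigma2 instead of profiling it (0 reduces the model to
    OLS with a Gaussian likelihood).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("too few observations for the requested fixed effects")
    _check_X(X)
    if names is None:
        names = [f"x{j}" for j in range(k)]
    Z = _window_indicator(windows)
    ZZt = Z @ Z.T
    I = np.eye(n)

    if fix_gamma is not None:
        fit = _finish(y, X, names, I + fix_gamma * ZZt, fix_gamma, 0.0, k_var=2)
        return fit

    def neg_ll(u: float) -> float:
        gamma = math.exp(u)
        _, _, ll, _ = _profile_loglik(y, X, I + gamma * ZZt)
        return -ll

    # profile over log gamma, including the no-window-variance boundary
    res = optimize.minimize_scalar(neg_ll, bounds=(-14.0, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    u = float(res.x)
    if neg_ll(-30.0) <= res.fun:   # boundary sigma2_w -> 0
        u = -30.0
    gamma = math.exp(u)
    fit = _finish(y, X, names, I + gamma * ZZt, gamma, 0.0, k_var=2)
    fit.converged = bool(res.success)
    return fit


def mlpe_share_matrix(pairs: Sequence[tuple]) -> np.ndarray:
    """S_pq = 1 when two distinct population pairs share exactly one member."""
    pops = sorted({p for pair in pairs for p in pair})
    M = np.zeros((len(pairs), len(pops)))
    pidx = {p: j for j, p in enumerate(pops)}
    for i, (a, b) in enumerate(pairs):
        if a == b:
            raise ValueError("a pair must join two distinct populations")
        M[i, pidx[a]] = 1.0
        M[i, pidx[b]] = 1.0
    S = M @ M.T
    np.fill_diagonal(S, 0.0)
    if (S > 1).any():
        raise ValueError("duplicate population pair in the design")
    return S


def fit_link_mlpe(y: np.ndarray, X: np.ndarray, pairs: Sequence[tuple],
                  windows: Sequence, names: Sequence[str] | None = None,
                  rho_max: float = 0.4999,
                  fix_rho: float | None = None,
                  fix_gamma: float | None = None) -> FitResult:
    """ML fit of a pairwise response with MLPE correlation + window intercept.

    ``pairs`` gives the two population labels of each row; rows sharing one
    population get residual correlation rho.  ``fix_rho``/``fix_gamma`` pin
    variance parameters instead of profiling them; with both fixed at 0 the
    fit reduces to OLS.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("too few observations for the requested fixed effects")
    _check_X(X)
    if names is None:
        names = [f"x{j}" for j in range(k)]
    S = mlpe_share_matrix(pairs)
    Z = _window_indicator(windows)
    ZZt = Z @ Z.T
    I = np.eye(n)

    if fix_rho is not None and fix_gamma is not None:
        return _finish(y, X, names, I + fix_rho * S + fix_gamma * ZZt,
                       fix_gamma, fix_rho, k_var=3)

    def neg_ll(theta) -> float:
        rho, u = theta
        V0 = I + rho * S + math.exp(u) * ZZt
        try:
            _, _, ll, _ = _profile_loglik(y, X, V0)
        except linalg.LinAlgError:
            return 1e10
        return -ll

    best = None
    for rho0 in (0.05, 0.25):
        for u0 in (-4.0, 0.0):
            res = optimize.minimize(
                neg_ll, x0=np.array([rho0, u0]), method="L-BFGS-B",
                bounds=[(0.0, rho_max), (-14.0, 10.0)],
            )
            if best is None or res.fun < best.fun:
                best = res
    rho, u = float(best.x[0]), float(best.x[1])
    if neg_ll([rho, -30.0]) <= best.fun + 1e-10:
        u = -30.0
    gamma = math.exp(u)
    fit = _finish(y, X, names, I + rho * S + gamma * ZZt, gamma, rho, k_var=3)
    fit.converged = bool(best.success) and rho < rho_max - 1e-6
    return fit
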