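"""Gaussian linear mixed models with crossed random intercepts.

The group-level model for per-epoch reconstruction accuracy is

    y = X beta + Z_subject b_s + Z_stimulus b_g + e,
    b_s ~ N(0, sigma_s^2 I),  b_g ~ N(0, sigma_g^2 I),  e ~ N(0, sigma_e^2 I)

with Subject and Stimulus crossed (every subject hears every stimulus).
This module fits such models by profiled (RE)ML and provides the
inferential pieces group analyses need:

* REML or ML estimation via the profiled deviance over relative variance
  ratios, with the Woodbury identity keeping every likelihood evaluation
  O(n q^2) for q total random-effect levels;
* Wald t statistics with Satterthwaite denominator degrees of freedom
  (finite-difference Hessian of the restricted likelihood on the variance
  scale, the same construction lmerTest uses);
* marginal / conditional R^2 by the variance-partition formulas
  (fixed-effect variance over total, plus random-intercept variances);
* likelihood-ratio tests between nested fits.

Fixed effects are supplied as an explicit design matrix; the factor-coding
conveniences live in :mod:`cortrack.stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy import stats as sps

__all__ = ["MixedLMResult", "fit_mixed_lm", "likelihood_ratio"]

_ZERO_GAMMA = 1e-7  # relative variance below this is treated as zero


@dataclass
class MixedLMResult:
    """A fitted crossed-random-intercepts model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    var_components: dict  # factor name -> variance
    loglik: float
    reml: bool
    n: int
    p: int
    converged: bool
    singular: bool
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    Z_list: list = field(repr=False, default_factory=list)
    factor_names: list = field(default_factory=list)
    fitted_fixed: np.ndarray = field(repr=False, default=None)

    # ---- degrees of freedom / tests -------------------------------------

    def _nu_hat(self) -> np.ndarray:
        return np.array([self.var_components[k] for k in self.factor_names] + [self.sigma2])

    def _neg2_reml_at(self, nu: np.ndarray) -> float:
        return _neg2_reml_nu(nu, self.y, self.X, self.Z_list)

    def _cbeta_var(self, c: np.ndarray, nu: np.ndarray) -> float:
        C = _cov_beta_nu(nu, self.X, self.Z_list)
        return float(c @ C @ c)

    def satterthwaite_dof(self, c: np.ndarray) -> float:
        """Satterthwaite denominator dof for the contrast c' beta.

        dof = 2 f^2 / (grad f' A grad f) with f(nu) = c' Cov(beta|nu) c and
        A the asymptotic covariance of the variance estimates nu (twice the
        inverse Hessian of the -2 restricted log-likelihood).  Falls back
        to the residual dof n - p when the curvature is degenerate.
        """
        c = np.asarray(c, dtype=float)
        nu = self._nu_hat()
        free = [i for i in range(len(nu)) if nu[i] > 0 or i == len(nu) - 1]
        if not free:
            return float(self.n - self.p)

        def m_of(theta):
            full = nu.copy()
            full[free] = theta
            return self._neg2_reml_at(full)

        theta = nu[free]
        H = _fd_hessian(m_of, theta)
        try:
            A = 2.0 * linalg.pinvh(H)
        except linalg.LinAlgError:
            return float(self.n - self.p)

        def f_of(theta):
            full = nu.copy()
            full[free] = theta
            return self._cbeta_var(c, full)

        g = _fd_gradient(f_of, theta)
        f0 = self._cbeta_var(c, nu)
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0 or f0 <= 0:
            return float(self.n - self.p)
        dof = 2.0 * f0**2 / denom
        if not np.isfinite(dof) or dof <= 0:
            return float(self.n - self.p)
        return float(min(dof, 1e7))

    def t_test(self, index: int) -> tuple[float, float, float, float, float]:
        """(estimate, se, t, satterthwaite dof, p) for coefficient ``index``."""
        c = np.zeros(self.p)
        c[index] = 1.0
        se = float(np.sqrt(self.cov_beta[index, index]))
        t = float(self.beta[index] / se) if se > 0 else np.nan
        dof = self.satterthwaite_dof(c)
        pval = float(2.0 * sps.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan
        return float(self.beta[index]), se, t, dof, pval

    # ---- variance explained ---------------------------------------------

    def r2(self) -> tuple[float, float]:
        """(marginal, conditional) R^2 by variance partition."""
        var_f = float(np.var(self.fitted_fixed, ddof=1)) if self.p > 1 else 0.0
        var_r = float(sum(self.var_components.values()))
        total = var_f + var_r + self.sigma2
        if total <= 0:
            return 0.0, 0.0
        return var_f / total, (var_f + var_r) / total


def _one_hot(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((codes.size, inv.max() + 1))
    Z[np.arange(codes.size), inv] = 1.0
    return Z


def _profiled_pieces(gammas, y, X, Z_list):
    """Core GLS quantities for V_r = I + sum_k gamma_k Z_k Z_k'."""
    n, p = X.shape
    if len(Z_list) and np.any(np.asarray(gammas) > 0):
        Zsc = np.hstack([np.sqrt(g) * Z for g, Z in zip(gammas, Z_list) if g > 0])
        q = Zsc.shape[1]
        M = np.eye(q) + Zsc.T @ Zsc
        cf = linalg.cho_factor(M, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

        def solveV(A):
            return A - Zsc @ linalg.cho_solve(cf, Zsc.T @ A)

    else:
        logdetV = 0.0

        def solveV(A):
            return A

    ViX = solveV(X)
    Viy = solveV(y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    ytViy = float(y @ Viy)
    beta = linalg.solve(XtViX, XtViy, assume_a="pos")
    rss = max(ytViy - float(XtViy @ beta), 1e-300)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    return beta, rss, logdetV, logdetXtViX, XtViX


def _profiled_neg2ll(gammas, y, X, Z_list, reml):
    n, p = X.shape
    beta, rss, logdetV, logdetXtViX, _ = _profiled_pieces(gammas, y, X, Z_list)
    if reml:
        s2 = rss / (n - p)
        return (n - p) * np.log(2.0 * np.pi * s2) + logdetV + logdetXtViX + (n - p)
    s2 = rss / n
    return n * np.log(2.0 * np.pi * s2) + logdetV + n


def _neg2_reml_nu(nu, y, X, Z_list):
    """-2 restricted log-likelihood on the variance scale (sigma^2 not profiled)."""
    n, p = X.shape
    nu = np.asarray(nu, dtype=float)
    s2 = max(nu[-1], 1e-12)
    gammas = np.clip(nu[:-1], 0.0, None) / s2
    beta, rss, logdetV, logdetXtViX, _ = _profiled_pieces(gammas, y, X, Z_list)
    return (
        (n - p) * np.log(2.0 * np.pi)
        + n * np.log(s2)
        + logdetV
        + (-p * np.log(s2) + logdetXtViX)
        + rss / s2
    )


def _cov_beta_nu(nu, X, Z_list):
    nu = np.asarray(nu, dtype=float)
    s2 = max(nu[-1], 1e-12)
    gammas = np.clip(nu[:-1], 0.0, None) / s2
    n, p = X.shape
    if len(Z_list) and np.any(gammas > 0):
        Zsc = np.hstack([np.sqrt(g) * Z for g, Z in zip(gammas, Z_list) if g > 0])
        M = np.eye(Zsc.shape[1]) + Zsc.T @ Zsc
        cf = linalg.cho_factor(M, lower=True)
        ViX = X - Zsc @ linalg.cho_solve(cf, Zsc.T @ X)
    else:
        ViX = X
    XtViX = X.T @ ViX
    return s2 * linalg.inv(XtViX)


def _fd_gradient(f, x, rel=1e-4):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        h = rel * max(abs(x[i]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0) if i < x.size else xm[i] - h
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _fd_hessian(f, x, rel=1e-3):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = np.array([rel * max(abs(v), 1e-8) for v in x])
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += h[i]
                xpp[j] += h[j]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[i] -= h[i]
                xmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
    return H


def fit_mixed_lm(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray] | None = None,
    reml: bool = True,
) -> MixedLMResult:
    """Fit a Gaussian LMM with crossed random intercepts.

    Parameters
    ----------
    y, X
        Response vector and fixed-effects design matrix (with intercept).
    factors
        Mapping from factor name to a length-n array of level codes; each
        factor contributes one random-intercept variance component.  Empty
        or ``None`` reduces to ordinary least squares.
    reml
        Restricted (default) or full maximum likelihood.  Use ML fits for
        likelihood-ratio tests that compare fixed-effect structures.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with n matching y")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite data")
    n, p = X.shape
    if n <= p:
        raise ValueError("more coefficients than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "fixed-effects design matrix is rank deficient; the data cannot "
            "identify all requested terms (reduce the model or enlarge the study)"
        )
    factors = dict(factors or {})
    names = list(factors)
    Z_list = [_one_hot(np.asarray(factors[k])) for k in names]
    k = len(Z_list)

    if k == 0:
        beta, rss, logdetV, logdetXtViX, XtViX = _profiled_pieces([], y, X, Z_list)
        dof = n - p if reml else n
        s2 = rss / dof
        ll = -0.5 * _profiled_neg2ll([], y, X, Z_list, reml)
        res = MixedLMResult(
            beta=beta,
            cov_beta=s2 * linalg.inv(XtViX),
            sigma2=rss / (n - p),
            var_components={},
            loglik=ll,
            reml=reml,
            n=n,
            p=p,
            converged=True,
            singular=False,
            X=X,
            y=y,
            Z_list=[],
            factor_names=[],
            fitted_fixed=X @ beta,
        )
        return res

    def objective(eta):
        return _profiled_neg2ll(np.exp(eta), y, X, Z_list, reml)

    best = None
    for start in (np.full(k, np.log(0.05)), np.full(k, np.log(0.5)), np.full(k, np.log(5.0))):
        opt = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=[(-16.0, 10.0)] * k,
        )
        if best is None or opt.fun < best.fun:
            best = opt
    converged = bool(best.success) or np.isfinite(best.fun)
    gammas = np.exp(best.x)
    singular = bool(np.any(gammas < _ZERO_GAMMA))
    gammas = np.where(gammas < _ZERO_GAMMA, 0.0, gammas)
    if singular:
        warnings.warn(
            "singular fit: a random-effect variance was pinned at 0", stacklevel=2
        )

    beta, rss, logdetV, logdetXtViX, XtViX = _profiled_pieces(gammas, y, X, Z_list)
    s2 = rss / (n - p) if reml else rss / n
    loglik = -0.5 * _profiled_neg2ll(gammas, y, X, Z_list, reml)
    var_components = {name: float(g * s2) for name, g in zip(names, gammas)}
    cov_beta = _cov_beta_nu(np.array(list(var_components.values()) + [s2]), X, Z_list)
    return MixedLMResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(s2),
        var_components=var_components,
        loglik=float(loglik),
        reml=reml,
        n=n,
        p=p,
        converged=converged,
        singular=singular,
        X=X,
        y=y,
        Z_list=Z_list,
        factor_names=names,
        fitted_fixed=X @ beta,
    )


def likelihood_ratio(full: MixedLMResult, reduced: MixedLMResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns (chisq, dof, p).  Both fits must use the same likelihood type;
    for fixed-effect comparisons that means ML fits.
    """
    if full.reml != reduced.reml:
        raise ValueError("cannot compare an ML fit against a REML fit")
    df_full = full.p + len(full.factor_names)
    df_red = reduced.p + len(reduced.factor_names)
    dof = df_full - df_red
    if dof < 0:
        raise ValueError("models are not nested (reduced model is larger)")
    chisq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if dof == 0:
        if abs(full.loglik - reduced.loglik) < 1e-6:
            return 0.0, 0, 1.0  # identical models
        raise ValueError("models are not nested (no parameter difference)")
    return chisq, dof, float(sps.chi2.sf(chisq, dof))
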