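"""Random-intercept linear mixed models fitted by profiled (RE)ML.

The model is

    y = X beta + Z b + e,      b ~ N(0, tau^2 I_g),  e ~ N(0, sigma^2 I_n),

with one random intercept per group (here: per study participant).  Writing
lambda = tau^2 / sigma^2, the marginal covariance is sigma^2 (I + lambda Z Z'),
block diagonal over groups, so both sigma^2 and beta can be profiled out and
the (restricted) likelihood reduces to a smooth one-dimensional function of
lambda.  This module evaluates that profile on a log-spaced grid — jointly for
every response column sharing the same design — and polishes the optimum by
parabolic interpolation in log10(lambda).

The grid evaluation is fully vectorised across grid points *and* response
columns, which is what makes resampling schemes with tens of thousands of
per-feature refits affordable.  The per-group inverse uses the Woodbury
identity: (I + lambda J)^(-1) = I - c J with c = lambda / (1 + lambda n_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LMMResult", "fit_random_intercept"]

# lambda = tau^2/sigma^2 search grid; 0 (pure OLS) is included explicitly.
_DEFAULT_GRID = np.concatenate([[0.0], np.logspace(-6.0, 4.0, 101)])


@dataclass
class LMMResult:
    """Fits for one or more response columns sharing a design matrix.

    Arrays are indexed ``[coefficient, column]`` (``beta``, ``se``) or
    ``[column]`` (``sigma2``, ``tau2``, ``var_ratio``, ``converged``).
    """

    beta: np.ndarray
    se: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    var_ratio: np.ndarray
    converged: np.ndarray
    n_obs: int
    n_groups: int
    n_params: int
    reml: bool

    @property
    def resid_df(self) -> int:
        return self.n_obs - self.n_params

    @property
    def within_df(self) -> int:
        """Residual df once group means and fixed effects are absorbed."""
        return self.n_obs - self.n_groups - self.n_params + 1


def _sufficient_stats(X, Y, codes, n_groups):
    """Per-group sums and cross-products reused by every grid evaluation."""
    p = X.shape[1]
    f = Y.shape[1]
    xtx = X.T @ X
    xty = X.T @ Y
    yty = np.einsum("nf,nf->f", Y, Y)
    sx = np.zeros((n_groups, p))
    sy = np.zeros((n_groups, f))
    np.add.at(sx, codes, X)
    np.add.at(sy, codes, Y)
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    return xtx, xty, yty, sx, sy, sizes


def _profile(lams, stats, n_obs, reml):
    """-2 profile (restricted) log-likelihood, up to a constant.

    Returns an (L, F) array for L grid points and F response columns.
    """
    xtx, xty, yty, sx, sy, sizes = stats
    p = xtx.shape[0]
    c = lams[:, None] / (1.0 + lams[:, None] * sizes[None, :])  # (L, g)
    a = xtx[None] - np.einsum("gi,lg,gj->lij", sx, c, sx)  # (L, p, p)
    b = xty[None] - np.einsum("gi,lg,gf->lif", sx, c, sy)  # (L, p, F)
    beta = np.linalg.solve(a, b)
    quad = yty[None, :] - np.einsum("lg,gf->lf", c, sy**2)
    rss = quad - np.einsum("lpf,lpf->lf", beta, b)
    rss = np.maximum(rss, np.finfo(float).tiny)
    logdet_v = np.log1p(lams[:, None] * sizes[None, :]).sum(axis=1)  # (L,)
    if reml:
        crit = (n_obs - p) * np.log(rss) + logdet_v[:, None]
        crit = crit + np.linalg.slogdet(a)[1][:, None]
    else:
        crit = n_obs * np.log(rss) + logdet_v[:, None]
    return crit


def _parabolic_refine(grid, crit):
    """Per-column minimiser of the profile, refined in log10(lambda)."""
    idx = np.argmin(crit, axis=0)
    lam = grid[idx]
    # interior points with strictly positive neighbours admit a log-space fit
    interior = (idx >= 2) & (idx <= len(grid) - 2)
    for j in np.nonzero(interior)[0]:
        m = idx[j]
        xs = np.log10(grid[m - 1 : m + 2])
        fs = crit[m - 1 : m + 2, j]
        d1 = (xs[1] - xs[0]) * (fs[1] - fs[2])
        d2 = (xs[1] - xs[2]) * (fs[1] - fs[0])
        denom = d1 - d2
        if abs(denom) > 1e-12:
            xstar = xs[1] - 0.5 * ((xs[1] - xs[0]) * d1 - (xs[1] - xs[2]) * d2) / denom
            lam[j] = 10.0 ** np.clip(xstar, xs[0], xs[2])
    return lam


def _final_fit(lam, stats, n_obs, reml):
    """Exact GLS at per-column lambda; returns beta, se, sigma2."""
    xtx, xty, yty, sx, sy, sizes = stats
    p = xtx.shape[0]
    c = lam[:, None] / (1.0 + lam[:, None] * sizes[None, :])  # (F, g)
    a = xtx[None] - np.einsum("gi,fg,gj->fij", sx, c, sx)  # (F, p, p)
    b = xty.T - np.einsum("gi,fg,gf->fi", sx, c, sy)  # (F, p)
    a_inv = np.linalg.inv(a)
    beta = np.einsum("fij,fj->fi", a_inv, b)
    quad = yty - np.einsum("fg,gf->f", c, sy**2)
    rss = np.maximum(quad - np.einsum("fi,fi->f", beta, b), 0.0)
    sigma2 = rss / (n_obs - p if reml else n_obs)
    var_diag = np.einsum("fii->fi", a_inv)
    se = np.sqrt(np.maximum(sigma2[:, None] * var_diag, 0.0))
    return beta.T, se.T, sigma2


def fit_random_intercept(X, Y, groups, reml=True, var_ratio=None, grid=None):
    """Fit random-intercept LMMs for each column of ``Y`` on a shared design.

    Parameters
    ----------
    X : (n, p) array
        Fixed-effect design matrix (include the intercept column).
    Y : (n,) or (n, f) array
        Response column(s); no missing values (reduce to complete cases
        before calling).
    groups : (n,) array-like
        Group labels defining the random intercepts.
    reml : bool
        Restricted (default) versus full maximum likelihood.
    var_ratio : float, optional
        Fix lambda = tau^2/sigma^2 instead of estimating it; the fit then
        reduces to generalized least squares under the implied covariance.
    grid : array, optional
        Search grid for lambda (must be non-negative, sorted).

    Returns
    -------
    LMMResult
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the sample dimension")
    n, p = X.shape
    f = Y.shape[1]
    codes, uniques = _encode_groups(groups)
    g = len(uniques)
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed effects ({p})")

    stats = _sufficient_stats(X, Y, codes, g)
    converged = np.ones(f, dtype=bool)
    try:
        if var_ratio is not None:
            lam = np.full(f, float(var_ratio))
        else:
            lam_grid = _DEFAULT_GRID if grid is None else np.asarray(grid, float)
            crit = _profile(lam_grid, stats, n, reml)
            bad = ~np.isfinite(crit)
            if bad.any():
                crit = np.where(bad, np.inf, crit)
            lam = _parabolic_refine(lam_grid, crit)
        beta, se, sigma2 = _final_fit(lam, stats, n, reml)
        converged &= np.isfinite(beta).all(axis=0) & np.isfinite(se).all(axis=0)
    except np.linalg.LinAlgError:
        beta = np.full((p, f), np.nan)
        se = np.full((p, f), np.nan)
        sigma2 = np.full(f, np.nan)
        lam = np.full(f, np.nan)
        converged[:] = False

    return LMMResult(
        beta=beta,
        se=se,
        sigma2=sigma2,
        tau2=lam * sigma2,
        var_ratio=lam,
        converged=converged,
        n_obs=n,
        n_groups=g,
        n_params=p,
        reml=reml,
    )


def _encode_groups(groups):
    groups = np.asarray(groups)
    uniques, codes = np.unique(groups, return_inverse=True)
    return codes, uniques
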