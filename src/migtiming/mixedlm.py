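"""Random-intercept linear mixed model with Satterthwaite degrees of freedom.

The timing models only ever need one random effect — an individual-identity
intercept shared across seasons — so the likelihood is written in its
closed per-group form: with ``lambda = sigma_b^2 / sigma_e^2`` and group size
``n_g``,

    (I + lambda J)^-1 = I - lambda/(1 + lambda n_g) J,
    log det(I + lambda J) = log(1 + lambda n_g),

and the scale ``sigma_e^2`` profiles out, leaving a one-dimensional (RE)ML
optimization in ``lambda``.  Per-coefficient degrees of freedom follow
Satterthwaite's approximation: ``df = 2 f^2 / (g' A g)`` with
``f = c' Cov(beta) c``, ``g`` its gradient in the variance components, and
``A`` the inverse observed information of the REML log-likelihood, both
obtained by central finite differences.

A singular random-effect variance (lambda at the zero boundary) falls back to
ordinary least squares with residual degrees of freedom and a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LMMFit:
    params: pd.Series
    se: pd.Series
    df: pd.Series            # Satterthwaite-type per-coefficient df
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    reml: bool
    n_obs: int
    n_groups: int
    ols_fallback: bool
    theta_cov: np.ndarray | None  # covariance of (sigma2_group, sigma2_resid)

    def wald_f(self, names: list[str]) -> tuple[float, float, float, float]:
        """Wald F-test that all listed coefficients are zero.

        Returns (F, df_num, df_den, p); the denominator df is the smallest
        Satterthwaite df among the tested coefficients.
        """
        idx = [list(self.params.index).index(n) for n in names]
        b = self.params.to_numpy()[idx]
        C = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        k = len(idx)
        f_stat = float(b @ np.linalg.solve(C, b)) / k
        df_den = float(min(self.df.iloc[i] for i in idx))
        p = float(stats.f.sf(f_stat, k, df_den))
        return f_stat, float(k), df_den, p


def _group_structure(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(groups)
    sizes = np.bincount(codes)
    return codes, sizes


def _profiled(lam: float, X, y, codes, sizes, reml: bool):
    """GLS quantities at fixed lambda with sigma_e^2 profiled out."""
    n, p = X.shape
    c = lam / (1.0 + lam * sizes)  # per group
    # group sums of rows of X and of y
    Xg = np.zeros((len(sizes), p))
    np.add.at(Xg, codes, X)
    yg = np.bincount(codes, weights=y)
    A = X.T @ X - (Xg * c[:, None]).T @ Xg
    u = X.T @ y - Xg.T @ (c * yg)
    beta = np.linalg.solve(A, u)
    r = y - X @ beta
    rg = np.bincount(codes, weights=r)
    rss = float(r @ r - np.sum(c * rg**2))
    logdet_v = float(np.sum(np.log1p(lam * sizes)))
    dof = n - p if reml else n
    sigma2 = rss / dof
    ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + logdet_v + dof)
    if reml:
        sign, logdet_a = np.linalg.slogdet(A)
        ll -= 0.5 * logdet_a
    return ll, beta, A, sigma2, rss


def _loglik_theta(theta: np.ndarray, X, y, codes, sizes, reml: bool) -> float:
    """(RE)ML log-likelihood as a function of (sigma2_group, sigma2_resid)."""
    s2b, s2e = theta
    if s2e <= 0 or s2b < 0:
        return -np.inf
    lam = s2b / s2e
    n, p = X.shape
    c = lam / (1.0 + lam * sizes)
    Xg = np.zeros((len(sizes), p))
    np.add.at(Xg, codes, X)
    yg = np.bincount(codes, weights=y)
    A = (X.T @ X - (Xg * c[:, None]).T @ Xg) / s2e  # X' V^-1 X
    u = (X.T @ y - Xg.T @ (c * yg)) / s2e
    beta = np.linalg.solve(A, u)
    r = y - X @ beta
    rg = np.bincount(codes, weights=r)
    quad = (r @ r - np.sum(c * rg**2)) / s2e
    logdet_v = n * np.log(s2e) + np.sum(np.log1p(lam * sizes))
    ll = -0.5 * ((n - p if reml else n) * np.log(2 * np.pi) + logdet_v + quad)
    if reml:
        sign, logdet_a = np.linalg.slogdet(A)
        ll -= 0.5 * logdet_a
    return float(ll)


def fit_lmm(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    reml: bool = True,
) -> LMMFit:
    """Fit ``y = X beta + b_group + eps`` and report Satterthwaite inference."""
    names = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    codes, sizes = _group_structure(np.asarray(groups))
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("design matrix is rank-deficient")

    # 1-d profiled search over lambda (log grid + local refinement + boundary)
    def neg(loglam: float) -> float:
        return -_profiled(np.exp(loglam), Xm, yv, codes, sizes, reml)[0]

    grid = np.linspace(-8.0, 8.0, 49)
    vals = [neg(g) for g in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded")
    lam = float(np.exp(res.x))
    ll_lam = -res.fun
    ll_zero = _profiled(0.0, Xm, yv, codes, sizes, reml)[0]
    singular = ll_zero >= ll_lam - 1e-8 or lam < 1e-7

    if singular:
        warnings.warn(
            "random-intercept variance estimated at the zero boundary; "
            "falling back to ordinary least squares",
            stacklevel=2,
        )
        ll, beta, A, sigma2, _ = _profiled(0.0, Xm, yv, codes, sizes, reml)
        cov = sigma2 * np.linalg.inv(Xm.T @ Xm)
        df = np.full(p, float(n - p))
        s2b, s2e = 0.0, sigma2
        theta_cov = None
        ols = True
    else:
        ll, beta, A, sigma2, _ = _profiled(lam, Xm, yv, codes, sizes, reml)
        s2e = sigma2
        s2b = lam * sigma2
        cov = s2e * np.linalg.inv(A)
        theta = np.array([s2b, s2e])

        def cov_fn(th: np.ndarray) -> np.ndarray:
            lam_t = th[0] / th[1]
            c = lam_t / (1.0 + lam_t * sizes)
            Xg = np.zeros((len(sizes), p))
            np.add.at(Xg, codes, Xm)
            At = (Xm.T @ Xm - (Xg * c[:, None]).T @ Xg) / th[1]
            return np.linalg.inv(At)

        # observed information of the REML loglik in theta, by central FD
        h = np.maximum(1e-4 * theta, 1e-10)
        H = np.zeros((2, 2))
        f0 = _loglik_theta(theta, Xm, yv, codes, sizes, True)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                fpp = _loglik_theta(theta + ei + ej, Xm, yv, codes, sizes, True)
                fpm = _loglik_theta(theta + ei - ej, Xm, yv, codes, sizes, True)
                fmp = _loglik_theta(theta - ei + ej, Xm, yv, codes, sizes, True)
                fmm = _loglik_theta(theta - ei - ej, Xm, yv, codes, sizes, True)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            theta_cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            theta_cov = None

        df = np.empty(p)
        for jx in range(p):
            f_val = cov[jx, jx]
            if theta_cov is None:
                df[jx] = n - p
                continue
            grad = np.zeros(2)
            for i in range(2):
                step = np.eye(2)[i] * h[i]
                grad[i] = (cov_fn(theta + step)[jx, jx] - cov_fn(theta - step)[jx, jx]) / (2 * h[i])
            denom = float(grad @ theta_cov @ grad)
            df[jx] = 2 * f_val**2 / denom if denom > 0 else n - p
            df[jx] = float(np.clip(df[jx], 1.0, 10 * n))
        ols = False

    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    idx = pd.Index(names)
    return LMMFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        df=pd.Series(df, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        sigma2_group=float(s2b),
        sigma2_resid=float(s2e),
        loglik=float(ll),
        reml=reml,
        n_obs=n,
        n_groups=len(sizes),
        ols_fallback=ols,
        theta_cov=theta_cov,
    )
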