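"""Vectorized univariable model fits and Wald power arithmetic.

Screening a thousand candidate variables one at a time is the dominant cost of
the baseline (Bonferroni) workflow, so the univariable fits here are vectorized
across columns: one pass fits all p single-predictor models with an intercept.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "univariable_ols",
    "univariable_logistic",
    "univariable_fit",
    "wald_power",
    "wald_se",
]


def univariable_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit y ~ 1 + x_j for every column j by closed form.

    Returns (slopes, standard errors, two-sided p-values). p-values come from
    the t distribution with n-2 degrees of freedom (the usual Wald test for a
    single OLS coefficient).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations for a univariable OLS test")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    if np.any(sxx <= 0):
        bad = int(np.flatnonzero(sxx <= 0)[0])
        raise ValueError(f"constant column at index {bad}")
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, pval


def _score_test_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided score-test p-values for the slope in y ~ 1 + x_j."""
    xc = X - X.mean(axis=0)
    pbar = y.mean()
    u = xc.T @ (y - pbar)
    v = pbar * (1 - pbar) * np.einsum("ij,ij->j", xc, xc)
    z = u / np.sqrt(v)
    return 2.0 * stats.norm.sf(np.abs(z))


def univariable_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    max_abs_beta: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(E y) = a_j + b_j x_j for every column j by vectorized Newton.

    Returns (slopes, Wald standard errors, two-sided Wald p-values). Columns
    where Newton diverges (quasi-separation) fall back to the score test for
    the p-value, with the slope capped; a warning reports how many.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary outcome must be coded 0/1")
    a = np.full(p, np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0)
    b = np.zeros(p)
    for _ in range(max_iter):
        eta = a[None, :] + X * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g_a = r.sum(axis=0)
        g_b = np.einsum("ij,ij->j", X, r)
        h_aa = w.sum(axis=0)
        h_ab = np.einsum("ij,ij->j", X, w)
        h_bb = np.einsum("ij,ij,ij->j", X, X, w)
        det = h_aa * h_bb - h_ab**2
        det = np.where(det <= 1e-300, 1e-300, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a += da
        b += db
        np.clip(b, -max_abs_beta, max_abs_beta, out=b)
        np.clip(a, -max_abs_beta, max_abs_beta, out=a)
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + X * b[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h_aa = w.sum(axis=0)
    h_ab = np.einsum("ij,ij->j", X, w)
    h_bb = np.einsum("ij,ij,ij->j", X, X, w)
    det = h_aa * h_bb - h_ab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = np.where(det > 0, h_aa / det, np.inf)
    se = np.sqrt(var_b)
    z = np.where(se > 0, b / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(np.where(np.isfinite(z), z, 0.0)))
    diverged = (np.abs(b) >= max_abs_beta - 1e-9) | ~np.isfinite(se)
    if np.any(diverged):
        warnings.warn(
            f"{int(diverged.sum())} univariable logistic fits hit the slope cap "
            "(quasi-separation); using score-test p-values for those columns",
            stacklevel=2,
        )
        pval_score = _score_test_logistic(X, y)
        pval = np.where(diverged, pval_score, pval)
    return b, se, pval


def univariable_fit(X, y, family: str):
    """Dispatch to the OLS or logistic univariable fitter by outcome family."""
    if family == "continuous":
        return univariable_ols(X, y)
    if family == "binary":
        return univariable_logistic(X, y)
    raise ValueError(f"unknown family {family!r}")


def wald_se(family: str, n: int, prevalence: float = 0.5) -> float:
    """Asymptotic SE of the slope for a standardized predictor.

    Continuous outcomes with unit error variance give SE = 1/sqrt(n); a binary
    outcome at baseline prevalence pi gives SE = 1/sqrt(n*pi*(1-pi)).
    """
    if family == "continuous":
        return 1.0 / np.sqrt(n)
    if family == "binary":
        return 1.0 / np.sqrt(n * prevalence * (1.0 - prevalence))
    raise ValueError(f"unknown family {family!r}")


def wald_power(beta: float, se: float, alpha: float) -> float:
    """Power of the two-sided Wald test at effect beta and standard error se."""
    z = stats.norm.isf(alpha / 2.0)
    mu = abs(beta) / se
    return float(stats.norm.sf(z - mu) + stats.norm.cdf(-z - mu))
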