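"""Sparse group lasso solver (blockwise proximal coordinate descent).

The penalty combines a group-level L2 term and an element-level L1 term,

    lambda * [ (1 - mix) * sum_g sqrt(p_g) * ||beta_g||_2 + mix * ||beta||_1 ],

so entire groups can be zeroed while selection stays sparse within surviving
groups. The smooth loss is squared error (continuous) or the logistic negative
log-likelihood (binary), both scaled by 1/n, with an unpenalized intercept.
For singleton groups the penalty collapses to lambda*|beta_j| whatever the
mixing weight, so all-singleton problems reproduce the plain lasso with the
same 1/(2n) normalization as scikit-learn's ``Lasso(alpha=lambda)``.

The solver cycles over groups. Singleton groups take an exact coordinate
update (continuous) or a proximal gradient step (binary); multi-member groups
take proximal gradient steps — soft-threshold by ``t*lambda*mix`` elementwise,
then group soft-scale by ``t*lambda*(1-mix)*sqrt(p_g)`` — with step size
t = 1/L_g from the exact group Lipschitz constant, which makes the objective
monotonically non-increasing. Hot loops are numba-compiled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["SGLProblem", "sgl_solve", "sgl_lambda_max", "sgl_path", "sgl_objective"]


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@dataclass
class SGLProblem:
    """Pre-processed problem: columns reordered so groups are contiguous."""

    X: np.ndarray          # n x p, group-contiguous column order (C-contiguous)
    y: np.ndarray
    family: str
    starts: np.ndarray     # group start offsets, len n_groups + 1
    weights: np.ndarray    # sqrt(p_g) per group
    order: np.ndarray      # original column index per reordered column
    lips: np.ndarray       # per-group Lipschitz constant of the smooth loss

    @classmethod
    def build(cls, X, y, family, group_labels) -> "SGLProblem":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        labels = np.asarray(group_labels, dtype=int)
        if labels.shape[0] != X.shape[1]:
            raise ValueError("group labels must cover all columns")
        order = np.argsort(labels, kind="stable")
        sizes = np.bincount(labels[order])
        sizes = sizes[sizes > 0]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        Xo = np.asfortranarray(X[:, order])
        n = X.shape[0]
        lips = np.empty(len(sizes))
        for g in range(len(sizes)):
            Xg = Xo[:, starts[g]: starts[g + 1]]
            if sizes[g] == 1:
                s = float(Xg[:, 0] @ Xg[:, 0]) / n
            else:
                s = np.linalg.norm(Xg, 2) ** 2 / n
            lips[g] = max(s if family == "continuous" else s / 4.0, 1e-12)
        return cls(X=Xo, y=y, family=family, starts=starts.astype(np.int64),
                   weights=np.sqrt(sizes.astype(float)), order=order, lips=lips)

    @property
    def n_groups(self) -> int:
        return len(self.starts) - 1


def sgl_objective(prob: SGLProblem, intercept: float, beta: np.ndarray,
                  lam: float, mix: float) -> float:
    """Penalized objective at (intercept, beta) in the reordered basis."""
    eta = intercept + prob.X @ beta
    n = len(prob.y)
    if prob.family == "continuous":
        loss = 0.5 * np.sum((prob.y - eta) ** 2) / n
    else:
        loss = np.sum(np.logaddexp(0.0, eta) - prob.y * eta) / n
    pen = mix * np.sum(np.abs(beta))
    for g in range(prob.n_groups):
        bg = beta[prob.starts[g]: prob.starts[g + 1]]
        pen += (1.0 - mix) * prob.weights[g] * np.linalg.norm(bg)
    return float(loss + lam * pen)


def sgl_lambda_max(prob: SGLProblem, mix: float) -> float:
    """Smallest lambda at which every group is zero (group KKT threshold)."""
    n = len(prob.y)
    # gradient at beta = 0 with the intercept at its optimum; mu0 is the
    # constant outcome mean for both families
    g0 = -(prob.X.T @ (prob.y - prob.y.mean())) / n
    lam = 0.0
    for g in range(prob.n_groups):
        z = g0[prob.starts[g]: prob.starts[g + 1]]
        w = prob.weights[g]
        if len(z) == 1 or mix >= 1.0:
            lam_g = np.max(np.abs(z))  # singleton: penalty is lam*|beta| for any mix
        elif mix <= 0.0:
            lam_g = np.linalg.norm(z) / w
        else:
            lo, hi = 0.0, np.max(np.abs(z)) / mix + 1e-12
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.linalg.norm(_soft(z, mid * mix)) > mid * (1.0 - mix) * w:
                    lo = mid
                else:
                    hi = mid
            lam_g = hi
        lam = max(lam, lam_g)
    return float(lam)


@njit(cache=False)
def _cd_continuous(X, y, starts, w, lips, lam, mix, tol, max_cycles, b0, beta, r):
    n, _ = X.shape
    G = len(starts) - 1
    cycles = 0
    for _cycle in range(max_cycles):
        cycles += 1
        maxch = 0.0
        for g in range(G):
            s, e = starts[g], starts[g + 1]
            if e - s == 1:
                j = s
                gj = 0.0
                for i in range(n):
                    gj -= X[i, j] * r[i]
                gj /= n
                c = lips[g]
                z = beta[j] - gj / c
                thr = lam / c
                nb = 0.0
                if z > thr:
                    nb = z - thr
                elif z < -thr:
                    nb = z + thr
                d = nb - beta[j]
                if d != 0.0:
                    beta[j] = nb
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    if abs(d) > maxch:
                        maxch = abs(d)
            else:
                t = 1.0 / lips[g]
                for _inner in range(200):
                    nu = 0.0
                    step = 0.0
                    u = np.empty(e - s)
                    for kk in range(e - s):
                        j = s + kk
                        gj = 0.0
                        for i in range(n):
                            gj -= X[i, j] * r[i]
                        gj /= n
                        z = beta[j] - t * gj
                        thr = t * lam * mix
                        uj = 0.0
                        if z > thr:
                            uj = z - thr
                        elif z < -thr:
                            uj = z + thr
                        u[kk] = uj
                        nu += uj * uj
                    nu = np.sqrt(nu)
                    shrink = 0.0
                    if nu > 0.0:
                        shrink = 1.0 - t * lam * (1.0 - mix) * w[g] / nu
                        if shrink < 0.0:
                            shrink = 0.0
                    for kk in range(e - s):
                        j = s + kk
                        d = shrink * u[kk] - beta[j]
                        if d != 0.0:
                            beta[j] = shrink * u[kk]
                            for i in range(n):
                                r[i] -= X[i, j] * d
                        if abs(d) > step:
                            step = abs(d)
                    if step > maxch:
                        maxch = step
                    if step < tol:
                        break
        d0 = 0.0
        for i in range(n):
            d0 += r[i]
        d0 /= n
        b0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > maxch:
            maxch = abs(d0)
        if maxch < tol:
            return b0, cycles
    return b0, -cycles  # negative signals non-convergence


@njit(cache=False)
def _cd_logistic(X, y, starts, w, lips, lam, mix, tol, max_cycles, b0, beta, eta):
    n, _ = X.shape
    G = len(starts) - 1
    cycles = 0
    resid = np.empty(n)  # y - mu
    for _cycle in range(max_cycles):
        cycles += 1
        maxch = 0.0
        for i in range(n):
            resid[i] = y[i] - 1.0 / (1.0 + np.exp(-eta[i]))
        for g in range(G):
            s, e = starts[g], starts[g + 1]
            t = 1.0 / lips[g]
            size = e - s
            n_inner = 1 if size == 1 else 30
            for _inner in range(n_inner):
                nu = 0.0
                step = 0.0
                u = np.empty(size)
                for kk in range(size):
                    j = s + kk
                    gj = 0.0
                    for i in range(n):
                        gj -= X[i, j] * resid[i]
                    gj /= n
                    z = beta[j] - t * gj
                    thr = t * lam * (1.0 if size == 1 else mix)
                    uj = 0.0
                    if z > thr:
                        uj = z - thr
                    elif z < -thr:
                        uj = z + thr
                    u[kk] = uj
                    nu += uj * uj
                nu = np.sqrt(nu)
                shrink = 1.0
                if size > 1:
                    shrink = 0.0
                    if nu > 0.0:
                        shrink = 1.0 - t * lam * (1.0 - mix) * w[g] / nu
                        if shrink < 0.0:
                            shrink = 0.0
                changed = False
                for kk in range(size):
                    j = s + kk
                    d = shrink * u[kk] - beta[j]
                    if d != 0.0:
                        changed = True
                        beta[j] = shrink * u[kk]
                        for i in range(n):
                            eta[i] += X[i, j] * d
                    if abs(d) > step:
                        step = abs(d)
                if changed:
                    for i in range(n):
                        resid[i] = y[i] - 1.0 / (1.0 + np.exp(-eta[i]))
                if step > maxch:
                    maxch = step
                if step < tol:
                    break
        # intercept: gradient step with the global curvature bound 1/4
        d0 = 0.0
        for i in range(n):
            d0 += resid[i]
        d0 = 4.0 * d0 / n
        b0 += d0
        for i in range(n):
            eta[i] += d0
        if abs(d0) > maxch:
            maxch = abs(d0)
        if maxch < tol:
            return b0, cycles
    return b0, -cycles


def sgl_solve(
    prob: SGLProblem,
    lam: float,
    mix: float = 0.95,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    warm: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Minimize the SGL objective at a fixed lambda.

    Returns (intercept, beta) in the reordered basis. ``tol`` bounds the max
    absolute coefficient change over a full cycle; ``max_iter`` bounds the
    number of full cycles.
    """
    X, y = prob.X, prob.y  # X is column-major (fast per-column scans in the kernels)
    continuous = prob.family == "continuous"
    if warm is not None:
        b0, beta = float(warm[0]), warm[1].copy()
    else:
        if continuous:
            b0 = float(y.mean())
        else:
            q = min(max(y.mean(), 1e-10), 1 - 1e-10)
            b0 = float(np.log(q / (1 - q)))
        beta = np.zeros(X.shape[1])
    max_cycles = max(500, max_iter // max(prob.n_groups, 1))
    if continuous:
        r = y - b0 - X @ beta
        b0, cycles = _cd_continuous(prob.X, y, prob.starts, prob.weights, prob.lips,
                                    lam, mix, tol, max_cycles, b0, beta, r)
    else:
        eta = b0 + X @ beta
        b0, cycles = _cd_logistic(prob.X, y, prob.starts, prob.weights, prob.lips,
                                  lam, mix, tol, max_cycles, b0, beta, eta)
    if cycles < 0:
        raise RuntimeError(
            f"SGL solver did not converge within {max_cycles} cycles "
            f"(lambda={lam:.3e}, mix={mix})"
        )
    return float(b0), beta


def sgl_path(
    prob: SGLProblem,
    mix: float,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve along a decreasing lambda path with warm starts.

    Returns (lambdas, intercepts, betas) where betas is (n_lambdas, p) in the
    reordered basis.
    """
    if lambdas is None:
        lmax = max(sgl_lambda_max(prob, mix), 1e-3)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    intercepts = np.empty(len(lambdas))
    betas = np.empty((len(lambdas), prob.X.shape[1]))
    warm = None
    for i, lam in enumerate(lambdas):
        b0, beta = sgl_solve(prob, lam, mix=mix, tol=tol, max_iter=max_iter, warm=warm)
        warm = (b0, beta)
        intercepts[i] = b0
        betas[i] = beta
    return np.asarray(lambdas), intercepts, betas
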