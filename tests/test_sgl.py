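"""Sparse group lasso solver: lasso equivalence, KKT conditions, group sparsity."""
import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import Lasso, LogisticRegression

from censelect.sgl import (
    SGLProblem,
    sgl_lambda_max,
    sgl_objective,
    sgl_path,
    sgl_solve,
)


def _random_problem(rng, n=80, p=12, family="continuous", groups=None):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(p)
    beta[: p // 3] = rng.normal(0, 1, p // 3)
    eta = X @ beta
    if family == "continuous":
        y = eta + rng.standard_normal(n)
    else:
        y = (rng.random(n) < expit(eta)).astype(float)
    labels = np.arange(1, p + 1) if groups is None else groups
    return SGLProblem.build(X, y, family, labels), X, y


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def kkt_violation(prob, b0, beta, lam, mix):
    """Max violation of the SGL stationarity conditions at (b0, beta)."""
    eta = b0 + prob.X @ beta
    n = len(prob.y)
    mu = eta if prob.family == "continuous" else expit(eta)
    grad = -(prob.X.T @ (prob.y - mu)) / n
    viol = abs(np.mean(prob.y - mu))  # unpenalized intercept
    for g in range(prob.n_groups):
        s, e = prob.starts[g], prob.starts[g + 1]
        bg, gg, w = beta[s:e], grad[s:e], prob.weights[g]
        if e - s == 1:
            # singleton: penalty lam*|b| regardless of mix
            if bg[0] == 0.0:
                viol = max(viol, max(abs(gg[0]) - lam, 0.0))
            else:
                viol = max(viol, abs(gg[0] + lam * np.sign(bg[0])))
        elif np.all(bg == 0.0):
            viol = max(viol, max(np.linalg.norm(_soft(gg, lam * mix))
                                 - lam * (1 - mix) * w, 0.0))
        else:
            grp = lam * (1 - mix) * w * bg / np.linalg.norm(bg)
            for j in range(len(bg)):
                if bg[j] == 0.0:
                    viol = max(viol, max(abs(gg[j] + grp[j]) - lam * mix, 0.0))
                else:
                    viol = max(viol, abs(gg[j] + grp[j] + lam * mix * np.sign(bg[j])))
    return viol


class TestLassoEquivalence:
    def test_singleton_mix_zero_is_still_lasso(self):
        # singleton groups collapse to lam*|beta| for ANY mix, including 0
        rng = np.random.default_rng(2)
        prob, X, y = _random_problem(rng)
        lam = 0.05
        for mix in (0.0, 0.5, 1.0):
            b0, beta = sgl_solve(prob, lam, mix=mix, tol=1e-9)
            ref = Lasso(alpha=lam, tol=1e-10, max_iter=100_000).fit(X, y)
            assert np.abs(beta[np.argsort(prob.order)] - ref.coef_).max() < 1e-5

    def test_binary_singleton_matches_saga(self):
        rng = np.random.default_rng(4)
        prob, X, y = _random_problem(rng, family="binary")
        lam = 0.02
        b0, beta = sgl_solve(prob, lam, mix=1.0, tol=1e-10)
        ref = LogisticRegression(l1_ratio=1.0, solver="saga", C=1.0 / (len(y) * lam),
                                 tol=1e-10, max_iter=200_000).fit(X, y)
        assert np.abs(beta[np.argsort(prob.order)] - ref.coef_.ravel()).max() < 1e-4
        assert abs(b0 - ref.intercept_[0]) < 1e-4


class TestLambdaMax:
    @pytest.mark.parametrize("family", ["continuous", "binary"])
    @pytest.mark.parametrize("mix", [0.0, 0.5, 0.95, 1.0])
    def test_zero_at_lambda_max_active_below(self, family, mix):
        rng = np.random.default_rng(7)
        groups = np.repeat(np.arange(1, 5), 3)  # four groups of three
        prob, _, _ = _random_problem(rng, family=family, groups=groups)
        lmax = sgl_lambda_max(prob, mix)
        _, beta_hi = sgl_solve(prob, lmax * 1.001, mix=mix, tol=1e-9)
        assert np.all(beta_hi == 0.0)
        _, beta_lo = sgl_solve(prob, lmax * 0.5, mix=mix, tol=1e-9)
        assert np.any(beta_lo != 0.0)


class TestKKT:
    @pytest.mark.parametrize("family", ["continuous", "binary"])
    def test_stationarity_random_problems(self, family):
        rng = np.random.default_rng(11)
        groups = np.repeat(np.arange(1, 5), 3)
        for trial in range(3):
            prob, _, _ = _random_problem(rng, family=family, groups=groups)
            lmax = sgl_lambda_max(prob, 0.5)
            for lam in (0.5 * lmax, 0.1 * lmax):
                b0, beta = sgl_solve(prob, lam, mix=0.5, tol=1e-10)
                assert kkt_violation(prob, b0, beta, lam, 0.5) < 1e-4

    def test_local_optimality_probe(self):
        rng = np.random.default_rng(13)
        prob, _, _ = _random_problem(rng)
        lam, mix = 0.05, 0.95
        b0, beta = sgl_solve(prob, lam, mix=mix, tol=1e-10)
        f_star = sgl_objective(prob, b0, beta, lam, mix)
        assert f_star <= sgl_objective(prob, float(prob.y.mean()),
                                       np.zeros_like(beta), lam, mix) + 1e-12
        for _ in range(20):
            d = rng.standard_normal(len(beta)) * 1e-3
            assert f_star <= sgl_objective(prob, b0, beta + d, lam, mix) + 1e-12


class TestGroupStructure:
    def test_within_group_sparsity(self):
        # one strong signal inside a 5-member group: at moderate lambda the
        # group survives but some members are zeroed by the L1 part
        rng = np.random.default_rng(17)
        n, p = 300, 10
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 1.5 * X[:, 0] + rng.standard_normal(n)
        labels = np.array([1] * 5 + list(range(2, 7)))
        prob = SGLProblem.build(X, y, "continuous", labels)
        lmax = sgl_lambda_max(prob, 0.5)
        _, beta = sgl_solve(prob, 0.3 * lmax, mix=0.5, tol=1e-9)
        coef = np.empty(p)
        coef[prob.order] = beta
        assert coef[0] != 0.0
        assert np.any(coef[1:5] == 0.0)

    def test_path_warm_starts_match_cold(self):
        rng = np.random.default_rng(19)
        groups = np.repeat(np.arange(1, 5), 3)
        prob, _, _ = _random_problem(rng, groups=groups)
        lambdas, b0s, betas = sgl_path(prob, mix=0.95, n_lambdas=8,
                                       lambda_min_ratio=0.05, tol=1e-10)
        for i in (3, 7):
            b0c, bc = sgl_solve(prob, lambdas[i], mix=0.95, tol=1e-10)
            assert np.abs(betas[i] - bc).max() < 1e-6

    def test_bad_labels_raise(self, rng):
        X = rng.standard_normal((30, 4))
        with pytest.raises(ValueError, match="cover"):
            SGLProblem.build(X, rng.standard_normal(30), "continuous", [1, 1, 2])
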