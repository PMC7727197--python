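"""Regression-based selection: univariable screening, lasso / elastic net with
cross-validated penalties (min and 1SE rules), and the clustered sparse group
lasso.

All estimators follow the scikit-learn selector protocol: ``fit(X, y)`` sets
``support_`` / ``selected_``, and ``get_support()`` / ``transform`` behave as
for any feature selector. Lasso and elastic net solve

    min_beta  (1/2n) sum_i (y_i - x_i' beta)^2
              + lambda * ( (1-alpha)/2 * ||beta||_2^2 + alpha * ||beta||_1 )

(logistic deviance replacing squared error for binary outcomes). lambda is
chosen by K-fold cross-validation at the minimum prediction error, or by the
stricter one-standard-error rule: the largest lambda whose CV error is within
one SE of the minimum. The elastic-net mixing alpha runs over a grid
(default 0.05 to 0.95 by 0.05) with the fold assignment shared across the
whole grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, LogisticRegression, enet_path
from sklearn.model_selection import KFold

from ._glm import univariable_fit
from .cluster import ClusterAssignment, bootstrap_clusters, hierarchical_clusters, spearman_distance_matrix
from .selection import BaseSelector, SelectionResult
from .sgl import SGLProblem, sgl_lambda_max, sgl_path, sgl_solve
from .simdata import CovariateMatrix

__all__ = [
    "PenalizedPath",
    "UnivariableScreen",
    "PenalizedSelectorCV",
    "SparseGroupLassoCV",
    "HierarchicalSGL",
    "univ_screen",
    "fit_penalized_cv",
    "sgl_fit",
    "hclst_sgl",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
_ZERO_TOL = 1e-8


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CovariateMatrix) else np.asarray(X, dtype=float)


@dataclass
class PenalizedPath:
    """CV error profile along the winning alpha's lambda path."""

    alpha: float
    lambda_grid: np.ndarray
    cv_error_mean: np.ndarray
    cv_error_se: np.ndarray
    chosen_lambda_min: float
    chosen_lambda_1se: float

    def __post_init__(self):
        if self.chosen_lambda_1se < self.chosen_lambda_min - 1e-12:
            raise ValueError("lambda_1se must be >= lambda_min")


class UnivariableScreen(BaseSelector):
    """Bonferroni-corrected univariable screening (the GWAS-style baseline).

    One model with an intercept is fitted per variable; variables whose
    two-sided Wald p-value falls below ``p_threshold`` (default 0.05/p) are
    selected.
    """

    def __init__(self, family: str = "continuous", p_threshold: float | None = None,
                 family_wise_alpha: float = 0.05):
        self.family = family
        self.p_threshold = p_threshold
        self.family_wise_alpha = family_wise_alpha

    method_id = "UNIV-BFN"

    def fit(self, X, y):
        V = _values(X)
        est, se, pval = univariable_fit(V, np.asarray(y, dtype=float), self.family)
        thr = self.p_threshold if self.p_threshold is not None else self.family_wise_alpha / V.shape[1]
        self.estimates_, self.standard_errors_, self.pvalues_ = est, se, pval
        self.threshold_ = float(thr)
        return self._finalize(V, pval < thr)


def _binary_deviance(y, eta):
    return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)


class PenalizedSelectorCV(BaseSelector):
    """Lasso / elastic net selection with cross-validated (alpha, lambda).

    ``alpha_grid=(1.0,)`` is the lasso; the default grid 0.05–0.95 by 0.05 is
    the elastic net. ``rule`` picks lambda at the CV minimum ('min') or by the
    one-standard-error rule ('1se'). Continuous fits use coordinate-descent
    paths; binary fits use saga with warm starts along the path.
    """

    def __init__(self, family: str = "continuous", alpha_grid=(1.0,), rule: str = "min",
                 n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
                 cv: int = 10, random_state: int | None = 0, max_iter: int = 100_000):
        self.family = family
        self.alpha_grid = alpha_grid
        self.rule = rule
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter

    @property
    def method_id(self) -> str:
        base = "LASSO" if tuple(self.alpha_grid) == (1.0,) else "ELNET"
        return f"{base}-{'1SE' if self.rule == '1se' else 'MIN'}"

    def _lambda_grid(self, X, y, alpha):
        n = len(y)
        if self.family == "continuous":
            g0 = X.T @ (y - y.mean()) / n
        else:
            g0 = X.T @ (y - y.mean()) / n
        lmax = np.max(np.abs(g0)) / max(alpha, 0.05)
        lmax = max(lmax, 1e-6)
        return np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambdas)

    def _cv_errors_continuous(self, X, y, alpha, lambdas, folds):
        errs = np.zeros((len(folds), len(lambdas)))
        for f, (tr, te) in enumerate(folds):
            Xtr, ytr = X[tr], y[tr]
            xm, ym = Xtr.mean(axis=0), ytr.mean()
            _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=alpha,
                                    alphas=lambdas, max_iter=self.max_iter)
            pred = ym + (X[te] - xm) @ coefs  # (n_te, n_lambdas)
            errs[f] = np.mean((y[te][:, None] - pred) ** 2, axis=0)
        return errs

    def _cv_errors_binary(self, X, y, alpha, lambdas, folds):
        errs = np.zeros((len(folds), len(lambdas)))
        for f, (tr, te) in enumerate(folds):
            clf = LogisticRegression(solver="saga", l1_ratio=alpha,
                                     warm_start=True, max_iter=2000, tol=1e-6)
            for i, lam in enumerate(lambdas):
                clf.C = 1.0 / (len(tr) * lam)
                clf.fit(X[tr], y[tr])
                eta = clf.decision_function(X[te])
                errs[f, i] = _binary_deviance(y[te], eta) / len(te)
        return errs

    def fit(self, X, y):
        V = _values(X)
        y = np.asarray(y, dtype=float)
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(V))
        best = None
        for alpha in self.alpha_grid:
            lambdas = self._lambda_grid(V, y, alpha)
            if self.family == "continuous":
                errs = self._cv_errors_continuous(V, y, alpha, lambdas, folds)
            else:
                errs = self._cv_errors_binary(V, y, alpha, lambdas, folds)
            mean = errs.mean(axis=0)
            se = errs.std(axis=0, ddof=1) / np.sqrt(len(folds))
            i_min = int(np.argmin(mean))
            if best is None or mean[i_min] < best[0]:
                best = (mean[i_min], alpha, lambdas, mean, se, i_min)
        _, alpha, lambdas, mean, se, i_min = best
        within = np.flatnonzero(mean <= mean[i_min] + se[i_min])
        i_1se = int(within[0])  # lambdas decreasing: first index = largest lambda
        self.path_ = PenalizedPath(
            alpha=float(alpha), lambda_grid=lambdas, cv_error_mean=mean, cv_error_se=se,
            chosen_lambda_min=float(lambdas[i_min]), chosen_lambda_1se=float(lambdas[i_1se]),
        )
        lam = lambdas[i_1se] if self.rule == "1se" else lambdas[i_min]
        self.alpha_, self.lambda_ = float(alpha), float(lam)
        if self.family == "continuous":
            model = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=self.max_iter)
            model.fit(V, y)
            self.coef_, self.intercept_ = model.coef_.copy(), float(model.intercept_)
        else:
            clf = LogisticRegression(solver="saga", l1_ratio=alpha,
                                     C=1.0 / (len(y) * lam), max_iter=5000, tol=1e-7)
            clf.fit(V, y)
            self.coef_, self.intercept_ = clf.coef_.ravel().copy(), float(clf.intercept_[0])
        return self._finalize(V, np.abs(self.coef_) > _ZERO_TOL)


class SparseGroupLassoCV(BaseSelector):
    """Sparse group lasso with lambda chosen by K-fold CV at the minimum error.

    ``groups`` is a ClusterAssignment or an integer label vector (None means
    all singletons). ``mix`` trades the element-level L1 penalty (mix = 1,
    plain lasso) against the group-level L2 penalty (mix = 0, group lasso).
    """

    def __init__(self, family: str = "continuous", groups=None, mix: float = 0.95,
                 n_lambdas: int = 100, lambda_min_ratio: float = 1e-3, cv: int = 10,
                 random_state: int | None = 0, tol: float = 1e-7, max_iter: int = 100_000):
        self.family = family
        self.groups = groups
        self.mix = mix
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    method_id = "HCLST-CORR-SGL"

    def _labels(self, p: int) -> np.ndarray:
        if self.groups is None:
            return np.arange(1, p + 1)
        if isinstance(self.groups, ClusterAssignment):
            return self.groups.group_id
        return np.asarray(self.groups, dtype=int)

    def fit(self, X, y):
        V = _values(X)
        y = np.asarray(y, dtype=float)
        labels = self._labels(V.shape[1])
        prob_full = SGLProblem.build(V, y, self.family, labels)
        lmax = sgl_lambda_max(prob_full, self.mix)
        lambdas = np.geomspace(max(lmax, 1e-6), max(lmax, 1e-6) * self.lambda_min_ratio,
                               self.n_lambdas)
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        errs = np.zeros((self.cv, len(lambdas)))
        for f, (tr, te) in enumerate(kf.split(V)):
            prob = SGLProblem.build(V[tr], y[tr], self.family, labels)
            _, b0s, betas = sgl_path(prob, self.mix, lambdas=lambdas,
                                     tol=max(self.tol, 1e-6), max_iter=self.max_iter)
            Xte = V[te][:, prob.order]
            eta = b0s[None, :] + Xte @ betas.T
            if self.family == "continuous":
                errs[f] = np.mean((y[te][:, None] - eta) ** 2, axis=0)
            else:
                errs[f] = np.array([_binary_deviance(y[te], eta[:, i]) / len(te)
                                    for i in range(len(lambdas))])
        mean = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(self.cv)
        i_min = int(np.argmin(mean))
        self.lambda_path_, self.cv_error_mean_, self.cv_error_se_ = lambdas, mean, se
        self.lambda_ = float(lambdas[i_min])
        # warm-started refit on the full data down to the chosen lambda
        _, b0s, betas = sgl_path(prob_full, self.mix, lambdas=lambdas[: i_min + 1],
                                 tol=self.tol, max_iter=self.max_iter)
        coef = np.empty(V.shape[1])
        coef[prob_full.order] = betas[-1]
        self.coef_, self.intercept_ = coef, float(b0s[-1])
        self.group_labels_ = labels
        return self._finalize(V, np.abs(coef) > _ZERO_TOL)


class HierarchicalSGL(BaseSelector):
    """Cluster variables (threshold or bootstrap), then sparse group lasso.

    The discovery-set pipeline of the clustered penalized approach: complete
    linkage on 1 - |rho_S|, groups from a dendrogram cut (default |rho| > 0.8)
    or bootstrap stability, then SGL with CV-chosen lambda.
    """

    def __init__(self, family: str = "continuous", cluster_method: str = "corr_threshold",
                 cut_height: float = 0.2, mix: float = 0.95, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-3, cv: int = 10, bootstrap_B: int = 1000,
                 stability_threshold: float = 0.95, random_state: int | None = 0,
                 tol: float = 1e-7, max_iter: int = 100_000):
        self.family = family
        self.cluster_method = cluster_method
        self.cut_height = cut_height
        self.mix = mix
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.bootstrap_B = bootstrap_B
        self.stability_threshold = stability_threshold
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    @property
    def method_id(self) -> str:
        return "HCLST-BOOT-SGL" if self.cluster_method == "bootstrap" else "HCLST-CORR-SGL"

    def fit(self, X, y):
        V = _values(X)
        if self.cluster_method == "bootstrap":
            assignment = bootstrap_clusters(V, B=self.bootstrap_B,
                                            stability_threshold=self.stability_threshold,
                                            cut_height=self.cut_height,
                                            seed=self.random_state or 0)
        else:
            D = spearman_distance_matrix(V)
            assignment = hierarchical_clusters(D, cut_height=self.cut_height)
        self.clusters_ = assignment
        inner = SparseGroupLassoCV(family=self.family, groups=assignment, mix=self.mix,
                                   n_lambdas=self.n_lambdas,
                                   lambda_min_ratio=self.lambda_min_ratio, cv=self.cv,
                                   random_state=self.random_state, tol=self.tol,
                                   max_iter=self.max_iter)
        inner.fit(V, y)
        self.sgl_ = inner
        self.coef_, self.intercept_ = inner.coef_, inner.intercept_
        self.lambda_ = inner.lambda_
        return self._finalize(V, inner.support_)


# ---------------------------------------------------------------------------
# thin functional wrappers

def univ_screen(X, y, family: str, p_threshold: float | None = None) -> SelectionResult:
    est = UnivariableScreen(family=family, p_threshold=p_threshold).fit(X, y)
    return SelectionResult("UNIV-BFN", est.selected_,
                           tuning={"p_threshold": est.threshold_})


def fit_penalized_cv(X, y, family: str, alpha_grid=(1.0,), rule: str = "min",
                     folds: int = 10, seed: int | None = 0,
                     **kw) -> tuple[SelectionResult, PenalizedPath]:
    est = PenalizedSelectorCV(family=family, alpha_grid=alpha_grid, rule=rule,
                              cv=folds, random_state=seed, **kw).fit(X, y)
    res = SelectionResult(est.method_id, est.selected_,
                          tuning={"alpha": est.alpha_, "lambda": est.lambda_,
                                  "folds": folds, "seed": seed})
    return res, est.path_


def sgl_fit(X, y, family: str, groups, mix: float = 0.95, lambda_grid=None,
            folds: int = 10, seed: int | None = 0, **kw) -> SelectionResult:
    est = SparseGroupLassoCV(family=family, groups=groups, mix=mix, cv=folds,
                             random_state=seed, **kw)
    if lambda_grid is not None:  # fixed-grid variant used for solver cross-checks
        est.n_lambdas = len(lambda_grid)
    est.fit(X, y)
    return SelectionResult("HCLST-CORR-SGL", est.selected_,
                           tuning={"mix": mix, "lambda": est.lambda_,
                                   "folds": folds, "seed": seed})


def hclst_sgl(X, y, family: str, cluster_method: str = "corr_threshold",
              seed: int | None = 0, **kw) -> SelectionResult:
    est = HierarchicalSGL(family=family, cluster_method=cluster_method,
                          random_state=seed, **kw).fit(X, y)
    return SelectionResult(est.method_id, est.selected_,
                           tuning={"mix": est.mix, "lambda": est.lambda_,
                                   "cut_height": est.cut_height, "seed": seed})
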