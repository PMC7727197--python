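"""Tree-ensemble variable selection.

Two families of selection rules are implemented:

* Random forests / bagging with permutation variable importance (VIMP) and
  subsampling-based standard errors. A variable is selected when its
  100*(1 - alpha/p)% normal-approximation confidence interval lies strictly
  above zero — a Bonferroni-style adjustment of the CI level rather than of a
  p-value. Bagging is the special case where every split considers all p
  variables; random forests consider p/3 (regression) or sqrt(p)
  (classification) candidates per split.

* BART with permutation-null thresholds on the variable inclusion
  proportions: refitting the sampler on outcome-permuted data P times yields
  a null distribution per variable, and three increasingly strict criteria
  (local quantile, global SE multiplier, global max) decide selection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .bart import BartParams, bart_inclusion_proportions
from .selection import BaseSelector, SelectionResult
from .simdata import CovariateMatrix

__all__ = [
    "VimpEstimate",
    "InclusionProfile",
    "rf_vimp",
    "vimp_ci_select",
    "bart_fit",
    "bart_permutation_null",
    "bart_select",
    "VimpSelector",
    "BartSelector",
]


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CovariateMatrix) else np.asarray(X, dtype=float)


@dataclass
class VimpEstimate:
    """Per-variable permutation importance with subsampling standard errors."""

    importance: np.ndarray
    standard_error: np.ndarray
    ci_level: float
    mode: str

    def ci(self, alpha: float, p: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        p = p if p is not None else len(self.importance)
        z = stats.norm.isf(alpha / p / 2.0)
        return self.importance - z * self.standard_error, self.importance + z * self.standard_error


@dataclass
class InclusionProfile:
    """Observed BART inclusion proportions and the permutation-null matrix."""

    proportions: np.ndarray
    null_matrix: np.ndarray | None = None

    @property
    def n_permutations(self) -> int:
        return 0 if self.null_matrix is None else self.null_matrix.shape[0]


# ---------------------------------------------------------------------------
# random forest / bagging VIMP


def _max_features(mode: str, family: str, p: int):
    if mode == "bagging":
        return None
    return max(1, p // 3) if family == "continuous" else max(1, int(np.sqrt(p)))


def _oob_vimp(X, y, family, mode, n_trees, rng) -> np.ndarray:
    """Permutation importance from out-of-bag prediction degradation.

    For each tree: baseline OOB error, then the error after permuting one
    column among OOB rows; the importance is the mean degradation over trees.
    Error is MSE (continuous) or misclassification rate (binary).
    """
    n, p = X.shape
    mf = _max_features(mode, family, p)
    Tree = DecisionTreeRegressor if family == "continuous" else DecisionTreeClassifier
    vimp = np.zeros(p)
    counts = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        if oob.sum() < 2:
            continue
        tree = Tree(max_features=mf, random_state=int(rng.integers(2**31)))
        tree.fit(X[boot], y[boot])
        Xo, yo = X[oob], y[oob]
        pred = tree.predict(Xo)
        if family == "continuous":
            base = np.mean((yo - pred) ** 2)
        else:
            base = np.mean(yo != pred)
        perm = rng.permutation(len(yo))
        Xp = Xo.copy()
        for j in range(p):
            saved = Xp[:, j].copy()
            Xp[:, j] = saved[perm]
            pj = tree.predict(Xp)
            err = np.mean((yo - pj) ** 2) if family == "continuous" else np.mean(yo != pj)
            vimp[j] += err - base
            counts[j] += 1
            Xp[:, j] = saved
    return vimp / np.maximum(counts, 1)


def rf_vimp(
    X,
    y,
    family: str,
    mode: str = "forest",
    n_trees: int = 1000,
    seed: int = 0,
    n_subsamples: int = 100,
    subsample_exponent: float = 0.75,
    alpha: float = 0.05,
) -> VimpEstimate:
    """Permutation VIMP with delete-d jackknife standard errors.

    SEs come from refitting the ensemble on ``n_subsamples`` subsamples of
    size m = ceil(n^0.75) drawn without replacement:
    SE^2 = (m/(n-m)) * var over subsamples of the subsample VIMP.
    """
    if n_trees < 250:
        raise ValueError("n_trees must be >= 250 for stable VIMP estimates")
    if mode not in ("forest", "bagging"):
        raise ValueError(f"unknown mode {mode!r}")
    V = _values(X)
    y = np.asarray(y, dtype=float)
    n, p = V.shape
    m = int(np.ceil(n**subsample_exponent))
    if m >= n or m < 10:
        raise ValueError(f"subsample size {m} unusable for n={n}")
    rng = np.random.default_rng(seed)
    imp = _oob_vimp(V, y, family, mode, n_trees, rng)
    sub = np.empty((n_subsamples, p))
    for b in range(n_subsamples):
        rows = rng.choice(n, size=m, replace=False)
        sub[b] = _oob_vimp(V[rows], y[rows], family, mode, n_trees, rng)
    var = (m / (n - m)) * sub.var(axis=0, ddof=1)
    return VimpEstimate(importance=imp, standard_error=np.sqrt(var),
                        ci_level=1.0 - alpha / p, mode=mode)


def vimp_ci_select(v: VimpEstimate, alpha: float, p: int) -> SelectionResult:
    """Select variables whose 100*(1-alpha/p)% CI lies strictly above zero."""
    lower, _ = v.ci(alpha, p)
    idx = np.flatnonzero(lower > 0)
    method = "BAGGING" if v.mode == "bagging" else "RF"
    return SelectionResult(method, idx, tuning={"alpha": alpha, "p": p,
                                                "ci_level": 1.0 - alpha / p})


class VimpSelector(BaseSelector):
    """Random forest / bagging selection by VIMP confidence intervals."""

    def __init__(self, family: str = "continuous", mode: str = "forest",
                 n_trees: int = 1000, alpha: float = 0.05,
                 n_subsamples: int = 100, random_state: int = 0):
        self.family = family
        self.mode = mode
        self.n_trees = n_trees
        self.alpha = alpha
        self.n_subsamples = n_subsamples
        self.random_state = random_state

    @property
    def method_id(self) -> str:
        return "BAGGING" if self.mode == "bagging" else "RF"

    def fit(self, X, y):
        V = _values(X)
        self.vimp_ = rf_vimp(V, y, self.family, mode=self.mode, n_trees=self.n_trees,
                             seed=self.random_state, n_subsamples=self.n_subsamples,
                             alpha=self.alpha)
        lower, _ = self.vimp_.ci(self.alpha, V.shape[1])
        return self._finalize(V, lower > 0)


# ---------------------------------------------------------------------------
# BART permutation thresholds


def bart_fit(X, y, family: str, n_trees: int = 20, n_burn: int = 1000,
             n_post: int = 1000, seed: int = 0) -> InclusionProfile:
    """Observed inclusion proportions from one BART fit."""
    params = BartParams(n_trees=n_trees, n_burn=n_burn, n_post=n_post)
    props = bart_inclusion_proportions(_values(X), y, family, params, seed=seed)
    return InclusionProfile(proportions=props)


def bart_permutation_null(X, y, family: str, P: int = 100, seed: int = 0,
                          n_trees: int = 20, n_burn: int = 1000,
                          n_post: int = 1000) -> InclusionProfile:
    """Null inclusion proportions from P refits on outcome-permuted data."""
    if P < 1:
        raise ValueError("need at least one permutation")
    V = _values(X)
    y = np.asarray(y, dtype=float)
    params = BartParams(n_trees=n_trees, n_burn=n_burn, n_post=n_post)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(P):
        yp = y[rng.permutation(len(y))]
        rows.append(bart_inclusion_proportions(V, yp, family, params,
                                               seed=int(rng.integers(2**31))))
    return InclusionProfile(proportions=None, null_matrix=np.vstack(rows))


def _global_se_multiplier(null: np.ndarray, m, s, alpha: float) -> float:
    """Smallest C such that >= 1-alpha of permutation rows satisfy
    null[i, j] <= m_j + C * s_j for every j simultaneously."""
    safe_s = np.where(s > 0, s, np.inf)  # degenerate columns: threshold is m_j
    need = (null - m[None, :]) / safe_s[None, :]
    per_row = need.max(axis=1)
    return float(np.quantile(per_row, 1.0 - alpha, method="higher"))


def bart_select(profile: InclusionProfile, criterion: str = "local",
                alpha: float = 0.05) -> SelectionResult:
    """Apply one of the three permutation-null thresholds.

    local: per-variable 1-alpha null quantile. global_max: 1-alpha quantile
    of the row-wise maxima (family-wise control). global_se: m_j + C* s_j
    with the smallest global multiplier C* covering 1-alpha of permutations.
    """
    if profile.null_matrix is None:
        raise ValueError("profile must carry a permutation null matrix")
    null = profile.null_matrix
    props = profile.proportions
    if criterion == "local":
        thr = np.quantile(null, 1.0 - alpha, axis=0, method="higher")
        method = "BART-LOCAL"
    elif criterion == "global_max":
        thr = np.full(null.shape[1], np.quantile(null.max(axis=1), 1.0 - alpha,
                                                 method="higher"))
        method = "BART-GLOBALMAX"
    elif criterion == "global_se":
        m, s = null.mean(axis=0), null.std(axis=0, ddof=1)
        cstar = _global_se_multiplier(null, m, s, alpha)
        thr = m + cstar * np.where(s > 0, s, 0.0)
        method = "BART-GLOBALSE"
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    idx = np.flatnonzero(props > thr)
    return SelectionResult(method, idx, tuning={"alpha": alpha, "criterion": criterion,
                                                "P": profile.n_permutations})


class BartSelector(BaseSelector):
    """BART selection via permutation-null thresholds on inclusion proportions."""

    def __init__(self, family: str = "continuous", criterion: str = "local",
                 alpha: float = 0.05, n_trees: int = 20, n_burn: int = 1000,
                 n_post: int = 1000, n_permutations: int = 100, random_state: int = 0):
        self.family = family
        self.criterion = criterion
        self.alpha = alpha
        self.n_trees = n_trees
        self.n_burn = n_burn
        self.n_post = n_post
        self.n_permutations = n_permutations
        self.random_state = random_state

    @property
    def method_id(self) -> str:
        return {"local": "BART-LOCAL", "global_se": "BART-GLOBALSE",
                "global_max": "BART-GLOBALMAX"}[self.criterion]

    def fit(self, X, y):
        V = _values(X)
        obs = bart_fit(V, y, self.family, n_trees=self.n_trees, n_burn=self.n_burn,
                       n_post=self.n_post, seed=self.random_state)
        null = bart_permutation_null(V, y, self.family, P=self.n_permutations,
                                     seed=self.random_state + 1, n_trees=self.n_trees,
                                     n_burn=self.n_burn, n_post=self.n_post)
        self.profile_ = InclusionProfile(proportions=obs.proportions,
                                         null_matrix=null.null_matrix)
        res = bart_select(self.profile_, criterion=self.criterion, alpha=self.alpha)
        mask = np.zeros(V.shape[1], dtype=bool)
        mask[res.selected_discovery] = True
        return self._finalize(V, mask)
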