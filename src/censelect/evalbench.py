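"""Discovery/validation evaluation, strict and relaxed scoring, and the
replicated benchmark runner.

Each simulation replicate draws an outcome from the fixed covariate matrix,
splits rows 2/3 discovery / 1/3 validation, runs every configured selection
method on the discovery set, confirms the selected variables on the validation
set (univariable p < 0.05 by default), and scores the validated set against
the 10 known truths:

* strict — TP are exact truths; everything else selected is an FP.
* relaxed — a truth counts as identified if it *or* one of its surrogates
  (|corr| > 0.8 with it) is selected; surrogates leave the false-positive
  pool, but the TP ceiling stays at 10.

The F2 score 5*TP / (5*TP + 4*FN + FP) summarizes both, up-weighting
sensitivity over precision.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import univariable_fit
from .selection import SelectionResult
from .simdata import (
    CovariateDesign,
    CovariateMatrix,
    TruthSpec,
    choose_true_variables,
    default_design,
    sample_covariates,
    simulate_outcome,
    split_discovery_validation,
)
from .sparse_select import (
    HierarchicalSGL,
    PenalizedSelectorCV,
    UnivariableScreen,
)
from .tree_select import BartSelector, VimpSelector

logger = logging.getLogger("censelect")

__all__ = [
    "ScoreRecord",
    "BenchmarkTable",
    "BenchmarkConfig",
    "validate_selection",
    "surrogate_map",
    "score_strict",
    "score_relaxed",
    "f2_score",
    "run_benchmark",
    "make_selector",
]


@dataclass
class ScoreRecord:
    method_id: str
    replicate: int
    tp_strict: int
    fp_strict: int
    fn_strict: int
    tp_relaxed: int
    fp_relaxed: int
    fn_relaxed: int
    f2_strict: float
    f2_relaxed: float
    n_selected: int = 0
    n_validated: int = 0

    def __post_init__(self):
        assert self.tp_strict + self.fn_strict == 10
        assert self.tp_relaxed + self.fn_relaxed == 10
        assert self.tp_relaxed >= self.tp_strict
        assert self.fp_relaxed <= self.fp_strict


def validate_selection(selected, X_val, y_val, family: str, mode: str = "univariable",
                       p_threshold: float = 0.05, seed: int | None = 0) -> np.ndarray:
    """Confirm discovery selections on held-out data.

    ``univariable``: keep variables with two-sided Wald p < ``p_threshold`` in
    a one-variable model on the validation rows. ``lasso``: keep variables
    with a nonzero coefficient in a CV lasso restricted to the selected
    columns (useful when discovery returns many correlated variables).
    """
    selected = np.asarray(sorted(set(map(int, selected))))
    if selected.size == 0:
        return selected
    Xv = X_val.values if isinstance(X_val, CovariateMatrix) else np.asarray(X_val, float)
    y_val = np.asarray(y_val, dtype=float)
    if mode == "univariable":
        _, _, pvals = univariable_fit(Xv[:, selected], y_val, family)
        return selected[pvals < p_threshold]
    if mode == "lasso":
        est = PenalizedSelectorCV(family=family, alpha_grid=(1.0,), rule="min",
                                  cv=10, random_state=seed)
        est.fit(Xv[:, selected], y_val)
        return selected[est.support_]
    raise ValueError(f"unknown validation mode {mode!r}")


def surrogate_map(X, truth: TruthSpec, threshold: float = 0.8,
                  method: str = "pearson") -> dict[int, set[int]]:
    """Per-truth surrogate sets: S(t) = {j not in truth : |corr(x_j, x_t)| > threshold}.

    Correlation is Pearson on the standardized matrix by default (Spearman by
    flag); the boundary |corr| == threshold is excluded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    V = X.values if isinstance(X, CovariateMatrix) else np.asarray(X, float)
    if method == "pearson":
        C = np.corrcoef(V, rowvar=False)
    elif method == "spearman":
        from scipy import stats as _st
        C = _st.spearmanr(V).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    truths = set(truth.true_indices)
    out: dict[int, set[int]] = {}
    for t in truth.true_indices:
        mask = np.abs(C[:, t]) > threshold
        out[t] = {int(j) for j in np.flatnonzero(mask) if j not in truths}
    return out


def surrogate_pool(surrogates: dict[int, set[int]]) -> set[int]:
    return set().union(*surrogates.values()) if surrogates else set()


def score_strict(validated, truth: TruthSpec) -> tuple[int, int, int]:
    v = set(map(int, validated))
    t = set(truth.true_indices)
    tp = len(v & t)
    return tp, len(v - t), 10 - tp


def score_relaxed(validated, truth: TruthSpec,
                  surrogates: dict[int, set[int]]) -> tuple[int, int, int]:
    v = set(map(int, validated))
    t = set(truth.true_indices)
    tp = sum(1 for ti in truth.true_indices if ti in v or (surrogates[ti] & v))
    fp = len(v - t - surrogate_pool(surrogates))
    return tp, fp, 10 - tp


def f2_score(tp: int, fn: int, fp: int) -> float:
    """F2 = 5*TP / (5*TP + 4*FN + FP); defined as 0 when all counts are 0."""
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    denom = 5 * tp + 4 * fn + fp
    return 0.0 if denom == 0 else 5 * tp / denom


# ---------------------------------------------------------------------------
# benchmark runner


@dataclass
class BenchmarkConfig:
    """Study conditions for one benchmark run.

    ``method_settings`` maps a method id to estimator keyword overrides (e.g.
    reduced CV folds for a scaled-down run); unlisted methods use defaults.
    """

    design: CovariateDesign = field(default_factory=default_design)
    family: str = "binary"
    methods: tuple[str, ...] = ("UNIV-BFN", "LASSO-MIN", "LASSO-1SE",
                                "ELNET-MIN", "ELNET-1SE", "HCLST-CORR-SGL")
    n_reps: int = 500
    master_seed: int = 20201210
    power: float = 0.80
    alpha: float = 5e-5
    validation_mode: str = "univariable"
    surrogate_threshold: float = 0.8
    beta: float | None = None
    method_settings: dict = field(default_factory=dict)


@dataclass
class BenchmarkTable:
    """Aggregated benchmark output (per-method means and per-truth rates)."""

    summary: pd.DataFrame
    records: pd.DataFrame
    detection: pd.DataFrame
    truth: TruthSpec

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(float_format="%.10g")
        self.summary.to_csv(outdir / "summary.csv", index=False, **kw)
        self.records.to_csv(outdir / "records.csv", index=False, **kw)
        self.detection.to_csv(outdir / "detection.csv", index=False, **kw)
        self.truth.to_json(outdir / "truth.json")


def make_selector(method_id: str, family: str, seed: int, settings: dict | None = None):
    """Instantiate the estimator behind a benchmark method id."""
    s = dict(settings or {})
    if method_id == "UNIV-BFN":
        return UnivariableScreen(family=family, **s)
    if method_id in ("LASSO-MIN", "LASSO-1SE"):
        return PenalizedSelectorCV(family=family, alpha_grid=(1.0,),
                                   rule="1se" if method_id.endswith("1SE") else "min",
                                   random_state=seed, **s)
    if method_id in ("ELNET-MIN", "ELNET-1SE"):
        from .sparse_select import DEFAULT_ALPHA_GRID
        s.setdefault("alpha_grid", DEFAULT_ALPHA_GRID)
        return PenalizedSelectorCV(family=family,
                                   rule="1se" if method_id.endswith("1SE") else "min",
                                   random_state=seed, **s)
    if method_id == "HCLST-CORR-SGL":
        return HierarchicalSGL(family=family, cluster_method="corr_threshold",
                               random_state=seed, **s)
    if method_id == "HCLST-BOOT-SGL":
        return HierarchicalSGL(family=family, cluster_method="bootstrap",
                               random_state=seed, **s)
    if method_id == "RF":
        return VimpSelector(family=family, mode="forest", random_state=seed, **s)
    if method_id == "BAGGING":
        return VimpSelector(family=family, mode="bagging", random_state=seed, **s)
    if method_id == "BART-LOCAL":
        return BartSelector(family=family, criterion="local", random_state=seed, **s)
    if method_id == "BART-GLOBALSE":
        return BartSelector(family=family, criterion="global_se", random_state=seed, **s)
    if method_id == "BART-GLOBALMAX":
        return BartSelector(family=family, criterion="global_max", random_state=seed, **s)
    raise ValueError(f"unknown method id {method_id!r}")


def run_benchmark(config: BenchmarkConfig, X: CovariateMatrix | None = None,
                  truth: TruthSpec | None = None) -> BenchmarkTable:
    """Run the replicated discovery/validation benchmark.

    The covariate matrix and truth are fixed across replicates; outcomes,
    splits and method seeds are re-drawn per replicate from independent
    streams spawned off the master seed. Method failures are logged and
    excluded from that method's means.
    """
    root = np.random.SeedSequence(config.master_seed)
    seeds = root.spawn(config.n_reps + 2)
    if X is None:
        X = sample_covariates(config.design)
    if truth is None:
        truth = choose_true_variables(
            X, seed=int(seeds[-1].generate_state(1)[0] % 2**31),
            family=config.family, beta=config.beta)
    if config.beta is not None and truth.beta != config.beta:
        truth = TruthSpec(truth.true_indices, config.beta, config.family)
    surro = surrogate_map(X, truth, threshold=config.surrogate_threshold)
    rows: list[dict] = []
    detect = {m: np.zeros(10) for m in config.methods}
    n_ok = {m: 0 for m in config.methods}
    beta_hat = np.zeros((config.n_reps, 10))
    truth_idx = np.asarray(truth.true_indices)

    for r in range(config.n_reps):
        sub = seeds[r].generate_state(4) % (2**31)
        sim = simulate_outcome(X, truth, seed=int(sub[0]))
        split = split_discovery_validation(X.n, seed=int(sub[1]))
        Xd = X.values[split.discovery_idx]
        yd = sim.y[split.discovery_idx]
        Xv = X.values[split.validation_idx]
        yv = sim.y[split.validation_idx]
        est_t, _, _ = univariable_fit(Xd[:, truth_idx], yd, config.family)
        beta_hat[r] = est_t
        for m in config.methods:
            t0 = time.perf_counter()
            try:
                sel = make_selector(m, config.family, int(sub[2]),
                                    config.method_settings.get(m))
                sel.fit(Xd, yd)
                validated = validate_selection(sel.selected_, Xv, yv, config.family,
                                               mode=config.validation_mode,
                                               seed=int(sub[3]))
            except Exception:
                logger.exception("replicate %d: method %s failed", r, m)
                continue
            tp_s, fp_s, fn_s = score_strict(validated, truth)
            tp_r, fp_r, fn_r = score_relaxed(validated, truth, surro)
            rec = ScoreRecord(m, r, tp_s, fp_s, fn_s, tp_r, fp_r, fn_r,
                              f2_score(tp_s, fn_s, fp_s), f2_score(tp_r, fn_r, fp_r),
                              n_selected=len(sel.selected_), n_validated=len(validated))
            rows.append(vars(rec).copy())
            vset = set(map(int, validated))
            detect[m] += np.array([int(t in vset) for t in truth_idx])
            n_ok[m] += 1
            logger.info("rep %d %s: %d selected, %d validated (%.2fs)",
                        r, m, len(sel.selected_), len(validated),
                        time.perf_counter() - t0)

    records = pd.DataFrame(rows)
    agg_cols = ["tp_strict", "fp_strict", "f2_strict",
                "tp_relaxed", "fp_relaxed", "f2_relaxed"]
    summary = (records.groupby("method_id", sort=False)[agg_cols].mean()
               .reindex(list(config.methods)).reset_index())
    det_rows = []
    for k, t in enumerate(truth_idx):
        row = {"truth_rank": k + 1, "variable": X.names[t],
               "mean_univariable_beta": float(beta_hat[:, k].mean())}
        for m in config.methods:
            row[f"detection_rate[{m}]"] = detect[m][k] / max(n_ok[m], 1)
        det_rows.append(row)
    return BenchmarkTable(summary=summary, records=records,
                          detection=pd.DataFrame(det_rows), truth=truth)
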