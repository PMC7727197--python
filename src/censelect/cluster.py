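"""Correlation-based variable clustering for the sparse group lasso.

Distance between variables is one minus the absolute Spearman correlation, so
the dendrogram height stays on the interpretable [0, 1] scale under complete
linkage: cutting at height h groups variables whose pairwise |rho_S| all
exceed 1 - h. A bootstrap variant scores each candidate dendrogram node by how
often its exact member set reappears when observations are resampled, keeping
only stable clusters.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .simdata import CovariateMatrix

__all__ = [
    "ClusterAssignment",
    "spearman_distance_matrix",
    "hierarchical_clusters",
    "bootstrap_clusters",
]


@dataclass
class ClusterAssignment:
    """Per-variable group labels, contiguous 1..n_groups."""

    group_id: np.ndarray
    cut_height: float
    method: str
    names: list[str] | None = None

    @property
    def n_groups(self) -> int:
        return int(self.group_id.max())

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.group_id)[1:]

    def groups(self) -> list[np.ndarray]:
        """Member indices per group, ordered by group id."""
        order = np.argsort(self.group_id, kind="stable")
        bounds = np.searchsorted(self.group_id[order], np.arange(1, self.n_groups + 2))
        return [order[bounds[g] : bounds[g + 1]] for g in range(self.n_groups)]

    def to_csv(self, path, meta_path=None, **meta) -> None:
        names = self.names or [f"V{j + 1:04d}" for j in range(len(self.group_id))]
        pd.DataFrame({"variable": names, "group": self.group_id}).to_csv(path, index=False)
        if meta_path is not None:
            payload = {"cut_height": self.cut_height, "method": self.method, **meta}
            Path(meta_path).write_text(json.dumps(payload, indent=1))


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, CovariateMatrix) else np.asarray(X, dtype=float)


def spearman_distance_matrix(X) -> np.ndarray:
    """D[j,k] = 1 - |rho_Spearman(x_j, x_k)|, with average ranks for ties."""
    V = _as_values(X)
    sd = V.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant column at index {bad}")
    rho = stats.spearmanr(V).statistic
    if np.ndim(rho) == 0:  # p == 2 returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    D = 1.0 - np.abs(rho)
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _complete_linkage(D: np.ndarray) -> np.ndarray:
    return linkage(squareform(D, checks=False), method="complete")


def _labels_from_cut(Z: np.ndarray, p: int, cut_height: float) -> np.ndarray:
    """Flat clusters from merges at height strictly below the cut."""
    from scipy.cluster.hierarchy import fcluster

    t = np.nextafter(cut_height, -np.inf)  # strict: merge height == cut stays split
    raw = fcluster(Z, t=t, criterion="distance")
    return _relabel(raw)


def _relabel(raw: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..k in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, g in enumerate(raw):
        out[i] = seen.setdefault(int(g), len(seen) + 1)
    return out


def _assert_complete_linkage_bound(D: np.ndarray, labels: np.ndarray, cut: float) -> None:
    for g in range(1, labels.max() + 1):
        members = np.flatnonzero(labels == g)
        if len(members) > 1:
            sub = D[np.ix_(members, members)]
            assert sub.max() <= cut + 1e-12, (
                f"complete-linkage bound violated in group {g}: {sub.max():.4f} > {cut}"
            )


def hierarchical_clusters(D: np.ndarray, cut_height: float = 0.2,
                          names: list[str] | None = None) -> ClusterAssignment:
    """Complete-linkage clusters from merges strictly below ``cut_height``.

    With distance 1 - |rho_S| and the default cut of 0.2, members of a
    multi-variable cluster all satisfy |rho_S| > 0.8 pairwise; a pair at
    exactly 0.8 stays split. Singletons are allowed and common.
    """
    D = np.asarray(D, dtype=float)
    Z = _complete_linkage(D)
    labels = _labels_from_cut(Z, D.shape[0], cut_height)
    _assert_complete_linkage_bound(D, labels, cut_height)
    return ClusterAssignment(group_id=labels, cut_height=cut_height,
                             method="corr_threshold", names=names)


def _node_member_sets(Z: np.ndarray, p: int) -> list[frozenset]:
    """Member sets of all internal dendrogram nodes (size >= 2)."""
    members: list[frozenset] = [frozenset([i]) for i in range(p)]
    out = []
    for a, b, _, _ in Z:
        s = members[int(a)] | members[int(b)]
        members.append(s)
        out.append(s)
    return out


def bootstrap_clusters(
    X,
    B: int = 1000,
    stability_threshold: float = 0.95,
    cut_height: float = 0.2,
    seed: int = 0,
    names: list[str] | None = None,
) -> ClusterAssignment:
    """Stability-filtered clusters from bootstrap resampling of observations.

    Each candidate node of the original complete-linkage dendrogram (restricted
    to nodes merging below ``cut_height``) is scored by the fraction of B
    bootstrap dendrograms in which its exact member set appears as a node.
    Accepted clusters are the maximal non-overlapping candidates with
    stability >= threshold; everything else becomes a singleton.
    """
    V = _as_values(X)
    n, p = V.shape
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is low; stability estimates are noisy")
    if n < 50:
        warnings.warn(f"n={n} is small for bootstrap resampling; clusters may be unstable")
    rng = np.random.default_rng(seed)
    D = spearman_distance_matrix(V)
    Z = _complete_linkage(D)
    heights = Z[:, 2]
    candidates = [
        s for s, h in zip(_node_member_sets(Z, p), heights) if h < cut_height
    ]
    counts = {s: 0 for s in candidates}
    if candidates:
        for _ in range(B):
            rows = rng.integers(0, n, n)
            Vb = V[rows]
            if np.any(Vb.std(axis=0) == 0):
                continue  # degenerate resample; skip (counts as instability)
            Db = spearman_distance_matrix(Vb)
            Zb = _complete_linkage(Db)
            for s in set(_node_member_sets(Zb, p)):
                if s in counts:
                    counts[s] += 1
    stable = {s for s, c in counts.items() if c / max(B, 1) >= stability_threshold}
    # maximal non-overlapping stable sets: largest first, skip overlaps
    labels = np.zeros(p, dtype=int)
    next_id = 0
    for s in sorted(stable, key=lambda s: (-len(s), sorted(s))):
        ms = sorted(s)
        if np.all(labels[ms] == 0):
            next_id += 1
            labels[ms] = next_id
    for j in range(p):
        if labels[j] == 0:
            next_id += 1
            labels[j] = next_id
    return ClusterAssignment(group_id=_relabel(labels), cut_height=cut_height,
                             method="bootstrap", names=names)
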