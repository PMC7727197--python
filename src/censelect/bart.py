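"""A compact Bayesian additive regression trees (BART) sampler.

Sum-of-m-trees model fitted by Metropolis-within-Gibbs backfitting. Priors are
the standard ones: a node at depth d splits with probability a*(1+d)^(-b)
(a=0.95, b=2), leaf values are N(0, sigma_mu^2) with sigma_mu chosen so the sum
of trees spans the (internally rescaled) outcome range, and the error variance
has a scaled inverse-chi-squared prior calibrated to the sample variance.
Binary outcomes use probit data augmentation (truncated-normal latent draws,
sigma fixed at 1). Tree moves are GROW / PRUNE, accepted by Metropolis-
Hastings with the leaf values integrated out.

What this module is for is *variable selection*: across post-burn-in draws it
records each variable's share of all splitting rules (the inclusion
proportion). The permutation-null machinery and the three selection
thresholds built on these proportions live in ``tree_select``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BartParams", "bart_inclusion_proportions"]


@dataclass(frozen=True)
class BartParams:
    """Sampler settings; defaults follow common variable-selection practice
    (a small ensemble sharpens the inclusion proportions)."""

    n_trees: int = 20
    n_burn: int = 1000
    n_post: int = 1000
    split_alpha: float = 0.95
    split_beta: float = 2.0
    k: float = 2.0
    nu: float = 3.0
    q: float = 0.90
    n_cutpoints: int = 100
    p_grow: float = 0.5


class _Node:
    __slots__ = ("idx", "var", "cut", "left", "right", "depth")

    def __init__(self, idx, depth):
        self.idx = idx          # row indices reaching this node
        self.var = None
        self.cut = None
        self.left = None
        self.right = None
        self.depth = depth

    @property
    def is_leaf(self):
        return self.var is None


class _Tree:
    def __init__(self, n):
        self.root = _Node(np.arange(n), 0)
        self.fit = np.zeros(n)

    def leaves(self):
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.extend((nd.left, nd.right))
        return out

    def nog_nodes(self):
        """Internal nodes whose both children are leaves (prunable)."""
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                if nd.left.is_leaf and nd.right.is_leaf:
                    out.append(nd)
                stack.extend((nd.left, nd.right))
        return out

    def split_counts(self, p):
        counts = np.zeros(p)
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                counts[nd.var] += 1
                stack.extend((nd.left, nd.right))
        return counts


def _log_marginal(r_sum, r_sq, n_l, sigma2, s_mu2):
    """Log marginal likelihood of residuals in one leaf, leaf mean integrated out."""
    v = sigma2 + n_l * s_mu2
    return (-0.5 * n_l * np.log(2 * np.pi * sigma2)
            + 0.5 * np.log(sigma2 / v)
            - 0.5 * (r_sq - r_sum**2 * s_mu2 / v) / sigma2)


class _BartSampler:
    def __init__(self, X, y, family, params: BartParams, rng: np.random.Generator):
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.family = family
        self.pr = params
        self.rng = rng
        qs = np.linspace(0, 1, params.n_cutpoints + 2)[1:-1]
        self.cuts = [np.unique(np.quantile(self.X[:, j], qs)) for j in range(self.p)]
        y = np.asarray(y, dtype=float)
        if family == "continuous":
            lo, hi = y.min(), y.max()
            rngy = hi - lo if hi > lo else 1.0
            self.y_off, self.y_scale = (lo + hi) / 2.0, rngy
            self.z = (y - self.y_off) / rngy
            self.s_mu = 0.5 / (params.k * np.sqrt(params.n_trees))
            shat2 = max(np.var(self.z), 1e-10)
            self.lam = shat2 * stats.chi2.ppf(1 - params.q, params.nu) / params.nu
            self.sigma2 = shat2
        else:
            self.y01 = y
            self.z = np.where(y > 0, 0.5, -0.5)  # latent init
            self.s_mu = 3.0 / (params.k * np.sqrt(params.n_trees))
            self.sigma2 = 1.0
        self.trees = [_Tree(self.n) for _ in range(params.n_trees)]
        self.total_fit = np.zeros(self.n)

    # -- structure priors ---------------------------------------------------
    def _p_split(self, depth):
        return self.pr.split_alpha * (1.0 + depth) ** (-self.pr.split_beta)

    # -- one MH move on one tree -------------------------------------------
    def _propose(self, tree: _Tree, resid):
        pr, rng = self.pr, self.rng
        leaves = tree.leaves()
        nogs = tree.nog_nodes()
        can_prune = len(nogs) > 0
        do_grow = (not can_prune) or (rng.random() < pr.p_grow)
        s_mu2 = self.s_mu**2

        if do_grow:
            leaf = leaves[rng.integers(len(leaves))]
            j = int(rng.integers(self.p))
            cuts = self.cuts[j]
            c = float(cuts[rng.integers(len(cuts))])
            x = self.X[leaf.idx, j]
            go_left = x <= c
            nL = int(go_left.sum())
            nR = len(leaf.idx) - nL
            if nL == 0 or nR == 0:
                return  # invalid proposal, auto-reject
            rl = resid[leaf.idx]
            sumL, sqL = rl[go_left].sum(), (rl[go_left] ** 2).sum()
            sumA, sqA = rl.sum(), (rl**2).sum()
            sumR, sqR = sumA - sumL, sqA - sqL
            ll_new = (_log_marginal(sumL, sqL, nL, self.sigma2, s_mu2)
                      + _log_marginal(sumR, sqR, nR, self.sigma2, s_mu2))
            ll_old = _log_marginal(sumA, sqA, len(leaf.idx), self.sigma2, s_mu2)
            d = leaf.depth
            ps, ps_child = self._p_split(d), self._p_split(d + 1)
            log_prior = np.log(ps) + 2 * np.log1p(-ps_child) - np.log1p(-ps)
            # apply the grow, count prunable nodes on the new tree, revert on reject
            leaf.var, leaf.cut = j, c
            leaf.left = _Node(leaf.idx[go_left], d + 1)
            leaf.right = _Node(leaf.idx[~go_left], d + 1)
            n_nog_new = len(tree.nog_nodes())
            p_prune_new = 1.0 - pr.p_grow
            p_grow_old = pr.p_grow if can_prune else 1.0
            log_trans = (np.log(p_prune_new) - np.log(n_nog_new)
                         - np.log(p_grow_old) + np.log(len(leaves)))
            if not (np.log(rng.random()) < ll_new - ll_old + log_prior + log_trans):
                leaf.var = leaf.cut = None
                leaf.left = leaf.right = None
        else:
            node = nogs[rng.integers(len(nogs))]
            rl = resid[node.idx]
            ridxL = node.left.idx
            rlL = resid[ridxL]
            sumL, sqL = rlL.sum(), (rlL**2).sum()
            sumA, sqA = rl.sum(), (rl**2).sum()
            sumR, sqR = sumA - sumL, sqA - sqL
            nL, nR = len(node.left.idx), len(node.right.idx)
            ll_split = (_log_marginal(sumL, sqL, nL, self.sigma2, s_mu2)
                        + _log_marginal(sumR, sqR, nR, self.sigma2, s_mu2))
            ll_merged = _log_marginal(sumA, sqA, len(node.idx), self.sigma2, s_mu2)
            d = node.depth
            ps, ps_child = self._p_split(d), self._p_split(d + 1)
            log_prior = -(np.log(ps) + 2 * np.log1p(-ps_child) - np.log1p(-ps))
            n_leaves_after = len(leaves) - 1
            # apply the prune, inspect the new tree, revert on reject
            old = (node.var, node.cut, node.left, node.right)
            node.var = node.cut = None
            node.left = node.right = None
            p_grow_new = pr.p_grow if tree.nog_nodes() else 1.0
            log_trans = (np.log(p_grow_new) - np.log(n_leaves_after)
                         - np.log(1.0 - pr.p_grow) + np.log(len(nogs)))
            if not (np.log(rng.random()) < ll_merged - ll_split + log_prior + log_trans):
                node.var, node.cut, node.left, node.right = old

    def _draw_leaves(self, tree: _Tree, resid):
        s_mu2 = self.s_mu**2
        fit = np.zeros(self.n)
        for leaf in tree.leaves():
            rl = resid[leaf.idx]
            v = self.sigma2 * s_mu2 / (self.sigma2 + len(rl) * s_mu2)
            m = rl.sum() * s_mu2 / (self.sigma2 + len(rl) * s_mu2)
            fit[leaf.idx] = m + np.sqrt(v) * self.rng.standard_normal()
        tree.fit = fit

    def _gibbs_iteration(self):
        for tree in self.trees:
            self.total_fit -= tree.fit
            resid = self.z - self.total_fit
            self._propose(tree, resid)
            self._draw_leaves(tree, resid)
            self.total_fit += tree.fit
        if self.family == "continuous":
            e = self.z - self.total_fit
            shape_df = self.pr.nu + self.n
            scale = self.pr.nu * self.lam + e @ e
            self.sigma2 = scale / self.rng.chisquare(shape_df)
        else:
            mu = self.total_fit
            u = self.rng.random(self.n)
            cdf0 = stats.norm.cdf(-mu)  # P(z < 0 | mu)
            pos = self.y01 > 0
            # inverse-CDF truncated normal draws
            q = np.where(pos, cdf0 + u * (1 - cdf0), u * cdf0)
            q = np.clip(q, 1e-12, 1 - 1e-12)
            self.z = mu + stats.norm.ppf(q)
            if not np.all(np.isfinite(self.z)):
                raise FloatingPointError("non-finite latent draw in probit augmentation")

    def run(self):
        pr = self.pr
        props = np.zeros(self.p)
        for it in range(pr.n_burn + pr.n_post):
            self._gibbs_iteration()
            if not np.isfinite(self.total_fit).all():
                raise FloatingPointError(f"non-finite fit at draw {it}")
            if it >= pr.n_burn:
                counts = sum(t.split_counts(self.p) for t in self.trees)
                total = counts.sum()
                props += counts / total if total > 0 else np.full(self.p, 1.0 / self.p)
        return props / pr.n_post


def bart_inclusion_proportions(X, y, family: str, params: BartParams | None = None,
                               seed: int = 0) -> np.ndarray:
    """Posterior-mean variable inclusion proportions (sum to 1 over variables)."""
    params = params or BartParams()
    rng = np.random.default_rng(seed)
    sampler = _BartSampler(X, y, family, params, rng)
    return sampler.run()
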