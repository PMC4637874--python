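"""Felsenstein pruning likelihoods over a mixture of site classes.

The engine is generic over the state space: an amino-acid model with k
discrete-Gamma categories and a codon model with site classes (possibly
with branch-heterogeneous generators, as in branch-site and clade
models) both reduce to a list of :class:`MixtureClass` entries, each
carrying a weight, root frequencies, and a per-branch eigendecomposed
generator.  Internally all classes are stacked into (n_classes, L,
n_states) arrays so one batched matrix product serves every class, and
per-node rescaling keeps 61-state likelihoods from underflowing on
deep trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .alignment import MISSING, Alignment
from .substmodels import AAModel, EigenQ
from .trees import Node, PhyloTree

_TINY = 1e-300


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0, without scipy overhead."""
    m = a.max(axis=0)
    m = np.where(np.isfinite(m), m, 0.0)
    return m + np.log(np.exp(a - m).sum(axis=0))


@dataclass
class MixtureClass:
    """One mixture component: weight, root frequencies, branch generators."""

    weight: float
    pi: np.ndarray
    eigen_for: Callable[[Node], EigenQ]

    def pmat(self, node: Node) -> np.ndarray:
        return self.eigen_for(node).transition(node.length)


def aa_mixture_classes(model: AAModel) -> list[MixtureClass]:
    """Discrete-Gamma mixture for an amino-acid model."""
    eig = model.eigen()
    rates = model.rates()
    k = len(rates)
    return [
        MixtureClass(weight=1.0 / k, pi=model.pi,
                     eigen_for=(lambda node, e=eig.scaled(r): e))
        for r in rates
    ]


@dataclass
class SiteLikelihoodProfile:
    """Per-site log-likelihoods under one tree/model fit."""

    site_lnl: np.ndarray
    params: dict

    @property
    def total(self) -> float:
        return float(self.site_lnl.sum())


class TreeLikelihood:
    """Pruning-algorithm likelihood for one (tree, alignment, mixture).

    Down (conditional) partials, up partials and per-site
    log-likelihoods are computed lazily and cached; mutate the tree's
    branch lengths only through a fresh instance.
    """

    def __init__(self, tree: PhyloTree, alignment: Alignment,
                 classes: list[MixtureClass]):
        missing = set(alignment.taxa) - set(tree.leaf_names)
        if missing:
            raise ValueError(
                f"alignment taxa absent from tree: {sorted(missing)}")
        self.tree = tree
        self.alignment = alignment
        self.classes = classes
        self.nodes: list[Node] = list(tree.postorder())  # root last
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self._taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
        self.n_states = len(classes[0].pi)
        self.nc = len(classes)
        self.n_sites = alignment.n_columns
        # compress to unique site patterns; everything internal works on
        # patterns, public per-site quantities are expanded on the way out
        cache = getattr(alignment, "_pattern_cache", None)
        if cache is None:
            cache = np.unique(alignment.matrix, axis=1,
                              return_inverse=True, return_counts=True)
            alignment._pattern_cache = cache
        patterns, self.site_to_pattern, counts = cache
        self._patterns = patterns
        self.pattern_weights = counts.astype(float)
        self.L = patterns.shape[1]
        self.pi_stack = np.stack([np.asarray(c.pi) for c in classes])
        self.log_weights = np.log([c.weight for c in classes])
        self._down: Optional[list] = None
        self._down_scale: Optional[list] = None
        self._up: Optional[list] = None
        self._up_scale: Optional[list] = None
        self._pmat_memo: dict = {}

    # ------------------------------------------------------------ helpers

    def _precompute_pmats(self) -> None:
        """Batch-build P(t) for every branch and class in one pass each,
        grouped by shared eigensystem (beats per-branch calls on 61x61)."""
        branch_nodes = [n for n in self.nodes if n.parent is not None]
        per_class = []
        for c, cls in enumerate(self.classes):
            groups: dict[int, tuple] = {}
            order = []
            for n in branch_nodes:
                eig = cls.eigen_for(n)
                groups.setdefault(id(eig), (eig, []))[1].append(n)
                order.append(id(eig))
            mats: dict[int, np.ndarray] = {}
            for key, (eig, nodes) in groups.items():
                stack = eig.transition_batch([n.length for n in nodes])
                for n, p in zip(nodes, stack):
                    mats[id(n)] = p
            per_class.append(mats)
        for n in branch_nodes:
            self._pmat_memo[(id(n), n.length)] = np.stack(
                [per_class[c][id(n)] for c in range(self.nc)])

    def pmats(self, node: Node, t: Optional[float] = None) -> np.ndarray:
        """(nc, S, S) stacked transition matrices for the branch above node.

        Calls at the node's current length are memoized and batch-built
        lazily (trial lengths from line searches bypass the cache).
        """
        if t is None:
            key = (id(node), node.length)
            hit = self._pmat_memo.get(key)
            if hit is None:
                self._precompute_pmats()
                hit = self._pmat_memo.get(key)
            if hit is not None:
                return hit
            hit = np.stack([c.eigen_for(node).transition(node.length)
                            for c in self.classes])
            self._pmat_memo[key] = hit
            return hit
        return np.stack([c.eigen_for(node).transition(t)
                         for c in self.classes])

    def _leaf_states(self, node: Node) -> Optional[np.ndarray]:
        """Pattern states for a leaf; None when the taxon is unsampled."""
        if node.name in self._taxon_row:
            return self._patterns[self._taxon_row[node.name]]
        return None

    def _leaf_partial(self, node: Node) -> np.ndarray:
        part = np.zeros((self.nc, self.L, self.n_states))
        states = self._leaf_states(node)
        if states is not None:
            obs = states != MISSING
            part[:, obs, states[obs]] = 1.0
            part[:, ~obs, :] = 1.0
        else:
            # taxon present in tree but not sampled: fully missing
            part[:, :, :] = 1.0
        return part

    @staticmethod
    def _rescale(acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        return acc / m[:, :, None], np.log(m)

    def child_contribution(self, child: Node, down: list,
                           dscale: list,
                           p: Optional[np.ndarray] = None
                           ) -> tuple[np.ndarray, np.ndarray]:
        """(nc, L, S) message a child sends to its parent, with scalers.

        For leaves the one-hot partial makes the matrix product a row
        gather from P, which dominates the runtime saved on large state
        spaces.
        """
        if p is None:
            p = self.pmats(child)
        if child.is_leaf:
            states = self._leaf_states(child)
            if states is None:
                return (np.ones((self.nc, self.L, self.n_states)),
                        np.zeros((self.nc, self.L)))
            obs = states != MISSING
            pt = np.ascontiguousarray(np.swapaxes(p, 1, 2))
            contrib = pt[:, np.where(obs, states, 0), :]
            if not obs.all():
                contrib[:, ~obs, :] = 1.0
            return contrib, np.zeros((self.nc, self.L))
        j = self.node_index[id(child)]
        return down[j] @ np.swapaxes(p, 1, 2), dscale[j]

    # ------------------------------------------------------------ partials

    def down_partials(self) -> tuple[list, list]:
        """Per node: (nc, L, S) conditionals plus (nc, L) log-scalers.

        Leaf entries are populated lazily (only when requested through
        ``down_partials_with_leaves``); internal computation routes leaf
        messages through :meth:`child_contribution`.
        """
        if self._down is not None:
            return self._down, self._down_scale
        down: list = [None] * len(self.nodes)
        scale: list = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                continue
            acc = None
            s = np.zeros((self.nc, self.L))
            for child in node.children:
                contrib, cs = self.child_contribution(child, down, scale)
                acc = contrib if acc is None else acc * contrib
                s += cs
            acc, ls = self._rescale(acc)
            down[i] = acc
            scale[i] = s + ls
        self._down, self._down_scale = down, scale
        return down, scale

    def up_partials(self) -> tuple[list, list]:
        """Per node: U[n] = P(data outside subtree(n), state at n), scaled.

        U at the root is the root frequency stack; for any node,
        sum_i U[n][c, :, i] * down[n][c, :, i] recovers the class-c site
        likelihood.
        """
        if self._up is not None:
            return self._up, self._up_scale
        down, dscale = self.down_partials()
        up: list = [None] * len(self.nodes)
        uscale: list = [None] * len(self.nodes)
        ri = self.node_index[id(self.tree.root)]
        up[ri] = np.broadcast_to(self.pi_stack[:, None, :],
                                 (self.nc, self.L, self.n_states)).copy()
        uscale[ri] = np.zeros((self.nc, self.L))
        for node in self.tree.preorder():
            i = self.node_index[id(node)]
            for child in node.children:
                j = self.node_index[id(child)]
                acc = up[i].copy()
                s = uscale[i].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    contrib, cs = self.child_contribution(sib, down, dscale)
                    acc *= contrib
                    s += cs
                acc = acc @ self.pmats(child)
                acc, ls = self._rescale(acc)
                up[j] = acc
                uscale[j] = s + ls
        self._up, self._up_scale = up, uscale
        return up, uscale

    # ---------------------------------------------------------- likelihood

    def per_class_pattern_lnl(self) -> np.ndarray:
        """(n_classes, n_patterns) log-likelihood conditional on each class."""
        down, scale = self.down_partials()
        ri = self.node_index[id(self.tree.root)]
        lik = np.einsum("kls,ks->kl", down[ri], self.pi_stack)
        return np.log(np.maximum(lik, _TINY)) + scale[ri]

    def pattern_lnl(self) -> np.ndarray:
        per_class = self.per_class_pattern_lnl()
        return _logsumexp0(per_class + self.log_weights[:, None])

    def site_lnl(self) -> np.ndarray:
        return self.pattern_lnl()[self.site_to_pattern]

    def total_lnl(self) -> float:
        return float(self.pattern_lnl() @ self.pattern_weights)

    def class_posteriors(self) -> np.ndarray:
        """(n_classes, n_sites) posterior probability of each class per site."""
        joint = self.per_class_pattern_lnl() + self.log_weights[:, None]
        post = np.exp(joint - _logsumexp0(joint)[None, :])
        return post[:, self.site_to_pattern]

    def node_state_posteriors(self, node: Node) -> np.ndarray:
        """(n_sites, S) marginal posterior over states at an internal node."""
        down, dscale = self.down_partials()
        up, uscale = self.up_partials()
        i = self.node_index[id(node)]
        if node.is_leaf:
            down = list(down)
            dscale = list(dscale)
            down[i] = self._leaf_partial(node)
            dscale[i] = np.zeros((self.nc, self.L))
        log_joint = (np.log(np.maximum(up[i] * down[i], _TINY))
                     + (uscale[i] + dscale[i])[:, :, None]
                     + self.log_weights[:, None, None])
        m = log_joint.max(axis=(0, 2), keepdims=True)
        w = np.exp(log_joint - m)
        post = w.sum(axis=0)
        post = post / post.sum(axis=1, keepdims=True)
        return post[self.site_to_pattern]

    # -------------------------------------------------- branch-length view

    def edge_likelihood_fn(self, node: Node) -> Callable[[float], float]:
        """Total lnL as a function of the branch length above ``node``.

        All other branch lengths and model parameters are held fixed;
        the returned callable is cheap (one batched product per call).
        """
        if node.parent is None:
            raise ValueError("the root has no branch")
        down, dscale = self.down_partials()
        up, uscale = self.up_partials()
        parent = node.parent
        pidx = self.node_index[id(parent)]

        # up partial at the TOP of the branch: parent's up partial times
        # sibling contributions (U[node] already includes the branch, so
        # rebuild the pre-branch quantity here)
        top = up[pidx].copy()
        tscale = uscale[pidx].copy()
        for sib in parent.children:
            if sib is node:
                continue
            contrib, cs = self.child_contribution(sib, down, dscale)
            top *= contrib
            tscale += cs
        top, ls = self._rescale(top)
        tscale = tscale + ls
        logw = self.log_weights

        def lnl(t: float) -> float:
            contrib, cs = self.child_contribution(
                node, down, dscale, p=self.pmats(node, t))
            lik = np.einsum("kls,kls->kl", top, contrib)
            per = np.log(np.maximum(lik, _TINY)) + tscale + cs
            return float(_logsumexp0(per + logw[:, None]) @ self.pattern_weights)

        return lnl


def site_log_likelihoods(tree: PhyloTree, alignment: Alignment,
                         model: AAModel) -> SiteLikelihoodProfile:
    """Per-site log-likelihoods of an amino-acid alignment on a fixed tree."""
    engine = TreeLikelihood(tree, alignment, aa_mixture_classes(model))
    return SiteLikelihoodProfile(
        site_lnl=engine.site_lnl(),
        params={"model": model.name, "alpha": model.alpha, "k": model.k,
                "frequencies": model.frequencies},
    )
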