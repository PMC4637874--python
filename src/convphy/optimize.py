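"""Maximum-likelihood parameter optimization on a fixed topology.

Coordinate-wise bounded optimization: each branch length in turn by
Brent's method on the one-branch likelihood view (other parameters
fixed), then the Gamma shape, sweeping until the total log-likelihood
improves by less than a tolerance.  The same branch-sweep machinery is
reused by the codon models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .likelihood import (MixtureClass, SiteLikelihoodProfile, TreeLikelihood,
                         aa_mixture_classes, site_log_likelihoods)
from .substmodels import ALPHA_BOUNDS, AAModel
from .trees import PhyloTree

BRANCH_BOUNDS = (1e-6, 20.0)


class OptimizationError(RuntimeError):
    """Raised when the likelihood becomes non-finite during a search."""


def _clamp_branch_lengths(tree: PhyloTree) -> None:
    lo, hi = BRANCH_BOUNDS
    for node in tree.preorder():
        if node.parent is not None:
            node.length = min(max(node.length, lo), hi)


def _branch_sweep(tree: PhyloTree, alignment: Alignment,
                  classes: list[MixtureClass], xatol: float = 1e-6) -> float:
    """One depth-first sweep of Brent updates over all branch lengths.

    Down partials are computed once and refreshed on DFS exit, so every
    branch is optimized against exact current partials (each accepted
    update strictly improves the total lnL).  Returns the final lnL.
    """
    from .likelihood import _logsumexp0

    engine = TreeLikelihood(tree, alignment, classes)
    down, dscale = engine.down_partials()
    idx = engine.node_index
    logw = engine.log_weights
    wts = engine.pattern_weights
    rescale = engine._rescale

    def refresh_down(node) -> None:
        i = idx[id(node)]
        acc = None
        s = np.zeros_like(dscale[i])
        for child in node.children:
            contrib, cs = engine.child_contribution(child, down, dscale)
            acc = contrib if acc is None else acc * contrib
            s += cs
        acc, ls = rescale(acc)
        down[i] = acc
        dscale[i] = s + ls

    def visit(node, up, upscale) -> None:
        # ``up``: (nc, L, S) partial of everything outside subtree(node),
        # evaluated at node itself; the root gets the class frequencies.
        for child in node.children:
            top = up.copy()
            tscale = upscale.copy()
            for sib in node.children:
                if sib is child:
                    continue
                contrib, cs = engine.child_contribution(sib, down, dscale)
                top *= contrib
                tscale += cs
            top, ls = rescale(top)
            tscale += ls

            def neg(t: float) -> float:
                contrib, cs = engine.child_contribution(
                    child, down, dscale, p=engine.pmats(child, t))
                lik = np.einsum("kls,kls->kl", top, contrib)
                per = np.log(np.maximum(lik, 1e-300)) + tscale + cs
                return -float(_logsumexp0(per + logw[:, None]) @ wts)

            cur = neg(child.length)
            # search a multiplicative window around the current value;
            # successive sweeps widen the reach, keeping each Brent cheap
            lo = max(BRANCH_BOUNDS[0], child.length / 10.0)
            hi = min(BRANCH_BOUNDS[1], max(child.length * 10.0, 0.05))
            res = minimize_scalar(neg, bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": xatol + 0.01 * child.length})
            if np.isfinite(res.fun) and res.fun < cur:
                child.length = float(res.x)
            child_up = top @ engine.pmats(child)
            child_up, ls = rescale(child_up)
            visit(child, child_up, tscale + ls)
            if not child.is_leaf:
                refresh_down(child)

    root_up = np.broadcast_to(
        engine.pi_stack[:, None, :],
        (engine.nc, engine.L, engine.n_states)).copy()
    visit(tree.root, root_up, np.zeros((engine.nc, engine.L)))
    refresh_down(tree.root)
    ri = idx[id(tree.root)]
    lik = np.einsum("kls,ks->kl", down[ri], engine.pi_stack)
    per = np.log(np.maximum(lik, 1e-300)) + dscale[ri]
    return float(_logsumexp0(per + logw[:, None]) @ wts)


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    classes_fn: Callable[[], list[MixtureClass]],
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> float:
    """Brent-per-branch sweeps, in place on ``tree``; returns final lnL.

    Monotone by construction: a proposed branch length is accepted only
    if it improves the likelihood against exact current partials.
    """
    _clamp_branch_lengths(tree)
    lnl = TreeLikelihood(tree, alignment, classes_fn()).total_lnl()
    if not np.isfinite(lnl):
        raise OptimizationError(
            f"non-finite starting likelihood ({lnl}) on tree "
            f"{tree.to_newick(precision=3)}")
    for _ in range(max_sweeps):
        new = _branch_sweep(tree, alignment, classes_fn())
        if not np.isfinite(new):
            raise OptimizationError("non-finite likelihood during sweep")
        improved = new - lnl
        lnl = max(lnl, new)
        if improved < tol:
            break
    return lnl


def optimize_likelihood(
    tree: PhyloTree,
    alignment: Alignment,
    model: AAModel,
    free: Iterable[str] = ("branch_lengths", "alpha"),
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> tuple[PhyloTree, AAModel, SiteLikelihoodProfile]:
    """Fit branch lengths and/or the Gamma shape by ML.

    Returns a fitted copy of the tree, the fitted model, and the
    per-site log-likelihood profile at the optimum.
    """
    free = set(free)
    tree = tree.copy()
    _clamp_branch_lengths(tree)
    model = model.replace()
    if model.frequencies == "empirical":
        model = model.with_empirical_frequencies(alignment)

    def classes() -> list[MixtureClass]:
        return aa_mixture_classes(model)

    lnl = TreeLikelihood(tree, alignment, classes()).total_lnl()
    if not np.isfinite(lnl):
        raise OptimizationError(f"non-finite starting likelihood ({lnl})")

    alpha_active = "alpha" in free and model.k > 1
    for sweep in range(max_sweeps):
        prev = lnl
        if "branch_lengths" in free:
            lnl = optimize_branch_lengths(tree, alignment, classes,
                                          tol=tol, max_sweeps=1)
        if alpha_active:
            def neg(log_a: float) -> float:
                trial = model.replace(alpha=float(np.exp(log_a)))
                return -TreeLikelihood(
                    tree, alignment, aa_mixture_classes(trial)).total_lnl()

            if sweep == 0:
                bounds = tuple(np.log(ALPHA_BOUNDS))
            else:  # narrow around the current estimate
                bounds = (max(np.log(ALPHA_BOUNDS[0]),
                              np.log(model.alpha) - np.log(3.0)),
                          min(np.log(ALPHA_BOUNDS[1]),
                              np.log(model.alpha) + np.log(3.0)))
            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": 2e-3})
            if np.isfinite(res.fun) and -res.fun > lnl:
                if abs(np.log(np.exp(res.x) / model.alpha)) < 1e-3:
                    alpha_active = False  # converged; stop re-estimating
                model = model.replace(alpha=float(np.exp(res.x)))
                lnl = float(-res.fun)
            else:
                alpha_active = False
        if lnl - prev < tol:
            break

    profile = site_log_likelihoods(tree, alignment, model)
    return tree, model, profile


@dataclass
class ModelSelection:
    """AIC comparison across candidate amino-acid models."""

    best: AAModel
    best_tree: PhyloTree
    best_profile: SiteLikelihoodProfile
    aic: dict[str, float]

    @property
    def delta_aic(self) -> dict[str, float]:
        lo = min(self.aic.values())
        return {k: v - lo for k, v in self.aic.items()}


def select_model(
    alignment: Alignment,
    tree: PhyloTree,
    candidates: Optional[Iterable[AAModel]] = None,
    **fit_kw,
) -> ModelSelection:
    """Pick the candidate minimizing AIC = 2p - 2 lnL after a full fit."""
    if candidates is None:
        candidates = [AAModel(name="JTT"), AAModel(name="WAG")]
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    n_branches = sum(1 for n in tree.preorder() if n.parent is not None)
    results = {}
    for cand in candidates:
        fitted_tree, fitted_model, profile = optimize_likelihood(
            tree, alignment, cand, **fit_kw)
        p = n_branches + cand.n_free_parameters
        aic = 2.0 * p - 2.0 * profile.total
        results[cand.name] = (aic, fitted_tree, fitted_model, profile)
    best_name = min(results, key=lambda k: results[k][0])
    aic_map = {k: v[0] for k, v in results.items()}
    _, best_tree, best_model, best_profile = results[best_name]
    return ModelSelection(best=best_model, best_tree=best_tree,
                          best_profile=best_profile, aic=aic_map)
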