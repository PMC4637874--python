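"""Sitewise log-likelihood support (SSLS) convergence detection.

For each gene the fit of the alignment to the accepted species topology
(H0) is compared, site by site, with its fit to alternative topologies
in which the focal lineages are forced into a monophyletic clade (HA):
dSSLS = lnL(HA) - lnL(H0) per site, with all free parameters (branch
lengths, Gamma shape) re-optimized independently under each topology.
Positive gene-mean dSSLS supports convergence.  Significance comes from
a simulation null: alignments simulated under fitted H0 models are
scored the same way and the observed statistic is referred to the
stepwise empirical cdf (linear interpolation between order statistics)
of the null sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import MISSING, Alignment
from .likelihood import SiteLikelihoodProfile
from .optimize import optimize_likelihood
from .substmodels import AAModel
from .trees import Node, PhyloTree, TreeError, _subtree_leaves


class HypothesisError(ValueError):
    """Raised for degenerate or malformed convergence hypotheses."""


@dataclass
class ConvergenceHypothesis:
    """A (H0, HA) topology pair with the focal taxa forced monophyletic."""

    id: str
    h_0: PhyloTree
    h_a: PhyloTree
    focal: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.h_0.leaf_names) != set(self.h_a.leaf_names):
            raise HypothesisError(
                f"{self.id}: H0 and HA leaf sets differ")
        if not self.h_a.is_monophyletic(list(self.focal)):
            raise HypothesisError(
                f"{self.id}: focal taxa not monophyletic in HA")


@dataclass
class SiteSupport:
    """Per-site and gene-level dSSLS for one gene under one hypothesis."""

    gene: str
    hypothesis_id: str
    dssls: np.ndarray
    mean_dssls: float
    p_value: Optional[float] = None
    n_sites: int = 0
    fit_h0: Optional[SiteLikelihoodProfile] = None
    fit_ha: Optional[SiteLikelihoodProfile] = None


@dataclass
class NullDistribution:
    """Sorted null sample of dSSLS statistics with ecdf evaluation."""

    values: np.ndarray
    statistic: str = "gene_mean"

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size < 2:
            raise ValueError("null distribution needs at least 2 values")

    @property
    def size(self) -> int:
        return int(self.values.size)

    def cdf(self, x: float) -> float:
        """Stepwise ecdf with plotting positions i/R, linearly interpolated."""
        r = self.size
        positions = np.arange(1, r + 1) / r
        if x < self.values[0]:
            return 0.0
        if x >= self.values[-1]:
            return 1.0
        return float(np.interp(x, self.values, positions))


def empirical_p(observed: float, null: NullDistribution) -> float:
    """P = 1 - cdf(observed), clamped to [1/(R+1), 1]."""
    p = 1.0 - null.cdf(observed)
    floor = 1.0 / (null.size + 1)
    return float(min(1.0, max(floor, p)))


# ------------------------------------------------- alternative topologies


def _rooted_resolutions(names: Sequence[str]) -> list[list]:
    """All rooted binary shapes over the named leaves (n <= 3)."""
    names = list(names)
    if len(names) == 2:
        return [[names[0], names[1]]]
    if len(names) == 3:
        out = []
        for pair in combinations(names, 2):
            other = next(n for n in names if n not in pair)
            out.append([[pair[0], pair[1]], other])
        return out
    raise HypothesisError(
        "topology enumeration is implemented for 2 or 3 focal taxa; "
        "supply alternative topologies explicitly for larger focal sets")


def _build_clade(shape, leaf_lengths: dict[str, float],
                 internal_length: float = 0.1) -> Node:
    if isinstance(shape, str):
        return Node(name=shape, length=leaf_lengths.get(shape, 0.05))
    node = Node(length=internal_length)
    for part in shape:
        node.add_child(_build_clade(part, leaf_lengths, internal_length))
    return node


def generate_alternative_topologies(
    species_tree: PhyloTree,
    focal_taxa: Sequence[str],
    stem_length: float = 0.1,
) -> list[ConvergenceHypothesis]:
    """Enumerate forced-monophyly alternatives to the species tree.

    The focal clade's internal resolutions are crossed with its
    attachment to each branch where a focal taxon was originally
    attached; for three non-sister focal taxa this yields the canonical
    nine alternative topologies.  Regrafted branch lengths are starting
    values only and are re-optimized downstream.
    """
    focal = list(focal_taxa)
    if len(focal) < 2:
        raise HypothesisError("need at least two focal taxa")
    for name in focal:
        species_tree.find_leaf(name)  # raises TreeError if absent
    if species_tree.is_monophyletic(focal):
        raise HypothesisError(
            "focal taxa already monophyletic in the species tree; "
            "HA degenerate (dSSLS undefined)")

    # original sibling context of each focal leaf, recorded as a leaf set
    # that survives pruning, so the attachment edge can be recovered
    anchor_sets = []
    focal_set = set(focal)
    for name in focal:
        leaf = species_tree.find_leaf(name)
        node = leaf.parent
        anchor: Optional[set] = None
        while node is not None:
            below = {lf.name for lf in _subtree_leaves(node)} - focal_set
            if below:
                anchor = below
                break
            node = node.parent
        if anchor is None:
            raise HypothesisError("tree contains only focal taxa")
        anchor_sets.append(frozenset(anchor))

    leaf_lengths = {name: species_tree.find_leaf(name).length
                    for name in focal}
    pruned = species_tree.copy()
    for name in focal:
        pruned.prune_leaf(name)

    # map anchors to attachment nodes in the pruned tree, deduplicated
    attach_nodes = []
    seen = set()
    for anchor in anchor_sets:
        node = (pruned.find_leaf(next(iter(anchor)))
                if len(anchor) == 1 else pruned.mrca(sorted(anchor)))
        if id(node) not in seen:
            seen.add(id(node))
            attach_nodes.append(anchor)

    hypotheses = []
    counter = 0
    for shape in _rooted_resolutions(focal):
        for anchor in attach_nodes:
            counter += 1
            ha = pruned.copy()
            target = (ha.find_leaf(next(iter(anchor)))
                      if len(anchor) == 1 else ha.mrca(sorted(anchor)))
            clade = _build_clade(shape, leaf_lengths)
            ha.attach_on_branch(target, clade, stem_length=stem_length)
            hypotheses.append(ConvergenceHypothesis(
                id=f"tree{counter}", h_0=species_tree, h_a=ha,
                focal=tuple(focal)))
    return hypotheses


# --------------------------------------------------------------- scoring


def _informative_mask(alignment: Alignment) -> np.ndarray:
    """Sites with at least one non-missing residue."""
    return ~(alignment.matrix == MISSING).all(axis=0)


def compute_delta_ssls(alignment: Alignment,
                       hypothesis: ConvergenceHypothesis,
                       model: AAModel,
                       fit_h0: Optional[SiteLikelihoodProfile] = None,
                       **fit_kw) -> SiteSupport:
    """Per-site dSSLS = site lnL(HA) - site lnL(H0), parameters
    re-optimized independently under each topology."""
    if fit_h0 is None:
        try:
            _, _, fit_h0 = optimize_likelihood(
                hypothesis.h_0, alignment, model, **fit_kw)
        except Exception as exc:
            raise RuntimeError(
                f"H0 optimization failed for {hypothesis.id}: {exc}") from exc
    try:
        _, _, fit_ha = optimize_likelihood(
            hypothesis.h_a, alignment, model, **fit_kw)
    except Exception as exc:
        raise RuntimeError(
            f"HA optimization failed for {hypothesis.id}: {exc}") from exc
    dssls = fit_ha.site_lnl - fit_h0.site_lnl
    mask = _informative_mask(alignment)
    mean = float(dssls[mask].mean()) if mask.any() else 0.0
    return SiteSupport(gene=alignment.gene or "",
                       hypothesis_id=hypothesis.id,
                       dssls=dssls, mean_dssls=mean,
                       n_sites=int(mask.sum()),
                       fit_h0=fit_h0, fit_ha=fit_ha)


@dataclass
class GeneFit:
    """A fitted H0 model snapshot used as a null-simulation template."""

    gene: str
    tree: PhyloTree          # H0 topology with ML branch lengths
    model: AAModel
    length: int


def fit_gene_h0(alignment: Alignment, tree: PhyloTree,
                model: AAModel, **fit_kw) -> GeneFit:
    fitted_tree, fitted_model, _ = optimize_likelihood(
        tree, alignment, model, **fit_kw)
    return GeneFit(gene=alignment.gene or "", tree=fitted_tree,
                   model=fitted_model, length=alignment.n_columns)


def simulate_null_distribution(
    gene_fits: Sequence[GeneFit],
    hypothesis: ConvergenceHypothesis,
    replicates: int,
    seed: int,
    statistic: str = "gene_mean",
    **fit_kw,
) -> NullDistribution:
    """Simulate alignments under fitted H0 models and score them.

    Each template gene contributes ``replicates`` simulated alignments
    (its fitted tree, model and length); every simulated alignment is
    scored by mean dSSLS (or pooled per-site dSSLS when ``statistic`` is
    "site") against the hypothesis.
    """
    from .simulate import SimulationSpec, simulate_alignment

    if not gene_fits:
        raise ValueError("need at least one template gene fit")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    for fit in gene_fits:
        for _ in range(replicates):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            spec = SimulationSpec.from_aa_model(
                fit.tree, fit.model, fit.length, seed=sim_seed)
            sim_aln, _ = simulate_alignment(spec)
            sim_aln.gene = f"{fit.gene}_null"
            support = compute_delta_ssls(sim_aln, hypothesis, fit.model,
                                         **fit_kw)
            if statistic == "site":
                values.extend(support.dssls.tolist())
            else:
                values.append(support.mean_dssls)
    return NullDistribution(np.array(values), statistic=statistic)


def score_support(supports: Iterable[SiteSupport],
                  nulls: dict[str, NullDistribution]) -> list[SiteSupport]:
    """Attach empirical P values (per hypothesis) to gene supports."""
    out = []
    for s in supports:
        null = nulls[s.hypothesis_id]
        s.p_value = empirical_p(s.mean_dssls, null)
        out.append(s)
    return out


def call_convergent_genes(
    supports: Sequence[SiteSupport],
    alpha_level: float = 0.05,
    aggregation: str = "any",
    pooled_null: Optional[NullDistribution] = None,
) -> pd.DataFrame:
    """Gene-level convergence calls across hypotheses.

    aggregation "any": P <= alpha under at least one hypothesis;
    "all": under every hypothesis; "mean": the across-hypothesis
    average dSSLS referred to ``pooled_null``.
    """
    if aggregation not in ("any", "all", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    rows = [{"gene": s.gene, "hypothesis": s.hypothesis_id,
             "mean_dssls": s.mean_dssls, "p": s.p_value}
            for s in supports]
    df = pd.DataFrame(rows)
    out = []
    for gene, grp in df.groupby("gene", sort=True):
        mean_over_hyp = grp["mean_dssls"].mean()
        if aggregation == "any":
            called = bool((grp["p"] <= alpha_level).any())
            best_p = float(grp["p"].min())
        elif aggregation == "all":
            called = bool((grp["p"] <= alpha_level).all())
            best_p = float(grp["p"].max())
        else:
            if pooled_null is None:
                raise ValueError(
                    "aggregation='mean' requires a pooled null distribution")
            best_p = empirical_p(float(mean_over_hyp), pooled_null)
            called = best_p <= alpha_level
        out.append({"gene": gene, "mean_dssls": float(mean_over_hyp),
                    "p": best_p, "n_hypotheses": len(grp),
                    "convergent": called})
    return pd.DataFrame(out)
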