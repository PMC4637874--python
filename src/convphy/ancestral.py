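"""Marginal ancestral reconstruction and substitution classification.

Ancestral states are reconstructed by empirical Bayes: the marginal
posterior over amino acids at each internal node and site is obtained
from up/down pruning partials under the fitted model, integrating over
the discrete-Gamma rate categories.  On top of the reconstruction,
substitutions in configured focal groups (e.g. three marine lineages)
are classified:

* parallel  — identical derived residue in every focal group, each
  differing from the group's ancestral (parent-of-MRCA) state;
  sub-labelled "strict parallel" when the ancestral states also agree,
  "convergent" otherwise;
* unique    — a parallel residue additionally absent from every
  background taxon and every group's ancestral node;
* backward  — a parallel/unique call whose derived residue matches the
  prevailing state in a distant reference clade.

Gaps and ambiguity codes are missing data throughout: they are never
evidence for or against a call, and a call requires at least one
non-missing leaf in every focal group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._aa_data import AA_ORDER
from .alignment import MISSING, Alignment
from .likelihood import TreeLikelihood, aa_mixture_classes
from .optimize import optimize_likelihood
from .substmodels import AAModel
from .trees import Node, PhyloTree, TreeError, _subtree_leaves

# lexicographically ordered amino-acid indices, for deterministic
# tie-breaking of equal posteriors
_LEX_RANK = np.argsort(np.argsort(list(AA_ORDER)))


def label_internal_nodes(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Assign stable preorder names N0, N1, ... to unnamed internal nodes."""
    counter = 0
    for node in tree.preorder():
        if not node.is_leaf and node.name is None:
            node.name = f"{prefix}{counter}"
        if not node.is_leaf:
            counter += 1
    return tree


@dataclass
class AncestralStateTable:
    """Posterior state distributions at every internal node.

    posteriors maps node name -> (n_sites, 20) array; map_states holds
    the modal state index per node and site; ambiguous flags MAP
    posteriors below ``threshold`` (or exact ties).
    """

    node_names: list[str]
    posteriors: dict[str, np.ndarray]
    map_states: dict[str, np.ndarray]
    map_posterior: dict[str, np.ndarray]
    ambiguous: dict[str, np.ndarray]
    threshold: float = 0.5

    def map_state(self, node: str, site: int) -> int:
        return int(self.map_states[node][site])


def marginal_ancestral_reconstruction(
    tree: PhyloTree,
    alignment: Alignment,
    model: AAModel,
    optimize: bool = True,
    ambiguity_threshold: float = 0.5,
    **fit_kw,
) -> tuple[PhyloTree, AncestralStateTable]:
    """Empirical-Bayes marginal reconstruction at every internal node.

    Branch lengths (and the Gamma shape) are first fitted by ML unless
    ``optimize`` is disabled; the returned tree carries the fitted
    lengths and stable internal-node names.
    """
    if alignment.alphabet != "aa":
        raise ValueError("ancestral reconstruction expects an amino-acid "
                         "alignment (translate codon alignments first)")
    if optimize:
        tree, model, _ = optimize_likelihood(tree, alignment, model,
                                             **fit_kw)
    else:
        tree = tree.copy()
    label_internal_nodes(tree)
    engine = TreeLikelihood(tree, alignment, aa_mixture_classes(model))
    node_names, posteriors, maps, map_post, ambig = [], {}, {}, {}, {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        post = engine.node_state_posteriors(node)
        # deterministic MAP: maximal posterior; exact ties broken by
        # alphabetical amino-acid order and flagged
        best = post.max(axis=1)
        tied_mask = np.isclose(post, best[:, None], rtol=0, atol=1e-12)
        lex = np.where(tied_mask, _LEX_RANK[None, :], 10**6)
        map_states = lex.argmin(axis=1)
        tied = tied_mask.sum(axis=1) > 1
        node_names.append(node.name)
        posteriors[node.name] = post
        maps[node.name] = map_states.astype(np.int16)
        map_post[node.name] = best
        ambig[node.name] = (best < ambiguity_threshold) | tied
    return tree, AncestralStateTable(
        node_names=node_names, posteriors=posteriors, map_states=maps,
        map_posterior=map_post, ambiguous=ambig,
        threshold=ambiguity_threshold)


# ------------------------------------------------------------ focal groups


@dataclass
class FocalGroupConfig:
    """Named focal lineages, their background, and optional references."""

    groups: dict[str, list[str]]
    background: Optional[list[str]] = None
    reference_taxa: Optional[list[str]] = None

    def validate(self, tree: PhyloTree) -> None:
        all_focal: set[str] = set()
        for name, leaves in self.groups.items():
            if not leaves:
                raise ValueError(f"focal group {name!r} is empty")
            overlap = all_focal & set(leaves)
            if overlap:
                raise ValueError(
                    f"focal groups overlap on taxa {sorted(overlap)}")
            all_focal |= set(leaves)
            for leaf in leaves:
                tree.find_leaf(leaf)
        mrcas = {name: tree.mrca(leaves)
                 for name, leaves in self.groups.items()}
        for a, ma in mrcas.items():
            below = set(_subtree_leaves(ma))
            for b, mb in mrcas.items():
                if a != b and mb in _ancestors_inclusive(ma):
                    raise ValueError(
                        f"MRCA of group {b!r} is an ancestor of group {a!r}")
        for name, mrca in mrcas.items():
            if mrca.parent is None:
                raise ValueError(
                    f"group {name!r} spans the root; no ancestral reference")

    def background_taxa(self, tree: PhyloTree) -> list[str]:
        if self.background is not None:
            return list(self.background)
        focal = {leaf for leaves in self.groups.values() for leaf in leaves}
        ref = set(self.reference_taxa or [])
        return [n for n in tree.leaf_names if n not in focal | ref]


def _ancestors_inclusive(node: Node):
    while node is not None:
        yield node
        node = node.parent


@dataclass
class SubstitutionCall:
    """One classified site in one gene."""

    gene: str
    site: int                    # 1-based alignment column
    ref_position: int            # 1-based ungapped position in reference, 0 if n/a
    category: str                # parallel | parallel_unique | unique
    sublabel: str                # strict_parallel | convergent | ""
    derived: str
    group_states: dict[str, tuple[str, str]]   # group -> (ancestral, derived)
    min_posterior: float
    flags: list[str] = field(default_factory=list)
    backward: Optional[bool] = None


def _group_context(tree: PhyloTree, config: FocalGroupConfig):
    """Per group: (leaf names, ancestral reference node name)."""
    ctx = {}
    for name, leaves in config.groups.items():
        mrca = tree.mrca(leaves)
        if mrca.parent is None:
            raise TreeError(
                f"group {name!r} MRCA equals the tree root; "
                "no ancestral reference")
        ctx[name] = (leaves, mrca.parent.name)
    return ctx


def _site_group_state(alignment: Alignment, leaves: Sequence[str],
                      site: int) -> Optional[int]:
    """The single shared state of a group at a site; None if missing
    everywhere or heterogeneous (caller counts those separately)."""
    states = {int(alignment.row(leaf)[site]) for leaf in leaves}
    states.discard(MISSING)
    if len(states) != 1:
        return None
    return states.pop()


def call_parallel_substitutions(
    tree: PhyloTree,
    alignment: Alignment,
    asr: AncestralStateTable,
    config: FocalGroupConfig,
    require_unique: bool = False,
) -> tuple[list[SubstitutionCall], dict]:
    """Sites with an identical derived residue in every focal group,
    each differing from that group's ancestral state.

    With ``require_unique`` the derived residue must additionally be
    absent from all background leaves and every group's ancestral node.
    Returns (calls, counters); counters track skipped heterogeneous and
    all-missing group sites.
    """
    config.validate(tree)
    ctx = _group_context(tree, config)
    background = config.background_taxa(tree)
    ref_pos = (alignment.reference_positions()
               if alignment.reference else None)
    calls: list[SubstitutionCall] = []
    counters = {"heterogeneous_group": 0, "missing_group": 0,
                "sites_scanned": alignment.n_columns}
    for site in range(alignment.n_columns):
        derived, ancestral, posteriors = {}, {}, []
        ok = True
        for gname, (leaves, anc_node) in ctx.items():
            state = _site_group_state(alignment, leaves, site)
            if state is None:
                non_missing = [alignment.row(l)[site] for l in leaves
                               if alignment.row(l)[site] != MISSING]
                key = ("missing_group" if not non_missing
                       else "heterogeneous_group")
                counters[key] += 1
                ok = False
                break
            derived[gname] = state
            ancestral[gname] = asr.map_state(anc_node, site)
            posteriors.append(float(asr.map_posterior[anc_node][site]))
        if not ok:
            continue
        shared = set(derived.values())
        if len(shared) != 1:
            continue
        d = shared.pop()
        if any(ancestral[g] == d for g in ctx):
            continue
        is_unique = _absent_from_background(alignment, background, site, d)
        if require_unique and not is_unique:
            continue
        category = "parallel_unique" if is_unique else "parallel"
        sublabel = ("strict_parallel"
                    if len(set(ancestral.values())) == 1 else "convergent")
        flags = []
        if any(asr.ambiguous[ctx[g][1]][site] for g in ctx):
            flags.append("ambiguous_ancestor")
        calls.append(SubstitutionCall(
            gene=alignment.gene or "", site=site + 1,
            ref_position=int(ref_pos[site]) if ref_pos is not None else 0,
            category=category, sublabel=sublabel, derived=AA_ORDER[d],
            group_states={g: (AA_ORDER[ancestral[g]], AA_ORDER[d])
                          for g in ctx},
            min_posterior=min(posteriors), flags=flags))
    return calls, counters


def _absent_from_background(alignment: Alignment, background: Sequence[str],
                            site: int, state: int) -> bool:
    for taxon in background:
        s = int(alignment.row(taxon)[site])
        if s != MISSING and s == state:
            return False
    return True


def call_unique_substitutions(
    tree: PhyloTree,
    alignment: Alignment,
    asr: AncestralStateTable,
    config: FocalGroupConfig,
) -> list[SubstitutionCall]:
    """Residues shared by all focal leaves and absent from both the
    background taxa and every group's ancestral node.

    Gapped focal leaves are missing data: the call stands on the
    non-missing leaves and is flagged.
    """
    config.validate(tree)
    if not config.background_taxa(tree):
        raise ValueError("background taxon set is empty")
    ctx = _group_context(tree, config)
    background = config.background_taxa(tree)
    focal_leaves = [leaf for leaves, _ in ctx.values() for leaf in leaves]
    ref_pos = (alignment.reference_positions()
               if alignment.reference else None)
    calls = []
    for site in range(alignment.n_columns):
        states = {int(alignment.row(l)[site]) for l in focal_leaves}
        missing = MISSING in states
        states.discard(MISSING)
        if len(states) != 1:
            continue
        d = states.pop()
        # every group must have at least one non-missing leaf
        group_ok = all(
            any(alignment.row(l)[site] != MISSING for l in leaves)
            for leaves, _ in ctx.values())
        if not group_ok:
            continue
        if not _absent_from_background(alignment, background, site, d):
            continue
        ancestral = {g: asr.map_state(anc, site)
                     for g, (_, anc) in ctx.items()}
        if any(a == d for a in ancestral.values()):
            continue
        flags = ["missing_focal_leaf"] if missing else []
        if any(asr.ambiguous[ctx[g][1]][site] for g in ctx):
            flags.append("ambiguous_ancestor")
        calls.append(SubstitutionCall(
            gene=alignment.gene or "", site=site + 1,
            ref_position=int(ref_pos[site]) if ref_pos is not None else 0,
            category="unique", sublabel="", derived=AA_ORDER[d],
            group_states={g: (AA_ORDER[ancestral[g]], AA_ORDER[d])
                          for g in ctx},
            min_posterior=min(float(asr.map_posterior[anc][site])
                              for _, anc in ctx.values()),
            flags=flags))
    return calls


def call_backward_substitutions(
    calls: Sequence[SubstitutionCall],
    reference_alignment: Alignment,
    fraction: float = 0.5,
) -> list[SubstitutionCall]:
    """Annotate calls whose derived residue recurs in a distant
    reference clade (e.g. non-mammal vertebrates) at the same column."""
    calls = list(calls)
    if calls and reference_alignment.n_columns < max(c.site for c in calls):
        raise ValueError(
            "reference alignment has fewer columns than the called sites")
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for call in calls:
        col = reference_alignment.column(call.site - 1)
        col = col[col != MISSING]
        if col.size == 0:
            call.backward = None
            call.flags.append("no reference data")
            continue
        match = (col == aa_index[call.derived]).mean()
        call.backward = bool(match >= fraction)
    return calls


def calls_to_frame(calls: Sequence[SubstitutionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene": c.gene, "site": c.site,
               "ref_position": c.ref_position, "category": c.category,
               "sublabel": c.sublabel, "derived": c.derived,
               "min_posterior": round(c.min_posterior, 6),
               "backward": c.backward,
               "flags": ";".join(c.flags)}
        for g, (anc, der) in sorted(c.group_states.items()):
            row[f"{g}_change"] = f"{anc}->{der}"
        rows.append(row)
    return pd.DataFrame(rows)
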