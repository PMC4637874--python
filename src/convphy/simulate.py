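"""Sequence simulation along phylogenies and study-shaped fixtures.

Sites evolve independently: a mixture class (rate category or selection
class) is drawn per site, a root state is drawn from the class's
equilibrium frequencies, and states are propagated down each branch by
exact transition-probability sampling at branch ends.  An event log of
per-branch endpoint differences provides planted-truth bookkeeping.
Planted convergent/unique features overwrite simulated states at chosen
sites after the neutral pass, leaving surrounding columns untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import CODON_TO_AA, CODONS, MISSING, Alignment
from .likelihood import MixtureClass, aa_mixture_classes
from .substmodels import AAModel
from .trees import Node, PhyloTree, parse_newick

# A synthetic ~20-taxon mammal-like species tree: three focal marine
# lineages (dolphin, walrus, manatee) placed non-sister among
# terrestrial relatives, branch lengths in amino-acid substitutions/site.
MARINE_MAMMAL_NEWICK = (
    "((((((human:0.02,(rhesus:0.01,baboon:0.01):0.015):0.01,"
    "marmoset:0.035):0.02,(mouse:0.08,rabbit:0.06):0.02):0.01,"
    "(((cat:0.04,(dog:0.035,walrus:0.02):0.01):0.02,"
    "(horse:0.05,flying_fox:0.06):0.005):0.005,"
    "((cow:0.045,dolphin:0.025):0.02,(pig:0.05,alpaca:0.045):0.01):0.01):0.01):0.015,"
    "((elephant:0.04,manatee:0.03):0.03,armadillo:0.07):0.01):0.05,"
    "(opossum:0.12,platypus:0.16):0.05);"
)

MARINE_GROUPS = {
    "cetaceans": ["dolphin"],
    "pinnipeds": ["walrus"],
    "sirenians": ["manatee"],
}


def marine_mammal_tree() -> PhyloTree:
    """The built-in synthetic species tree used by the toy study."""
    return parse_newick(MARINE_MAMMAL_NEWICK)


@dataclass
class PlantedFeature:
    """A ground-truth signal written into a simulated alignment."""

    site: int                     # 0-based column
    kind: str                     # "parallel" | "parallel_unique" | "unique"
    target_state: int             # state index in the alignment's alphabet
    focal_leaves: list[list[str]] # one leaf set per focal lineage


@dataclass
class SimulationSpec:
    tree: PhyloTree
    classes: list[MixtureClass]
    length: int
    seed: int
    planted: list[PlantedFeature] = field(default_factory=list)
    alphabet: str = "aa"

    @classmethod
    def from_aa_model(cls, tree: PhyloTree, model: AAModel, length: int,
                      seed: int, **kw) -> "SimulationSpec":
        return cls(tree=tree, classes=aa_mixture_classes(model),
                   length=length, seed=seed, alphabet="aa", **kw)


def _sample_categorical(rng: np.random.Generator,
                        probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; probs is (n, S)."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    return (u[:, None] > cum).sum(axis=1).astype(np.int16)


def simulate_alignment(spec: SimulationSpec
                       ) -> tuple[Alignment, pd.DataFrame]:
    """Simulate an alignment under the spec; returns (alignment, event log).

    The event log has one row per (branch, site) whose endpoint states
    differ, with columns branch (name of the child-side node), site
    (1-based), from_state, to_state.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    weights = np.array([c.weight for c in spec.classes])
    weights = weights / weights.sum()
    site_class = rng.choice(len(spec.classes), size=L, p=weights)

    states: dict[int, np.ndarray] = {}
    root = spec.tree.root
    root_states = np.empty(L, dtype=np.int16)
    for c, cls in enumerate(spec.classes):
        idx = np.where(site_class == c)[0]
        if idx.size:
            pi = np.asarray(cls.pi)
            root_states[idx] = rng.choice(len(pi), size=idx.size, p=pi / pi.sum())
    states[id(root)] = root_states

    internal_names = _internal_name_map(spec.tree)
    events = []
    for node in spec.tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child_states = np.empty(L, dtype=np.int16)
        for c, cls in enumerate(spec.classes):
            idx = np.where(site_class == c)[0]
            if not idx.size:
                continue
            p = cls.pmat(node)
            child_states[idx] = _sample_categorical(rng, p[parent_states[idx]])
        states[id(node)] = child_states
        changed = np.where(child_states != parent_states)[0]
        bname = node.name or internal_names[id(node)]
        for s in changed:
            events.append((bname, int(s) + 1,
                           int(parent_states[s]), int(child_states[s])))

    leaves = list(spec.tree.leaves())
    matrix = np.vstack([states[id(leaf)] for leaf in leaves])
    aln = Alignment([leaf.name for leaf in leaves], matrix, spec.alphabet)
    log = pd.DataFrame(events,
                       columns=["branch", "site", "from_state", "to_state"])
    log.attrs["internal_states"] = {
        (node.name or internal_names[id(node)]): states[id(node)]
        for node in spec.tree.preorder() if not node.is_leaf}
    log.attrs["site_class"] = site_class
    if spec.planted:
        features = _ensure_derived_targets(spec, states)
        aln, truth = plant_convergent_sites(aln, spec.tree, features,
                                            seed=spec.seed + 1)
        log.attrs["truth"] = truth
    return aln, log


def _ensure_derived_targets(spec: SimulationSpec,
                            states: dict[int, np.ndarray]
                            ) -> list[PlantedFeature]:
    """Resample planted targets that collide with the true ancestral
    state of any focal group (a planted 'substitution' must be derived).

    Comparison is at the amino-acid level for codon alignments.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_states = 20 if spec.alphabet == "aa" else 61

    def aa_of(state: int) -> str:
        return (CODON_TO_AA[state] if spec.alphabet == "codon"
                else str(state))

    adjusted = []
    for feat in spec.planted:
        anc_aas = set()
        for leafset in feat.focal_leaves:
            node = (spec.tree.mrca(leafset) if len(leafset) > 1
                    else spec.tree.find_leaf(leafset[0]))
            if node.parent is None:
                continue
            anc_aas.add(aa_of(int(states[id(node.parent)][feat.site])))
        target = feat.target_state
        if aa_of(target) in anc_aas:
            allowed = np.array([s for s in range(n_states)
                                if aa_of(s) not in anc_aas])
            target = int(rng.choice(allowed))
        adjusted.append(PlantedFeature(
            site=feat.site, kind=feat.kind, target_state=target,
            focal_leaves=feat.focal_leaves))
    return adjusted


def _internal_name_map(tree: PhyloTree) -> dict[int, str]:
    names = {}
    counter = 0
    for node in tree.preorder():
        if not node.is_leaf:
            names[id(node)] = f"N{counter}"
            counter += 1
    return names


def _states_conflicting(alphabet: str, target: int) -> np.ndarray:
    """States that would defeat a 'unique' feature at the amino-acid level."""
    if alphabet == "aa":
        return np.array([target])
    aa = CODON_TO_AA[target]
    return np.array([i for i, a in enumerate(CODON_TO_AA) if a == aa])


def plant_convergent_sites(alignment: Alignment, tree: PhyloTree,
                           features: Sequence[PlantedFeature],
                           seed: int = 0) -> tuple[Alignment, pd.DataFrame]:
    """Overwrite alignment columns with planted convergent signals.

    For each feature, every leaf in every focal leaf set is set to the
    target state.  For "unique"-flavored features all remaining leaves
    are guaranteed not to carry the target (amino-acid-level identity
    for codon alignments); offending background states are resampled.
    """
    rng = np.random.default_rng(seed)
    matrix = alignment.matrix.copy()
    rows = {t: i for i, t in enumerate(alignment.taxa)}
    truth_rows = []
    n_states = alignment.n_states
    for feat in features:
        if not (0 <= feat.site < alignment.n_columns):
            raise ValueError(f"planted site {feat.site} out of range")
        if not (0 <= feat.target_state < n_states):
            raise ValueError(f"invalid planted state {feat.target_state}")
        focal_rows = []
        for leafset in feat.focal_leaves:
            for name in leafset:
                if name not in rows:
                    raise ValueError(f"focal leaf {name!r} not in alignment")
                focal_rows.append(rows[name])
        matrix[focal_rows, feat.site] = feat.target_state
        if feat.kind in ("parallel_unique", "unique"):
            conflict = _states_conflicting(alignment.alphabet,
                                           feat.target_state)
            allowed = np.setdiff1d(np.arange(n_states), conflict)
            if allowed.size < 1:
                raise ValueError(
                    "unique feature impossible: no non-target states left")
            background = [i for i in range(alignment.n_taxa)
                          if i not in focal_rows]
            for i in background:
                if matrix[i, feat.site] in conflict:
                    matrix[i, feat.site] = rng.choice(allowed)
        truth_rows.append((feat.site + 1, feat.kind, feat.target_state))
    truth = pd.DataFrame(truth_rows, columns=["site", "kind", "target_state"])
    return (Alignment(list(alignment.taxa), matrix, alignment.alphabet,
                      reference=alignment.reference, gene=alignment.gene),
            truth)


# ---------------------------------------------------------------- toy study


@dataclass
class ToyStudyConfig:
    """Gene counts per generating regime and per-gene dimensions.

    Defaults are the study conditions emulated throughout: a 20-taxon
    mammal-like tree, three focal marine lineages, genes of 300-900
    codons, background purifying selection (omega 0.2), foreground
    relaxation at omega 0.8 for rapid genes, and a handful of planted
    parallel/unique amino-acid sites.
    """

    n_h0: int = 70
    n_ha: int = 10
    n_fg_omega: int = 15
    n_planted: int = 5
    codons_min: int = 300
    codons_max: int = 900
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_foreground: float = 0.8
    planted_sites_per_gene: int = 3
    ha_tree_index: int = 0


def generate_toy_study(config: ToyStudyConfig, seed: int,
                       outdir: str | os.PathLike) -> pd.DataFrame:
    """Write a complete runnable study to ``outdir``; returns the truth table.

    Layout: one FASTA (CDS) per gene under ``alignments/``, the species
    tree as ``species_tree.nwk``, ``truth.tsv``, a study ``config.yaml``
    and a reproducibility manifest.
    """
    from .codon import CodonModel, uniform_codon_frequencies
    from .convergence import generate_alternative_topologies

    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "alignments"), exist_ok=True)
    rng = np.random.default_rng(seed)
    tree = marine_mammal_tree()
    # codon branch lengths: amino-acid tree rescaled to subs/codon
    codon_tree = tree.copy().scale(2.5)
    focal = [leaves[0] for leaves in MARINE_GROUPS.values()]
    hypotheses = generate_alternative_topologies(codon_tree, focal)
    ha_tree = hypotheses[config.ha_tree_index % len(hypotheses)].h_a.copy()
    for node in ha_tree.preorder():
        if node.parent is not None and node.length <= 0:
            node.length = 0.05

    pi = uniform_codon_frequencies()
    truth_rows = []
    regimes = (["h0"] * config.n_h0 + ["ha"] * config.n_ha
               + ["fg_omega"] * config.n_fg_omega
               + ["planted"] * config.n_planted)
    for g, regime in enumerate(regimes):
        gene = f"g{g:04d}"
        length = int(rng.integers(config.codons_min, config.codons_max + 1))
        gene_seed = int(rng.integers(0, 2**31 - 1))
        sim_tree = ha_tree if regime == "ha" else codon_tree
        if regime == "fg_omega":
            sim_tree = codon_tree.copy()
            for name in focal:
                sim_tree.find_leaf(name).label = "fg"
            model = CodonModel(kappa=config.kappa, pi=pi,
                               omega=config.omega_background,
                               omega_by_label={"fg": config.omega_foreground})
        else:
            model = CodonModel(kappa=config.kappa, pi=pi,
                               omega=config.omega_background)
        planted = []
        if regime == "planted":
            sites = rng.choice(length, size=config.planted_sites_per_gene,
                               replace=False)
            for s in sites:
                target = int(rng.integers(0, 61))
                planted.append(PlantedFeature(
                    site=int(s), kind="parallel_unique", target_state=target,
                    focal_leaves=[list(v) for v in MARINE_GROUPS.values()]))
        spec = SimulationSpec(tree=sim_tree, classes=model.mixture_classes(),
                              length=length, seed=gene_seed, planted=planted,
                              alphabet="codon")
        aln, log = simulate_alignment(spec)
        aln.gene = gene
        aln.write_fasta(os.path.join(outdir, "alignments", f"{gene}.fasta"))
        truth_rows.append({"gene": gene, "regime": regime,
                           "n_codons": length, "seed": gene_seed,
                           "planted_sites": ",".join(
                               str(f.site + 1) for f in planted)})

    with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
        fh.write(codon_tree.to_newick() + "\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    config_doc = {
        "species_tree": "species_tree.nwk",
        "alignments_dir": "alignments",
        "focal_groups": {k: list(v) for k, v in MARINE_GROUPS.items()},
        "seed": seed,
    }
    import yaml
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config_doc, fh, sort_keys=True)
    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "n_genes": len(regimes),
        "truth_sha256": hashlib.sha256(
            truth.to_csv(sep="\t", index=False).encode()).hexdigest(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return truth
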