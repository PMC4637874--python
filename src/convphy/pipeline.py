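"""Study orchestration: filters, per-gene fan-out, and report tables.

A study directory (per-gene CDS FASTAs + species tree + focal-group
config) is pushed through the full battery: input filters, the
sitewise-likelihood convergence scan against forced-monophyly
topologies, ancestral reconstruction with parallel/unique substitution
classification, codon selection models (branch, branch-site, M7/M8,
Clade Model C), and the convergence-selection regressions.  Results
are written as TSV tables plus a machine-readable summary; per-gene
JSON checkpoints make reruns resumable and deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .alignment import Alignment, AlignmentError, read_alignment
from .ancestral import (FocalGroupConfig, calls_to_frame,
                        call_backward_substitutions,
                        call_parallel_substitutions,
                        call_unique_substitutions,
                        marginal_ancestral_reconstruction)
from .codon import (fit_branch_model, fit_branch_site_model,
                    fit_clade_model_c, fit_sites_m7_m8, flag_foreground)
from .convergence import (ConvergenceHypothesis, GeneFit, NullDistribution,
                          compute_delta_ssls, empirical_p, fit_gene_h0,
                          generate_alternative_topologies)
from .link import fit_locus_regressions, join_site_metrics
from .optimize import optimize_likelihood
from .simulate import SimulationSpec, simulate_alignment
from .substmodels import AAModel
from .trees import PhyloTree, parse_newick

FLOAT_FMT = "%.6g"


@dataclass
class StudyConfig:
    """Validated configuration of a full study run."""

    alignments_dir: str
    species_tree: str
    focal_groups: dict[str, list[str]]
    seed: int = 0
    reference_alignments_dir: Optional[str] = None
    alt_topology_dir: Optional[str] = None
    aa_model: str = "JTT"
    gamma_categories: int = 4
    alpha: float = 0.05
    aggregation: str = "any"
    mt_method: str = "bh"
    n_null_templates: int = 5
    null_replicates: int = 5
    max_hypotheses: Optional[int] = None
    fit_tol: float = 1e-4
    min_cds_length: int = 150
    stages: dict[str, bool] = field(default_factory=lambda: {
        "convergence": True, "asr": True, "branch": True,
        "branch_site": True, "sites": True, "cmc": True, "link": True})

    def __post_init__(self) -> None:
        if self.aggregation not in ("any", "all", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.mt_method not in ("bh", "bonferroni"):
            raise ValueError(f"unknown mt method {self.mt_method!r}")
        for path in (self.alignments_dir, self.species_tree):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if not self.focal_groups:
            raise ValueError("no focal groups configured")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if p is None or os.path.isabs(p) else os.path.join(base, p)

        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in doc.items() if k in known}
        for key in ("alignments_dir", "species_tree",
                    "reference_alignments_dir", "alt_topology_dir"):
            if kw.get(key):
                kw[key] = resolve(kw[key])
        kw.update(overrides)
        return cls(**kw)


# ------------------------------------------------------------------ filters


def filter_genes(alignment_paths: Sequence[str],
                 min_length: int = 150
                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Apply the CDS input filters.

    Sequences shorter than ``min_length`` nucleotides or with length not
    divisible by 3 are discarded; when several files share a gene id
    (the filename stem up to the first dot) the longest CDS is kept.
    Returns (gene id -> path, exclusion log).
    """
    candidates: dict[str, tuple[str, int]] = {}
    log_rows = []
    for path in sorted(alignment_paths):
        name = os.path.basename(path)
        gene = name.split(".")[0]
        try:
            length = _cds_length(path)
        except Exception as exc:
            log_rows.append({"file": name, "gene": gene, "status": "excluded",
                             "reason": f"malformed: {exc}"})
            continue
        if length < min_length:
            log_rows.append({"file": name, "gene": gene, "status": "excluded",
                             "reason": f"length < {min_length}"})
            continue
        if length % 3 != 0:
            log_rows.append({"file": name, "gene": gene, "status": "excluded",
                             "reason": "not divisible by 3"})
            continue
        prev = candidates.get(gene)
        if prev is None or length > prev[1]:
            if prev is not None:
                log_rows.append({"file": os.path.basename(prev[0]),
                                 "gene": gene, "status": "excluded",
                                 "reason": "shorter transcript"})
            candidates[gene] = (path, length)
        else:
            log_rows.append({"file": name, "gene": gene, "status": "excluded",
                             "reason": "shorter transcript"})
    for gene, (path, _) in candidates.items():
        log_rows.append({"file": os.path.basename(path), "gene": gene,
                         "status": "retained", "reason": ""})
    log = pd.DataFrame(log_rows).sort_values(["gene", "file"],
                                             ignore_index=True)
    return {g: p for g, (p, _) in sorted(candidates.items())}, log


def _cds_length(path: str) -> int:
    lengths = set()
    seq_len = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if seq_len:
                    lengths.add(seq_len)
                seq_len = 0
            elif line:
                seq_len += len(line)
    if seq_len:
        lengths.add(seq_len)
    if not lengths:
        raise AlignmentError("no sequences found")
    if len(lengths) > 1:
        raise AlignmentError(f"ragged rows (lengths {sorted(lengths)})")
    return lengths.pop()


# ------------------------------------------------------------ adjustments


def adjust_pvalues(p_values: Sequence[float],
                   method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, order kept."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    name = {"bh": "fdr_bh", "benjamini_hochberg": "fdr_bh",
            "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=name)[1]


# --------------------------------------------------------------- the study


def _gene_seed(master_seed: int, gene: str, salt: str = "") -> int:
    return zlib.crc32(f"{master_seed}:{gene}:{salt}".encode()) & 0x7FFFFFFF


def _load_hypotheses(config: StudyConfig,
                     species_tree: PhyloTree) -> list[ConvergenceHypothesis]:
    focal = [leaf for leaves in config.focal_groups.values()
             for leaf in leaves]
    if config.alt_topology_dir:
        hyps = []
        for name in sorted(os.listdir(config.alt_topology_dir)):
            if not name.endswith((".nwk", ".newick", ".tree")):
                continue
            with open(os.path.join(config.alt_topology_dir, name)) as fh:
                ha = parse_newick(fh.read())
            hyps.append(ConvergenceHypothesis(
                id=os.path.splitext(name)[0], h_0=species_tree, h_a=ha,
                focal=tuple(focal)))
        if hyps:
            return hyps[:config.max_hypotheses]
    hyps = generate_alternative_topologies(species_tree, focal)
    return hyps[:config.max_hypotheses]


def build_null_distributions(
    gene_fits: Sequence[GeneFit],
    hypotheses: Sequence[ConvergenceHypothesis],
    replicates: int,
    seed: int,
    **fit_kw,
) -> dict[str, NullDistribution]:
    """Simulate under fitted H0 models; score every hypothesis per
    replicate (one H0 re-fit shared across hypotheses)."""
    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {h.id: [] for h in hypotheses}
    for fit in gene_fits:
        for _ in range(replicates):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            spec = SimulationSpec.from_aa_model(
                fit.tree, fit.model, fit.length, seed=sim_seed)
            sim_aln, _ = simulate_alignment(spec)
            sim_aln.gene = f"{fit.gene}_null"
            _, _, fit_h0 = optimize_likelihood(
                hypotheses[0].h_0, sim_aln, fit.model, **fit_kw)
            for hyp in hypotheses:
                support = compute_delta_ssls(sim_aln, hyp, fit.model,
                                             fit_h0=fit_h0, **fit_kw)
                values[hyp.id].append(support.mean_dssls)
    return {hid: NullDistribution(np.array(v)) for hid, v in values.items()}


def run_study(config: StudyConfig, outdir: str,
              resume: bool = True) -> dict:
    """Run every enabled stage over every retained gene; write reports.

    Returns the summary dictionary.  Reruns with the same seed are
    byte-identical; per-gene checkpoints under ``outdir/checkpoints``
    are reused when ``resume`` is on.
    """
    os.makedirs(outdir, exist_ok=True)
    ckpt_dir = os.path.join(outdir, "checkpoints")
    os.makedirs(ckpt_dir, exist_ok=True)
    stages = config.stages

    with open(config.species_tree) as fh:
        species_tree = parse_newick(fh.read())
    group_cfg = FocalGroupConfig(groups=config.focal_groups)
    focal_leaves = [leaf for leaves in config.focal_groups.values()
                    for leaf in leaves]
    aa_model = AAModel(name=config.aa_model, alpha=1.0,
                       k=config.gamma_categories)

    paths = [os.path.join(config.alignments_dir, n)
             for n in sorted(os.listdir(config.alignments_dir))
             if n.endswith((".fa", ".fasta", ".phy"))]
    retained, filter_log = filter_genes(paths, config.min_cds_length)
    filter_log.to_csv(os.path.join(outdir, "filter_log.tsv"),
                      sep="\t", index=False)

    hypotheses = (_load_hypotheses(config, species_tree)
                  if stages.get("convergence") else [])

    nulls: dict[str, NullDistribution] = {}
    if stages.get("convergence"):
        template_genes = list(retained)[:config.n_null_templates]
        fits = []
        for gene in template_genes:
            aln = read_alignment(retained[gene], "codon", gene=gene)
            fits.append(fit_gene_h0(aln.to_amino_acids(), species_tree,
                                    aa_model, tol=config.fit_tol))
        nulls = build_null_distributions(
            fits, hypotheses, config.null_replicates,
            seed=_gene_seed(config.seed, "__null__"), tol=config.fit_tol)
        null_dump = pd.DataFrame(
            [{"hypothesis": hid, "dssls": v}
             for hid, null in sorted(nulls.items())
             for v in null.values])
        null_dump.to_csv(os.path.join(outdir, "null_distribution.tsv"),
                         sep="\t", index=False, float_format=FLOAT_FMT)

    reference_aln = None
    if config.reference_alignments_dir:
        ref_files = sorted(os.listdir(config.reference_alignments_dir))
        reference_aln = {
            os.path.basename(f).split(".")[0]:
                os.path.join(config.reference_alignments_dir, f)
            for f in ref_files}

    gene_rows = []
    site_rows = []
    call_frames = []
    for gene, path in retained.items():
        ckpt_path = os.path.join(ckpt_dir, f"{gene}.json")
        if resume and os.path.exists(ckpt_path):
            with open(ckpt_path) as fh:
                ckpt = json.load(fh)
            gene_rows.append(ckpt["row"])
            site_rows.extend(ckpt["sites"])
            if ckpt["calls"]:
                call_frames.append(pd.DataFrame(ckpt["calls"]))
            continue
        row, sites, calls = _run_gene(
            gene, path, config, species_tree, group_cfg, focal_leaves,
            aa_model, hypotheses, nulls, reference_aln)
        gene_rows.append(row)
        site_rows.extend(sites)
        if calls:
            call_frames.append(pd.DataFrame(calls))
        with open(ckpt_path, "w") as fh:
            json.dump({"row": row, "sites": sites, "calls": calls}, fh,
                      sort_keys=True)

    report = pd.DataFrame(gene_rows).sort_values("gene", ignore_index=True)
    if stages.get("branch") and "branch_p" in report:
        ok = report["branch_p"].notna()
        for method, col in (("bh", "branch_p_bh"),
                            ("bonferroni", "branch_p_bonferroni")):
            report[col] = np.nan
            if ok.any():
                report.loc[ok, col] = adjust_pvalues(
                    report.loc[ok, "branch_p"], method)
        report["rapid_adjusted"] = (
            (report["delta_omega"] > 0)
            & (report[f"branch_p_{config.mt_method}"] <= config.alpha))

    # candidate aquatic-adaptation flag: rapid AND convergent
    if stages.get("branch") and stages.get("convergence"):
        report["candidate"] = (report["rapid"].fillna(False).astype(bool)
                               & report["convergent"].fillna(False)
                               .astype(bool))
    report.to_csv(os.path.join(outdir, "gene_report.tsv"), sep="\t",
                  index=False, float_format=FLOAT_FMT)

    sites_df = pd.DataFrame(site_rows)
    if not sites_df.empty:
        sites_df.to_csv(os.path.join(outdir, "site_metrics.tsv"), sep="\t",
                        index=False, float_format=FLOAT_FMT)
    calls_df = (pd.concat(call_frames, ignore_index=True)
                if call_frames else pd.DataFrame())
    if not calls_df.empty:
        calls_df.to_csv(os.path.join(outdir, "substitution_calls.tsv"),
                        sep="\t", index=False, float_format=FLOAT_FMT)

    regression_summary = pd.DataFrame()
    if stages.get("link") and not sites_df.empty and {
            "dssls", "omega", "category"} <= set(sites_df.columns):
        usable = sites_df.dropna(subset=["dssls", "omega", "category"])
        if not usable.empty:
            usable = usable.astype({"category": int})
            regs, regression_summary = fit_locus_regressions(
                usable, min_sites=10, alpha=config.alpha)
            if regs:
                pd.DataFrame([r.__dict__ for r in regs]).to_csv(
                    os.path.join(outdir, "locus_regressions.tsv"),
                    sep="\t", index=False, float_format=FLOAT_FMT)
            if not regression_summary.empty:
                regression_summary.to_csv(
                    os.path.join(outdir, "regression_summary.tsv"),
                    sep="\t", index=False, float_format=FLOAT_FMT)

    summary = _summarize(report, calls_df, config)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config),
                       sort_keys=True).encode()).hexdigest(),
        "n_genes": len(retained),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _run_gene(gene, path, config, species_tree, group_cfg, focal_leaves,
              aa_model, hypotheses, nulls, reference_aln):
    stages = config.stages
    row: dict = {"gene": gene, "status": "ok"}
    sites: list[dict] = []
    calls: list[dict] = []
    try:
        codon_aln = read_alignment(path, "codon", gene=gene)
        aa_aln = codon_aln.to_amino_acids()
    except Exception as exc:
        row.update(status=f"load_error: {exc}")
        return row, sites, calls
    row["n_codons"] = codon_aln.n_columns

    dssls_by_site = None
    if stages.get("convergence"):
        try:
            _, _, fit_h0 = optimize_likelihood(species_tree, aa_aln, aa_model,
                                               tol=config.fit_tol)
            per_hyp = []
            dssls_stack = []
            for hyp in hypotheses:
                support = compute_delta_ssls(aa_aln, hyp, aa_model,
                                             fit_h0=fit_h0,
                                             tol=config.fit_tol)
                support.p_value = empirical_p(support.mean_dssls,
                                              nulls[hyp.id])
                per_hyp.append(support)
                dssls_stack.append(support.dssls)
                row[f"dssls_{hyp.id}"] = support.mean_dssls
                row[f"p_{hyp.id}"] = support.p_value
            p_vals = np.array([s.p_value for s in per_hyp])
            means = np.array([s.mean_dssls for s in per_hyp])
            row["mean_dssls"] = float(means.mean())
            if config.aggregation == "all":
                row["convergent"] = bool((p_vals <= config.alpha).all())
            elif config.aggregation == "mean":
                pooled = NullDistribution(np.concatenate(
                    [nulls[h.id].values for h in hypotheses]))
                row["p_mean_aggregate"] = empirical_p(float(means.mean()),
                                                      pooled)
                row["convergent"] = bool(
                    row["p_mean_aggregate"] <= config.alpha)
            else:  # "any"
                row["convergent"] = bool((p_vals <= config.alpha).any())
            row["convergent_all"] = bool((p_vals <= config.alpha).all())
            row["convergent_any"] = bool((p_vals <= config.alpha).any())
            dssls_by_site = np.mean(dssls_stack, axis=0)
        except Exception as exc:
            row["convergence_error"] = str(exc)

    if stages.get("asr"):
        try:
            fitted_tree, asr = marginal_ancestral_reconstruction(
                species_tree, aa_aln, aa_model, tol=config.fit_tol)
            par_calls, counters = call_parallel_substitutions(
                fitted_tree, aa_aln, asr, group_cfg)
            uniq_calls = call_unique_substitutions(
                fitted_tree, aa_aln, asr, group_cfg)
            all_calls = par_calls + uniq_calls
            if reference_aln and gene in reference_aln:
                ref = read_alignment(reference_aln[gene], "aa", gene=gene)
                all_calls = call_backward_substitutions(all_calls, ref)
            frame = calls_to_frame(all_calls)
            calls = frame.to_dict("records") if not frame.empty else []
            row["n_parallel"] = sum(
                1 for c in all_calls if c.category.startswith("parallel"))
            row["n_parallel_unique"] = sum(
                1 for c in all_calls if c.category == "parallel_unique")
            row["n_unique"] = sum(
                1 for c in all_calls if c.category == "unique")
            row["n_heterogeneous_skipped"] = counters["heterogeneous_group"]
        except Exception as exc:
            row["asr_error"] = str(exc)

    fg_tree = flag_foreground(species_tree, focal_leaves)
    if stages.get("branch"):
        try:
            res = fit_branch_model(fg_tree, codon_aln, alpha=config.alpha)
            if res.flagged:
                row["branch_flagged"] = res.flagged
                row["rapid"] = None
                row["branch_p"] = None
                row["delta_omega"] = None
            else:
                row["omega_fg"] = res.omega_fg
                row["omega_bg"] = res.omega_bg
                row["delta_omega"] = res.delta_omega
                row["branch_p"] = res.lrt.p_value
                row["rapid"] = res.rapid
                row["omega_fg_gt1"] = bool(res.omega_fg > 1.0)
        except Exception as exc:
            row["branch_error"] = str(exc)

    if stages.get("branch_site"):
        for lineage, leaves in config.focal_groups.items():
            try:
                tree_l = flag_foreground(species_tree, leaves)
                res = fit_branch_site_model(tree_l, codon_aln,
                                            alpha=config.alpha)
                row[f"psg_{lineage}"] = (None if res.flagged
                                         else res.positively_selected)
                if res.lrt is not None:
                    row[f"psg_p_{lineage}"] = res.lrt.p_value
            except Exception as exc:
                row[f"psg_error_{lineage}"] = str(exc)

    omega_by_site = None
    if stages.get("sites"):
        try:
            res = fit_sites_m7_m8(species_tree, codon_aln,
                                  alpha=config.alpha)
            if res.lrt is not None:
                row["m8_p"] = res.lrt.p_value
                row["m8_favored"] = bool(res.lrt.p_value <= config.alpha)
            if res.sitewise_omega is not None:
                omega_by_site = res.sitewise_omega
        except Exception as exc:
            row["sites_error"] = str(exc)

    category_by_site = None
    if stages.get("cmc"):
        try:
            res = fit_clade_model_c(fg_tree, codon_aln)
            if res.lrt is not None:
                row["cmc_p"] = res.lrt.p_value
            if res.params is not None:
                row["cmc_omega2_fg"] = res.params.get("omega2_fg")
                row["cmc_omega2_bg"] = res.params.get("omega2_bg")
            category_by_site = res.site_categories
        except Exception as exc:
            row["cmc_error"] = str(exc)

    if stages.get("link"):
        n = codon_aln.n_columns
        for j in range(n):
            entry = {"gene": gene, "site": j + 1}
            has_any = False
            if dssls_by_site is not None:
                entry["dssls"] = float(dssls_by_site[j])
                has_any = True
            if omega_by_site is not None:
                entry["omega"] = float(omega_by_site[j])
                has_any = True
            if category_by_site is not None:
                entry["category"] = int(category_by_site[j])
                has_any = True
            if has_any:
                sites.append(entry)

    return row, sites, calls


def _summarize(report: pd.DataFrame, calls_df: pd.DataFrame,
               config: StudyConfig) -> dict:
    summary: dict = {"n_genes": int(len(report)),
                     "alpha": config.alpha,
                     "aggregation": config.aggregation}

    def frac(mask, denom_mask=None):
        denom = (report[denom_mask].sum() if denom_mask is not None
                 else len(report))
        return {"count": int(report[mask].sum()) if mask in report else 0,
                "denominator": int(denom)}

    if "rapid" in report:
        rapid = report["rapid"].fillna(False).astype(bool)
        summary["rapid_genes"] = {
            "count": int(rapid.sum()), "denominator": int(len(report)),
            "fraction": float(rapid.mean()) if len(report) else 0.0}
        if "omega_fg_gt1" in report:
            n_rapid = int(rapid.sum())
            n_pos = int((rapid & report["omega_fg_gt1"].fillna(False)
                         .astype(bool)).sum())
            summary["rapid_with_omega_fg_gt1"] = {
                "count": n_pos, "denominator": n_rapid,
                "fraction": (n_pos / n_rapid) if n_rapid else 0.0}
        if "rapid_adjusted" in report:
            summary["rapid_genes_adjusted"] = {
                "count": int(report["rapid_adjusted"].fillna(False)
                             .astype(bool).sum()),
                "denominator": int(len(report)),
                "method": config.mt_method}
    for key in ("convergent_any", "convergent_all"):
        if key in report:
            mask = report[key].fillna(False).astype(bool)
            summary[f"{key}_genes"] = {
                "count": int(mask.sum()), "denominator": int(len(report)),
                "fraction": float(mask.mean()) if len(report) else 0.0}
    if "candidate" in report:
        cand = report["candidate"].fillna(False).astype(bool)
        summary["candidate_genes"] = {
            "count": int(cand.sum()), "denominator": int(len(report)),
            "genes": report.loc[cand, "gene"].tolist()}
    if "n_parallel" in report:
        has_par = report["n_parallel"].fillna(0) > 0
        summary["genes_with_parallel"] = {
            "count": int(has_par.sum()), "denominator": int(len(report))}
        for cls_key, cls_col in (("rapid", "rapid"),
                                 ("convergent", "convergent"),
                                 ("candidate", "candidate")):
            if cls_col in report:
                cls_mask = report[cls_col].fillna(False).astype(bool)
                n_cls = int(cls_mask.sum())
                summary[f"{cls_key}_with_parallel"] = {
                    "count": int((cls_mask & has_par).sum()),
                    "denominator": n_cls,
                    "fraction": (int((cls_mask & has_par).sum()) / n_cls
                                 if n_cls else 0.0)}
    psg_cols = [c for c in report.columns if c.startswith("psg_")
                and not c.startswith(("psg_p_", "psg_error_"))]
    if psg_cols:
        any_psg = report[psg_cols].fillna(False).astype(bool).any(axis=1)
        summary["psg_any_lineage"] = {
            "count": int(any_psg.sum()), "denominator": int(len(report))}
        for cls_col in ("rapid", "convergent", "candidate"):
            if cls_col in report:
                cls_mask = report[cls_col].fillna(False).astype(bool)
                n_cls = int(cls_mask.sum())
                summary[f"{cls_col}_psg_overlap"] = {
                    "count": int((cls_mask & any_psg).sum()),
                    "denominator": n_cls,
                    "fraction": (int((cls_mask & any_psg).sum()) / n_cls
                                 if n_cls else 0.0)}
    return summary
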