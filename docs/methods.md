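# Methods

`convphy` detects and characterizes molecular convergence in lineages that
independently evolved a shared phenotype — the motivating system is three
marine mammal lineages (cetaceans, pinnipeds, sirenians) among terrestrial
relatives.  This note documents the models, the numerical choices, and what
the synthetic-data validation does and does not demonstrate.

## Likelihood engine

Per-site log-likelihoods are computed by Felsenstein's pruning algorithm
over a mixture of site classes.  Each class carries a weight, root
frequencies, and a per-branch reversible generator given as an
eigendecomposition of the symmetrized rate matrix, so P(t) = U exp(Λt) U⁻¹
is exact.  Amino-acid models (JTT, WAG; POISSON for closed-form checks) use
the published exchangeabilities and frequencies, scaled to one expected
substitution per site, with among-site rate variation approximated by k
equal-weight discrete-Gamma categories (category means over
equal-probability bins, the codeml convention; k = 4 by default, shape
α ∈ [0.02, 100]).  Gaps and ambiguity codes are missing data and enter the
pruning recursion as all-ones partials — never as a 21st state.

Numerics: alignment columns are compressed to unique site patterns;
partial vectors are rescaled per node with accumulated log-scalers
(required for 61-state codon models on 20-taxon trees); one-hot leaf
partials are applied as row gathers from P rather than matrix products.
These are pure refactorings of the same sum and were validated against the
naive implementation and against exhaustive enumeration over internal
states on all trees with ≤ 5 leaves.

Branch lengths are estimated by coordinate ascent: Brent's method per
branch against exact up/down partials maintained along a depth-first
traversal, sweeping until the total log-likelihood improves by < 1e-6
(the study pipeline uses 1e-4; ΔSSLS contrasts two equally converged fits
so the looser tolerance cancels).  Each branch search uses a
multiplicative window around the current value, widened by successive
sweeps.  Bounds: branch lengths ∈ [1e-6, 20].  Every accepted update
strictly improves the likelihood, so optimization is monotone.  The Gamma
shape is profiled by a bounded 1-D search interleaved with branch sweeps.
Model choice between JTT+Γ and WAG+Γ is by AIC after a full fit of each
candidate; equilibrium frequencies default to the model's published
values, with an empirical (+F) option recorded in the fit metadata.

## Convergence scan (ΔSSLS)

For a species topology H0 and an alternative topology HA in which the
focal taxa are forced into a monophyletic clade, per-site support is
ΔSSLS = lnL(HA) − lnL(H0), with branch lengths and α re-optimized
independently under each topology (sharing parameters would bias the
contrast toward H0).  A gene is summarized by the mean ΔSSLS over sites
with at least one residue observed; positive values support convergence.

Alternative topologies are enumerated by crossing the focal clade's
rooted resolutions (three for three taxa) with its attachment to each
branch where a focal taxon was originally attached — nine topologies for
three non-sister focal lineages.  No canonical nine-tree set exists for
an arbitrary species tree, so the enumeration is the documented default
and user-supplied Newick files override it.  Regrafted stems start at
0.1 substitutions/site and are re-fitted.

Significance is simulation-based: template genes are re-simulated under
their fitted H0 models, scored identically, and the observed gene-mean
ΔSSLS is referred to the stepwise empirical cdf of the null sample with
linear interpolation between order statistics (plotting positions i/R).
P = 1 − cdf, clamped to [1/(R+1), 1] so a value beyond all null samples is
reported at the resolution limit rather than zero.  The null is built
from gene-level means by default; a site-level variant pools per-site
values instead (the appropriate statistic depends on whether site- or
gene-level calls are wanted, and both readings of the protocol are
defensible).  Gene-level calls across hypotheses use "any" (≥ 1
hypothesis significant), "all", or "mean" (across-hypothesis average
referred to a pooled null).

## Ancestral reconstruction and substitution classes

Marginal ancestral states are empirical-Bayes posteriors: at each internal
node the product of up- and down-partials, summed over rate categories and
normalized.  The MAP state is taken per node and site; exact posterior
ties are broken alphabetically and flagged, and MAP posteriors below 0.5
are flagged low-confidence (no posterior cutoff is canonical for
accepting reconstructed residues; 0.5 is this package's choice, and
calls built on flagged ancestors carry the flag downstream).

A site is a **parallel** substitution when every focal group carries the
same derived residue (shared by all non-missing group leaves; groups that
are internally heterogeneous at the site are skipped and counted) and that
residue differs from each group's ancestral state — the MAP state at the
parent of the group's MRCA, i.e. the ancestor shared with its terrestrial
sister taxa.  The call is sub-labelled strict-parallel when the ancestral
states agree across groups, convergent otherwise.  It is additionally
**unique** when no background leaf and no group's ancestral node carries
the derived residue.  **Backward** annotation compares the derived residue
with a distant reference clade (e.g. non-mammal vertebrates) aligned to
the same columns: backward iff ≥ 50% (configurable) of non-missing
reference taxa match.  Gaps are never evidence; each call needs ≥ 1
non-missing leaf per focal group.

## Codon selection models

The GY94 codon model over the 61 sense codons of the standard code:
single-nucleotide changes at rate π(target) × κ^[transition] ×
ω^[nonsynonymous]; multi-nucleotide changes are instantaneous-rate zero.
Codon frequencies are F3×4 (position-specific nucleotide frequencies,
stops excluded and renormalized; a 1e-6 pseudocount guards empty cells).
All site-class generators share a single scale factor — the class-weighted
expected substitution rate on background branches — so nested model pairs
are mutually consistent and branch lengths read as expected
substitutions per codon on the background partition.

Per gene, branch lengths and κ are estimated once under the one-ratio
model (M0) and held fixed across the heavier variants; κ remains free in
the branch model.  Fits use Powell's method on log/logit-transformed
parameters with the ω start grid {0.8, 1.0, 1.5}: the first start runs to
convergence, the rest are capped exploratory runs, and the best point is
polished.  The tested models:

* **branch** — two-ratio (foreground marine terminal branches vs
  background) against one-ratio; df = 1.  Rapidly evolving iff
  Δω = ω_fg − ω_bg > 0 and LRT p ≤ 0.05.  Foreground defaults to the
  three flagged terminal lineages; a whole-clade option exists.
* **branch-site model A** — classes 0/1/2a/2b with foreground ω₂ ≥ 1,
  against the ω₂ = 1 null; df = 1 with the plain χ²₁ reference
  (conservative; the 50:50 mixture is available behind a flag).
* **M7 vs M8** — β(p, q) in 10 equal-probability categories (bin means,
  shapes bounded to [0.005, 99]); M8 adds a proportion 1 − p₀ at ω_s ≥ 1;
  df = 2.  Sitewise ω is the posterior-mean over classes and is emitted
  only when M8 is favored at α = 0.05.
* **Clade Model C vs M1a** — classes purifying/neutral/divergent with the
  third class's ω distinct between the focal clade and the background;
  df = 3 (p₁, ω₂_fg, ω₂_bg added).  Sites are assigned to the class with
  posterior > 0.5, otherwise unassigned.

Site posteriors are naive empirical Bayes (evaluated at the MLEs); a full
Bayes empirical Bayes integration is out of scope and the output metadata
says so.  Genes without synonymous variation are flagged (dS
unidentifiable) and excluded from calls rather than fitted.

## Convergence–selection regressions

Per-site mean ΔSSLS (over hypotheses), M8 posterior-mean ω (only from
genes where M8 was favored), and the CmC site category are inner-joined on
(gene, site).  Within each (gene, category) group with ≥ 10 sites and
non-degenerate ω, ordinary least squares of ΔSSLS on ω classifies the
locus as positive/negative (slope t-test p ≤ 0.05) or non-significant;
the cohort summary reports the fraction of significant loci with positive
slope per category.  The ω covariate is the M8 sitewise estimate, with
CmC categories used for stratification only — both fits are described by
the protocol but the join is not, and this is the reading most consistent
with "sitewise dN/dS" stratified into three categories; a pooled
per-locus variant is available.

## Synthetic data

The simulator draws a class per site, a root state from the class's
equilibrium frequencies, and propagates states down each branch by exact
transition-probability sampling at branch ends (endpoint sampling, not
Gillespie paths — an event log of endpoint differences is kept, which
undercounts multiple hits by a few percent at the branch lengths used).
Planted parallel/unique features overwrite the simulated states at chosen
sites after the fact, leaving all other columns untouched; "unique"
features resample background carriers of the target residue.

The built-in study emulates the motivating design: a synthetic 20-taxon
mammal-like species tree (tree height ≈ 0.21 amino-acid
substitutions/site; codon branch lengths scaled ×2.5) with dolphin,
walrus and manatee as non-sister focal lineages.  Default generating
regimes: background purifying selection ω = 0.2 with κ = 2 (typical
mammalian ortholog values), foreground relaxation ω = 0.8 for
rapidly evolving genes (relaxed constraint rather than positive selection,
matching the observation that almost no rapid genes exceed ω = 1), genes
of 300–900 codons, convergence genes simulated under one of the forced
monophyly topologies, and a few planted parallel/unique amino-acid sites
per planted gene.  What this validates: the statistical machinery —
calibration of the empirical-cdf P under the null, power against planted
topological convergence and foreground rate shifts, recovery of planted
parallel sites.  What it does not: real-data complications such as
alignment error, GC-biased gene conversion, heterotachy, indels, and
reference-bias in orthology calls, none of which are simulated.

## Calibration notes

Two properties of the simulation-null scan are worth knowing.  First,
the parametric-bootstrap null inherits the templates' parameter-fit
noise; if the observed cohort is artificially homogeneous while the
templates are heterogeneous fits, the pooled null is overdispersed and
the scan under-calls (measured ~1–2% at nominal 5%).  When the
templates are drawn from the same heterogeneous population as the
cohort — the protocol's own premise — the false-call rate is close to
nominal (~5–7% in the shipped checks).  Second, the ecdf floor 1/(R+1)
means a null sample must contain at least 20 values for a 0.05
threshold to be reachable at all.

The branch-model LRT referred to χ²₁ is mildly anticonservative at
desk-scale data: across several hundred null replicates (300 codons, 12
taxa) the pooled empirical size is ~6–8% at nominal 5%, with individual
100-replicate blocks ranging from about 3% to 15% — ordinary binomial
spread in the tail, a typical finite-sample property of codon LRTs.
The branch-site and M7/M8 LRTs are conservative (near-zero empirical
size) because their nulls sit on parameter-space boundaries.

## Problem sizes in the shipped checks

The validation suite runs replicate simulations at reduced problem sizes
chosen as the package's own desk-scale defaults: ΔSSLS sign and
calibration checks use 120–1000-site amino-acid genes on the 20-taxon
tree with 2 of the 9 hypotheses for the calibrated false-call rate;
codon type-I/power suites use 6–12-taxon trees with 150–300 codons and
10–100 replicates per check.  Full-scale replications (50 × 50 null
simulations, hundreds of genes, all 9 hypotheses) use the same code paths
through the public API and scale linearly.
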