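"""Codon substitution models and likelihood-ratio tests for selection.

The generator follows Goldman-Yang (1994): instantaneous change is
allowed only between codons differing at a single nucleotide, with a
transition/transversion multiplier kappa, a nonsynonymous multiplier
omega, and target-codon equilibrium frequencies (F3x4).  On top of this
sit the standard selection scans:

* branch model (two-ratio vs one-ratio) for rapidly evolving genes,
* branch-site model A vs its omega2=1 null for lineage-specific
  positive selection,
* M7 (beta) vs M8 (beta + omega_s >= 1) for sitewise selection, and
* Clade Model C vs M1a for clade-divergent site classes.

Branch lengths are estimated once per gene under the one-ratio model
and then held fixed across model variants; every variant is optimized
from multiple omega starting values (0.8 / 1.0 / 1.5) and the best
likelihood kept.  Site-class posteriors are naive empirical Bayes
(posteriors evaluated at the MLEs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .alignment import CODON_TO_AA, CODONS, MISSING, Alignment
from .likelihood import MixtureClass, TreeLikelihood
from .optimize import optimize_branch_lengths
from .substmodels import EigenQ
from .trees import PhyloTree

N_CODONS = 61
OMEGA_STARTS = (0.8, 1.0, 1.5)
BETA_SHAPE_BOUNDS = (0.005, 99.0)

# ------------------------------------------------------------ structure

_codon_nt = np.array([[("TCAG").index(ch) for ch in c] for c in CODONS])


def _structural_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    diff = (_codon_nt[:, None, :] != _codon_nt[None, :, :])
    ndiff = diff.sum(axis=2)
    single = ndiff == 1
    pos = diff.argmax(axis=2)
    a = np.take_along_axis(_codon_nt[:, None, :].repeat(N_CODONS, 1),
                           pos[:, :, None], axis=2)[:, :, 0]
    b = np.take_along_axis(_codon_nt[None, :, :].repeat(N_CODONS, 0),
                           pos[:, :, None], axis=2)[:, :, 0]
    # transitions: T<->C (0,1) and A<->G (2,3) in TCAG encoding
    is_ts = ((a // 2) == (b // 2)) & single
    aa = np.array([CODON_TO_AA[i] for i in range(N_CODONS)])
    nonsyn = (aa[:, None] != aa[None, :]) & single
    return single, is_ts, nonsyn


SINGLE_NT, IS_TRANSITION, IS_NONSYN = _structural_masks()


def f3x4_frequencies(alignment: Alignment,
                     pseudocount: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts."""
    if alignment.alphabet != "codon":
        raise ValueError("F3x4 requires a codon alignment")
    counts = np.zeros((3, 4))
    obs = alignment.matrix[alignment.matrix != MISSING]
    for p in range(3):
        counts[p] = np.bincount(_codon_nt[obs, p], minlength=4)
    if (counts == 0).any():
        counts = counts + pseudocount
    freq = counts / counts.sum(axis=1, keepdims=True)
    pi = (freq[0, _codon_nt[:, 0]] * freq[1, _codon_nt[:, 1]]
          * freq[2, _codon_nt[:, 2]])
    return pi / pi.sum()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def codon_rate_matrix(kappa: float, omega: float,
                      pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 generator; rows sum to zero."""
    q = np.where(SINGLE_NT, pi[None, :], 0.0)
    q = q * np.where(IS_TRANSITION, kappa, 1.0)
    q = q * np.where(IS_NONSYN, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _flow(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon site under Q at stationarity."""
    return float(-(pi * np.diag(q)).sum())


@dataclass
class CodonModel:
    """Single- or branch-heterogeneous-omega GY94 model (one site class).

    ``omega_by_label`` maps tree node labels (e.g. "fg") to a distinct
    omega for the branches carrying that label; unlabeled branches use
    ``omega``.  The generator is scaled so the background branches see
    one expected substitution per codon per unit branch length.
    """

    kappa: float
    pi: np.ndarray
    omega: float
    omega_by_label: dict[str, float] = field(default_factory=dict)

    def mixture_classes(self) -> list[MixtureClass]:
        spec = ClassSpec(weight=1.0, omega_bg=self.omega,
                         omega_by_label=dict(self.omega_by_label))
        return _classes_from_specs([spec], self.kappa, self.pi)


def build_codon_model(alignment: Alignment, kappa: float = 2.0,
                      omega: float = 0.2,
                      omega_by_label: Optional[dict[str, float]] = None
                      ) -> CodonModel:
    """GY94 model with F3x4 frequencies estimated from the alignment."""
    pi = f3x4_frequencies(alignment)
    return CodonModel(kappa=kappa, pi=pi, omega=omega,
                      omega_by_label=dict(omega_by_label or {}))


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested model fits."""

    lnl0: float
    lnl1: float
    df: int
    statistic: float
    p_value: float

    @classmethod
    def from_lnl(cls, lnl0: float, lnl1: float, df: int) -> "LRTResult":
        return likelihood_ratio_test(lnl0, lnl1, df)


def likelihood_ratio_test(lnl0: float, lnl1: float, df: int) -> LRTResult:
    """2*(lnL1 - lnL0) against a chi-square with ``df`` degrees of freedom."""
    if df <= 0:
        raise ValueError("df must be positive")
    if lnl1 < lnl0 - 1e-3:
        raise ValueError(
            f"nesting violated (lnL1={lnl1:.6f} < lnL0={lnl0:.6f}); "
            "re-optimize the alternative model")
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(lnl0=lnl0, lnl1=lnl1, df=df, statistic=stat, p_value=p)


# ----------------------------------------------------------- optimization


class _EigenCache:
    """Memoizes eigendecompositions of scaled GY94 generators."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self._store: dict[tuple, EigenQ] = {}

    def get(self, kappa: float, omega: float, scale: float) -> EigenQ:
        key = (round(kappa, 12), round(omega, 12), round(scale, 12))
        if key not in self._store:
            q = codon_rate_matrix(kappa, omega, self.pi) / scale
            self._store[key] = EigenQ.from_q(q, self.pi)
        return self._store[key]


@dataclass
class ClassSpec:
    """One site class: weight plus omega per branch partition label."""

    weight: float
    omega_bg: float
    omega_by_label: dict[str, float] = field(default_factory=dict)


def _classes_from_specs(specs: Sequence[ClassSpec], kappa: float,
                        pi: np.ndarray) -> list[MixtureClass]:
    """Mixture classes scaled per branch partition.

    Each branch-type's generators are scaled by that type's
    class-weighted expected substitution rate, so a branch length reads
    as expected substitutions per codon on that branch regardless of
    its omegas (the codeml convention); omegas are then identified from
    the nonsynonymous/synonymous composition alone, and nested variants
    stay mutually consistent.
    """
    labels = {None}
    for spec in specs:
        labels |= set(spec.omega_by_label)
    total_w = sum(spec.weight for spec in specs if spec.weight > 0)
    scales = {}
    for lab in labels:
        scales[lab] = sum(
            spec.weight / total_w * _flow(codon_rate_matrix(
                kappa, spec.omega_by_label.get(lab, spec.omega_bg)
                if lab is not None else spec.omega_bg, pi), pi)
            for spec in specs if spec.weight > 0)
    cache = _EigenCache(pi)
    classes = []
    for spec in specs:
        if spec.weight <= 0:
            continue
        bg = cache.get(kappa, spec.omega_bg, scales[None])
        table = {lab: cache.get(kappa,
                                spec.omega_by_label.get(lab, spec.omega_bg),
                                scales[lab])
                 for lab in labels if lab is not None}

        def eigen_for(node, bg=bg, table=table):
            return table.get(node.label, bg)

        classes.append(MixtureClass(weight=spec.weight, pi=pi,
                                    eigen_for=eigen_for))
    return classes


@dataclass
class CodonFit:
    """A maximized codon-model fit."""

    name: str
    lnl: float
    params: dict
    classes: Optional[list[MixtureClass]] = None
    engine: Optional[TreeLikelihood] = None


def _maximize(tree: PhyloTree, alignment: Alignment, pi: np.ndarray,
              build: Callable[[np.ndarray], list[ClassSpec]],
              x0_list: Sequence[np.ndarray], kappa0: float,
              name: str, fix_kappa: bool = False) -> CodonFit:
    """Nelder-Mead over (log kappa, model params) with multi-start.

    With ``fix_kappa`` the transition/transversion ratio is pinned at
    ``kappa0`` (shared per gene from the one-ratio fit), which removes a
    dimension from the heavier site-class models.
    """

    def split(x: np.ndarray) -> tuple[float, np.ndarray]:
        if fix_kappa:
            return kappa0, x
        return float(np.exp(x[0])), x[1:]

    def neg(x: np.ndarray) -> float:
        kappa, rest = split(x)
        try:
            engine = TreeLikelihood(
                tree, alignment, _classes_from_specs(build(rest), kappa, pi))
            lnl = engine.total_lnl()
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    # the first start runs to convergence; the remaining grid starts are
    # exploratory (capped) and the best point is polished at the end
    best = None
    for i, x0 in enumerate(x0_list):
        full0 = x0 if fix_kappa else np.concatenate([[np.log(kappa0)], x0])
        res = minimize(neg, full0, method="Powell",
                       options={"xtol": 1e-3, "ftol": 1e-6,
                                "maxiter": None if i == 0 else 2})
        if best is None or res.fun < best.fun:
            best = res
    if len(x0_list) > 1:
        res = minimize(neg, best.x, method="Powell",
                       options={"xtol": 1e-3, "ftol": 1e-6})
        if res.fun < best.fun:
            best = res
    kappa, rest = split(best.x)
    specs = build(rest)
    classes = _classes_from_specs(specs, kappa, pi)
    engine = TreeLikelihood(tree, alignment, classes)
    return CodonFit(name=name, lnl=float(-best.fun),
                    params={"kappa": kappa, "specs": specs,
                            "x": best.x.tolist()},
                    classes=classes, engine=engine)


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _stick(z: Sequence[float]) -> np.ndarray:
    """Stick-breaking map from R^n to an (n+1)-simplex."""
    props = []
    remaining = 1.0
    for zi in z:
        p = float(_sigmoid(zi)) * remaining
        props.append(p)
        remaining -= p
    props.append(remaining)
    return np.array(props)


# ----------------------------------------------------- data-quality guards


def has_synonymous_variation(alignment: Alignment) -> bool:
    """True if any column shows two codons encoding the same amino acid."""
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        col = col[col != MISSING]
        if col.size < 2:
            continue
        codons = np.unique(col)
        if len(codons) > 1:
            aas = {CODON_TO_AA[c] for c in codons}
            if len(aas) < len(codons):
                return True
    return False


def _is_invariant(alignment: Alignment) -> bool:
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        col = col[col != MISSING]
        if col.size and not (col == col[0]).all():
            return False
    return True


# ----------------------------------------------------------------- M0 fit


def fit_m0(tree: PhyloTree, alignment: Alignment,
           pi: Optional[np.ndarray] = None,
           optimize_branches: bool = True,
           rounds: int = 2) -> tuple[PhyloTree, CodonFit]:
    """One-ratio fit; returns (tree with ML branch lengths, fit)."""
    if pi is None:
        pi = f3x4_frequencies(alignment)
    tree = tree.copy()

    def build(p: np.ndarray) -> list[ClassSpec]:
        return [ClassSpec(weight=1.0, omega_bg=float(np.exp(p[0])))]

    fit = None
    for _ in range(rounds):
        starts = [np.array([np.log(w)]) for w in OMEGA_STARTS]
        if fit is not None:
            starts = [np.array([np.log(fit.params["specs"][0].omega_bg)])]
        fit = _maximize(tree, alignment, pi, build, starts,
                        kappa0=fit.params["kappa"] if fit else 2.0, name="M0")
        if not optimize_branches:
            break
        kappa = fit.params["kappa"]
        omega = fit.params["specs"][0].omega_bg

        def classes_fn(k=kappa, w=omega):
            return _classes_from_specs([ClassSpec(1.0, w)], k, pi)

        optimize_branch_lengths(tree, alignment, classes_fn, max_sweeps=2)
    # polish (kappa, omega) on the final branch lengths; without this the
    # one-ratio lnL is evaluated at slightly stale parameters, which
    # understates every null and inflates downstream LRTs
    warm = [np.array([np.log(fit.params["specs"][0].omega_bg)])]
    fit = _maximize(tree, alignment, pi, build, warm,
                    kappa0=fit.params["kappa"], name="M0")
    kappa = fit.params["kappa"]
    omega = fit.params["specs"][0].omega_bg
    fit = CodonFit(name="M0", lnl=fit.lnl,
                   params={"kappa": kappa, "omega": omega},
                   engine=fit.engine)
    return tree, fit


# ------------------------------------------------------------ branch model


@dataclass
class BranchModelResult:
    lrt: Optional[LRTResult]
    omega_fg: Optional[float]
    omega_bg: Optional[float]
    kappa: Optional[float]
    rapid: Optional[bool]
    flagged: Optional[str] = None

    @property
    def delta_omega(self) -> Optional[float]:
        if self.omega_fg is None:
            return None
        return self.omega_fg - self.omega_bg


def flag_foreground(tree: PhyloTree, leaves: Sequence[str],
                    label: str = "fg",
                    include_internal: bool = False) -> PhyloTree:
    """Label the terminal branches of ``leaves`` (optionally their MRCA
    clades) as foreground on a copy of the tree."""
    tree = tree.copy()
    for name in leaves:
        tree.find_leaf(name).label = label
    if include_internal and len(leaves) > 1:
        mrca = tree.mrca(list(leaves))
        stack = [mrca]
        while stack:
            node = stack.pop()
            node.label = label
            stack.extend(node.children)
    return tree


def fit_branch_model(tree: PhyloTree, alignment: Alignment,
                     alpha: float = 0.05,
                     pi: Optional[np.ndarray] = None) -> BranchModelResult:
    """Two-ratio (foreground/background) vs one-ratio LRT, df = 1.

    The tree must carry foreground flags (``node.label == "fg"``).  A
    gene is called rapidly evolving iff delta-omega > 0 and LRT p <=
    ``alpha``.
    """
    if not any(n.label == "fg" for n in tree.preorder() if n.parent):
        raise ValueError("no foreground branch flagged on the tree")
    if not has_synonymous_variation(alignment):
        return BranchModelResult(None, None, None, None, None,
                                 flagged="no synonymous variation; "
                                         "dS unidentifiable")
    if pi is None:
        pi = f3x4_frequencies(alignment)
    fitted_tree, m0 = fit_m0(tree, alignment, pi=pi)

    def build(p: np.ndarray) -> list[ClassSpec]:
        return [ClassSpec(weight=1.0, omega_bg=float(np.exp(p[0])),
                          omega_by_label={"fg": float(np.exp(p[1]))})]

    w0 = m0.params["omega"]
    starts = [np.array([np.log(w0), np.log(ws)]) for ws in OMEGA_STARTS]
    starts.append(np.array([np.log(w0), np.log(w0)]))
    alt = _maximize(fitted_tree, alignment, pi, build, starts,
                    kappa0=m0.params["kappa"], name="branch")
    lrt = likelihood_ratio_test(m0.lnl, alt.lnl, df=1)
    spec = alt.params["specs"][0]
    w_bg = spec.omega_bg
    w_fg = spec.omega_by_label["fg"]
    rapid = (w_fg - w_bg) > 0 and lrt.p_value <= alpha
    return BranchModelResult(lrt=lrt, omega_fg=w_fg, omega_bg=w_bg,
                             kappa=alt.params["kappa"], rapid=bool(rapid))


# -------------------------------------------------------- branch-site model


@dataclass
class BranchSiteResult:
    lrt: Optional[LRTResult]
    params: Optional[dict]
    site_posteriors: Optional[np.ndarray]  # (4, L) class posteriors
    positively_selected: Optional[bool]
    flagged: Optional[str] = None


def _branch_site_specs(p0: float, p1: float, w0: float,
                       w2: float) -> list[ClassSpec]:
    """Model A classes 0, 1, 2a, 2b with proportional 2a/2b split."""
    rest = max(0.0, 1.0 - p0 - p1)
    denom = p0 + p1 if (p0 + p1) > 0 else 1.0
    p2a = rest * p0 / denom
    p2b = rest * p1 / denom
    return [
        ClassSpec(weight=p0, omega_bg=w0),
        ClassSpec(weight=p1, omega_bg=1.0),
        ClassSpec(weight=p2a, omega_bg=w0, omega_by_label={"fg": w2}),
        ClassSpec(weight=p2b, omega_bg=1.0, omega_by_label={"fg": w2}),
    ]


def fit_branch_site_model(tree: PhyloTree, alignment: Alignment,
                          alpha: float = 0.05,
                          chi2_mixture: bool = False,
                          pi: Optional[np.ndarray] = None
                          ) -> BranchSiteResult:
    """Branch-site model A vs its omega2 = 1 null; LRT against chi2_1.

    The plain chi-square reference is conservative; ``chi2_mixture``
    switches to the 50:50 mixture of chi2_0 and chi2_1.
    """
    if not any(n.label == "fg" for n in tree.preorder() if n.parent):
        raise ValueError("no foreground lineage flagged on the tree")
    if not has_synonymous_variation(alignment):
        return BranchSiteResult(None, None, None, None,
                                flagged="no synonymous variation")
    if pi is None:
        pi = f3x4_frequencies(alignment)
    fitted_tree, m0 = fit_m0(tree, alignment, pi=pi)

    def build_null(p: np.ndarray) -> list[ClassSpec]:
        props = _stick(p[0:2])
        w0 = float(_sigmoid(p[2]))
        return _branch_site_specs(props[0], props[1], w0, 1.0)

    def build_alt(p: np.ndarray) -> list[ClassSpec]:
        props = _stick(p[0:2])
        w0 = float(_sigmoid(p[2]))
        w2 = 1.0 + float(np.exp(p[3]))
        return _branch_site_specs(props[0], props[1], w0, w2)

    base = np.array([1.0, 1.0, 0.0])
    null_starts = [base, np.array([0.0, 0.0, 0.0]),
                   np.array([2.0, -1.0, -1.0])]
    null = _maximize(fitted_tree, alignment, pi, build_null, null_starts,
                     kappa0=m0.params["kappa"], name="branch-site-null",
                     fix_kappa=True)
    starts = [np.concatenate([base, [np.log(max(ws - 1.0, 0.05))]])
              for ws in (1.1, 1.5, 3.0)]
    alt = _maximize(fitted_tree, alignment, pi, build_alt, starts,
                    kappa0=m0.params["kappa"], name="branch-site-alt",
                    fix_kappa=True)
    if alt.lnl < null.lnl:  # boundary case: alternative includes the null
        alt = CodonFit(name=alt.name, lnl=null.lnl, params=null.params,
                       classes=null.classes, engine=null.engine)
    lrt = likelihood_ratio_test(null.lnl, alt.lnl, df=1)
    p_value = lrt.p_value
    if chi2_mixture:
        p_value = 0.5 * float(stats.chi2.sf(lrt.statistic, 1))
        if lrt.statistic <= 0:
            p_value = 1.0
        lrt = LRTResult(lrt.lnl0, lrt.lnl1, 1, lrt.statistic, p_value)
    posteriors = alt.engine.class_posteriors()
    specs = alt.params["specs"]
    params = {
        "kappa": alt.params["kappa"],
        "p0": specs[0].weight, "p1": specs[1].weight,
        "omega0": specs[0].omega_bg,
        "omega2": specs[2].omega_by_label.get("fg", 1.0),
    }
    return BranchSiteResult(lrt=lrt, params=params,
                            site_posteriors=posteriors,
                            positively_selected=bool(p_value <= alpha))


# --------------------------------------------------------------- M7 and M8


@dataclass
class SitesModelResult:
    lrt: Optional[LRTResult]
    m7_params: Optional[dict]
    m8_params: Optional[dict]
    sitewise_omega: Optional[np.ndarray]  # None unless M8 favored
    posterior_mean_omega: Optional[np.ndarray]  # always available from M8
    flagged: Optional[str] = None


def _beta_category_means(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of k equal-probability bins of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
    # mean of Beta(p,q) on a bin via the Beta(p+1,q) incomplete-beta identity
    mass = np.diff(stats.beta.cdf(edges, p + 1.0, q))
    means = mass * (p / (p + q)) * k
    return np.clip(means, 1e-8, 1.0)


def _m7_specs(p: float, q: float, k: int = 10) -> list[ClassSpec]:
    return [ClassSpec(weight=1.0 / k, omega_bg=float(w))
            for w in _beta_category_means(p, q, k)]


def fit_sites_m7_m8(tree: PhyloTree, alignment: Alignment,
                    alpha: float = 0.05, n_beta_categories: int = 10,
                    pi: Optional[np.ndarray] = None,
                    warn_taxa: int = 6) -> SitesModelResult:
    """M7 (beta) vs M8 (beta & omega_s >= 1) LRT with df = 2.

    Sitewise omega (naive-empirical-Bayes posterior mean over classes
    under M8) is emitted only when the LRT favors M8 at ``alpha``.
    """
    import warnings
    if alignment.n_taxa < warn_taxa:
        warnings.warn(f"only {alignment.n_taxa} taxa; sitewise selection "
                      "estimates will be weak", stacklevel=2)
    if _is_invariant(alignment):
        return SitesModelResult(None, None, None, None, None,
                                flagged="alignment invariant; "
                                        "site model unidentifiable")
    if pi is None:
        pi = f3x4_frequencies(alignment)
    fitted_tree, m0 = fit_m0(tree, alignment, pi=pi)
    lo, hi = np.log(BETA_SHAPE_BOUNDS)

    def shape(z: float) -> float:
        return float(np.exp(np.clip(z, lo, hi)))

    def build_m7(x: np.ndarray) -> list[ClassSpec]:
        return _m7_specs(shape(x[0]), shape(x[1]), n_beta_categories)

    def build_m8(x: np.ndarray) -> list[ClassSpec]:
        specs = _m7_specs(shape(x[0]), shape(x[1]), n_beta_categories)
        p0 = float(_sigmoid(x[2]))
        ws = 1.0 + float(np.exp(x[3]))
        for s in specs:
            s.weight *= p0
        specs.append(ClassSpec(weight=1.0 - p0, omega_bg=ws))
        return specs

    m7 = _maximize(fitted_tree, alignment, pi, build_m7,
                   [np.array([0.0, 0.7]), np.array([-1.0, 0.0]),
                    np.array([0.7, 1.4])],
                   kappa0=m0.params["kappa"], name="M7", fix_kappa=True)
    pq = np.asarray(m7.params["x"][:2], dtype=float)  # warm start from M7
    m8_starts = [np.array([pq[0], pq[1], 2.0, np.log(0.5)]),
                 np.array([pq[0], pq[1], 1.0, np.log(2.0)]),
                 np.array([pq[0], pq[1], 3.0, np.log(0.1)])]
    m8 = _maximize(fitted_tree, alignment, pi, build_m8, m8_starts,
                   kappa0=m0.params["kappa"], name="M8", fix_kappa=True)
    if m8.lnl < m7.lnl:  # p0 -> 1 boundary: refuse spurious deficit
        m8 = CodonFit(name="M8", lnl=m7.lnl, params=m7.params,
                      classes=m7.classes, engine=m7.engine)
    lrt = likelihood_ratio_test(m7.lnl, m8.lnl, df=2)
    omegas = np.array([s.omega_bg for s in m8.params["specs"]
                       if s.weight > 0])
    post = m8.engine.class_posteriors()
    post_mean = omegas @ post
    flagged = None
    x = m8.params.get("x")
    if x is not None and len(x) >= 2:
        for z in x[0:2]:
            if not (lo < z < hi):
                flagged = "beta shape at bound"
    m7_specs_fit = m7.params["specs"]
    return SitesModelResult(
        lrt=lrt,
        m7_params={"kappa": m7.params["kappa"]},
        m8_params={"kappa": m8.params["kappa"],
                   "omegas": omegas.tolist(),
                   "weights": [s.weight for s in m8.params["specs"]]},
        sitewise_omega=post_mean if lrt.p_value <= alpha else None,
        posterior_mean_omega=post_mean,
        flagged=flagged,
    )


# ------------------------------------------------------------ clade model C


@dataclass
class CladeModelResult:
    lrt: Optional[LRTResult]
    params: Optional[dict]
    site_categories: Optional[np.ndarray]  # -1 unassigned, else 0/1/2
    site_posteriors: Optional[np.ndarray]  # (3, L)
    flagged: Optional[str] = None


def fit_clade_model_c(tree: PhyloTree, alignment: Alignment,
                      assign_threshold: float = 0.5,
                      pi: Optional[np.ndarray] = None) -> CladeModelResult:
    """Clade Model C vs M1a, df = 3.

    Class 0: purifying (omega0 in (0,1), both partitions); class 1:
    neutral (omega = 1); class 2: omega free and distinct between the
    focal ("fg"-labeled) and background partitions.  Sites are assigned
    to the category with posterior above ``assign_threshold``.
    """
    if not any(n.label == "fg" for n in tree.preorder() if n.parent):
        raise ValueError("no focal clade partition flagged on the tree")
    if _is_invariant(alignment):
        return CladeModelResult(None, None, None, None,
                                flagged="alignment invariant")
    if pi is None:
        pi = f3x4_frequencies(alignment)
    fitted_tree, m0 = fit_m0(tree, alignment, pi=pi)

    def build_m1a(x: np.ndarray) -> list[ClassSpec]:
        p0 = float(_sigmoid(x[0]))
        w0 = float(_sigmoid(x[1]))
        return [ClassSpec(weight=p0, omega_bg=w0),
                ClassSpec(weight=1.0 - p0, omega_bg=1.0)]

    def build_cmc(x: np.ndarray) -> list[ClassSpec]:
        props = _stick(x[0:2])
        w0 = float(_sigmoid(x[2]))
        w2_fg = float(np.exp(x[3]))
        w2_bg = float(np.exp(x[4]))
        return [
            ClassSpec(weight=props[0], omega_bg=w0),
            ClassSpec(weight=props[1], omega_bg=1.0),
            ClassSpec(weight=props[2], omega_bg=w2_bg,
                      omega_by_label={"fg": w2_fg}),
        ]

    m1a = _maximize(fitted_tree, alignment, pi, build_m1a,
                    [np.array([1.0, 0.0]), np.array([0.0, -1.0]),
                     np.array([2.0, 1.0])],
                    kappa0=m0.params["kappa"], name="M1a", fix_kappa=True)
    starts = [np.array([1.0, 0.0, 0.0, np.log(ws), np.log(0.5)])
              for ws in OMEGA_STARTS]
    cmc = _maximize(fitted_tree, alignment, pi, build_cmc, starts,
                    kappa0=m0.params["kappa"], name="CmC", fix_kappa=True)
    if cmc.lnl < m1a.lnl:
        cmc = CodonFit(name="CmC", lnl=m1a.lnl, params=m1a.params,
                       classes=m1a.classes, engine=m1a.engine)
    lrt = likelihood_ratio_test(m1a.lnl, cmc.lnl, df=3)
    post = cmc.engine.class_posteriors()
    if post.shape[0] < 3:  # degenerate: CmC collapsed to M1a
        pad = np.zeros((3 - post.shape[0], post.shape[1]))
        post = np.vstack([post, pad])
    categories = np.where(post.max(axis=0) > assign_threshold,
                          post.argmax(axis=0), -1)
    specs = cmc.params["specs"]
    params = {"kappa": cmc.params["kappa"],
              "omega0": specs[0].omega_bg,
              "p_categories": [s.weight for s in specs]}
    if len(specs) > 2:
        params["omega2_fg"] = specs[2].omega_by_label.get(
            "fg", specs[2].omega_bg)
        params["omega2_bg"] = specs[2].omega_bg
    return CladeModelResult(lrt=lrt, params=params,
                            site_categories=categories,
                            site_posteriors=post)
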