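import numpy as np
import pytest
from scipy import stats

from convphy.alignment import Alignment, CODONS, CODON_INDEX, CODON_TO_AA
from convphy.codon import (ClassSpec, CodonModel, LRTResult,
                           _classes_from_specs, codon_rate_matrix,
                           f3x4_frequencies, fit_branch_model, fit_m0,
                           flag_foreground, has_synonymous_variation,
                           likelihood_ratio_test, uniform_codon_frequencies)
from convphy.likelihood import TreeLikelihood
from convphy.simulate import SimulationSpec, simulate_alignment
from convphy.trees import parse_newick

PI = uniform_codon_frequencies()


def hand_built_gy94(kappa, omega, pi):
    """Independent construction of the GY94 generator, codon by codon."""
    nts = "TCAG"
    purine = {"A", "G"}
    q = np.zeros((61, 61))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            is_ts = ((a in purine) == (b in purine))
            rate = pi[j]
            if is_ts:
                rate *= kappa
            if CODON_TO_AA[i] != CODON_TO_AA[j]:
                rate *= omega
            q[i, j] = rate
        q[i, i] = -q[i].sum()
    return q


class TestGeneratorStructure:
    def test_matches_hand_construction(self):
        got = codon_rate_matrix(2.0, 0.3, PI)
        want = hand_built_gy94(2.0, 0.3, PI)
        assert np.allclose(got, want, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        q = codon_rate_matrix(2.0, 0.0, PI)
        for i in range(61):
            for j in range(61):
                if i != j and CODON_TO_AA[i] != CODON_TO_AA[j]:
                    assert q[i, j] == 0.0

    def test_detailed_balance_with_f3x4(self):
        rng = np.random.default_rng(3)
        aln = Alignment(
            ["a", "b"], rng.integers(0, 61, (2, 200)), "codon")
        pi = f3x4_frequencies(aln)
        q = codon_rate_matrix(1.7, 0.4, pi)
        flow = pi[:, None] * q
        assert np.allclose(flow, flow.T, atol=1e-12)

    def test_build_codon_model_from_alignment(self):
        rng = np.random.default_rng(12)
        aln = Alignment(["a", "b"], rng.integers(0, 61, (2, 300)), "codon")
        from convphy.codon import build_codon_model
        model = build_codon_model(aln, kappa=2.5, omega=0.3)
        assert model.pi.shape == (61,)
        assert model.pi.sum() == pytest.approx(1.0)
        classes = model.mixture_classes()
        assert len(classes) == 1

    def test_f3x4_exactly_uniform_when_positions_uniform(self):
        # with exactly uniform position-specific nucleotide frequencies
        # the F3x4 product is constant over the 61 sense codons
        import convphy.codon as codon_mod
        freq = np.full((3, 4), 0.25)
        nt = codon_mod._codon_nt
        pi = (freq[0, nt[:, 0]] * freq[1, nt[:, 1]] * freq[2, nt[:, 2]])
        pi = pi / pi.sum()
        assert np.allclose(pi, 1.0 / 61.0, atol=1e-12)

    def test_scaled_class_flow_is_unit(self):
        classes = _classes_from_specs([ClassSpec(1.0, 0.2)], 2.0, PI)
        eig = classes[0].eigen_for(parse_newick("(A:1,B:1);").root.children[0])
        q = (eig.evecs * eig.evals) @ eig.inv_evecs
        assert -(PI * np.diag(q)).sum() == pytest.approx(1.0, abs=1e-8)


@pytest.fixture(scope="module")
def setup():
    tree = parse_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
    model = CodonModel(kappa=2.0, pi=PI, omega=0.4)
    aln, _ = simulate_alignment(SimulationSpec(
        tree=tree, classes=model.mixture_classes(), length=120,
        seed=17, alphabet="codon"))
    one_ratio = _classes_from_specs([ClassSpec(1.0, 1.0)], 2.0, PI)
    ref = TreeLikelihood(tree, aln, one_ratio).total_lnl()
    return tree, aln, ref


class TestModelReductions:
    """With a single neutral class every model collapses to one-ratio."""

    def test_m8_with_neutral_point_mass(self, setup):
        tree, aln, ref = setup
        specs = [ClassSpec(weight=0.0, omega_bg=0.5),
                 ClassSpec(weight=1.0, omega_bg=1.0)]
        lnl = TreeLikelihood(tree, aln,
                             _classes_from_specs(specs, 2.0, PI)).total_lnl()
        assert lnl == pytest.approx(ref, abs=1e-4)

    def test_cmc_collapsed_to_neutral(self, setup):
        tree, aln, ref = setup
        fg = tree.copy()
        fg.find_leaf("A").label = "fg"
        specs = [ClassSpec(weight=1.0, omega_bg=1.0,
                           omega_by_label={"fg": 1.0})]
        lnl = TreeLikelihood(fg, aln,
                             _classes_from_specs(specs, 2.0, PI)).total_lnl()
        assert lnl == pytest.approx(ref, abs=1e-4)

    def test_branch_model_equal_ratios(self, setup):
        tree, aln, ref = setup
        fg = tree.copy()
        fg.find_leaf("B").label = "fg"
        model = CodonModel(kappa=2.0, pi=PI, omega=1.0,
                           omega_by_label={"fg": 1.0})
        lnl = TreeLikelihood(fg, aln, model.mixture_classes()).total_lnl()
        assert lnl == pytest.approx(ref, abs=1e-4)


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        res = likelihood_ratio_test(-100.0, -100.0, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        res = likelihood_ratio_test(-100.0, -100.0 + 3.841 / 2, 1)
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError, match="nesting"):
            likelihood_ratio_test(-100.0, -100.01, 1)

    def test_tiny_negative_statistic_clamped(self):
        res = likelihood_ratio_test(-100.0, -100.0000005, 1)
        assert res.statistic == 0.0

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-10, -9, 0)


class TestDataGuards:
    def test_synonymous_variation_detected(self):
        a = Alignment.from_sequences(
            [("x", "CTTACG"), ("y", "CTCACG")], "codon")  # CTT/CTC both Leu
        assert has_synonymous_variation(a)
        b = Alignment.from_sequences(
            [("x", "ATGACG"), ("y", "ATGACG")], "codon")
        assert not has_synonymous_variation(b)

    def test_branch_model_flags_unidentifiable_gene(self):
        tree = parse_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
        fg = flag_foreground(tree, ["A"])
        aln = Alignment.from_sequences(
            [(t, "ATGAAACCC") for t in "ABCD"], "codon")
        res = fit_branch_model(fg, aln)
        assert res.flagged is not None
        assert res.rapid is None

    def test_foreground_flag_required(self):
        tree = parse_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
        aln = Alignment.from_sequences(
            [(t, "ATGAAACCC") for t in "ABCD"], "codon")
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_model(tree, aln)


class TestBranchSite:
    def test_detects_lineage_specific_positive_selection(
            self, twelve_taxon_tree):
        # a flagged two-leaf clade with 20% of sites at foreground
        # omega 6 is a clearly detectable signal at 400 codons
        from convphy.codon import fit_branch_site_model
        fg = flag_foreground(twelve_taxon_tree, ["A", "B"],
                             include_internal=True)
        detected = 0
        for rep in range(2):
            sim = flag_foreground(twelve_taxon_tree, ["A", "B"],
                                  include_internal=True)
            specs = [ClassSpec(0.6, 0.1), ClassSpec(0.2, 1.0),
                     ClassSpec(0.2, 1.0, {"fg": 6.0})]
            aln, _ = simulate_alignment(SimulationSpec(
                tree=sim, classes=_classes_from_specs(specs, 2.0, PI),
                length=400, seed=8300 + rep, alphabet="codon"))
            res = fit_branch_site_model(fg, aln)
            detected += bool(res.positively_selected)
            assert res.params["omega2"] >= 1.0
            assert np.allclose(res.site_posteriors.sum(axis=0), 1.0,
                               atol=1e-8)
        assert detected >= 1

    def test_null_data_rarely_called(self, twelve_taxon_tree):
        from convphy.codon import fit_branch_site_model
        fg = flag_foreground(twelve_taxon_tree, ["A", "B"],
                             include_internal=True)
        hits = 0
        for rep in range(4):
            m = CodonModel(kappa=2.0, pi=PI, omega=0.2)
            aln, _ = simulate_alignment(SimulationSpec(
                tree=twelve_taxon_tree, classes=m.mixture_classes(),
                length=200, seed=8600 + rep, alphabet="codon"))
            res = fit_branch_site_model(fg, aln)
            hits += bool(res.positively_selected)
            # nesting: the alternative can never fall below its null
            assert res.lrt.lnl1 >= res.lrt.lnl0 - 1e-6
        assert hits <= 1

    def test_single_lineage_flag_required(self, twelve_taxon_tree):
        from convphy.codon import fit_branch_site_model
        aln = Alignment.from_sequences(
            [(t, "ATGAAACCC") for t in "ABCDEFGHIJKL"], "codon")
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_site_model(twelve_taxon_tree, aln)


class TestM0Recovery:
    def test_kappa_and_omega_recovered(self, twelve_taxon_tree):
        model = CodonModel(kappa=3.0, pi=PI, omega=0.25)
        aln, _ = simulate_alignment(SimulationSpec(
            tree=twelve_taxon_tree, classes=model.mixture_classes(),
            length=400, seed=19, alphabet="codon"))
        _, fit = fit_m0(twelve_taxon_tree, aln, pi=PI)
        assert fit.params["kappa"] == pytest.approx(3.0, rel=0.25)
        assert fit.params["omega"] == pytest.approx(0.25, rel=0.25)

    def test_multi_start_agreement(self, twelve_taxon_tree):
        # starting omega at 0.8 / 1.0 / 1.5 must reach the same optimum
        from convphy.codon import _maximize
        model = CodonModel(kappa=2.0, pi=PI, omega=0.3)
        aln, _ = simulate_alignment(SimulationSpec(
            tree=twelve_taxon_tree, classes=model.mixture_classes(),
            length=200, seed=23, alphabet="codon"))
        tree, m0 = fit_m0(twelve_taxon_tree, aln, pi=PI)

        def build(p):
            return [ClassSpec(weight=1.0, omega_bg=float(np.exp(p[0])))]

        lnls = []
        for w in (0.8, 1.0, 1.5):
            fit = _maximize(tree, aln, PI, build, [np.array([np.log(w)])],
                            kappa0=m0.params["kappa"], name="M0")
            lnls.append(fit.lnl)
        assert max(lnls) - min(lnls) < 1e-4
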