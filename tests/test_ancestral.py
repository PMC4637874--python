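import numpy as np
import pytest

from convphy._aa_data import AA_ORDER
from convphy.alignment import MISSING, Alignment
from convphy.ancestral import (FocalGroupConfig, call_backward_substitutions,
                               call_parallel_substitutions,
                               call_unique_substitutions,
                               marginal_ancestral_reconstruction)
from convphy.simulate import (MARINE_GROUPS, PlantedFeature, SimulationSpec,
                              marine_mammal_tree, simulate_alignment)
from convphy.substmodels import AAModel
from convphy.trees import parse_newick
from tests.conftest import aln_from_ints

AA = {aa: i for i, aa in enumerate(AA_ORDER)}
GROUPS = FocalGroupConfig(groups={k: list(v) for k, v in
                                  MARINE_GROUPS.items()})


def brute_force_root_posterior(tree, alignment, model, site):
    """Bayes posterior at the root by exhaustive joint enumeration."""
    from tests.test_likelihood import enumeration_site_lnl
    internals = [n for n in tree.preorder() if not n.is_leaf]
    root_ax = 0  # root is first in preorder
    eig = model.eigen()
    pmats = {id(n): eig.transition(n.length)
             for n in tree.preorder() if n.parent is not None}
    row = {t: i for i, t in enumerate(alignment.taxa)}
    axis = {id(n): i for i, n in enumerate(internals)}
    nax = len(internals)
    acc = np.ones((20,) * nax)

    def expand(vec, ax):
        shape = [1] * nax
        shape[ax] = 20
        return vec.reshape(shape)

    acc = acc * expand(model.pi, axis[id(tree.root)])
    for node in tree.preorder():
        if node.parent is None:
            continue
        pax = axis[id(node.parent)]
        if node.is_leaf:
            state = alignment.matrix[row[node.name], site]
            vec = (np.ones(20) if state == MISSING
                   else pmats[id(node)][:, state])
            acc = acc * expand(vec, pax)
        else:
            shape = [1] * nax
            shape[pax] = 20
            shape[axis[id(node)]] = 20
            mat = (pmats[id(node)] if pax < axis[id(node)]
                   else pmats[id(node)].T)
            acc = acc * mat.reshape(shape)
    joint = acc.sum(axis=tuple(i for i in range(nax)
                               if i != axis[id(tree.root)]))
    return joint / joint.sum()


class TestReconstruction:
    def test_agreeing_descendants_fix_root(self, jtt1):
        tree = parse_newick("(A:0.2,B:0.2);")
        aln = aln_from_ints([[AA["L"]], [AA["L"]]], taxa=["A", "B"])
        fitted, asr = marginal_ancestral_reconstruction(
            tree, aln, jtt1, optimize=False)
        root = fitted.root.name
        assert AA_ORDER[asr.map_state(root, 0)] == "L"

    def test_root_posterior_matches_brute_force(self, jtt1):
        tree = parse_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.3);")
        rng = np.random.default_rng(13)
        aln = aln_from_ints(rng.integers(0, 20, (4, 6)),
                            taxa=["A", "B", "C", "D"])
        fitted, asr = marginal_ancestral_reconstruction(
            tree, aln, jtt1, optimize=False)
        for site in range(6):
            want = brute_force_root_posterior(fitted, aln, jtt1, site)
            got = asr.posteriors[fitted.root.name][site]
            assert np.allclose(got, want, atol=1e-8)

    def test_missing_site_posterior_equals_prior(self, jtt1):
        tree = parse_newick("((A:0.3,B:0.5):0.2,C:0.4);")
        mat = np.full((3, 2), MISSING, dtype=np.int16)
        mat[:, 0] = 3
        aln = aln_from_ints(mat, taxa=["A", "B", "C"])
        _, asr = marginal_ancestral_reconstruction(
            tree, aln, jtt1, optimize=False)
        for node in asr.node_names:
            assert np.allclose(asr.posteriors[node][1], jtt1.pi, atol=1e-8)

    def test_posteriors_sum_to_one(self):
        model = AAModel(name="JTT", alpha=0.7, k=4)
        tree = marine_mammal_tree()
        aln, _ = simulate_alignment(
            SimulationSpec.from_aa_model(tree, model, 40, seed=14))
        _, asr = marginal_ancestral_reconstruction(
            tree, aln, model, optimize=False)
        for node in asr.node_names:
            assert np.allclose(asr.posteriors[node].sum(axis=1), 1.0,
                               atol=1e-8)

    def test_codon_alignment_rejected(self, jtt1):
        tree = parse_newick("(A:0.1,B:0.1);")
        aln = Alignment.from_sequences([("A", "ATG"), ("B", "ATG")], "codon")
        with pytest.raises(ValueError, match="amino-acid"):
            marginal_ancestral_reconstruction(tree, aln, jtt1)


def _classification_fixture(columns, model=None, seed=15):
    """Build a study-shaped alignment with hand-set columns.

    ``columns``: list of dicts taxon -> residue char; unspecified taxa
    get 'A'.
    """
    tree = marine_mammal_tree()
    taxa = tree.leaf_names
    mat = np.full((len(taxa), len(columns)), AA["A"], dtype=np.int16)
    for j, overrides in enumerate(columns):
        for taxon, ch in overrides.items():
            mat[taxa.index(taxon), j] = MISSING if ch == "-" else AA[ch]
    aln = aln_from_ints(mat, taxa=taxa)
    aln.gene = "toy"
    model = model or AAModel(name="JTT", k=1)
    fitted, asr = marginal_ancestral_reconstruction(
        tree, aln, model, optimize=False)
    return fitted, aln, asr


class TestParallelCalls:
    def test_planted_parallel_unique_site_called(self):
        cols = [{"dolphin": "L", "walrus": "L", "manatee": "L"},
                {}]  # second column invariant
        tree, aln, asr = _classification_fixture(cols)
        calls, counters = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert len(calls) == 1
        call = calls[0]
        assert call.site == 1
        assert call.category == "parallel_unique"
        assert call.sublabel == "strict_parallel"
        assert call.derived == "L"

    def test_background_homoplasy_downgrades_to_parallel(self):
        cols = [{"dolphin": "L", "walrus": "L", "manatee": "L",
                 "mouse": "L"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert len(calls) == 1
        assert calls[0].category == "parallel"
        # and requiring uniqueness drops it
        calls2, _ = call_parallel_substitutions(tree, aln, asr, GROUPS,
                                                require_unique=True)
        assert calls2 == []

    def test_convergent_sublabel_for_differing_ancestors(self):
        # make one marine group's neighborhood derive from a different
        # ancestral residue by changing its terrestrial context
        cols = [{"dolphin": "L", "walrus": "L", "manatee": "L",
                 "cow": "S", "pig": "S", "alpaca": "S"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert len(calls) == 1
        anc_states = {anc for anc, _ in calls[0].group_states.values()}
        if len(anc_states) > 1:
            assert calls[0].sublabel == "convergent"

    def test_no_change_not_called(self):
        tree, aln, asr = _classification_fixture([{}])
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert calls == []

    def test_discordant_focal_residues_not_called(self):
        cols = [{"dolphin": "L", "walrus": "K", "manatee": "L"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert calls == []

    def test_multi_leaf_group_heterogeneity_skipped_and_counted(self):
        groups = FocalGroupConfig(groups={
            "cetaceans": ["dolphin", "cow"],  # deliberately heterogeneous
            "pinnipeds": ["walrus"], "sirenians": ["manatee"]})
        cols = [{"dolphin": "L", "cow": "K", "walrus": "L", "manatee": "L"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, counters = call_parallel_substitutions(tree, aln, asr, groups)
        assert calls == []
        assert counters["heterogeneous_group"] == 1


class TestUniqueCalls:
    def test_unique_call_requires_absence_everywhere(self):
        cols = [{"dolphin": "K", "walrus": "K", "manatee": "K"}]
        tree, aln, asr = _classification_fixture(cols)
        calls = call_unique_substitutions(tree, aln, asr, GROUPS)
        assert len(calls) == 1 and calls[0].category == "unique"

    def test_single_background_carrier_blocks_call(self):
        cols = [{"dolphin": "K", "walrus": "K", "manatee": "K",
                 "human": "K"}]
        tree, aln, asr = _classification_fixture(cols)
        assert call_unique_substitutions(tree, aln, asr, GROUPS) == []

    def test_gapped_focal_leaf_is_missing_not_mismatch(self):
        groups = FocalGroupConfig(groups={
            "cetaceans": ["dolphin", "cow"],
            "pinnipeds": ["walrus"], "sirenians": ["manatee"]})
        cols = [{"dolphin": "K", "cow": "-", "walrus": "K", "manatee": "K"}]
        tree, aln, asr = _classification_fixture(cols)
        # background excludes cow (focal), so the derived K is unique
        calls = call_unique_substitutions(tree, aln, asr, groups)
        assert len(calls) == 1
        assert "missing_focal_leaf" in calls[0].flags

    def test_empty_background_rejected(self):
        tree, aln, asr = _classification_fixture([{}])
        groups = FocalGroupConfig(
            groups={k: list(v) for k, v in MARINE_GROUPS.items()},
            background=[])
        with pytest.raises(ValueError, match="background"):
            call_unique_substitutions(tree, aln, asr, groups)


class TestBackwardAnnotation:
    def _call(self):
        cols = [{"dolphin": "E", "walrus": "E", "manatee": "E"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        assert len(calls) == 1
        return calls

    @pytest.mark.parametrize("ref_states, expected", [
        ("EEDE", True),     # 3/4 >= 0.5
        ("AAAA", False),
        ("EEAA", True),     # exactly at threshold
    ])
    def test_threshold_rule(self, ref_states, expected):
        calls = self._call()
        ref = Alignment.from_sequences(
            [(f"ref{i}", ch) for i, ch in enumerate(ref_states)], "aa")
        annotated = call_backward_substitutions(calls, ref)
        assert annotated[0].backward is expected

    def test_all_gapped_reference_flagged(self):
        calls = self._call()
        ref = Alignment.from_sequences(
            [("r1", "-"), ("r2", "-")], "aa")
        annotated = call_backward_substitutions(calls, ref)
        assert annotated[0].backward is None
        assert "no reference data" in annotated[0].flags

    def test_column_count_mismatch_rejected(self):
        cols = [{}, {"dolphin": "E", "walrus": "E", "manatee": "E"}]
        tree, aln, asr = _classification_fixture(cols)
        calls, _ = call_parallel_substitutions(tree, aln, asr, GROUPS)
        ref = Alignment.from_sequences([("r1", "E")], "aa")
        with pytest.raises(ValueError, match="columns"):
            call_backward_substitutions(calls, ref)


class TestConfigValidation:
    def test_overlapping_groups_rejected(self):
        tree = marine_mammal_tree()
        cfg = FocalGroupConfig(groups={"a": ["dolphin"],
                                       "b": ["dolphin", "walrus"]})
        with pytest.raises(ValueError, match="overlap"):
            cfg.validate(tree)

    def test_root_spanning_group_rejected(self):
        tree = marine_mammal_tree()
        cfg = FocalGroupConfig(groups={"a": ["opossum", "human"]})
        with pytest.raises(ValueError, match="root"):
            cfg.validate(tree)

    def test_nested_group_mrcas_rejected(self):
        tree = marine_mammal_tree()
        cfg = FocalGroupConfig(groups={"a": ["cow", "pig"],
                                       "b": ["dolphin"]})
        with pytest.raises(ValueError, match="ancestor"):
            cfg.validate(tree)
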