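import numpy as np
import pytest

from convphy.alignment import MISSING, Alignment
from convphy.likelihood import (TreeLikelihood, aa_mixture_classes,
                                site_log_likelihoods)
from convphy.substmodels import AAModel
from convphy.trees import parse_newick
from tests.conftest import aln_from_ints


def enumeration_site_lnl(tree, alignment, model):
    """Independent oracle: full joint over internal-state assignments.

    Builds the complete likelihood tensor over every internal node's
    state axis (root prior x all branch transition factors x leaf
    observations) and sums it — no pruning involved.
    """
    internals = [n for n in tree.preorder() if not n.is_leaf]
    axis = {id(n): i for i, n in enumerate(internals)}
    nax = len(internals)
    rates = model.rates()
    eig = model.eigen()
    pi = model.pi
    out = np.empty(alignment.n_columns)
    row = {t: i for i, t in enumerate(alignment.taxa)}
    for site in range(alignment.n_columns):
        site_lik = 0.0
        for r in rates:
            pmats = {id(n): eig.transition(n.length * r)
                     for n in tree.preorder() if n.parent is not None}
            acc = np.ones((20,) * nax)

            def expand(vec, ax):
                shape = [1] * nax
                shape[ax] = 20
                return vec.reshape(shape)

            acc = acc * expand(pi, axis[id(tree.root)])
            for node in tree.preorder():
                if node.parent is None:
                    continue
                pax = axis[id(node.parent)]
                if node.is_leaf:
                    state = alignment.matrix[row[node.name], site] \
                        if node.name in row else MISSING
                    vec = (np.ones(20) if state == MISSING
                           else pmats[id(node)][:, state])
                    acc = acc * expand(vec, pax)
                else:
                    shape = [1] * nax
                    shape[pax] = 20
                    shape[axis[id(node)]] = 20
                    if pax < axis[id(node)]:
                        mat = pmats[id(node)]
                    else:
                        mat = pmats[id(node)].T
                    acc = acc * mat.reshape(shape)
            site_lik += acc.sum() / len(rates)
        out[site] = np.log(site_lik)
    return out


def random_tree(rng, n_leaves):
    """Random rooted binary tree by sequential attachment."""
    from convphy.trees import Node, PhyloTree
    names = [f"t{i}" for i in range(n_leaves)]
    root = Node()
    root.add_child(Node(name=names[0], length=rng.uniform(0.02, 0.8)))
    root.add_child(Node(name=names[1], length=rng.uniform(0.02, 0.8)))
    tree = PhyloTree(root)
    for name in names[2:]:
        target = rng.choice([n for n in tree.preorder()
                             if n.parent is not None])
        tree.attach_on_branch(target, Node(name=name,
                                           length=rng.uniform(0.02, 0.8)),
                              stem_length=rng.uniform(0.02, 0.5))
    return tree


class TestAgainstEnumeration:
    def test_three_leaf_five_sites(self, three_leaf_tree, jtt1):
        rng = np.random.default_rng(0)
        aln = aln_from_ints(rng.integers(0, 20, (3, 5)),
                            taxa=["A", "B", "C"])
        got = site_log_likelihoods(three_leaf_tree, aln, jtt1).site_lnl
        want = enumeration_site_lnl(three_leaf_tree, aln, jtt1)
        assert np.allclose(got, want, atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_trees_with_gaps_and_gamma(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        tree = random_tree(rng, n)
        model = AAModel(name=rng.choice(["JTT", "WAG"]),
                        alpha=float(rng.uniform(0.3, 2.0)),
                        k=int(rng.integers(1, 3)))
        mat = rng.integers(0, 20, (n, 3)).astype(np.int16)
        mat[rng.random(mat.shape) < 0.2] = MISSING
        aln = aln_from_ints(mat, taxa=[f"t{i}" for i in range(n)])
        got = site_log_likelihoods(tree, aln, model).site_lnl
        want = enumeration_site_lnl(tree, aln, model)
        assert np.allclose(got, want, atol=1e-8)


class TestBoundaryCases:
    def test_single_observed_leaf_gives_log_pi(self, jtt1):
        tree = parse_newick("(A:1,B:1);")
        mat = np.array([[7], [MISSING]], dtype=np.int16)
        aln = aln_from_ints(mat, taxa=["A", "B"])
        lnl = site_log_likelihoods(tree, aln, jtt1).site_lnl
        assert lnl[0] == pytest.approx(np.log(jtt1.pi[7]), abs=1e-10)

    def test_all_gap_column_contributes_zero(self, jtt1):
        tree = parse_newick("(A:1,B:1);")
        mat = np.full((2, 1), MISSING, dtype=np.int16)
        aln = aln_from_ints(mat, taxa=["A", "B"])
        assert site_log_likelihoods(tree, aln, jtt1).site_lnl[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_site_lnl_nonpositive(self, jtt1):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 5)
        aln = aln_from_ints(rng.integers(0, 20, (5, 20)),
                            taxa=[f"t{i}" for i in range(5)])
        assert (site_log_likelihoods(tree, aln, jtt1).site_lnl <= 0).all()

    def test_total_is_sum_of_sites(self, jtt1):
        rng = np.random.default_rng(2)
        tree = random_tree(rng, 4)
        aln = aln_from_ints(rng.integers(0, 20, (4, 30)),
                            taxa=[f"t{i}" for i in range(4)])
        prof = site_log_likelihoods(tree, aln, jtt1)
        engine = TreeLikelihood(tree, aln, aa_mixture_classes(jtt1))
        assert prof.total == pytest.approx(prof.site_lnl.sum(), abs=1e-8)
        assert engine.total_lnl() == pytest.approx(prof.total, abs=1e-8)

    def test_taxon_mismatch_reported(self, jtt1):
        tree = parse_newick("(A:1,B:1);")
        aln = aln_from_ints(np.zeros((2, 3)), taxa=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            site_log_likelihoods(tree, aln, jtt1)


class TestReversibility:
    def test_lnl_invariant_to_rerooting(self, jtt1):
        # the same unrooted 4-leaf tree rooted on two different edges
        t1 = parse_newick("((A:1,B:2):0.5,(C:3,D:1):0.7);")
        t2 = parse_newick("(A:0.4,(B:2,(C:3,D:1):1.2):0.6);")
        rng = np.random.default_rng(3)
        aln = aln_from_ints(rng.integers(0, 20, (4, 40)),
                            taxa=["A", "B", "C", "D"])
        l1 = site_log_likelihoods(t1, aln, jtt1).site_lnl
        l2 = site_log_likelihoods(t2, aln, jtt1).site_lnl
        assert np.allclose(l1, l2, atol=1e-8)

    def test_gamma_mixture_rerooting(self):
        model = AAModel(name="WAG", alpha=0.7, k=4)
        t1 = parse_newick("((A:1,B:2):0.5,(C:3,D:1):0.7);")
        t2 = parse_newick("(A:0.4,(B:2,(C:3,D:1):1.2):0.6);")
        rng = np.random.default_rng(4)
        aln = aln_from_ints(rng.integers(0, 20, (4, 25)),
                            taxa=["A", "B", "C", "D"])
        assert site_log_likelihoods(t1, aln, model).total == pytest.approx(
            site_log_likelihoods(t2, aln, model).total, abs=1e-8)


class TestEngineInternals:
    def test_up_down_identity_at_every_node(self, jtt1):
        rng = np.random.default_rng(5)
        tree = random_tree(rng, 5)
        aln = aln_from_ints(rng.integers(0, 20, (5, 10)),
                            taxa=[f"t{i}" for i in range(5)])
        engine = TreeLikelihood(tree, aln, aa_mixture_classes(jtt1))
        ref = engine.pattern_lnl()
        down, ds = engine.down_partials()
        up, us = engine.up_partials()
        for node in tree.preorder():
            if node.is_leaf:
                continue
            i = engine.node_index[id(node)]
            v = (np.log((up[i] * down[i]).sum(axis=2)) + us[i] + ds[i])
            assert np.allclose(v[0], ref, atol=1e-8)

    def test_class_posteriors_normalized(self):
        model = AAModel(name="JTT", alpha=0.5, k=4)
        rng = np.random.default_rng(6)
        tree = random_tree(rng, 4)
        aln = aln_from_ints(rng.integers(0, 20, (4, 15)),
                            taxa=[f"t{i}" for i in range(4)])
        engine = TreeLikelihood(tree, aln, aa_mixture_classes(model))
        post = engine.class_posteriors()
        assert np.allclose(post.sum(axis=0), 1.0, atol=1e-8)

    def test_edge_view_matches_full_recompute(self, jtt1):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 5)
        aln = aln_from_ints(rng.integers(0, 20, (5, 12)),
                            taxa=[f"t{i}" for i in range(5)])
        classes = aa_mixture_classes(jtt1)
        engine = TreeLikelihood(tree, aln, classes)
        node = tree.find_leaf("t3")
        f = engine.edge_likelihood_fn(node)
        for t in (0.01, 0.2, 1.5):
            old = node.length
            node.length = t
            fresh = TreeLikelihood(tree, aln, classes).total_lnl()
            node.length = old
            assert f(t) == pytest.approx(fresh, abs=1e-8)
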