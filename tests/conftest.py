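import numpy as np
import pytest

from convphy._aa_data import AA_ORDER
from convphy.alignment import Alignment
from convphy.substmodels import AAModel
from convphy.trees import parse_newick


@pytest.fixture
def poisson_model():
    """20-state equal-rates model, single rate category."""
    return AAModel(name="POISSON", k=1)


@pytest.fixture
def jtt1():
    return AAModel(name="JTT", k=1)


@pytest.fixture
def three_leaf_tree():
    return parse_newick("((A:0.1,B:0.2):0.15,C:0.3);")


@pytest.fixture
def twelve_taxon_tree():
    return parse_newick(
        "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
        "((E:0.1,F:0.1):0.05,((G:0.1,H:0.1):0.05,"
        "((I:0.1,J:0.1):0.05,(K:0.1,L:0.1):0.05):0.02):0.02):0.05);")


def aln_from_ints(matrix, taxa=None, alphabet="aa", **kw):
    matrix = np.asarray(matrix, dtype=np.int16)
    if taxa is None:
        taxa = [f"t{i}" for i in range(matrix.shape[0])]
    return Alignment(list(taxa), matrix, alphabet, **kw)


def random_aa_alignment(rng, taxa, length):
    return aln_from_ints(rng.integers(0, 20, size=(len(taxa), length)),
                         taxa=taxa)


def aa_string(states):
    return "".join(AA_ORDER[s] for s in states)
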