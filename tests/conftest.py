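import numpy as np
import pytest

from glycospec.fragments import FragmentIndex, GlycopeptidePrecursor
from glycospec.glycans import GlycanTree, parse_glycan_struct
from glycospec.peptides import PeptideSequence

CORE = "(N(N(H(H)(H))))"

CODES = "HNAGF"


def random_tree(rng: np.random.Generator, n_nodes: int) -> GlycanTree:
    """A random rooted tree with random monosaccharide codes."""
    codes = [CODES[int(rng.integers(5))] for _ in range(n_nodes)]
    parent = [-1] + [int(rng.integers(i)) for i in range(1, n_nodes)]
    return GlycanTree(codes=codes, parent=parent)


def shuffle_children(
    rng: np.random.Generator, tree: GlycanTree
) -> GlycanTree:
    """Rebuild the same tree with child lists permuted (new node ids)."""
    new_codes: list[str] = []
    new_parent: list[int] = []

    def visit(v: int, parent_new: int) -> None:
        me = len(new_codes)
        new_codes.append(tree.codes[v])
        new_parent.append(parent_new)
        kids = list(tree.children[v])
        for c in rng.permutation(len(kids)):
            visit(kids[int(c)], me)

    visit(tree.root, -1)
    return GlycanTree(codes=new_codes, parent=new_parent)


@pytest.fixture
def core_tree() -> GlycanTree:
    return parse_glycan_struct(CORE)


@pytest.fixture
def simple_precursor(core_tree) -> GlycopeptidePrecursor:
    pep = PeptideSequence("LNSTAVK", glycosite=1)
    return GlycopeptidePrecursor(pep, core_tree, charge=2)


@pytest.fixture
def simple_index(simple_precursor) -> FragmentIndex:
    return FragmentIndex(simple_precursor, with_B=False)
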