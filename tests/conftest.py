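import numpy as np
import pytest

from parsiphy import CharacterMatrix, PhyloTree
from parsiphy import _topology as topo
from parsiphy.simulate import make_paper_fixture


def random_standard_matrix(rng, n_taxa, n_chars, n_states=2,
                           p_missing=0.0, p_poly=0.0, partitions=None):
    """Random unordered-character matrix for property tests."""
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            r = rng.random()
            if r < p_missing:
                row.append(frozenset())
            elif r < p_missing + p_poly:
                a, b = rng.choice(n_states, size=2, replace=False)
                row.append(frozenset({str(a), str(b)}))
            else:
                row.append(frozenset({str(rng.integers(n_states))}))
        cells.append(row)
    taxa = [f"t{i}" for i in range(n_taxa)]
    return CharacterMatrix(taxa, cells, ["standard"] * n_chars,
                           partitions=partitions)


def random_tree(rng, labels):
    """Uniform-ish random binary PhyloTree over the labels."""
    n = len(labels)
    t = (0, 1)
    for x in range(2, n):
        cands = topo.all_insertions(t, x)
        t = cands[int(rng.integers(len(cands)))]
    return phylo_from_int(t, labels)


def phylo_from_int(t, labels):
    def conv(u):
        if isinstance(u, int):
            return labels[u]
        return tuple(conv(c) for c in u)
    return PhyloTree.from_label_tuples(conv(t))


def support_value(supports, clade, all_taxa):
    """Support of a split given either side (keys exclude the anchor)."""
    clade = frozenset(clade)
    comp = frozenset(all_taxa) - clade
    return supports.get(clade, supports.get(comp, 0.0))


@pytest.fixture(scope="session")
def mini_matrix():
    return make_paper_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
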