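"""Synthetic mixed matrices evolved on known trees.

The generator emulates the data regime of a combined molecular +
morphological parsimony matrix: a DNA partition evolved site-i.i.d.
under an HKY-like process (unequal base frequencies, a
transition/transversion rate ratio, optional discrete-gamma rate
heterogeneity), a multistate morphology partition under the Mk model,
a small binary indel partition, and injected missing and polymorphic
cells.  Because the generating tree is returned alongside the matrix,
every downstream stage — scoring, search, support, rooting — can be
tested against known truth without any external data.

Branch lengths are in expected substitutions per character.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from . import _topology as topo
from .matrix import MISSING, CharacterMatrix
from .tree import PhyloTree

_DNA = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic matrix.

    Defaults mirror the empirical study regime: 913 DNA sites with
    GHR-like composition and gamma shape, 144 morphological characters,
    8 binary indels.
    """

    n_taxa: int = 8
    tree: PhyloTree | None = None          #: user tree; random Yule-like if None
    branch_length: float = 0.1             #: mean expected changes per character
    n_sites: int = 913
    base_frequencies: tuple = (0.2805, 0.265, 0.2218, 0.2327)
    tstv_ratio: float = 2.2696             #: HKY kappa
    gamma_shape: float | None = 0.8383     #: None = equal rates
    n_gamma_categories: int = 4
    n_morphology: int = 144
    morphology_states: int = 3             #: Mk state count per character
    n_indels: int = 8
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        freqs = np.asarray(self.base_frequencies, float)
        if freqs.shape != (4,) or (freqs <= 0).any() or \
                abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("base_frequencies must be a positive 4-simplex")
        if self.branch_length < 0 or self.tstv_ratio <= 0:
            raise ValueError("branch_length >= 0 and tstv_ratio > 0 required")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        for f in (self.missing_fraction, self.polymorphic_fraction):
            if not 0 <= f <= 1:
                raise ValueError("cell-injection fractions must be in [0,1]")
        if self.morphology_states < 2:
            raise ValueError("morphology needs >= 2 states")


# ----------------------------------------------------------------------
# rate matrices

def hky_rate_matrix(freqs, kappa) -> np.ndarray:
    """HKY85 generator scaled to one expected change per unit length."""
    pi = np.asarray(freqs, float)
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def mk_rate_matrix(k: int) -> np.ndarray:
    """Jukes-Cantor-like k-state generator, mean rate 1."""
    Q = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(Q, -1.0)
    return Q


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-one rate multipliers: k equal-probability category midpoints."""
    q = (2 * np.arange(k) + 1) / (2 * k)
    rates = gamma_dist.ppf(q, shape, scale=1.0 / shape)
    return rates / rates.mean()


# ----------------------------------------------------------------------
# tree generation

class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[_Node] = []
        self.length = length
        self.label = label


def _random_tree(n_taxa: int, mean_length: float, rng) -> _Node:
    """Yule-like topology: repeatedly split a uniformly chosen tip.

    Every branch gets an i.i.d. exponential length with the given mean.
    """
    root = _Node()
    tips = []
    for _ in range(2):
        c = _Node()
        root.children.append(c)
        tips.append(c)
    while len(tips) < n_taxa:
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            c = _Node()
            tip.children.append(c)
            tips.append(c)
    labels = [f"T{i + 1:02d}" for i in range(n_taxa)]
    order = rng.permutation(n_taxa)
    for tip, j in zip(tips, order):
        tip.label = labels[int(j)]

    def set_lengths(node):
        for c in node.children:
            c.length = float(rng.exponential(mean_length)) \
                if mean_length > 0 else 0.0
            set_lengths(c)

    set_lengths(root)
    return root


def _from_phylo(tree: PhyloTree, default_length: float) -> _Node:
    """Rooted copy of an unrooted tree for simulation.

    The root is placed at the internal node adjacent to the anchor
    leaf, so every edge of the unrooted tree appears exactly once with
    its own length (no split root edge).
    """
    ann = tree.branch_annotations

    def conv(u) -> _Node:
        node = _Node()
        if isinstance(u, int):
            node.label = tree.labels[u]
            key = frozenset((node.label,))
        else:
            node.children = [conv(c) for c in u]
            key = frozenset(tree.labels[i] for i in topo.leafset(u))
        node.length = float(ann.get(key, default_length))
        return node

    t = tree.topology
    anchor, rest = t  # canonical form: (anchor leaf, remainder)
    root = _Node()
    kids = [anchor] + (list(rest) if isinstance(rest, tuple) else [rest])
    root.children = [conv(c) for c in kids]
    return root


def _to_phylo(root: _Node) -> PhyloTree:
    def conv(node):
        if not node.children:
            return node.label
        kids = tuple(conv(c) for c in node.children)
        return kids[0] if len(kids) == 1 else kids

    return PhyloTree.from_label_tuples(conv(root))


# ----------------------------------------------------------------------
# evolution

def _evolve_block(root: _Node, Q: np.ndarray, freqs: np.ndarray,
                  site_rates: np.ndarray, rng) -> dict[str, np.ndarray]:
    """States at every leaf for one block of characters.

    ``site_rates`` gives each site's rate multiplier; transition
    matrices are exp(Q * t * r), cached per (branch, rate).
    """
    k = Q.shape[0]
    n_sites = site_rates.shape[0]
    rate_values, rate_index = np.unique(site_rates, return_inverse=True)
    out: dict[str, np.ndarray] = {}
    root_states = rng.choice(k, size=n_sites, p=freqs)

    def walk(node: _Node, states: np.ndarray):
        for child in node.children:
            if child.length <= 0:
                child_states = states.copy()
            else:
                child_states = np.empty_like(states)
                for ri, r in enumerate(rate_values):
                    P = expm(Q * child.length * r)
                    P = np.clip(P, 0, None)
                    P /= P.sum(axis=1, keepdims=True)
                    sel = rate_index == ri
                    for s in range(k):
                        mask = sel & (states == s)
                        n = int(mask.sum())
                        if n:
                            child_states[mask] = rng.choice(k, size=n,
                                                            p=P[s])
            if child.children:
                walk(child, child_states)
            else:
                out[child.label] = child_states

    walk(root, root_states)
    return out


def simulate_matrix(config: SimulationConfig, seed=None
                    ) -> tuple[CharacterMatrix, PhyloTree]:
    """Simulate a mixed matrix and return it with its generating tree.

    Partitions are named ``GHR`` (DNA), ``morphology`` (Mk multistate)
    and ``indels`` (binary Mk).  Missing cells are injected uniformly
    at ``missing_fraction``; polymorphic cells (the true state plus one
    random alternative) at ``polymorphic_fraction``, in the morphology
    partition only.  Deterministic under (config, seed).
    """
    rng = np.random.default_rng(seed)
    if config.tree is not None:
        if config.tree.n_leaves != config.n_taxa:
            raise ValueError("config.tree size disagrees with n_taxa")
        root = _from_phylo(config.tree, config.branch_length)
    else:
        root = _random_tree(config.n_taxa, config.branch_length, rng)
    true_tree = _to_phylo(root)
    taxa = sorted(true_tree.labels)

    pi = np.asarray(config.base_frequencies, float)
    blocks: list[tuple[str, str, dict, list[str]]] = []

    if config.n_sites:
        if config.gamma_shape is not None:
            cat = discrete_gamma_rates(config.gamma_shape,
                                       config.n_gamma_categories)
            site_rates = rng.choice(cat, size=config.n_sites)
        else:
            site_rates = np.ones(config.n_sites)
        leaves = _evolve_block(root, hky_rate_matrix(pi, config.tstv_ratio),
                               pi, site_rates, rng)
        blocks.append(("GHR", "dna", leaves, list(_DNA)))
    if config.n_morphology:
        k = config.morphology_states
        leaves = _evolve_block(root, mk_rate_matrix(k), np.full(k, 1 / k),
                               np.ones(config.n_morphology), rng)
        blocks.append(("morphology", "standard", leaves,
                       [str(i) for i in range(k)]))
    if config.n_indels:
        leaves = _evolve_block(root, mk_rate_matrix(2), np.full(2, 0.5),
                               np.ones(config.n_indels), rng)
        blocks.append(("indels", "binary", leaves, ["0", "1"]))

    cells = [[] for _ in taxa]
    datatypes: list[str] = []
    partitions: dict[str, list[int]] = {}
    for name, dtype, leaves, symbols in blocks:
        n_block = len(next(iter(leaves.values())))
        start = len(datatypes)
        partitions[name] = list(range(start, start + n_block))
        datatypes.extend([dtype] * n_block)
        for i, t in enumerate(taxa):
            states = leaves[t]
            for j in range(n_block):
                cell = frozenset((symbols[int(states[j])],))
                if name == "morphology" and config.polymorphic_fraction and \
                        rng.random() < config.polymorphic_fraction:
                    alt = symbols[int(rng.integers(len(symbols)))]
                    cell = cell | {alt}
                if config.missing_fraction and \
                        rng.random() < config.missing_fraction:
                    cell = MISSING
                cells[i].append(cell)

    matrix = CharacterMatrix(taxa, cells, datatypes, partitions=partitions)
    return matrix, true_tree


# ----------------------------------------------------------------------
# packaged miniature fixture

FIXTURE_SEED = 20100

def make_paper_fixture(seed: int = FIXTURE_SEED) -> CharacterMatrix:
    """Miniature 8-taxon mixed matrix shaped like the study regime.

    Three partitions (DNA, multistate morphology, binary indels), some
    missing and polymorphic cells, and few enough taxa for exhaustive
    search.  The default-seed version ships frozen with the package
    (``data/mini_fixture.nex``).
    """
    config = SimulationConfig(
        n_taxa=8, branch_length=0.15, n_sites=60,
        gamma_shape=0.8383, n_morphology=20, morphology_states=3,
        n_indels=4, missing_fraction=0.05, polymorphic_fraction=0.05,
    )
    matrix, _ = simulate_matrix(config, seed=seed)
    return matrix


def load_mini_fixture() -> CharacterMatrix:
    """The frozen copy of :func:`make_paper_fixture` shipped in the package."""
    from .nexus import parse_nexus
    text = resources.files("parsiphy").joinpath(
        "data/mini_fixture.nex").read_text()
    return parse_nexus(text)
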