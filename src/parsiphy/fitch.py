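"""Parsimony scoring of trees on character matrices.

The workhorse is Fitch's intersect/union pass for unordered characters,
vectorised across characters with per-character state bitmasks.  A unit
cost Sankoff dynamic program backs everything the plain Fitch pass
cannot do: multifurcating trees, per-branch minimum lengths (the
MINBRLEN collapse test), ACCTRAN branch step counts, and the
polymorphism scoring mode, in which a multi-state cell must be fully
accounted for (every observed state has to arise) rather than being
satisfiable by any one of its members.

Missing cells never force steps in either mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _topology as topo
from .matrix import CharacterMatrix, MatrixError
from .tree import PhyloTree, TreeError

LARGE = 1.0e9
_MAX_BF_ASSIGNMENTS = 2_000_000


# ----------------------------------------------------------------------
# encoding

class MatrixEncoding:
    """Numeric encoding of a CharacterMatrix for vectorised scoring.

    Per character the state universe is sorted (a stable, documented
    order used for all deterministic tie-breaks) and each cell becomes
    a bitmask over those states.  Missing cells get the full mask.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        n, m = matrix.n_taxa, matrix.n_characters
        self.weights = np.asarray(matrix.weights, dtype=np.int64)
        self.states: list[tuple[str, ...]] = []
        self.k = np.zeros(m, dtype=np.int64)
        for j in range(m):
            uni = tuple(sorted(matrix.state_universe(j)))
            if len(uni) > 16:
                raise MatrixError(
                    f"character {j + 1} has {len(uni)} states (max 16)"
                )
            self.states.append(uni)
            self.k[j] = len(uni)
        self.kmax = int(self.k.max()) if m else 1

        self.masks = np.zeros((n, m), dtype=np.int64)
        self.costs = np.full((n, m, self.kmax), LARGE)
        self.poly_cols: list[int] = []
        for j in range(m):
            index = {s: b for b, s in enumerate(self.states[j])}
            full = (1 << int(self.k[j])) - 1
            has_poly = False
            for i in range(n):
                cell = matrix.cells[i][j]
                if not cell:
                    self.masks[i, j] = full
                    self.costs[i, j, : self.k[j]] = 0.0
                else:
                    bits = 0
                    for s in cell:
                        bits |= 1 << index[s]
                        self.costs[i, j, index[s]] = 0.0
                    self.masks[i, j] = bits
                    if len(cell) > 1:
                        has_poly = True
            if has_poly:
                self.poly_cols.append(j)

    @property
    def n_characters(self) -> int:
        return self.matrix.n_characters


# ----------------------------------------------------------------------
# plain Fitch pass (binary trees, uncertainty mode)

def fitch_counts(t, enc: MatrixEncoding, cols=None) -> np.ndarray:
    """Per-character minimum steps on a binary unrooted tuple tree."""
    masks = enc.masks if cols is None else enc.masks[:, cols]
    steps = np.zeros(masks.shape[1], dtype=np.int64)

    def down(u):
        if isinstance(u, int):
            return masks[u]
        if len(u) != 2:
            raise TreeError("fitch_counts requires a binary tree")
        a = down(u[0])
        b = down(u[1])
        inter = a & b
        zero = inter == 0
        steps[zero] += 1
        return np.where(zero, a | b, inter)

    if isinstance(t, int):
        return steps
    if len(t) != 2:
        raise TreeError("fitch_counts requires a binary tree")
    a = down(t[0])
    b = down(t[1])
    steps[(a & b) == 0] += 1
    return steps


# ----------------------------------------------------------------------
# unit-cost Sankoff (any resolution, uncertainty mode)

def _fold(D: np.ndarray) -> np.ndarray:
    """min over child states of D + [change]: min(D, min(D)+1)."""
    return np.minimum(D, D.min(axis=-1, keepdims=True) + 1.0)


def sankoff_counts(t, enc: MatrixEncoding, cols=None) -> np.ndarray:
    """Per-character minimum steps; handles multifurcations exactly."""
    costs = enc.costs if cols is None else enc.costs[:, cols]

    def down(u):
        if isinstance(u, int):
            return costs[u]
        return sum(_fold(down(c)) for c in u)

    t = topo.canonical(t)
    if isinstance(t, int):
        return np.zeros(costs.shape[1], dtype=np.int64)
    DL = down(t[0])
    DR = down(t[1])
    no_change = (DL + DR).min(axis=-1)
    change = DL.min(axis=-1) + DR.min(axis=-1) + 1.0
    out = np.minimum(no_change, change)
    return np.rint(out).astype(np.int64)


# ----------------------------------------------------------------------
# polymorphism mode: Sankoff over non-empty state subsets

@lru_cache(maxsize=None)
def _subset_cost_matrix(k: int) -> np.ndarray:
    """Cost between state subsets: max(#gains, #losses) of member states.

    This keeps single-state substitutions at unit cost while letting a
    polymorphic ancestor account for shared polymorphism in adjacent
    taxa at the cost of one gain per extra state.
    """
    K = (1 << k) - 1
    C = np.zeros((K, K))
    for a in range(1, K + 1):
        for b in range(1, K + 1):
            gains = bin(b & ~a).count("1")
            losses = bin(a & ~b).count("1")
            C[a - 1, b - 1] = max(gains, losses)
    return C


def polymorphism_counts(t, enc: MatrixEncoding, cols) -> np.ndarray:
    """Per-character steps charging multi-state cells for every member."""
    cols = list(cols)
    if not cols:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(len(cols), dtype=np.int64)
    t = topo.canonical(t)
    # group columns by state-universe size so each group shares one DP
    by_k: dict[int, list[int]] = {}
    for pos, j in enumerate(cols):
        by_k.setdefault(int(enc.k[j]), []).append(pos)
    for k, positions in by_k.items():
        js = [cols[p] for p in positions]
        K = (1 << k) - 1
        C = _subset_cost_matrix(k)
        n = enc.masks.shape[0]
        leaf = np.full((n, len(js), K), LARGE)
        for i in range(n):
            for jj, j in enumerate(js):
                bits = int(enc.masks[i, j])
                if not enc.matrix.cells[i][j]:  # missing: no requirement
                    leaf[i, jj, :] = 0.0
                else:
                    leaf[i, jj, bits - 1] = 0.0

        def down(u):
            if isinstance(u, int):
                return leaf[u]
            total = None
            for c in u:
                D = down(c)
                folded = (D[:, :, None] + C[None, :, :]).min(axis=1)
                total = folded if total is None else total + folded
            return total

        if isinstance(t, int):
            vals = np.zeros(len(js))
        else:
            DL = down(t[0])
            DR = down(t[1])
            folded = (DR[:, :, None] + C[None, :, :]).min(axis=1)
            vals = (DL + folded).min(axis=-1)
        out[positions] = np.rint(vals).astype(np.int64)
    return out


# ----------------------------------------------------------------------
# per-character step counts with mode dispatch

def character_steps(t, enc: MatrixEncoding,
                    polymorphism_mode: str = "uncertainty") -> np.ndarray:
    """Unweighted per-character minimum steps for tuple tree *t*."""
    if polymorphism_mode not in ("uncertainty", "polymorphism"):
        raise ValueError(f"unknown scoring mode {polymorphism_mode!r}")
    t = topo.canonical(t)
    if topo.is_binary(t):
        steps = fitch_counts(t, enc)
    else:
        steps = sankoff_counts(t, enc)
    if polymorphism_mode == "polymorphism" and enc.poly_cols:
        steps = steps.copy()
        steps[enc.poly_cols] = polymorphism_counts(t, enc, enc.poly_cols)
    return steps


def tree_length(t, enc: MatrixEncoding,
                polymorphism_mode: str = "uncertainty") -> int:
    steps = character_steps(t, enc, polymorphism_mode)
    return int((steps * enc.weights).sum())


# ----------------------------------------------------------------------
# reports on PhyloTree / CharacterMatrix

@dataclass
class LengthReport:
    """Tree length, overall and per partition / character."""

    total_steps: int
    per_partition_steps: dict[str, int]
    per_character_steps: np.ndarray = field(repr=False)

    def __post_init__(self):
        assert self.total_steps == sum(self.per_partition_steps.values()) or \
            not self.per_partition_steps


@dataclass
class BranchSteps:
    """Per-branch step counts keyed by the clade below each branch."""

    acctran: dict[frozenset, int]
    minimum: dict[frozenset, int]
    total_steps: int
    root: str


def matrix_topology(tree: PhyloTree, matrix: CharacterMatrix):
    """Tree topology re-indexed onto matrix taxon indices."""
    missing = tree.leaf_set - set(matrix.taxa)
    if missing:
        raise MatrixError(
            f"tree leaves absent from matrix: {sorted(missing)}"
        )
    lut = {i: matrix.taxon_index(lbl) for i, lbl in enumerate(tree.labels)}

    def conv(u):
        if isinstance(u, int):
            return lut[u]
        return tuple(conv(c) for c in u)

    return topo.canonical(conv(tree.topology))


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix,
                 polymorphism_mode: str = "uncertainty") -> LengthReport:
    """Minimum steps of *tree* on *matrix*, with per-partition breakdown.

    In ``uncertainty`` mode (the default, standard Fitch) a multi-state
    cell is satisfied by any one member state; in ``polymorphism`` mode
    every member must be accounted for, so lengths can only grow.
    """
    if tree.leaf_set != set(matrix.taxa):
        sub = matrix.select_taxa(sorted(tree.leaf_set))
    else:
        sub = matrix
    enc = MatrixEncoding(sub)
    t = matrix_topology(tree, sub)
    steps = character_steps(t, enc, polymorphism_mode)
    weighted = steps * enc.weights
    per_part = {
        name: int(weighted[list(idx)].sum())
        for name, idx in sub.partitions.items()
    }
    if not per_part:
        per_part = {"all": int(weighted.sum())}
    return LengthReport(int(weighted.sum()), per_part, steps)


def partition_length(tree: PhyloTree, matrix: CharacterMatrix,
                     partition: str,
                     polymorphism_mode: str = "uncertainty") -> int:
    """Fitch length restricted to one named partition's characters."""
    idx = matrix.partition_indices(partition)
    rep = fitch_length(tree, matrix, polymorphism_mode)
    w = np.asarray(matrix.weights)
    return int((rep.per_character_steps[list(idx)] * w[list(idx)]).sum())


# ----------------------------------------------------------------------
# up-down pass: branch minima and ACCTRAN steps

def _down_pass(rooted, costs):
    """Subtree cost vectors for every node of rooted = (leaf, rest)."""
    D: dict = {}

    def down(u):
        if isinstance(u, int):
            D[u] = costs[u]
            return D[u]
        D[u] = sum(_fold(down(c)) for c in u)
        return D[u]

    g, R = rooted
    D[g] = costs[g]
    down(R)
    return D


def _edge_analysis(rooted, enc: MatrixEncoding):
    """Per-edge forced-change flags and per-char tree lengths.

    Returns (forced, L) where forced maps each non-root node (keyed by
    subtree tuple) to a boolean per-character vector that is True when
    every most-parsimonious reconstruction changes state on the edge
    above that node.
    """
    g, R = rooted
    D = _down_pass(rooted, enc.costs)
    L = np.minimum((D[g] + D[R]).min(-1),
                   D[g].min(-1) + D[R].min(-1) + 1.0)
    Out: dict = {R: D[g]}
    forced: dict = {}

    def walk(u):
        if isinstance(u, int):
            return
        Gu = _fold(Out[u])
        folded = {c: _fold(D[c]) for c in u}
        total_f = sum(folded.values())
        for c in u:
            Out[c] = Gu + total_f - folded[c]
            M0 = (Out[c] + D[c]).min(-1)
            forced[c] = M0 > L + 0.5
            walk(c)
    # root edge g--R
    M0 = (D[g] + D[R]).min(-1)
    forced[R] = M0 > L + 0.5
    walk(R)
    return forced, np.rint(L).astype(np.int64)


def min_branch_lengths(t, enc: MatrixEncoding) -> dict[frozenset, int]:
    """Minimum possible steps on each branch over all MP reconstructions.

    Keys are leaf-id clades (side away from the anchor leaf).  A value
    of zero on an internal branch means the branch has no unambiguous
    optimization and is removed by the MINBRLEN collapse rule.
    """
    t = topo.canonical(t)
    rooted = topo.reroot_at_leaf(t, topo.min_leaf(t))
    forced, _ = _edge_analysis(rooted, enc)
    out = {}
    for node, flags in forced.items():
        clade = topo.leafset(node)
        out[clade] = int((flags * enc.weights).sum())
    return out


def collapse_zero_branches(t, enc: MatrixEncoding,
                           protect: frozenset | None = None):
    """MINBRLEN collapse: contract internal branches of minimum length 0.

    ``protect`` names a leaf-id clade whose branch is never collapsed
    (used to keep an enforced constraint clade visible).
    """
    t = topo.canonical(t)
    if isinstance(t, int) or topo.n_leaves(t) < 4:
        return t
    full = topo.leafset(t)
    rooted = topo.reroot_at_leaf(t, topo.min_leaf(t))
    forced, _ = _edge_analysis(rooted, enc)
    g, R = rooted

    def protected(c) -> bool:
        if protect is None:
            return False
        cl = topo.leafset(c)
        return cl == protect or cl == full - protect

    def rebuild(u):
        if isinstance(u, int):
            return u
        kids = []
        for c in u:
            rc = rebuild(c)
            if isinstance(rc, tuple) and not protected(c) and \
                    int((forced[c] * enc.weights).sum()) == 0:
                kids.extend(rc)  # zero-minimum internal edge: splice
            else:
                kids.append(rc)
        return tuple(kids)

    R2 = rebuild(R)
    return topo.canonical((g, R2))


def _acctran_assign(rooted, enc: MatrixEncoding):
    """ACCTRAN most-parsimonious reconstruction (changes pulled rootward).

    Ambiguity on an edge is resolved toward *change* (accelerated
    transformation); residual ties pick the lowest-sorted state.
    """
    g, R = rooted
    D = _down_pass(rooted, enc.costs)
    m = enc.n_characters
    idx = np.arange(m)
    state: dict = {}
    s_root = np.argmin(D[g] + _fold(D[R]), axis=-1)
    state[g] = s_root

    def assign(u, parent_state):
        cand = D[u] + 1.0
        cand[idx, parent_state] = D[u][idx, parent_state]
        mv = cand.min(-1)
        tie = cand <= mv[:, None] + 1e-9
        tie_alt = tie.copy()
        tie_alt[idx, parent_state] = False
        has_alt = tie_alt.any(-1)
        s = np.where(has_alt, tie_alt.argmax(-1), parent_state)
        state[u] = s
        if isinstance(u, tuple):
            for c in u:
                assign(c, s)

    assign(R, s_root)
    return state


def branch_steps(tree: PhyloTree, matrix: CharacterMatrix,
                 root: str | None = None) -> BranchSteps:
    """ACCTRAN branch step counts and per-branch minima.

    The tree must be fully resolved.  ``root`` names the taxon whose
    terminal branch orients the optimization (typically the designated
    outgroup); it defaults to the first matrix taxon present in the
    tree.  Branches are keyed by the label set below them with respect
    to that rooting.  ACCTRAN sums exactly to the total tree length.
    """
    if not tree.is_binary():
        raise TreeError(
            "branch_steps requires a fully resolved (binary) tree; "
            "resolve or collapse polytomies first"
        )
    sub = (matrix if tree.leaf_set == set(matrix.taxa)
           else matrix.select_taxa(sorted(tree.leaf_set)))
    enc = MatrixEncoding(sub)
    t = matrix_topology(tree, sub)
    if root is None:
        root = next(l for l in sub.taxa if l in tree.leaf_set)
    rooted = topo.reroot_at_leaf(t, sub.taxon_index(root))
    g, R = rooted

    state = _acctran_assign(rooted, enc)
    forced, L = _edge_analysis(rooted, enc)
    w = enc.weights

    def label_clade(node) -> frozenset:
        return frozenset(sub.taxa[i] for i in topo.leafset(node))

    acctran: dict[frozenset, int] = {}
    minimum: dict[frozenset, int] = {}

    def walk(u, parent):
        changes = state[u] != state[parent]
        key = label_clade(u)
        acctran[key] = int((changes * w).sum())
        minimum[key] = int((forced[u] * w).sum())
        if isinstance(u, tuple):
            for c in u:
                walk(c, u)

    walk(R, g)
    total = int((L * w).sum())
    return BranchSteps(acctran, minimum, total, root)


# ----------------------------------------------------------------------
# brute-force oracle

def brute_force_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Exhaustive minimum steps over all internal state assignments.

    Independent of the Fitch machinery: enumerates every labelling of
    the internal nodes and counts changes directly (uncertainty
    semantics — a leaf cell is satisfied by any member state, missing
    cells by anything).  Only feasible on small instances.
    """
    if tree.n_leaves > 8:
        raise ValueError(
            f"brute force limited to 8 leaves, got {tree.n_leaves}"
        )
    sub = (matrix if tree.leaf_set == set(matrix.taxa)
           else matrix.select_taxa(sorted(tree.leaf_set)))
    t = matrix_topology(tree, sub)
    if tree.n_leaves == 2:
        a, b = (sub.cells[i] for i in topo.leafset(t))
        total = 0
        for j in range(sub.n_characters):
            if a[j] and b[j] and not (a[j] & b[j]):
                total += int(sub.weights[j])
        return total
    rooted = topo.reroot_at_leaf(t, topo.min_leaf(t))
    g, R = rooted

    internal: list = []
    parent_of: dict = {}
    leaf_parent: list[tuple[int, int]] = []  # (leaf id, internal index)

    def walk(u, parent_idx):
        my = len(internal)
        internal.append(u)
        if parent_idx is not None:
            parent_of[my] = parent_idx
        for c in u:
            if isinstance(c, int):
                leaf_parent.append((c, my))
            else:
                walk(c, my)

    walk(R, None)
    leaf_parent.append((g, 0))
    n_int = len(internal)

    total = 0
    for j in range(sub.n_characters):
        uni = sorted(sub.state_universe(j))
        k = len(uni)
        if k ** n_int > _MAX_BF_ASSIGNMENTS:
            raise ValueError(
                f"character {j + 1}: {k}^{n_int} assignments exceed "
                f"bound {_MAX_BF_ASSIGNMENTS}"
            )
        grids = np.meshgrid(*([np.arange(k)] * n_int), indexing="ij")
        assign = np.stack([a.ravel() for a in grids])  # (n_int, k**n_int)
        cost = np.zeros(assign.shape[1])
        for child, par in parent_of.items():
            cost += assign[child] != assign[par]
        for leaf, par in leaf_parent:
            cell = sub.cells[leaf][j]
            if not cell:
                continue
            ok = np.zeros(k, dtype=bool)
            for s in cell:
                ok[uni.index(s)] = True
            cost += ~ok[assign[par]]
        total += int(cost.min()) * int(sub.weights[j])
    return total
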