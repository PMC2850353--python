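"""Most-parsimonious tree search, consensus, and bootstrap.

The heuristic search follows the classic two-phase recipe: a stepwise
addition starting tree (taxon order random under seed, or file order),
followed by TBR branch swapping that keeps all equally best trees.
Optimal trees are condensed with the MINBRLEN rule (internal branches
with no unambiguous optimization are collapsed) and de-duplicated.  An
exhaustive enumerator over all unrooted binary topologies serves as the
oracle on small instances.

Searches can be restricted by a positive clade constraint (only trees
containing the clade) or its converse (only trees lacking it, as used
for Bremer support); candidate trees violating the constraint are
discarded outright rather than penalized.

The primary entry points are the scikit-learn style estimators
:class:`MaxParsimonySearch`, :class:`ExhaustiveParsimonySearch` and
:class:`ParsimonyBootstrap`; the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _topology as topo
from .fitch import MatrixEncoding, collapse_zero_branches, tree_length
from .matrix import CharacterMatrix, MatrixError
from .tree import PhyloTree


# ----------------------------------------------------------------------
# constraints

@dataclass(frozen=True)
class CladeConstraint:
    """A clade to be enforced (positive) or forbidden (converse)."""

    taxa: frozenset
    converse: bool = False

    def __post_init__(self):
        object.__setattr__(self, "taxa", frozenset(self.taxa))

    def validate(self, matrix: CharacterMatrix) -> frozenset:
        unknown = self.taxa - set(matrix.taxa)
        if unknown:
            raise MatrixError(
                f"constraint taxa not in matrix: {sorted(unknown)}"
            )
        ids = frozenset(matrix.taxon_index(t) for t in self.taxa)
        if not 2 <= len(ids) <= matrix.n_taxa - 2:
            raise MatrixError(
                "constraint clade must be a non-trivial proper subset "
                f"(got {len(ids)} of {matrix.n_taxa} taxa)"
            )
        return ids


def _has_clade(t, clade: frozenset) -> bool:
    full = topo.leafset(t)
    want = clade & full
    comp = full - want
    if len(want) < 2 or len(comp) < 2:
        return True  # trivial under this leaf set
    return any(s == want or s == comp for s in topo.clades(t))


def _satisfied(t, clade_ids: frozenset, converse: bool) -> bool:
    has = _has_clade(t, clade_ids)
    return not has if converse else has


# ----------------------------------------------------------------------
# results

@dataclass
class SearchResult:
    """Outcome of a parsimony search."""

    best_length: int
    optimal_trees: tuple
    replicates_run: int
    seed: int | None = None
    note: str | None = None

    def __post_init__(self):
        self.optimal_trees = tuple(self.optimal_trees)


@dataclass
class ConsensusTree:
    """Strict or majority-rule consensus with per-clade frequencies."""

    tree: PhyloTree
    method: str
    cutoff: float
    clade_frequencies: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# internal machinery (integer leaf ids)

class _Scorer:
    """Length cache keyed by canonical topology."""

    def __init__(self, enc: MatrixEncoding, mode: str):
        self.enc = enc
        self.mode = mode
        self.cache: dict = {}

    def __call__(self, t) -> int:
        s = self.cache.get(t)
        if s is None:
            s = tree_length(t, self.enc, self.mode)
            self.cache[t] = s
        return s


def _stepwise_addition(order, scorer, clade_ids=None, converse=False,
                       rng=None):
    """Greedy stepwise-addition tree for the given taxon order."""
    t = topo.canonical((int(order[0]), int(order[1])))
    remaining = [int(x) for x in order[2:]]
    for pos, x in enumerate(remaining):
        last = pos == len(remaining) - 1
        cands = [topo.canonical(c) for c in topo.all_insertions(t, x)]
        if clade_ids is not None:
            if converse:
                if last:  # only complete trees can violate for good
                    kept = [c for c in cands
                            if _satisfied(c, clade_ids, True)]
                    cands = kept or cands
            else:
                kept = [c for c in cands if _has_clade(c, clade_ids)]
                cands = kept or cands
        scores = [scorer(c) for c in cands]
        best = min(scores)
        ties = [c for c, s in zip(cands, scores) if s == best]
        t = ties[0] if rng is None or len(ties) == 1 else \
            ties[int(rng.integers(len(ties)))]
    return t


def _force_positive(t, clade_ids, scorer):
    """Repair a tree so it contains the clade (rarely needed fallback).

    Prunes the clade's taxa, regroups them as a subtree, and reattaches
    that subtree at its best position; TBR refines from there.
    """
    members = sorted(clade_ids & topo.leafset(t))
    rest = t
    for m in members:
        rest = topo.remove_leaf(rest, m)
    sub = (members[0], members[1])
    for m in members[2:]:
        sub = (sub, m)
    best_t, best_s = None, None
    for sr in topo.plantings(sub):
        for cand in topo.attach_everywhere(rest, sr):
            c = topo.canonical(cand)
            s = scorer(c)
            if best_s is None or s < best_s:
                best_t, best_s = c, s
    return best_t


def _tbr_swap(start, scorer, clade_ids=None, converse=False,
              max_trees=None):
    """Swap to a TBR local optimum, keeping all equally best trees."""
    best = scorer(start)
    pool = {start}
    unswapped = [start]
    while unswapped:
        t = unswapped.pop()
        improved = False
        for nb in topo.tbr_neighbors(t):
            if clade_ids is not None and \
                    not _satisfied(nb, clade_ids, converse):
                continue
            s = scorer(nb)
            if s < best:
                best, pool, unswapped = s, {nb}, [nb]
                improved = True
                break
            if s == best and nb not in pool:
                if max_trees is None or len(pool) < max_trees:
                    pool.add(nb)
                    unswapped.append(nb)
    return best, pool


def _condense(trees, enc, collapse=True, protect=None):
    """MINBRLEN-collapse and de-duplicate a set of tuple trees."""
    out = {}
    for t in trees:
        c = collapse_zero_branches(t, enc, protect) if collapse \
            else topo.canonical(t)
        out[c] = None
    return list(out)


def _as_phylo(trees, labels) -> list[PhyloTree]:
    phylo = []
    for t in trees:
        def conv(u):
            if isinstance(u, int):
                return labels[u]
            return tuple(conv(c) for c in u)
        phylo.append(PhyloTree.from_label_tuples(conv(t)))
    return phylo


# ----------------------------------------------------------------------
# estimators

class MaxParsimonySearch(BaseEstimator):
    """Heuristic maximum-parsimony tree search.

    Stepwise addition (random order per replicate under
    ``random_state``, or file order for ``addition="as-is"``) followed
    by TBR branch swapping, pooling all shortest trees across
    replicates, MINBRLEN-collapsing and de-duplicating them.

    Parameters
    ----------
    n_replicates : int
        Number of addition-sequence replicates.
    addition : {"random", "as-is"}
    random_state : int or numpy Generator, optional
    constraint : CladeConstraint, optional
        Positive constraints retain only trees containing the clade;
        converse constraints only trees lacking it.
    polymorphism_mode : {"uncertainty", "polymorphism"}
        How multi-state cells are scored.
    max_trees : int, optional
        Cap on the equally-best tree buffer (unbounded by default).
    collapse : bool
        Apply the MINBRLEN collapse to the stored optimal trees.

    Attributes
    ----------
    best_length_ : int
    optimal_trees_ : tuple of PhyloTree
    replicates_run_ : int
    result_ : SearchResult
    """

    def __init__(self, n_replicates=10, addition="random",
                 random_state=None, constraint=None,
                 polymorphism_mode="uncertainty", max_trees=None,
                 collapse=True):
        self.n_replicates = n_replicates
        self.addition = addition
        self.random_state = random_state
        self.constraint = constraint
        self.polymorphism_mode = polymorphism_mode
        self.max_trees = max_trees
        self.collapse = collapse

    def fit(self, X: CharacterMatrix, y=None):
        if not isinstance(X, CharacterMatrix):
            raise TypeError("X must be a CharacterMatrix")
        if self.addition not in ("random", "as-is"):
            raise ValueError(f"unknown addition mode {self.addition!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        n = X.n_taxa
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) \
            else None
        rng = np.random.default_rng(self.random_state)
        enc = MatrixEncoding(X)
        scorer = _Scorer(enc, self.polymorphism_mode)

        clade_ids, converse = None, False
        if self.constraint is not None:
            clade_ids = self.constraint.validate(X)
            converse = self.constraint.converse

        note = None
        if n < 4:
            t = topo.canonical((0, 1) if n == 2 else (0, (1, 2)))
            best, pool = scorer(t), {t}
            note = "fewer than 4 taxa: single unrooted topology"
            reps = 0
        else:
            best, pool = None, set()
            reps = int(self.n_replicates)
            for _ in range(reps):
                if self.addition == "random":
                    order = list(rng.permutation(n))
                else:
                    order = list(range(n))
                start = _stepwise_addition(order, scorer, clade_ids,
                                           converse, rng)
                if clade_ids is not None and \
                        not _satisfied(start, clade_ids, converse):
                    if not converse:
                        start = _force_positive(start, clade_ids, scorer)
                    if start is None or \
                            not _satisfied(start, clade_ids, converse):
                        continue
                b, p = _tbr_swap(start, scorer, clade_ids, converse,
                                 self.max_trees)
                if best is None or b < best:
                    best, pool = b, set(p)
                elif b == best:
                    pool |= p
            if best is None:
                raise MatrixError(
                    "no replicate produced a constraint-satisfying tree"
                )

        protect = clade_ids if (clade_ids is not None and not converse) \
            else None
        condensed = _condense(pool, enc, self.collapse, protect)
        trees = _as_phylo(condensed, X.taxa)
        self.best_length_ = int(best)
        self.optimal_trees_ = tuple(trees)
        self.replicates_run_ = reps
        self.result_ = SearchResult(self.best_length_, self.optimal_trees_,
                                    reps, seed, note)
        return self

    def score(self, X=None, y=None):
        """Negated best length (higher is better, sklearn convention)."""
        return -self.best_length_


class ExhaustiveParsimonySearch(BaseEstimator):
    """Score every unrooted binary topology; the oracle for small instances.

    Refuses instances above ``max_taxa`` (default 9, i.e. 135,135
    topologies).
    """

    def __init__(self, constraint=None, polymorphism_mode="uncertainty",
                 collapse=True, max_taxa=9):
        self.constraint = constraint
        self.polymorphism_mode = polymorphism_mode
        self.collapse = collapse
        self.max_taxa = max_taxa

    def fit(self, X: CharacterMatrix, y=None):
        n = X.n_taxa
        if n > self.max_taxa:
            raise ValueError(
                f"exhaustive search on {n} taxa would score "
                f"{topo.n_unrooted_topologies(n):,} topologies "
                f"(limit {self.max_taxa} taxa)"
            )
        enc = MatrixEncoding(X)
        scorer = _Scorer(enc, self.polymorphism_mode)
        clade_ids, converse = None, False
        if self.constraint is not None:
            clade_ids = self.constraint.validate(X)
            converse = self.constraint.converse
        best, pool = None, []
        if n < 4:
            t = topo.canonical((0, 1) if n == 2 else (0, (1, 2)))
            best, pool = scorer(t), [t]
            n_scored = 1
        else:
            n_scored = 0
            for t in topo.all_topologies(list(range(n))):
                t = topo.canonical(t)
                if clade_ids is not None and \
                        not _satisfied(t, clade_ids, converse):
                    continue
                n_scored += 1
                s = scorer(t)
                if best is None or s < best:
                    best, pool = s, [t]
                elif s == best:
                    pool.append(t)
            if best is None:
                raise MatrixError("constraint excludes every topology")
        protect = clade_ids if (clade_ids is not None and not converse) \
            else None
        condensed = _condense(pool, enc, self.collapse, protect)
        self.best_length_ = int(best)
        self.optimal_trees_ = tuple(_as_phylo(condensed, X.taxa))
        self.n_topologies_scored_ = n_scored
        self.result_ = SearchResult(self.best_length_, self.optimal_trees_,
                                    n_scored, None)
        return self


class ParsimonyBootstrap(BaseEstimator):
    """Nonparametric bootstrap of clade support under parsimony.

    Each pseudoreplicate resamples characters with replacement
    (implemented by re-weighting, so original weights are preserved
    multiplicatively), runs one addition-sequence-plus-TBR search, and
    records clades.  ``tree_mode="consensus"`` (default) takes each
    pseudoreplicate's clades from the strict consensus of its optimal
    trees; ``tree_mode="all"`` weights all optimal trees equally.

    Attributes
    ----------
    supports_ : dict mapping frozenset(labels) -> percent (0..100)
    """

    def __init__(self, n_pseudoreplicates=100, addition="simple",
                 random_state=None, polymorphism_mode="uncertainty",
                 tree_mode="consensus", max_trees=50):
        self.n_pseudoreplicates = n_pseudoreplicates
        self.addition = addition
        self.random_state = random_state
        self.polymorphism_mode = polymorphism_mode
        self.tree_mode = tree_mode
        self.max_trees = max_trees

    def fit(self, X: CharacterMatrix, y=None):
        if self.n_pseudoreplicates < 1:
            raise ValueError("need at least one pseudoreplicate")
        if self.addition not in ("simple", "random"):
            raise ValueError(f"unknown addition mode {self.addition!r}")
        rng = np.random.default_rng(self.random_state)
        n, m = X.n_taxa, X.n_characters
        counts: dict[frozenset, float] = {}
        base_w = np.asarray(X.weights)
        for _ in range(int(self.n_pseudoreplicates)):
            draw = rng.integers(0, m, size=m)
            mult = np.bincount(draw, minlength=m)
            Xb = X.reweight(base_w * mult)
            enc = MatrixEncoding(Xb)
            scorer = _Scorer(enc, self.polymorphism_mode)
            order = list(rng.permutation(n)) if self.addition == "random" \
                else list(range(n))
            start = _stepwise_addition(order, scorer, rng=rng)
            _, pool = _tbr_swap(start, scorer, max_trees=self.max_trees)
            trees = _condense(pool, enc, collapse=True)
            if self.tree_mode == "consensus":
                clades = _strict_bipartitions(trees)
                for c in clades:
                    counts[c] = counts.get(c, 0) + 1.0
            else:
                for t in trees:
                    for c in topo.bipartitions(t):
                        counts[c] = counts.get(c, 0) + 1.0 / len(trees)
        pct = 100.0 / self.n_pseudoreplicates
        self.supports_ = {
            frozenset(X.taxa[i] for i in c): v * pct
            for c, v in counts.items()
        }
        self.n_pseudoreplicates_run_ = int(self.n_pseudoreplicates)
        return self

    def reported(self, min_support=50.0) -> dict:
        """Supports at or above the reporting threshold (PAUP-style)."""
        return {c: v for c, v in self.supports_.items() if v >= min_support}


def _strict_bipartitions(trees) -> frozenset:
    sets = [topo.bipartitions(t) for t in trees]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


# ----------------------------------------------------------------------
# consensus

def consensus(trees, method: str = "strict", cutoff: float = 50.0
              ) -> ConsensusTree:
    """Strict or majority-rule consensus of trees on one leaf set.

    Majority rule keeps splits whose frequency strictly exceeds
    ``cutoff`` percent (50 by default); frequencies are attached to the
    result.  With a cutoff below 50, splits are admitted greedily by
    decreasing frequency, skipping any that conflict.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = {t.leaf_set for t in trees}
    if len(leaf_sets) > 1:
        a = min(leaf_sets, key=sorted)
        diffs = {frozenset(s ^ a) for s in leaf_sets} - {frozenset()}
        raise ValueError(
            f"trees have mismatched leaf sets; differing taxa: "
            f"{sorted(frozenset().union(*diffs))}"
        )
    if method not in ("strict", "majority"):
        raise ValueError(f"unknown consensus method {method!r}")
    n = len(trees)
    freq: dict[frozenset, int] = {}
    for t in trees:
        for c in t.bipartitions():
            freq[c] = freq.get(c, 0) + 1
    if method == "strict":
        chosen = [c for c, k in freq.items() if k == n]
    else:
        chosen = [c for c, k in freq.items() if 100.0 * k / n > cutoff]
    # greedy compatibility filter (no-op for strict / majority>=50)
    chosen.sort(key=lambda c: (-freq[c], len(c), sorted(c)))
    accepted: list[frozenset] = []
    for c in chosen:
        if all(_compatible(c, d) for d in accepted):
            accepted.append(c)
    labels = sorted(trees[0].leaf_set)
    tree = _tree_from_clades(labels, accepted)
    freqs = {c: 100.0 * k / n for c, k in freq.items()}
    return ConsensusTree(tree, method, cutoff,
                         {c: freqs[c] for c in accepted})


def _compatible(a: frozenset, b: frozenset) -> bool:
    return not (a & b) or a <= b or b <= a


def _tree_from_clades(labels, clades) -> PhyloTree:
    """Assemble the (possibly multifurcating) tree containing the clades.

    Clades are label sets not containing the anchor (first sorted
    label), pairwise compatible.
    """
    anchor = labels[0]
    others = [l for l in labels[1:]]
    by_size = sorted(clades, key=len)
    parent: dict = {}
    items: list = [frozenset((l,)) for l in others] + by_size
    for it in items:
        best = None
        for c in by_size:
            if it != c and it <= c and (best is None or len(c) < len(best)):
                best = c
        parent[it] = best

    def build(c) -> tuple:
        kids = []
        for it in items:
            if parent[it] == c:
                if len(it) == 1 and it not in by_size:
                    (l,) = it
                    kids.append(l)
                elif it in by_size and it != c:
                    kids.append(build(it))
        # singleton clades listed explicitly: avoid double-adding
        return tuple(kids) if len(kids) > 1 else kids[0]

    top = []
    for it in items:
        if parent[it] is None:
            if len(it) == 1 and it not in by_size:
                (l,) = it
                top.append(l)
            else:
                top.append(build(it))
    rest = tuple(top) if len(top) > 1 else top[0]
    return PhyloTree.from_label_tuples((anchor, rest))


# ----------------------------------------------------------------------
# functional wrappers

def heuristic_search(matrix: CharacterMatrix, n_replicates: int = 10,
                     addition: str = "random", seed=None,
                     constraint: CladeConstraint | None = None,
                     polymorphism_mode: str = "uncertainty",
                     max_trees: int | None = None,
                     collapse: bool = True) -> SearchResult:
    """Random-addition + TBR search; see :class:`MaxParsimonySearch`."""
    est = MaxParsimonySearch(
        n_replicates=n_replicates, addition=addition, random_state=seed,
        constraint=constraint, polymorphism_mode=polymorphism_mode,
        max_trees=max_trees, collapse=collapse,
    ).fit(matrix)
    return est.result_


def exhaustive_search(matrix: CharacterMatrix,
                      constraint: CladeConstraint | None = None,
                      polymorphism_mode: str = "uncertainty",
                      collapse: bool = True) -> SearchResult:
    """Global optimum by enumeration; see :class:`ExhaustiveParsimonySearch`."""
    est = ExhaustiveParsimonySearch(
        constraint=constraint, polymorphism_mode=polymorphism_mode,
        collapse=collapse,
    ).fit(matrix)
    return est.result_


def bootstrap(matrix: CharacterMatrix, n_pseudoreplicates: int = 100,
              seed=None, addition: str = "simple",
              tree_mode: str = "consensus") -> dict:
    """Bootstrap clade support percentages; see :class:`ParsimonyBootstrap`."""
    est = ParsimonyBootstrap(
        n_pseudoreplicates=n_pseudoreplicates, addition=addition,
        random_state=seed, tree_mode=tree_mode,
    ).fit(matrix)
    return est.supports_
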