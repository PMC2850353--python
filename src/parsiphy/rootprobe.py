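"""Random-outgroup rooting diagnostic for long-branch attraction.

Artificial outgroup taxa — i.i.d. nucleotides at stated base
frequencies followed by random binary morphology and indel characters —
are appended one at a time to an ingroup matrix.  Each is used as the
sole outgroup of a parsimony search, the optimal trees are rooted at
it, and the ingroup branch it attaches to is recorded.  Branches that
attract many random outgroups are the places a real long-branched
outgroup would tend to root the tree, whether or not that rooting is
historically correct.

A replicate's root position is read from the strict agreement of its
optimal trees; failing that, from a >50% majority among them; if still
ambiguous the replicate counts as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _topology as topo
from .matrix import CharacterMatrix, MatrixError
from .search import MaxParsimonySearch
from .tree import PhyloTree

_DNA = ("A", "C", "G", "T")


@dataclass
class RandomOutgroupSpec:
    """Composition of the artificial outgroup rows.

    Defaults follow the empirical regime of a ~900-nucleotide nuclear
    exon with afrotherian base composition plus binary morphology and
    indel blocks.
    """

    n_nucleotides: int = 913
    base_frequencies: tuple = (0.28, 0.27, 0.22, 0.23)
    n_morphology: int = 145
    n_indel: int = 8

    def __post_init__(self):
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any() or \
                abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base_frequencies must be a 4-simplex")
        for name in ("n_nucleotides", "n_morphology", "n_indel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RootSurveyResult:
    """Tally of root attachments over the survey replicates.

    ``counts`` maps each attachment branch — keyed by the smaller side
    of the ingroup split it induces — to the number of random outgroups
    that rooted the tree there.  Counts plus ``unresolved_count`` sum
    to ``n_total``.
    """

    counts: dict
    unresolved_count: int
    n_total: int
    records: list = field(default_factory=list)


def generate_random_outgroup(spec: RandomOutgroupSpec, seed=None,
                             matrix: CharacterMatrix | None = None,
                             override: bool = False) -> list[frozenset]:
    """One artificial taxon row (list of singleton cells, no missing).

    When *matrix* is given, the row follows the matrix's column order
    and datatypes, and the spec's counts must match the matrix's DNA /
    standard / binary column counts unless ``override`` is set.
    """
    rng = np.random.default_rng(seed)
    if matrix is not None:
        n_dna = sum(1 for d in matrix.datatypes if d == "dna")
        n_std = sum(1 for d in matrix.datatypes if d == "standard")
        n_bin = sum(1 for d in matrix.datatypes if d == "binary")
        want = (spec.n_nucleotides, spec.n_morphology, spec.n_indel)
        if (n_dna, n_std, n_bin) != want and not override:
            raise MatrixError(
                f"spec counts {want} do not match matrix column counts "
                f"(dna={n_dna}, standard={n_std}, binary={n_bin}); "
                "pass override=True to generate against the matrix shape"
            )
        datatypes = matrix.datatypes
    else:
        datatypes = (["dna"] * spec.n_nucleotides
                     + ["standard"] * spec.n_morphology
                     + ["binary"] * spec.n_indel)
    n_dna_total = sum(1 for d in datatypes if d == "dna")
    dna_draws = iter(rng.choice(4, size=n_dna_total,
                                p=np.asarray(spec.base_frequencies)))
    bin_draws = iter(rng.integers(0, 2, size=len(datatypes) - n_dna_total))
    row = []
    for d in datatypes:
        if d == "dna":
            row.append(frozenset((_DNA[int(next(dna_draws))],)))
        else:
            row.append(frozenset((str(int(next(bin_draws))),)))
    return row


def classify_attachment(reference_tree: PhyloTree, split: frozenset,
                        named_clades: dict) -> str:
    """Describe an attachment branch relative to named reference clades.

    Returns ``"at X"`` when the branch is clade X's stem, ``"within X"``
    when it lies inside X, otherwise a label built from the split
    itself — or ``"other"`` when the split does not occur in the
    reference tree.
    """
    split = frozenset(split)
    full = reference_tree.leaf_set
    comp = full - split
    for name, taxa in named_clades.items():
        taxa = frozenset(taxa)
        if split == taxa or comp == taxa:
            return f"at {name}"
    within = [
        (len(taxa), name) for name, taxa in named_clades.items()
        if split < frozenset(taxa) or comp < frozenset(taxa)
    ]
    if within:
        return f"within {min(within)[1]}"
    if not reference_tree.contains_clade(split):
        return "other"
    side = min((split, comp), key=lambda s: (len(s), sorted(s)))
    return "branch " + "+".join(sorted(side))


def at_or_within(result: RootSurveyResult, clade, ingroup_taxa) -> int:
    """Total outgroups attaching at the clade's stem or inside it."""
    clade = frozenset(clade)
    full = frozenset(ingroup_taxa)
    total = 0
    for split, k in result.counts.items():
        comp = full - split
        if split == clade or comp == clade or split < clade or comp < clade:
            total += k
    return total


class RandomOutgroupSurvey(BaseEstimator):
    """Survey where random pseudo-outgroups root an ingroup tree.

    Parameters
    ----------
    spec : RandomOutgroupSpec, optional
        Composition of the artificial taxa (defaults above).  A warning
        is raised as an error only on count mismatch with the matrix;
        pass ``override=True`` to generate rows following the matrix's
        own column layout regardless of the spec counts.
    n_outgroups : int
    n_replicates : int
        Random-addition replicates per per-outgroup search.
    random_state : int, optional
        Master seed; per-replicate streams are spawned from it by
        counter (SeedSequence), so replicate *i* is reproducible in
        isolation.

    Attributes
    ----------
    counts_ : dict frozenset(labels) -> int
    unresolved_count_ : int
    result_ : RootSurveyResult
    """

    def __init__(self, spec=None, n_outgroups=100, n_replicates=25,
                 random_state=None, override=False, max_trees=50,
                 outgroup_label="__random_outgroup__"):
        self.spec = spec
        self.n_outgroups = n_outgroups
        self.n_replicates = n_replicates
        self.random_state = random_state
        self.override = override
        self.max_trees = max_trees
        self.outgroup_label = outgroup_label

    def fit(self, X: CharacterMatrix, y=None):
        if X.n_taxa < 4:
            raise MatrixError("ingroup needs at least 4 taxa")
        spec = self.spec if self.spec is not None else RandomOutgroupSpec()
        master = np.random.SeedSequence(self.random_state)
        children = master.spawn(int(self.n_outgroups))
        counts: dict[frozenset, int] = {}
        unresolved = 0
        records = []
        og = self.outgroup_label
        for i, ss in enumerate(children):
            rng = np.random.default_rng(ss)
            row = generate_random_outgroup(
                spec, seed=rng, matrix=X, override=self.override)
            Xi = X.add_taxon(og, row)
            res = MaxParsimonySearch(
                n_replicates=self.n_replicates,
                random_state=int(rng.integers(2 ** 31)),
                max_trees=self.max_trees,
            ).fit(Xi).result_
            split, how = self._root_position(res.optimal_trees, og)
            if split is None:
                unresolved += 1
            else:
                counts[split] = counts.get(split, 0) + 1
            records.append({
                "replicate": i, "best_length": res.best_length,
                "n_optimal_trees": len(res.optimal_trees),
                "split": split, "resolved_by": how,
            })
        self.counts_ = counts
        self.unresolved_count_ = unresolved
        self.result_ = RootSurveyResult(
            counts, unresolved, int(self.n_outgroups), records)
        return self

    @staticmethod
    def _root_position(trees, outgroup_label):
        """Attachment split agreed by the optimal trees, if any.

        Strict first (all trees place the outgroup on the same ingroup
        branch), then >50% majority; None when neither resolves — e.g.
        when the outgroup sits on a collapsed polytomy.
        """
        votes: list[frozenset | None] = []
        for t in trees:
            og_idx = t.labels.index(outgroup_label)
            s = topo.attachment_split(t.topology, og_idx)
            if s is None:
                votes.append(None)
            else:
                votes.append(frozenset(t.labels[j] for j in s))
        defined = [v for v in votes if v is not None]
        if defined and len(set(defined)) == 1 and len(defined) == len(votes):
            return defined[0], "strict"
        tally: dict[frozenset, int] = {}
        for v in defined:
            tally[v] = tally.get(v, 0) + 1
        for split, k in sorted(tally.items(),
                               key=lambda kv: (-kv[1], sorted(kv[0]))):
            if k * 2 > len(votes):
                return split, "majority"
        return None, "unresolved"


def survey_root(matrix_ingroup: CharacterMatrix,
                spec: RandomOutgroupSpec | None = None,
                n_outgroups: int = 100, n_replicates: int = 25,
                seed=None, override: bool = False) -> RootSurveyResult:
    """Run the survey; see :class:`RandomOutgroupSurvey`."""
    est = RandomOutgroupSurvey(
        spec=spec, n_outgroups=n_outgroups, n_replicates=n_replicates,
        random_state=seed, override=override,
    ).fit(matrix_ingroup)
    return est.result_
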