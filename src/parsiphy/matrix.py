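"""Character matrices for parsimony analysis.

A :class:`CharacterMatrix` holds a taxa-by-characters table of *state
sets*: a singleton set is an ordinary observation, a multi-element set a
polymorphic or ambiguous cell, and the empty set a missing entry.
Characters carry a datatype tag (``dna``, ``standard`` or ``binary``),
an integer weight, and may be grouped into named, disjoint partitions
(e.g. a gene, a morphology block, and indel presence/absence codes).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

DNA_STATES = frozenset("ACGT")

#: IUPAC ambiguity codes expanded to state sets; gap and ? map to missing.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "X": "ACGT", "-": "", "?": "",
}

MISSING: frozenset = frozenset()

VALID_DATATYPES = ("dna", "standard", "binary")


class MatrixError(ValueError):
    """Raised for malformed matrices or invalid partition references."""


class CharacterMatrix:
    """Taxa x characters table of state sets with datatypes and partitions.

    Parameters
    ----------
    taxa : sequence of str
        Unique taxon labels, row order preserved.
    cells : sequence of sequence of frozenset
        One row per taxon; each cell a (possibly empty) frozenset of
        state symbols.  The empty set denotes missing data.
    datatypes : sequence of str
        Per-character tag in ``{"dna", "standard", "binary"}``.
    weights : sequence of int, optional
        Per-character non-negative integer weights (default all 1).
    partitions : mapping of str to index sequence, optional
        Named, disjoint character index sets.  Indices not covered by
        any named partition are collected into a partition called
        ``"unassigned"``.  When omitted, no named partitions exist and
        only the pseudo-partition ``"all"`` is addressable.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence[frozenset]],
        datatypes: Sequence[str],
        weights: Sequence[int] | None = None,
        partitions: Mapping[str, Iterable[int]] | None = None,
    ):
        self.taxa = tuple(str(t) for t in taxa)
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon label(s): {dup}")
        self.cells = [tuple(frozenset(c) for c in row) for row in cells]
        if len(self.cells) != len(self.taxa):
            raise MatrixError(
                f"{len(self.taxa)} taxa but {len(self.cells)} rows"
            )
        ncols = {len(r) for r in self.cells}
        if len(ncols) > 1:
            for t, row in zip(self.taxa, self.cells):
                if len(row) != len(self.cells[0]):
                    raise MatrixError(
                        f"ragged matrix: row for taxon {t!r} has "
                        f"{len(row)} cells, expected {len(self.cells[0])}"
                    )
        self.n_characters = len(self.cells[0]) if self.cells else 0
        self.n_taxa = len(self.taxa)

        self.datatypes = tuple(datatypes)
        if len(self.datatypes) != self.n_characters:
            raise MatrixError("one datatype tag required per character")
        for d in set(self.datatypes):
            if d not in VALID_DATATYPES:
                raise MatrixError(f"unknown datatype {d!r}")

        if weights is None:
            self.weights = np.ones(self.n_characters, dtype=int)
        else:
            self.weights = np.asarray(list(weights), dtype=int)
            if self.weights.shape != (self.n_characters,) or (self.weights < 0).any():
                raise MatrixError("weights must be per-character non-negative ints")

        self.partitions: dict[str, tuple[int, ...]] = {}
        if partitions:
            seen: set[int] = set()
            for name, idx in partitions.items():
                idx = tuple(sorted(int(i) for i in idx))
                for i in idx:
                    if not 0 <= i < self.n_characters:
                        raise MatrixError(
                            f"partition {name!r} index {i} out of range"
                        )
                    if i in seen:
                        raise MatrixError(
                            f"partition {name!r} overlaps another at index {i}"
                        )
                seen.update(idx)
                self.partitions[name] = idx
            rest = tuple(i for i in range(self.n_characters) if i not in seen)
            if rest:
                self.partitions["unassigned"] = rest

        self._universes: list[frozenset] | None = None
        self._validate_states()

    # ------------------------------------------------------------------
    def _validate_states(self) -> None:
        for j in range(self.n_characters):
            uni = self.state_universe(j)
            for i, t in enumerate(self.taxa):
                bad = self.cells[i][j] - uni
                if bad:
                    raise MatrixError(
                        f"taxon {t!r}, character {j + 1}: state(s) "
                        f"{sorted(bad)} outside universe {sorted(uni)}"
                    )

    def state_universe(self, j: int) -> frozenset:
        """Set of admissible states for character *j* (column index, 0-based)."""
        if self._universes is None:
            unis: list[frozenset] = []
            for k in range(self.n_characters):
                if self.datatypes[k] == "dna":
                    unis.append(DNA_STATES)
                elif self.datatypes[k] == "binary":
                    unis.append(frozenset({"0", "1"}))
                else:
                    obs = frozenset().union(*(row[k] for row in self.cells))
                    unis.append(obs if obs else frozenset({"0"}))
            self._universes = unis
        return self._universes[j]

    # ------------------------------------------------------------------
    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise MatrixError(f"unknown taxon {label!r}") from None

    def partition_indices(self, partition: str | None = None) -> tuple[int, ...]:
        """Character indices of a named partition; ``None``/"all" = everything."""
        if partition is None or partition == "all":
            return tuple(range(self.n_characters))
        if partition not in self.partitions:
            raise MatrixError(
                f"unknown partition {partition!r}; "
                f"known: {sorted(self.partitions)}"
            )
        return self.partitions[partition]

    def column(self, j: int) -> list[frozenset]:
        return [row[j] for row in self.cells]

    # ------------------------------------------------------------------
    def select_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        """Row subset (in the given order), partitions preserved."""
        idx = [self.taxon_index(t) for t in labels]
        return CharacterMatrix(
            [self.taxa[i] for i in idx],
            [self.cells[i] for i in idx],
            self.datatypes,
            self.weights,
            self.partitions or None,
        )

    def select_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Column subset; partitions are re-indexed and dropped if emptied."""
        indices = list(indices)
        pos = {j: p for p, j in enumerate(indices)}
        parts = {}
        for name, idx in self.partitions.items():
            kept = tuple(pos[j] for j in idx if j in pos)
            if kept:
                parts[name] = kept
        return CharacterMatrix(
            self.taxa,
            [[row[j] for j in indices] for row in self.cells],
            [self.datatypes[j] for j in indices],
            [int(self.weights[j]) for j in indices],
            parts or None,
        )

    def add_taxon(self, label: str, row: Sequence[frozenset]) -> "CharacterMatrix":
        """Return a copy with one extra row appended."""
        if len(row) != self.n_characters:
            raise MatrixError(
                f"row for {label!r} has {len(row)} cells, "
                f"expected {self.n_characters}"
            )
        return CharacterMatrix(
            list(self.taxa) + [label],
            list(self.cells) + [list(row)],
            self.datatypes,
            self.weights,
            self.partitions or None,
        )

    def reweight(self, weights: Sequence[int]) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa, self.cells, self.datatypes, weights,
            self.partitions or None,
        )

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and self.datatypes == other.datatypes
            and np.array_equal(self.weights, other.weights)
            and self.partitions == other.partitions
        )

    def __repr__(self) -> str:
        parts = ",".join(self.partitions) or "none"
        return (
            f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} "
            f"characters; partitions: {parts}>"
        )


def count_parsimony_informative(
    matrix: CharacterMatrix, partition: str | None = None
) -> int:
    """Number of parsimony-informative characters in a partition.

    A character is informative when at least two of its states each
    occur in at least two taxa.  Only unambiguous singleton cells count
    as occurrences; missing and polymorphic/ambiguous cells contribute
    nothing.
    """
    n = 0
    for j in matrix.partition_indices(partition):
        counts: dict[str, int] = {}
        for row in matrix.cells:
            cell = row[j]
            if len(cell) == 1:
                (s,) = cell
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            n += 1
    return n
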