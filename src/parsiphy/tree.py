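"""Phylogenetic trees over named taxa.

:class:`PhyloTree` is a thin, immutable wrapper around the tuple
topologies of :mod:`parsiphy._topology`, carrying taxon labels and
optional per-branch annotations (step counts, support percentages).
Equality and hashing use the unrooted bipartition set, so trees that
differ only in rooting or child order compare equal.  Newick parsing is
delegated to dendropy.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy

from . import _topology as topo


class TreeError(ValueError):
    pass


class PhyloTree:
    """Unrooted (or leaf-anchored) tree over a set of taxon labels.

    Internally the taxa are sorted and the topology stored as a
    canonical nested tuple of indices into the sorted label list.
    Branch annotations are keyed by the *clade* below each branch: a
    frozenset of labels on the side of the branch away from the anchor
    (the alphabetically first taxon).
    """

    __slots__ = ("labels", "topology", "branch_annotations", "_bip")

    def __init__(self, labels: Sequence[str], topology,
                 branch_annotations: Mapping[frozenset, float] | None = None):
        self.labels = tuple(sorted(labels))
        if len(set(self.labels)) != len(self.labels):
            raise TreeError("duplicate taxon labels")
        got = topo.leafset(topology)
        if got != frozenset(range(len(self.labels))):
            raise TreeError("topology leaves do not match label indices")
        self.topology = topo.canonical(topology)
        self._bip = None
        ann = dict(branch_annotations or {})
        valid = set(self.clades())
        for k in ann:
            if frozenset(k) not in valid:
                raise TreeError(f"annotation for non-existent branch {sorted(k)}")
        self.branch_annotations = {frozenset(k): v for k, v in ann.items()}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_label_tuples(cls, t, annotations=None) -> "PhyloTree":
        """Build from nested tuples of taxon labels, e.g. (("A","B"),("C","D"))."""
        labels = sorted(_collect_labels(t))
        index = {l: i for i, l in enumerate(labels)}

        def conv(u):
            if isinstance(u, tuple):
                return tuple(conv(c) for c in u)
            return index[u]

        return cls(labels, conv(t), annotations)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        lengths = {}

        def conv(node):
            if node.is_leaf():
                sub = node.taxon.label
            else:
                kids = [conv(c) for c in node.child_nodes()]
                sub = kids[0] if len(kids) == 1 else tuple(kids)
            if node.edge.length is not None:
                lengths[sub] = node.edge.length
            return sub

        root_kids = [conv(c) for c in dtree.seed_node.child_nodes()]
        t = root_kids[0] if len(root_kids) == 1 else tuple(root_kids)
        tree = cls.from_label_tuples(t)
        ann = {}
        for sub, val in lengths.items():
            if val is None:
                continue
            clade = frozenset(_collect_labels(sub))
            if clade in set(tree.clades()):
                ann[clade] = val
        tree.branch_annotations.update(ann)
        return tree

    # -- basic queries ---------------------------------------------------
    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def is_binary(self) -> bool:
        return topo.is_binary(self.topology)

    def clades(self) -> list[frozenset]:
        """Label sets below every branch (anchor side excluded)."""
        return [
            frozenset(self.labels[i] for i in s)
            for s in topo.clades(self.topology)
        ]

    def bipartitions(self) -> frozenset:
        """Non-trivial splits, each as the label set not containing the anchor."""
        if self._bip is None:
            self._bip = frozenset(
                frozenset(self.labels[i] for i in s)
                for s in topo.bipartitions(self.topology)
            )
        return self._bip

    def contains_clade(self, taxa) -> bool:
        """Does some branch separate exactly these taxa from the rest?"""
        taxa = frozenset(taxa)
        if not taxa <= self.leaf_set:
            return False
        if len(taxa) in (0, self.n_leaves):
            return True
        if len(taxa) == 1 or len(taxa) == self.n_leaves - 1:
            return True  # trivial splits are always present
        comp = self.leaf_set - taxa
        return taxa in self.bipartitions() or comp in self.bipartitions()

    # -- output ----------------------------------------------------------
    def to_newick(self, annotations: str | None = None) -> str:
        """Serialize to newick.

        ``annotations="lengths"`` writes branch annotations as branch
        length values (``:<value>``); ``None`` writes topology only.
        """
        use = annotations == "lengths" and bool(self.branch_annotations)

        def fmt(u) -> str:
            if isinstance(u, int):
                s = _quote(self.labels[u])
                key = frozenset((self.labels[u],))
            else:
                s = "(" + ",".join(fmt(c) for c in u) + ")"
                key = frozenset(
                    self.labels[i] for i in topo.leafset(u)
                )
            if use and key in self.branch_annotations:
                s += f":{self.branch_annotations[key]:g}"
            return s

        t = self.topology
        if isinstance(t, int):
            return _quote(self.labels[t]) + ";"
        return "(" + ",".join(fmt(c) for c in t) + ");"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(annotations="lengths"),
            schema="newick",
            taxon_namespace=taxon_namespace,
        )

    # -- dunder ----------------------------------------------------------
    def __eq__(self, other):
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (
            self.leaf_set == other.leaf_set
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self):
        return hash((self.leaf_set, self.bipartitions()))

    def __repr__(self):
        return f"<PhyloTree {self.n_leaves} leaves: {self.to_newick()}>"


def _collect_labels(t) -> list[str]:
    if isinstance(t, tuple):
        out = []
        for c in t:
            out.extend(_collect_labels(c))
        return out
    return [t]


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_tree(tree: PhyloTree, annotations: str | None = None) -> str:
    """Newick text for a tree; see :meth:`PhyloTree.to_newick`."""
    return tree.to_newick(annotations=annotations)


def read_trees(text: str, schema: str = "newick") -> list[PhyloTree]:
    """Parse one or more trees from newick text."""
    tl = dendropy.TreeList.get(data=text, schema=schema)
    return [PhyloTree.from_dendropy(t) for t in tl]
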