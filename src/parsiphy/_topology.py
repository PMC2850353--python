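"""Low-level tuple representation of unrooted trees.

An unrooted tree over integer leaf ids is stored as a nested tuple: a
leaf is an ``int`` and an internal node a tuple of child subtrees.  The
outermost tuple's "root" is *suppressed* — a top-level pair ``(L, R)``
means an edge between the roots of ``L`` and ``R``, so the structure as
a whole is unrooted.  Canonical form anchors the tree at its smallest
leaf id (``(min_leaf, rest)``) and orders children by minimum leaf, so
equal topologies compare equal as tuples.

Binary trees are used throughout the searches; consensus and collapsed
trees may contain multifurcations (tuples of arity > 2).
"""

from __future__ import annotations

Topo = int | tuple


def leafset(t: Topo) -> frozenset[int]:
    if isinstance(t, int):
        return frozenset((t,))
    out: set[int] = set()
    stack = [t]
    while stack:
        u = stack.pop()
        if isinstance(u, int):
            out.add(u)
        else:
            stack.extend(u)
    return frozenset(out)


def min_leaf(t: Topo) -> int:
    return t if isinstance(t, int) else min(min_leaf(c) for c in t)


def n_leaves(t: Topo) -> int:
    return len(leafset(t))


def is_binary(t: Topo) -> bool:
    """True when every internal node of the unrooted tree has degree 3."""
    if isinstance(t, int):
        return True
    if len(t) != 2:
        return False

    def ok(u: Topo) -> bool:
        if isinstance(u, int):
            return True
        return len(u) == 2 and all(ok(c) for c in u)

    return all(ok(c) for c in t)


# ----------------------------------------------------------------------
# adjacency form (node ids are the subtree tuples themselves, which are
# unique within one tree because their leaf sets differ)

def to_adjacency(t: Topo) -> dict:
    """Unrooted adjacency map; the top-level node of *t* is suppressed."""
    if isinstance(t, int):
        raise ValueError("single-leaf tree has no edges")
    adj: dict = {}

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def walk(u):
        if isinstance(u, tuple):
            for c in u:
                add_edge(u, c)
                walk(c)

    if len(t) == 2:
        add_edge(t[0], t[1])  # suppressed top node
        walk(t[0])
        walk(t[1])
    else:
        walk(t)  # multifurcating top: keep it as a real node
    return adj


def _subtree_from(adj: dict, node, parent) -> Topo:
    """Rooted tuple of everything on *node*'s side of edge (parent, node)."""
    if isinstance(node, int):
        return node
    children = [n for n in adj[node] if n is not parent]
    subs = sorted((_subtree_from(adj, c, node) for c in children), key=min_leaf)
    if len(subs) == 1:  # suppress degree-2 remnant
        return subs[0]
    return tuple(subs)


def undirected_edges(adj: dict) -> list[tuple]:
    seen = set()
    out = []
    for u, nbrs in adj.items():
        for v in nbrs:
            key = frozenset((id(u), id(v)))
            if key not in seen:
                seen.add(key)
                out.append((u, v))
    return out


def canonical(t: Topo) -> Topo:
    """Anchor at the smallest leaf and sort children by minimum leaf id."""
    if isinstance(t, int):
        return t
    if len(leafset(t)) == 2:
        a, b = sorted(leafset(t))
        return (a, b)
    adj = to_adjacency(t)
    m = min(leafset(t))
    # locate the leaf node m and its neighbour
    (nbr,) = adj[m]
    return (m, _subtree_from(adj, nbr, m))


# ----------------------------------------------------------------------
# edges and clades

def clades(t: Topo) -> list[frozenset[int]]:
    """Leaf sets under every non-top node (one per edge of the tree)."""
    out: list[frozenset[int]] = []

    def walk(u: Topo) -> frozenset[int]:
        if isinstance(u, int):
            s = frozenset((u,))
        else:
            s = frozenset().union(*(walk(c) for c in u))
        out.append(s)
        return s

    if isinstance(t, int):
        return [frozenset((t,))]
    for c in t:
        walk(c)
    return out


def bipartitions(t: Topo) -> frozenset[frozenset[int]]:
    """Non-trivial splits as the side not containing the smallest leaf."""
    full = leafset(t)
    m = min(full)
    out = set()
    for s in clades(t):
        if 1 < len(s) < len(full) - 1:
            out.add(s if m not in s else full - s)
    return frozenset(out)


def same_topology(a: Topo, b: Topo) -> bool:
    return leafset(a) == leafset(b) and bipartitions(a) == bipartitions(b)


# ----------------------------------------------------------------------
# insertion (stepwise addition) — binary trees only

def _insertions_sub(t: Topo, g: Topo) -> list[Topo]:
    """Attach subtree g on the edge above t and on every edge inside t.

    First element is always the edge-above attachment.
    """
    out: list[Topo] = [(t, g) if min_leaf(t) <= min_leaf(g) else (g, t)]
    if isinstance(t, tuple):
        L, R = t
        out.extend(_order(l2, R) for l2 in _insertions_sub(L, g))
        out.extend(_order(L, r2) for r2 in _insertions_sub(R, g))
    return out


def _order(a: Topo, b: Topo) -> tuple:
    return (a, b) if min_leaf(a) <= min_leaf(b) else (b, a)


def all_insertions(t: Topo, g: Topo) -> list[Topo]:
    """All trees obtained by attaching g on each of the 2n-3 edges of t."""
    if isinstance(t, int):
        return [_order(t, g)]
    L, R = t
    out = [_order(l2, R) for l2 in _insertions_sub(L, g)]
    out.extend(_order(L, r2) for r2 in _insertions_sub(R, g)[1:])
    return out


def all_topologies(leaves: list[int]) -> list[Topo]:
    """Every unrooted binary topology over the leaves, each exactly once."""
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    trees: list[Topo] = [_order(leaves[0], leaves[1])]
    for x in leaves[2:]:
        trees = [t2 for t in trees for t2 in all_insertions(t, x)]
    return trees


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary trees on n leaves."""
    c = 1
    for k in range(3, n + 1):
        c *= 2 * k - 5
    return c


# ----------------------------------------------------------------------
# TBR rearrangement — binary trees only

def plantings(s: Topo) -> list[Topo]:
    """All rooted ("planted") versions of the unrooted subtree s."""
    if isinstance(s, int) or len(leafset(s)) == 2:
        return [s]
    adj = to_adjacency(s)
    out = []
    for u, v in undirected_edges(adj):
        out.append(_order(_subtree_from(adj, u, v), _subtree_from(adj, v, u)))
    return out


def attach_everywhere(base: Topo, sub: Topo) -> list[Topo]:
    """Attach planted subtree *sub* on every edge of full tree *base*."""
    if isinstance(base, int):
        return [_order(base, sub)]
    return all_insertions(base, sub)


def tbr_neighbors(t: Topo) -> set[Topo]:
    """Canonicalized TBR neighborhood of a binary unrooted tree.

    Every edge is bisected; the pruned part is re-rooted on each of its
    edges and reattached on each edge of the remainder.  The original
    topology is excluded.
    """
    t = canonical(t)
    if n_leaves(t) < 4:
        return set()
    adj = to_adjacency(t)
    out: set[Topo] = set()
    for u, v in undirected_edges(adj):
        sub = _subtree_from(adj, u, v)
        base = _subtree_from(adj, v, u)
        # every (edge of sub) x (edge of base) rejoin; a single-leaf base
        # only admits the original rejoin for a leaf sub, but re-rooted
        # subs still give new topologies
        for sr in plantings(sub):
            for cand in attach_everywhere(base, sr):
                out.add(canonical(cand))
    out.discard(t)
    return out


# ----------------------------------------------------------------------
# rerooting helpers

def reroot_at_leaf(t: Topo, leaf: int) -> tuple:
    """Return (leaf, rest) — the tree anchored at a designated leaf."""
    if leaf not in leafset(t):
        raise ValueError(f"leaf {leaf} not in tree")
    if n_leaves(t) == 2:
        other = (leafset(t) - {leaf}).pop()
        return (leaf, other)
    adj = to_adjacency(t)
    (nbr,) = adj[leaf]
    return (leaf, _subtree_from(adj, nbr, leaf))


def remove_leaf(t: Topo, leaf: int) -> Topo:
    """Delete a leaf and suppress the resulting degree-2 node."""

    def walk(u: Topo) -> Topo | None:
        if isinstance(u, int):
            return None if u == leaf else u
        kept = [w for w in (walk(c) for c in u) if w is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return tuple(kept)

    out = walk(t if isinstance(t, tuple) else (t,))
    if out is None or isinstance(out, int):
        raise ValueError("removal would leave fewer than 2 leaves")
    return canonical(out)


def attachment_split(t: Topo, leaf: int) -> frozenset[int] | None:
    """Split of the remaining taxa induced by *leaf*'s attachment edge.

    Returns the smaller side (ties broken by smallest member) of the
    bipartition that the leaf's attachment point induces on the tree
    with the leaf removed, or None when the leaf sits on a polytomy of
    degree > 3 (attachment ambiguous).
    """
    full = leafset(t) - {leaf}
    adj = to_adjacency(canonical(t))
    node = leaf
    (nbr,) = adj[node]
    if isinstance(nbr, int):
        # two-leaf tree: no split to speak of
        return None
    rest = [n for n in adj[nbr] if n is not node]
    if len(rest) != 2:
        return None
    side = leafset(_subtree_from(adj, rest[0], nbr))
    other = full - side
    if (len(side), sorted(side)) <= (len(other), sorted(other)):
        return frozenset(side)
    return frozenset(other)
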