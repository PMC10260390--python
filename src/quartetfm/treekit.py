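"""Unrooted leaf-labeled trees: newick I/O, splits, nRF, induced quartets.

Trees are stored as plain adjacency maps over integer vertex ids, with
labels on leaves only.  Everything downstream works on unrooted
topologies, so rooted newick input is accepted and silently unrooted
(a degree-2 root is suppressed); branch lengths and support values are
accepted on input and dropped.

The induced topology of four leaves is decided with the four-point
condition on topological (unit-edge) path lengths: among the three pair
sums d(a,b)+d(c,d), d(a,c)+d(b,d), d(a,d)+d(b,c) the two largest are
equal, and a strictly smallest sum names the induced split; all three
equal means the restriction is a star (possible only with polytomies).
"""

from __future__ import annotations

from collections import deque
from typing import Dict, FrozenSet, Iterable, Optional, Tuple

import dendropy

from ._errors import ParseError, TreeError
from .quartet_store import QuartetKey, QuartetStore, canonicalize


class _Unresolved:
    def __repr__(self):
        return "UNRESOLVED"


#: Sentinel returned by induced_quartet_topology for star restrictions.
UNRESOLVED = _Unresolved()


class Tree:
    """Connected acyclic graph with uniquely labeled leaves."""

    __slots__ = ("_adj", "_label", "_node_of", "_next")

    def __init__(self):
        self._adj: Dict[int, set] = {}
        self._label: Dict[int, str] = {}
        self._node_of: Dict[str, int] = {}
        self._next = 0

    # -- construction -----------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        v = self._next
        self._next += 1
        self._adj[v] = set()
        if label is not None:
            if label in self._node_of:
                raise TreeError(f"duplicate leaf label {label!r}")
            self._label[v] = label
            self._node_of[label] = v
        return v

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def remove_node(self, v: int) -> None:
        for u in list(self._adj[v]):
            self.remove_edge(u, v)
        del self._adj[v]
        label = self._label.pop(v, None)
        if label is not None:
            del self._node_of[label]

    def subdivide_edge(self, u: int, v: int) -> int:
        """Replace edge (u, v) with u - w - v; return the new vertex w."""
        if v not in self._adj[u]:
            raise TreeError(f"no edge ({u}, {v})")
        self.remove_edge(u, v)
        w = self.new_node()
        self.add_edge(u, w)
        self.add_edge(w, v)
        return w

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t._adj = {v: set(nb) for v, nb in self._adj.items()}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._next = self._next
        return t

    # -- queries ----------------------------------------------------------

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(self._node_of)

    def node_of(self, label: str) -> int:
        try:
            return self._node_of[label]
        except KeyError:
            raise TreeError(f"no leaf labeled {label!r}") from None

    def label_of(self, v: int) -> Optional[str]:
        return self._label.get(v)

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def neighbors(self, v: int) -> set:
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def nodes(self):
        return self._adj.keys()

    def edges(self):
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def leaf_distances(self, label: str) -> Dict[str, int]:
        """Topological (edge-count) distance from one leaf to every leaf."""
        start = self.node_of(label)
        dist = {start: 0}
        out: Dict[str, int] = {}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            lbl = self._label.get(v)
            if lbl is not None:
                out[lbl] = dist[v]
            for u in self._adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        return out

    # -- normalization ----------------------------------------------------

    def suppress_degree_two(self) -> None:
        """Remove unlabeled degree-2 vertices (incl. a suppressed root)."""
        changed = True
        while changed:
            changed = False
            for v in list(self._adj):
                if v not in self._label and len(self._adj[v]) == 2:
                    a, b = self._adj[v]
                    self.remove_node(v)
                    self.add_edge(a, b)
                    changed = True

    def validate(self) -> None:
        """Check connectivity and acyclicity; raise TreeError otherwise."""
        if not self._adj:
            raise TreeError("empty tree")
        n_edges = sum(len(nb) for nb in self._adj.values()) // 2
        if n_edges != len(self._adj) - 1:
            raise TreeError("edge count does not match a tree")
        seen = set()
        queue = deque([next(iter(self._adj))])
        while queue:
            v = queue.popleft()
            if v in seen:
                continue
            seen.add(v)
            queue.extend(self._adj[v])
        if len(seen) != len(self._adj):
            raise TreeError("tree is disconnected")


# -- newick ---------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a newick string (rooted inputs are unrooted, lengths dropped)."""
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"bad newick: {exc}") from None
    tree = Tree()
    node_map = {}
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ParseError("newick leaf without a label")
            node_map[node] = tree.new_node(node.taxon.label)
        else:
            node_map[node] = tree.new_node()
        if node.parent_node is not None:
            tree.add_edge(node_map[node.parent_node], node_map[node])
    tree.suppress_degree_two()
    tree.validate()
    return tree


def read_newick_file(path) -> Tree:
    """Read the first newick tree in a file; '#'-prefixed lines are skipped."""
    with open(path, "r", encoding="utf-8") as fh:
        text = "".join(
            line for line in fh if not line.lstrip().startswith("#")
        )
    return parse_newick(text)


def read_newick_trees(path) -> list:
    """Read every ';'-terminated newick tree in a file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = "".join(
            line for line in fh if not line.lstrip().startswith("#")
        )
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    return [parse_newick(c + ";") for c in chunks]


def write_newick(tree: Tree) -> str:
    """Deterministic newick serialization (children ordered by min leaf)."""
    labels = sorted(tree.leaf_labels)
    if not labels:
        raise TreeError("cannot serialize a tree with no leaves")
    if len(labels) == 1:
        return f"{labels[0]};"
    if len(labels) == 2:
        return f"({labels[0]},{labels[1]});"
    root = next(iter(tree.neighbors(tree.node_of(labels[0]))))

    def subtree(v: int, parent: int) -> Tuple[str, str]:
        # returns (min leaf label in subtree, newick text)
        lbl = tree.label_of(v)
        if lbl is not None:
            return lbl, lbl
        parts = sorted(
            subtree(u, v) for u in tree.neighbors(v) if u != parent
        )
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    parts = sorted(subtree(u, root) for u in tree.neighbors(root))
    return "(" + ",".join(p[1] for p in parts) + ");"


# -- splits and distances -------------------------------------------------


def splits(tree: Tree) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial bipartitions, one per internal edge.

    Each split is stored as the side containing the lexicographically
    smallest leaf, as a frozenset of labels.
    """
    labels = tree.leaf_labels
    if len(labels) < 4:
        return frozenset()
    smallest = min(labels)
    root = next(iter(tree.nodes()))
    # iterative postorder accumulating leaf sets per (parent -> child) edge
    leafset: Dict[int, frozenset] = {}
    stack = [(root, None, False)]
    result = set()
    while stack:
        v, parent, processed = stack.pop()
        if not processed:
            stack.append((v, parent, True))
            for u in tree.neighbors(v):
                if u != parent:
                    stack.append((u, v, False))
        else:
            lbl = tree.label_of(v)
            if lbl is not None:
                leafset[v] = frozenset([lbl])
            else:
                acc = frozenset().union(
                    *(leafset[u] for u in tree.neighbors(v) if u != parent)
                )
                leafset[v] = acc
            if parent is not None:
                side = leafset[v]
                if 2 <= len(side) <= len(labels) - 2:
                    if smallest not in side:
                        side = labels - side
                    result.add(frozenset(side))
    return frozenset(result)


def nrf(t1: Tree, t2: Tree) -> float:
    """Normalized Robinson-Foulds distance: |S1 xor S2| / (2(n-3))."""
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        raise TreeError(
            "leaf sets differ: only in first = %s; only in second = %s"
            % (sorted(l1 - l2), sorted(l2 - l1))
        )
    n = len(l1)
    if n < 4:
        raise TreeError("nRF needs at least 4 shared leaves")
    s1, s2 = splits(t1), splits(t2)
    return len(s1 ^ s2) / (2 * (n - 3))


def _topology_from_distances(dists, a, b, c, d):
    s_ab = dists[a][b] + dists[c][d]
    s_ac = dists[a][c] + dists[b][d]
    s_ad = dists[a][d] + dists[b][c]
    lo = min(s_ab, s_ac, s_ad)
    if [s_ab, s_ac, s_ad].count(lo) > 1:
        return UNRESOLVED
    if lo == s_ab:
        return canonicalize(a, b, c, d)
    if lo == s_ac:
        return canonicalize(a, c, b, d)
    return canonicalize(a, d, b, c)


def induced_quartet_topology(tree: Tree, taxa: Iterable[str]):
    """Topology induced by restricting the tree to 4 leaves.

    Returns a :class:`QuartetKey`, or :data:`UNRESOLVED` when the
    restriction is a star (only possible with polytomies).
    """
    a, b, c, d = sorted(taxa)
    for t in (a, b, c, d):
        tree.node_of(t)  # raises TreeError on a missing leaf
    dists = {t: tree.leaf_distances(t) for t in (a, b, c)}
    dists[d] = {a: dists[a][d], b: dists[b][d], c: dists[c][d]}
    return _topology_from_distances(dists, a, b, c, d)


def quartet_support_score(tree: Tree, store: QuartetStore):
    """Classify every stored quartet against the tree's induced topologies.

    Returns ``(satisfied_weight, violated_weight, deferred_weight)``; the
    deferred bucket is nonzero only for keys whose restriction is a star
    (polytomies).
    """
    missing = [t for t in store.taxa if t not in tree.leaf_labels]
    if missing:
        raise TreeError(f"store taxa missing from tree: {missing}")
    dists = {t: tree.leaf_distances(t) for t in store.taxa}
    sat = viol = deferred = 0
    for key, w in store.entries.items():
        induced = _topology_from_distances(dists, *sorted(key.taxa))
        if induced is UNRESOLVED:
            deferred += w
        elif induced == key:
            sat += w
        else:
            viol += w
    return sat, viol, deferred
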