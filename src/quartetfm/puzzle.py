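"""Recursive divide-and-conquer amalgamation (short quartet puzzling).

Each level bipartitions the current taxon set by quartet support, then
routes every quartet into the child problems:

* 4-0 quartets (all four taxa on one side) pass unchanged to that side;
* 3-1 quartets have their lone ("deserted") taxon replaced by a fresh
  dummy taxon and go to the 3-taxon side;
* 2-2 quartets carry no information below this level and are consumed.

The dummy taxon joins both children's taxon sets as an ordinary taxon;
after the recursion returns, the two subtrees are merged by deleting the
dummy leaf from each and joining the attachment points with an edge.
Recursion bottoms out at three taxa (a star), two (an edge) or one.

Two variants are exposed.  ``fi`` (the default) merges dummy-modified
quartets that become topologically identical, summing their
frequencies, and re-sorts each child's quartets by weight at every
divide step.  ``f`` keeps duplicate records unmerged and sorts only at
the top level, so children inherit their parent's processing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from ._errors import InputError, QuartetFMError, TreeError
from .bipartition import (
    LEFT,
    RIGHT,
    PartitionState,
    _contrib,
    _status_of,
    initial_bipartition,
    mfm_bipartition,
    partition_score,
)
from .quartet_store import (
    DUMMY_PREFIX,
    QuartetStore,
    canonicalize,
    count_frequencies,
)
from .treekit import Tree

VARIANTS = ("fi", "f")


def _check_variant(variant: str) -> str:
    v = variant.lower()
    if v not in VARIANTS:
        raise InputError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return v


@dataclass
class RoutedSets:
    """Child quartet sets produced by one divide step."""

    q_left: QuartetStore
    q_right: QuartetStore
    dummy: str
    consumed_weight: float


def route_quartets(
    store: QuartetStore,
    state: PartitionState,
    dummy: str,
    variant: str = "fi",
) -> RoutedSets:
    """Split a store across a bipartition, dummy-substituting 3-1 quartets."""
    variant = _check_variant(variant)
    if dummy in store.index or dummy in state.side:
        raise InputError(f"dummy label {dummy!r} collides with an existing taxon")
    side = state.side
    left_records, right_records = [], []
    consumed = 0
    for key, w in store.order:
        n_left = sum(1 for t in key.taxa if side[t] == LEFT)
        if n_left == 4:
            left_records.append((key, w))
        elif n_left == 0:
            right_records.append((key, w))
        elif n_left == 3:
            deserted = next(t for t in key.taxa if side[t] == RIGHT)
            newkey = canonicalize(
                *(dummy if t == deserted else t for t in key.taxa)
            )
            left_records.append((newkey, w))
        elif n_left == 1:
            deserted = next(t for t in key.taxa if side[t] == LEFT)
            newkey = canonicalize(
                *(dummy if t == deserted else t for t in key.taxa)
            )
            right_records.append((newkey, w))
        else:  # 2-2, satisfied or violated: no 4-leaf topology survives
            consumed += w
    return RoutedSets(
        q_left=_child_store(left_records, variant),
        q_right=_child_store(right_records, variant),
        dummy=dummy,
        consumed_weight=consumed,
    )


def _child_store(records: list, variant: str) -> QuartetStore:
    entries: dict = {}
    for key, w in records:
        entries[key] = entries.get(key, 0) + w
    if variant == "fi":
        # merge identical dummy-modified quartets and re-sort by weight
        return QuartetStore(entries, m_records=len(records))
    return QuartetStore(entries, order=records, m_records=len(records))


def merge_trees(t_left: Tree, t_right: Tree, dummy: str) -> Tree:
    """Join two subtrees at their shared dummy leaf.

    The dummy leaf is deleted from both trees and the former attachment
    points are connected by a single edge; degree-2 relics are
    suppressed, so binary inputs yield a binary output.
    """
    for t in (t_left, t_right):
        if dummy not in t.leaf_labels:
            raise TreeError(f"dummy {dummy!r} missing from a subtree")
    overlap = (t_left.leaf_labels - {dummy}) & (t_right.leaf_labels - {dummy})
    if overlap:
        raise TreeError(f"subtrees share non-dummy leaves: {sorted(overlap)}")

    merged = Tree()
    attach = []
    for src in (t_left, t_right):
        mapping = {}
        for v in src.nodes():
            mapping[v] = merged.new_node(src.label_of(v))
        for u, v in src.edges():
            merged.add_edge(mapping[u], mapping[v])
        dummy_node = mapping[src.node_of(dummy)]
        if merged.degree(dummy_node) != 1:
            raise TreeError(f"dummy {dummy!r} is not a leaf")
        attach.append(next(iter(merged.neighbors(dummy_node))))
        merged.remove_node(dummy_node)
    merged.add_edge(attach[0], attach[1])
    merged.suppress_degree_two()
    merged.validate()
    return merged


def _leaf_tree(label: str) -> Tree:
    t = Tree()
    t.new_node(label)
    return t


def _edge_tree(a: str, b: str) -> Tree:
    t = Tree()
    t.add_edge(t.new_node(a), t.new_node(b))
    return t


def _star_tree(labels) -> Tree:
    t = Tree()
    center = t.new_node()
    for lbl in labels:
        t.add_edge(center, t.new_node(lbl))
    return t


def _rebalance_singleton_side(store: QuartetStore, state: PartitionState) -> None:
    """Guard against non-reducing recursion.

    An (n-1, 1) bipartition makes the big child (big side + dummy) as
    large as the parent, so the recursion would not shrink.  Move the
    maximum-gain taxon (ties: smallest label) from the big side over,
    yielding (n-2, 2) and two strictly smaller children.
    """
    left, right = state.left_taxa(), state.right_taxa()
    if min(len(left), len(right)) != 1 or len(left) + len(right) < 4:
        return
    big = left if len(left) > 1 else right
    side = state.side

    def move_gain(t: str):
        g = 0
        for key in store.relevant.get(t, ()):
            w = store.entries[key]
            g += _contrib(_status_of(key, side, flip=t), w) - _contrib(
                _status_of(key, side), w
            )
        return g

    mover = min(big, key=lambda t: (-move_gain(t), t))
    side[mover] = RIGHT if side[mover] == LEFT else LEFT
    partition_score(store, state)


def modified_sqp(
    store: QuartetStore,
    taxa: Iterable[str],
    variant: str = "fi",
    *,
    pass_cap: Optional[int] = None,
    observer=None,
) -> Tree:
    """Amalgamate a quartet store over ``taxa`` into an unrooted tree."""
    variant = _check_variant(variant)
    counter = [0]
    return _sqp(store, sorted(set(taxa)), variant, pass_cap, observer, counter, 0, "root")


def _sqp(store, taxa, variant, pass_cap, observer, counter, depth, path):
    n = len(taxa)
    if n == 0:
        raise InputError("empty taxon set")
    if n == 1:
        return _leaf_tree(taxa[0])
    if n == 2:
        return _edge_tree(*taxa)
    if n == 3:
        return _star_tree(taxa)

    try:
        state = initial_bipartition(store, taxa)
        state = mfm_bipartition(store, state, pass_cap=pass_cap, observer=observer)
        _rebalance_singleton_side(store, state)
    except QuartetFMError as exc:
        if hasattr(exc, "add_note"):
            exc.add_note(f"while bipartitioning at recursion path {path}")
        raise

    left, right = state.left_taxa(), state.right_taxa()
    dummy = f"{DUMMY_PREFIX}{depth}_{counter[0]}"
    counter[0] += 1
    routed = route_quartets(store, state, dummy, variant)
    if observer:
        observer(
            "route",
            {
                "depth": depth,
                "path": path,
                "parent_weight": store.total_weight,
                "left_weight": routed.q_left.total_weight,
                "right_weight": routed.q_right.total_weight,
                "consumed_weight": routed.consumed_weight,
                "left_size": len(left),
                "right_size": len(right),
            },
        )
    t_left = _sqp(
        routed.q_left, sorted(left + [dummy]), variant, pass_cap, observer,
        counter, depth + 1, path + "/L",
    )
    t_right = _sqp(
        routed.q_right, sorted(right + [dummy]), variant, pass_cap, observer,
        counter, depth + 1, path + "/R",
    )
    return merge_trees(t_left, t_right, dummy)


def run_pipeline(
    records,
    variant: str = "fi",
    *,
    pass_cap: Optional[int] = None,
    observer=None,
) -> Tree:
    """Frequency counting followed by the full recursive amalgamation."""
    store = count_frequencies(records)
    if store.n < 4:
        raise InputError(
            f"need at least 4 distinct taxa to build a tree, got {store.n}"
        )
    return modified_sqp(
        store, store.taxa, variant, pass_cap=pass_cap, observer=observer
    )
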