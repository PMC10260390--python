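"""Exhaustive maximum-quartet-consistency search on small taxon sets.

There are (2n-5)!! distinct unrooted binary topologies on n labeled
leaves; for n <= 8 that is at most 10,395, cheap enough to scan.  The
scan is the ground truth the heuristic pipeline is tested against: no
output of the pipeline may satisfy more weight than the exhaustive
optimum, and on complete consistent inputs it must match it.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

from ._errors import InputError
from .quartet_store import QuartetStore
from .treekit import Tree, quartet_support_score

#: Hard cap on the exhaustive search (10,395 topologies at n = 8).
MAX_TAXA = 8


def enumerate_unrooted_trees(taxa: Iterable[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once.

    Stepwise leaf insertion: the tree on the first three taxa is the
    star, and each further taxon is attached to every edge of every
    partial tree.  Deterministic order.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 3:
        raise InputError("tree enumeration needs at least 3 taxa")
    if len(taxa) > MAX_TAXA:
        raise InputError(
            f"refusing to enumerate trees on {len(taxa)} taxa "
            f"(cap is {MAX_TAXA}; (2n-5)!! grows too fast)"
        )

    base = Tree()
    center = base.new_node()
    for t in taxa[:3]:
        base.add_edge(center, base.new_node(t))

    def insert(tree: Tree, i: int) -> Iterator[Tree]:
        if i == len(taxa):
            yield tree
            return
        for u, v in tree.edges():
            t2 = tree.copy()
            w = t2.subdivide_edge(u, v)
            t2.add_edge(w, t2.new_node(taxa[i]))
            yield from insert(t2, i + 1)

    yield from insert(base, 3)


def exhaustive_best_tree(store: QuartetStore) -> Tuple[Tree, float]:
    """Tree maximizing the satisfied weight over the full enumeration.

    Ties go to the first tree in enumeration order.
    """
    best_tree = None
    best_sat = None
    for tree in enumerate_unrooted_trees(store.taxa):
        sat, _v, _d = quartet_support_score(tree, store)
        if best_sat is None or sat > best_sat:
            best_tree, best_sat = tree, sat
    if best_tree is None:
        raise InputError("store has no taxa to enumerate over")
    return best_tree, best_sat
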