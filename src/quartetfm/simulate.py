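"""Synthetic quartet data.

Two generators are provided, matching the two ways quartet sets arise in
practice:

* a *model-tree* sampler: a random binary species tree on ``n`` taxa and
  ``m = round(n**k)`` quartet records drawn over uniform 4-subsets, each
  agreeing with the model tree with probability ``c`` (the consistency
  level) and otherwise showing one of the two alternative splits,
  uniformly.  This emulates noisy quartet sets whose error rate is
  controlled exactly.
* a *gene-tree decomposition*: every 4-subset of each gene tree's leaf
  set contributes its induced topology, and frequencies across gene
  trees become weights.  Gene trees may be incomplete and non-binary;
  star restrictions are skipped.

All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from ._errors import InputError
from .quartet_store import QuartetStore, canonicalize, count_frequencies
from .treekit import UNRESOLVED, Tree, _topology_from_distances


@dataclass
class SimConfig:
    """Model-tree sampling parameters.

    ``n``: taxon count (>= 4).  ``k``: exponent giving the number of
    records m = round(n**k).  ``c``: consistency level in [0, 1], the
    probability that a record agrees with the model tree.  ``weighted``:
    return a deduplicated store with frequencies as weights instead of
    raw records.
    """

    n: int
    k: float
    c: float
    seed: int = 0
    weighted: bool = False

    def __post_init__(self):
        if self.n < 4:
            raise InputError(f"need n >= 4 taxa, got {self.n}")
        if not 0 <= self.c <= 1:
            raise InputError(f"consistency level must be in [0, 1], got {self.c}")
        if self.m < 1:
            raise InputError(f"m = round(n**k) = {self.m} must be >= 1")

    @property
    def m(self) -> int:
        return round(self.n ** self.k)


def random_binary_tree(n: int, seed: int = 0) -> Tree:
    """Random unrooted binary tree on leaves T1..Tn by uniform edge attachment."""
    if n < 3:
        raise InputError(f"need at least 3 taxa, got {n}")
    rng = random.Random(seed)
    tree = Tree()
    a = tree.new_node("T1")
    b = tree.new_node("T2")
    tree.add_edge(a, b)
    for i in range(3, n + 1):
        edges = tree.edges()
        u, v = edges[rng.randrange(len(edges))]
        w = tree.subdivide_edge(u, v)
        tree.add_edge(w, tree.new_node(f"T{i}"))
    return tree


def _alternatives(key):
    """The two resolved splits of the same four taxa other than ``key``."""
    a, b = key.left_pair
    c, d = key.right_pair
    return sorted((canonicalize(a, c, b, d), canonicalize(a, d, b, c)))


def sample_quartet_set(tree: Tree, config: SimConfig):
    """Draw ``config.m`` quartet records from a binary model tree.

    Returns raw records, or the weighted frequency store when
    ``config.weighted`` is set.
    """
    labels = sorted(tree.leaf_labels)
    if len(labels) < 4:
        raise InputError("model tree needs at least 4 leaves")
    rng = random.Random(config.seed)
    dists = {t: tree.leaf_distances(t) for t in labels}
    records = []
    for _ in range(config.m):
        four = sorted(rng.sample(labels, 4))
        true_key = _topology_from_distances(dists, *four)
        if true_key is UNRESOLVED:
            raise InputError("model tree must be binary (star restriction found)")
        if rng.random() < config.c:
            key = true_key
        else:
            key = _alternatives(true_key)[rng.randrange(2)]
        records.append((key.taxa, None))
    if config.weighted:
        return count_frequencies(records)
    return records


def agreement_fraction(records, tree: Tree) -> float:
    """Fraction of raw records whose topology matches the tree."""
    labels = sorted(tree.leaf_labels)
    dists = {t: tree.leaf_distances(t) for t in labels}
    hits = 0
    for taxa, _w in records:
        key = canonicalize(*taxa)
        if _topology_from_distances(dists, *sorted(taxa)) == key:
            hits += 1
    return hits / len(records)


def decompose_gene_trees(gene_trees, weighted: bool = False):
    """Enumerate every induced quartet of every gene tree.

    Unresolved (star) 4-subsets are skipped; with ``weighted`` the
    records are merged across trees into a frequency-weighted store.
    """
    records = []
    for tree in gene_trees:
        labels = sorted(tree.leaf_labels)
        if len(labels) < 4:
            continue
        dists = {t: tree.leaf_distances(t) for t in labels}
        for four in itertools.combinations(labels, 4):
            top = _topology_from_distances(dists, *four)
            if top is UNRESOLVED:
                continue
            records.append((top.taxa, None))
    if weighted:
        return count_frequencies(records)
    return records


def perturb_gene_tree(tree: Tree, nni_moves: int, seed: int = 0) -> Tree:
    """Apply random nearest-neighbor interchanges to a binary tree."""
    if nni_moves < 0:
        raise InputError("nni_moves must be >= 0")
    rng = random.Random(seed)
    t = tree.copy()
    for _ in range(nni_moves):
        internal = [
            (u, v) for u, v in t.edges() if not t.is_leaf(u) and not t.is_leaf(v)
        ]
        if not internal:
            break
        u, v = internal[rng.randrange(len(internal))]
        nu = sorted(t.neighbors(u) - {v})
        nv = sorted(t.neighbors(v) - {u})
        b_node = nu[rng.randrange(len(nu))]
        c_node = nv[rng.randrange(len(nv))]
        t.remove_edge(u, b_node)
        t.remove_edge(v, c_node)
        t.add_edge(u, c_node)
        t.add_edge(v, b_node)
    return t
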