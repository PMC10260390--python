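"""Shared helpers: random stores, complete consistent quartet sets, oracles."""

import random

import pytest

from quartetfm.quartet_store import count_frequencies
from quartetfm.simulate import decompose_gene_trees, random_binary_tree


def make_random_records(n_taxa, m, rng, weighted=False, max_weight=5):
    """Raw records over random 4-subsets with random topology."""
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    records = []
    for _ in range(m):
        four = rng.sample(taxa, 4)
        rng.shuffle(four)
        w = float(rng.randint(1, max_weight)) if weighted else None
        records.append((tuple(four), w))
    return records


def make_random_store(n_taxa, m, rng, weighted=False, max_weight=5):
    return count_frequencies(make_random_records(n_taxa, m, rng, weighted, max_weight))


def complete_consistent_records(tree):
    """All induced quartets of a binary tree (one record per 4-subset)."""
    return decompose_gene_trees([tree])


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def tree10():
    return random_binary_tree(10, seed=5)


# -- independent oracles ----------------------------------------------------


def status_oracle(key, side):
    """Set-logic reimplementation of quartet status (independent of the
    arithmetic coding used in the package)."""
    left = {t for t in key.taxa if side[t] == "L"}
    if len(left) != 2:
        return "deferred"
    if left == set(key.left_pair) or left == set(key.right_pair):
        return "satisfied"
    return "violated"


def score_oracle(store, side):
    """From-scratch satisfied-minus-violated recount."""
    s = v = 0
    for key, w in store.entries.items():
        st = status_oracle(key, side)
        if st == "satisfied":
            s += w
        elif st == "violated":
            v += w
    return s - v


def induced_topology_oracle(tree, four):
    """Induced quartet split via path-disjointness (independent of the
    four-point distance logic in treekit)."""

    def path(x, y):
        # BFS parent tracing between two leaves
        from collections import deque

        start, goal = tree.node_of(x), tree.node_of(y)
        parent = {start: None}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if u == goal:
                break
            for w in tree.neighbors(u):
                if w not in parent:
                    parent[w] = u
                    queue.append(w)
        nodes = set()
        u = goal
        while u is not None:
            nodes.add(u)
            u = parent[u]
        return nodes

    from quartetfm.quartet_store import canonicalize

    a, b, c, d = sorted(four)
    for x, y, z, w in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
        if not (path(x, y) & path(z, w)):
            return canonicalize(x, y, z, w)
    return None  # star
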