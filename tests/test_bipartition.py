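"""Quartet status, partition scoring, greedy seeding and the FM refinement."""

import itertools
import random

import pytest

from quartetfm.bipartition import (
    DEFERRED,
    LEFT,
    RIGHT,
    SATISFIED,
    VIOLATED,
    MoveLog,
    PartitionState,
    best_prefix,
    initial_bipartition,
    mfm_bipartition,
    partition_score,
    quartet_status,
)
from quartetfm._errors import InputError, PassCapError, StateError
from quartetfm.quartet_store import canonicalize, count_frequencies
from quartetfm.simulate import decompose_gene_trees
from quartetfm.treekit import parse_newick

from conftest import make_random_store, score_oracle, status_oracle


def state_of(left, right):
    side = {t: LEFT for t in left}
    side.update({t: RIGHT for t in right})
    return PartitionState(side=side)


KEY = canonicalize("a", "b", "c", "d")


class TestQuartetStatus:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ("ab", "cd", SATISFIED),
            ("cd", "ab", SATISFIED),
            ("ac", "bd", VIOLATED),
            ("ad", "bc", VIOLATED),
            ("abc", "d", DEFERRED),
            ("a", "bcd", DEFERRED),
            ("abcd", "", DEFERRED),
        ],
    )
    def test_examples(self, left, right, expected):
        assert quartet_status(KEY, state_of(left, right)) == expected

    def test_unassigned_taxon_errors(self):
        with pytest.raises(StateError):
            quartet_status(KEY, state_of("ab", "c"))

    def test_agrees_with_set_oracle(self, rng):
        taxa = "abcdefgh"
        for _ in range(200):
            four = rng.sample(taxa, 4)
            key = canonicalize(*four)
            side = {t: rng.choice([LEFT, RIGHT]) for t in taxa}
            assert quartet_status(key, PartitionState(side=side)) == status_oracle(
                key, side
            )


class TestPartitionScore:
    def test_simple_arithmetic(self):
        store = count_frequencies(
            [(("a", "b", "c", "d"), 2.0), (("a", "c", "b", "d"), 1.0)]
        )
        state = state_of("ab", "cd")
        assert partition_score(store, state) == 1
        assert (state.s, state.v, state.d) == (2, 1, 0)

    def test_all_deferred_scores_zero(self):
        store = count_frequencies([(("a", "b", "c", "d"), None)])
        state = state_of("abcd", "e")
        assert partition_score(store, state) == 0
        assert state.d == store.total_weight

    def test_matches_recount_oracle(self, rng):
        for _ in range(25):
            store = make_random_store(8, 60, rng, weighted=True)
            side = {t: rng.choice([LEFT, RIGHT]) for t in store.taxa}
            state = PartitionState(side=side)
            assert partition_score(store, state) == score_oracle(store, side)
            assert state.s + state.v + state.d == pytest.approx(store.total_weight)


class TestInitialBipartition:
    def test_first_quartet_seeds_sides(self):
        store = count_frequencies([(("a", "b", "c", "d"), None)])
        state = initial_bipartition(store, "abcd")
        assert set(state.left_taxa()) == {"a", "b"}
        assert set(state.right_taxa()) == {"c", "d"}

    def test_satisfy_if_possible_placement(self):
        # ab|cd (weight 2) processed first, then ab|ce: e must go RIGHT
        store = count_frequencies(
            [(("a", "b", "c", "d"), 2.0), (("a", "b", "c", "e"), 1.0)]
        )
        state = initial_bipartition(store, "abcde")
        assert state.side["e"] == RIGHT

    def test_assigned_taxa_never_move(self):
        # second quartet conflicts with the seeded sides -> no change
        store = count_frequencies(
            [(("a", "b", "c", "d"), 2.0), (("a", "c", "b", "d"), 1.0)]
        )
        state = initial_bipartition(store, "abcd")
        assert set(state.left_taxa()) == {"a", "b"}

    def test_leftover_taxa_alternate(self):
        state = initial_bipartition(count_frequencies([]), "abcde")
        assert state.size_left == 3 and state.size_right == 2

    def test_both_sides_nonempty(self, rng):
        for _ in range(20):
            store = make_random_store(7, 15, rng)
            state = initial_bipartition(store, store.taxa)
            assert state.size_left >= 1 and state.size_right >= 1
            assert set(state.side) == set(store.taxa)

    def test_empty_taxon_set_errors(self):
        with pytest.raises(InputError):
            initial_bipartition(count_frequencies([]), [])


class TestBestPrefix:
    @pytest.mark.parametrize(
        "gains,expected",
        [
            ([3, -1, 2], (3, 4)),
            ([2, 0], (1, 2)),
            ([-1], (1, -1)),
            ([], (0, 0)),
        ],
    )
    def test_examples(self, gains, expected):
        log = MoveLog()
        for i, g in enumerate(gains):
            log.append(f"t{i}", g)
        assert best_prefix(log) == expected


def exhaustive_bipartition_optimum(store):
    """Scan every two-sided assignment with both sides non-empty."""
    taxa = list(store.taxa)
    best = None
    for bits in itertools.product([LEFT, RIGHT], repeat=len(taxa)):
        if len(set(bits)) < 2:
            continue
        side = dict(zip(taxa, bits))
        sc = score_oracle(store, side)
        best = sc if best is None else max(best, sc)
    return best


class TestMfmBipartition:
    def test_five_taxon_complete_set_reaches_optimum(self):
        tree = parse_newick("(((a,b),c),(d,e));")
        store = count_frequencies(decompose_gene_trees([tree]))
        # oracle: best possible score over all bipartitions of 5 taxa
        optimum = exhaustive_bipartition_optimum(store)
        assert optimum == 3  # 3 satisfiable, 2 necessarily deferred
        state = state_of("ad", "bce")
        out = mfm_bipartition(store, state)
        assert out.score == optimum

    def test_already_optimal_is_a_fixed_point(self):
        tree = parse_newick("(((a,b),c),(d,e));")
        store = count_frequencies(decompose_gene_trees([tree]))
        state = state_of("ab", "cde")
        assert partition_score(store, state) == 3
        out = mfm_bipartition(store, state)
        assert out.score == 3 and out.passes == 0
        assert out.side == state.side

    def test_empty_side_rejected(self):
        store = count_frequencies([(("a", "b", "c", "d"), None)])
        with pytest.raises(StateError):
            mfm_bipartition(store, state_of("abcd", ""))

    def test_pass_cap_carries_best_state(self, rng):
        store = make_random_store(8, 40, rng)
        state = initial_bipartition(store, store.taxa)
        with pytest.raises(PassCapError) as exc:
            mfm_bipartition(store, state, pass_cap=0)
        assert isinstance(exc.value.state, PartitionState)

    def test_contracts_on_random_instances(self, rng):
        """Monotone score, exact bookkeeping, exact gain cache, FM discipline."""
        for _ in range(30):
            store = make_random_store(8, 40, rng)
            state = initial_bipartition(store, store.taxa)
            score_in = partition_score(store, state)
            events = []
            out = mfm_bipartition(
                store, state, observer=lambda e, p: events.append((e, p))
            )
            assert out.score >= score_in
            moved_per_pass = {}
            for event, payload in events:
                if event != "move":
                    continue
                side = payload["side"]
                # bookkeeping: s + v + d conserves the total weight
                assert payload["s"] + payload["v"] + payload["d"] == pytest.approx(
                    store.total_weight
                )
                # recount oracle agrees with incremental s - v
                assert payload["s"] - payload["v"] == score_oracle(store, side)
                # gain cache equals from-scratch gains for all FREE taxa
                for u, g in payload["free_gains"].items():
                    flipped = dict(side)
                    flipped[u] = RIGHT if side[u] == LEFT else LEFT
                    assert g == score_oracle(store, flipped) - score_oracle(
                        store, side
                    ), f"stale gain for {u}"
                moved_per_pass.setdefault(payload["pass"], []).append(
                    payload["taxon"]
                )
            # FM discipline: no taxon moves twice within a pass
            for moved in moved_per_pass.values():
                assert len(moved) == len(set(moved))
            # integer weights: committed passes bounded by quartet count
            assert out.passes <= store.m_records
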