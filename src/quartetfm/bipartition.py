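"""Taxon bipartitioning driven by quartet support.

Given a weighted quartet store and a two-sided assignment of taxa, each
quartet is *satisfied* (its two pairs occupy opposite sides), *violated*
(a 2-2 split that crosses the pairs) or *deferred* (at least three of
its taxa share a side).  The partition score is

    score = satisfied_weight - violated_weight

and deferred quartets contribute zero (they are postponed to deeper
recursion levels).  The initial bipartition seeds sides greedily from
the quartets in descending weight order; an FM-style
(Fiduccia-Mattheyses) refinement then repeatedly moves the maximum-gain
free taxon, locks it, logs the move, and at the end of the pass rolls
back to the prefix of moves with maximum cumulative gain (MCGain).
Passes repeat while MCGain stays positive.  Because the score is an
integer for integer weights and bounded by the total weight, the number
of committed passes is at most the number of quartets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from ._errors import InputError, PassCapError, StateError
from .quartet_store import QuartetKey, QuartetStore

LEFT = "L"
RIGHT = "R"
FREE = "free"
LOCKED = "locked"

SATISFIED = "satisfied"
VIOLATED = "violated"
DEFERRED = "deferred"

#: Minimum MCGain for committing a pass when weights are not integral
#: (with integer weights any positive gain is >= 1 and the cap below is
#: never the binding constraint).
REAL_GAIN_EPS = 1e-9


@dataclass
class PartitionState:
    """Two-sided taxon assignment with cached scores.

    ``side`` maps every taxon to LEFT or RIGHT; ``lock`` is the FM
    free/locked status (all FREE outside a pass).  ``s``, ``v``, ``d``
    are the satisfied/violated/deferred weights last computed by
    :func:`partition_score`.
    """

    side: Dict[str, str]
    lock: Dict[str, str] = field(default_factory=dict)
    s: float = 0
    v: float = 0
    d: float = 0
    passes: int = 0

    def __post_init__(self):
        if not self.lock:
            self.lock = {t: FREE for t in self.side}

    @property
    def size_left(self) -> int:
        return sum(1 for s in self.side.values() if s == LEFT)

    @property
    def size_right(self) -> int:
        return sum(1 for s in self.side.values() if s == RIGHT)

    @property
    def score(self):
        return self.s - self.v

    def left_taxa(self) -> List[str]:
        return sorted(t for t, s in self.side.items() if s == LEFT)

    def right_taxa(self) -> List[str]:
        return sorted(t for t, s in self.side.items() if s == RIGHT)


class MoveLog:
    """Ordered (taxon, gain) record of one FM pass, with prefix queries."""

    __slots__ = ("entries",)

    def __init__(self):
        self.entries: List[Tuple[str, float]] = []

    def append(self, taxon: str, gain) -> None:
        self.entries.append((taxon, gain))

    def __len__(self):
        return len(self.entries)


def best_prefix(log: MoveLog) -> Tuple[int, float]:
    """Smallest 1-based prefix length maximizing cumulative gain.

    Returns ``(0, 0)`` for an empty log.  Note the maximum over
    non-empty prefixes may be negative; the caller decides whether to
    commit.
    """
    if not log.entries:
        return 0, 0
    best_c, best_gain, running = 1, None, 0
    for i, (_, g) in enumerate(log.entries, start=1):
        running += g
        if best_gain is None or running > best_gain:
            best_c, best_gain = i, running
    return best_c, best_gain


def _status_of(key: QuartetKey, side: Dict[str, str], flip: Optional[str] = None) -> str:
    a, b = key.left_pair
    c, d = key.right_pair
    la = (side[a] == LEFT) != (flip == a)
    lb = (side[b] == LEFT) != (flip == b)
    lc = (side[c] == LEFT) != (flip == c)
    ld = (side[d] == LEFT) != (flip == d)
    left_pair_l = la + lb
    total_l = left_pair_l + lc + ld
    if total_l != 2:
        return DEFERRED
    if left_pair_l == 1:
        return VIOLATED
    return SATISFIED


def quartet_status(key: QuartetKey, state: PartitionState) -> str:
    """SATISFIED / VIOLATED / DEFERRED for one key under a full assignment."""
    for t in key.taxa:
        if state.side.get(t) not in (LEFT, RIGHT):
            raise StateError(f"taxon {t!r} is unassigned")
    return _status_of(key, state.side)


def partition_score(store: QuartetStore, state: PartitionState):
    """Satisfied minus violated weight; refreshes the s/v/d caches."""
    side = state.side
    for t in store.taxa:
        if side.get(t) not in (LEFT, RIGHT):
            raise StateError(f"taxon {t!r} is unassigned")
    s = v = d = 0
    for key, w in store.entries.items():
        st = _status_of(key, side)
        if st == SATISFIED:
            s += w
        elif st == VIOLATED:
            v += w
        else:
            d += w
    state.s, state.v, state.d = s, v, d
    return s - v


def initial_bipartition(store: QuartetStore, taxa: Iterable[str]) -> PartitionState:
    """Greedy frequency-ordered seeding of the two sides.

    Quartets are processed in descending weight (ties by canonical key).
    The first quartet seeds left_pair -> LEFT, right_pair -> RIGHT.  For
    later quartets, already-placed taxa never move; unassigned taxa are
    placed so the quartet becomes satisfied if some orientation permits
    it, otherwise they go to the currently smaller side (ties LEFT).
    Taxa untouched by any quartet are finally distributed alternately
    starting with the smaller side, so both sides end non-empty for
    |taxa| >= 2.
    """
    taxa = sorted(set(taxa))
    if not taxa:
        raise InputError("cannot bipartition an empty taxon set")
    if len(taxa) < 2:
        raise InputError("bipartitioning needs at least 2 taxa")
    taxa_set = set(taxa)
    stray = [t for t in store.taxa if t not in taxa_set]
    if stray:
        raise InputError(f"store mentions taxa outside the input set: {stray}")

    side: Dict[str, str] = {}
    sizes = {LEFT: 0, RIGHT: 0}

    def place(t: str, s: str) -> None:
        side[t] = s
        sizes[s] += 1

    for key, _w in store.order:
        placed = False
        for lp, rp in ((key.left_pair, key.right_pair), (key.right_pair, key.left_pair)):
            if all(side.get(t, LEFT) == LEFT for t in lp) and all(
                side.get(t, RIGHT) == RIGHT for t in rp
            ):
                for t in lp:
                    if t not in side:
                        place(t, LEFT)
                for t in rp:
                    if t not in side:
                        place(t, RIGHT)
                placed = True
                break
        if not placed:
            for t in key.taxa:
                if t not in side:
                    place(t, LEFT if sizes[LEFT] <= sizes[RIGHT] else RIGHT)

    for t in taxa:
        if t not in side:
            place(t, LEFT if sizes[LEFT] <= sizes[RIGHT] else RIGHT)

    state = PartitionState(side=side)
    partition_score(store, state)
    return state


def _contrib(status: str, w) -> float:
    if status == SATISFIED:
        return w
    if status == VIOLATED:
        return -w
    return 0


Observer = Callable[[str, dict], None]


def mfm_bipartition(
    store: QuartetStore,
    state: PartitionState,
    *,
    pass_cap: Optional[int] = None,
    observer: Optional[Observer] = None,
) -> PartitionState:
    """FM refinement of a bipartition; never returns a worse score.

    Every outer pass resets all taxa to FREE, recomputes statuses and
    gains, then greedily moves-and-locks the maximum-gain eligible taxon
    (ties: lexicographically smallest label) until none remains, with
    gain updates restricted to the moved taxon's relevant quartets.  A
    taxon whose side has a single member is ineligible, which keeps both
    sides non-empty.  If the best move prefix has positive cumulative
    gain the pass is rolled back to that prefix and committed; otherwise
    all moves are undone and the pre-pass state is returned.

    ``observer`` (optional) receives ("pass_start"|"move"|"pass_end",
    payload) events; payloads carry copies, so observing cannot corrupt
    the run.  Exceeding ``pass_cap`` outer passes raises
    :class:`PassCapError` carrying the best state reached.
    """
    side = dict(state.side)
    for t in store.taxa:
        if side.get(t) not in (LEFT, RIGHT):
            raise StateError(f"taxon {t!r} is unassigned")
    taxa = sorted(side)
    sizes = {
        LEFT: sum(1 for s in side.values() if s == LEFT),
        RIGHT: sum(1 for s in side.values() if s == RIGHT),
    }
    if sizes[LEFT] == 0 or sizes[RIGHT] == 0:
        raise StateError("both sides must be non-empty at MFM entry")

    entries = store.entries
    threshold = 0 if store.integer_weights else REAL_GAIN_EPS
    if pass_cap is None:
        pass_cap = max(1000, math.ceil(store.total_weight))

    committed_passes = 0
    outer = 0
    while True:
        outer += 1
        if outer > pass_cap:
            final = PartitionState(side=side, passes=committed_passes)
            partition_score(store, final)
            raise PassCapError(
                f"MFM exceeded the pass cap of {pass_cap}", state=final
            )

        # pass setup: statuses, s/v/d and gains from scratch
        status: Dict[QuartetKey, str] = {}
        s = v = d = 0
        gain = {t: 0 for t in taxa}
        for key, w in entries.items():
            st = _status_of(key, side)
            status[key] = st
            base = _contrib(st, w)
            if st == SATISFIED:
                s += w
            elif st == VIOLATED:
                v += w
            else:
                d += w
            for t in key.taxa:
                gain[t] += _contrib(_status_of(key, side, flip=t), w) - base

        pass_start_side = dict(side)
        free = set(taxa)
        log = MoveLog()
        if observer:
            observer(
                "pass_start",
                {"pass": outer, "score": s - v, "s": s, "v": v, "d": d},
            )

        while True:
            eligible = [t for t in free if sizes[side[t]] > 1]
            if not eligible:
                break
            t_m = min(eligible, key=lambda t: (-gain[t], t))
            g_m = gain[t_m]
            affected = store.relevant.get(t_m, ())
            old_delta: Dict[Tuple[QuartetKey, str], float] = {}
            for key in affected:
                w = entries[key]
                st = status[key]
                if st == SATISFIED:
                    s -= w
                elif st == VIOLATED:
                    v -= w
                else:
                    d -= w
                base = _contrib(st, w)
                for u in key.taxa:
                    if u != t_m and u in free:
                        old_delta[(key, u)] = (
                            _contrib(_status_of(key, side, flip=u), w) - base
                        )
            frm = side[t_m]
            to = RIGHT if frm == LEFT else LEFT
            side[t_m] = to
            sizes[frm] -= 1
            sizes[to] += 1
            for key in affected:
                w = entries[key]
                st = _status_of(key, side)
                status[key] = st
                if st == SATISFIED:
                    s += w
                elif st == VIOLATED:
                    v += w
                else:
                    d += w
                base = _contrib(st, w)
                for u in key.taxa:
                    if u != t_m and u in free:
                        new_delta = _contrib(_status_of(key, side, flip=u), w) - base
                        gain[u] += new_delta - old_delta[(key, u)]
            free.discard(t_m)
            log.append(t_m, g_m)
            if observer:
                observer(
                    "move",
                    {
                        "pass": outer,
                        "taxon": t_m,
                        "gain": g_m,
                        "s": s,
                        "v": v,
                        "d": d,
                        "side": dict(side),
                        "free_gains": {u: gain[u] for u in free},
                    },
                )

        c, mcgain = best_prefix(log)
        if observer:
            observer(
                "pass_end",
                {"pass": outer, "c": c, "mcgain": mcgain, "moves": len(log)},
            )
        if mcgain > threshold:
            committed_passes += 1
            side = dict(pass_start_side)
            for t, _g in log.entries[:c]:
                side[t] = RIGHT if side[t] == LEFT else LEFT
            sizes = {
                LEFT: sum(1 for x in side.values() if x == LEFT),
                RIGHT: sum(1 for x in side.values() if x == RIGHT),
            }
        else:
            side = pass_start_side
            break

    final = PartitionState(side=side, passes=committed_passes)
    partition_score(store, final)
    return final
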