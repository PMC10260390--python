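"""Canonical quartet keys, frequency counting, and the quartet file dialect.

A *quartet* is an unrooted 4-leaf topology, written ``a,b|c,d`` for the
split pairing ``{a,b}`` against ``{c,d}``.  The same split can be written
8 ways (swapping within a pair, swapping the pairs); :func:`canonicalize`
collapses them to one hashable key, so counting the frequency of each
distinct topology is a single hash-map pass over the input records.

The on-disk dialect is the one used by the quartet max-cut family of
tools: one quartet per line, ``t1,t2|t3,t4`` optionally followed by
whitespace and a positive decimal weight; blank lines and ``#`` comments
are ignored.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Tuple

from ._errors import InputError, InvalidQuartetError, ParseError

#: Prefix reserved for the dummy taxa introduced by the divide-and-conquer
#: recursion; user-supplied labels must not collide with them.
DUMMY_PREFIX = "__D"

_LABEL_RE = re.compile(r"[A-Za-z0-9_.\-]+\Z")

RawRecord = Tuple[Tuple[str, str, str, str], Optional[float]]


class QuartetKey(NamedTuple):
    """Canonical representation of one unrooted 4-leaf topology.

    ``left_pair`` and ``right_pair`` are each sorted, and the pair with the
    lexicographically smaller first element comes first, so equal splits
    compare equal and distinct splits of the same four taxa do not.
    """

    left_pair: Tuple[str, str]
    right_pair: Tuple[str, str]

    @property
    def taxa(self) -> Tuple[str, str, str, str]:
        return self.left_pair + self.right_pair

    def __str__(self) -> str:
        return "{},{}|{},{}".format(*self.left_pair, *self.right_pair)


def validate_label(label: str) -> str:
    if not label or not _LABEL_RE.match(label):
        raise InputError(
            f"invalid taxon label {label!r}: labels are non-empty strings "
            "over [A-Za-z0-9_.-]"
        )
    if label.startswith(DUMMY_PREFIX):
        raise InputError(
            f"taxon label {label!r} uses the reserved prefix {DUMMY_PREFIX!r}"
        )
    return label


def canonicalize(a: str, b: str, c: str, d: str) -> QuartetKey:
    """Return the unique canonical key for the split ``{a,b} | {c,d}``.

    Raises :class:`InvalidQuartetError` if the four taxa are not distinct.
    """
    if len({a, b, c, d}) != 4:
        raise InvalidQuartetError(
            f"quartet {a},{b}|{c},{d} does not have four distinct taxa"
        )
    left = (a, b) if a < b else (b, a)
    right = (c, d) if c < d else (d, c)
    if right < left:
        left, right = right, left
    return QuartetKey(left, right)


class QuartetStore:
    """Deduplicated weighted quartet multiset with O(1) lookups.

    Attributes
    ----------
    entries : dict[QuartetKey, number]
        One row per distinct topology, weight summed over input records.
    order : list[(QuartetKey, weight)]
        The processing order used by initial bipartitioning.  By default
        it is the entries sorted by descending weight (ties by key); the
        recursion's F variant instead threads through an inherited
        per-record order that may contain duplicate keys.
    taxa : tuple[str, ...]
        Sorted distinct taxa; ``index[t]`` gives t's stable integer index.
    relevant : dict[str, list[QuartetKey]]
        For each taxon, the distinct keys containing it (a quartet is a
        relevant quartet for all four of its taxa).
    """

    __slots__ = (
        "entries",
        "order",
        "taxa",
        "index",
        "relevant",
        "n",
        "m_records",
        "total_weight",
        "integer_weights",
    )

    def __init__(
        self,
        entries: dict,
        *,
        order: Optional[list] = None,
        m_records: Optional[int] = None,
    ):
        self.entries = entries
        if order is None:
            order = sorted(entries.items(), key=lambda kw: (-kw[1], kw[0]))
        self.order = order
        taxa = set()
        relevant: dict = {}
        for key in entries:
            for t in key.taxa:
                taxa.add(t)
                relevant.setdefault(t, []).append(key)
        self.taxa = tuple(sorted(taxa))
        self.index = {t: i for i, t in enumerate(self.taxa)}
        self.relevant = relevant
        self.n = len(self.taxa)
        self.m_records = len(order) if m_records is None else m_records
        self.total_weight = sum(entries.values())
        self.integer_weights = all(
            isinstance(w, int) or (isinstance(w, float) and w.is_integer())
            for w in entries.values()
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[QuartetKey]:
        return iter(self.entries)

    def weight(self, key: QuartetKey):
        return self.entries.get(key, 0)


def count_frequencies(records: Iterable[RawRecord]) -> QuartetStore:
    """Canonicalize, deduplicate and count a stream of raw quartet records.

    Each record is ``((a, b, c, d), weight)`` for the split ``ab|cd``;
    ``weight`` is ``None`` for unweighted records (which count 1 each).
    Weights stay exact integers whenever every input weight is integral.
    """
    entries: dict = {}
    n_records = 0
    all_int = True
    for lineno, (taxa, weight) in enumerate(records, start=1):
        if len(taxa) != 4:
            raise ParseError(f"expected 4 taxa, got {len(taxa)}", line=lineno)
        for t in taxa:
            validate_label(t)
        key = canonicalize(*taxa)
        if weight is None:
            weight = 1
        else:
            if weight <= 0:
                raise InputError(
                    f"record {lineno}: weight must be positive, got {weight}"
                )
            if isinstance(weight, float) and weight.is_integer():
                weight = int(weight)
            if not isinstance(weight, int):
                all_int = False
        entries[key] = entries.get(key, 0) + weight
        n_records += 1
    if all_int:
        entries = {k: int(w) for k, w in entries.items()}
    return QuartetStore(entries, m_records=n_records)


def _parse_line(line: str, lineno: int) -> Optional[RawRecord]:
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    parts = stripped.split()
    if len(parts) > 2:
        raise ParseError(f"unknown trailing tokens {parts[2:]!r}", line=lineno)
    halves = parts[0].split("|")
    if len(halves) != 2:
        raise ParseError(f"expected one '|' in {parts[0]!r}", line=lineno)
    pairs = []
    for half in halves:
        labels = half.split(",")
        if len(labels) != 2:
            raise ParseError(
                f"expected two comma-separated taxa in {half!r}", line=lineno
            )
        pairs.append(labels)
    (a, b), (c, d) = pairs
    for t in (a, b, c, d):
        try:
            validate_label(t)
        except InputError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    weight: Optional[float] = None
    if len(parts) == 2:
        try:
            weight = float(parts[1])
        except ValueError:
            raise ParseError(f"bad weight {parts[1]!r}", line=lineno) from None
        if not math.isfinite(weight) or weight <= 0:
            raise ParseError(f"weight must be positive, got {parts[1]}", line=lineno)
    return (a, b, c, d), weight


def read_quartet_file(path) -> list:
    """Read a quartet file into raw records.

    Weighted and unweighted lines may not be mixed in one file: a bare
    line in a weighted file would be ambiguous between "weight 1" and
    "unweighted".
    """
    records = []
    saw_weighted = saw_unweighted = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = _parse_line(line, lineno)
            if rec is None:
                continue
            if rec[1] is None:
                saw_unweighted = True
            else:
                saw_weighted = True
            if saw_weighted and saw_unweighted:
                raise ParseError(
                    "file mixes weighted and unweighted quartet lines",
                    line=lineno,
                )
            records.append(rec)
    return records


def _format_weight(w) -> str:
    if isinstance(w, int) or (isinstance(w, float) and w.is_integer()):
        return str(int(w))
    return repr(float(w))


def write_quartet_file(store: QuartetStore, path, weighted: bool = True) -> None:
    """Write a store in the quartet dialect.

    ``weighted=True`` emits one ``key weight`` line per entry.
    ``weighted=False`` emits each key ``weight`` times (requires integer
    weights), so re-reading and re-counting reproduces the entries exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key, w in store.order:
            if weighted:
                fh.write(f"{key} {_format_weight(w)}\n")
            else:
                if not (isinstance(w, int) or float(w).is_integer()):
                    raise InputError(
                        "unweighted output requires integer weights; "
                        f"{key} has weight {w}"
                    )
                for _ in range(int(w)):
                    fh.write(f"{key}\n")


def records_to_store(records: Sequence[RawRecord]) -> QuartetStore:
    """Alias for :func:`count_frequencies` over an in-memory sequence."""
    return count_frequencies(records)
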