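"""Pairwise same/different rating bookkeeping.

Each rater sees every unordered pair of events and rates it "same" or
"different".  A rater's implied identity partition is the set of connected
components of the graph whose edges are that rater's "same" verdicts;
"different" verdicts that land inside one component are reported as
contradictions, never auto-resolved.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "SAME",
    "DIFFERENT",
    "PairRatingSet",
    "RaterPartition",
    "RatingsError",
    "enumerate_pairs",
    "partition_from_ratings",
    "count_individuals",
    "singleton_adjust",
    "IndividualCounts",
    "SingletonAdjustment",
]

SAME = "same"
DIFFERENT = "different"
_VERDICTS = {SAME, DIFFERENT}

Pair = tuple[str, str]


class RatingsError(ValueError):
    """Malformed or incomplete rating data."""


def canonical_pair(a: str, b: str) -> Pair:
    if a == b:
        raise RatingsError(f"self-pairing not allowed: {a}")
    return (a, b) if a < b else (b, a)


def enumerate_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs (i < j) in lexicographic order; n(n-1)/2 of them."""
    if n < 1:
        raise RatingsError("need at least one event")
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class PairRatingSet:
    """Complete verdict grid: every (unordered event pair, rater) cell present."""

    event_ids: list[str]
    raters: list[str]
    verdicts: dict[tuple[Pair, str], str]

    def __post_init__(self) -> None:
        if len(set(self.event_ids)) != len(self.event_ids):
            raise RatingsError("duplicate event ids")
        if len(set(self.raters)) != len(self.raters):
            raise RatingsError("duplicate rater ids")
        normalized: dict[tuple[Pair, str], str] = {}
        for ((a, b), rater), verdict in self.verdicts.items():
            if verdict not in _VERDICTS:
                raise RatingsError(f"verdict {verdict!r} for pair ({a}, {b}) is not same/different")
            normalized[(canonical_pair(a, b), rater)] = verdict
        self.verdicts = normalized
        missing = [
            (pair, rater)
            for pair in self.pairs()
            for rater in self.raters
            if (pair, rater) not in self.verdicts
        ]
        if missing:
            raise RatingsError(f"missing verdict cells: {missing[:10]}" + ("..." if len(missing) > 10 else ""))

    def pairs(self) -> list[Pair]:
        ids = sorted(self.event_ids)
        return [(ids[i], ids[j]) for i, j in enumerate_pairs(len(ids))]

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def votes(self, pair: Pair) -> list[str]:
        return [self.verdicts[(pair, r)] for r in self.raters]


@dataclass
class RaterPartition:
    rater: str
    components: list[frozenset[str]]
    contradictions: set[Pair] = field(default_factory=set)

    @property
    def n_individuals(self) -> int:
        return len(self.components)


def partition_from_ratings(ratings: PairRatingSet, rater: str) -> RaterPartition:
    """Identity partition implied by one rater's "same" verdicts.

    Components are connected components of the "same" graph; pairs rated
    "different" falling inside one component are flagged as contradictions.
    """
    if rater not in ratings.raters:
        raise RatingsError(f"unknown rater: {rater}")
    g = nx.Graph()
    g.add_nodes_from(ratings.event_ids)
    for pair in ratings.pairs():
        if ratings.verdicts[(pair, rater)] == SAME:
            g.add_edge(*pair)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)[0]
    )
    member_of = {node: i for i, comp in enumerate(components) for node in comp}
    contradictions = {
        pair
        for pair in ratings.pairs()
        if ratings.verdicts[(pair, rater)] == DIFFERENT and member_of[pair[0]] == member_of[pair[1]]
    }
    return RaterPartition(rater=rater, components=components, contradictions=contradictions)


@dataclass(frozen=True)
class IndividualCounts:
    per_rater: Mapping[str, int]
    mean: float
    min: int
    max: int
    sd: float


def count_individuals(ratings: PairRatingSet) -> IndividualCounts:
    """Per-rater implied individual counts with mean/min/max and sample SD."""
    per_rater = {
        rater: partition_from_ratings(ratings, rater).n_individuals for rater in ratings.raters
    }
    counts = list(per_rater.values())
    return IndividualCounts(
        per_rater=per_rater,
        mean=statistics.fmean(counts),
        min=min(counts),
        max=max(counts),
        sd=statistics.stdev(counts) if len(counts) > 1 else float("nan"),
    )


@dataclass(frozen=True)
class SingletonAdjustment:
    adjusted: PairRatingSet
    n_flipped: int
    singleton_fraction: float
    n_disagreeing_pairs: int


def singleton_adjust(ratings: PairRatingSet) -> SingletonAdjustment:
    """Flip lone dissents to the consensus of the other raters.

    For every pair where exactly one rater differs from the unanimous verdict
    of all the others, that verdict is flipped.  ``singleton_fraction`` is the
    share of disagreeing pairs that were such R-1 vs 1 splits.
    """
    if ratings.n_raters < 3:
        raise RatingsError("singleton adjustment needs at least 3 raters")
    new_verdicts = dict(ratings.verdicts)
    n_flipped = 0
    n_disagree = 0
    n_singleton = 0
    for pair in ratings.pairs():
        votes = ratings.votes(pair)
        n_same = votes.count(SAME)
        if 0 < n_same < len(votes):
            n_disagree += 1
            if n_same == 1 or n_same == len(votes) - 1:
                n_singleton += 1
                majority = SAME if n_same > 1 else DIFFERENT
                for rater in ratings.raters:
                    if new_verdicts[(pair, rater)] != majority:
                        new_verdicts[(pair, rater)] = majority
                        n_flipped += 1
    adjusted = PairRatingSet(
        event_ids=list(ratings.event_ids), raters=list(ratings.raters), verdicts=new_verdicts
    )
    fraction = n_singleton / n_disagree if n_disagree else 0.0
    return SingletonAdjustment(
        adjusted=adjusted,
        n_flipped=n_flipped,
        singleton_fraction=fraction,
        n_disagreeing_pairs=n_disagree,
    )


def ratings_from_long(
    records: Iterable[tuple[str, str, str, str]],
) -> PairRatingSet:
    """Build a PairRatingSet from (event_a, event_b, rater, verdict) rows.

    Rejects duplicate cells; completeness is enforced by the constructor.
    """
    verdicts: dict[tuple[Pair, str], str] = {}
    events: set[str] = set()
    raters: list[str] = []
    for event_a, event_b, rater, verdict in records:
        pair = canonical_pair(event_a, event_b)
        key = (pair, rater)
        if key in verdicts:
            raise RatingsError(f"duplicate verdict for pair {pair}, rater {rater}")
        verdicts[key] = verdict
        events.update(pair)
        if rater not in raters:
            raters.append(rater)
    return PairRatingSet(event_ids=sorted(events), raters=raters, verdicts=verdicts)
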