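"""Aggregate individual rank ballots into a group ranking per behaviour.

The aggregation operates on the pairwise-majority graph: for every ordered
pair of barriers ``(a, b)``, count the ballots ranking ``a`` strictly
better than ``b`` in the canonical direction (more influential / less
difficult).  Three Condorcet-aware voting rules turn that graph into a
tie-permitting group ranking:

``schulze`` (default)
    Beatpath method: the strength of the strongest path from ``a`` to
    ``b`` through the majority graph decides ``a`` vs ``b``.  The induced
    strict relation is transitive, Condorcet-consistent and monotone.
``copeland``
    Pairwise wins minus losses; simple but can rank a Condorcet winner
    tied with another item only in contrived profiles (it is still
    uniquely top whenever it exists, since it wins every pairing).
``kemeny``
    Exact Kemeny-Young consensus: the total order minimising the summed
    pairwise disagreement with the ballots, found by exact dynamic
    programming over item subsets.

All rules emit the same :class:`GroupRanking` type.  Ties share a
top-anchored competition rank: ``rank(i) = n_items - #{j better than i}``,
so the best indifference class always holds rank ``n_items`` and a
Condorcet winner is uniquely top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalogue import SurveyDataset, ValidationError
from .summaries import canonical_ranks

__all__ = [
    "AGGREGATION_METHODS",
    "PairwiseMatrix",
    "GroupRanking",
    "pairwise_matrix",
    "aggregate",
    "aggregate_kemeny_exact",
    "kemeny_score",
    "schulze_relation",
]

AGGREGATION_METHODS = ("schulze", "copeland", "kemeny")

#: exact Kemeny search is O(2^n * n^2); beyond this, use the default method
MAX_KEMENY_ITEMS = 12


@dataclass(frozen=True)
class PairwiseMatrix:
    """Pairwise-majority counts for one behaviour x attribute.

    ``prefer[i, j]`` = number of ballots ranking ``items[i]`` strictly
    better than ``items[j]`` (canonical direction).  Within-ballot ties are
    impossible (ballots are total orders), so ``prefer[i, j] +
    prefer[j, i]`` equals the number of ballots covering the pair.
    """

    behaviour_id: str
    attribute: str
    items: tuple[str, ...]
    prefer: np.ndarray
    n_ballots: int

    def __post_init__(self) -> None:
        n = len(self.items)
        if self.prefer.shape != (n, n):
            raise ValidationError("prefer matrix shape mismatch")
        if np.diagonal(self.prefer).any():
            raise ValidationError("prefer diagonal must be zero")

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class GroupRanking:
    """Tie-permitting consensus ranks, canonical direction (higher =
    more influential / less difficult)."""

    behaviour_id: str
    attribute: str
    rank: Mapping[str, int]
    method: str

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.rank)

    def top_barriers(self) -> tuple[str, ...]:
        """Barrier(s) holding the maximum (best) rank."""
        best = max(self.rank.values())
        return tuple(b for b, r in self.rank.items() if r == best)


def pairwise_matrix(
    dataset: SurveyDataset, behaviour_id: str, attribute: str
) -> PairwiseMatrix:
    """Build the pairwise-majority matrix from the available ballots."""
    behaviour = dataset.catalogue.behaviour(behaviour_id)
    ballots = dataset.ballots_for(behaviour_id, attribute)
    if not ballots:
        raise ValidationError(
            f"no ballots for behaviour {behaviour_id!r}, attribute "
            f"{attribute!r}"
        )
    items = behaviour.barrier_ids
    index = {b: i for i, b in enumerate(items)}
    n = len(items)
    prefer = np.zeros((n, n), dtype=int)
    for ballot in ballots:
        canon = canonical_ranks(behaviour, ballot)
        ranks = np.empty(n, dtype=int)
        for b, r in canon.items():
            ranks[index[b]] = r
        # higher canonical rank = better to target
        prefer += (ranks[:, None] > ranks[None, :]).astype(int)
    return PairwiseMatrix(
        behaviour_id=behaviour_id,
        attribute=attribute,
        items=items,
        prefer=prefer,
        n_ballots=len(ballots),
    )


def _beats_to_ranks(items: Sequence[str], beats: np.ndarray) -> dict[str, int]:
    """Top-anchored competition ranks from a transitive strict relation.

    ``beats[i, j]`` true means item i is strictly better than item j.
    ``rank(i) = n - #{j : beats[j, i]}``; ties (mutually unbeaten items
    with the same dominator count) share a value and the best class holds
    rank ``n``.
    """
    n = len(items)
    better_counts = beats.sum(axis=0)  # how many items beat each item
    return {item: int(n - c) for item, c in zip(items, better_counts)}


def _schulze_beats(prefer: np.ndarray) -> np.ndarray:
    """Strict beatpath relation: p[a,b] > p[b,a] on strongest-path strengths."""
    n = prefer.shape[0]
    strength = np.where(prefer > prefer.T, prefer, 0).astype(float)
    np.fill_diagonal(strength, 0.0)
    for i in range(n):  # Floyd-Warshall widest-path relaxation
        strength = np.maximum(
            strength, np.minimum.outer(strength[:, i], strength[i, :])
        )
        np.fill_diagonal(strength, 0.0)
    return strength > strength.T


def schulze_relation(matrix: PairwiseMatrix) -> set[tuple[str, str]]:
    """The strict beatpath relation as a set of ``(winner, loser)`` pairs.

    Pairs absent in both directions are incomparable (tied beatpath
    strengths); the integer ranks in :func:`aggregate` linearise such ties
    by dominator count, so two incomparable items may still receive
    different ranks.
    """
    beats = _schulze_beats(matrix.prefer)
    return {
        (matrix.items[i], matrix.items[j])
        for i in range(matrix.n_items)
        for j in range(matrix.n_items)
        if beats[i, j]
    }


def _copeland_beats(prefer: np.ndarray) -> np.ndarray:
    wins = (prefer > prefer.T).sum(axis=1)
    losses = (prefer < prefer.T).sum(axis=1)
    score = wins - losses
    return score[:, None] > score[None, :]


def aggregate(matrix: PairwiseMatrix, method: str = "schulze") -> GroupRanking:
    """Turn a pairwise-majority matrix into a group ranking.

    Unanimous ballots reproduce the shared ballot exactly; a Condorcet
    winner (beats every other item pairwise) is uniquely top under
    ``schulze`` and ``kemeny``.
    """
    if method not in AGGREGATION_METHODS:
        raise ValidationError(
            f"unknown aggregation method {method!r} "
            f"(expected one of {AGGREGATION_METHODS})"
        )
    if method == "kemeny":
        return aggregate_kemeny_exact(matrix)
    if method == "schulze":
        beats = _schulze_beats(matrix.prefer)
    else:
        beats = _copeland_beats(matrix.prefer)
    return GroupRanking(
        behaviour_id=matrix.behaviour_id,
        attribute=matrix.attribute,
        rank=_beats_to_ranks(matrix.items, beats),
        method=method,
    )


def kemeny_score(matrix: PairwiseMatrix, order: Sequence[str]) -> int:
    """Total pairwise disagreement of a best-to-worst order with the ballots."""
    index = {b: i for i, b in enumerate(matrix.items)}
    if sorted(order) != sorted(matrix.items):
        raise ValidationError("order must be a permutation of the items")
    score = 0
    for pos, a in enumerate(order):
        for b in order[pos + 1:]:
            score += int(matrix.prefer[index[b], index[a]])
    return score


def aggregate_kemeny_exact(matrix: PairwiseMatrix) -> GroupRanking:
    """Exact Kemeny-Young consensus by dynamic programming over subsets.

    Among co-optimal total orders, the lexicographically smallest by
    barrier id is returned (deterministic tie rule).  The result is a
    strict order: best item gets rank ``n_items``, worst gets 1.
    """
    n = matrix.n_items
    if n > MAX_KEMENY_ITEMS:
        raise ValidationError(
            f"exact Kemeny search supports at most {MAX_KEMENY_ITEMS} items "
            f"(got {n}); use the default 'schulze' method"
        )
    # sort item indices by id so greedy reconstruction is lexicographic
    order_ix = sorted(range(n), key=lambda i: matrix.items[i])
    prefer = matrix.prefer
    # cost of placing item x at the top of the suffix formed by subset S:
    # every ballot preferring some other y in S over x disagrees.
    full = (1 << n) - 1
    INF = float("inf")
    best = [INF] * (1 << n)
    best[0] = 0.0
    members: list[list[int]] = [[] for _ in range(1 << n)]
    for s in range(1 << n):
        members[s] = [i for i in order_ix if s >> i & 1]
    for s in range(1, 1 << n):
        acc = INF
        for x in members[s]:
            rest = s & ~(1 << x)
            cost = best[rest] + sum(prefer[y, x] for y in members[rest])
            if cost < acc:
                acc = cost
        best[s] = acc
    # reconstruct best-to-worst greedily, lexicographic among minimisers
    order: list[str] = []
    s = full
    while s:
        for x in members[s]:
            rest = s & ~(1 << x)
            if best[rest] + sum(prefer[y, x] for y in members[rest]) == best[s]:
                order.append(matrix.items[x])
                s = rest
                break
    rank = {b: n - pos for pos, b in enumerate(order)}
    return GroupRanking(
        behaviour_id=matrix.behaviour_id,
        attribute=matrix.attribute,
        rank=rank,
        method="kemeny",
    )


def aggregate_dataset(
    dataset: SurveyDataset, method: str = "schulze"
) -> list[GroupRanking]:
    """Group rankings for every behaviour x attribute with ballots."""
    out = []
    for behaviour in dataset.catalogue:
        for attribute in ("influence", "difficulty"):
            if not dataset.ballots_for(behaviour.behaviour_id, attribute):
                continue
            matrix = pairwise_matrix(dataset, behaviour.behaviour_id, attribute)
            out.append(aggregate(matrix, method=method))
    return out
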