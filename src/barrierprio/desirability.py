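"""Classify barriers by how desirable they are to target.

Each barrier is a point in the (influence, difficulty) plane of canonical
group ranks — higher influence rank = more influential, higher difficulty
rank = less difficult, so "up and to the right" is unambiguously better.
Classification uses weak Pareto dominance and three rules:

most desirable
    weakly dominates every other barrier (at least as good on both axes
    against each, strictly better somewhere, or exactly tied with it);
desirable
    not dominated by any barrier (the Pareto frontier minus the case
    above);
least desirable
    weakly dominated by at least one barrier.

Weak (not strict) dominance is required: a barrier that matches another
on one axis and loses on the other is worse to target, and barriers tied
on both axes share a label.  A barrier exactly tied with a most-desirable
barrier shares the most-desirable label (an extrapolation — such a tie
cannot be decided by dominance and never occurs in the bundled survey).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .aggregation import GroupRanking
from .catalogue import ValidationError

__all__ = [
    "LABELS",
    "AttributePoint",
    "DesirabilityResult",
    "dominates",
    "classify",
    "points_from_rankings",
    "classify_dataset",
    "desirability_table",
]

MOST = "most_desirable"
DESIRABLE = "desirable"
LEAST = "least_desirable"
LABELS = (MOST, DESIRABLE, LEAST)


@dataclass(frozen=True)
class AttributePoint:
    """One barrier's two canonical group ranks."""

    barrier_id: str
    influence_rank: int
    difficulty_rank: int


def dominates(a: AttributePoint, b: AttributePoint) -> bool:
    """Weak Pareto dominance: ``a`` at least as good as ``b`` on both
    axes and strictly better on at least one.  Exact ties dominate in
    neither direction."""
    return (
        a.influence_rank >= b.influence_rank
        and a.difficulty_rank >= b.difficulty_rank
        and (
            a.influence_rank > b.influence_rank
            or a.difficulty_rank > b.difficulty_rank
        )
    )


@dataclass(frozen=True)
class DesirabilityResult:
    """Labels for every barrier of one behaviour plus the dominance
    relation that produced them."""

    behaviour_id: str
    labels: Mapping[str, str]
    dominance_edges: tuple[tuple[str, str], ...]

    def barriers_with(self, label: str) -> tuple[str, ...]:
        return tuple(b for b, lab in self.labels.items() if lab == label)


def classify(
    points: Sequence[AttributePoint], behaviour_id: str = ""
) -> DesirabilityResult:
    """Label each point most/desirable/least desirable to target."""
    if len(points) < 2:
        raise ValidationError("classification needs at least 2 barriers")
    ids = [p.barrier_id for p in points]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate barrier_id among points: {ids}")

    edges = tuple(
        (a.barrier_id, b.barrier_id)
        for a in points
        for b in points
        if dominates(a, b)
    )
    dominated = {b for _, b in edges}

    def ties(a: AttributePoint, b: AttributePoint) -> bool:
        return (
            a.influence_rank == b.influence_rank
            and a.difficulty_rank == b.difficulty_rank
        )

    labels: dict[str, str] = {}
    for p in points:
        if p.barrier_id in dominated:
            labels[p.barrier_id] = LEAST
        elif all(dominates(p, q) or ties(p, q) for q in points if q is not p):
            labels[p.barrier_id] = MOST
        else:
            labels[p.barrier_id] = DESIRABLE
    return DesirabilityResult(
        behaviour_id=behaviour_id, labels=labels, dominance_edges=edges
    )


def points_from_rankings(
    influence: GroupRanking, difficulty: GroupRanking
) -> list[AttributePoint]:
    """Join the two attribute rankings of one behaviour into points."""
    if influence.behaviour_id != difficulty.behaviour_id:
        raise ValidationError(
            "influence and difficulty rankings are for different behaviours"
        )
    if set(influence.rank) != set(difficulty.rank):
        raise ValidationError(
            f"behaviour {influence.behaviour_id!r}: attribute rankings "
            f"cover different barrier sets"
        )
    return [
        AttributePoint(b, influence.rank[b], difficulty.rank[b])
        for b in influence.rank
    ]


def classify_dataset(
    group_rankings: Iterable[GroupRanking],
) -> list[DesirabilityResult]:
    """One :class:`DesirabilityResult` per behaviour.

    Every behaviour must supply exactly one ranking per attribute.
    """
    by_behaviour: dict[str, dict[str, GroupRanking]] = {}
    for ranking in group_rankings:
        slot = by_behaviour.setdefault(ranking.behaviour_id, {})
        if ranking.attribute in slot:
            raise ValidationError(
                f"behaviour {ranking.behaviour_id!r}: duplicate "
                f"{ranking.attribute!r} ranking"
            )
        slot[ranking.attribute] = ranking
    results = []
    for behaviour_id, slot in by_behaviour.items():
        missing = {"influence", "difficulty"} - set(slot)
        if missing:
            raise ValidationError(
                f"behaviour {behaviour_id!r} is missing "
                f"{sorted(missing)} ranking(s)"
            )
        points = points_from_rankings(slot["influence"], slot["difficulty"])
        results.append(classify(points, behaviour_id=behaviour_id))
    return results


def desirability_table(
    results: Iterable[DesirabilityResult],
    group_rankings: Iterable[GroupRanking],
) -> pd.DataFrame:
    """Tidy export: behaviour, barrier, both ranks, desirability label."""
    ranks: dict[tuple[str, str], dict[str, int]] = {}
    for g in group_rankings:
        for barrier_id, r in g.rank.items():
            ranks.setdefault((g.behaviour_id, barrier_id), {})[g.attribute] = r
    rows = []
    for res in results:
        for barrier_id, label in res.labels.items():
            r = ranks[(res.behaviour_id, barrier_id)]
            rows.append(
                {
                    "behaviour_id": res.behaviour_id,
                    "barrier_id": barrier_id,
                    "influence_rank": r["influence"],
                    "difficulty_rank": r["difficulty"],
                    "desirability": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["behaviour_id", "barrier_id", "influence_rank",
                 "difficulty_rank", "desirability"],
    )
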