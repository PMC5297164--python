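"""Per-barrier median ranks with interquartile ranges.

Raw ballots are elicited with higher rank = *lower* influence and higher
rank = *least* difficult.  All reporting uses the canonical direction,
where higher always means "better to target": higher = more influential,
higher = less difficult.  The influence scale is therefore reversed
(``n + 1 - raw``) and the difficulty scale kept as elicited.

Quartiles use linear interpolation between closest ranks (the common
default percentile rule); the convention is fixed and documented because
half-integer medians arise from even panel sizes regardless of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import (
    ATTRIBUTES,
    Ballot,
    Behaviour,
    SurveyDataset,
    ValidationError,
)

__all__ = [
    "RankSummary",
    "canonicalize_rank",
    "canonical_ranks",
    "summarize_ranks",
    "summaries_table",
]

#: canonical-direction captions, per attribute
CANONICAL_DIRECTION = {
    "influence": "higher = more influential",
    "difficulty": "higher = less difficult",
}


def canonicalize_rank(raw_rank: int, n_barriers: int, attribute: str) -> int:
    """Convert a raw elicited rank to the canonical direction.

    Influence is reversed (``n_barriers + 1 - raw_rank``) so that higher
    means more influential; difficulty is already canonical (higher raw
    rank = least difficult) and passes through unchanged.
    """
    if attribute not in ATTRIBUTES:
        raise ValidationError(f"unknown attribute {attribute!r}")
    if not 1 <= raw_rank <= n_barriers:
        raise ValidationError(
            f"rank {raw_rank} out of range 1..{n_barriers}"
        )
    if attribute == "influence":
        return n_barriers + 1 - raw_rank
    return raw_rank


def canonical_ranks(behaviour: Behaviour, ballot: Ballot) -> dict[str, int]:
    """A ballot's ranking converted to the canonical direction."""
    n = behaviour.n_barriers
    return {
        barrier_id: canonicalize_rank(raw, n, ballot.attribute)
        for barrier_id, raw in ballot.ranking.items()
    }


@dataclass(frozen=True)
class RankSummary:
    """Median and IQR of one barrier's canonical ranks over the panel."""

    barrier_id: str
    attribute: str
    median: float
    iqr_low: float
    iqr_high: float
    n_ballots: int
    direction: str

    def __post_init__(self) -> None:
        if not self.iqr_low <= self.median <= self.iqr_high:
            raise ValidationError(
                f"{self.barrier_id}: IQR ({self.iqr_low}, {self.iqr_high}) "
                f"does not bracket median {self.median}"
            )


def summarize_ranks(
    dataset: SurveyDataset, behaviour_id: str, attribute: str
) -> list[RankSummary]:
    """Median (IQR) canonical rank per barrier for one behaviour/attribute.

    Returned in descending order of median (ties broken by barrier id), so
    the most influential / least difficult barrier comes first.  Raises if
    no ballots exist for the behaviour/attribute.
    """
    behaviour = dataset.catalogue.behaviour(behaviour_id)
    ballots = dataset.ballots_for(behaviour_id, attribute)
    if not ballots:
        raise ValidationError(
            f"no ballots for behaviour {behaviour_id!r}, attribute "
            f"{attribute!r}"
        )
    per_barrier: dict[str, list[int]] = {b: [] for b in behaviour.barrier_ids}
    for ballot in ballots:
        for barrier_id, rank in canonical_ranks(behaviour, ballot).items():
            per_barrier[barrier_id].append(rank)
    out = []
    for barrier_id, ranks in per_barrier.items():
        arr = np.asarray(ranks, dtype=float)
        q25, q50, q75 = np.percentile(arr, [25, 50, 75], method="linear")
        out.append(
            RankSummary(
                barrier_id=barrier_id,
                attribute=attribute,
                median=float(q50),
                iqr_low=float(q25),
                iqr_high=float(q75),
                n_ballots=len(ranks),
                direction=CANONICAL_DIRECTION[attribute],
            )
        )
    out.sort(key=lambda s: (-s.median, s.barrier_id))
    return out


def summaries_table(dataset: SurveyDataset) -> pd.DataFrame:
    """All behaviours x attributes as one tidy table.

    Columns: behaviour_id, barrier_id, attribute, median, iqr_low,
    iqr_high, n_ballots.  Behaviours with no ballots for an attribute are
    omitted (respondents may skip eligible behaviours).
    """
    rows = []
    for behaviour in dataset.catalogue:
        for attribute in ATTRIBUTES:
            if not dataset.ballots_for(behaviour.behaviour_id, attribute):
                continue
            for s in summarize_ranks(dataset, behaviour.behaviour_id, attribute):
                rows.append(
                    {
                        "behaviour_id": behaviour.behaviour_id,
                        "barrier_id": s.barrier_id,
                        "attribute": s.attribute,
                        "median": s.median,
                        "iqr_low": s.iqr_low,
                        "iqr_high": s.iqr_high,
                        "n_ballots": s.n_ballots,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["behaviour_id", "barrier_id", "attribute", "median",
                 "iqr_low", "iqr_high", "n_ballots"],
    )
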