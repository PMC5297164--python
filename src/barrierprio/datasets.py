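"""Bundled reference data from the stroke-care barrier survey.

The package ships the published artefacts of a 17-member multidisciplinary
expert panel (emergency and stroke doctors and nurses, speech pathologists,
bed managers) that ranked barriers to nine evidence-based elements of acute
stroke care in emergency departments:

* the behaviour/barrier catalogue (9 behaviours, 53 barriers, with each
  behaviour's eligible professional groups),
* the panel's demographics,
* per-barrier median (IQR) individual ranks — reference values only: the
  raw ballots behind them were never published, so they cannot be
  recomputed here,
* the published group rankings with their desirability labels.  The group
  ranks were produced by the original panel's own consensus tool, whose
  exact tie-breaking internals are unpublished; they are shipped as data,
  and :func:`barrierprio.desirability.classify_dataset` reproduces their
  desirability labels exactly.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .aggregation import GroupRanking
from .catalogue import (
    BehaviourCatalogue,
    Respondent,
    load_catalogue,
    load_respondents,
)

__all__ = [
    "study_catalogue",
    "study_respondents",
    "study_group_ranks",
    "study_desirability_labels",
    "study_rank_summaries",
]


def _data_path(name: str):
    return files("barrierprio").joinpath("data", name)


def study_catalogue() -> BehaviourCatalogue:
    """The nine targeted behaviours and their 53 barriers."""
    return load_catalogue(str(_data_path("catalogue.csv")))


def study_respondents() -> tuple[Respondent, ...]:
    """The 17-member panel with demographics.

    Only the published marginal counts (sex, age band, role, years of
    experience, qualification) are authoritative; the assignment of
    categories to individual panel members is synthetic, chosen to
    reproduce those marginals exactly.
    """
    return load_respondents(str(_data_path("respondents.csv")))


def load_group_ranks(path) -> list[GroupRanking]:
    """Read a precomputed group-rank table.

    Columns: ``behaviour_id, barrier_id, influence_rank, difficulty_rank``
    (a ``desirability`` column, if present, is ignored here — see
    :func:`study_desirability_labels`).  Ranks are canonical: higher =
    more influential / less difficult.
    """
    df = pd.read_csv(path, dtype={"behaviour_id": str, "barrier_id": str})
    rankings = []
    for behaviour_id, rows in df.groupby("behaviour_id", sort=False):
        for attribute in ("influence", "difficulty"):
            rankings.append(
                GroupRanking(
                    behaviour_id=str(behaviour_id),
                    attribute=attribute,
                    rank={
                        r.barrier_id: int(getattr(r, f"{attribute}_rank"))
                        for r in rows.itertuples()
                    },
                    method="precomputed",
                )
            )
    return rankings


def study_group_ranks() -> list[GroupRanking]:
    """The published group rankings (both attributes, all 9 behaviours)."""
    return load_group_ranks(str(_data_path("group_ranks.csv")))


def study_desirability_labels() -> dict[str, str]:
    """The published desirability label per barrier id."""
    df = pd.read_csv(str(_data_path("group_ranks.csv")), dtype=str)
    return dict(zip(df["barrier_id"], df["desirability"]))


def study_rank_summaries() -> pd.DataFrame:
    """Published per-barrier median (IQR) individual ranks, canonical
    direction (reference values; the underlying ballots are unpublished)."""
    return pd.read_csv(
        str(_data_path("individual_summaries.csv")),
        dtype={"behaviour_id": str, "barrier_id": str},
    )
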