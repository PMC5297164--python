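"""Data model and I/O for barrier-prioritisation surveys.

A survey elicits, from each eligible respondent, a complete rank-ordering of
the barriers to a targeted clinical behaviour on two attributes:

* ``influence`` — how strongly the barrier prevents the behaviour
  (elicited so that a *higher* raw rank means *lower* influence), and
* ``difficulty`` — how hard the barrier would be to overcome
  (elicited so that a *higher* raw rank means *least* difficult).

Ballots are stored exactly as elicited (``direction="raw"``); conversion to
the canonical "higher = better to target" direction happens downstream (see
:mod:`barrierprio.summaries`) so the raw data stays auditable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "PROFESSIONAL_GROUPS",
    "ATTRIBUTES",
    "ParseError",
    "ValidationError",
    "Barrier",
    "Behaviour",
    "BehaviourCatalogue",
    "Respondent",
    "Ballot",
    "SurveyDataset",
    "load_catalogue",
    "load_respondents",
    "load_survey",
    "write_survey",
    "demographic_percentages",
]

#: Professional-group codes eligible to hold ballots: emergency nurses,
#: emergency doctors, stroke nurses, stroke doctors, speech pathologists and
#: bed managers.  "Academic" is a secondary role tag carried in respondent
#: demographics, never a ballot-eligibility group.
PROFESSIONAL_GROUPS = ("EN", "EDr", "SN", "SDr", "SP", "BM")

ATTRIBUTES = ("influence", "difficulty")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A survey or catalogue file could not be parsed (names the line)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a survey invariant."""


@dataclass(frozen=True)
class Barrier:
    """One barrier to one targeted behaviour, e.g. ``8.2``."""

    barrier_id: str
    behaviour_id: str
    description: str = ""


@dataclass(frozen=True)
class Behaviour:
    """A targeted clinical behaviour and its ordered barrier list.

    The ranking scale for both attributes is exactly ``1..n_barriers``.
    """

    behaviour_id: str
    name: str
    barriers: tuple[Barrier, ...]
    eligible_groups: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.barriers) < 2:
            raise ValidationError(
                f"behaviour {self.behaviour_id!r} needs >= 2 barriers, "
                f"got {len(self.barriers)}"
            )
        unknown = set(self.eligible_groups) - set(PROFESSIONAL_GROUPS)
        if unknown:
            raise ValidationError(
                f"behaviour {self.behaviour_id!r}: unknown professional "
                f"group codes {sorted(unknown)}"
            )
        for b in self.barriers:
            if b.behaviour_id != self.behaviour_id:
                raise ValidationError(
                    f"barrier {b.barrier_id!r} belongs to behaviour "
                    f"{b.behaviour_id!r}, not {self.behaviour_id!r}"
                )

    @property
    def n_barriers(self) -> int:
        return len(self.barriers)

    @property
    def barrier_ids(self) -> tuple[str, ...]:
        return tuple(b.barrier_id for b in self.barriers)


@dataclass(frozen=True)
class BehaviourCatalogue:
    """All targeted behaviours of one survey, with unique barrier ids."""

    behaviours: tuple[Behaviour, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for beh in self.behaviours:
            for b in beh.barriers:
                if b.barrier_id in seen:
                    raise ValidationError(
                        f"duplicate barrier_id {b.barrier_id!r} in catalogue"
                    )
                seen.add(b.barrier_id)
        ids = [b.behaviour_id for b in self.behaviours]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate behaviour_id in catalogue")

    def __iter__(self):
        return iter(self.behaviours)

    def __len__(self) -> int:
        return len(self.behaviours)

    @property
    def behaviour_ids(self) -> tuple[str, ...]:
        return tuple(b.behaviour_id for b in self.behaviours)

    @property
    def n_barriers_total(self) -> int:
        return sum(b.n_barriers for b in self.behaviours)

    def behaviour(self, behaviour_id: str) -> Behaviour:
        for b in self.behaviours:
            if b.behaviour_id == behaviour_id:
                return b
        raise KeyError(f"unknown behaviour_id {behaviour_id!r}")


@dataclass(frozen=True)
class Respondent:
    """One expert-panel member; ``group`` controls ballot eligibility."""

    respondent_id: str
    group: str
    demographics: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in PROFESSIONAL_GROUPS:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: unknown group "
                f"{self.group!r} (expected one of {PROFESSIONAL_GROUPS})"
            )


@dataclass(frozen=True)
class Ballot:
    """One respondent's complete, tie-free ranking of one behaviour's
    barriers on one attribute, in the raw elicitation direction.

    Raw direction: higher rank = lower influence; higher rank = least
    difficult.  ``ranking`` must be a bijection from the behaviour's
    barrier set onto ``{1..n_barriers}``.
    """

    respondent_id: str
    behaviour_id: str
    attribute: str
    ranking: Mapping[str, int]
    direction: str = "raw"

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise ValidationError(
                f"ballot attribute must be one of {ATTRIBUTES}, "
                f"got {self.attribute!r}"
            )


def validate_ballot(behaviour: Behaviour, ballot: Ballot) -> None:
    """Check the bijection invariant of *ballot* against *behaviour*.

    Raises :class:`ValidationError` on a tie, gap, out-of-range rank, or a
    barrier-set mismatch, identifying the respondent and behaviour.
    """
    who = f"respondent {ballot.respondent_id!r}, behaviour {ballot.behaviour_id!r}"
    expected = set(behaviour.barrier_ids)
    got = set(ballot.ranking)
    if got != expected:
        raise ValidationError(
            f"{who} ({ballot.attribute}): ballot covers barriers "
            f"{sorted(got)} but behaviour has {sorted(expected)}"
        )
    n = behaviour.n_barriers
    ranks = sorted(ballot.ranking.values())
    if ranks != list(range(1, n + 1)):
        counts = Counter(ballot.ranking.values())
        tied = sorted(r for r, c in counts.items() if c > 1)
        if tied:
            raise ValidationError(
                f"{who} ({ballot.attribute}): tied rank(s) {tied} — "
                f"ballots must be complete total orders"
            )
        raise ValidationError(
            f"{who} ({ballot.attribute}): ranks {ranks} are not a "
            f"permutation of 1..{n}"
        )


@dataclass(frozen=True)
class SurveyDataset:
    """A catalogue plus respondents and their validated ballots."""

    catalogue: BehaviourCatalogue
    respondents: tuple[Respondent, ...]
    ballots: tuple[Ballot, ...]

    def __post_init__(self) -> None:
        by_id = {r.respondent_id: r for r in self.respondents}
        if len(by_id) != len(self.respondents):
            raise ValidationError("duplicate respondent_id in dataset")
        seen: set[tuple[str, str, str]] = set()
        for ballot in self.ballots:
            if ballot.respondent_id not in by_id:
                raise ValidationError(
                    f"ballot references unknown respondent "
                    f"{ballot.respondent_id!r}"
                )
            behaviour = self.catalogue.behaviour(ballot.behaviour_id)
            validate_ballot(behaviour, ballot)
            key = (ballot.respondent_id, ballot.behaviour_id, ballot.attribute)
            if key in seen:
                raise ValidationError(
                    f"respondent {ballot.respondent_id!r} has more than one "
                    f"ballot for behaviour {ballot.behaviour_id!r} "
                    f"({ballot.attribute})"
                )
            seen.add(key)

    def respondent(self, respondent_id: str) -> Respondent:
        for r in self.respondents:
            if r.respondent_id == respondent_id:
                return r
        raise KeyError(f"unknown respondent_id {respondent_id!r}")

    def ballots_for(self, behaviour_id: str, attribute: str) -> tuple[Ballot, ...]:
        """All ballots for one behaviour/attribute (possibly empty:
        respondents may skip eligible behaviours)."""
        return tuple(
            b
            for b in self.ballots
            if b.behaviour_id == behaviour_id and b.attribute == attribute
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: PathLike) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table (delimiter autodetected)."""
    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str,
                           keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def load_catalogue(path: PathLike) -> BehaviourCatalogue:
    """Load a behaviour/barrier catalogue.

    Two on-disk forms are accepted: a delimited table (one row per barrier,
    columns ``behaviour_id, behaviour_name, barrier_id, barrier_description,
    eligible_groups`` with groups ``|``-separated), or — for ``.yaml`` /
    ``.yml`` paths — a structured mapping with the same content.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _load_catalogue_yaml(path)
    df = _read_table(path)
    _require_columns(
        df,
        ["behaviour_id", "behaviour_name", "barrier_id", "barrier_description",
         "eligible_groups"],
        path,
    )
    behaviours: list[Behaviour] = []
    for behaviour_id, rows in df.groupby("behaviour_id", sort=False):
        names = rows["behaviour_name"].unique()
        if len(names) > 1:
            first = rows.index[0] + 2  # header is line 1
            raise ParseError(
                f"{path}: line {first}: behaviour {behaviour_id!r} has "
                f"conflicting names {list(names)}"
            )
        groups_raw = rows["eligible_groups"].unique()
        if len(groups_raw) > 1:
            raise ParseError(
                f"{path}: behaviour {behaviour_id!r} has conflicting "
                f"eligible_groups entries"
            )
        barriers = tuple(
            Barrier(
                barrier_id=r.barrier_id,
                behaviour_id=str(behaviour_id),
                description=r.barrier_description,
            )
            for r in rows.itertuples()
        )
        behaviours.append(
            Behaviour(
                behaviour_id=str(behaviour_id),
                name=str(names[0]),
                barriers=barriers,
                eligible_groups=frozenset(
                    g for g in str(groups_raw[0]).split("|") if g
                ),
            )
        )
    return BehaviourCatalogue(tuple(behaviours))


def _load_catalogue_yaml(path: Path) -> BehaviourCatalogue:
    import yaml

    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict) or "behaviours" not in doc:
        raise ParseError(f"{path}: expected a mapping with a 'behaviours' key")
    behaviours = []
    for entry in doc["behaviours"]:
        behaviour_id = str(entry["behaviour_id"])
        barriers = tuple(
            Barrier(
                barrier_id=str(b["barrier_id"]),
                behaviour_id=behaviour_id,
                description=str(b.get("description", "")),
            )
            for b in entry["barriers"]
        )
        behaviours.append(
            Behaviour(
                behaviour_id=behaviour_id,
                name=str(entry.get("name", behaviour_id)),
                barriers=barriers,
                eligible_groups=frozenset(entry.get("eligible_groups", [])),
            )
        )
    return BehaviourCatalogue(tuple(behaviours))


#: demographic columns recognised in a respondents table (all optional)
_DEMOGRAPHIC_COLUMNS = (
    "sex", "age_band", "role", "discipline", "years_experience",
    "qualification", "academic",
)


def load_respondents(path: PathLike) -> tuple[Respondent, ...]:
    """Load respondents from a delimited table.

    Required columns: ``respondent_id, group``.  Any of the demographic
    columns (sex, age band, role, discipline, years of experience band,
    qualification, academic tag) present are carried into
    :attr:`Respondent.demographics`.
    """
    df = _read_table(path)
    _require_columns(df, ["respondent_id", "group"], path)
    respondents = []
    for row in df.itertuples():
        demo = {
            c: getattr(row, c)
            for c in _DEMOGRAPHIC_COLUMNS
            if c in df.columns and getattr(row, c) != ""
        }
        respondents.append(
            Respondent(
                respondent_id=row.respondent_id,
                group=row.group,
                demographics=demo,
            )
        )
    return tuple(respondents)


def load_survey(
    catalogue: BehaviourCatalogue,
    ballots_path: PathLike,
    respondents_path: Optional[PathLike] = None,
    on_ineligible: str = "error",
) -> SurveyDataset:
    """Load ballots (long format) and assemble a validated dataset.

    The ballots table has one row per ``(respondent, behaviour, attribute,
    barrier, rank)``; required columns ``respondent_id, behaviour_id,
    attribute, barrier_id, rank`` plus — when *respondents_path* is not
    given — a ``group`` column from which respondents are inferred.

    A ballot from a respondent whose group is not eligible for the
    behaviour is rejected (``on_ineligible="error"``, default) or dropped
    with a warning (``on_ineligible="drop"``).
    """
    if on_ineligible not in ("error", "drop"):
        raise ValueError("on_ineligible must be 'error' or 'drop'")
    df = _read_table(ballots_path)
    _require_columns(
        df, ["respondent_id", "behaviour_id", "attribute", "barrier_id", "rank"],
        ballots_path,
    )
    if respondents_path is not None:
        respondents = load_respondents(respondents_path)
    else:
        _require_columns(df, ["group"], ballots_path)
        pairs = df[["respondent_id", "group"]].drop_duplicates()
        dup = pairs["respondent_id"].duplicated()
        if dup.any():
            bad = pairs.loc[dup, "respondent_id"].iloc[0]
            raise ValidationError(
                f"respondent {bad!r} appears with more than one group"
            )
        respondents = tuple(
            Respondent(r.respondent_id, r.group) for r in pairs.itertuples()
        )
    group_of = {r.respondent_id: r.group for r in respondents}

    ballots: list[Ballot] = []
    keep_respondents = set()
    for (rid, behaviour_id, attribute), rows in df.groupby(
        ["respondent_id", "behaviour_id", "attribute"], sort=False
    ):
        if rid not in group_of:
            raise ValidationError(
                f"{ballots_path}: ballot from unknown respondent {rid!r}"
            )
        behaviour = catalogue.behaviour(str(behaviour_id))
        if group_of[rid] not in behaviour.eligible_groups:
            msg = (
                f"respondent {rid!r} (group {group_of[rid]!r}) is not "
                f"eligible for behaviour {behaviour_id!r} "
                f"(eligible: {sorted(behaviour.eligible_groups)})"
            )
            if on_ineligible == "error":
                raise ValidationError(msg)
            warnings.warn(msg + " — ballot dropped", stacklevel=2)
            continue
        try:
            ranking = {
                r.barrier_id: int(r.rank) for r in rows.itertuples()
            }
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{ballots_path}: non-integer rank for respondent {rid!r}, "
                f"behaviour {behaviour_id!r}"
            ) from exc
        if len(ranking) != len(rows):
            raise ValidationError(
                f"respondent {rid!r}, behaviour {behaviour_id!r} "
                f"({attribute}): duplicate barrier rows"
            )
        ballot = Ballot(
            respondent_id=rid,
            behaviour_id=str(behaviour_id),
            attribute=str(attribute),
            ranking=ranking,
        )
        validate_ballot(behaviour, ballot)
        ballots.append(ballot)
        keep_respondents.add(rid)

    if respondents_path is None:
        respondents = tuple(
            r for r in respondents if r.respondent_id in keep_respondents
        )
    return SurveyDataset(catalogue, tuple(respondents), tuple(ballots))


def survey_frame(dataset: SurveyDataset) -> pd.DataFrame:
    """Long-format ballots table (one row per ranked barrier)."""
    records = []
    for ballot in dataset.ballots:
        group = dataset.respondent(ballot.respondent_id).group
        behaviour = dataset.catalogue.behaviour(ballot.behaviour_id)
        for barrier_id in behaviour.barrier_ids:  # stable catalogue order
            records.append(
                {
                    "respondent_id": ballot.respondent_id,
                    "group": group,
                    "behaviour_id": ballot.behaviour_id,
                    "attribute": ballot.attribute,
                    "barrier_id": barrier_id,
                    "rank": ballot.ranking[barrier_id],
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["respondent_id", "group", "behaviour_id", "attribute",
                 "barrier_id", "rank"],
    )


def write_survey(
    dataset: SurveyDataset,
    ballots_path: PathLike,
    respondents_path: Optional[PathLike] = None,
) -> None:
    """Write ballots (and optionally respondents) as delimited text.

    ``load_survey(catalogue, ballots_path, respondents_path)`` round-trips
    the dataset record for record.
    """
    survey_frame(dataset).to_csv(ballots_path, index=False)
    if respondents_path is not None:
        rows = []
        for r in dataset.respondents:
            row = {"respondent_id": r.respondent_id, "group": r.group}
            row.update({c: r.demographics.get(c, "") for c in _DEMOGRAPHIC_COLUMNS
                        if any(c in x.demographics for x in dataset.respondents)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(respondents_path, index=False)


# ---------------------------------------------------------------------------
# demographics


def demographic_percentages(
    respondents: Iterable[Respondent], field_name: str
) -> dict[str, tuple[int, float]]:
    """Tabulate one demographic field as ``category -> (count, percent)``.

    Percentages are ``100 * count / n`` rounded to one decimal place; the
    counts always sum to the panel size.  Raises on an empty panel or if
    the field is missing for any respondent.
    """
    respondents = list(respondents)
    if not respondents:
        raise ValidationError("cannot tabulate an empty respondent list")
    values = []
    for r in respondents:
        if field_name == "group":
            values.append(r.group)
            continue
        if field_name not in r.demographics:
            raise ValidationError(
                f"respondent {r.respondent_id!r} is missing demographic "
                f"field {field_name!r}"
            )
        values.append(str(r.demographics[field_name]))
    n = len(values)
    counts = Counter(values)
    return {
        cat: (c, round(100.0 * c / n, 1)) for cat, c in sorted(counts.items())
    }
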