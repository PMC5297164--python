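import pytest

from barrierprio import datasets
from barrierprio.catalogue import (
    Ballot,
    Barrier,
    Behaviour,
    BehaviourCatalogue,
    Respondent,
    SurveyDataset,
)


@pytest.fixture(scope="session")
def study_catalogue():
    return datasets.study_catalogue()


@pytest.fixture(scope="session")
def study_respondents():
    return datasets.study_respondents()


@pytest.fixture(scope="session")
def study_group_ranks():
    return datasets.study_group_ranks()


@pytest.fixture(scope="session")
def study_labels():
    return datasets.study_desirability_labels()


def make_behaviour(behaviour_id="t", n=3, groups=("EN",), name=None):
    barriers = tuple(
        Barrier(f"{behaviour_id}.{i + 1}", behaviour_id) for i in range(n)
    )
    return Behaviour(
        behaviour_id=behaviour_id,
        name=name or f"behaviour {behaviour_id}",
        barriers=barriers,
        eligible_groups=frozenset(groups),
    )


def make_dataset(behaviour, ballots_spec, group="EN"):
    """Dataset with one behaviour; ballots_spec = list of
    (respondent_id, attribute, {barrier_id: raw_rank})."""
    catalogue = BehaviourCatalogue((behaviour,))
    respondents = tuple(
        Respondent(rid, group) for rid in sorted({s[0] for s in ballots_spec})
    )
    ballots = tuple(
        Ballot(rid, behaviour.behaviour_id, attribute, ranking)
        for rid, attribute, ranking in ballots_spec
    )
    return SurveyDataset(catalogue, respondents, ballots)


@pytest.fixture
def three_barrier_behaviour():
    return make_behaviour("t", 3)
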