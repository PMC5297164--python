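import textwrap

import pytest

from barrierprio.catalogue import (
    Ballot,
    BehaviourCatalogue,
    ParseError,
    Respondent,
    SurveyDataset,
    ValidationError,
    demographic_percentages,
    load_catalogue,
    load_survey,
    validate_ballot,
    write_survey,
)
from barrierprio.panelsim import PanelSimConfig, simulate_panel

from conftest import make_behaviour, make_dataset


class TestStudyCatalogue:
    def test_shape(self, study_catalogue):
        assert len(study_catalogue) == 9
        counts = [b.n_barriers for b in study_catalogue]
        assert counts == [6, 9, 8, 5, 4, 2, 7, 8, 4]
        assert study_catalogue.n_barriers_total == 53

    def test_thrombolysis_eligibility_behaviour(self, study_catalogue):
        beh = study_catalogue.behaviour("2")
        assert beh.name == "Full assessment for rt-PA eligibility"
        assert beh.n_barriers == 9

    def test_eligibility_groups(self, study_catalogue):
        assert study_catalogue.behaviour("8").eligible_groups == {"EN", "SN", "SP"}
        assert study_catalogue.behaviour("1").eligible_groups == {"EN", "EDr", "SDr"}
        assert study_catalogue.behaviour("9").eligible_groups == {"EN", "SN", "BM"}

    def test_barrier_ids_unique(self, study_catalogue):
        ids = [b.barrier_id for beh in study_catalogue for b in beh.barriers]
        assert len(ids) == len(set(ids))


class TestLoadCatalogue:
    def test_duplicate_barrier_rejected(self, tmp_path):
        path = tmp_path / "cat.csv"
        path.write_text(textwrap.dedent("""\
            behaviour_id,behaviour_name,barrier_id,barrier_description,eligible_groups
            1,one,1.1,x,EN
            1,one,1.1,y,EN
        """))
        with pytest.raises(ValidationError, match="duplicate barrier_id"):
            load_catalogue(path)

    def test_malformed_names_line(self, tmp_path):
        path = tmp_path / "cat.csv"
        path.write_text(textwrap.dedent("""\
            behaviour_id,behaviour_name,barrier_id,barrier_description,eligible_groups
            1,one,1.1,x,EN
            1,another,1.2,y,EN
        """))
        with pytest.raises(ParseError, match="line"):
            load_catalogue(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "cat.csv"
        path.write_text("behaviour_id,barrier_id\n1,1.1\n")
        with pytest.raises(ParseError, match="missing required column"):
            load_catalogue(path)

    def test_yaml_form(self, tmp_path):
        path = tmp_path / "cat.yaml"
        path.write_text(textwrap.dedent("""\
            behaviours:
              - behaviour_id: t
                name: tiny
                eligible_groups: [EN, SN]
                barriers:
                  - {barrier_id: t.1, description: first}
                  - {barrier_id: t.2, description: second}
        """))
        cat = load_catalogue(path)
        assert cat.behaviour("t").barrier_ids == ("t.1", "t.2")
        assert cat.behaviour("t").eligible_groups == {"EN", "SN"}

    def test_single_barrier_behaviour_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 barriers"):
            make_behaviour("t", 1)


class TestBallotValidation:
    def test_complete_ranking_accepted(self, three_barrier_behaviour):
        ballot = Ballot("r1", "t", "influence",
                        {"t.1": 1, "t.2": 2, "t.3": 3})
        validate_ballot(three_barrier_behaviour, ballot)  # no raise

    @pytest.mark.parametrize(
        "ranking, message",
        [
            ({"t.1": 1, "t.2": 1, "t.3": 3}, "tied rank"),
            ({"t.1": 1, "t.2": 2, "t.3": 4}, "not a permutation"),
            ({"t.1": 1, "t.2": 2}, "covers barriers"),
        ],
    )
    def test_bad_rankings_rejected(self, three_barrier_behaviour, ranking, message):
        ballot = Ballot("r1", "t", "influence", ranking)
        with pytest.raises(ValidationError, match=message):
            validate_ballot(three_barrier_behaviour, ballot)

    def test_rank_beyond_scale_rejected(self):
        # a 2-barrier behaviour has scale 1..2: rank 3 is invalid
        behaviour = make_behaviour("u", 2)
        ballot = Ballot("r1", "u", "difficulty", {"u.1": 1, "u.2": 3})
        with pytest.raises(ValidationError):
            validate_ballot(behaviour, ballot)

    def test_bad_attribute_rejected(self):
        with pytest.raises(ValidationError, match="attribute"):
            Ballot("r1", "t", "importance", {"t.1": 1, "t.2": 2})


class TestLoadSurvey:
    def _write_ballots(self, tmp_path, rows):
        path = tmp_path / "ballots.csv"
        header = "respondent_id,group,behaviour_id,attribute,barrier_id,rank\n"
        path.write_text(header + "".join(f"{r}\n" for r in rows))
        return path

    def test_valid_ballot_accepted(self, tmp_path):
        catalogue = BehaviourCatalogue((make_behaviour("t", 3),))
        path = self._write_ballots(tmp_path, [
            "r1,EN,t,influence,t.1,1",
            "r1,EN,t,influence,t.2,2",
            "r1,EN,t,influence,t.3,3",
        ])
        ds = load_survey(catalogue, path)
        assert len(ds.ballots) == 1
        assert ds.ballots[0].ranking == {"t.1": 1, "t.2": 2, "t.3": 3}

    def test_tied_ballot_rejected_with_identity(self, tmp_path):
        catalogue = BehaviourCatalogue((make_behaviour("t", 3),))
        path = self._write_ballots(tmp_path, [
            "r1,EN,t,influence,t.1,1",
            "r1,EN,t,influence,t.2,1",
            "r1,EN,t,influence,t.3,3",
        ])
        with pytest.raises(ValidationError) as err:
            load_survey(catalogue, path)
        assert "r1" in str(err.value) and "t" in str(err.value)

    def test_ineligible_group_rejected_by_default(self, tmp_path, study_catalogue):
        # speech pathologists only rank the swallow-screen behaviour,
        # so an SP ballot on the triage behaviour is invalid
        beh = study_catalogue.behaviour("1")
        rows = [
            f"r1,SP,1,influence,{b},{i + 1}"
            for i, b in enumerate(beh.barrier_ids)
        ]
        path = self._write_ballots(tmp_path, rows)
        with pytest.raises(ValidationError, match="not eligible"):
            load_survey(study_catalogue, path)

    def test_ineligible_group_dropped_with_warning(self, tmp_path, study_catalogue):
        beh = study_catalogue.behaviour("1")
        rows = [
            f"r1,SP,1,influence,{b},{i + 1}"
            for i, b in enumerate(beh.barrier_ids)
        ]
        path = self._write_ballots(tmp_path, rows)
        with pytest.warns(UserWarning, match="dropped"):
            ds = load_survey(study_catalogue, path, on_ineligible="drop")
        assert len(ds.ballots) == 0

    def test_duplicate_ballot_rejected(self):
        behaviour = make_behaviour("t", 2)
        spec = [
            ("r1", "influence", {"t.1": 1, "t.2": 2}),
            ("r1", "influence", {"t.1": 2, "t.2": 1}),
        ]
        with pytest.raises(ValidationError, match="more than one ballot"):
            make_dataset(behaviour, spec)

    def test_roundtrip_record_for_record(self, tmp_path, study_catalogue):
        config = PanelSimConfig.from_catalogue(study_catalogue, seed=7)
        ds = simulate_panel(config)
        ballots_path = tmp_path / "ballots.csv"
        respondents_path = tmp_path / "resp.csv"
        write_survey(ds, ballots_path, respondents_path)
        back = load_survey(study_catalogue, ballots_path, respondents_path)
        assert {r.respondent_id: r.group for r in back.respondents} == {
            r.respondent_id: r.group for r in ds.respondents
        }
        original = {
            (b.respondent_id, b.behaviour_id, b.attribute): dict(b.ranking)
            for b in ds.ballots
        }
        restored = {
            (b.respondent_id, b.behaviour_id, b.attribute): dict(b.ranking)
            for b in back.ballots
        }
        assert restored == original


class TestDemographics:
    def test_study_panel_discipline_split(self, study_respondents):
        pct = demographic_percentages(study_respondents, "discipline")
        assert pct["medical"] == (6, 35.3)
        assert pct["nursing"] == (6, 35.3)
        assert pct["speech pathology"] == (3, 17.6)
        assert pct["bed management"] == (2, 11.8)

    def test_study_panel_sex(self, study_respondents):
        assert demographic_percentages(study_respondents, "sex")["Male"] == (9, 52.9)

    @pytest.mark.parametrize(
        "field", ["sex", "age_band", "discipline", "years_experience",
                  "qualification", "group"]
    )
    def test_percentages_sum_to_100(self, study_respondents, field):
        pct = demographic_percentages(study_respondents, field)
        assert sum(c for c, _ in pct.values()) == len(study_respondents)
        total = sum(p for _, p in pct.values())
        assert abs(total - 100.0) <= 0.1 * len(pct)

    def test_single_respondent(self):
        r = Respondent("r1", "EN", {"sex": "Female"})
        assert demographic_percentages([r], "sex") == {"Female": (1, 100.0)}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            demographic_percentages([], "sex")

    def test_missing_field_rejected(self):
        r = Respondent("r1", "EN")
        with pytest.raises(ValidationError, match="missing demographic"):
            demographic_percentages([r], "sex")
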