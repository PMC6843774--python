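"""Traversal, measurement confirmation, restart rule, batch identification."""

import pandas as pd
import pytest

from diatomkey import (
    batch_identify,
    candidates_remaining,
    confirm_measurements,
    identify_observation,
)
from diatomkey.content import worked_examples_path
from diatomkey.engine import (
    ContradictoryAnswersError,
    ScriptedAnswers,
    identify,
)
from diatomkey.model import (
    Interval,
    MeasurementSet,
    Observation,
    SpeciesRecord,
    Status,
    node_successor,
)

REC = SpeciesRecord(
    "probe", "Probe species", "Probe",
    length_range_um=Interval(10.0, 20.0),
    width_range_um=Interval(2.0, 4.0),
    striae_range_per_10um=Interval(12.0, 18.0),
)


class TestConfirmMeasurements:
    def test_all_inside_confirms(self):
        rep = confirm_measurements(
            MeasurementSet(length_um=15, width_um=3, striae_per_10um=14), REC
        )
        assert rep.overall and not rep.out_fields()

    def test_single_field_below_lower_bound_fails(self):
        rep = confirm_measurements(
            MeasurementSet(length_um=9.9, width_um=3, striae_per_10um=14), REC
        )
        assert not rep.overall
        assert rep.out_fields() == ("length_um",)

    @pytest.mark.parametrize("length", [10.0, 20.0])
    def test_interval_endpoints_count_as_matches(self, length):
        rep = confirm_measurements(MeasurementSet(length_um=length), REC)
        assert rep.overall

    def test_fields_absent_on_either_side_are_not_compared(self):
        # observed fibulae density but the record ranges only striae:
        # no evidence against the candidate
        rep = confirm_measurements(
            MeasurementSet(length_um=15, fibulae_per_10um=99), REC
        )
        assert rep.overall
        verdicts = {f.field: f.verdict for f in rep.fields}
        assert verdicts["fibulae_per_10um"] == "absent"
        assert verdicts["striae_per_10um"] == "absent"
        assert verdicts["length_um"] == "in"

    def test_relative_tolerance_widens_the_interval(self):
        m = MeasurementSet(length_um=21.0)
        assert not confirm_measurements(m, REC).overall
        assert confirm_measurements(m, REC, tolerance=0.1).overall


WORKED = [
    ("a_valve_fibulae_margin", "nitzschia_capitellata", ["C1", "C3", "C5"]),
    ("b_valve_central_heteropolar", "gomphonema_olivaceum", ["C1", "C3", "C10"]),
    ("c_valve_central_dorsoventral", "encyonema_caespitosum", ["C1", "C3", "C11"]),
    ("d_valve_fibulae_all_around", "cymatopleura_solea", ["C1", "C3", "C12"]),
    ("e_valve_radiate_circular", "cyclotella_ocellata", ["C1", "C2"]),
]


class TestIdentify:
    def test_five_published_specimens_batch(self, key, db):
        result = batch_identify(key, db, worked_examples_path())
        assert result.counts == {"identified": 5}
        got = [(r["label"], r["species_id"], r["charts_visited"]) for r in result.rows]
        assert got == [(label, sid, charts) for label, sid, charts in WORKED]

    def test_girdle_view_identifies_rhoicosphenia_within_c1(self, key, db):
        obs = Observation(
            answers={"c1_view": "girdle_view", "c1_girdle_shape": "cuneate_flexed"},
            measurements=MeasurementSet(length_um=30, width_um=5, striae_per_10um=12),
        )
        res = identify_observation(key, db, obs)
        assert res.status is Status.IDENTIFIED
        assert res.species_id == "rhoicosphenia_abbreviata"
        assert res.charts_visited == ("C1",)

    def test_out_of_range_measurement_triggers_restart_status(self, key, db):
        obs = Observation(
            answers={
                "c1_view": "valve_view", "c1_symmetry": "radiate_triangular",
                "c2_shape": "circular", "c2_ornament": "ornament_present",
                "c2_zone": "clearly_distinct", "c2_pattern": "irregular_with_punctae",
            },
            measurements=MeasurementSet(length_um=80, width_um=15, striae_per_10um=15),
        )
        res = identify_observation(key, db, obs)
        assert res.status is Status.NO_MATCH_RESTART
        assert res.species_id is None
        assert res.measurement_report.out_fields() == ("length_um",)

    def test_unknown_answer_reports_frontier_candidates(self, key, db):
        obs = Observation(
            answers={"c1_view": "valve_view", "c1_symmetry": "other_symmetry",
                     "c3_raphe": "fibulae_around"},
            measurements=MeasurementSet(length_um=30),
        )
        res = identify_observation(key, db, obs)
        assert res.status is Status.UNRESOLVED
        # frontier is the raphe-fibulae position couplet: Surirellaceae,
        # Bacillaria, Bacillariaceae and Rhopalodiaceae candidates
        assert "bacillaria_paxillifera" in res.frontier_candidates
        assert "rhopalodia_gibba" in res.frontier_candidates
        assert "gomphonema_olivaceum" not in res.frontier_candidates

    def test_trace_steps_agree_with_node_successor(self, key, db):
        result = batch_identify(key, db, worked_examples_path())
        for row in result.rows:
            for node_id, answer, ref in row["trace"]:
                assert node_successor(key, node_id, answer).ref == ref

    def test_scripted_identification_is_deterministic(self, key, db):
        a = batch_identify(key, db, worked_examples_path())
        b = batch_identify(key, db, worked_examples_path())
        assert a.rows == b.rows

    def test_interactive_restart_excludes_failed_candidate(self, linear_key):
        toy, toy_db = linear_key
        source = ScriptedAnswers({"n1": "round", "n2": "round"})
        res = identify(
            toy, toy_db, source, MeasurementSet(length_um=99),  # out of range
            restart_on_mismatch=True, max_restarts=2,
        )
        # same answers each pass: candidate excluded, budget exhausted
        assert res.status is Status.UNRESOLVED
        assert res.excluded_tried == ("only_one",)
        assert "restart" in res.note or "excluded" in res.note

    def test_excluded_option_prevents_identification(self, linear_key):
        toy, toy_db = linear_key
        obs = Observation(answers={"n1": "round", "n2": "round"},
                          measurements=MeasurementSet(length_um=15))
        res = identify_observation(toy, toy_db, obs, excluded={"only_one"})
        assert res.status is Status.UNRESOLVED


class TestBatchIdentify:
    def test_empty_table_empty_results(self, key, db):
        cols = ["label", "c1_view", "length_um"]
        result = batch_identify(key, db, pd.DataFrame(columns=cols))
        assert result.rows == [] and result.counts == {}

    def test_undeclared_token_flags_row_without_aborting(self, key, db):
        df = pd.read_csv(worked_examples_path(), dtype=str)
        df.loc[2, "c1_view"] = "upside_down"
        result = batch_identify(key, db, df)
        statuses = [r["status"] for r in result.rows]
        assert statuses == ["identified", "identified", "error",
                            "identified", "identified"]
        assert "upside_down" in result.rows[2]["error"]
        assert result.counts == {"identified": 4, "error": 1}

    def test_jsonl_round_trip(self, key, db, tmp_path):
        import json

        result = batch_identify(key, db, worked_examples_path())
        out = tmp_path / "results.jsonl"
        from diatomkey.engine import results_to_jsonl

        results_to_jsonl(result, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 5
        assert json.loads(lines[0])["species_id"] == "nitzschia_capitellata"


class TestCandidatesRemaining:
    def test_empty_answers_keep_all_sixty(self, key):
        assert len(candidates_remaining(key, {})) == 60

    def test_answers_forcing_the_rhopalodiaceae_chart(self, key):
        got = candidates_remaining(key, {
            "c1_view": "valve_view", "c1_symmetry": "other_symmetry",
            "c3_raphe": "fibulae_around", "c3_fibulae": "margin_not_visible",
        })
        assert got == {"rhopalodia_gibba", "epithemia_sorex", "epithemia_adnata"}

    def test_full_path_answers_leave_a_singleton(self, key, db):
        from diatomkey import generate_observation

        obs = generate_observation(key, db, "nitzschia_sigma", 0)
        got = candidates_remaining(key, obs.answers)
        assert got == {"nitzschia_sigma"}

    def test_contradictory_answers_are_a_described_failure(self, key):
        with pytest.raises(ContradictoryAnswersError):
            candidates_remaining(
                key, [("c1_view", "valve_view"), ("c1_view", "girdle_view")]
            )
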