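"""Static key analysis: error codes, chart-graph conformance, audits."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from diatomkey import check_chart_graph, load_bundled_chart_graph, validate
from diatomkey.content import ChartGraph
from diatomkey.engine import ScriptedAnswers, identify
from diatomkey.model import (
    Chart,
    CharacterDef,
    DecisionNode,
    EdgeTarget,
    FlowChart,
    MeasurementSet,
    SpeciesDB,
)
from diatomkey.validator import roundtrip_audit


def test_bundled_key_validates_clean(key, db):
    rep = validate(key, db)
    assert rep.ok
    assert rep.stats["leaf_count"] == 60
    assert rep.stats["genera_count"] == 25
    assert rep.stats["chart_count"] == 12
    assert rep.stats["character_count"] == 11
    assert rep.stats["unreachable_nodes"] == 0


def test_validate_is_idempotent_and_stable_under_serialization(key, db, tmp_path):
    from diatomkey.io import load_key, write_key

    first = validate(key, db)
    second = validate(key, db)
    assert first.to_dict() == second.to_dict()
    path = tmp_path / "again.json"
    write_key(key, path)
    assert validate(load_key(path), db).to_dict() == first.to_dict()


def _with_broken_edge(key, node_id, state, target):
    """Copy of the key with one edge rewired (bypasses loader checks)."""
    node = key.nodes[node_id]
    edges = dict(node.edges)
    edges[state] = target
    nodes = dict(key.nodes)
    nodes[node_id] = dataclasses.replace(node, edges=edges)
    return FlowChart(key.characters, key.charts, nodes, key.entry_chart, key.meta)


def test_dangling_edge_is_e1(key, db):
    broken = _with_broken_edge(
        key, "c1_view", "girdle_view", EdgeTarget.node("deleted_node")
    )
    rep = validate(broken, db)
    assert [f.code for f in rep.errors()].count("E1") == 1


def test_missing_species_is_e4_naming_the_leaf(key, db):
    smaller = SpeciesDB(
        {k: v for k, v in db.records.items() if k != "bacillaria_paxillifera"}
    )
    rep = validate(key, smaller)
    e4 = [f for f in rep.errors() if f.code == "E4"]
    assert len(e4) == 1
    assert e4[0].location.startswith("c3_fibulae")
    assert "bacillaria_paxillifera" in e4[0].message


def test_cycle_is_e5(key, db):
    broken = _with_broken_edge(
        key, "c2_pattern", "regular_no_punctae", EdgeTarget.node("c2_shape")
    )
    rep = validate(broken, db)
    assert any(f.code == "E5" for f in rep.errors())


def test_unreachable_node_is_e3():
    char = CharacterDef("c", "c", states=("a", "b"))
    nodes = [
        DecisionNode("n1", "K1", "c", "?", {"a": EdgeTarget.species("sp1")}),
        DecisionNode("n2", "K1", "c", "orphan", {"a": EdgeTarget.species("sp1")}),
    ]
    key = FlowChart.build([char], [Chart("K1", "t", "n1")], nodes, "K1")
    rep = validate(key)
    assert [f.code for f in rep.errors()] == ["E3"]
    assert rep.errors()[0].location == "n2"


class TestChartGraph:
    def test_bundled_key_matches_shipped_expected_graph(self, key):
        rep = check_chart_graph(key, load_bundled_chart_graph())
        assert rep.ok and rep.stats["difference"] == 0

    def test_missing_expected_transition_is_one_finding(self, key):
        expected = load_bundled_chart_graph()
        pruned = ChartGraph(
            tuple(t for t in expected.transitions if (t[0], t[1]) != ("C1", "C2"))
        )
        rep = check_chart_graph(key, pruned)
        assert len(rep.errors()) == 1
        assert rep.errors()[0].location == "C1->C2"

    def test_empty_expected_graph_reports_all_induced(self, key):
        rep = check_chart_graph(key, ChartGraph(()))
        assert len(rep.errors()) == rep.stats["induced_transitions"] == 11


class TestRoundtripAudit:
    def test_every_species_recovered_without_noise(self, key, db):
        audit = roundtrip_audit(key, db, seeds=range(2))
        assert len(audit) == 120
        assert audit["ok"].all()

    def test_deleting_a_leaf_edge_fails_exactly_that_species(self, key, db):
        # reroute the Bacillaria leaf into the Surirellaceae chart
        broken = _with_broken_edge(
            key, "c3_fibulae", "central", EdgeTarget.chart("C12")
        )
        audit = roundtrip_audit(broken, db, seeds=[0])
        bad = set(audit.loc[~audit["ok"], "species_id"])
        assert "bacillaria_paxillifera" not in set(audit["species_id"])  # no longer a leaf
        assert bad == set()  # all remaining leaves still round-trip


# fuzz: a structurally clean key never raises on declared answers
@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_clean_key_never_raises_structural_failures_on_declared_states(data):
    from diatomkey.synthetic import toy_key

    toy, toy_db = toy_key(n_charts=2, n_leaves=5, seed=7)
    assert validate(toy, toy_db).ok

    class RandomDeclared:
        def ask(self, node, states):
            return data.draw(st.sampled_from(list(states)), label=node.node_id)

    res = identify(toy, toy_db, RandomDeclared(), MeasurementSet(length_um=11.0))
    assert res.status.value in ("identified", "no_match_restart", "unresolved")
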