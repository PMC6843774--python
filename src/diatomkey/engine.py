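"""Identification engine: key traversal, measurement confirmation, restart.

An identification walks the key from the entry chart under an
:class:`AnswerSource`.  Reaching a species leaf triggers *confirmation of
measurements*: each observed measurement is compared with the like-named
range of the candidate's :class:`~diatomkey.model.SpeciesRecord` (closed
intervals; striae and fibulae densities are alternatives and are only ever
compared with their like-named range).  If every compared field is in range
the specimen is identified; if any field falls outside, the method's rule is
to restart from the beginning of the flow chart.

With a fixed (scripted) observation a restart would deterministically walk
the same path again, so scripted mode reports ``no_match_restart`` and
stops.  Interactive mode actually restarts — with the failed candidate
excluded and a bounded restart budget — letting the user revise answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

import json

import pandas as pd

from .model import (
    DeadEndError,
    DecisionNode,
    FlowChart,
    IdentificationResult,
    MEASUREMENT_FIELDS,
    MeasurementSet,
    Observation,
    SpeciesDB,
    Status,
    TargetKind,
    TraceStep,
    UndeclaredStateError,
    UnknownNodeError,
)

__all__ = [
    "UNKNOWN",
    "AnswerSource",
    "ScriptedAnswers",
    "InteractiveAnswers",
    "FieldVerdict",
    "MatchReport",
    "confirm_measurements",
    "identify",
    "identify_observation",
    "batch_identify",
    "BatchResult",
    "candidates_remaining",
    "ContradictoryAnswersError",
    "OBSERVATION_MEASUREMENT_COLUMNS",
    "observation_from_row",
    "results_to_jsonl",
]

UNKNOWN = "unknown"

OBSERVATION_MEASUREMENT_COLUMNS = MEASUREMENT_FIELDS


class ContradictoryAnswersError(Exception):
    """Two different states were supplied for the same node."""


# ---------------------------------------------------------------------------
# answer sources


class AnswerSource:
    """Contract: given a node, return one of its character's states or 'unknown'."""

    def ask(self, node: DecisionNode, states: tuple[str, ...]) -> str:
        raise NotImplementedError


class ScriptedAnswers(AnswerSource):
    """Answers read from an observation; missing answers become 'unknown'."""

    def __init__(self, answers: Union[Observation, dict]):
        self.answers = dict(
            answers.answers if isinstance(answers, Observation) else answers
        )

    def ask(self, node: DecisionNode, states: tuple[str, ...]) -> str:
        return self.answers.get(node.node_id, UNKNOWN)


class InteractiveAnswers(AnswerSource):
    """Prompt-driven source for terminal sessions (used by the CLI)."""

    def __init__(
        self,
        input_fn: Callable[[str], str] = input,
        output_fn: Callable[[str], None] = print,
    ):
        self.input_fn = input_fn
        self.output_fn = output_fn

    def ask(self, node: DecisionNode, states: tuple[str, ...]) -> str:
        self.output_fn(f"[{node.chart_id}] {node.prompt}")
        for i, s in enumerate(states, start=1):
            self.output_fn(f"  {i}. {s}")
        self.output_fn(f"  0. {UNKNOWN}")
        while True:
            raw = self.input_fn("> ").strip()
            if raw == "0" or raw == UNKNOWN:
                return UNKNOWN
            if raw.isdigit() and 1 <= int(raw) <= len(states):
                return states[int(raw) - 1]
            if raw in states:
                return raw
            self.output_fn("  please answer with a listed state or number")


# ---------------------------------------------------------------------------
# measurement confirmation


@dataclass(frozen=True)
class FieldVerdict:
    """Comparison of one measurement field with the species range."""

    field: str
    observed: Optional[float]
    interval: Optional[tuple[float, float]]
    verdict: str  # "in" | "out" | "absent"


@dataclass(frozen=True)
class MatchReport:
    """Per-field verdicts plus the overall all-in-range outcome.

    Fields absent on either side are not compared ("absent" verdict): a
    measurement the observer took but the record does not range, or vice
    versa, is no evidence against the candidate.
    """

    fields: tuple[FieldVerdict, ...]
    overall: bool

    def out_fields(self) -> tuple[str, ...]:
        return tuple(f.field for f in self.fields if f.verdict == "out")

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "fields": {
                f.field: {
                    "observed": f.observed,
                    "interval": list(f.interval) if f.interval else None,
                    "verdict": f.verdict,
                }
                for f in self.fields
            },
        }


def confirm_measurements(
    m: MeasurementSet, rec, tolerance: float = 0.0
) -> MatchReport:
    """Compare observed measurements with a species record's ranges.

    ``tolerance`` is a relative widening of each closed interval
    (default 0: strict membership, endpoints included).
    """
    verdicts = []
    ok = True
    for fname in MEASUREMENT_FIELDS:
        observed = getattr(m, fname)
        interval = rec.range_for(fname)
        if observed is None or interval is None:
            verdicts.append(
                FieldVerdict(
                    fname,
                    observed,
                    (interval.lo, interval.hi) if interval else None,
                    "absent",
                )
            )
            continue
        inside = interval.contains(observed, tolerance)
        ok = ok and inside
        verdicts.append(
            FieldVerdict(
                fname, observed, (interval.lo, interval.hi), "in" if inside else "out"
            )
        )
    return MatchReport(tuple(verdicts), ok)


# ---------------------------------------------------------------------------
# traversal


def _traverse(key: FlowChart, source: AnswerSource):
    """Walk from the entry node until a leaf, an 'unknown', or a dead end.

    Returns (species_id_or_None, trace, charts_visited, stopped_node).
    Raises UndeclaredStateError if the source returns a token that is not a
    state of the asked character (and not 'unknown').
    """
    trace: list[TraceStep] = []
    charts: list[str] = []
    node: Optional[DecisionNode] = key.entry_node
    while node is not None:
        if not charts or charts[-1] != node.chart_id:
            charts.append(node.chart_id)
        states = key.characters[node.character_id].states
        answer = source.ask(node, states)
        if answer == UNKNOWN:
            return None, tuple(trace), tuple(charts), node
        if answer not in states:
            raise UndeclaredStateError(
                f"answer {answer!r} at node {node.node_id!r} is not a state of "
                f"character {node.character_id!r}"
            )
        target = node.edges.get(answer)
        if target is None:  # declared state with no branch encoded
            return None, tuple(trace), tuple(charts), node
        trace.append(TraceStep(node.node_id, answer, target))
        if target.kind is TargetKind.SPECIES:
            return target.ref, tuple(trace), tuple(charts), None
        node = key.resolve(target)
    raise AssertionError("unreachable")


def identify(
    key: FlowChart,
    db: SpeciesDB,
    source: AnswerSource,
    measurements: MeasurementSet,
    *,
    max_restarts: int = 3,
    tolerance: float = 0.0,
    excluded: Iterable[str] = (),
    restart_on_mismatch: bool = False,
) -> IdentificationResult:
    """Run one identification from the key's entry chart.

    ``restart_on_mismatch`` enables the interactive restart rule: after a
    failed measurement confirmation the traversal starts over with the
    failed candidate excluded, up to ``max_restarts`` additional passes.
    With a scripted source the answers cannot change, so the default is to
    report ``no_match_restart`` after the first mismatch.
    """
    excluded_set = set(excluded)
    tried: list[str] = []
    attempts = max_restarts + 1 if restart_on_mismatch else 1
    result: Optional[IdentificationResult] = None
    for _ in range(attempts):
        species_id, trace, charts, stopped = _traverse(key, source)
        if species_id is None:
            # 'unknown' answer or dead-end branch: report the frontier
            frontier = (
                _leaves_below(key, stopped) if stopped is not None else ()
            )
            return IdentificationResult(
                status=Status.UNRESOLVED,
                trace=trace,
                charts_visited=charts,
                frontier_candidates=tuple(sorted(set(frontier) - excluded_set)),
                excluded_tried=tuple(tried),
                note="traversal stopped before a species leaf",
            )
        if species_id in excluded_set:
            result = IdentificationResult(
                status=Status.UNRESOLVED,
                trace=trace,
                charts_visited=charts,
                excluded_tried=tuple(tried),
                note=f"candidate {species_id} already excluded",
            )
            break
        report = confirm_measurements(measurements, db[species_id], tolerance)
        if report.overall:
            return IdentificationResult(
                status=Status.IDENTIFIED,
                species_id=species_id,
                binomial=db[species_id].binomial,
                trace=trace,
                charts_visited=charts,
                measurement_report=report,
                excluded_tried=tuple(tried),
            )
        # measurements do not match: the method restarts from the beginning
        tried.append(species_id)
        excluded_set.add(species_id)
        result = IdentificationResult(
            status=Status.NO_MATCH_RESTART,
            trace=trace,
            charts_visited=charts,
            measurement_report=report,
            excluded_tried=tuple(tried),
            note=f"measurements outside ranges of {species_id}: "
            + ", ".join(report.out_fields()),
        )
        if not restart_on_mismatch:
            return result
    assert result is not None
    if result.status is Status.NO_MATCH_RESTART:
        # restart budget exhausted
        return IdentificationResult(
            status=Status.UNRESOLVED,
            trace=result.trace,
            charts_visited=result.charts_visited,
            measurement_report=result.measurement_report,
            excluded_tried=tuple(tried),
            note="restart budget exhausted; excluded candidates: " + ", ".join(tried),
        )
    return result


def identify_observation(
    key: FlowChart, db: SpeciesDB, obs: Observation, **options
) -> IdentificationResult:
    """Identify a scripted observation (answers + measurements)."""
    return identify(
        key, db, ScriptedAnswers(obs), obs.measurements, **options
    )


def _leaves_below(key: FlowChart, node: DecisionNode) -> set[str]:
    """Species leaves reachable from a node (the frontier's candidate set)."""
    out: set[str] = set()
    seen: set[str] = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.node_id in seen:
            continue
        seen.add(cur.node_id)
        for tgt in cur.edges.values():
            if tgt.kind is TargetKind.SPECIES:
                out.add(tgt.ref)
            else:
                nxt = key.resolve(tgt)
                if nxt is not None:
                    stack.append(nxt)
    return out


# ---------------------------------------------------------------------------
# candidate narrowing


def candidates_remaining(
    key: FlowChart, partial_answers: Union[dict, Iterable[tuple[str, str]]]
) -> set[str]:
    """Species leaves still reachable under a set of partial answers.

    An answered node is followed along the answered edge only; an unanswered
    node contributes all its branches.  Equals ``enumerate_leaves(key)`` for
    the empty answer set.  Raises :class:`ContradictoryAnswersError` when two
    states are supplied for one node, and the model's errors for invalid
    node/state references.
    """
    if isinstance(partial_answers, dict):
        answers = dict(partial_answers)
    else:
        answers = {}
        for node_id, state in partial_answers:
            if node_id in answers and answers[node_id] != state:
                raise ContradictoryAnswersError(
                    f"node {node_id!r} answered both {answers[node_id]!r} and {state!r}"
                )
            answers[node_id] = state
    for node_id, state in answers.items():
        node = key.nodes.get(node_id)
        if node is None:
            raise UnknownNodeError(f"no node {node_id!r} in the key")
        states = key.characters[node.character_id].states
        if state not in states:
            raise UndeclaredStateError(
                f"{state!r} is not a state of character {node.character_id!r} "
                f"at node {node_id!r}"
            )

    out: set[str] = set()
    seen: set[str] = set()
    stack = [key.entry_node]
    while stack:
        node = stack.pop()
        if node.node_id in seen:
            continue
        seen.add(node.node_id)
        answered = answers.get(node.node_id)
        if answered is not None:
            targets = [node.edges[answered]] if answered in node.edges else []
        else:
            targets = list(node.edges.values())
        for tgt in targets:
            if tgt.kind is TargetKind.SPECIES:
                out.add(tgt.ref)
            else:
                nxt = key.resolve(tgt)
                if nxt is not None:
                    stack.append(nxt)
    return out


# ---------------------------------------------------------------------------
# batch identification


@dataclass
class BatchResult:
    """Per-row identification outcomes plus summary counts by status."""

    rows: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def observation_from_row(key: FlowChart, row: dict) -> Observation:
    """Build an Observation from one batch-CSV row.

    Columns that are node_ids of the key become answers; the four
    measurement columns become the MeasurementSet; ``label`` is free text.
    """
    answers = {}
    for col, val in row.items():
        if col in key.nodes:
            s = str(val).strip() if val is not None and not pd.isna(val) else ""
            if s:
                answers[col] = s
    meas = {}
    for col in OBSERVATION_MEASUREMENT_COLUMNS:
        val = row.get(col)
        if val is not None and not pd.isna(val) and str(val).strip() != "":
            meas[col] = float(val)
    label = str(row.get("label", "") or "")
    return Observation(
        answers=answers,
        measurements=MeasurementSet(**meas) if meas else MeasurementSet(length_um=1.0),
        label=label,
    )


def batch_identify(
    key: FlowChart,
    db: SpeciesDB,
    observations: Union[str, Path, pd.DataFrame],
    **options,
) -> BatchResult:
    """Identify every row of a batch observation table, order preserved.

    Per-row failures (e.g. an undeclared state token) are captured in the
    row's ``error`` field and never abort the batch.
    """
    if isinstance(observations, (str, Path)):
        df = pd.read_csv(observations, dtype=str)
    else:
        df = observations
    result = BatchResult()
    counts: dict[str, int] = {}
    for _, raw in df.iterrows():
        row = raw.to_dict()
        out = {"label": str(row.get("label", "") or "")}
        try:
            obs = observation_from_row(key, row)
            res = identify_observation(key, db, obs, **options)
            out.update(
                status=res.status.value,
                species_id=res.species_id,
                binomial=res.binomial,
                charts_visited=list(res.charts_visited),
                trace=[[s.node_id, s.answer, s.target.ref] for s in res.trace],
                measurement_report=(
                    res.measurement_report.to_dict()
                    if res.measurement_report is not None
                    else None
                ),
                error=None,
            )
        except (UndeclaredStateError, UnknownNodeError, DeadEndError, ValueError) as e:
            out.update(
                status="error",
                species_id=None,
                binomial=None,
                charts_visited=[],
                trace=[],
                measurement_report=None,
                error=str(e),
            )
        counts[out["status"]] = counts.get(out["status"], 0) + 1
        result.rows.append(out)
    result.counts = counts
    return result


def results_to_jsonl(result: BatchResult, path: Union[str, Path]) -> None:
    """Write batch results as JSON lines, one object per observation."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in result.rows:
            fh.write(json.dumps(row) + "\n")
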