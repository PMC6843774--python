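"""Typed data model of a single-access taxonomic key as a decision graph.

A key is a set of *charts* (pages of a flow chart), each holding a small
directed acyclic graph of :class:`DecisionNode` objects.  Every node asks one
question about a morphological character and maps each possible answer state
to an :class:`EdgeTarget`: another node in the same chart, the entry of
another chart, or a *species leaf*.  Reaching a leaf triggers a measurement
confirmation step against a :class:`SpeciesRecord` (see
:mod:`diatomkey.engine`); the model itself is content-agnostic and knows
nothing about diatoms.

Cycles are forbidden: the only loop in the method is the explicit global
restart after a failed measurement confirmation, which is engine behaviour,
never an edge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "KeyError_",
    "KeyStructureError",
    "UnknownNodeError",
    "UndeclaredStateError",
    "DeadEndError",
    "SpeciesNotFoundError",
    "TargetKind",
    "CharacterKind",
    "CharacterDef",
    "MeasurementSet",
    "EdgeTarget",
    "DecisionNode",
    "Chart",
    "FlowChart",
    "Interval",
    "SpeciesRecord",
    "SpeciesDB",
    "Observation",
    "TraceStep",
    "Status",
    "IdentificationResult",
    "node_successor",
    "enumerate_leaves",
    "paths_for_species",
]


# ---------------------------------------------------------------------------
# errors


class KeyError_(Exception):
    """Base class for all key-model failures."""


class KeyStructureError(KeyError_):
    """The key violates a structural invariant (dangling reference, cycle...)."""


class UnknownNodeError(KeyError_):
    """A node_id does not exist in the key."""


class UndeclaredStateError(KeyError_):
    """An answer token is not a declared state of the node's character."""


class DeadEndError(KeyError_):
    """An answer is a declared state but the node maps no edge for it."""


class SpeciesNotFoundError(KeyError_):
    """A species_id is not a leaf of the key / not in the species table."""


# ---------------------------------------------------------------------------
# enums


class TargetKind(str, enum.Enum):
    """What an answer edge points at."""

    NODE = "node"          # another decision node in the same chart
    CHART = "chart"        # the entry node of another chart
    SPECIES = "species"    # a species leaf (identification candidate)


class CharacterKind(str, enum.Enum):
    CATEGORICAL = "categorical"
    MEASUREMENT = "measurement"


class Status(str, enum.Enum):
    """Outcome of one identification attempt."""

    IDENTIFIED = "identified"
    NO_MATCH_RESTART = "no_match_restart"
    UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# character & measurement types


@dataclass(frozen=True)
class CharacterDef:
    """One distinctive morphological character.

    A categorical character declares the finite vocabulary of answer states
    its questions may use; individual nodes ask with a subset of those
    states.  A measurement character has no states — it is consulted only in
    the terminal measurement-confirmation step.
    """

    character_id: str
    name: str
    kind: CharacterKind = CharacterKind.CATEGORICAL
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is CharacterKind.CATEGORICAL and not self.states:
            raise ValueError(
                f"categorical character {self.character_id!r} declares no states"
            )
        if self.kind is CharacterKind.MEASUREMENT and self.states:
            raise ValueError(
                f"measurement character {self.character_id!r} must not declare states"
            )
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"duplicate states on character {self.character_id!r}")


MEASUREMENT_FIELDS = ("length_um", "width_um", "striae_per_10um", "fibulae_per_10um")


@dataclass(frozen=True)
class MeasurementSet:
    """Measurements taken from one specimen image, in micrometres.

    ``striae_per_10um`` and ``fibulae_per_10um`` are densities per 10 µm and
    are alternatives: a taxon shows one or the other, rarely both.
    """

    length_um: Optional[float] = None
    width_um: Optional[float] = None
    striae_per_10um: Optional[float] = None
    fibulae_per_10um: Optional[float] = None

    def __post_init__(self) -> None:
        for name in MEASUREMENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def present_fields(self) -> tuple[str, ...]:
        return tuple(f for f in MEASUREMENT_FIELDS if getattr(self, f) is not None)

    def is_empty(self) -> bool:
        return not self.present_fields()


# ---------------------------------------------------------------------------
# graph types


@dataclass(frozen=True)
class EdgeTarget:
    """Destination of one answer edge."""

    kind: TargetKind
    ref: str

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("EdgeTarget.ref must be a non-empty token")

    @staticmethod
    def node(ref: str) -> "EdgeTarget":
        return EdgeTarget(TargetKind.NODE, ref)

    @staticmethod
    def chart(ref: str) -> "EdgeTarget":
        return EdgeTarget(TargetKind.CHART, ref)

    @staticmethod
    def species(ref: str) -> "EdgeTarget":
        return EdgeTarget(TargetKind.SPECIES, ref)


@dataclass(frozen=True)
class DecisionNode:
    """One question of the key: a character asked with a set of answer edges.

    ``edges`` maps answer-state tokens to targets.  A declared state of the
    character *may* lack an edge (a branch the key's author left open); the
    engine treats that as an unresolvable dead end, not an error.
    ``reconstructed`` marks couplets whose placement was inferred from
    standard flora characters rather than narrated explicitly.
    """

    node_id: str
    chart_id: str
    character_id: str
    prompt: str
    edges: Mapping[str, EdgeTarget]
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError(f"node {self.node_id!r} has no edges")
        object.__setattr__(self, "edges", dict(self.edges))


@dataclass(frozen=True)
class Chart:
    """One page of the flow chart, scoped to a genus/family group."""

    chart_id: str
    title: str
    entry_node: str


@dataclass
class FlowChart:
    """The full decision graph: characters, charts, nodes, and an entry chart.

    Reference integrity (every edge target resolves, entry nodes belong to
    their chart, answer states are declared) is enforced by
    :meth:`check_references`, which loaders call; deeper structural analysis
    (reachability, acyclicity) lives in :mod:`diatomkey.validator`.
    """

    characters: dict[str, CharacterDef]
    charts: dict[str, Chart]
    nodes: dict[str, DecisionNode]
    entry_chart: str
    meta: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def build(
        cls,
        characters: Iterable[CharacterDef],
        charts: Iterable[Chart],
        nodes: Iterable[DecisionNode],
        entry_chart: str,
        meta: Optional[dict] = None,
    ) -> "FlowChart":
        chars = {}
        for c in characters:
            if c.character_id in chars:
                raise KeyStructureError(f"duplicate character_id {c.character_id!r}")
            chars[c.character_id] = c
        chmap = {}
        for ch in charts:
            if ch.chart_id in chmap:
                raise KeyStructureError(f"duplicate chart_id {ch.chart_id!r}")
            chmap[ch.chart_id] = ch
        nmap = {}
        for n in nodes:
            if n.node_id in nmap:
                raise KeyStructureError(f"duplicate node_id {n.node_id!r}")
            nmap[n.node_id] = n
        key = cls(chars, chmap, nmap, entry_chart, dict(meta or {}))
        key.check_references()
        return key

    def check_references(self) -> None:
        """Raise :class:`KeyStructureError` on any dangling reference."""
        if self.entry_chart not in self.charts:
            raise KeyStructureError(f"entry chart {self.entry_chart!r} not defined")
        for ch in self.charts.values():
            entry = self.nodes.get(ch.entry_node)
            if entry is None:
                raise KeyStructureError(
                    f"chart {ch.chart_id}: entry node {ch.entry_node!r} not defined"
                )
            if entry.chart_id != ch.chart_id:
                raise KeyStructureError(
                    f"chart {ch.chart_id}: entry node {ch.entry_node!r} "
                    f"belongs to chart {entry.chart_id!r}"
                )
        for n in self.nodes.values():
            if n.chart_id not in self.charts:
                raise KeyStructureError(
                    f"node {n.node_id}: unknown chart {n.chart_id!r}"
                )
            char = self.characters.get(n.character_id)
            if char is None:
                raise KeyStructureError(
                    f"node {n.node_id}: unknown character {n.character_id!r}"
                )
            for state, tgt in n.edges.items():
                if state not in char.states:
                    raise KeyStructureError(
                        f"node {n.node_id}: answer {state!r} is not a declared "
                        f"state of character {char.character_id!r}"
                    )
                if tgt.kind is TargetKind.NODE:
                    dest = self.nodes.get(tgt.ref)
                    if dest is None:
                        raise KeyStructureError(
                            f"node {n.node_id}: edge {state!r} points at "
                            f"missing node {tgt.ref!r}"
                        )
                    if dest.chart_id != n.chart_id:
                        raise KeyStructureError(
                            f"node {n.node_id}: within-chart edge {state!r} "
                            f"crosses into chart {dest.chart_id!r}"
                        )
                elif tgt.kind is TargetKind.CHART:
                    if tgt.ref not in self.charts:
                        raise KeyStructureError(
                            f"node {n.node_id}: edge {state!r} points at "
                            f"missing chart {tgt.ref!r}"
                        )
                # species refs are resolved against a SpeciesDB by the validator

    # -- graph views ----------------------------------------------------------

    @property
    def entry_node(self) -> DecisionNode:
        return self.nodes[self.charts[self.entry_chart].entry_node]

    def resolve(self, target: EdgeTarget) -> Optional[DecisionNode]:
        """Next decision node a target leads to, or None for a species leaf."""
        if target.kind is TargetKind.NODE:
            return self.nodes[target.ref]
        if target.kind is TargetKind.CHART:
            return self.nodes[self.charts[target.ref].entry_node]
        return None

    def node_digraph(self) -> "nx.DiGraph":
        """Node-level directed graph; goto-chart edges land on chart entries.

        Dangling targets are skipped — this is a structural view the
        validator uses even on broken keys, where it reports the dangling
        edges separately.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n in self.nodes.values():
            for state, tgt in n.edges.items():
                if tgt.kind is TargetKind.SPECIES:
                    continue
                if tgt.kind is TargetKind.NODE:
                    dest = tgt.ref if tgt.ref in self.nodes else None
                else:
                    ch = self.charts.get(tgt.ref)
                    dest = ch.entry_node if ch and ch.entry_node in self.nodes else None
                if dest is not None:
                    g.add_edge(n.node_id, dest, answer=state)
        return g

    def iter_leaf_edges(self) -> Iterator[tuple[DecisionNode, str, str]]:
        """Yield (node, answer, species_id) for every species-leaf edge."""
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            for state in sorted(n.edges):
                tgt = n.edges[state]
                if tgt.kind is TargetKind.SPECIES:
                    yield n, state, tgt.ref


# ---------------------------------------------------------------------------
# species table types


@dataclass(frozen=True)
class Interval:
    """Closed interval [lo, hi]; floras print inclusive min–max ranges."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper {self.hi}")

    def contains(self, x: float, tolerance: float = 0.0) -> bool:
        """Membership with optional symmetric relative tolerance."""
        lo = self.lo * (1.0 - tolerance)
        hi = self.hi * (1.0 + tolerance)
        return lo <= x <= hi


RANGE_FIELDS = {
    "length_um": "length_range_um",
    "width_um": "width_range_um",
    "striae_per_10um": "striae_range_per_10um",
    "fibulae_per_10um": "fibulae_range_per_10um",
}


@dataclass(frozen=True)
class SpeciesRecord:
    """Taxon identity plus the measurement ranges used for confirmation."""

    species_id: str
    binomial: str
    genus: str
    length_range_um: Optional[Interval] = None
    width_range_um: Optional[Interval] = None
    striae_range_per_10um: Optional[Interval] = None
    fibulae_range_per_10um: Optional[Interval] = None
    family: Optional[str] = None
    ecology_tag: Optional[str] = None
    synonyms: tuple[str, ...] = ()
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genus != self.binomial.split()[0]:
            raise ValueError(
                f"{self.species_id}: genus {self.genus!r} is not the first "
                f"word of binomial {self.binomial!r}"
            )
        if self.ecology_tag is not None and self.ecology_tag not in (
            "oligotrophic",
            "mesotrophic",
            "eutrophic",
            "unknown",
        ):
            raise ValueError(f"{self.species_id}: bad ecology_tag {self.ecology_tag!r}")

    def range_for(self, measurement_field: str) -> Optional[Interval]:
        return getattr(self, RANGE_FIELDS[measurement_field])


@dataclass
class SpeciesDB:
    """Species table indexed by species_id and by genus."""

    records: dict[str, SpeciesRecord]

    @classmethod
    def build(cls, records: Iterable[SpeciesRecord]) -> "SpeciesDB":
        out: dict[str, SpeciesRecord] = {}
        for r in records:
            if r.species_id in out:
                raise ValueError(f"duplicate species_id {r.species_id!r}")
            out[r.species_id] = r
        return cls(out)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.records

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        try:
            return self.records[species_id]
        except KeyError:
            raise SpeciesNotFoundError(
                f"species {species_id!r} not in the species table"
            ) from None

    def genera(self) -> tuple[str, ...]:
        return tuple(sorted({r.genus for r in self.records.values()}))

    def by_genus(self, genus: str) -> tuple[SpeciesRecord, ...]:
        return tuple(
            self.records[sid]
            for sid in sorted(self.records)
            if self.records[sid].genus == genus
        )


# ---------------------------------------------------------------------------
# observation & result types


@dataclass(frozen=True)
class Observation:
    """Character-state answers plus measurements for one specimen image.

    Answers are keyed by ``node_id`` (not character_id): the same character
    is asked with different state subsets in different charts, so node-level
    keying avoids collisions.
    """

    answers: Mapping[str, str]
    measurements: MeasurementSet = MeasurementSet(length_um=1.0)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "answers", dict(self.answers))


@dataclass(frozen=True)
class TraceStep:
    """One traversal step: the node asked, the answer given, the target taken."""

    node_id: str
    answer: str
    target: EdgeTarget


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of one identification attempt with its full traversal trace."""

    status: Status
    trace: tuple[TraceStep, ...]
    charts_visited: tuple[str, ...]
    species_id: Optional[str] = None
    binomial: Optional[str] = None
    measurement_report: Optional[object] = None  # engine.MatchReport
    excluded_tried: tuple[str, ...] = ()
    frontier_candidates: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if (self.status is Status.IDENTIFIED) != (self.species_id is not None):
            raise ValueError("species_id present iff status is identified")


# ---------------------------------------------------------------------------
# operations


def node_successor(key: FlowChart, node_id: str, answer: str) -> EdgeTarget:
    """Target of the edge an answer selects at a node.

    Raises :class:`UnknownNodeError` for a missing node,
    :class:`UndeclaredStateError` when the answer is not a state of the
    node's character, and :class:`DeadEndError` when the state is declared
    but the node maps no edge for it.
    """
    node = key.nodes.get(node_id)
    if node is None:
        raise UnknownNodeError(f"no node {node_id!r} in the key")
    target = node.edges.get(answer)
    if target is not None:
        return target
    char = key.characters[node.character_id]
    if answer not in char.states:
        raise UndeclaredStateError(
            f"{answer!r} is not a declared state of character "
            f"{char.character_id!r} asked at node {node_id!r} "
            f"(declared: {', '.join(char.states)})"
        )
    raise DeadEndError(
        f"node {node_id!r} maps no branch for declared state {answer!r}"
    )


def enumerate_leaves(key: FlowChart, within_chart: Optional[str] = None) -> set[str]:
    """Set of species_ids appearing as species-leaf targets in the key.

    ``within_chart`` restricts the census to the nodes of one chart.
    """
    out: set[str] = set()
    for node, _state, species_id in key.iter_leaf_edges():
        if within_chart is None or node.chart_id == within_chart:
            out.add(species_id)
    return out


def _dfs_paths(
    key: FlowChart, start: DecisionNode
) -> Iterator[tuple[tuple[TraceStep, ...], str]]:
    """All root-to-leaf answer paths from ``start``, lexicographic by answer.

    Yields (trace, species_id).  The key must be acyclic; a cycle would make
    this recursion diverge, so loaders/validators guarantee acyclicity first.
    """
    stack: list[TraceStep] = []

    def rec(node: DecisionNode) -> Iterator[tuple[tuple[TraceStep, ...], str]]:
        for state in sorted(node.edges):
            tgt = node.edges[state]
            stack.append(TraceStep(node.node_id, state, tgt))
            if tgt.kind is TargetKind.SPECIES:
                yield tuple(stack), tgt.ref
            else:
                nxt = key.resolve(tgt)
                assert nxt is not None
                yield from rec(nxt)
            stack.pop()

    yield from rec(start)


def paths_for_species(key: FlowChart, species_id: str) -> list[tuple[TraceStep, ...]]:
    """All answer sequences from the key's entry to a leaf for one species.

    Exhaustive depth-first enumeration in deterministic order (edges visited
    lexicographically by answer token, so paths come out lexicographically
    by their (node, answer) sequence).  Species that can be reached through
    several charts — e.g. a taxon keyed out in girdle view, in valve view
    without raphe, and in valve view with raphe — yield one path per route.
    """
    if species_id not in enumerate_leaves(key):
        raise SpeciesNotFoundError(f"{species_id!r} is not a leaf of this key")
    return [
        trace
        for trace, sid in _dfs_paths(key, key.entry_node)
        if sid == species_id
    ]


def all_leaf_paths(key: FlowChart) -> list[tuple[tuple[TraceStep, ...], str]]:
    """Every root-to-leaf path with its species, in deterministic order."""
    return list(_dfs_paths(key, key.entry_node))


def charts_of_trace(trace: Sequence[TraceStep], key: FlowChart) -> tuple[str, ...]:
    """Ordered chart_ids a trace passes through (consecutive duplicates merged)."""
    out: list[str] = []
    for step in trace:
        cid = key.nodes[step.node_id].chart_id
        if not out or out[-1] != cid:
            out.append(cid)
    return tuple(out)
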