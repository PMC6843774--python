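"""Static analysis of a key + species table pair.

Error codes (structural breaks) and warning codes (completeness gaps):

====  ========================================================
E1    dangling edge (target node/chart/species missing)
E2    duplicate or undeclared answer state at a node
E3    node unreachable from the entry chart's entry node
E4    leaf species missing from the species table
E5    directed cycle in the decision graph
E6    chart with no incoming transition (other than the entry)
W1    species in the table that is never a leaf of the key
W2    declared character state never used by any node
W3    declared state with no branch at a node (dead end)
====  ========================================================

A key passes all structural invariants of the model exactly when its report
carries zero error-severity findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .content import ChartGraph, chart_graph
from .model import (
    FlowChart,
    SpeciesDB,
    Status,
    TargetKind,
    enumerate_leaves,
    paths_for_species,
)

__all__ = ["Finding", "ValidationReport", "validate", "check_chart_graph",
           "roundtrip_audit"]


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    location: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors()

    def add(self, severity: str, code: str, location: str, message: str) -> None:
        self.findings.append(Finding(severity, code, location, message))

    def to_dict(self) -> dict:
        return {
            "findings": [
                {"severity": f.severity, "code": f.code,
                 "location": f.location, "message": f.message}
                for f in self.findings
            ],
            "stats": dict(self.stats),
        }

    def render(self) -> str:
        lines = []
        for f in self.findings:
            lines.append(f"{f.severity.upper():7s} {f.code} {f.location}: {f.message}")
        for k in sorted(self.stats):
            lines.append(f"stat    {k} = {self.stats[k]}")
        lines.append("result  " + ("PASS (0 errors)" if self.ok else "FAIL"))
        return "\n".join(lines)


def validate(key: FlowChart, db: Optional[SpeciesDB] = None) -> ValidationReport:
    """Full structural + reconciliation check; findings, never exceptions."""
    rep = ValidationReport()

    # E1/E2: edge-level integrity (load_key enforces these too, but a key
    # built in memory may bypass the loader)
    for nid in sorted(key.nodes):
        node = key.nodes[nid]
        char = key.characters.get(node.character_id)
        if char is None:
            rep.add("error", "E1", nid, f"unknown character {node.character_id!r}")
            continue
        for state in sorted(node.edges):
            tgt = node.edges[state]
            if state not in char.states:
                rep.add("error", "E2", f"{nid}.{state}",
                        f"answer {state!r} not a declared state of {char.character_id!r}")
            if tgt.kind is TargetKind.NODE and tgt.ref not in key.nodes:
                rep.add("error", "E1", f"{nid}.{state}",
                        f"edge points at missing node {tgt.ref!r}")
            elif tgt.kind is TargetKind.CHART and tgt.ref not in key.charts:
                rep.add("error", "E1", f"{nid}.{state}",
                        f"edge points at missing chart {tgt.ref!r}")
            elif tgt.kind is TargetKind.SPECIES and db is not None and tgt.ref not in db:
                rep.add("error", "E4", f"{nid}.{state}",
                        f"leaf species {tgt.ref!r} missing from the species table")
        # W3: a couplet the key's author left open — the node asks a
        # question but encodes only one branch, so the sibling states are
        # dead ends the engine reports as unresolved
        if len(node.edges) == 1 and len(char.states) > 1:
            unmapped = [s for s in char.states if s not in node.edges]
            rep.add("warning", "W3", nid,
                    f"single-branch couplet; dead-end states possible "
                    f"(e.g. {unmapped[0]!r})")

    # E5: cycles (within-chart edges plus goto-chart transitions)
    g = key.node_digraph()
    try:
        cycle = nx.find_cycle(g)
        rep.add("error", "E5", cycle[0][0],
                "directed cycle: " + " -> ".join(a for a, _ in cycle))
        acyclic = False
    except nx.NetworkXNoCycle:
        acyclic = True

    # E3: reachability from the entry node over the union graph
    entry = key.charts[key.entry_chart].entry_node if key.entry_chart in key.charts else None
    unreachable: list[str] = []
    if entry is not None and entry in g:
        reached = {entry} | nx.descendants(g, entry)
        unreachable = sorted(set(key.nodes) - reached)
        for nid in unreachable:
            rep.add("error", "E3", nid, "node unreachable from the entry node")

    # E6: chart-level incoming transitions
    cg = chart_graph(key)
    incoming = {b for _, b, _ in cg.transitions}
    for cid in sorted(key.charts):
        if cid != key.entry_chart and cid not in incoming:
            rep.add("error", "E6", cid, "chart has no incoming transition")

    leaves = enumerate_leaves(key)

    # W1/W2: completeness gaps
    if db is not None:
        for sid in sorted(db.records):
            if sid not in leaves:
                rep.add("warning", "W1", sid,
                        "species in the table is never a leaf of the key")
    used_states: dict[str, set] = {cid: set() for cid in key.characters}
    for node in key.nodes.values():
        used_states.setdefault(node.character_id, set()).update(node.edges)
    for cid in sorted(key.characters):
        char = key.characters[cid]
        for state in char.states:
            if state not in used_states[cid]:
                rep.add("warning", "W2", f"{cid}.{state}",
                        "declared state never used by any node")

    multi_path = 0
    if acyclic and not unreachable and entry is not None:
        for sid in sorted(leaves):
            if len(paths_for_species(key, sid)) > 1:
                multi_path += 1

    rep.stats = {
        "node_count": len(key.nodes),
        "chart_count": len(key.charts),
        "character_count": len(key.characters),
        "leaf_count": len(leaves),
        "species_reachable": len(leaves & set(db.records)) if db is not None else None,
        "genera_count": (
            len({db.records[s].genus for s in leaves if s in db}) if db is not None else None
        ),
        "unreachable_nodes": len(unreachable),
        "multi_path_species": multi_path,
    }
    return rep


def check_chart_graph(key: FlowChart, expected: ChartGraph) -> ValidationReport:
    """Symmetric difference of the induced vs the expected chart graph."""
    rep = ValidationReport()
    induced = chart_graph(key).pairs()
    wanted = expected.pairs()
    for a, b in sorted(induced - wanted):
        rep.add("error", "CG1", f"{a}->{b}", "induced transition not in the expected graph")
    for a, b in sorted(wanted - induced):
        rep.add("error", "CG2", f"{a}->{b}", "expected transition missing from the key")
    rep.stats = {
        "induced_transitions": len(induced),
        "expected_transitions": len(wanted),
        "difference": len(induced ^ wanted),
    }
    return rep


def roundtrip_audit(
    key: FlowChart,
    db: SpeciesDB,
    seeds: Iterable[int],
    noise=None,
) -> pd.DataFrame:
    """Generate-then-identify every species under every seed.

    For each (species, seed) a synthetic observation is generated (cycling
    over the species' paths by seed) and fed back through the engine; the
    table records which species was recovered.  With no noise every row
    must recover its own species.
    """
    from .engine import identify_observation
    from .synthetic import NoiseSpec, generate_observation

    rows = []
    leaves = sorted(enumerate_leaves(key))
    for sid in leaves:
        n_paths = len(paths_for_species(key, sid))
        for seed in seeds:
            spec = (noise or NoiseSpec()).with_seed_mixin(seed, sid)
            path_index = seed % n_paths
            obs = generate_observation(key, db, sid, path_index, spec)
            res = identify_observation(key, db, obs)
            rows.append(
                {
                    "species_id": sid,
                    "seed": seed,
                    "path_index": path_index,
                    "status": res.status.value,
                    "recovered": res.species_id,
                    "ok": res.status is Status.IDENTIFIED and res.species_id == sid,
                }
            )
    return pd.DataFrame(rows)
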