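"""The bundled Italian freshwater-diatom key and its species table.

Ships, under ``diatomkey/data/``:

* ``key.json`` (canonical) and ``key.yaml`` (equivalent surface syntax) —
  the 12-chart key over 11 distinctive characters;
* ``species.csv`` — 60 species / 25 genera with measurement ranges.
  The ranges are approximate values from the standard flora literature
  (marked ``provenance=flora_approx``); the chart path, not the range,
  selects the species, so these numbers only gate the final confirmation;
* ``chart_graph.json`` — the expected chart-level transition graph, used by
  :func:`diatomkey.validator.check_chart_graph`;
* ``worked_examples.csv`` — five specimen observations (batch-CSV form)
  transcribing the published example identifications: a Nitzschia
  capitellata, a Gomphonema olivaceum, an Encyonema caespitosum, a
  Cymatopleura solea and a Cyclotella ocellata.

The documents are regenerated by ``scripts/build_key.py``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import json

from .io import load_key, load_species_table
from .model import FlowChart, SpeciesDB, TargetKind

__all__ = [
    "ChartGraph",
    "data_path",
    "load_bundled_key",
    "load_bundled_species",
    "load_bundled_chart_graph",
    "worked_examples_path",
    "chart_graph",
    "chart_graph_dot",
]


@dataclass(frozen=True)
class ChartGraph:
    """Chart-level transition graph: (from_chart, to_chart, condition label)."""

    transitions: tuple[tuple[str, str, str], ...]

    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.transitions}

    def incoming(self, chart_id: str) -> tuple[tuple[str, str, str], ...]:
        return tuple(t for t in self.transitions if t[1] == chart_id)


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("diatomkey") / "data" / name)


def load_bundled_key(fmt: str = "json") -> FlowChart:
    """The shipped 12-chart diatom key (``fmt`` selects json or yaml mirror)."""
    if fmt not in ("json", "yaml"):
        raise ValueError("fmt must be 'json' or 'yaml'")
    return load_key(data_path(f"key.{fmt}"))


def load_bundled_species() -> SpeciesDB:
    """The shipped species table: 60 species in 25 genera."""
    return load_species_table(data_path("species.csv"))


def load_bundled_chart_graph() -> ChartGraph:
    """The expected chart-transition graph shipped alongside the key."""
    doc = json.loads(data_path("chart_graph.json").read_text(encoding="utf-8"))
    return ChartGraph(
        tuple(
            (t["from"], t["to"], t.get("condition", ""))
            for t in doc["transitions"]
        )
    )


def worked_examples_path() -> Path:
    """Batch CSV with the five published example specimens."""
    return data_path("worked_examples.csv")


def chart_graph(key: FlowChart) -> ChartGraph:
    """Chart-level transition graph induced by a key's goto-chart edges.

    One transition per (from_chart, to_chart, answer) triple, in
    deterministic (sorted) order.
    """
    seen = set()
    for nid in sorted(key.nodes):
        node = key.nodes[nid]
        for state in sorted(node.edges):
            tgt = node.edges[state]
            if tgt.kind is TargetKind.CHART:
                seen.add((node.chart_id, tgt.ref, state))
    return ChartGraph(tuple(sorted(seen)))


def chart_graph_dot(key: FlowChart) -> str:
    """Graphviz DOT rendering of the chart-transition graph."""
    cg = chart_graph(key)
    lines = ["digraph charts {", "  rankdir=TB;"]
    for cid in sorted(key.charts):
        title = key.charts[cid].title.replace('"', "'")
        lines.append(f'  {cid} [label="{cid}\\n{title}"];')
    for a, b, label in cg.transitions:
        lines.append(f'  {a} -> {b} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_chart_graph_dot(key: FlowChart, path: Union[str, Path]) -> None:
    Path(path).write_text(chart_graph_dot(key), encoding="utf-8")
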