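"""Readers and writers for key documents and species tables.

The canonical key document is JSON; YAML is accepted as an equivalent
surface syntax (chosen by file extension).  Top-level keys: ``characters``,
``charts``, ``nodes``, ``entry_chart``, ``meta``.  Schema violations are
reported with a path to the offending field, e.g. ``nodes[3].edges.linear``.

The species table is CSV with the fixed header documented in
:data:`SPECIES_COLUMNS`; empty cells mean an optional field is absent.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .model import (
    Chart,
    CharacterDef,
    CharacterKind,
    DecisionNode,
    EdgeTarget,
    FlowChart,
    Interval,
    KeyStructureError,
    SpeciesDB,
    SpeciesRecord,
    TargetKind,
)

__all__ = [
    "DocumentError",
    "SpeciesTableError",
    "SPECIES_COLUMNS",
    "load_key",
    "key_from_dict",
    "key_to_dict",
    "write_key",
    "load_species_table",
    "write_species_table",
]


class DocumentError(Exception):
    """A key document violates the schema; ``path`` locates the field."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class SpeciesTableError(Exception):
    """A species CSV violates its contract."""


# ---------------------------------------------------------------------------
# key documents

_TARGET_KINDS = {k.value for k in TargetKind}
_CHARACTER_KINDS = {k.value for k in CharacterKind}


def _expect(obj: Any, typ: type, path: str) -> Any:
    if not isinstance(obj, typ):
        raise DocumentError(path, f"expected {typ.__name__}, got {type(obj).__name__}")
    return obj


def _expect_token(obj: Any, path: str) -> str:
    s = _expect(obj, str, path)
    if not s:
        raise DocumentError(path, "empty token")
    return s


def key_from_dict(doc: dict) -> FlowChart:
    """Build a :class:`FlowChart` from a parsed key document.

    Raises :class:`DocumentError` on schema violations (with path-to-field)
    and :class:`~diatomkey.model.KeyStructureError` on dangling references.
    """
    _expect(doc, dict, "$")
    for required in ("characters", "charts", "nodes", "entry_chart"):
        if required not in doc:
            raise DocumentError("$", f"missing top-level key {required!r}")
    unknown = set(doc) - {"characters", "charts", "nodes", "entry_chart", "meta"}
    if unknown:
        raise DocumentError("$", f"unknown top-level keys: {sorted(unknown)}")

    characters = []
    for i, c in enumerate(_expect(doc["characters"], list, "characters")):
        p = f"characters[{i}]"
        _expect(c, dict, p)
        kind = c.get("kind", "categorical")
        if kind not in _CHARACTER_KINDS:
            raise DocumentError(f"{p}.kind", f"unknown character kind {kind!r}")
        states = _expect(c.get("states", []), list, f"{p}.states")
        try:
            characters.append(
                CharacterDef(
                    character_id=_expect_token(c.get("character_id"), f"{p}.character_id"),
                    name=_expect(c.get("name", ""), str, f"{p}.name"),
                    kind=CharacterKind(kind),
                    states=tuple(
                        _expect_token(s, f"{p}.states[{j}]") for j, s in enumerate(states)
                    ),
                )
            )
        except ValueError as e:
            raise DocumentError(p, str(e)) from None

    charts = []
    for i, ch in enumerate(_expect(doc["charts"], list, "charts")):
        p = f"charts[{i}]"
        _expect(ch, dict, p)
        charts.append(
            Chart(
                chart_id=_expect_token(ch.get("chart_id"), f"{p}.chart_id"),
                title=_expect(ch.get("title", ""), str, f"{p}.title"),
                entry_node=_expect_token(ch.get("entry_node"), f"{p}.entry_node"),
            )
        )

    nodes = []
    for i, n in enumerate(_expect(doc["nodes"], list, "nodes")):
        p = f"nodes[{i}]"
        _expect(n, dict, p)
        node_id = _expect_token(n.get("node_id"), f"{p}.node_id")
        edges_doc = _expect(n.get("edges"), dict, f"{p}.edges")
        if not edges_doc:
            raise DocumentError(f"{p}.edges", "node declares no edges")
        edges = {}
        for state, tgt in edges_doc.items():
            ep = f"{p}.edges.{state}"
            _expect(tgt, dict, ep)
            kind = tgt.get("kind")
            if kind not in _TARGET_KINDS:
                raise DocumentError(f"{ep}.kind", f"unknown target kind {kind!r}")
            edges[state] = EdgeTarget(
                TargetKind(kind), _expect_token(tgt.get("ref"), f"{ep}.ref")
            )
        nodes.append(
            DecisionNode(
                node_id=node_id,
                chart_id=_expect_token(n.get("chart_id"), f"{p}.chart_id"),
                character_id=_expect_token(n.get("character_id"), f"{p}.character_id"),
                prompt=_expect(n.get("prompt", ""), str, f"{p}.prompt"),
                edges=edges,
                reconstructed=bool(n.get("reconstructed", False)),
            )
        )

    entry_chart = _expect_token(doc["entry_chart"], "entry_chart")
    meta = _expect(doc.get("meta", {}), dict, "meta")
    return FlowChart.build(characters, charts, nodes, entry_chart, meta)


def key_to_dict(key: FlowChart) -> dict:
    """Serialize a key to its canonical document form (deterministic order)."""
    return {
        "meta": dict(key.meta),
        "entry_chart": key.entry_chart,
        "characters": [
            {
                "character_id": c.character_id,
                "name": c.name,
                "kind": c.kind.value,
                "states": list(c.states),
            }
            for c in (key.characters[cid] for cid in sorted(key.characters))
        ],
        "charts": [
            {"chart_id": ch.chart_id, "title": ch.title, "entry_node": ch.entry_node}
            for ch in (key.charts[cid] for cid in sorted(key.charts))
        ],
        "nodes": [
            {
                "node_id": n.node_id,
                "chart_id": n.chart_id,
                "character_id": n.character_id,
                "prompt": n.prompt,
                "reconstructed": n.reconstructed,
                "edges": {
                    s: {"kind": n.edges[s].kind.value, "ref": n.edges[s].ref}
                    for s in sorted(n.edges)
                },
            }
            for n in (key.nodes[nid] for nid in sorted(key.nodes))
        ],
    }


def _is_yaml(path: Path) -> bool:
    return path.suffix.lower() in (".yaml", ".yml")


def load_key(source: Union[str, Path, dict]) -> FlowChart:
    """Load a key from a JSON/YAML file path or an already-parsed mapping."""
    if isinstance(source, dict):
        return key_from_dict(source)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text) if _is_yaml(path) else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise DocumentError("$", f"cannot parse {path.name}: {e}") from e
    return key_from_dict(doc)


def write_key(key: FlowChart, path: Union[str, Path]) -> None:
    """Write a key document; format follows the file extension."""
    path = Path(path)
    doc = key_to_dict(key)
    if _is_yaml(path):
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# species tables

SPECIES_COLUMNS = (
    "species_id",
    "binomial",
    "genus",
    "family",
    "length_min_um",
    "length_max_um",
    "width_min_um",
    "width_max_um",
    "striae_min_10um",
    "striae_max_10um",
    "fibulae_min_10um",
    "fibulae_max_10um",
    "ecology_tag",
)
# provenance/synonyms are optional annotation columns on top of the contract
_OPTIONAL_COLUMNS = ("synonyms", "provenance")

_RANGE_COLS = {
    "length_range_um": ("length_min_um", "length_max_um"),
    "width_range_um": ("width_min_um", "width_max_um"),
    "striae_range_per_10um": ("striae_min_10um", "striae_max_10um"),
    "fibulae_range_per_10um": ("fibulae_min_10um", "fibulae_max_10um"),
}


def _parse_interval(row: dict, lo_col: str, hi_col: str, where: str) -> Optional[Interval]:
    lo_s, hi_s = (row.get(lo_col) or "").strip(), (row.get(hi_col) or "").strip()
    if not lo_s and not hi_s:
        return None
    if not lo_s or not hi_s:
        raise SpeciesTableError(f"{where}: {lo_col}/{hi_col} must both be set or both empty")
    try:
        lo, hi = float(lo_s), float(hi_s)
    except ValueError:
        raise SpeciesTableError(f"{where}: non-numeric bound in {lo_col}/{hi_col}") from None
    if lo > hi:
        raise SpeciesTableError(f"{where}: malformed interval {lo_col}={lo} > {hi_col}={hi}")
    if lo <= 0:
        raise SpeciesTableError(f"{where}: bounds must be positive in {lo_col}")
    return Interval(lo, hi)


def load_species_table(source: Union[str, Path, _io.TextIOBase]) -> SpeciesDB:
    """Load and validate a species CSV into a :class:`SpeciesDB`."""
    if isinstance(source, (str, Path)):
        fh: Any = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        unknown = [c for c in header if c not in SPECIES_COLUMNS + _OPTIONAL_COLUMNS]
        if unknown:
            raise SpeciesTableError(f"unknown column(s): {unknown}")
        missing = [c for c in SPECIES_COLUMNS if c not in header]
        if missing:
            raise SpeciesTableError(f"missing column(s): {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("species_id") or "").strip()
            where = f"line {lineno} ({sid or '?'})"
            if not sid:
                raise SpeciesTableError(f"{where}: empty species_id")
            intervals = {
                field: _parse_interval(row, lo, hi, where)
                for field, (lo, hi) in _RANGE_COLS.items()
            }
            synonyms = tuple(
                s.strip() for s in (row.get("synonyms") or "").split(";") if s.strip()
            )
            try:
                records.append(
                    SpeciesRecord(
                        species_id=sid,
                        binomial=(row.get("binomial") or "").strip(),
                        genus=(row.get("genus") or "").strip(),
                        family=(row.get("family") or "").strip() or None,
                        ecology_tag=(row.get("ecology_tag") or "").strip() or None,
                        synonyms=synonyms,
                        provenance=(row.get("provenance") or "").strip() or None,
                        **intervals,
                    )
                )
            except ValueError as e:
                raise SpeciesTableError(f"{where}: {e}") from None
        try:
            return SpeciesDB.build(records)
        except ValueError as e:
            raise SpeciesTableError(str(e)) from None
    finally:
        if close:
            fh.close()


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_species_table(db: SpeciesDB, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SPECIES_COLUMNS + _OPTIONAL_COLUMNS)
        for sid in sorted(db.records):
            r = db.records[sid]
            row = [r.species_id, r.binomial, r.genus, r.family or ""]
            for field in ("length_range_um", "width_range_um",
                          "striae_range_per_10um", "fibulae_range_per_10um"):
                iv: Optional[Interval] = getattr(r, field)
                row += [_fmt(iv.lo if iv else None), _fmt(iv.hi if iv else None)]
            row += [r.ecology_tag or "", ";".join(r.synonyms), r.provenance or ""]
            w.writerow(row)
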