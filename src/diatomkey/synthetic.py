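"""Synthetic observations and toy keys with known ground truth.

Observations are generated by inverting the identification procedure: pick
one of a species' root-to-leaf answer paths, emit exactly its answer
sequence, and draw measurements uniformly within the species' ranges.
Noise then degrades the observation in controlled ways — pushing a
measurement beyond an interval bound, or blanking answers to ``unknown`` —
so that failure modes (restart, unresolved) can be exercised with exact
expectations.  Everything is reproducible from the integer seed.

Toy keys are random valid keys (random chart chain, random couplet trees,
non-overlapping species intervals) for property tests: they validate with
zero errors by construction, at any size.
"""

from __future__ import annotations

import csv
import io
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model import (
    Chart,
    CharacterDef,
    CharacterKind,
    DecisionNode,
    EdgeTarget,
    FlowChart,
    Interval,
    MEASUREMENT_FIELDS,
    MeasurementSet,
    Observation,
    SpeciesDB,
    SpeciesRecord,
    SpeciesNotFoundError,
    paths_for_species,
)

__all__ = [
    "NoiseSpec",
    "generate_observation",
    "generate_observation_table",
    "toy_key",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Degradation applied to a generated observation.

    measurement_jitter: unused headroom fraction of each interval kept away
        from the bounds when drawing in-range values (0 draws over the full
        closed interval).
    out_of_range_prob: probability, per present measurement field, that the
        value is displaced beyond one of the interval bounds.
    unknown_prob: probability, per answer, of replacing it with "unknown".
    seed: RNG seed; identical spec => identical observation.
    """

    measurement_jitter: float = 0.0
    out_of_range_prob: float = 0.0
    unknown_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("out_of_range_prob", "unknown_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.measurement_jitter < 0 or self.measurement_jitter >= 0.5:
            raise ValueError("measurement_jitter must be in [0, 0.5)")

    def with_seed_mixin(self, seed: int, token: str) -> "NoiseSpec":
        """Derive a per-item spec deterministically from (seed, token)."""
        mixed = zlib.crc32(f"{self.seed}:{seed}:{token}".encode()) & 0x7FFFFFFF
        return replace(self, seed=mixed)


def _draw_measurements(
    rec: SpeciesRecord, rng: np.random.Generator, spec: NoiseSpec
) -> MeasurementSet:
    values = {}
    for fname in MEASUREMENT_FIELDS:
        interval: Optional[Interval] = rec.range_for(fname)
        if interval is None:
            continue
        lo, hi = interval.lo, interval.hi
        pad = spec.measurement_jitter * (hi - lo)
        value = rng.uniform(lo + pad, hi - pad) if hi > lo else lo
        if rng.random() < spec.out_of_range_prob:
            # displace beyond a bound; below keeps the value positive
            span = max(hi - lo, lo, 1.0)
            if rng.random() < 0.5 and lo - 0.5 * span > 0:
                value = lo - rng.uniform(0.1, 0.5) * span
            else:
                value = hi + rng.uniform(0.1, 0.5) * span
        values[fname] = round(value, 3)
    return MeasurementSet(**values)


def generate_observation(
    key: FlowChart,
    db: SpeciesDB,
    species_id: str,
    path_index: int = 0,
    noise: Optional[NoiseSpec] = None,
) -> Observation:
    """Observation whose answers follow one encoded path to a species leaf.

    ``path_index`` selects among the species' root-to-leaf paths (in the
    deterministic order of :func:`~diatomkey.model.paths_for_species`); the
    measurements are drawn within the species' ranges and then degraded per
    the noise spec.
    """
    spec = noise or NoiseSpec()
    paths = paths_for_species(key, species_id)
    if not 0 <= path_index < len(paths):
        raise SpeciesNotFoundError(
            f"path_index {path_index} out of range: {species_id!r} has "
            f"{len(paths)} path(s)"
        )
    rng = np.random.default_rng(spec.seed)
    answers = {}
    for step in paths[path_index]:
        if rng.random() < spec.unknown_prob:
            continue  # an absent answer reads back as "unknown"
        answers[step.node_id] = step.answer
    measurements = _draw_measurements(db[species_id], rng, spec)
    return Observation(
        answers=answers,
        measurements=measurements,
        label=f"{species_id}/path{path_index}/seed{spec.seed}",
    )


def generate_observation_table(
    key: FlowChart,
    db: SpeciesDB,
    n_per_species: int = 1,
    noise: Optional[NoiseSpec] = None,
    out: Union[str, Path, None] = None,
) -> str:
    """Batch observation CSV: ``n_per_species`` rows per leaf species.

    Rows cycle over each species' paths; labels encode the ground truth
    (``species_id/pathK/seedS``) for audit.  Returns the CSV text and
    optionally writes it to ``out``.  Byte-identical for identical seeds.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    spec = noise or NoiseSpec()
    from .model import enumerate_leaves

    leaves = sorted(enumerate_leaves(key))
    node_cols = sorted(key.nodes)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["label", *node_cols, *MEASUREMENT_FIELDS])
    for sid in leaves:
        n_paths = len(paths_for_species(key, sid))
        for k in range(n_per_species):
            sub = spec.with_seed_mixin(k, sid)
            obs = generate_observation(key, db, sid, k % n_paths, sub)
            row = [obs.label]
            row += [obs.answers.get(nid, "") for nid in node_cols]
            row += [
                "" if getattr(obs.measurements, f) is None
                else f"{getattr(obs.measurements, f):g}"
                for f in MEASUREMENT_FIELDS
            ]
            w.writerow(row)
    text = buf.getvalue()
    if out is not None:
        Path(out).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# toy keys


def toy_key(
    n_charts: int = 3,
    n_leaves: int = 6,
    seed: int = 0,
    max_fanout: int = 3,
) -> tuple[FlowChart, SpeciesDB]:
    """Random valid key + consistent species table with known structure.

    The chart-transition graph is a random tree rooted at the first chart;
    within each chart the couplets form a random tree.  Terminal slots are
    split between goto-chart transitions (one incoming per non-root chart)
    and the ``n_leaves`` species leaves, so the generated key validates
    with zero errors.  Species intervals are random, positive, and
    non-overlapping across species, making measurement confirmation
    discriminative.
    """
    if n_charts < 1 or n_leaves < 1:
        raise ValueError("need at least one chart and one leaf")
    if n_leaves < n_charts:  # every chart must hold at least one terminal
        raise ValueError("need n_leaves >= n_charts so every chart can key out")
    rng = np.random.default_rng(seed)

    chart_ids = [f"T{i+1}" for i in range(n_charts)]
    species_ids = [f"sp{i+1:03d}" for i in range(n_leaves)]

    # distribute species across charts, >=1 each
    owner = list(range(n_charts)) + list(
        rng.integers(0, n_charts, size=n_leaves - n_charts)
    )
    rng.shuffle(owner)
    chart_species: dict[str, list[str]] = {cid: [] for cid in chart_ids}
    for sp, ci in zip(species_ids, owner):
        chart_species[chart_ids[ci]].append(sp)

    # chart tree: chart i>0 hangs off a random earlier chart
    chart_children: dict[str, list[str]] = {cid: [] for cid in chart_ids}
    for i in range(1, n_charts):
        parent = chart_ids[int(rng.integers(0, i))]
        chart_children[parent].append(chart_ids[i])

    # one shared categorical character with enough states for any fanout
    n_states = max(max_fanout, 2)
    char = CharacterDef(
        "toy_character",
        "synthetic categorical character",
        states=tuple(f"state{i+1}" for i in range(n_states)),
    )

    nodes: list[DecisionNode] = []
    charts: list[Chart] = []

    def build_chart(cid: str) -> None:
        # terminal slots of this chart: its species + gotos to child charts
        slots: list[EdgeTarget] = [EdgeTarget.species(s) for s in chart_species[cid]]
        slots += [EdgeTarget.chart(c) for c in chart_children[cid]]
        counter = 0

        def grow(targets: list[EdgeTarget]) -> EdgeTarget:
            nonlocal counter
            if len(targets) == 1:
                return targets[0]
            fanout = int(rng.integers(2, min(max_fanout, len(targets)) + 1))
            cuts = sorted(
                rng.choice(np.arange(1, len(targets)), size=fanout - 1, replace=False)
            )
            groups = [targets[a:b] for a, b in
                      zip([0, *cuts], [*cuts, len(targets)])]
            counter += 1
            nid = f"{cid.lower()}_n{counter}"
            edges = {
                char.states[i]: grow(group) for i, group in enumerate(groups)
            }
            nodes.append(
                DecisionNode(nid, cid, char.character_id,
                             f"synthetic couplet {nid}", edges)
            )
            return EdgeTarget.node(nid)

        if len(slots) == 1:
            # a chart still needs an entry node: one-question couplet
            counter += 1
            nid = f"{cid.lower()}_n{counter}"
            nodes.append(
                DecisionNode(nid, cid, char.character_id,
                             f"synthetic couplet {nid}",
                             {char.states[0]: slots[0]})
            )
            entry = nid
        else:
            entry = grow(slots).ref
        charts.append(Chart(cid, f"synthetic chart {cid}", entry))

    for cid in chart_ids:
        build_chart(cid)

    key = FlowChart.build(
        [char,
         CharacterDef("measurements", "measurements",
                      kind=CharacterKind.MEASUREMENT)],
        charts,
        nodes,
        chart_ids[0],
        {"version": "toy", "provenance": f"synthetic toy key seed={seed}"},
    )

    # non-overlapping intervals: species i lives on [10i+1, 10i+6]
    records = []
    for i, sid in enumerate(species_ids):
        base = 10.0 * (i + 1)
        jitter = float(rng.uniform(0, 2))
        records.append(
            SpeciesRecord(
                species_id=sid,
                binomial=f"Toyspecies n{i+1}",
                genus="Toyspecies",
                length_range_um=Interval(base + jitter, base + jitter + 5.0),
                width_range_um=Interval(1.0 + i, 1.5 + i),
            )
        )
    return key, SpeciesDB.build(records)
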