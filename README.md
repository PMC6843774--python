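# diatomkey

A decision-graph engine for single-access taxonomic keys, bundled with a
12-chart flow-chart key to 60 common freshwater diatom species (25 genera)
of Italian watercourses.

Benthic diatoms are the standard phytobenthos element for assessing the
ecological status of rivers, and the assessment indices require
identification at species level — a slow, error-prone step that demands
iconographic floras and experience. This package implements that
identification procedure as software: a fixed sequence of questions about
11 distinctive characters of the silica frustule (symmetry and shape,
presence and position of the raphe, valve polarity, apices, central and
axial areas, fibulae or striae, punctae, pseudosepta, and measurements),
organised in 12 charts (C1–C12). Every route through the charts ends in
the same terminal step: *confirmation of measurements* — valve length,
width and the number of striae or fibulae in 10 µm are compared with the
closed ranges in a species table. If every compared measurement falls in
range the specimen is identified; if any falls outside, the method's rule
is to restart from the beginning of the flow chart.

Formally, the key is a directed acyclic graph. Each decision node *n*
asks one character with an edge map `answers(n): state → target`, where a
target is another node, the entry of another chart, or a species leaf.
An observation is a partial map `node_id → state` plus a measurement set
*m*; a leaf *s* confirms iff for every field *f* present in both *m* and
the species record, `lo_f ≤ m_f ≤ hi_f` (closed intervals, optional
relative tolerance). The same species may be a leaf in several charts —
e.g. *Rhoicosphenia abbreviata* keys out in girdle view (C1), in valve
view without raphe (C6) and with raphe (C10), and the monoraphid taxa
(*Achnanthidium*, *Cocconeis*) appear in both C7 (rapheless valve) and C9
(raphe valve) — so the engine treats species as reachable by multiple
root-to-leaf paths, not as unique tree leaves.

The package provides:

* `diatomkey.model` — the typed decision-graph model (characters, nodes,
  edges, charts, species records, observations) with `node_successor`,
  `enumerate_leaves` and `paths_for_species`;
* `diatomkey.content` — the bundled key (JSON canonical, YAML mirror),
  species table CSV, chart-transition graph and Graphviz export;
* `diatomkey.engine` — scripted, batch and interactive identification
  with measurement confirmation, the restart rule and
  `candidates_remaining` for partial observations;
* `diatomkey.validator` — static analysis (dangling edges, cycles,
  unreachable nodes, chart-graph conformance, key/table reconciliation)
  and a generate-then-identify round-trip audit;
* `diatomkey.synthetic` — synthetic observations with controllable noise
  and random valid toy keys with known ground truth;
* an `identify` command-line tool over all of the above.

## Worked example

The five specimens published with the method ship as a batch observation
table. Identifying them:

```python
from diatomkey import load_bundled_key, load_bundled_species, batch_identify
from diatomkey.content import worked_examples_path

key = load_bundled_key()
db = load_bundled_species()
result = batch_identify(key, db, worked_examples_path())
for row in result.rows:
    print(row["binomial"], row["charts_visited"])
print(result.counts)
```

prints

```
Nitzschia capitellata ['C1', 'C3', 'C5']
Gomphonema olivaceum ['C1', 'C3', 'C10']
Encyonema caespitosum ['C1', 'C3', 'C11']
Cymatopleura solea ['C1', 'C3', 'C12']
Cyclotella ocellata ['C1', 'C2']
{'identified': 5}
```

Specimen (a), for instance, is a valve in "other symmetry" (C1→C3) whose
raphe is held by fibulae and clearly visible on the valve margin only
(C3→C5, the *Nitzschia* chart); striae are not clearly visible, the valve
is linear with differentiated capitate/subrostrate apices and a slightly
convex central part, and its measurements (30 × 4.5 µm, 10 fibulae/10 µm)
fall inside the ranges of *Nitzschia capitellata* — so the chart sequence
is C1, C3, C5 and the status is `identified`. Had any measurement fallen
out of range, the status would be `no_match_restart`: the method restarts
from the beginning of the flow chart (interactively, with the failed
candidate excluded and a bounded restart budget).

The same run from the shell:

```
identify run --batch src/diatomkey/data/worked_examples.csv
identify validate --roundtrip 3
identify interactive
```

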