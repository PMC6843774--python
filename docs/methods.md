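# Methods

## The identification model

The engine implements a *single-access* key: identification is a walk
through a fixed decision graph, not a similarity search over a character
matrix. The graph is partitioned into 12 charts. Chart C1 is the entry:
it separates girdle-view from valve-view images and, for valve views,
Centrales (radiate/triangular symmetry, → C2) from Pennales (other
symmetry, → C3). C3 routes the pennate valves by the raphe: absent
(→ C6 striae, C7 irregular areas, C8 costae), on the valve surface in a
roughly central position (→ C9 bilateral, C10 heteropolar, C11
dorsoventral), or held by fibulae around the valve (→ C12 all around,
*Bacillaria paxillifera* central, C5 margin visible, C4 margin not
visible). The chart-transition graph is a tree rooted at C1; within each
chart the couplets form a tree as well, so every species-leaf edge is
reached by exactly one root path. Species may own several leaf edges
(multi-route taxa), which is how girdle-view identification and the
monoraphid raphe/rapheless valve pairs are represented without
duplicating species records.

Assumptions inherited from the method: the observer has one image (plus
measurements) of a single specimen; every question on the path can in
principle be answered from that image; and measurement ranges in the
species table are authoritative closed intervals. The model deliberately
contains no scoring, ranking or probabilistic matching — a wrong answer
leads to the wrong leaf or a dead end, exactly as with a printed key.

### Traversal semantics

* An answer must be a declared state of the asked character; anything
  else is a described failure (batch rows capture it without aborting).
* `unknown` stops the walk and reports the *frontier*: all species
  leaves still reachable from the stopped node (`candidates_remaining`
  generalises this to arbitrary partial answer sets).
* A declared state with no encoded branch (an *open couplet*) also stops
  the walk as `unresolved`. The bundled key has two such dead ends,
  flagged W3 by the validator: the triangular/quadrate centric branch in
  C2 and the heteropolar-without-pseudosepta branch in C6, both of which
  the key poses as questions but for which no bundled species exists.
* Reaching a leaf triggers measurement confirmation. All compared
  intervals are closed; endpoint values confirm. Striae and fibulae
  densities are alternatives and are only compared like-for-like; a field
  absent on either side is not compared and never counts against the
  candidate. An optional relative tolerance `t` widens every interval to
  `[lo·(1−t), hi·(1+t)]`; the default is `t = 0` (strict membership)
  because the method requires measurements to match, and tolerance is a
  practical extension, off by default.
* On mismatch the status is `no_match_restart`. A scripted observation
  cannot change between passes, so scripted mode stops there. Interactive
  mode implements the restart literally: the walk starts over with the
  failed candidate excluded and a restart budget (default 3), letting the
  user revise answers; an exhausted budget returns `unresolved` with the
  excluded-candidate history. Whether the original software re-prompts
  or only re-checks on restart is not specified; both behaviours exist
  here (`restart_on_mismatch`), with the scripted no-restart behaviour as
  the default because it is the only deterministic reading.

## Content decisions in the bundled key

The 60 species and their chart placement follow the per-chart species
lists of the published flow chart; the union of those lists is exactly 60
names in 25 genera. *Diatoma tenuis*, mentioned in passing in one
narrative, is not among the C8 species of that chart's list and is
therefore not a bundled leaf — including it would break the 60/25
totals. Spelling variants are resolved to one record each with the
variant kept as a synonym (`nitzschia_angusta` ~ "Nitzschia angustata";
`amphora_lybica` ~ "Amphora libyca"), and the four named varieties are
distinct records, as they are distinct leaves.

Where the narrative names only some couplets of a chart, the remaining
branch placements (e.g. *N. hungarica* opposite *N. constricta*, the C6
*Ulnaria*/*Staurosira* block, the C9 sub-branches, the C12 *Surirella*
block, and the raphe-absent routing C3 → C6/C7/C8) were reconstructed
from standard flora characters (Krammer & Lange-Bertalot volumes; the
Atlas of Benthic Diatoms of Italian Watercourses). Every such node
carries `reconstructed: true` in the key document; the package makes no
claim that these couplets reproduce the original figures verbatim.

Measurement ranges are not published with the flow chart. The shipped
`species.csv` carries approximate ranges from the flora literature,
marked per-row `provenance=flora_approx`. They are internally consistent
(positive, lo ≤ hi) and realistic, but users doing operational
monitoring should replace them with their laboratory's calibrated table —
the CSV contract and `load_species_table` exist for exactly that. No
engine correctness test depends on these numbers: the chart path, not
the range, selects the candidate, and numeric tests use synthetic tables.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tolerance` | 0.0 | relative widening of every measurement interval |
| `max_restarts` | 3 | extra interactive passes after a mismatch |
| `excluded` | ∅ | species the engine may not propose |
| `NoiseSpec.measurement_jitter` | 0.0 | fraction of each interval kept clear of the bounds when sampling in-range values |
| `NoiseSpec.out_of_range_prob` | 0.0 | per-field probability of displacing a value beyond a bound |
| `NoiseSpec.unknown_prob` | 0.0 | per-answer probability of blanking to `unknown` |
| `NoiseSpec.seed` | 0 | RNG seed; identical spec ⇒ identical observation |

## The synthetic generator

`generate_observation` inverts the procedure: it takes one of the
species' root-to-leaf paths verbatim as the answer set and samples
measurements uniformly inside the species' closed intervals, then applies
the noise spec (out-of-range displacement moves a value 10–50 % of the
interval span beyond a bound, below only when the result stays positive).
Uniform sampling is deliberate — the method only tests interval
membership, so modelling realistic morphometric distributions would add
nothing the engine could detect. What the generator does **not** emulate:
observer error on categorical characters (answers are path-perfect unless
blanked to `unknown`), correlated measurement errors, image quality, and
the overlap of real species' ranges. Passing round-trip tests therefore
show the engine faithfully executes the encoded key, not that the key
discriminates real Italian material; that discrimination power is a
property of the published chart content and the quality of the species
table.

`toy_key` generates random valid keys of any size (random chart tree,
random couplet trees, one incoming transition per non-root chart, species
intervals non-overlapping by construction) so engine properties can be
checked against a brute-force path-enumeration oracle on hundreds of
small keys, independent of the bundled content.

## Numerical and procedural choices

* Path order: `paths_for_species` visits edges lexicographically by
  answer token, so path lists are deterministic and lexicographic by
  their (node, answer) sequence.
* Answers are keyed by `node_id`, not character, because one character is
  asked with different state subsets in different charts.
* Sub-seeds for per-item randomness are derived with CRC32 over
  `seed:token` strings, keeping every derived seed below 2³¹ and making
  batch outputs byte-reproducible.
* Validation severities: structural breaks (dangling edges, duplicate
  states, unreachable nodes, missing leaf species, cycles, orphan charts)
  are errors; completeness gaps (species never keyed out, unused states,
  open couplets) are warnings, since the key format is designed to be
  extended with new species and charts.
* Reachability and acyclicity are computed over the union graph of
  within-chart edges and chart transitions (networkx); the global restart
  is engine behaviour, never an edge, which is what keeps the graph
  acyclic.

## Problem sizes used in tests

The default suite validates the full bundled key (55 nodes), re-identifies
the five published specimens, round-trips 60 species × 10 seeds (600
identifications), compares the engine with the brute-force oracle on 100
random toy keys of ≤ 20 nodes, and runs a 200-trial binomial calibration
of the out-of-range noise. All of it is pure graph traversal and runs in
a few seconds.

## Known limitations

* The reconstructed couplets are flora-consistent but not guaranteed to
  match the original figures word for word.
* The shipped measurement ranges are approximate literature values, not a
  calibrated dataset.
* No multi-access (matrix) identification, no ranking of near misses, no
  image processing, and no teratological-form charts; the key document
  format supports adding charts and species, which is the intended
  extension path.
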