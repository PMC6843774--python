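"""Regenerate the bundled key documents shipped in src/diatomkey/data/.

This is a maintenance script: the single source of truth for the Italian
freshwater-diatom key (charts C1–C12) lives here as Python, and the shipped
JSON/YAML/DOT/chart-graph artifacts are derived from it.  Run from the
repository root:

    python scripts/build_key.py

Couplets whose placement is inferred from standard flora characters rather
than narrated in full are built with r(...) and carry reconstructed=True in
node metadata.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from diatomkey.io import load_species_table, write_key  # noqa: E402
from diatomkey.model import (  # noqa: E402
    Chart,
    CharacterDef,
    CharacterKind,
    DecisionNode,
    EdgeTarget,
    FlowChart,
)
from diatomkey.validator import validate  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "src" / "diatomkey" / "data"

N = EdgeTarget.node
C = EdgeTarget.chart
S = EdgeTarget.species


# --- the 11 distinctive characters -----------------------------------------

CHARACTERS = [
    CharacterDef(
        "symmetry_shape",
        "Symmetry and shape of the frustule",
        states=(
            "girdle_view", "valve_view",
            "radiate_triangular", "other_symmetry",
            "bilateral_isopolar", "heteropolar", "dorsoventral",
            "circular", "triangular_quadrate",
            "cylindrical_chains", "cuneate_flexed",
            "sigmoidal", "linear", "lanceolate", "linear_lanceolate",
            "very_elongate_needle", "small_elliptic_cruciform",
            "elliptic", "cruciform", "oval", "rounded_rhombic",
            "small_linear", "small_elliptic", "small_elliptic_lanceolate",
            "elongate_narrow", "short_small",
            "elliptic_rhomboid", "elongate_constricted",
            "ovate", "small_linear_elliptic",
            "constricted", "not_constricted",
            "ventral_strongly_arcuate", "ventral_slightly_arcuate",
        ),
    ),
    CharacterDef(
        "raphe_presence",
        "Absence or presence of the raphe",
        states=("absent", "central_surface", "fibulae_around"),
    ),
    CharacterDef(
        "raphe_position",
        "Position of the raphe",
        states=(
            "all_around", "central", "margin_visible", "margin_not_visible",
            "near_ventral_margin", "central_position",
            "ends_at_apices", "ends_dorsal_side",
            "eccentric_fibulae_regular", "not_eccentric",
            "visible", "not_visible",
        ),
    ),
    CharacterDef(
        "valve_polarity",
        "Polarity of valves",
        states=("isopolar", "heteropolar"),
    ),
    CharacterDef(
        "apices",
        "Description of apices",
        states=(
            "capitate", "rostrate", "rounded", "subcapitate",
            "acuminate_with_central_notch", "rostrate_rounded_v_system",
            "differentiated_capitate_subrostrate", "not_differentiated",
            "rounded_headpole", "constricted_headpole",
        ),
    ),
    CharacterDef(
        "central_area",
        "Description of the central area",
        states=(
            "clearly_distinct", "not_distinct",
            "band", "small_round", "asymmetric_one_side",
            "expanded_one_side", "expanded_both_sides",
            "central_fascia_present", "central_fascia_absent",
            "rectangular_fascia", "small_rounded",
            "stigma_present", "stigma_absent",
            "central_node_present", "central_node_absent",
            "slightly_convex", "straight",
            "hyaline_dorsal_area", "no_hyaline_area",
        ),
    ),
    CharacterDef(
        "axial_area",
        "Description of the axial area",
        states=(
            "horseshoe_on_central_valve",
            "linear_axial_absent_central", "linear_axial_small_central",
            "canal_present", "canal_absent",
            "undulate_valve_face", "longitudinal_hyaline_canal",
        ),
    ),
    CharacterDef(
        "striae_fibulae",
        "Presence of fibulae or striae",
        states=(
            "ornament_present", "ornament_absent",
            "striae", "irregular_areas", "costae",
            "striae_clearly_visible", "striae_not_clearly_visible",
            "fine", "coarse", "striae_fine", "striae_coarse",
            "interrupted_by_hyaline_ring", "not_interrupted",
        ),
    ),
    CharacterDef(
        "punctae",
        "Presence of punctae",
        states=("regular_no_punctae", "irregular_with_punctae"),
    ),
    CharacterDef(
        "pseudosepta",
        "Presence of pseudosepta",
        states=("present", "absent"),
    ),
    CharacterDef(
        "measurements",
        "Measurements (valve length, width and striae or fibulae per 10 um)",
        kind=CharacterKind.MEASUREMENT,
    ),
]


# --- charts -----------------------------------------------------------------

CHARTS = [
    Chart("C1", "Melosira and Rhoicosphenia (entry; girdle vs valve view)", "c1_view"),
    Chart("C2", "Cyclotella and Melosira (Centrales)", "c2_shape"),
    Chart("C3", "Bacillariaceae, Surirellaceae and Rhopalodiaceae (Pennales entry)", "c3_raphe"),
    Chart("C4", "Rhopalodia and Epithemia", "c4_form"),
    Chart("C5", "Nitzschia", "c5_striae"),
    Chart("C6", "Rhoicosphenia, Fragilaria, Ulnaria, Staurosira and Pseudostaurosira", "c6_polarity"),
    Chart("C7", "Planothidium, Achnanthidium and Cocconeis (araphid valves)", "c7_area"),
    Chart("C8", "Diatoma and Meridion (costae)", "c8_polarity"),
    Chart("C9", "Achnanthidium, Eolimna, Sellaphora, Navicula and Cocconeis", "c9_shape"),
    Chart("C10", "Gomphonema and Rhoicosphenia (heteropolar, raphe)", "c10_stigma"),
    Chart("C11", "Amphora and Cymbella (dorsoventral, raphe)", "c11_raphe"),
    Chart("C12", "Cymatopleura and Surirella (raphe all around)", "c12_face"),
]


def n(node_id, chart_id, character_id, prompt, edges, reconstructed=False):
    return DecisionNode(node_id, chart_id, character_id, prompt, edges, reconstructed)


def r(node_id, chart_id, character_id, prompt, edges):
    return n(node_id, chart_id, character_id, prompt, edges, reconstructed=True)


NODES = [
    # --- C1: entry; girdle-view taxa and the Centrales/Pennales split -------
    n("c1_view", "C1", "symmetry_shape",
      "Is the frustule seen in girdle (lateral) or valve (frontal) view?",
      {"girdle_view": N("c1_girdle_shape"), "valve_view": N("c1_symmetry")}),
    n("c1_girdle_shape", "C1", "symmetry_shape",
      "Girdle view: frustule cylindrical, forming chains, or cuneate/flexed?",
      {"cylindrical_chains": S("melosira_varians"),
       "cuneate_flexed": S("rhoicosphenia_abbreviata")}),
    n("c1_symmetry", "C1", "symmetry_shape",
      "Valve symmetry: radiate/triangular (Centrales) or other symmetry (Pennales)?",
      {"radiate_triangular": C("C2"), "other_symmetry": C("C3")}),

    # --- C2: Centrales -------------------------------------------------------
    n("c2_shape", "C2", "symmetry_shape",
      "Valve shape: circular, or triangular/quadrate?",
      {"circular": N("c2_ornament")}),  # triangular_quadrate: no species encoded
    n("c2_ornament", "C2", "striae_fibulae",
      "Ornament on the valve face: present or absent?",
      {"ornament_present": N("c2_zone"), "ornament_absent": S("melosira_varians")}),
    n("c2_zone", "C2", "central_area",
      "Central zone clearly distinct from the marginal zone?",
      {"clearly_distinct": N("c2_pattern"), "not_distinct": S("cyclotella_comta")}),
    n("c2_pattern", "C2", "punctae",
      "Central zone regular, or irregular with punctae?",
      {"regular_no_punctae": S("cyclotella_meneghiniana"),
       "irregular_with_punctae": S("cyclotella_ocellata")}),

    # --- C3: Pennales entry --------------------------------------------------
    n("c3_raphe", "C3", "raphe_presence",
      "Raphe: absent; on the valve surface in roughly central position; or "
      "partially/totally around the valve and held by fibulae?",
      {"absent": N("c3_araphid"),
       "central_surface": N("c3_symmetry"),
       "fibulae_around": N("c3_fibulae")}),
    r("c3_araphid", "C3", "striae_fibulae",
      "Valve without raphe: ornamented with striae, irregular hyaline areas, or costae?",
      {"striae": C("C6"), "irregular_areas": C("C7"), "costae": C("C8")}),
    n("c3_symmetry", "C3", "symmetry_shape",
      "Valve with central raphe: bilateral isopolar, heteropolar, or dorsoventral?",
      {"bilateral_isopolar": C("C9"), "heteropolar": C("C10"), "dorsoventral": C("C11")}),
    n("c3_fibulae", "C3", "raphe_position",
      "Raphe-fibulae system: all around the valve; central; or on the valve "
      "margin, clearly visible or not?",
      {"all_around": C("C12"),
       "central": S("bacillaria_paxillifera"),
       "margin_visible": C("C5"),
       "margin_not_visible": C("C4")}),

    # --- C4: Rhopalodiaceae --------------------------------------------------
    n("c4_form", "C4", "apices",
      "Valves isopolar: apices acuminate with a notch at valve centre, or apices "
      "rostrate/rounded with the raphe-fibulae system visible as a V at valve centre?",
      {"acuminate_with_central_notch": S("rhopalodia_gibba"),
       "rostrate_rounded_v_system": N("c4_margin")}),
    n("c4_margin", "C4", "symmetry_shape",
      "Ventral valve margin strongly arcuate (apices rostrate) or slightly "
      "arcuate (apices rostrate or capitate)?",
      {"ventral_strongly_arcuate": S("epithemia_sorex"),
       "ventral_slightly_arcuate": S("epithemia_adnata")}),

    # --- C5: Nitzschia -------------------------------------------------------
    n("c5_striae", "C5", "striae_fibulae",
      "Striae clearly visible on the valve surface, or not?",
      {"striae_clearly_visible": N("c5_canal"),
       "striae_not_clearly_visible": N("c5_eccentric")}),
    n("c5_canal", "C5", "axial_area",
      "Longitudinal hyaline canal present?",
      {"canal_present": N("c5_constriction"), "canal_absent": N("c5_raphe_margin")}),
    r("c5_constriction", "C5", "symmetry_shape",
      "Valves slightly or heavily constricted at the centre, or not constricted?",
      {"constricted": S("nitzschia_constricta"),
       "not_constricted": S("nitzschia_hungarica")}),
    n("c5_raphe_margin", "C5", "raphe_position",
      "Raphe clearly visible on the valve margin?",
      {"visible": N("c5_central_node"), "not_visible": N("c5_size")}),
    n("c5_central_node", "C5", "central_area",
      "Central node present? (if absent: valves linear/lanceolate, apices rostrate)",
      {"central_node_present": S("nitzschia_linearis"),
       "central_node_absent": S("nitzschia_amphibia")}),
    r("c5_size", "C5", "symmetry_shape",
      "Raphe not visible: measurements are the main factor — valve elongate and "
      "narrow, or short and small?",
      {"elongate_narrow": S("nitzschia_angusta"),
       "short_small": S("nitzschia_angustatula")}),
    n("c5_eccentric", "C5", "raphe_position",
      "Raphe system slightly eccentric towards the apices with regularly spaced "
      "fibulae?",
      {"eccentric_fibulae_regular": S("nitzschia_dissipata"),
       "not_eccentric": N("c5_outline")}),
    n("c5_outline", "C5", "symmetry_shape",
      "Striae not clearly countable: valve sigmoidal, linear, or lanceolate?",
      {"sigmoidal": N("c5_sigmoid"),
       "linear": N("c5_linear_apices"),
       "lanceolate": N("c5_lanceolate_apices")}),
    n("c5_sigmoid", "C5", "striae_fibulae",
      "Sigmoidal valve: striae fine or coarse?",
      {"fine": S("nitzschia_clausii"), "coarse": S("nitzschia_sigma")}),
    n("c5_linear_apices", "C5", "apices",
      "Linear valve: apices differentiated from the rest of the valve "
      "(capitate/subrostrate), or not differentiated?",
      {"not_differentiated": S("nitzschia_inconspicua"),
       "differentiated_capitate_subrostrate": N("c5_central_part")}),
    n("c5_central_part", "C5", "central_area",
      "Central part of the valve slightly convex, or straight?",
      {"slightly_convex": S("nitzschia_capitellata"),
       "straight": S("nitzschia_palea")}),
    r("c5_lanceolate_apices", "C5", "apices",
      "Lanceolate valve: apices rostrate, or not differentiated?",
      {"rostrate": S("nitzschia_fonticola"),
       "not_differentiated": S("nitzschia_frustulum")}),

    # --- C6: araphid valves with striae --------------------------------------
    n("c6_polarity", "C6", "valve_polarity",
      "Valve heteropolar or isopolar?",
      {"heteropolar": N("c6_pseudosepta"), "isopolar": N("c6_outline")}),
    n("c6_pseudosepta", "C6", "pseudosepta",
      "Pseudosepta at the poles?",
      {"present": S("rhoicosphenia_abbreviata")}),  # absent: no species encoded
    r("c6_outline", "C6", "symmetry_shape",
      "Isopolar valve: linear/lanceolate; very elongate needle-like; or small "
      "elliptic/cruciform?",
      {"linear_lanceolate": N("c6_central"),
       "very_elongate_needle": N("c6_ulnaria"),
       "small_elliptic_cruciform": N("c6_small")}),
    n("c6_central", "C6", "central_area",
      "Central area expanded on only one side of the valve, or on both sides?",
      {"expanded_one_side": N("c6_apices"),
       "expanded_both_sides": S("fragilaria_capucina_var_capucina")}),
    n("c6_apices", "C6", "apices",
      "Apices capitate or rostrate?",
      {"capitate": S("fragilaria_capucina_var_capitellata"),
       "rostrate": S("fragilaria_vaucheriae")}),
    r("c6_ulnaria", "C6", "central_area",
      "Needle-like valve: central fascia (rectangular unornamented area) present?",
      {"central_fascia_present": S("ulnaria_ulna"),
       "central_fascia_absent": S("ulnaria_acus")}),
    r("c6_small", "C6", "symmetry_shape",
      "Small valve: outline elliptic, or cruciform?",
      {"elliptic": S("pseudostaurosira_brevistriata"),
       "cruciform": S("staurosira_construens_var_venter")}),

    # --- C7: araphid valves of monoraphid taxa --------------------------------
    n("c7_area", "C7", "axial_area",
      "Axial/central area: horseshoe shape on the central valve; linear axial "
      "area with absent central area; or linear axial area with small central area?",
      {"horseshoe_on_central_valve": S("planothidium_lanceolatum"),
       "linear_axial_absent_central": N("c7_shape_a"),
       "linear_axial_small_central": N("c7_shape_b")}),
    r("c7_shape_a", "C7", "symmetry_shape",
      "Valve elliptic, or lanceolate?",
      {"elliptic": S("achnanthidium_minutissimum"),
       "lanceolate": S("achnanthidium_eutrophilum")}),
    r("c7_shape_b", "C7", "symmetry_shape",
      "Valve oval, or rounded-rhombic?",
      {"oval": S("cocconeis_placentula"),
       "rounded_rhombic": S("cocconeis_pediculus")}),

    # --- C8: costae -----------------------------------------------------------
    n("c8_polarity", "C8", "valve_polarity",
      "Valve isopolar or heteropolar?",
      {"heteropolar": N("c8_headpole"), "isopolar": N("c8_outline")}),
    r("c8_headpole", "C8", "apices",
      "Headpole rounded, or with a constriction?",
      {"rounded_headpole": S("meridion_circulare"),
       "constricted_headpole": S("meridion_circulare_var_constricta")}),
    r("c8_outline", "C8", "symmetry_shape",
      "Isopolar valve: small elliptic-lanceolate, or linear-lanceolate?",
      {"small_elliptic_lanceolate": S("diatoma_mesodon"),
       "linear_lanceolate": S("diatoma_vulgaris")}),

    # --- C9: bilateral valves with raphe ---------------------------------------
    r("c9_shape", "C9", "symmetry_shape",
      "Valve small linear; oval; lanceolate; or small elliptic?",
      {"small_linear": N("c9_achnanthidium"),
       "oval": N("c9_cocconeis"),
       "lanceolate": N("c9_navicula"),
       "small_elliptic": N("c9_naviculoid")}),
    r("c9_achnanthidium", "C9", "central_area",
      "Central area: a transverse band; small and round; or asymmetric, "
      "expanded on one side?",
      {"band": S("achnanthidium_minutissimum"),
       "small_round": S("achnanthidium_biasolettianum"),
       "asymmetric_one_side": S("achnanthidium_eutrophilum")}),
    n("c9_cocconeis", "C9", "striae_fibulae",
      "Striae interrupted by a hyaline ring near the margin?",
      {"interrupted_by_hyaline_ring": S("cocconeis_placentula"),
       "not_interrupted": S("cocconeis_pediculus")}),
    r("c9_navicula", "C9", "apices",
      "Apices capitate, or rostrate?",
      {"capitate": S("navicula_capitatoradiata"),
       "rostrate": S("navicula_cryptotenella")}),
    r("c9_naviculoid", "C9", "central_area",
      "Central area a rectangular fascia, or small and rounded?",
      {"rectangular_fascia": S("sellaphora_seminulum"),
       "small_rounded": N("c9_eolimna")}),
    r("c9_eolimna", "C9", "striae_fibulae",
      "Striae coarse, or fine?",
      {"striae_coarse": S("eolimna_subminuscula"),
       "striae_fine": S("eolimna_minima")}),

    # --- C10: heteropolar valves with raphe -------------------------------------
    n("c10_stigma", "C10", "central_area",
      "Stigma (isolated pore) in the central area: present or absent?",
      {"stigma_present": N("c10_gomphonema"),
       "stigma_absent": N("c10_pseudosepta")}),
    n("c10_pseudosepta", "C10", "pseudosepta",
      "Pseudosepta at the poles?",
      {"present": S("rhoicosphenia_abbreviata"),
       "absent": S("gomphonema_olivaceum")}),
    r("c10_gomphonema", "C10", "apices",
      "Apices rostrate; subcapitate; or rounded?",
      {"rostrate": S("gomphonema_parvulum"),
       "subcapitate": S("gomphonema_pumilum"),
       "rounded": S("gomphonema_micropus")}),

    # --- C11: dorsoventral valves with raphe -------------------------------------
    n("c11_raphe", "C11", "raphe_position",
      "Raphe near the ventral margin of the valve, or in a more or less central "
      "position?",
      {"near_ventral_margin": N("c11_amphora"),
       "central_position": N("c11_ends")}),
    n("c11_amphora", "C11", "central_area",
      "Dorsal side with a central hyaline area, or without?",
      {"hyaline_dorsal_area": S("amphora_lybica"),
       "no_hyaline_area": S("amphora_pediculus")}),
    n("c11_ends", "C11", "raphe_position",
      "Raphe ends at the apices of the valve, or on the dorsal side "
      "(apices rounded or slightly rostrate)?",
      {"ends_at_apices": S("cymbella_excisa"),
       "ends_dorsal_side": S("encyonema_caespitosum")}),

    # --- C12: Surirellaceae -------------------------------------------------------
    n("c12_face", "C12", "axial_area",
      "Valve face undulate, or with a longitudinal hyaline canal?",
      {"undulate_valve_face": N("c12_cymatopleura"),
       "longitudinal_hyaline_canal": N("c12_polarity")}),
    n("c12_cymatopleura", "C12", "symmetry_shape",
      "Valve elliptic/rhomboid, or elongate with a constriction at the centre?",
      {"elliptic_rhomboid": S("cymatopleura_elliptica"),
       "elongate_constricted": S("cymatopleura_solea")}),
    r("c12_polarity", "C12", "valve_polarity",
      "Valve isopolar or heteropolar?",
      {"isopolar": N("c12_iso_apices"), "heteropolar": N("c12_het_shape")}),
    r("c12_iso_apices", "C12", "apices",
      "Apices rostrate with fibulae clearly visible, or rounded?",
      {"rostrate": S("surirella_angusta"), "rounded": S("surirella_bifrons")}),
    r("c12_het_shape", "C12", "symmetry_shape",
      "Valve ovate; elliptic; or small linear-elliptic?",
      {"ovate": S("surirella_ovalis"),
       "elliptic": S("surirella_brebissonii"),
       "small_linear_elliptic": S("surirella_minuta")}),
]

META = {
    "version": "1.0",
    "provenance": (
        "Single-access key to 60 common freshwater diatom species of Italian "
        "watercourses, encoded as 12 charts over 11 distinctive morphological "
        "characters; couplets flagged reconstructed were placed from standard "
        "flora characters (Krammer & Lange-Bertalot; Atlas of Benthic Diatoms "
        "of Italian Watercourses)."
    ),
}


def build() -> FlowChart:
    return FlowChart.build(CHARACTERS, CHARTS, NODES, "C1", META)


def chart_graph_doc(key: FlowChart) -> dict:
    from diatomkey.content import chart_graph

    cg = chart_graph(key)
    return {
        "transitions": [
            {"from": a, "to": b, "condition": lbl} for a, b, lbl in cg.transitions
        ]
    }


def main() -> None:
    key = build()
    species = load_species_table(DATA / "species.csv")
    report = validate(key, species)
    if report.errors():
        for f in report.errors():
            print(f"ERROR {f.code} {f.location}: {f.message}")
        raise SystemExit(1)
    write_key(key, DATA / "key.json")
    write_key(key, DATA / "key.yaml")
    (DATA / "chart_graph.json").write_text(
        json.dumps(chart_graph_doc(key), indent=1) + "\n", encoding="utf-8"
    )
    print(
        f"wrote key.json/key.yaml/chart_graph.json: "
        f"{len(key.charts)} charts, {len(key.nodes)} nodes, "
        f"{len(key.characters)} characters"
    )


if __name__ == "__main__":
    main()
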