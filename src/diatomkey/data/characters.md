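# Character vocabulary of the bundled key

The key asks questions about 11 distinctive morphological characters of the
diatom frustule. Character states are frozen snake_case tokens; the table
below maps each token to the flora wording it stands for. The same
character is asked with different state subsets in different charts, which
is why observations key their answers by `node_id` rather than by
character.

## symmetry_shape — Symmetry and shape of the frustule

| token | wording |
|---|---|
| girdle_view / valve_view | frustule seen in girdle (lateral) / valve (frontal) view |
| radiate_triangular | radiate or triangular symmetry (Centrales) |
| other_symmetry | other (bilateral) symmetry (Pennales) |
| bilateral_isopolar | bilateral symmetry, poles identical |
| heteropolar | poles different |
| dorsoventral | dorsal and ventral margins different |
| circular / triangular_quadrate | valve outline circular / triangular-quadrate |
| cylindrical_chains | cylindrical frustules joined in chains |
| cuneate_flexed | valve cuneate or flexed in girdle view |
| sigmoidal / linear / lanceolate / linear_lanceolate | valve outline |
| very_elongate_needle | needle-like, very elongate valve |
| small_elliptic_cruciform | small valve, elliptic to cruciform |
| elliptic / cruciform / oval / ovate / rounded_rhombic | valve outline |
| small_linear / small_elliptic / small_linear_elliptic | small valve outlines |
| small_elliptic_lanceolate | small elliptic-lanceolate valve |
| elongate_narrow / short_small | valve proportions (confirm with measurements) |
| elliptic_rhomboid | elliptic to rhomboid valve |
| elongate_constricted | elongate valve with a central constriction |
| constricted / not_constricted | valve constricted at the centre, or not |
| ventral_strongly_arcuate / ventral_slightly_arcuate | curvature of the ventral margin |

## raphe_presence — Absence or presence of the raphe

| token | wording |
|---|---|
| absent | no raphe on this valve |
| central_surface | raphe on the valve surface, roughly central |
| fibulae_around | raphe partially/totally around the valve, held by fibulae |

## raphe_position — Position of the raphe

| token | wording |
|---|---|
| all_around | raphe-fibulae system all around the valve |
| central | raphe-fibulae system in a central position |
| margin_visible / margin_not_visible | system on the valve margin, clearly visible or not |
| near_ventral_margin / central_position | raphe near the ventral margin / roughly central |
| ends_at_apices / ends_dorsal_side | where the raphe ends |
| eccentric_fibulae_regular | raphe slightly eccentric, fibulae regularly spaced |
| not_eccentric | raphe not eccentric |
| visible / not_visible | raphe clearly visible on the valve margin, or not |

## valve_polarity — Polarity of valves

`isopolar` (ends identical), `heteropolar` (ends different).

## apices — Description of apices

capitate, rostrate, rounded, subcapitate, acuminate_with_central_notch,
rostrate_rounded_v_system (apices rostrate or rounded with the
raphe-fibulae system as a V at valve centre),
differentiated_capitate_subrostrate, not_differentiated,
rounded_headpole, constricted_headpole.

## central_area — Description of the central area

clearly_distinct / not_distinct (central vs marginal zone of a centric
valve), band, small_round, asymmetric_one_side, expanded_one_side,
expanded_both_sides, central_fascia_present / central_fascia_absent,
rectangular_fascia, small_rounded, stigma_present / stigma_absent
(isolated pore in the central area), central_node_present /
central_node_absent, slightly_convex / straight (central part of the
valve margin), hyaline_dorsal_area / no_hyaline_area.

## axial_area — Description of the axial area

horseshoe_on_central_valve, linear_axial_absent_central,
linear_axial_small_central, canal_present / canal_absent (longitudinal
hyaline canal), undulate_valve_face, longitudinal_hyaline_canal.

## striae_fibulae — Presence of fibulae or striae

ornament_present / ornament_absent, striae / irregular_areas / costae
(ornament type of a raphe-less valve), striae_clearly_visible /
striae_not_clearly_visible, fine / coarse, striae_fine / striae_coarse,
interrupted_by_hyaline_ring / not_interrupted.

## punctae — Presence of punctae

regular_no_punctae, irregular_with_punctae.

## pseudosepta — Presence of pseudosepta

present, absent (internal silica projections at the valve poles).

## measurements — Measurements

No categorical states. Valve length (µm), width (µm) and the number of
striae or fibulae in 10 µm are compared with the species table in the
terminal confirmation step of every chart.
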