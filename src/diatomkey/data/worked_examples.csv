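label,c1_view,c1_symmetry,c2_shape,c2_ornament,c2_zone,c2_pattern,c3_raphe,c3_symmetry,c3_fibulae,c5_striae,c5_eccentric,c5_outline,c5_linear_apices,c5_central_part,c10_stigma,c10_pseudosepta,c11_raphe,c11_ends,c12_face,c12_cymatopleura,length_um,width_um,striae_per_10um,fibulae_per_10um
a_valve_fibulae_margin,valve_view,other_symmetry,,,,,fibulae_around,,margin_visible,striae_not_clearly_visible,not_eccentric,linear,differentiated_capitate_subrostrate,slightly_convex,,,,,,,30,4.5,,10
b_valve_central_heteropolar,valve_view,other_symmetry,,,,,central_surface,heteropolar,,,,,,,stigma_absent,absent,,,,,25,7,12,
c_valve_central_dorsoventral,valve_view,other_symmetry,,,,,central_surface,dorsoventral,,,,,,,,,central_position,ends_dorsal_side,,,30,9,10,
d_valve_fibulae_all_around,valve_view,other_symmetry,,,,,fibulae_around,,all_around,,,,,,,,,,undulate_valve_face,elongate_constricted,100,25,,7
e_valve_radiate_circular,valve_view,radiate_triangular,circular,ornament_present,clearly_distinct,irregular_with_punctae,,,,,,,,,,,,,,,15,15,15,
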