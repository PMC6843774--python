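{
 "transitions": [
  {
   "from": "C1",
   "to": "C2",
   "condition": "radiate_triangular"
  },
  {
   "from": "C1",
   "to": "C3",
   "condition": "other_symmetry"
  },
  {
   "from": "C3",
   "to": "C10",
   "condition": "heteropolar"
  },
  {
   "from": "C3",
   "to": "C11",
   "condition": "dorsoventral"
  },
  {
   "from": "C3",
   "to": "C12",
   "condition": "all_around"
  },
  {
   "from": "C3",
   "to": "C4",
   "condition": "margin_not_visible"
  },
  {
   "from": "C3",
   "to": "C5",
   "condition": "margin_visible"
  },
  {
   "from": "C3",
   "to": "C6",
   "condition": "striae"
  },
  {
   "from": "C3",
   "to": "C7",
   "condition": "irregular_areas"
  },
  {
   "from": "C3",
   "to": "C8",
   "condition": "costae"
  },
  {
   "from": "C3",
   "to": "C9",
   "condition": "bilateral_isopolar"
  }
 ]
}
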