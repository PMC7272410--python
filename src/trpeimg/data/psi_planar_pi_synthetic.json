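{
 "label": "planar-pi-synthetic",
 "comment": "Synthetic stand-in for a planar conjugated pi-type Dyson orbital: parallel p primitives perpendicular to the molecular plane on collinear centres (pi* nodal pattern). Not a quantum-chemistry orbital.",
 "units": "atomic (bohr, bohr^-2)",
 "primitives": [
  {"center": [-2.5, 0.0, 0.0], "powers": [0, 0, 1], "alpha": 0.25, "coeff": 1.0},
  {"center": [0.0, 0.0, 0.0], "powers": [0, 0, 1], "alpha": 0.25, "coeff": -1.2},
  {"center": [2.5, 0.0, 0.0], "powers": [0, 0, 1], "alpha": 0.25, "coeff": 1.0}
 ]
}
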