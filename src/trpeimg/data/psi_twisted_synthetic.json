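{
 "label": "twisted-delocalised-synthetic",
 "comment": "Synthetic stand-in for a twisted, delocalised Dyson orbital spread over two fragments with perpendicular p orientations. Not a quantum-chemistry orbital.",
 "units": "atomic (bohr, bohr^-2)",
 "primitives": [
  {"center": [-2.5, 0.0, 0.0], "powers": [0, 0, 1], "alpha": 0.35, "coeff": 1.0},
  {"center": [-0.5, 0.0, 0.0], "powers": [0, 0, 1], "alpha": 0.35, "coeff": 0.8},
  {"center": [1.5, 0.0, 0.0], "powers": [1, 0, 0], "alpha": 0.35, "coeff": 2.4},
  {"center": [3.5, 0.0, 0.0], "powers": [1, 0, 0], "alpha": 0.35, "coeff": 1.92}
 ]
}
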