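8
PM planar S1 minimum (synthetic surrogate)
O       0.000000       0.000000       0.000000
C       1.230000       0.000000       0.000000
C       2.003682      -1.238150       0.000000
C       3.343478      -1.214764       0.000000
H       0.142655      -0.076035       0.000000
H       1.475240      -2.191486       0.000000
H       3.915791      -2.130656       0.000000
H       3.875295      -0.274780       0.000000
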