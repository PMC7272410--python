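8
SB single-bond-rotated S1 minimum (synthetic surrogate)
O       0.000000       0.000000       0.000000
C       1.230000       0.000000       0.000000
C       1.971887      -1.187267       0.000000
C       2.353987      -1.798755       1.200034
H       0.958828       0.433967      -0.962413
H       2.251919      -1.635412      -0.953335
H       2.926300      -2.714647       1.200034
H       2.080903      -1.361729       2.149157
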