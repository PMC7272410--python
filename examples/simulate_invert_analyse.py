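"""Simulate a pump-probe imaging run, invert it, and extract the dynamics.

A reduced version of the packaged study conditions (smaller images, fewer
delays) keeps this example fast; the physics — a wavepacket oscillating
between the planar and single-bond-rotated minima with a 400 fs period, a
100 fs instrument response and Poisson counting noise — is unchanged.
"""

import numpy as np

from trpeimg.config import pck_fixture
from trpeimg.pipeline import run_pipeline

cfg = pck_fixture()
# shrink the problem so the example runs in seconds
cfg.generator.image_size = 256
cfg.generator.k_cal_eV_per_px2 = 1.28e-4
cfg.generator.n_electrons = 2e5
cfg.inversion.k_cal_eV_per_px2 = cfg.generator.k_cal_eV_per_px2

res = run_pipeline(cfg, include_sparse=True, seed=11)

osc = res["oscillation_eps1"]
dec = res["decay_eps2"]
b2_early, u_early = res["beta2_eps1_early"]
b2_late, u_late = res["beta2_eps2_late"]

print(f"oscillation period (eps1 window): {osc.params['period_fs']:7.1f} "
      f"+/- {osc.stderr('period_fs'):.1f} fs   (generator: {cfg.generator.period_fs} fs)")
print(f"eps1/eps2 phase difference:       {res['phase_difference_rad']:7.2f} rad "
      "(pi = antiphase)")
print(f"S1 population lifetime:           {dec.params['tau_fs'] / 1e3:7.1f} "
      f"+/- {dec.stderr('tau_fs') / 1e3:.1f} ps   (generator: {cfg.generator.lifetime_ps} ps)")
print(f"feature beta2, eps1 window @ t~0:   {b2_early:+.3f} +/- {u_early:.3f} "
      "(generator: -0.36)")
print(f"feature beta2, eps2 window @ t~1ps: {b2_late:+.3f} +/- {u_late:.3f} "
      "(generator: -0.11)")
print()
print("The high-energy peak's damped oscillation tracks the wavepacket's round")
print("trips toward the twisted minimum; the antiphase of the two windows and")
print("the shift of beta2 toward ~-0.1 signal the changing electronic structure.")
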