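# Study conditions for the model PYP chromophore anion (pCK-).
# These values define the synthetic-data generator and analysis defaults:
# wavepacket period 400 fs, instrument response 100 fs FWHM, S1 lifetime
# 120 ps, moving peak 1.4 -> 0.8 eV with feature anisotropies -0.36 / -0.11,
# pump/probe photons 2.79 / 1.55 eV and VDE 2.94 eV.
generator:
  period_fs: 400.0
  coherence_fs: 400.0
  lifetime_ps: 120.0
  eps_pm_center_eV: 1.4
  eps_sb_center_eV: 0.8
  peak_width_eV: 0.15
  beta2_pm: -0.36
  beta2_sb: -0.11
  eps3_center_eV: 0.12
  eps3_width_eV: 0.05
  eps3_amplitude: 0.3
  background_amplitude: 0.25
  background_center_eV: 0.25
  background_width_eV: 0.12
  irf_fwhm_fs: 100.0
  k_cal_eV_per_px2: 3.2e-5
  image_size: 512
  n_electrons: 5.0e+5
  seed: 20200604
  n_dense: 40
  dense_start_fs: -300.0
  dense_stop_fs: 1200.0
  n_sparse: 12
  sparse_start_ps: 5.0
  sparse_stop_ps: 400.0
inversion:
  n_theta: 128
  freeze_beta4: false
  k_cal_eV_per_px2: 3.2e-5
analysis:
  mask_threshold: 0.1
  smooth_window: 5
  eps1_window_eV: [1.15, 1.65]
  eps2_window_eV: [0.55, 1.05]
  eps3_window_eV: [0.02, 0.25]
  decay_t_min_ps: 2.0
energetics:
  hv_pump_eV: 2.79
  hv_probe_eV: 1.55
  vde_eV: 2.94
  compat_margin_eV: 0.2
  geometries:
    FC: {gap_eV: 0.15, e_s1_eV: 2.79}
    PM: {gap_eV: 0.21, e_s1_eV: 2.75}
    SB: {gap_eV: 0.68, e_s1_eV: 2.35}
    DB: {gap_eV: 1.34, e_s1_eV: 2.40}
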