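# trpeimg

Time-resolved photoelectron imaging analysis of excited-state isomerisation
in a model photoactive-yellow-protein (PYP) chromophore anion.

When the deprotonated *para*-coumaric ketone chromophore (pCK⁻) absorbs a
pump photon (hv₁ = 2.79 eV) it reaches its bright S₁ state and a nuclear
wavepacket sets off along the isomerisation coordinate. A delayed probe
photon (hv₂ = 1.55 eV) detaches the excess electron, and a velocity-map
imaging (VMI) spectrometer records the photoelectrons. Both the electron
kinetic energy ε and the laboratory-frame photoelectron angular
distribution (PAD) evolve with pump–probe delay, so the experiment tracks
nuclear *and* electronic structure at once. This package re-implements the
full analysis chain of that experiment and couples it to a synthetic-data
generator, so every stage is testable without the instrument.

## What it computes

The PAD at each energy is parameterised by

    I(ε, θ) = σ/4π · [1 + β₂(ε) P₂(cosθ) + β₄(ε) P₄(cosθ)],

with θ measured from the laser polarisation axis: β₂ = +2 means emission
parallel to the polarisation, −1 perpendicular, 0 isotropic. The pipeline:

- **`synthetic`** — velocity-map image stacks from a 1-D wavepacket model:
  a reaction coordinate q(t) oscillates between the S₁ planar minimum
  (spectral peak at 1.4 eV) and the single-bond-rotated minimum (0.8 eV)
  with period T ≈ 400 fs, damps onto the twisted minimum, and the S₁
  population decays with τ ≈ 120 ps; Gaussian 100 fs FWHM instrument
  response and Poisson counting statistics included.
- **`projection` / `inversion`** — forward Abel projection of
  cylindrically symmetric distributions, and its inverse by polar onion
  peeling (POP): shells are fitted and subtracted ring-by-ring from the
  outermost radius inward, giving S(r), β₂(r), β₄(r); energy calibration
  ε = k_cal·r².
- **`analysis`** — delay × energy signal and β₂ maps with t < 0 background
  subtraction, spectral-window integration (ε₁/ε₂/ε₃), masking below 10 %
  of the normalised signal with a 5-point moving average in ε,
  signal-weighted feature anisotropies, and IRF-convolved damped-cosine and
  exponential transient fits.
- **`dyson`** — photodetachment cross-sections and β₂(ε) from Dyson
  orbitals (Cartesian-Gaussian expansions) in the plane-wave/length-gauge
  approximation, with exact analytic Fourier transforms and orientation
  averaging.
- **`liic` / `energetics`** — linear interpolation in internal coordinates
  between critical geometries (no reoptimisation), dihedral tracking
  (φ_SB, φ_DB), predicted maximum electron energies per geometry
  (ε = hv − gap) and energetic + anisotropy-based feature assignment.

## Worked example

`examples/simulate_invert_analyse.py` generates a reduced synthetic run
(256² images, 2×10⁵ electrons per frame), inverts every frame by polar
onion peeling and fits the dynamics:

```
oscillation period (eps1 window):   402.8 +/- 14.4 fs   (generator: 400.0 fs)
eps1/eps2 phase difference:          3.00 rad (pi = antiphase)
S1 population lifetime:             119.2 +/- 0.7 ps   (generator: 120.0 ps)
feature beta2, eps1 window @ t~0:   -0.299 +/- 0.067 (generator: -0.36)
feature beta2, eps2 window @ t~1ps: -0.118 +/- 0.053 (generator: -0.11)
```

The high-energy window (ε₁, around 1.4 eV) decays with a damped ~400 fs
oscillation while the intermediate window (ε₂, around 0.8 eV) rises in
antiphase — the wavepacket shuttling between the planar and twisted
minima — and the feature-averaged anisotropy relaxes from ≈ −0.36 toward
≈ −0.11 as the electronic structure adapts to single-bond rotation.

Other examples: `dyson_pads.py` (β₂(ε) curves of a planar π-like vs a
twisted delocalised model orbital — the sign discriminates the two),
`liic_energetics.py` (PM→SB pathway dihedrals, per-geometry energy limits
and feature assignment), `image_stacks.py` (HDF5 stack round trip and
single-frame inversion).

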