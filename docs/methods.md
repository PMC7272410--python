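# Methods

This note documents the models, numerical choices and limitations behind
`trpeimg`. Units: energies in eV at all interfaces (hartree internally in
the photodetachment model), lengths in Å for geometries and bohr for
orbitals (1 bohr = 0.52917721067 Å), delays in fs, β₂ dimensionless.

## Synthetic wavepacket model

The generator emulates a pump–probe photoelectron imaging run on an
isomerising chromophore anion with a single effective reaction coordinate
q ∈ [0, 1]: q = 0 is the S₁ planar minimum (PM), q = 1 the single-bond
rotated minimum (SB). The trajectory is

    q(t) = 1 − cos²(πt/T) · e^(−t/τ_d),   q(t<0) = 0,

which starts at PM, reaches SB at T/2, swings back, and settles at SB as
the coherent oscillation damps. In the undamped limit it reduces to
sin²(πt/T), exactly periodic with period T. The damped form is chosen so
that the long-time spectrum sits at the twisted minimum — the peak stays
near 0.8 eV and carries the SB anisotropy at late delays — while only a
single clear oscillation survives for τ_d ≈ T. Defaults (the packaged
`pck_fixture` study conditions): T = 400 fs, τ_d = 400 fs, S₁ lifetime
τ = 120 ps, instrument response 100 fs FWHM.

The instantaneous spectrum is a Gaussian peak (σ = 0.15 eV) centred at
(1−q)·1.4 + q·0.8 eV with amplitude e^(−t/τ), plus two β₂ = 0 components:
a static low-energy channel (0.12 eV, amplitude 0.3, constant after the
excitation step) and a delay-independent probe-only background (0.25 eV,
amplitude 0.25). The background position and the ε₃ amplitude are not
constrained by any measured number; they are fixed once here, placed at
low energy so they do not overlap the ε₁/ε₂ analysis windows — as in the
experiment, where probe-only signal appears at low ε. The peak's β₂(ε) is
the q-linear blend of the endpoint curves (adiabatic following); the
endpoint curves default to the constants −0.36 (PM) and −0.11 (SB), the
experimentally observed feature averages. β₄ ≡ 0.

The instrument response acts on the time axis: the expectation spectrum at
delay t is the Gaussian-weighted average of the instantaneous model over
t′ (81 nodes spanning ±5σ), which convolves the population rise/decay and
the coherent peak motion but leaves the delay-independent background
untouched. Images are then built per delay and Poisson-sampled. One common
intensity scale is used for the whole stack — the largest-total frame
carries `n_electrons` (default 5×10⁵) on average — because renormalising
every frame separately would erase the population decay the analysis must
recover. `sample_counts` on a single image, by contrast, scales that image
to the requested total, matching its contract. Frame seeds are derived as
(seed, frame-index) so a dataset is bit-reproducible.

## Forward projection and polar onion peeling

Both directions share one discretised shell basis. A 1-pixel radial shell
[s, s+1] with uniform radial density and angular weight P_n(cosθ)
projects along the line of sight to chord(ρ)·P_n(z/R)/V, with chord(ρ) the
path length through the shell, z the in-plane coordinate along the
polarisation axis, R the shell mid-radius and V the shell volume. Pixels
receive the analytic radial average of the chord across their width, which
integrates the inverse-square-root rim exactly, and each shell is
renormalised so its summed pixel counts equal its spectral weight: total
counts are conserved by construction. The expectation image is everywhere
non-negative for β₂ ∈ [−1, 2], β₄ = 0, since 1 + β₂P₂ ≥ 0 there.

Inversion resamples the image onto a polar grid (bilinear, 1-pixel radial
bins, 128 angular bins on [0, π/2]) averaging the four reflection-
equivalent quadrants, then peels from the outermost ring inward: the
residual ring intensity is fitted by least squares to the ring's own shell
basis {1, P₂, P₄}(cosθ), the coefficients give S(r) and β₂, β₄ with
covariances (delta method for the ratios), and the fitted shell's
projection is subtracted from all interior rings. Negative fitted shell
amplitudes are clipped to zero and counted (`clip_fraction` diagnostic);
unbounded propagation of negative residuals would otherwise corrupt
interior rings under noise. β₄ can be frozen at zero via configuration.
Energy calibration applies ε = k_cal·r² with the Jacobian
S(ε) = S(r)/(2·k_cal·r); the fixture uses k_cal = 3.2×10⁻⁵ eV px⁻², which
places the upper edge of the ε₁ window (1.65 eV) at r ≈ 227 px inside a
512² frame.

Verified behaviour (see the test suite): noiseless round trips recover β₂
to a mean absolute error well below 0.05 where the signal exceeds 10 % of
its maximum, an inner isotropic shell is recovered as isotropic underneath
an overlapping outer β₂ = 2 shell, and the peel is linear.

## Time-resolved analysis

The background is the mean of all t < 0 rows (at least two such frames are
required). Window integrals are trapezoidal with interpolated window
edges, making them exactly additive over windows sharing a boundary.
Default windows: ε₁ = [1.15, 1.65], ε₂ = [0.55, 1.05],
ε₃ = [0.02, 0.25] eV — chosen to bracket the 1.4 eV, 0.8 eV and low-energy
features. β₂ maps are masked where the normalised signal is below 0.1 and
smoothed with a centred 5-point moving average along ε that shrinks at run
edges and never crosses a mask boundary. Feature anisotropies are
signal-weighted window means; their uncertainty combines the propagated
per-ring fit errors and the weighted dispersion in quadrature (the
experimental uncertainty recipe is not public, so this package defines its
own and reports it consistently).

The coherent dynamics are fitted by

    s(t) = [a·e^(−t/τ_d)·cos(2πt/T − φ) + c₁·e^(−t/τ) + c₀] · Θ(t) ⊗ G(σ_IRF)

with the exponential and constant terms convolved analytically
(erfc closed forms) and the cosine term numerically (81-node Gaussian
quadrature). Eight multi-start period guesses (0.5–2× the initial guess,
geometric) guard against local minima; the best residual wins. The
amplitude is canonicalised to a ≥ 0 with the phase wrapped to (−π, π], so
antiphase traces differ by π rather than by an amplitude sign. Long-delay
population decay is fitted separately as a single exponential plus offset
for t ≥ 2 ps; a trace whose decaying amplitude is indistinguishable from
zero is flagged `unbounded_lifetime` instead of reporting a number.

## Plane-wave Dyson-orbital PADs

The detachment amplitude is M = ⟨e^(ik·r)|ê·r|Ψ_D⟩ in the length gauge
with a plane-wave continuum (free-electron dispersion ε = k²/2 in atomic
units; σ carries the density-of-states factor k, which cancels in β₂).
Because M is linear in ê, M = ê·A(k) with A the Fourier-space dipole
vector of the orbital, available in closed form for Cartesian Gaussians
via the 1-D moment recursion J_{l+1} = i·dJ_l/dk. The azimuthal average of
ê about k̂ is then analytic and the laboratory-frame PAD reduces exactly
to c_par·cos²θ + c_perp·sin²θ — the expansion truncates at P₂ for
one-photon detachment, and β₂ = 2(c_par − c_perp)/(c_par + 2c_perp) ∈
[−1, 2] by construction. The remaining k̂ average uses a Gauss–Legendre ×
uniform-azimuth product grid refined on a fixed ladder until σ and β₂
change by < 10⁻³ (non-convergence raises). An explicit SO(3) Euler-grid
average that never uses the analytic contraction is shipped as the
independent cross-check route.

Consequences used as anchors: a single s Gaussian gives β₂ = 2 at every
energy; any orbital with a non-zero static dipole integral becomes
isotropic at threshold; σ scales quadratically and β₂ not at all under
orbital scaling; and all results are invariant under rigid rotation.

The packaged fixture orbitals are synthetic constructions, not
quantum-chemistry output: a planar π-like orbital (three parallel p
primitives on collinear centres, π* nodal pattern, α = 0.25 bohr⁻²,
2.5 bohr spacing) whose β₂ is negative across 0.2–1.5 eV, and a twisted
delocalised two-fragment orbital (p orientations perpendicular between
fragments) with |β₂| ≤ 0.15 there. They reproduce the *sign-based*
discrimination of planar-π versus twisted electronic character; computing
real Dyson orbitals is out of scope, so ab-initio β₂ values are not
reproduced.

The plane-wave approximation ignores the electron–core interaction; for a
neutral core with a large permanent dipole this is a recognised source of
quantitative error, which is why window-averaged values and trends, not
point values, are the meaningful comparison.

## LIIC pathways and energetic assignment

Geometries convert to Z-matrix internal coordinates over a user-supplied
connectivity; reconstruction uses the natural-extension reference frame.
Paths interpolate every internal coordinate affinely in λ with *no*
reoptimisation — an LIIC path is a straight line in internal-coordinate
space, not a minimum-energy path, and barriers along it are upper bounds.
Dihedrals follow the shorter angular arc with ±180° wrapping
(0°→90° passes 45°; 170°→−170° passes 180°); an explicit rotation sense
can be forced per atom for arcs near the 180° ambiguity. Endpoint frames
are returned exactly as supplied; intermediate frames are aligned to their
predecessor (Kabsch) for visual continuity.

The energetics table stores the printed study inputs: hv_pump = 2.79 eV,
hv_probe = 1.55 eV, VDE = 2.94 eV, and per-geometry D₀−S₁ gaps
back-derived from the predicted maximum kinetic energies
ε_FC/ε_PM/ε_SB/ε_DB = 1.40/1.34/0.87/0.21 eV. The expected signal range at
a geometry is ε_hi = hv_probe − gap down to ε_lo = ε_hi − E_vib, where
E_vib = hv_pump − [E_S1(geometry) − E_S0(FC)] is the vibrational energy
available above the local minimum — the natural reading of the qualitative
statement behind the printed 0.43 eV lower bound; only the SB value of
E_S1 (2.35 eV) is fixed by that bound, the PM/DB entries are labelled
synthetic placeholders. Feature assignment declares a feature compatible
with a geometry when its centre lies in the range widened by δ = 0.2 eV
(the stated electronic-structure uncertainty, configurable) and ranks by
compatibility, then normalised anisotropy deviation, with ties kept in
candidate order and documented.

The packaged PM/SB geometries are a surrogate chromophore tail
(O=C–C=C backbone with hydrogens) whose single-bond dihedral sweeps
180°→90° along the path while the double-bond dihedral stays planar; they
stand in for the real critical points, which are not distributed here.

## Problem sizes and determinism

The full verification pipeline uses 512² images, 40 dense delays
(−0.3 … 1.2 ps) plus 12 sparse delays (5 … 400 ps), 5×10⁵ electrons per
frame and five noise seeds; the expectation stack is computed once and
re-sampled per seed. Smaller images simply rescale k_cal. All randomness
flows from explicit seeds; identical configuration and seed reproduce
identical images bit for bit.

## What passing tests do and do not show

The generator shares its shell basis with the inversion, so round-trip
tests validate the peeling logic, not the instrument: detector
inhomogeneity, centre-finding error, non-Poissonian backgrounds and the
energy-dependent spectral resolution of a real VMI spectrometer are not
modelled. The wavepacket model is 1-D and phenomenological — it encodes
the observed phenomenology (antiphase shifting peaks, one damped
oscillation, slow decay) rather than dynamics on computed surfaces, so
parameter-recovery tests demonstrate that the analysis chain is unbiased
under the stated noise model, not that the model is the true dynamics.
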