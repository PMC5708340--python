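# Methods

## Problem and scope

β-carboxysomes are icosahedral bacterial microcompartments: a
single-layer shell of CcmK hexamers with CcmL pentamers at the twelve
vertices encloses paracrystalline arrays of Rubisco. Two experimental
observables drive this package: AFM nanoindentation approach curves
(force vs piezo displacement on top of an immobilised particle) and
height images / electron-density profiles of shells and their cargo.
The package converts the former into particle stiffness and Young's
moduli under three standard contact models, and the latter into lattice
spacings, layer thicknesses and protein counts for the icosahedral
packing model. Wet-lab steps (isolation, proteomics, activity assays)
and instrument control are out of scope.

## Coordinate and unit conventions

Piezo displacement `z_p` increases toward the sample; forces are
positive in compression; only approach segments are analysed. All
lengths are nm, forces pN, moduli MPa, so `1 pN/nm² = 1 MPa` and no
conversion factors appear in the model code. The text dialects (force
curves, topographs) carry units in `#key=value` headers and are
normalised on read (e.g. 0.35 N/m → 350 pN/nm).

## Curve pre-processing

**Baseline.** A least-squares line fitted on the first
`pre_contact_fraction` (default 0.2) of samples is subtracted from the
whole curve, removing offset and tilt; the operation is idempotent.
Force noise is estimated as the SD of the detrended pre-contact window.

**Contact point.** The crossing estimate is the first `z_p` where force
exceeds `threshold_multiple × noise_sd` (default 3×) and stays above it
for 3 samples. Because force clears the noise floor only after the tip
is already indenting, the crossing is systematically late — about
`(3σ/c)^(2/3) ≈ 1.2 nm` for a 0.59 MPa sample at σ = 2 pN. By default
the estimate is therefore refined by the Hertz linearisation: near
contact `F^(2/3)` is linear in `z_p − F/k_cantilever`, and the fitted
line extrapolated to zero force intersects at `z_0`. The refinement is
exact on noiseless Hertz curves, reduces the noisy-curve bias to
< 0.5 nm, and falls back to the raw crossing when the local fit is
ill-conditioned (force steps, flat plateaus). `refine=False` restores
the literal crossing. The commercial instrument software's contact
criterion is not public; this is the package's own documented
convention, and the Hertz fitter can additionally co-fit `z_0`.

**Indentation.** Post-contact samples map through
`d = z_p − z_0 − F/k_cantilever`; negative `d` from noise is clipped to
zero and the clip count reported.

## Mechanical models

**Series springs** (linear model): `k_total` is the least-squares slope
of F vs `z_p` restricted to the 50–150 pN force window (configurable),
the regime of quasi-linear whole-particle compression;
`k_CB = k_c·k_total/(k_c − k_total)`. A slope at or above the cantilever
constant invalidates the series model and is rejected. Note the model
mismatch when this window is applied to a purely Hertzian curve: the
fitted slope then tracks the local analytic slope at the window
midpoint within ~15%, which is a property test, not an error.

**Thin shell**: `E_S = α·k_CB·R/h²` with defaults α = 1, R = 75 nm,
h = 4.5 nm for the carboxysome and R = 30 nm, h = 7.5 nm for the P22
comparison capsid. Applied to the published P22 stiffness mean
(192.38 pN/nm) the relation gives 102.6 MPa, within 2% of the published
101.04 MPa modulus mean — the residual comes from averaging unrounded
per-curve fits rather than applying the formula to the rounded mean,
so the cross-check is asserted as a 5% tolerance property, not an
exact value.

**Hertz**: `F = (4/3)·E/(1−ν²)·√R_tip·d^{3/2}` fitted by
Levenberg–Marquardt (lmfit) on the 0–10 nm indentation window with
ν = 0.5 and R_tip = 20 nm. By default a contact-point shift δ is
co-fitted (`d → max(d − δ, 0)`, bounded at ±5 nm), since `z_0`
misestimation is the dominant bias at shallow indentation; window
membership is fixed before the fit. Initialisation is the median of
`F/(pref·d^{3/2})` over the deeper half of the window. Non-convergence
or a non-positive modulus raises with diagnostics.

**Forward simulation and bracketing.** Simulated curves use the
two-material reduced modulus `1/E* = (1−ν_s²)/E_s + (1−ν_t²)/E_t` with
a 130 GPa, ν = 0.3 tip; for samples up to a few MPa this is within
1e-4 of the rigid-tip formula (at 500 MPa the difference grows to
~0.5%, which is why the reduced form is used). Bracketing integrates
the signed residual `∫(F_exp − F_sim) dd` over the shared indentation
range (optionally restricted to the Hertz window — necessary for
curves with a linear tail); since simulated force increases strictly
with E at fixed depth, the residual decreases monotonically along the
grid and its sign change selects the unique adjacent pair. A curve
exactly on a grid modulus brackets to (that modulus, next higher);
curves outside the grid return an open-bracket flag.

**No rupture handling.** Intact shells showed no rupture events up to
the 1 nN cap, so curves exceeding 300 pN are analysed unchanged with a
note in the per-curve record.

## Geometry model

Along one facet edge between two vertex pentamers, hexamer positions
advance by the across-flats width `√3 × edge` (≈ 6.06 nm for a 3.5 nm
hexamer edge) and alternate pair, single, pair, …, starting and ending
with a pair: `N = floor(facet_edge/(√3·edge))` positions give
`ceil(N/2)` pairs and `floor(N/2)` singles (72.16 nm → 11 positions →
6 pairs + 5 singles, 17 hexamers). Whether the pairs and singles sit in
one row or two staggered rows is not constrained — only the counts are.
Rubisco per edge is `floor(facet_edge/diameter)` with the ~10 nm
holoenzyme default (the 9.5 nm lattice periodicity is an available
alternative); the per-facet pyramid is the tetrahedral number
`n(n+1)(n+2)/6`, verified against brute-force lattice enumeration; the
shell total multiplies by 20 facets with no edge/vertex deduplication
and is labelled an upper bound in the report. The icosahedron
circumdiameter from the 72.16 nm edge (137.3 nm) is reported alongside
the measured ~150 nm population mean for consistency, never asserted —
real particles are rounded and heterogeneous.

## Image and profile analysis

Heights sit at pixel centers (physical coordinate = index × pixel
size); profiles are bilinear interpolations sampled at half-pixel
steps. Periodicity is the first positive-lag local maximum of the
linearly detrended, normalised autocorrelation with parabolic
sub-sample refinement — chosen over an FFT peak because the profiles of
interest are short (tens of nm, a handful of periods). The peak must
exceed `3/√n`, the white-noise autocorrelation scale, else the profile
is declared aperiodic. Particle height is region maximum minus the
median of the region's one-pixel border ring (background convention;
the instrument software's is unspecified). Layer features (shell
thickness, shell–cargo gap) come from a two-Gaussian decomposition of
the two outermost profile peaks: thickness is the FWHM of the outer
peak and the gap runs from its inner half-maximum to the next peak's
outer half-maximum, both computed from the fitted parameters. Raw
half-maximum crossings would be biased by ~0.5 nm at the relevant
overlap (4.5 nm wide peaks 6.5 nm apart), which is why the
decomposition convention is used; whether the published readings were
FWHM or edge-threshold values is unknown, so this is a stated
convention.

## Synthetic data

Generators are pure functions of their arguments including the seed.
Force curves are built on a uniform indentation grid, mapped to piezo
space via `z_p = z_0 + d + F/k_cantilever`, prefixed with a zero-force
baseline, truncated at 1 nN (the experimental force cap) and given
additive white Gaussian force noise — default 2 pN, a stand-in chosen
to be small against the 50–150 pN analysis window, since the true
instrument noise spectrum is unknown. The composite generator is
Hertzian up to a 50 pN regime-switch force and then linear at the
particle stiffness (continuous at the switch): the switch places the
linear fit window (50–150 pN) entirely in the linear regime while
leaving the Hertz window (0–10 nm) Hertz-dominated; the linear tail
inside that window biases the fitted modulus upward by ~5–7%, which is
why recovery is asserted at the 10% level for noisy curves and the
1e-6 round-trips are asserted on the pure-Hertz curve (for E) and on
the composite curve (for k_CB). Topographs are hexagonal lattices of
Gaussian bumps (σ = spacing/5) with one bump row through the grid
center; populations are Gaussian truncated at ±4 SD. What the
generators do **not** emulate: tip convolution, feedback/drift
artefacts, adhesion, viscoelastic rate dependence, particle-to-particle
modulus scatter (the published between-particle SDs of ~45–60% reflect
biological heterogeneity, not fit noise). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not instrument-grade accuracy on real curves.

## Problem sizes and numerical choices

Synthetic campaigns use 25 curves of 520 samples and 128×128 topographs
at 0.5 nm/pixel — enough for the CLT bounds and sub-sample peak
refinement the tests assert while keeping the whole suite in seconds.
Tolerances asserted in tests: 1e-6 relative on noiseless round-trips,
10% on noisy medians (25 seeds), ±0.25 nm on clean periodicity
(half the sampling step), ±0.5 nm with noise, ±0.2 nm on layer
features. Degenerate inputs (flat profiles, zero indentation, empty
windows, sub-minimum regions) raise typed errors rather than returning
NaNs.

## Known limitations

- The alternating pair/single construction reproduces the published
  counts but is one of several arrangements consistent with them.
- Thin-shell theory assumes a homogeneous thin wall; the inner
  protein layer under the shell makes the effective `h` uncertain, and
  `E_S` scales as `1/h²`.
- The Hertz model assumes a half-space; for shells it is an effective
  description valid only at shallow indentation, hence the 0–10 nm
  window.
- Contact-point and background conventions are package choices where
  the original instrument software is undocumented; both are
  configurable and tested, but absolute comparability with
  vendor-software fits is not guaranteed.
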