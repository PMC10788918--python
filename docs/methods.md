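# Methods

This note records the models implemented in `trastkit`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter.

## Photophysical state schemes

Two reduced electronic-state schemes are implemented
(`trastkit.photophysics`):

**Isomerization (cyanines).**  States: fluorescent all-*trans* N and dark
*cis* P.  Within a pulse, the fast S0/S1 cycling of N is adiabatically
eliminated: the S1 occupancy is k_exc/(k_exc + k10), so the effective
forward rate is k'_iso = k_exc/(k_exc + k10)·k_iso, saturating at k_iso.
The return path combines a lumped photo-driven channel, σ_biso times the
photon flux Φλ/(hc), with a thermal rate k_biso^Th.  σ_biso is a single
effective cross section because the *cis*-side parameters (σ_P, k_biso,
the *cis* S1 lifetime) are not individually identifiable from any of the
four readouts; no direct *cis*-state kinetics beyond this lumped term are
represented.

**Triplet (rhodamines).**  States: singlet manifold S (S0 + S1) and triplet
T, with k'_isc = k_exc/(k_exc + k10)·k_isc and an excitation-independent
decay k_T.

Irradiance is converted to an absorption rate by the standard photon-flux
formula k_exc = σΦλ/(hc) with CODATA h, c.  This reproduces the benchmark
steady-state dark fraction of free Cy5 at 16 kW/cm², 640 nm (53.7%,
i.e. "around half").

A three-state extension of the cyanine scheme (N, P, T) handles the minor
triplet buildup seen only at very high irradiance; it is solved by matrix
exponential and activates automatically above a configurable threshold
(default 100 kW/cm²).  Below the threshold the two-state closed forms are
used; occupancies from the matrix-exponential path are renormalized to
strip floating-point drift, since the rate matrix conserves probability
exactly.

**Parameter defaults** (all stored in SI: cm², W/cm², s⁻¹):

| preset | scheme | values |
|---|---|---|
| `cy5_free` | isomerization | σ_N = 6.2×10⁻¹⁶ cm², k_iso = 29 μs⁻¹, σ_biso = 0.15×10⁻¹⁶ cm², k_biso^Th = 0, k10 = 10⁹ s⁻¹; triplet branch k_isc = 1.1 μs⁻¹, k_T = 0.5 μs⁻¹ |
| `cy5_suv` | isomerization | k_iso = 6.2 μs⁻¹, σ_biso = 0.042×10⁻¹⁶ cm² (slower isomerization when membrane-bound) |
| `cf640r` | triplet | σ_S = 4×10⁻¹⁶ cm², k_isc = 0.7 μs⁻¹, k_T = 0.5 μs⁻¹ |

k10 = 10⁹ s⁻¹ corresponds to the customary 1 ns excited-state lifetime and
is configurable.  These presets are the literature-fitted values for the
dyes they are named after and serve as generating ground truth throughout
the test suite.

## Stationary TRAST

A TRAST point is the pulse-averaged emissive fraction
⟨F_exc(w)⟩ = (1/w)∫₀ʷ[S](t)dt.  For two-state schemes and for the
monoexponential parameterization ([S](t) = 1 − A(1 − e^(−t/τ))) the closed
form 1 − A + (Aτ/w)(1 − e^(−w/τ)) is used, implemented with `expm1` so it
is stable for w ≪ τ; the three-state extension integrates the
eigen-decomposition of the rate matrix exactly.  Curves are normalized to
a reference width w0 (default: the smallest width of the series), which
cancels concentration, quantum-yield and detection factors.  A warning is
emitted when the model predicts more than 0.1% dark buildup already at w0;
note that the canonical free-Cy5 conditions (w0 = 100 ns, τ ≈ 12 μs,
A ≈ 0.45) sit slightly above this threshold (≈0.2%), which the
normalization handles but the warning makes visible.

The default width grid is 30 log-spaced points from 100 ns to 1 ms at duty
cycle η = 0.01 and constant illumination time t_ill = N·w = 5 ms.  At this
low η the per-train summation collapses to the single-pulse expression;
for η > 0.05 (or on request) the per-pulse path propagates incomplete
inter-pulse recovery through the train.  The inter-pulse recursion —
exponential recovery of the dark pool at the thermal rate over the gap
w(1−η)/η, combined with the in-pulse relaxation — is affine in the
start-of-pulse bright fraction, so its geometric fixed point is returned
in closed form.  The exact published recovery expression for this effect
is not printed anywhere we could source it; the recursion here is a
self-consistent reconstruction validated by round-trip recovery of the
generating thermal rate, not against an external reference.

Mixture TRAST curves combine a flat (non-isomerizing, relative brightness
Q) and a relaxing component; the mixture amplitude is R·A/(R + (1−R)·Q).
The global mixture fit shares Q across curves while each curve's cyanine
fraction may move within ±0.03 of its externally supplied value,
mirroring the protocol of fixing fractions from a companion FCS
measurement up to small pipetting differences.

## FCS

The dark-state FCS model is G(τ) = (1/N_m)·G_diff(τ)·
(1 + A/(1−A)e^(−τ/τ_dark)) with a 3-D Gaussian diffusion factor
G_diff = (1 + τ/τ_D)⁻¹(1 + τ/(s²τ_D))^(−1/2), structure parameter s = 5 by
default (s = ∞ gives the 2-D variant).  The exact diffusion term used in
the original instrument software is not printed; all recovery tests fix s
between generation and fitting, so results are insensitive to this choice.
The lag grid is a quasi-logarithmic multi-tau layout (16 points per
octave, 0.1 μs – 1 s).

Mixtures are brightness-squared weighted: w_i ∝ R_i·Q_i², normalized so a
single component reduces to the one-species formula.  Global fits share
the photophysical pair — (k_iso, σ_biso) or (k_isc, k_T) — across an
irradiance series with per-curve τ_D and N_m free, using
Levenberg–Marquardt with unweighted residuals (the convention for this
kind of data).  Free parameters are internally scaled (rates in μs⁻¹,
cross sections in 10⁻¹⁶ cm²) to keep them near unit magnitude.

One point worth recording: with the saturation factor included, the Cy5
FCS amplitude is *almost* but not exactly irradiance-independent — over
1–100 kW/cm² the relative standard deviation is ≈3% but the peak-to-peak
spread reaches ≈8%, because k'_iso bends sublinear at the top of the range
while k'_biso stays linear.

The burst filter excises bins above mean + kσ·SD of a binned intensity
trace, with the baseline statistics computed on the lower 90% quantile so
the bursts themselves do not inflate the threshold.  It is a simplified
stand-in for instrument-specific spike rejection and is applied to
synthetic traces only; raw-trace correlation of experimental data is out
of scope.

## Flow-TRAST

The excitation field is two Gaussian curtains along the flow axis (1/e
radius 15 μm, length 100 μm across the channel, default center separation
50 μm — the real separation was tunable and unpublished, so it is a free
config).  Peak irradiance can be calibrated from total delivered power via
the Gaussian integral √π·r·L_y per curtain.  Flow velocity is volumetric
rate over channel cross section (500 × 50 μm defaults); plug flow is
assumed over the mid-channel averaging window, so the parabolic profile
correction is out of scope.  Triplet buildup and photobleaching are
omitted: at the ≲3.4 kW/cm² peak irradiances and single-pass transit
times involved, both are negligible for these dyes.

The bright fraction N(t) along a transit obeys
dN/dt = −k'_iso(t)·N + k'_biso(t)·(1−N) with N(0) = 1 at entry.  The
integrator applies the *exact* exponential relaxation toward the local
steady state on each step (piecewise-constant rates, trapezoidal in the
rate samples), which keeps N ∈ [0,1] unconditionally; grids coarser than
0.5 relaxation phases per step are refused.  The default grid (≥2001
points, refined to ≤0.05 phases per step) agrees with a stiff LSODA
reference solution to |ΔN| < 10⁻⁴ (measured ≈2×10⁻⁶).

Profiles are Φ(t)·N(t) normalized to the first-curtain peak; a
non-isomerizing species reproduces the normalized excitation profile
identically.  Fits freeze the FCS-determined parameters (σ_N, σ_biso,
k_iso, Q) and globally fit only the thermal back-isomerization rate, plus
per-profile mixture fractions where applicable.  Because the real
measured excitation field and curtain separation are unpublished, these
fits are validated by self-consistent round trips (fit what the package
generates), not against the published profile shapes.

## Imaging and unmixing

Pipeline: background subtraction → bleach correction → 3×3 Gaussian
smoothing → w0 normalization → per-pixel monoexponential fit → 2-D
(A_TRAST, τ_TRAST) histograms → PDF-based unmixing.

Bleach correction assumes two w0 reference frames bracketing the series in
acquisition order and interpolates the per-pixel attenuation
geometrically (log-linearly), which inverts monoexponential per-frame
bleaching exactly; the correction is swappable since acquisition schemes
vary.  Per-pixel fits use bounded trust-region least squares with
data-driven starts (amplitude from the curve minimum, τ from the
half-decay width); failures are recorded as NaN, never raised.

Histograms use 50 linear amplitude bins on [0,1] and 60 logarithmic τ bins
on [0.5 μs, 1 ms]; the axis projections are smoothed with a σ = 1 bin
Gaussian kernel (avoiding zero-probability holes) and normalized to unit
area — per unit A on the linear axis and per unit log₁₀τ on the
logarithmic one.  Unmixing maximizes, over the cyanine fraction R, the
product over the two projected axes of R·PDF_cy5 + (1−R)·PDF_other
evaluated at the pixel's (A, τ); the published description ("a linear
combination of their PDFs") is ambiguous between a product and a sum over
axes and between joint and projected histograms, so the
product-of-projections form is the default and an additive variant is
available behind a flag.  The maximization is a 0.01-step grid search with
bounded local refinement (the objective is quadratic in R, so this is
cheap and exact to ~10⁻³).  Degenerate pixels (equal PDFs) return 0.5 with
a flag; pixels outside both supports return NaN.

## Synthetic data

Generators drive the package's own forward models (`trastkit.synthetic`):

- TRAST points are Poisson photon counts (expected count = photon budget ×
  relative signal, default budgets 10⁵–10⁶ per point), normalized noisy
  over noisy so the reference point's noise propagates as in a real
  measurement.
- FCS noise is multiplicative with relative SD level/√(lag index + 1),
  mimicking the decreasing variance of a multi-tau correlator at longer
  lags; the default level is 2%.
- Flow profiles carry 1% multiplicative noise.
- Cell stacks emulate the dual-label geometry of the imaging experiments:
  a nuclear-rim structure with a triplet-like label (A = 0.2, τ = 2.5 μs)
  and filaments with an isomerization-like label (A = 0.45, τ = 30 μs),
  at a default budget of 2×10⁴ counts per labelled pixel over a constant
  background of 20 counts, Poisson throughout, on a 48×48 frame — sizes
  chosen so a full pipeline run takes seconds.  The label masks are
  disjoint, so the per-pixel ground-truth fraction is binary.

What the generators do *not* emulate: camera read noise and fixed-pattern
noise, detector afterpulsing and dead time, diffusion-in-focus intensity
traces (FCS curves are generated at model level), pulse-shape
imperfections, cell-to-cell parameter variability, and spatial structure
beyond the rim/filament masks.  Passing recovery tests therefore
demonstrates correctness and identifiability of the estimators under
shot-noise-limited conditions, not robustness to every instrument
artifact.

All generators are driven by integer-seeded `numpy` Generators; outputs
are fully deterministic for a fixed seed.

## Problem sizes and reproduction

Recovery studies use 50 seeded replicates of three-irradiance FCS series
(the free-dye set at 10/30/100 kW/cm², the triplet set at 20/60/150
kW/cm²), five-velocity flow sets at 200–1000 μL/min, and single 48×48
image stacks; these sizes give stable means while keeping the whole suite
in the tens of seconds.  `scripts/acceptance.py --seed N --out out.json`
re-runs the headline computations from scratch and writes them as JSON.

## Known limitations

- No photobleaching, redox, or photoionized-state channels anywhere.
- The *cis* manifold is represented only through the lumped σ_biso.
- The curtain field is an idealized Gaussian pair; published experimental
  profile shapes are not reproducible without the measured field map.
- The burst filter and the FCS diffusion term are documented
  reconstructions, configurable but not validated against the original
  instrument software.
- Unmixing uses the two axis-projected PDFs, discarding the A–τ
  correlation within a species; with strongly correlated clusters the
  joint-histogram variant would be preferable.
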