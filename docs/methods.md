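# Methods

This note records the models implemented in `corneamech`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical decisions that matter.

## Phase-difference OCE

**Forward physics.** A pressure reduction Δp applied to the sealed chamber
compresses the cornea axially. Between the reference and deformed complex
B-scans, an axial displacement u_z produces a double-pass phase shift
4π·n·u_z/λ (λ = 878 nm, tissue refractive index n = 1.375). The analysis
chain is:

1. `complex_cross_correlation` — conjugate product R = B_ref·B_def\*,
   boxcar-smoothed over 6 px axially × 9 px laterally. The window is sized
   to the strain-imaging resolution of the emulated instrument (~26 μm
   axially at asu = 4.48 μm/px, ~112 μm laterally at 12.5 μm A-scan
   spacing). Smoothing uses `scipy.ndimage.uniform_filter`; its
   normalisation does not affect the phase.
2. `axial_strain` — Δε = λ·∠(R_s(z)·R_s\*(z+1))/(4π·n·asu). The angle is
   taken in (−π, π] with **no explicit unwrapping**: the lag-1 product is
   wrap-free for |Δε| < λ/(4·n·asu) ≈ 35.6 ‰, an order of magnitude above
   the few-permil strains of interest. Saturated pixels (|phase| ≥ 0.999π)
   are masked, not corrected.
3. `segment_cornea` — per A-scan, the axially smoothed log-intensity is
   thresholded halfway between its noise floor (column median) and peak;
   first/last crossings give anterior/posterior. Columns with < 1 decade
   of contrast or a < 3 px layer are discarded, boundaries are
   median-filtered across x (7 px), and only the largest contiguous
   segmented run is kept so isolated noise columns cannot masquerade as
   the apex. Geometric thickness = pixel extent · asu / n, averaged over a
   0.5 mm central zone around the apex (anterior minimum).
4. `mean_central_strain` — arithmetic mean of masked strain in either a
   0.5 mm-diameter physical central zone (default) or a 21 × 21 px block.
   Both modes exist because the emulated study states both and they are
   mutually inconsistent with the stated axial sampling; the discrepancy
   is preserved, not resolved.
5. `laplace_stress` / `estimate_modulus` — Δσ = Δp·R/(2·cct) with
   R = 1.5 mm (corneal radius of curvature) and 133.322 Pa/mmHg, then
   E = |Δσ|/|Δε|. Sign convention: a pressure *reduction* gives negative
   stress and compressive (negative) strain; the modulus is reported
   positive from the magnitude ratio.

**Estimator noise floor.** Because the specified operation order smooths R
*before* forming the lag-1 depth product, the two smoothed fields share
all but one row of speckle; the residual decorrelation leaves ~0.4 % SD on
the ROI-mean strain even on noiseless phantoms (worst case ~1 % across
seeds). Reversing the order (smoothing the lag-1 product, Kasai-style)
would be exact on noiseless data but would no longer be the implemented
estimator identity that the unwrap-oracle equivalence test pins down, so
the specified order is kept and the noise floor documented. At 30 dB SNR
the ROI-mean strain recovers within ~1.5 % and the full pipeline recovers
an injected modulus within ~3 % (dominated by the ±1 px thickness
quantisation of the phantom grid).

## Speckle phantoms (`synthetic.gen_oct_pair`)

The phantom is a curved layer with circular-arc boundaries (apex thickness
`cct`, radius 1.5 mm) on a flat zero background. Inside the tissue mask
each pixel holds fully developed speckle: complex circular-Gaussian
reflectivity of unit power. The deformed scan multiplies the reference by
exp(i·4π·n·asu·ε·d/λ) with d the pixel depth below the anterior surface —
a pure axial phase ramp, chosen so the lag-1 estimator is exact on
noiseless data and self-consistent with the thickness convention
(geometric thickness = pixel extent · asu / n). Additive complex white
Gaussian noise at `snr_db` (power ratio against the unit tissue signal) is
drawn independently for the two scans.

Deliberately **not** emulated: depth roll-off, dispersion, speckle
decorrelation, lateral/out-of-plane motion, heartbeat artefacts, and
depth-dependent strain. Passing round trips therefore validate the
estimator chain and its noise behaviour, not robustness to instrument
imperfections. The per-eye phase SNR of real data is unknown; the 30 dB
default is a free parameter of the emulation, with 25 dB exercised in the
property tests.

Grid defaults not fixed by the emulated optics: 160 depth px, 1000
A-scans at 12.5 μm spacing, apex at 30 px — sized so the arc stays in
frame across the 0.5 mm central zone with margin.

## 2D extensometry

**Conversions.** σ = F/(2π·R·cct) and the arc-chord strain
ε = (r/R)·arcsin(R/r) − 1 with r = (Δl² + R²)/(2Δl). The arcsin form is
used because the sin variant that appears in print is negative for small
Δl and non-monotone; the printed form remains available behind
`form="printed"` for comparison. The radius R is the **holder-aperture
radius, default 0.8 mm** (1.6 mm central opening): the deformed region is
the clamped aperture, not the whole cornea. ε is strictly increasing on
0 ≤ Δl ≤ R with ceiling π/2 − 1 ≈ 0.571; the numerical inverse
(`travel_from_strain`, Brent root-finding at float tolerance) is used by
the generators.

**Protocol splitting.** The relaxation segment is the longest
non-increasing force run (≥ 20 samples) starting near the running force
maximum; everything before is pre-conditioning, the persistent rise after
is the ramp. The relaxation clock re-zeroes at the plateau start, which
also defines σ(t₀) for the 100 s reduction statistic
100·(σ(t₀) − σ(t₀+100 s))/σ(t₀) (a *percentage* of initial stress, not an
absolute drop). Rupture is an instantaneous force drop exceeding 50 % of
the running maximum; a rupture before the 10–15 % window completes flags
the eye "premature" and the window slope is withheld.

**Prony fitting.** σ(t) = ε₀·(E∞ + Σᵢ Eᵢ·e^(−t/τᵢ)), all parameters
positive, fitted by variable projection: non-negative least squares
(`scipy.optimize.nnls`) for (E∞, Eᵢ) nested inside a bounded trust-region
optimisation of log τ (`scipy.optimize.least_squares`, tolerances 1e−15),
multi-started from every multiset of {1, 10, 100} s. Terms are reported
sorted by ascending τ; ties in residual resolve to the first multiset
found. On noiseless traces both published constant sets refit exactly —
including the nearly degenerate mutant pair (τ₂ = 56 s, τ₃ = 57 s).

**Identifiability.** Sums of three exponentials on a 120 s window are
sloppy. At 1 % stress noise the least-squares optimum routinely merges
the two slow terms or pushes τ₃ beyond the window *even when started at
the true parameters* — this is a property of the objective, not of the
optimiser. What is stably identified is the relaxation function itself:
across 50 seeded noisy traces the fitted E(t) tracks the truth within
0.4 % (median worst-case over the window), E(0) within 0.4 %, and the
model-implied 100 s reduction within ~0.2 percentage points. The property
tests assert these functional bounds; individual τ recovery is only
guaranteed (and tested) on noiseless data. Practical consequence:
group-level Prony constants from noisy data should be read as a curve
parameterisation, not as physically separated relaxation modes.

**Ramp generator.** The published window-slope moduli (tens of kPa)
combined with the stress scale of these geometries imply strains far
beyond the arc-chord ceiling long before 4 N; a literal 0.4→4 N ramp is
therefore not representable. `gen_ramp_trace` instead ramps strain
linearly to 0.20 (covering the analysis window) with stress affine in
strain at the target slope, starting at the 0.4 N stress; time follows
the commanded force rate. Recovery of the injected slope is exact to
float tolerance, which is what the round-trip checks require.

## Cohort statistics

Shapiro–Wilk on each group; Student's two-tailed independent t-test if
*both* groups pass (p > α = 0.05), Mann–Whitney U otherwise — requiring
both groups to pass is the conservative reading of a per-study gate. A
zero-range sample is treated as failing normality (Shapiro–Wilk is
undefined on constant data), which routes identical samples to the U
test. No multiple-testing correction is applied, matching the emulated
workflow; SDs are sample SDs (n−1). Summary "factors" are the larger
group mean over the smaller, rounded to one decimal.

## Study emulation pipeline

`RunConfig.study_default()` encodes the two-group study: 14 eyes/group,
group thickness and modulus distributions, per-group Prony constants, and
all physical constants (λ, n, asu, radii, 133.322 Pa/mmHg). Per eye, the
pipeline draws (cct, E_oct, E_ext), builds a phantom whose uniform strain
is the Laplace-implied σ/E, runs the full OCE analysis, generates and
fits a 1 %-noise relaxation trace and a ramp trace, and records recovered
values; failures are logged per eye without aborting the run. Seeds
derive from `numpy.random.SeedSequence([seed, group, eye, stage])`, so
runs are bit-reproducible and any eye can be regenerated in isolation.
The default emulation uses 512-A-scan phantoms to keep a full 28-eye run
in tens of seconds; the estimator behaviour is unchanged from the
1000-A-scan canonical phantoms used in the recovery tests.

## Known limitations

- The OCE modulus assumes a uniform thin shell under Laplace stress;
  depth-varying stiffness, bending and boundary effects are outside the
  model, as in the emulated analysis.
- Phantom thickness is quantised to the 4.48 μm axial grid, bounding
  end-to-end modulus recovery at ~1–2 % even noiseless.
- The synthetic cohort draws all per-eye quantities independently;
  real thickness–modulus covariance is not modelled.
- The reduction statistic depends on the plateau-start definition; traces
  without a detectable plateau refuse relaxation analyses rather than
  guessing an origin.
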