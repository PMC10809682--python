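# Methods

## Scope and model

`linacqa` implements the analysis side of linac beam-model QA: given
phase-space files tallied on a plane below the target and 3D water-phantom
dose grids, it characterizes the beam (spectra, angular distributions,
radial energy fluence, percentage-of-agreement scores) and compares dose
distributions against measurement-like reference scans (gamma index,
profiles, output factors). It performs **no radiation transport**: the
synthetic generator that feeds the pipeline is a parametric sampling model
of transport *outputs*, chosen so that every downstream statistic has a
known ground truth.

## Phase-space format

A single fixed dialect is used: 25-byte little-endian records (1-byte
signed particle code, float32 energy/x/y/u/v/weight) with a plain-text
companion header. Two flags ride on signs, following the common convention
for this kind of format: the sign of the particle code carries the
direction of travel along the beam axis, and a negative stored energy marks
the first particle of a primary history. The z coordinate is constant over
a file and lives in the header; the magnitude of the z direction cosine is
derived as √(1 − u² − v²), with a tolerance of 10⁻⁶ on u² + v² overshoot
before a record is declared corrupt. Reading streams the binary payload in
chunks (default 2¹⁸ records) so file size does not bound memory.

Coordinates: +z from target toward isocenter, x crossline, y inline, units
cm and MeV throughout. Tally planes at different distances from the target
(e.g. 26.70 vs 25.45 cm) are *not* corrected for in any statistic; the
plane position is metadata only. The intervening air layer has a negligible
effect on the distributions at these energies, and carrying the correction
would imply a transport model the package deliberately does not contain.

## Synthetic beam model

Primary electrons: energy ~ Gaussian(E₀, σ_E) truncated at E > 0 by
resampling; focal spot ~ circular Gaussian(0, σ_R) in x and y; optional
Gaussian divergence ε (mrad, per transverse axis, small-angle tangent
construction). Presets for the four flattened beams studied carry
(E₀, σ_E, σ_R) = (6.18, 0.053, 0.072), (8.74, 0.074, 0.089),
(10.7, 0.091, 0.085), (13.5, 0.115, 0.061) MeV/MeV/cm. ε defaults to 0
mrad: its documented values could not be established unambiguously and none
of the analyses here depend on it.

Photons per history ~ Poisson(yield_per_history, default 0.5). Each photon
crosses the tally plane at a position drawn uniformly on a disc
(plane_radius, default 10 cm — flat planar fluence, which makes uniformity
properties exactly testable), with direction from its history's focal-spot
position to the crossing point plus optional Gaussian angular scatter.
Energy is drawn from f(E) ∝ (E_max − E)·E^a·exp(−bE) on (E_cut, E_max)
(defaults a = 1, b = 0.5 MeV⁻¹, E_cut = 0.05 MeV, E_max = E₀) by inverse
CDF on a 4001-point table, then scaled by (1 − s·r) with
s = offaxis_softening (default 0.005 cm⁻¹) to soften the spectrum off
axis. None of these shapes is a physics claim; they are configuration with
the right qualitative structure (bounded bremsstrahlung-like spectrum,
radial softening, forward-peaked angular distribution).

The `15MV-discrepant` preset adds Poisson(0.4 · n_band) extra photons in
the 0.10–0.75 MeV band within 1 cm of the CAX, reproducing qualitatively a
surrogate head whose target/flattening-filter assembly differs from the
reference design for the highest energy.

All generators are pure functions of (configuration, size, seed); streams
use a counter-based Philox generator seeded per call, so identical seeds
give byte-identical outputs.

## Beam statistics

* Spectra are **fluence-weighted** (Σ weight per energy bin), angular
  distributions are per unit solid angle (Σ weight / ΔΩ with
  ΔΩ = 2π(cos θ_lo − cos θ_hi)), and the radial distribution is
  **energy-fluence-weighted** (Σ E·weight per ring area). Planar
  quantities count plane crossings without dividing by |cos θ|.
* Bin values are per original history (header count); histograms from
  files with different history counts are each normalized by their own N
  before comparison. Per-bin uncertainty is √(Σw²)/N.
* Binning is half-open [lo, hi) with the final bin closed. Energy bins
  default to 50 keV, angular bins to 0.5° over [0°, 90°], the radial
  distribution to 0.2 cm rings up to 5 cm. Backward-travelling particles
  are accumulated into a separately reported overflow weight, never
  silently dropped.
* The spectrum bin value is a per-history *content* (Σw/N), not a density;
  with the uniform default binning the PA score is identical either way,
  and the content convention makes conservation checks exact
  (Σ value · N = Σ in-region weights).

**Percentage of agreement.** PA = 100·[1 − δ/max(A₁, A₂)] with areas
A = Σ value·Δbin and δ = Σ|f₁ − f₂|·Δbin. δ is read as an integrated
absolute difference — an area, commensurable with the denominator. For
histograms with disjoint support and equal areas the raw formula reaches
−100; PA is clamped at 0 so the score stays a percentage. Both areas zero
defines PA = 100. The default region set is seven 1-cm rings [0–1]…[6–7]
plus the 0–6 cm circle (eight regions).

## Synthetic dose model

Depth dose D(z) = D₁₀₀·OF(field)·(1 − e^(−μ_b z))·e^(−μ_a z) with
μ_b = 2.2 cm⁻¹, μ_a = 0.045 cm⁻¹ by default, giving a dose maximum at
z_max = ln(1 + μ_b/μ_a)/μ_b ≈ 1.78 cm and ~4%/cm distal falloff —
a 6 MV-like flattened beam. Lateral profile
0.5·[erf((F/2 − x)/√2σ) + erf((F/2 + x)/√2σ)]·(1 + c·x²) with penumbra
σ = 0.3 cm, optional horn coefficient c, and the field side F projected to
depth by (SSD + z)/SSD with SSD = 100 cm. The 3D grid dose is the
separable product PDD(z)·profile(x, z)·profile(y, z); grids use 0.15 cm
pitch along x and depth (the scan directions) and 0.5 cm along y, with the
CAX on a column of voxel centers.

The default output-factor table
{2: 0.92, 3: 0.94, 6: 0.97, 10: 1.00, 15: 1.02, 20: 1.04, 30: 1.055,
40: 1.06} is a typical flattened-beam scatter-factor curve; intermediate
fields interpolate linearly.

**Noise model.** Independent per-voxel Gaussian with σᵢ = k√Dᵢ, so the
relative uncertainty k/√Dᵢ falls with dose like Monte Carlo batch
statistics. k is calibrated in closed form,
k = target / mean(1/√Dᵢ over voxels with Dᵢ > D_max/2), making the mean
relative uncertainty over half-maximum voxels equal the target exactly for
the stored uncertainty raster (the measured value on the noisy grid moves
by well under the ±5% contract). No voxel-to-voxel correlations are
modelled.

**Reference scans.** The measurement-like dataset samples the analytic
model directly (no voxelization): depth dose every 0.1 cm through the
buildup region then 0.5 cm, crossline every 0.2 cm within 1.5 cm of the
projected field edge and 0.5 cm elsewhere, fields {3, 6, 10, 20, 30} cm by
default. Depth doses are normalized to their maximum (= 100), lateral
profiles to the CAX value (= 100) — the universal commissioning
conventions.

## Dose comparison

* **Trilinear extraction** uses `scipy` regular-grid interpolation over
  voxel centers; it is exact at centers and for affine dose fields, and
  refuses to extrapolate (out-of-hull points raise, listing offenders).
* **Gamma** is **global** by default: ΔD = dose_pct/100 · norm_value with
  norm_value = 100 after the profile normalizations, so "2%" means 2% of
  the normalization dose. Local gamma is available behind a flag. No
  low-dose threshold is applied by default (a flag exists).
* The search runs along the reference scan line: window
  3·DTA around each point, evaluation sub-sampled at step_fraction·DTA
  (default 1/10) including the point itself, by linear/trilinear
  interpolation. A DoseGrid evaluation is first rescaled to the
  reference's normalization convention. Reference points whose window
  leaves the evaluation domain are excluded from the pass rate and
  counted, never extrapolated.
* `gamma_brute_force` re-implements the definition with a naive per-point
  loop at a dense step of DTA/100 (window/⌈100·factor⌉ exactly, guarding
  against float round-up so the candidate grids of the two implementations
  coincide when the fast path is run at step_fraction 0.01). It is the
  equivalence oracle for the fast path and is intended for instances of
  ≲10³ points.
* The default step of DTA/10 is an accuracy/cost trade-off: on steep
  penumbrae it quantizes γ at the few-10⁻³ level, which is far below the
  criteria resolution that matters for a pass rate but visible when
  comparing against the dense oracle — equivalence checks therefore run
  both at the same dense step.
* Output factors are CAX dose ratios at 10 cm depth against the
  10 × 10 cm² reference field (configurable); uncertainties combine the
  two interpolated voxel relative uncertainties in quadrature, with the
  reference entry exactly 1 ± 0.
* Mean statistical uncertainty is averaged over voxels with dose
  **strictly above** half the maximum.

## Normalization caveat for scale errors

Because depth doses are renormalized to their maximum and lateral profiles
to the CAX, a pure output (calibration) error cancels in profile gamma
comparisons — by construction, not by accident. A 3% output error is
therefore demonstrated on the common dose scale (reference and scaled
evaluation passed as already-normalized point sets), where it drives the
in-field plateau pass rate to 0: the dose term alone is 1.5 and the
plateau gradient is too small for the spatial search to compensate. Scale
errors in practice are caught by output factors, not by normalized
profiles.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
per-history normalization, Poisson photon yield, radial softening, flat or
Gaussian-perturbed angular structure, buildup/attenuation depth dose,
erf penumbrae, √D noise. It does **not** reproduce electron contamination,
spectral detail of a real target/flattening filter, scatter tails,
voxel-to-voxel noise correlation, or detector volume averaging. Passing
tests therefore validate the *analysis machinery* (binning, scores,
interpolation, gamma search, normalizations, round trips) — they say
nothing about any particular clinical machine, and the preset spectra must
not be read as vendor-equivalent beam models.

## Problem sizes

Unit and acceptance tests run on 10³–10⁵-record phase spaces, 10⁶-history
samples for parameter recovery, and phantom grids up to ~7 × 10⁶ voxels
(30 cm field, 0.15/0.5 cm pitch, 32 cm depth); the whole suite completes
in well under a minute on one CPU. These sizes were chosen so every
stochastic tolerance (3–4 SE envelopes, χ² at p > 0.01) has comfortable
power while remaining desk-scale.

## Known limitations

* PA comparisons between *independently generated* phase spaces are
  noise-limited at desk-scale statistics: the per-bin counting noise sets
  a PA floor well below what ~10⁸-history production files would give, so
  cross-file PA values here are qualitative (self-comparison = 100,
  perturbed < base) rather than calibrated.
* The gamma search is one-dimensional along the scan line, matching the
  profile-versus-grid comparisons performed here; no volumetric 3D gamma.
* Phase-space dialect is fixed; no EGS-mode or LATCH-bit variants, no
  compressed containers.
* No absolute dosimetry: all doses are relative, and the output-factor
  table is configuration, not physics.
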