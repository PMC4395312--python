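# Methods

## Coordinate convention and units

All geometry lives in a section-local frame: origin at the central canal,
X medio-lateral (lateral positive), Y dorso-ventral (dorsal positive), in
*normalized hemicord units* — the baseline canal-to-lateral-edge distance is
1. On this scale, directional SDs of a motor pool are ≈ 0.1–0.25 and scatter
indices ≈ 5·10⁻⁴–4·10⁻³, consistent with the magnitudes group means are
reported on (π·0.11²·0.13² ≈ 6.4·10⁻⁴). Sections are indexed 0-based,
anterior → posterior, at a nominal 40 µm spacing; coordinates are continuous
reals (no pixel grid).

## Geometry pipeline

**Rigid alignment.** Every section is registered to the *first* section of
its series (an arbitrary but deterministic template) by the least-squares
rigid transform (rotation + translation, Kabsch/SVD with the reflection
excluded) fitted on the four optical reference points, applied to neurons
and all landmarks. A rigid rather than similarity transform is deliberate:
all scale correction is confined to the normalization step, so the diameter
trend cannot be corrected twice. Collinear or coincident fiducials raise a
geometry error naming the section. Per-section RMS residuals are reported;
with exact fiducials they are at machine precision, with fiducial noise of
SD s they are O(s).

**Reference curve and intercept.** The five lateral-edge landmarks (ordered
dorsal → ventral) define an interpolating cubic spline parameterized by
cumulative chord length. The section's radius proxy is the distance from the
central canal to the intersection of this curve with the line through the
canal perpendicular to the mid-sagittal axis. Intersections are bracketed on
a 512-point parameter grid and polished by Brent's method to 1e-10 in the
parameter. If several intersections exist, the lateral-side one nearest the
canal is used (the geometry of a hemicord arc admits exactly one in all
non-pathological cases). A section with no lateral intersection is dropped
with a logged warning rather than aborting the series, mirroring tolerant
manual workflows.

**Diameter normalization.** Intercept distances d_i are smoothed along the
section index with a cubic smoothing spline whose smoothing factor is
n·σ̂², where σ̂² is estimated from *third* differences of d_i
(Var(Δ³d) = 20σ² for white noise). Third differences annihilate
locally-quadratic trend, so a smooth enlargement profile is tracked almost
exactly (a noiseless profile is interpolated, making undistorted recovery
exact) while isolated outliers and measurement noise are damped. Each
section is then scaled isotropically about its central canal by D/d̂_i with
D the mean smoothed distance, flattening the smoothed profile at D. The
optical fiducials belong to the imaging frame, not the tissue, and are not
rescaled. An alternative reading — rescale raw to smoothed distances,
`trend="smoothed"` — denoises but *preserves* the enlargement trend; it is
available behind a flag and is not the default because it does not correct
the enlargement.

Because the smoothing factor is re-estimated from the already-flattened
profile, a second normalization pass can move coordinates by the residual
smoothing ripple (≲0.2% of a hemicord unit under default distortions);
normalization is exactly idempotent only for noise-free flat profiles.

**Projection.** All neurons of a pool are pooled across sections into one
2-D cloud (z discarded). Whether to analyse projected pools or per-section
clouds is a genuine design fork; the projected-pool reading is implemented
because the reconstruction schematics this analysis follows are themselves
anterior–posterior projections. A single hemicord is assumed per series
(labeling is unilateral); no left/right mirroring is applied.

## Scatter index

SI = π·λ₁·λ₂ with λ the eigenvalues of the sample covariance (n−1
denominator) of the pooled cloud — the eigen*values* (variances), not their
square roots, exactly as the defining formula states. The numerical
consistency of π·0.11²·0.13² with the published wildtype ventral mean
confirms this reading. The reported ellipse has semi-axes √λ (directional
SDs along the principal axes) so a drawn ellipse has width matched to the
spread; both λ and √λ are reported to avoid ambiguity. A minimum of 3
points is required (covariance rank); below that SI is undefined rather
than 0. Directional scattering is the plain sample SD of x and of y.
Centering choices are immaterial: covariance is translation invariant.

## Synthetic generator

The generator emulates the measurement process, not images:

- **Pools.** Per animal, each pool is a bivariate normal cloud
  (ground truth), assigned uniformly to sections. Defaults: 30 sections,
  60 neurons/pool, ventral center (0.50, −0.55), dorsal center
  (0.50, −0.25), zero ML–DV correlation (group reports are axis-aligned).
- **Enlargement.** A mean-one Gaussian bump in diameter
  (amplitude 0.3, width 5 sections by default) scales tissue (neurons +
  lateral edge) about the canal. Normalizing the profile to unit mean makes
  the enlargement a relative modulation: the mid/end diameter ratio is
  ≈ 1 + amplitude while coordinates stay on the common hemicord scale, so
  pipeline output is directly comparable to ground truth.
- **Misalignment.** Per-section rigid jitter (rotation SD 0.05 rad,
  translation SD 0.05 units) applied to everything including fiducials;
  landmark noise (SD 0.005 units) on the edge points and fiducials.
- **Landmarks.** Edge landmarks at fixed polar angles ±70°, ±35°, 0° on the
  hemicord arc; four fixed fiducials outside the grey matter. No placement
  rule is published; these are package choices.
- **Cohorts.** Group presets carry the published group means, SEMs and Ns
  for anatomy (ventral-pool directional SDs), ladder-rung behavior at
  4/8/12 weeks, synapse counts and PNN category probabilities. Between-animal
  SDs are SEM·√N. Dorsal-pool SDs are not published; they are derived from
  the published dorsal pool areas assuming isotropy, σ = (SI/π)^¼, and a
  missing ventral σ_ml at 4 weeks is back-solved from the published area and
  σ_dv. The enrichment-from-4-weeks cell at 4 weeks of age equals the
  normal-housing cell (enrichment has not started).
- **Behavior.** Per-animal values are means of 3 trials. The marginal
  between-animal SD matches SEM·√N; 30% of it is allotted to trial noise and
  animals share a latent performance factor giving a between-timepoint
  correlation of 0.6 (a mid-range test-retest correlation for rodent motor
  assays; the published group statistics do not constrain it).
- **Counts and categories.** Synapse counts are Poisson around a per-animal
  mean drawn at the preset SEM·√N (N = 3), 20 neurons/animal; PNN categories
  are multinomial over 60 neurons/animal at the preset probabilities.
- **SI–behavior link.** A linear link with configurable slope/intercept/
  noise. The published relation does not define which variable was the
  regressor, so orientation is a parameter of the regression
  (default: SI regressed on crossing time, matching the magnitude of the
  published slope in SI units per second).

What the generator does **not** emulate: image noise and segmentation error,
non-rigid tissue deformation, left/right asymmetries, anterior–posterior
trends in pool shape, non-Gaussian pool geometry, and count overdispersion
beyond Poisson. Passing recovery tests therefore demonstrate correctness of
the *algorithms* under the stated measurement model, not robustness to every
artifact of real histology.

## Statistics

- Two-group policy: Shapiro–Wilk per group at α = 0.05 (the normality test
  is not named in the source convention; Shapiro–Wilk is the standard small-N
  choice); both normal → unpaired two-tailed Student's t, otherwise
  Mann–Whitney U — exact two-tailed null for combined N ≤ 20 without ties,
  normal approximation with tie correction above. Identical constant groups
  return p = 1 by convention with a note.
- Longitudinal behavior: two-way mixed ANOVA (between = genotype,
  within = timepoint) via `pingouin.mixed_anova`, complete-case with a
  warning for dropped animals; the genotype × time interaction p is the
  criterion; no sphericity correction is applied to it by default (logged).
- The statistical unit is the animal everywhere: synapse counts and PNN
  categories are averaged (fractioned) within animal before testing, so
  N equals the number of animals.
- No multiple-testing correction by default (per-comparison reporting);
  Holm adjustment is available as `stats.holm_correct`.

## Problem sizes and numerical tolerances

Recovery and calibration checks are run at sizes chosen to make their Monte
Carlo error small relative to the asserted bounds: 50 series × 30 sections ×
120 neurons for geometry recovery (median relative SD error < 5% asserted,
< 0.5% typical), 1000 replicates for type-I calibration (binomial SE ≈ 0.7%
around 5%), and 100 cohort replicates for the significance-pattern checks.
The acceptance script averages SI over 200 pools of 100 neurons per group
(SE of the mean ≈ 1.5%). Intercept roots are found to 1e-10; rigid
round-trips are asserted at 1e-9; the SI eigenproduct agrees with π·det(Σ)
to 1e-12 at the covariance scale.

## Known limitations

- The small-sample bias of the SI (E[det Σ̂] = (n−2)/(n−1)·det Σ) is not
  corrected, matching the plain covariance definition; at n = 60 it is ≈ 2%.
- The smoothing-spline noise estimate assumes approximately white intercept
  noise; strongly autocorrelated landmark error would be partially absorbed
  into the profile.
- The exact Mann–Whitney path refuses ties (falls back to the corrected
  normal approximation), which is conservative for very small tied samples.
- Behavior slips are modeled as continuous (3-trial means), clipped at zero;
  extremely low slip rates are therefore slightly zero-inflated relative to
  a count model.
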