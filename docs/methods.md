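# Methods

This note documents the models, parameter choices and numerical decisions
behind `myodti`, and what the synthetic-data tests do and do not demonstrate
about real microscopy data.

## Stress mapping

A dead-weight flat circular indenter applies an external direct stress
σ_ext = F/(πr²) (reported in kPa; masses in g/kg and forces in N are
converted, g = 9.81 m/s² by default). The average compressive stress inside
the muscle layer is lower than the interface pressure. Rather than solving
the axisymmetric hyperelastic contact problem, the package uses the linear
structure of the finite-element result: the difference σ_ext − σ_int grows
linearly with σ_ext. `calibrate_internal_map` fits
σ_ext − σ_int = c₀ + c₁·σ_ext by ordinary least squares; the default
calibration uses the two bundled FE operating points (5 → 3.4 kPa,
103 → 69.1 kPa), giving c₁ ≈ 0.3296, c₀ ≈ −0.0480 and a 32 % reduction at
5 kPa. Predictions are clamped into [0, σ_ext]: the line can otherwise
predict a negative internal stress (c₀ > 0) or one above the interface
pressure (c₀ < 0) near zero load, neither of which is physical. With only
two calibration points R² is trivially 1; users with a full FE point set can
supply their own pairs in the configuration.

## Boltzmann stress–time thresholds

Cell tolerance is summarised by the decreasing four-parameter sigmoid
σ(t) = K/(1+e^{α(t−t₀)}) + C with K > 0 (kPa), α > 0 (min⁻¹), t₀ (min),
C ≥ 0 (kPa). Fitting minimises vertical (stress) residuals — stress is
modelled as a function of time — over box bounds:

- K ∈ (0, 50] kPa, α ∈ (0, 5] min⁻¹ — sanity boxes far wider than any
  plausible muscle threshold;
- t₀ confined to the observed time range (a midrange time outside the design
  is not identifiable);
- C ∈ [0, 6) kPa for cell-death fits and C ∈ (3.7, 20] kPa for no-damage
  fits — the conservative asymptote constraints that keep the cell-death
  curve below all cell-death points and the no-damage curve above all
  no-damage points at long durations.

The SSE surface of a sigmoid has local minima (e.g. flat-line fits with
extreme α), so the solver is multi-start: 16 Latin-hypercube starting points
over the bound box plus one data-driven start (K ≈ range of σ, t₀ ≈ median
t), each polished with a trust-region-reflective bounded least-squares
solver, and the winner re-polished so the returned parameters are a fixed
point. On noiseless data from any in-bounds truth this recovers all four
parameters to machine precision (verified over randomised truths in the test
suite). Parameters can alternatively be fixed (e.g. imposing a published α
and t₀ and estimating only K and C), since both workflows occur in practice.
The exponential argument is clipped at ±700 to avoid overflow; the curve is
saturated there anyway.

The package bundles two canonical fitted curves as constants — cell death
(K = 16.2, α = 0.5, t₀ = 90, C = 5.5) and no damage (K = 13.1, α = 0.5,
t₀ = 90, C = 4.2) — plus in vivo reference parameters reconstructed from the
reported reductions (K lower by 6.8 kPa and C by 3.1 kPa ex vivo, reference
α = 0.15 min⁻¹). The published record for these curves is internally
inconsistent: the printed equations carry α = 0.5 min⁻¹ and t₀ = 90 min
while the accompanying comparison table reports fitted α = 0.54/0.57 min⁻¹
and t₀ = 89.5/87.8 min. The package treats the printed equations as
canonical and does not attempt to adjudicate; anyone needing the table's
values can construct a `ThresholdModel` directly.

## Image quantification

**Preprocessing.** Background is estimated by grayscale morphological
opening with a disk (default radius 50 px; use ≳ 3× the fiber radius so
fibers are not absorbed into the background) and subtracted; the residual is
rescaled to [0, 1] by clipping at its 0.1th/99.9th percentiles. An optional
8-bit quantisation step mirrors acquisition pipelines that convert to 8-bit
before analysis; thresholds are computed on the same preprocessed scale
either way.

**Control threshold.** The dye-positivity threshold is the pooled mean dye
intensity over the *whole tissue region* of the sample's unloaded control
sections — fibers and the interstitial network together (the mask is the
morphological closing of the fiber foreground over the gaps). Pooling pixels
rather than averaging per-section means is exact for equal-area sections and
simpler otherwise. Including the interstitium matters: staining residue
retained in the endomysial space lifts the pooled mean above the
viable-fiber intensity range, which is what makes the "combined average"
rule a usable per-fiber cutoff (a mean taken over fiber pixels alone sits in
the middle of the viable-fiber distribution and would mark ~half of intact
fibers positive). A fiber is dye-positive iff its mean dye intensity
strictly exceeds the threshold — a per-fiber mean rule, not a per-pixel
fraction rule.

**Segmentation.** Default segmenter: Otsu foreground on the preprocessed
autofluorescence channel, Gaussian-smoothed Euclidean distance transform,
peak seeding (`peak_min_distance`) and watershed, with components below
`min_area` discarded. Defaults (`peak_min_distance=4`, `smoothing_sigma=1.5`,
`min_area=30`) suit fibers of ~8 px radius; as a rule of thumb use
`peak_min_distance ≈ 0.5–0.6` and `smoothing_sigma ≈ 0.15–0.2` times the
expected fiber radius in pixels. The segmenter is deliberately pluggable
(any callable mapping a preprocessed channel to a `FiberLabelMap`), so a
trained neural instance segmenter can be swapped in without touching the
rest of the pipeline.

**Counting region.** "Indented area" is a disk of configurable radius around
a user-supplied indent center; the default is the whole section, appropriate
when the indentation site was not recorded. Coordinates are 0-based
row/column pixel indices; areas are px² with µm conversion via `pixel_size`.

## Damage classification

The damaged/intact call is spatial. Per section, the statistic is the mean
pairwise distance among dye-positive fiber centroids; the null distribution
comes from equal-size subsets drawn uniformly from all fiber centroids, and
the p-value is the left-tail permutation rank (1 + #{null ≤ obs})/(1 + n_null)
— small p means the positives are more clustered than random fibers.
Sections with fewer than three positives are undefined and count as not
localized. The null subset sums are evaluated as sᵀDs with indicator rows in
float32 (chunked), which keeps a few thousand draws per section cheap.

A sample is localized when at least one section is significant. Because six
sections are tested per sample and a single falsely-localized intact sample
drags the count baseline down (the baseline is the *minimum* mean count over
localized samples) and thereby misclassifies every intact sample above it,
the classification stage applies a Šidák correction by default — across all
sections of the study (`sidak-study`), with per-sample (`sidak`) and
uncorrected variants available. The corrected alpha needs fine p-value
resolution, so study scoring is two-stage: every section is screened at
n_null = 199, then the minimum-p section of each sample (the only one that
can drive the call) is re-scored with fresh n_null = 2999 draws. Refinement
with fresh draws after selection remains a valid p-value for that section
and only reduces the family-wise error relative to refining all sections.

Baseline and labels: baseline = min mean count over localized samples;
`cell_death` iff mean count ≥ baseline (the boundary sample is itself
damaged, hence the inclusive convention). Exclusions are explicit user
inputs (sample id + reason), never automatic — outliers are a judgement
call, and the run report logs them. Fit points use the *internal* stress
coordinate, since that is what the fibers experience.

## Synthetic data

The generator emulates, at two levels, the study conditions of a
stress–time loading experiment; its defaults are fixed and the tests run
against them.

**Scene level.** Fibers are cells of a jittered hexagonal tessellation
(jitter ±22 % of the spacing) inside a roughly circular tissue region
(radius 0.47× the image side), separated by ~2 px interstitial gaps
(widenable via `extra_gap` for well-separated geometries). Intensity model:
per-fiber lognormal autofluorescence (median 0.6, σ_log 0.2), dim
interstitial autofluorescence (0.2, collagen); dye channel with faint
per-fiber viable baseline (median 0.04), interstitial staining residue
(0.3) and a strong per-fiber level on dead fibers (0.55); additive Gaussian
noise (sd 0.01) plus a signal-dependent term (0.05·√signal), clipped at
zero. Dead fibers are planted exactly — round(fraction·n) — either uniformly
(scattered) or with probability ∝ a Gaussian kernel at the indent center
(localized; kernel width 10 % of the image side). Everything is
deterministic given the seed.

Not emulated: point-spread blur, chromatic effects, illumination gradients,
stitching seams, partial dye uptake, and real fiber-shape variability.
Passing the counting tests therefore shows the pipeline's logic and
statistics are sound under a faithful-but-clean imaging model; it does not
certify segmentation accuracy on real micrographs, where the pluggable
segmenter exists precisely so a stronger model can be substituted.

**Study level.** The default design is 12 samples — four durations
(30/60/90/120 min) × three internal stress levels anchored at the
protocol's printed stresses (3.4, 21.1, 22.5, 69 kPa) with mid levels
interpolated into the band between the two canonical curves (the full
12-point stress list is published only graphically, so the interpolated
levels are a documented choice). Ground-truth labels follow the canonical
curves; conditions inside the uncertainty band get a stochastic label with
probability interpolated between the curves. Per-section counts are
negative binomial (damaged mean 170, undamaged mean 70, dispersion 30),
chosen so damaged sample means fall within the observed 110–254 range of
real studies and undamaged means sit below — an emulation, not a
reproduction. Section point patterns are localized (damaged) or scattered
(undamaged); full image rendering is optional (`simulate_study_to_dir`)
since centroid-level patterns suffice for the classification stages.

## Problem sizes in the test suite

The suite renders 512 px / 800-fiber sections for the counting and
false-positive checks (20 + controls), runs 500 null replicates for the
localization type-I calibration, 50 for power, and classifies ten full
12-sample studies at centroid level; threshold-fit recovery uses 7 time
points × 5 replicates at 0.3 kPa noise, matching the scale at which the
canonical curves were established. These sizes give stable Monte-Carlo
estimates while keeping the default run in the low minutes.

## Known limitations

- The internal-stress map is a two-point linear calibration by default;
  it reproduces the FE operating points exactly but carries no uncertainty.
- The localization test assumes positives are a subset of detected fiber
  centroids and tests clustering of any shape, not specifically
  indent-centred clustering (a ring of death at the indenter edge would also
  register as localized).
- With one sample per load–duration condition — the realistic regime — the
  Boltzmann fit is weakly identified and can sit at a bound (visible as a
  large SSE in the report); the fitter reports what the data support rather
  than hiding it.
- Real baselines, count ranges and fitted α/t₀ from the original tissue
  images cannot be reproduced here (raw data unavailable); the test suite
  substitutes property-based checks against synthetic ground truth.
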