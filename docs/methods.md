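# Methods

## The deficiency statistic

Raw per-ROI mean intensities are background-corrected by subtracting the
mean intensity of a matched no-primary-control (NPC) image, then natural-log
transformed. The natural log (rather than log10) is used because Z-scores
are invariant to the base and the natural log makes the generator-inversion
oracle exact. ROIs whose corrected value is non-positive in a channel are
*flagged excluded* for that channel and retained, never dropped: flooring at
an epsilon would fabricate extreme negative log values that distort the
control regression, and silent dropping would bias pool sizes.

The reference ("control") pool samples an equal number of islets from each
reference mouse — the minimum per-mouse ROI count, drawn without
replacement, seeded — so that no mouse dominates the fitted model. The
"equal number" rule is applied per mouse rather than per group; a
single-mouse (or single-population, e.g. β-cells-only) reference uses all
its ROIs with a logged warning. One seeded draw is made per analysis rather
than averaging repeated resamples; the seed is a first-class parameter and
is recorded in the serialized model.

On the pool, log-TOMM20 and log-insulin get location/scale models (sample
mean, sample SD with n−1; whether an n or n−1 convention is used upstream
of this implementation is not standardised, and n−1 is chosen here).
Each subunit (NDUFB8, MTCO1) is regressed on log-TOMM20 by OLS
(statsmodels), with SEE = √(RSS/(n−2)) using the regression residual
degrees of freedom. Insulin is scored unconditionally — location/scale only,
not regressed on TOMM20 — since insulin content is not a mitochondrial
protein and carries no mass-conditional expectation here. Residual normality
is checked with Shapiro-Wilk at α = 0.01 and is warn-only: a failed check
flags the SEE as suspect but does not abort, since the downstream Z-scores
remain well-defined as standardised residuals.

Degenerate guards: zero TOMM20 variance in the pool and pools below a
configurable floor (default 10) are errors; a (numerically) perfect subunit
fit is refused rather than allowed to emit infinite Z-scores — the guard
triggers below 1e−10 × SD(y) because floating-point OLS on collinear data
leaves ~1e−15 residuals.

Deficiency categories (deficient: Z < −3; low: −3 ≤ Z < −2) are
configuration defaults borrowed from SD-based deficiency-calling
conventions in single-cell immunoassays; they are *not* derived from the
data analysed here and are exposed as configuration.

## The synthetic generator

The generator is the study-condition oracle: it produces data with exactly
the structure the statistic assumes, so recovery tests are sharp.

Mitochondrial panel: latent log-TOMM20 ~ N(μ_T, σ_T); latent log-subunit =
β₀ + β₁·x − k·SEE + N(0, SEE), where k is the deficiency shift in SEE
units; raw intensity = exp(latent) + NPC background. Because background is
*added after* exponentiation, the subtract-then-log pipeline inverts the
generator exactly (to float rounding), which the tests exploit. Defaults:
μ_T = 6.0, σ_T = 0.35 (corrected intensities of a few hundred arbitrary
units with moderate islet-to-islet spread), slope ≈ 0.9, SEE = 0.25
(subunit signal tracking mass with realistic conditional scatter), NPC
means 20–35 AU. The mutant condition uses k_N = 2.5 (a pronounced complex-I
deficit) and k_M = 0.5 (a mild complex-IV change). Cohort sizes follow the
assay design: 50 islets/mouse for the mitochondrial panel, 25 islets/mouse
for the composition panel, 4 mice/group.

Composition panel: islets are non-overlapping ellipses (semi-axes 22–44 px);
cells are cytoplasmic disks (radius 4 px) with nuclear centres (radius
2 px) on a jittered grid so cells never overlap; classes are multinomial
per cell; with mantle placement, α-cells take the outermost radial
positions (radial-quantile rule), yielding the β-core/α-mantle architecture
of rodent islets. Ki67 marks flagged nuclei; a TUNEL-flagged islet carries
one apoptotic cell. Composition defaults: ~120 cells/islet, wild-type
α/β/bihormonal fractions 0.07/0.88/0.005 (β:α ≈ 13), mutant 0.24/0.72
(β:α = 3), Ki67 per-cell rates of 0.002 (wild-type) vs 0.008 for mutant
α-cells, TUNEL islet rate 0.02 — chosen to place the counted metrics at
the magnitudes a healthy-vs-mutator mouse contrast exhibits. A per-islet
multiplicative gain (uniform 0.7–1.4) emulates per-islet laser-power
optimisation and scales pixels only — the ground-truth cell table is
acquisition-invariant by construction.

What the generator does **not** emulate: point-spread blur, shot/read
noise (a Gaussian `noise_sd` exists but defaults to 0), spectral
bleed-through, illumination fields, 3D structure, and irregular islet or
cell shapes. Passing tests therefore demonstrate correctness of the
*computations* under the model's assumptions, not robustness to real-tissue
segmentation or staining artefacts; ROI masks are inputs, as they were
drawn manually in the assay this emulates.

RNG: one root seed; every operation derives a child stream from
(seed, fixed label) via CRC32-keyed `SeedSequence` spawning, so reordering
operations never perturbs another operation's draws and all outputs are
byte-reproducible.

## Cell classification

The assay identifies cells visually at per-islet-optimised laser power, so
the computational analogue must be gain-invariant. Default rule: a marker is
positive when its per-cell mean — perinuclear annulus (2 px band outside the
nucleus) for hormones, nuclear mean for Ki67 — exceeds 2× the islet's own
stromal background (median of islet pixels ≥5 px clear of any nucleus).
Referencing the islet's internal background, rather than splitting the
per-cell means bimodally, stays correct when a marker is absent from — or
present in every cell of — an islet; an Otsu bimodal-split mode is provided
as an alternative. Both are per-islet decisions and hence invariant to any
per-islet gain.

The "β-cell core" has no standard geometric definition; it is implemented
as the islet mask eroded by 30% of the equivalent-circle radius
(configurable), and a cell is in the core if its centroid falls inside the
eroded mask. Islet areas are mask pixel counts (× pixel area for µm²);
β:α ratios divide pooled β counts by pooled α counts, with a zero α pool an
explicit error. Mouse is the summarisation unit for Ki67 metrics; islet is
the unit for composition metrics.

## Group statistics

Shapiro-Wilk per group at α = 0.05 gates between Welch's unequal-variance
t-test (the safer default when "unpaired t-test" is unqualified) with
mean ± 95% CI summaries (t-quantile × SEM, n−1 df), and the two-sided
Mann-Whitney U with median (IQR) summaries. Constant samples, for which
Shapiro-Wilk is undefined, route to Mann-Whitney. Significance is p < 0.05
and no multiple-testing correction is applied — comparisons are reported
metric-by-metric and should be interpreted accordingly. Endpoint glycemia
is classified against the 13.3 mmol/l diagnostic cut-off for diabetes; the
boundary value itself counts as diabetic (the non-diabetic range is stated
as strictly below the cut-off).

## Problem sizes and numerical checks

The test suite and acceptance script use: 5-point closed-form regression
fixtures (identities to 1e−10); 500 islets per deficiency stratum ×
3 seeds, scored against a 2000-islet control reference, with stratum means
pooled over seeds (a single 500-islet stratum mean has sampling SE ≈ 0.045
in Z units, so per-seed checks against a ±0.1 band would be dominated by
that noise rather than by implementation error); rendered bundles of 4
islets × ~28 cells on 300² canvases for exact-count checks; and 10,000
replicates (n = 25/group) for type-I-error calibration. Full-run
determinism is asserted byte-for-byte on the pipeline artifacts.

## Known limitations

* Islets are pooled across mice within groups (no mixed-effects modelling
  of mouse as a random effect), mirroring the per-islet presentation of the
  assay; per-mouse hierarchical extensions are out of scope.
* The classification rule's `2×` background factor and annulus geometry are
  tuned to the renderer's noise-free contrast; real images would need the
  factor calibrated and probably the Otsu mode.
* NPC matching is one NPC image per batch via configuration; finer
  per-section matching is not modelled.
* The deficiency categories (−2/−3) are conventions, not calibrated
  clinical thresholds.
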