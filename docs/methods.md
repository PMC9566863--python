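# Methods

This note documents the models and procedures flyquant implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the original analysis
descriptions leave the design open.

## Coordinate and data conventions

Stacks are `(z, y, x)`, 0-based, half-open ranges throughout. Physical
scale is carried as `(µm per z-step, µm per xy-pixel)`; the default
z-step is 0.3 µm, the spacing typical of stacks spanning the full depth
of the tissue. Automatic thresholds operate on the gray-level histogram
only (native 256 levels for 8-bit data, 256 equal-width bins otherwise),
so they are invariant to pixel permutation by construction.

## Nuclear FOXO from two-channel stacks

The lamin immunostain rims each nucleus; FOXO is measured inside the
region the rim encloses.

1. **2D segmentation.** The lamin stack is maximum-projected and globally
   thresholded (Otsu by default; the moment-preserving method and fixed
   values are alternatives — the original MATLAB pipeline names no
   method, and Otsu is the canonical unnamed global threshold). Rim
   rings are hole-filled *before* cleanup, because the nucleus is the
   enclosed region, not the rim. Disk opening (radius 1 px), a 20-px²
   size floor, and a distance-transform watershed (seeds = h-maxima of
   the Euclidean distance transform, h = 1 px) yield per-nucleus
   footprints and centroids.
2. **No-signal guard.** An automatic threshold always splits a histogram,
   even of pure noise; a frame whose foreground/background mean-contrast
   ratio is below 1.5 is reported as empty rather than segmented into
   noise islands.
3. **z-scan.** For each footprint, the per-slice rim score is the mean
   lamin intensity on an *inner* boundary annulus of the footprint
   (3 px wide — the footprint is the filled projection of the rim, so
   the envelope signal concentrates just inside its boundary). The
   nucleus occupies the maximal contiguous run of slices, through the
   peak, whose score reaches `rim_fraction` (default 0.5) of the peak.
   The mask volume is monotonically non-increasing in this fraction.
4. **Per-slice mask.** Within an included slice the mask is the
   footprint ∩ the hole-filled thresholded rim minus the rim itself
   (the enclosed interior). A slice whose enclosed region falls below
   9 px is treated as a broken rim and falls back to the full
   footprint. Single-slice stacks have no depth information; there the
   footprint is the mask.
5. **Measurement.** Mean FOXO voxel intensity over the 3D mask, plus
   volume in voxels and µm³. One row per nucleus — the nucleus, not the
   fly, is the statistical unit of the downstream two-sided Wilcoxon
   rank-sum comparison (a per-fly aggregation is easy to add on the
   returned table but is not the default). A 2D alternative that
   averages the z-summation projection over the footprint is provided
   (`measure_nuclear_intensity_projected`), since intensity readouts are
   sometimes reported from summation projections; the 3D path is the
   default and both are exposed rather than guessing which produced a
   given figure.

On noiseless synthetic spheres the reconstructed volume lands within
15 % of 4/3·πr³ and the measured intensity is exact; at 5 % Gaussian
noise the per-nucleus mean stays within 5 % of truth (typically < 1 %).

## Puncta and integrated density

The ImageJ-style recipe: maximum projection → restrict to the ROI mask
(ROIs are inputs; drawing them is out of scope) → moment-preserving
threshold → watershed → count particles and the percentage of ROI area
covered. "Analyze Particles" defaults are kept: no size or circularity
exclusion unless configured (`min_size_px` is available and is useful
against single-pixel noise specks in 8-bit data). The threshold is
computed from ROI pixels by default (`roi_first`); a flag computes it
frame-wide instead, since the original order is unstated. A degenerate
histogram inside the ROI (blank tissue) yields zero puncta with a
warning, not an error. Integrated density is the sum of the z-summation
projection over the ROI, with the accumulator widened to avoid
overflow.

### Moment-preserving threshold

The threshold preserves the first three gray-level moments: the moments
determine a two-level distribution (levels z₀ < z₁, background fraction
p₀ = (z₁ − m₁)/(z₁ − z₀)), and the threshold is the histogram quantile
of p₀. When that quantile falls in a run of empty bins every threshold
in the run binarizes identically; the implementation centres the
threshold in the run (choosing the side of the cumulative jump whose
background fraction is closer to p₀), which is deterministic and places
the cut mid-valley on well-separated histograms.

## FLIC feeding events and the HDF contrast

A feeding event is signal above 40 a.u. Both readings of that rule are
implemented: `runs` mode (default) calls one event per maximal
contiguous supra-threshold run — a single feeding bout spans many
samples at any plausible sampling rate — and `samples` mode counts
every supra-threshold sample. Run-mode counts never exceed sample-mode
counts, and sub-threshold signal between bouts is invisible to the
detector. No debounce/merge gap is applied by default; a merge-gap in
seconds is available. Events are summarized over the first 3 hours
(half-open window on event starts; window splits are exactly additive).

The HDF contrast fits a two-way fixed-effects ANOVA (state × diet or
genotype) on per-fly event counts, then compares fed vs starved within
each level using pooled-error t statistics (t = Δmean/√(MSE·(1/n₁+1/n₂)),
df = residual df) with a Šidák adjustment over the m contrasts
performed — the post-test convention of the GUI package such assays are
usually analysed with; m is recorded in the output. HDF is declared for
a level when the starved mean exceeds the fed mean and the adjusted p
is below α = 0.05. Because the call is directional at a two-sided
adjusted α, the family-wise null rate of "any HDF declared" across two
diets is ≈ 5 %, which the calibration suite confirms.

## Metabolic tables

* **TAG.** Replicates pool 3 whole flies; values are normalized to
  µg/fly. Δ-TAG = mean(fed) − mean(stv) per-fly TAG within one diet/day
  group; the normalized value is stv mean / fed-control mean (0.5 ⇔
  half the fat stores mobilized). Outputs rescale exactly with assay
  units.
* **Lipidomics.** Species ("PE 36.2" dialect) are summed into class
  totals per replicate; totals conserve the input concentration
  exactly, and a species whose prefix contradicts its class column is an
  error naming the offender. Instrument units are carried opaquely — no
  conversion is attempted and every downstream statistic is
  unit-covariant. Two designs are exposed, since multi-day data can be
  analysed either way: per-class diet × day ANOVA with Šidák-corrected
  within-day contrasts, or per-class Welch t with a Šidák adjustment
  across classes for two-group designs.
* **qPCR.** Comparative CT in the standard Livak form: ΔCt = Ct_target −
  Ct_reference per sample, ΔΔCt centred on the arithmetic mean of the
  control group's ΔCt, fold = 2^−ΔΔCt. The control group's geometric
  mean fold is 1 by construction.
* **Survival.** Long (fly, group, death day) tables are reshaped for the
  log-rank test. Censoring is supported in the type but unused by
  default, matching assays run until every fly has died.

## Statistics

All tests are implemented directly, with tail probabilities from the
regularized incomplete beta/gamma functions; scipy/statsmodels/lifelines
appear only as cross-checking oracles in the tests.

* **Welch t**: Welch–Satterthwaite fractional df; zero-variance inputs
  degenerate explicitly (equal means → t = 0, p = 1; unequal → p = 0,
  flagged).
* **Wilcoxon rank-sum**: midranks for ties; exact p by enumerating all
  C(n₁+n₂, n₁) rank assignments when both groups have ≤ 8 observations
  and no ties; otherwise a normal approximation with tie correction and
  a 0.5 continuity correction. Against enumeration at n = 8/8 the
  approximation is good to about ±0.01 — worth knowing when p sits near
  a decision boundary.
* **Two-way ANOVA**: Type III sums of squares under sum-to-zero coding
  (the GUI-package convention), computed as full-vs-reduced least
  squares; Type II available; both reduce to the classical
  decomposition on balanced designs, where SS_A+SS_B+SS_AB+SS_error =
  SS_total to 1e-9 relative.
* **Šidák**: p' = 1 − (1 − p)^m via expm1/log1p for accuracy near 0.
* **Mantel–Cox**: hypergeometric expectation and covariance per distinct
  event time, (O−E)ᵀV⁻¹(O−E) over k−1 groups, df = k−1.

Type-I calibration (seeded Monte-Carlo, 2000–6000 reps per test) keeps
each test's rejection rate at α = 0.05 within [0.04, 0.06]; group sizes
for the discrete tests (20/group for the rank-sum, 90/group for the
log-rank — the survival assay's own scale) were chosen so the attained
size of the discrete/asymptotic procedures is itself near-nominal,
determined from their null distributions rather than tuned against the
checks.

## Synthetic data: what it does and does not emulate

Generators exist so every stage can be tested against known truth; all
randomness flows from one explicit integer seed per call, and identical
spec + seed gives bit-identical output.

* **Nuclei scenes**: spheres (radius 1.5–2.5 µm by default) with a
  0.45-µm bright lamin shell over a dim cytoplasm, a nuclear:cytoplasmic
  FOXO partition (defaults 120:40 a.u.), additive Gaussian noise
  (default 6 a.u. = 5 % of nuclear signal), rejection-sampled so nuclei
  never overlap rims included (1000 attempts, then an error). Scene
  acquisition parameters beyond the 0.3 µm z-step are fixtures of this
  artifact, not claims about any particular microscope. Not modelled:
  optical PSF, depth attenuation, detector (Poisson) statistics — a
  Poisson stage was considered and left out as Gaussian noise already
  stresses the thresholding; real stacks are harder than these scenes,
  so recovery rates here bound, not predict, field performance.
* **FLIC traces**: Gaussian baseline (10 ± 5 a.u.) clipped strictly
  below the 40 a.u. threshold so the ground truth is well-defined
  per-sample (specs whose baseline mean + 4 SD reaches the threshold are
  rejected); bouts are plateaus at a supra-threshold amplitude
  (60–120 a.u.), 1–5 s long, separated by at least one baseline sample,
  placed at a Poisson rate. Sampling rate defaults to 5 Hz — the
  instrument's true rate is not a published constant and the value is
  configurable. Not modelled: bout microstructure, circadian drift,
  signal calibration.
* **Tables**: Gaussian replicates around stated cell means (10
  replicates per cell by default, the lipidomics design of ten
  biological replicates of ten flies each).
* **Puncta scenes**: rasterized disks (radius 3 px) with optional
  Gaussian blur and noise over a flat background; the rasterized pixel
  count is the area oracle.

## Problem sizes in the checks

The acceptance suite segments 20 scenes of 5–15 nuclei at 256×256×32
voxels (about a second per scene), runs 2000–6000-rep null calibrations
per test, and calibrates the feeding-pipeline null with 600–800
shortened (600 s) recordings per seed — sizes chosen to give tight
Monte-Carlo error while keeping the whole suite under a minute of
statistics time. Directional power runs use the study-scale group sizes
(12 flies per FLIC cell, 30 nuclei, 10 flies per puncta group, 9 TAG
replicates).

## Known limitations

* The z-scan inclusion criterion (rim score ≥ fraction of peak) is this
  package's own concrete reading of "scan the z-stacks from the 2D
  centroids"; the fraction, band width and fallback are configuration,
  and other readings are plausible.
* Nuclei sharing an (y, x) footprint at different depths cannot be
  separated — the 2D-footprint-first design inherits this from the
  original pipeline; the scene generator's non-overlap invariant
  excludes the case.
* The moments threshold is histogram-global; heavy intensity gradients
  within an ROI would need local thresholding, which is out of scope.
* The HDF ANOVA treats event counts as Gaussian; at very low bout rates
  a count model would be more faithful. At the default rates the
  calibration stays nominal.
* Lipid class totals assume the species table is complete per replicate;
  missing species silently lower a class total (they are not imputed).
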