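# Methods

This note documents the models, estimators, and numerical choices behind
`mataging`, and what the synthetic-data generators do and do not emulate.

## Image preprocessing and binarization

All preprocessing is 2-D, applied per z-slice, matching how field-of-view
coverage is conventionally quantified from slice-processed confocal stacks.

*Rolling-ball background subtraction* (default radius 15 px) is implemented
as grayscale opening with a non-flat ball structuring element of height
profile √(r² − d²): the surface a ball of radius r traces when rolled
beneath the intensity landscape. The opening is anti-extensive, so after
clipping the background at zero the result is non-negative and bounded by
the input. Boundary handling replicates edge pixels (`mode="nearest"`);
within a ball radius of the border the background is therefore slightly
conservative. The ball radius is in pixel/intensity units with no separate
intensity scaling.

*De-speckling* is a 3×3 median filter per slice; *gamma correction*
rescales to [0, 1], raises to the power γ, and restores the original
maximum, preserving pixel ordering for any γ > 0.

*Maximum-entropy thresholding* (Kapur): the channel is linearly rescaled to
8-bit, one 256-bin histogram is accumulated over the whole stack (one mask
per field of view, not per slice), and the threshold maximizes the sum of
Shannon entropies of the below- and above-threshold sub-histograms.
Foreground is strictly above the threshold — tie pixels at the threshold
are background, a fixed convention for exact reproducibility. A constant
channel is an error rather than an arbitrary mask. For well-separated
bimodal histograms the criterion lands between the populations, though
characteristically close to the edge of the dominant mode; tests assert
equality with an exhaustive search over all 255 candidates rather than any
particular placement.

*Size partition* (default cutoff 150 px) separates planar 8-connected
components of the maximum-intensity projection into small (interstitial
matrix) and large (perineuronal/perivascular) groups. The projection is
used because the pixel cutoff is a planar unit; 3-D partitioning would need
a different calibration.

## Morphometry

Object counting uses 26-connectivity in 3-D with a 10-voxel minimum, both
declared explicitly since connectivity conventions differ between tools.
Density is objects per calibrated µm³.

The fractal dimension is the 2-D box-counting slope over dyadic box sizes
2–64 on the projected mask, with the grid anchored at the image origin and
no offset averaging (determinism over a marginal accuracy gain). The
estimator attains the analytic limits (filled square → 2, line → 1) and,
on triadic test fractals, converges to the self-similarity dimension only
once the pattern extends over enough dyadic scales: a depth-4 Sierpinski
carpet (81 px) reads ≈ 1.71 because the coarse dyadic boxes misalign with
the triadic construction, while depth 5 (243 px) reads 1.868, within 0.05
of log 8 / log 3 ≈ 1.893. Validation against the analytic value therefore
uses depth 5; oracle equality (against brute-force grid loops) holds at
every depth.

Sholl profiles are computed on the 2-D projection of a single-cell mask:
concentric circles from r₀ = 7.5 µm in 2.5 µm steps, each sampled at 1°
with nearest-pixel lookup; an intersection is a maximal run of foreground
samples, with single-sample gaps bridged (closing with a 3-sample window)
so binarization dropouts of one pixel do not split a process. Processes
thinner than the inter-sample arc spacing (≈ r·0.0175) can be missed at
large radii; the synthetic generator renders processes ~2 px wide so the
test geometry stays in the valid regime.

## Proximity scores and the rotation null

The shell ROI dilates the reference mask in-plane with a Euclidean disk
(default 4 px = 0.5 µm at 0.125 µm/px) and subtracts the original mask.
Dilation is 2-D per slice because the pixel unit is in-plane and the
z-spacing (0.3 µm) differs from the pixel pitch. Puncta membership is
centroid-in-shell (26-connected objects, rounded centroid), which counts
each punctum at most once regardless of size; densities are normalized by
the reference surface area estimated as the exposed-face count of boundary
voxels weighted by physical face area — simple, deterministic, and
monotone under mask growth. Microglia–ECM contact density instead counts
ECM objects overlapping any cell voxel per µm³ of cell mask.

The chance level for any association score recomputes the same metric
after rotating one channel 90° counter-clockwise about the field center
(square fields; optional center-crop otherwise). Rotation preserves each
channel's internal spatial statistics while destroying cross-channel
alignment, so observed − null is zero in expectation under spatial
randomness; a paired t-test across fields of view rejects at the nominal
rate under simulated randomness and detects planted colocalization
(puncta placed on fibrils) in essentially every simulated field.

## Bernoulli state-space learning curves

Binary foraging outcomes n_t are modeled with a latent Gaussian random walk
x_t = x_{t−1} + ε_t, ε_t ~ N(0, σ²), observed through
P(n_t = 1) = logistic(x_t). The state is anchored before the first trial at
x₀ = logit(chance) (chance 0.5 for consumed/not-consumed foraging). The
forward filter uses a Gaussian approximation with the posterior mode found
by Newton iteration and the curvature as precision; the backward pass is
the fixed-interval (RTS) smoother; σ² is estimated by EM (relative
tolerance 10⁻⁵, 200 iterations max).

σ² is constrained to [10⁻⁶, 0.02]. The constraint matters: for degenerate
sequences (a hard step, or all-identical outcomes) the marginal likelihood
is monotone increasing in σ² — the MLE diverges — and an unconstrained fit
drifts to a regime where the confidence band balloons at the sequence ends
and the Gaussian approximation degrades. The ceiling acts as a weakly
informative prior in the range typical of trial-by-trial learning data and
keeps the smoothed probabilities within 0.02 of an exact discretized-state
(grid) smoother at the fitted variance.

Per-trial 90% bounds map x̂_t ± 1.645·sd through the logistic. The learning
trial is the first trial whose lower bound exceeds chance **and stays
above chance for every remaining trial** — enforced literally, not just at
first crossing. On simulated steps from 0.2 to 0.95 at trial 15 (30-trial
sessions) the median estimate is trial 17: the sustained-crossing rule
needs a few trials of evidence, a conservative bias inherent to the
definition rather than the fit.

## Cognitive classification

The three battery features are z-scored over the full cohort (a constant
feature is an error), clustered by Ward-linkage agglomerative clustering on
Euclidean distances (scipy's implementation of the Lance–Williams
recurrence), and cut at k = 2. Middle-aged mice in the cluster holding the
majority of young mice are aging-unimpaired, the rest aging-impaired;
young mice keep the young-average label regardless of cluster, and an
exact young-count tie between clusters raises an error demanding manual
resolution. The alternation index divides by the trial count (maximum
(k−1)/k for k trials), the convention under which 10 uniform random trials
have expectation 0.45.

## Proteomic statistics

Intensities live in a protein × sample matrix with missing values kept
missing everywhere except per-mouse totals, where an undetected fraction
contributes zero physical signal before the log2.

*Normalization* quantile-normalizes samples (each sample's observed values
mapped by rank onto the rank-wise mean of sorted values, with interpolated
quantiles when observation counts differ) and then median-centers each
sample, on the log2 scale. The default normalizes within each solubility
fraction, since fractions have genuinely different global distributions; a
global mode is available. On complete tables the operation is idempotent
to machine precision.

*Fold changes* are ratios of linear-scale group means (aged/young) with
Student (equal-variance) two-sided t-tests on log2 intensities; the
equal-variance variant is recorded in the result metadata. Proteins with
fewer than two observations in a group are flagged missing. Zero-variance
degenerate cases resolve to p = 1 (identical groups) or p = 0 (pure
offset). No multiple-testing correction is applied by default;
Benjamini–Hochberg is available as a flag. Tests are intended to run
within one fraction (see `filter_samples`); pooling fractions leaves the
fraction offset as an unmodeled block and makes the t-test conservative.

*Solubility shifts* consider proteins detected in ≥ 2 fractions; for each,
the most- and least-soluble detected fractions (sequential-extraction
order: cytoplasmic > nuclear > membrane > cytoskeletal > insoluble) form
one pair per protein, each mouse observed in both contributes a log2
difference relative to the more insoluble member, and young vs aged
differences are compared by unpaired t-test. Direction is assigned only at
p < 0.05. Using the extreme detected pair keeps one test per protein when
more than two fractions qualify.

*Module eigengenes* are the first right singular vector of the
standardized member × sample matrix (per-protein mean imputation first),
sign-fixed to correlate positively with the members' mean profile. Trait
correlations are Pearson with 0/1 coding for binary traits (point-biserial
identity), p from the t distribution on n − 2 df. Robust regression is
IRLS with the Tukey bisquare (c = 4.685) via statsmodels RLM. Correlation
networks use pairwise-deletion Pearson r with the diagonal set to zero;
edge weights are signed r.

## What the generators emulate — and what they do not

The image generator reproduces the *statistical* structure the estimators
consume: Gaussian puncta (σ = 1 px in-plane, 0.5 slices axial) over
Poisson-noised background keep thresholding nontrivial; random-walk
fibrils dilated to 1–2 px give connected-component and box-counting
behavior comparable to interstitial matrix; enrichment is exact by
construction (rejection sampling against the fibril in-plane distance map,
acceptance ∝ the requested density ratio inside the 0.5 µm shell). It is
not an optical model: no PSF, chromatic, or depth effects, no perineuronal
net ring geometry, no spatially varying background. Passing tests
demonstrate correctness of the estimators under known truth, not
robustness to every real-microscopy artifact.

Foraging logs carry the four feeder zones, perimeter/center/start-box
events at 1-s resolution, and a win-stay rule (the encoded feeder is
correct); encode outcomes step from p_pre to p_post at the planted
learning trial. Default cohort sizes follow the study design (18 mice per
age group, 25 encode sessions over 5 weeks, interleaved 2 h and 24 h
probes; battery cohort 12 young + 24 middle-aged with 75% of young and
46% of middle-aged mice in the unimpaired cluster; proteome 4 mice per age
group across five fractions, log2 noise SD 0.25, +1 log2 planted matrisome
effect). Battery cluster separation is expressed per feature in SD units,
shifting all three features toward the impaired direction. Real behavior
has session-to-session autocorrelation and individual variability beyond a
single step; real proteomes have correlated proteins and intensity-
dependent missingness — neither is modeled.

## Problem sizes in the validation runs

The acceptance computations use sizes chosen to make Monte-Carlo error
small relative to every tolerance while remaining quick on one CPU: 10⁵
probe sessions for the chance levels, 50 images / 20 volumes / 20
sequences for the oracle suites, 200 experiments × 10 fields for null
calibration, 500 proteins / 200 replicates / 100 seeds for parameter
recovery, and 64–256 px fields for the imaging checks.

## Known limitations

- Sholl sampling at 1° can miss sub-pixel-wide processes at radii beyond
  ~60 µm at 0.5 µm/px; use finer `n_angles` for very large cells.
- The learning-trial estimator is conservative by definition (sustained
  lower-bound crossing) and reports `None` when the band never clears
  chance for good, as for short or failure-only sequences.
- The box-counting estimate is grid-anchored; values for small or sparse
  masks carry discretization bias.
- Quantile normalization across groups slightly compresses true
  group differences when a large fraction of proteins carries the effect;
  effect-recovery analyses run on raw generated tables where no batch
  effect exists.
- The solubility-shift test assumes at least two mice per age group are
  observed in both members of the fraction pair.
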