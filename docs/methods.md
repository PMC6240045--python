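# Methods

This note documents the models implemented in `wgctraj`, the synthetic data
they are validated on, the numerical choices made where the design was open,
and what passing tests do and do not demonstrate about real data.

## White–gray contrast and smoothing

WGC at a vertex is the ratio of the T1 intensity sampled 1 mm inside the
white surface to the intensity 1 mm outside. This package starts from
already-sampled intensity pairs; the geometric machinery that produces them
(distance maps, surface deformation, resampling to a common template) is an
upstream surface pipeline and out of scope. Intensities are smoothed on the
template mesh *before* the ratio is taken, with the ratio computed from the
smoothed maps.

Smoothing is iterated diffusion with the doubly-stochastic operator
P = I − (w/d_max)·L, where L is the graph Laplacian of the mesh edges. P is
symmetric with unit row and column sums, so constant maps and map totals are
preserved exactly and variance never increases. The step count is
n = ceil(2·(σ/h)²) for mean edge length h, and the per-step weight w is
solved so that n steps accumulate the per-axis positional variance σ² of the
requested Gaussian (σ = FWHM / (2√(2 ln 2))); on a regular planar grid the
diffused impulse reproduces the requested FWHM to better than 1%. A FWHM
below the mean edge length cannot be represented on the mesh and returns the
input unchanged with a warning. This heat-kernel approach avoids geodesic
distance computation entirely; its kernel deviates from a true geodesic
Gaussian near high-curvature regions, which is irrelevant on the synthetic
sphere but a known approximation on folded cortex.

## Angle metrics

The longitudinal angle is arctan(ΔWGC/Δage) per vertex within subject. The
cross-sectional analogue uses mean pairwise differences against same-site,
same-diagnosis peers; additive site, scanner and cell-level offsets cancel in
both the numerator and the denominator. Units are as stated: the arctangent
argument mixes WGC-ratio units with years, with no unit normalisation.

Numerical and policy choices:

- **Zero denominator** (a subject whose age equals the mean age of their
  peers): the subject's whole row is masked with a warning. The event is
  age-structure-driven and identical across vertices, so it is reported per
  subject rather than silently dropping anyone.
- **Cell sizes**: cells with one subject are an error; below four subjects a
  warning is emitted. `filter_small_cells` (threshold default 4) is the
  data-preparation filter that removes sites with an undersized group.
- **Standardisation**: z-scoring is per vertex across subjects with sample
  (n−1) standard deviation, separately within the cross-sectional and
  longitudinal samples; zero-variance columns map to 0. A pooled variant is
  available (`axis="pooled"`).
- **Saturation**: arctan maps a near-zero age denominator to ±π/2. Subjects
  with ages close to their cell mean therefore contribute heavy-tailed,
  whole-row noise to the cross-sectional sample. This is an inherent property
  of the metric, is the reason the angle histograms are skew/heavy-tailed
  (hence the extreme-value likelihood below), and drives several generator
  defaults.

For a two-subject cell the cross-sectional formula reduces exactly to the
longitudinal formula, and both members of the pair report the same angle
(numerator and denominator change sign together).

## Task PLS

Mean-centred task PLS: group means (groups × vertices) are centred by the
unweighted grand mean of group means and decomposed by SVD. Design scores are
U·S (unit-norm design vectors U are also reported, since the normalisation of
published design-score vectors varies); saliences are the right singular
vectors; covariance explained is S²/ΣS².

- **Permutation test**: group labels are resampled without replacement;
  p = (1 + #{S_perm ≥ S_obs}) / (1 + n_perm). Under a true null the LV1
  p-value is uniform (verified by a Kolmogorov–Smirnov calibration suite).
- **Bootstrap**: subjects are resampled with replacement within group; each
  replicate's LVs are re-matched to the original by maximal absolute
  correlation (order and sign) before the standard error is taken, preventing
  axis swaps/flips from corrupting the SE. BSR = original salience /
  bootstrap SE; an SE at float-noise level (< 1e-9 on unit-norm saliences)
  marks a degenerate vertex and is masked rather than divided by. Group
  confidence intervals are 95% percentile intervals of aligned design scores.
- **Brain scores** project the mean-centred subject data onto the BSR map
  (the convention adopted throughout this pipeline); the classical projection
  onto raw saliences is available via `projection="salience"`.
- **Sign conventions**: SVD signs are fixed deterministically (largest
  salience element positive), and `orient_to_contrast` flips an LV so its
  design scores align with the ASD-minus-TD contrast; with that orientation a
  negative BSR means greater contrast decrease in ASD. The conjunction of two
  BSR maps counts exact zeros as negative (a measure-zero event on
  continuous data, logged when it occurs).
- **n_perm defaults to 1000 and n_boot to 500** in the CLI; the desk-scale
  pipeline and tests use smaller counts (stated per run) since the reported
  quantities are sign/median statistics that stabilise quickly.

## Bayesian diagnostic prediction

Likelihood: P(α|dx) = σ⁻¹ exp(z − e^z) with z = (±α − μ)/σ — a Gumbel
density whose orientation (the ± sign, i.e. left- or right-skew) is selected
per class by the Pearson correlation between the fitted density and a
Freedman–Diaconis histogram of the data (FD binning is scale-adaptive and
deterministic). Parameters are maximum-likelihood fits (both orientations are
fitted; the better-correlating one is kept). Prior:
P(dx) = [1 + exp(±x·BSR/BSR_max)]⁻¹ with the positive sign for TD and
negative for ASD, evaluated at the subject's standardised angle clipped to
the training domain [α_min, α_max]; the two class priors sum to one for
every x. The likelihood and prior orientations are selected independently
(the likelihood by fit quality, the prior by diagnosis). Posteriors are
computed in log space and normalised over the two classes by log-sum-exp; an
exact 0.5/0.5 tie predicts TD (conservative toward the no-disorder label).

**Region reduction.** The default whole-region model feeds each subject's
mean standardised angle over the region to a single likelihood/prior pair
(prior BSR = region-mean BSR, BSR_max = max |BSR| over cortex). The region
means are then re-standardised per sample, each with its own moments: region
averaging compresses the two samples' scales differently (the
cross-sectional per-vertex z-scale is inflated by saturated subjects), and
the model is explicitly a comparison of distribution shapes, not magnitudes.
Without this step the test values fall in the far tails of both training
likelihoods and the decision degenerates to a comparison of tail shapes. For
a single-vertex region the extra step is an identity, so the per-vertex
sensitivity/specificity maps and the region-aggregation consistency property
are unaffected. Averaging per-vertex posteriors instead is available via
`mode="vertex_posterior_mean"`.

Per-vertex maps threshold single-vertex models at >50% sensitivity *and*
>50% specificity, screening out trivial all-one-class predictors. A metric
whose class is absent from the test set is reported as missing, never 0.

## Severity

Proxy calibrated severity scores come from a lookup table keyed by ADOS
module, age band, and social+communication total. The published calibration
tables are not redistributable from this package: the bundled table
(`synthetic_css_table.tsv`) is a clearly-labelled synthetic identity
placeholder (severity = total clipped to [1, 10]); real analyses must supply
a real table in the same TSV schema. Uncovered cells raise (scalar) or
return NaN with a recorded reason (batch) — never a silent default.

The severity model is OLS of severity on brain scores, plus the mean
training residual within an open, centred window of half-width
w = 0.05 × max(training BrSc); an empty window contributes no correction
(K = 0 falls back to the plain linear term). With w → ∞ the correction tends
to the training residual mean (zero); with w → 0⁺ on training points the
model returns the training scores exactly. Correlations with behavioural
scores use the positive part of the brain-score distribution on the log
scale, excluding non-positive brain scores and missing scores.

## Motion proxy

Central-difference gradient magnitude (scaled by voxel size), standard
deviation over a 6-connected-eroded white-matter mask core (default 2
erosion iterations; the appropriate depth depends on mask resolution).
Constant and linear-ramp volumes score exactly zero; the proxy is invariant
to additive intensity offsets and scales linearly with multiplicative gain.
Group comparison uses Welch's t-test (unequal variances). Gradient pooling
is by magnitude; per-axis pooling is a straightforward variant.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a multi-site developmental
cohort: 14 cross-sectional sites with fixed ASD/TD group sizes (359 subjects
total, 146 ASD), per-site age means/sds, a Siemens/Philips scanner split,
and a longitudinal sample of 12 ASD + 9 TD subjects over two sites with a
fixed 2.31-year inter-scan interval around a 12.75-year baseline mean. The
template mesh is a Fibonacci sphere (radius 100 mm) triangulated by its
convex hull; effect-sign regions are spatially coherent blobs obtained by
thresholding a smoothed random field, with optional BFS-grown patches
("primary-sensory-like" focal reversals) forced first and the global
negative fraction balanced exactly (to 1/V) on the remaining vertices.

Generative model per scan:

    WGC_v = baseline + (slope_dx,v + tempo_i) · (age − ā_cell)
            + site_offset + scanner_offset + intercept_i + ε_v

- `baseline_wgc_mean` = 1.25 (typical adolescent contrast ratio).
- `slope_td` = −0.008 WGC/year; ASD−TD slope contrast magnitude 0.012/year
  (sign per vertex from the template, default 81% negative). **These effect
  sizes are synthetic-only choices** — no published per-vertex rate values
  exist to match — sized so that the planted sign pattern is recoverable at
  the study's sample sizes, as the downstream validation targets require.
- `noise_sd` = 0.002: residual per-vertex measurement noise *after* 20-mm
  surface smoothing (raw vertex noise of a few percent averaged over the
  ~10² vertices under a 20-mm kernel).
- `subject_slope_sd` (tempo) = 0.002: between-subject variation in global
  developmental rate, the main source of within-group angle spread. Without
  it within-group distributions are near-degenerate and distribution-shape
  modelling is meaningless.
- **Trajectories are anchored at the (site, dx) cell mean age**: the planted
  effect is a pure rate-of-change difference with no static level
  difference between groups. Anchoring at a shared reference would leak a
  static diagnostic signal wherever group age distributions are imbalanced,
  contradicting the empirical regime being emulated (angle PLS significant,
  single-timepoint WGC PLS null). "site" and "global" anchors are available.
- `subject_intercept_sd` defaults to 0. A per-subject global level offset is
  realistic, but the cross-sectional angle *confounds level with rate* (a
  subject's level offset divided by their age deviation shifts their whole
  angle row), and even small values occasionally flip the whole recovered
  sign map. The knob exists precisely to probe that documented limitation.
- ADOS social+communication totals are integers in [0, 22], generated for
  ASD subjects so that their correlation with log-positive pattern
  expression approximates a target r (default 0.42); module is assigned from
  age by a synthetic convention. TD subjects receive no score; longitudinal
  subjects carry one timepoint-agnostic score.
- Motion volumes are smooth random fields plus a sinusoidal ripple along one
  axis with a central-block "white matter" mask.

Determinism: every public entry point takes a seed; identical spec + seed
gives bit-identical output. With all noise sources set to zero, every planted
slope, offset and sign fraction is recoverable exactly.

**What passing tests do not show.** The generator's vertex noise is
independent across vertices (real smoothed maps are spatially correlated);
trajectories are linear in age (no pubertal or other nonlinearity); there is
no planted static group difference, no sex structure (all-male cross-
sectional sample, as in the emulated design), and no realistic image content
behind the motion toy volumes. Recovery of the planted 81% coverage or of
high classification accuracy on this synthetic regime validates the
*implementation* of the chain, not the real-data effect sizes, which the
package does not claim to reproduce.

## Problem sizes used in validation

The shipped validation suite runs the full pipeline at 300–400 template
vertices, 150 bootstrap replicates and up to 500 permutations, with 20
seeded replicates for the conjunction-coverage summary and 100 for the
classifier operating-regime checks — sizes at which the reported summary
statistics (medians over replicates, sign fractions, calibration KS
statistics) are stable, as chosen for routine single-CPU runs.
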