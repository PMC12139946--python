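# Methods

This note documents the models, numerical choices and limitations behind
`traitscape`. The package re-implements, as a tested pipeline on synthetic
data, a staged analysis of how well negative affective traits can be read
out of task-fMRI contrast maps at three levels of neural organization —
single regions, large-scale networks, and distributed whole-brain patterns
— together with the psychometric and multiverse machinery needed to
interpret such readouts.

## The statistical problem

Each subject contributes a contrast map: a voxel image of the difference in
response between negative and neutral task conditions. The scientific
question is whether stable, questionnaire-measured traits (neuroticism and
its facets, affect dispositions) correlate with any function of these maps,
and at which granularity. Two empirical facts shape everything:

1. **Within-person state decoding is easy.** Across trials of one person,
   a linear pattern expression tracks momentary self-reported affect at
   correlations near .9.
2. **Between-person trait prediction is hard.** The same machinery predicts
   stable traits at best around r = .2–.3, because between-person variance
   is dominated by trait-irrelevant person-level structure: global activity
   offsets and regional response idiosyncrasies that inflate correlations
   among all regions and networks.

## The synthetic cohort generator

`synthdata.generate_cohort` simulates, at the contrast/trial-map level (no
hemodynamics, no GLM), a cohort with exactly this structure. For subject
*i*, trial *t*, voxel *v* (condition sign `s_c` = +1 negative / −1
neutral):

```
X_itv = g_i + h_ir + s_c/2 * (d_i + m_ir + beta_trait * z_i * w_trait_v)
        + beta_state * a_it * w_state_v + e_itv
```

* `g_i ~ N(0, sigma_global)` and `h_ir ~ N(0, sigma_region)` are
  condition-**common** person and person-by-region offsets. They cancel in
  the control contrast (mean negative − mean neutral) but dominate
  implicit-baseline maps (condition means).
* `d_i ~ N(0, sigma_global_diff)` and `m_ir ~ N(0, sigma_region_diff)` are
  condition-**differential** offsets that survive the contrast — the
  mechanism by which person-global structure reaches contrast maps and is
  removed (global part) or dampened (regional part) by image-wise
  centering.
* `a_it = (1 + rho_i) * s_c + state noise` is latent affect;
  `rho_i ~ N(0, sigma_reactivity)` is a stable response-amplitude trait.
  Ratings are `round(clip(3 + 0.8 * a_it + noise, 1, 5))` — noise added
  before rounding. Because the rating is Likert-rounded, even the
  noise-free limit decodes at slightly below r = 1.
* `w_state` is a broad, predominantly positive per-region pattern
  ("domain-general stimulation"); `w_trait` is sparse-then-smoothed: a
  random sign per region, constant within region, confined to a
  configurable subset of networks (default: somatomotor, dorsal attention,
  frontoparietal, default mode ≈ half the voxels). The brain couples to
  `z_i`, the facet-specific component of the stress-vulnerability latent
  (orthogonal to the shared neuroticism domain factor), so the broad domain
  is unpredictable by construction while the facet is weakly decodable.
* Questionnaire scores are reliability-attenuated latents on a T-score
  scale: `50 + 10 * (sqrt(rel) * latent + sqrt(1-rel) * noise)`. Six facets
  load .6 on a shared domain; negative affect loads .5 on the vulnerability
  facet (convergent), positive affect and extraversion are independent
  (discriminant); STAI/BDI load .7 on the anxiety/depression facets.
* The faces task shares the person-level offsets and reactivity but has its
  own state pattern and a trait signal attenuated by
  `beta_trait_faces_ratio` (default .25); its contrast maps are generated
  directly at the person level (the trial average is distributionally
  equivalent and trial maps for a second task are never consumed).

**Calibration.** Trial-level variance components are not observable from
published summaries, so the defaults were fixed once to land the reported
summary statistics and then frozen: grid 12x12x12 (1,728 voxels), 40
contiguous regions in 7 networks, 200 subjects, 20+20 trials,
`sigma_global = sigma_region = 1`, `sigma_noise = 1`,
`sigma_global_diff = 0.02`, `sigma_region_diff = 0.16`,
`sigma_reactivity = 0.25`, `sigma_state = 0.6`, `rating_noise = 0.3`,
`beta_state = 0.2`, `beta_trait = 0.025`, reliability .8. Under these
conditions (means over ≥8 seeds): between-network correlations of contrast
maps ≈ .66, within-person decoding ≈ .86, cross-validated between-person r
for the vulnerability facet ≈ .18 with hold-out confirmation ≈ .24. A
deliberate modelling consequence: most of the shared between-person
variance in contrast maps comes from reactivity (`rho_i`) along the state
pattern, with the differential offsets adding a smaller global component —
large condition-differential offsets would instead leak into within-person
decoding, which the data say is nearly noise-free.

**What the generator does not emulate:** spatial autocorrelation beyond
region-constant structure, hemodynamic and motion artifacts, non-Gaussian
heavy tails, site/session effects, missing data, and any nonlinear
brain-trait coupling. Passing recovery tests therefore shows the pipeline
is correct and well-calibrated under the assumed data model, not that the
effect sizes transfer to any real cohort.

## Atlas

`generate_atlas` partitions the grid into near-equal runs along a
boustrophedon (snake) traversal, so every region is a 6-connected parcel;
region r joins network r mod K, spreading each network over the volume.
The first six regions carry the canonical theory-ROI names (bilateral
amygdala, anterior insula, dACC) so the region battery runs verbatim.

## Preprocessing

Two orthogonal normalisations, both recorded in map provenance and
refusable when applied twice:

* image-wise scaling (rows): `center` subtracts the observation's mean
  across voxels — removing any per-person global offset exactly — and
  `zscore` additionally divides by the row SD (sample, n−1 convention).
* voxel-wise standardization (columns): z-scoring on the mean/SD of a
  *training* sample, refit inside every cross-validation training fold
  (outer and inner). Zero-variance voxels are zeroed, not dropped, to keep
  voxel spaces aligned.

Multivariate outlier screening computes Mahalanobis D² against the sample
mean and covariance, refers it to a chi-square with p degrees of freedom and
Holm-corrects across observations. The feature set is the caller's; the
recommended low-dimensional choice is the 7 network means.

## Predictive modelling

Four algorithms (PLS, principal-component regression, linear-kernel SVR,
and a random forest on a PCA reduction to the training-sample rank,
min(n−1, voxels)) under repeated nested cross-validation, default 2
repeats x 5 outer x 5 inner folds, Pearson correlation as selection and
evaluation metric, fold assignment random under the seed (not stratified).
Hyperparameter grids are config defaults, chosen as round component counts
{1, 2, 5, 10, 20} capped at half the training size for PLS/PCR, log-spaced
C in 10^-3..10^2 with epsilon fixed at 0.1 SD of the outcome for SVR, and a
single 500-tree configuration for the forest; inner-loop ties break toward
the simpler (earlier) grid entry. Per-repeat performance is the correlation
of pooled out-of-fold predictions with the outcome; fold-wise correlations
of constant or non-finite predictions are recorded as 0 with a warning so
sweep aggregation never propagates missing values.

Permutation tests re-run the full nested CV under outcome permutations
with p = (1 + #{null ≥ observed}) / (1 + n_perm); rejection uses p ≤ alpha,
which makes the test exact at the nominal level. Train/hold-out splitting
stratifies on outcome quantile bins (default 5), so realized sizes can
deviate from the nominal fraction by an observation or two. Final models
are refit on all training data; linear models are reduced to an explicit
voxel weight vector and intercept on the standardized scale, with the
training statistics and scaling tags stored so a model refuses maps with
different preprocessing provenance.

Weight thresholding bootstraps training subjects (default 500 resamples),
forms per-voxel z = bootstrap mean / SD, thresholds the two-sided normal p
at alpha or by Benjamini-Hochberg FDR, then removes 6-connected components
below the minimum cluster size. Note this bootstrap quantifies the
stability of the fitted weights in this sample, not a population null.

Virtual lesioning removes all voxels of a region or network; by default the
model is *retrained* on the reduced space (the stronger test of necessity),
with a `retrain=False` variant that keeps the full model and drops the
unit's weights, since either reading of a lesion analysis is defensible.

## Inference

Everything confirmatory is inference on a Pearson correlation: a one-sided
t-test (positive correlations are the only success), a two-sided 95%
Fisher-z interval regardless of test sidedness, and a Bayes factor. The BF
integrates the exact sampling density of r given rho (Fisher's 1915 form
with the Gaussian hypergeometric term) over a stretched-beta(1/kappa,
1/kappa) prior on (−1, 1), truncated and renormalized to (0, 1) for the
one-sided test, by adaptive quadrature (validated in tests against an
independent implementation and a 10^6-draw Monte-Carlo prior integration).
The default scale is the conventional "medium" kappa = 1/3. At the
two-decimal inputs r = .19, n = 102 this gives 2.50; a printed value of
2.53 corresponds to kappa ≈ 0.325 (or, equivalently, to an unrounded r of
about .192), and that calibrated scale is exposed as a named constant. Holm
correction is the standard step-down with an explicit, caller-declared
family size. Power for correlations uses the Fisher-z approximation.
Split-half reliabilities are projected to full length by Spearman-Brown,
2r/(1+r) — note the projection is strongly non-linear for negative
half-correlations, so null reliabilities should be averaged on the
half-correlation scale.

## Psychometrics

Split-half reliability rebuilds condition contrasts from odd/even trials
within condition (deterministic; random halves available behind a seed),
computes the pattern expression on each half and Spearman-Brown-corrects
the across-subject correlation. Expressions of a pattern trained on the
same subjects contain memorized person-level noise; reliability of a
pattern on pure-noise maps is only zero when the pattern is independent of
those maps. Leave-one-out validity refits model and standardization on
every n−1 subsample and correlates the left-out predictions with target,
convergent and discriminant traits. Within-person decoding folds by
subject (all trials of a subject share a fold — the only leakage-free
reading), scores each held-out subject by the correlation of predicted and
actual ratings across trials, and excludes constant-rating subjects with a
warning.

## Multiverse

Stage 1 crosses task (scenes/faces) x baseline (control contrast /
implicit) x image scaling (none/center/zscore) with outcome and algorithm
fixed: 12 models. Stage 2 multiplies in 7 neuroticism scores and 3 linear
algorithms: 252. Stage 3 multiplies the 12 base points by 14 affectivity
outcomes and 7 algorithm-sample pairs ({PLS, PCR, SVR} x {training, full}
plus forest on training only): 1,176 — this crossing is configuration, and
the builder reports whatever product the supplied factor lists imply. Each
executed point contributes its fold-wise correlations (2x5 = 10 per model
at the default CV) to a tidy table; failures are isolated per point.

Meta-analysis is descriptive, because fold rows are heavily dependent: a
1,000-tree bagged forest regresses fold correlations on one-hot design
factors and ranks factors by the RMSE increase when a factor's columns are
jointly permuted; a crossed random-intercept model (REML, one variance
component per factor, negative estimates truncated at zero) reports the SD
of fold correlations attributable to each factor and the residual.

## Problem sizes in the test suite

The suite exercises the full pipeline at the default cohort size (200
subjects, 1,728 voxels) for the recovery checks (10 seeds), and smaller
null generators (n = 30–60, 10–12 features, reduced fold counts, 99
permutations, 250–500 replicates) for type-I-error calibration — sizes
chosen so the whole suite runs on one CPU in well under half an hour while
keeping Monte-Carlo error within the asserted bands.

## Known limitations

* The generator's voxel noise is white; cluster-extent thresholds on such
  data are conservative relative to smoothed real data.
* Signature stand-ins are random or construction-correlated patterns; no
  published weight map is reproduced.
* The LOO validity and within-person decoding routines use a fixed
  hyperparameter (no nested tuning) for tractability.
* The variance decomposition assumes crossed factors and rejects confounded
  designs rather than attempting partial identification.
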