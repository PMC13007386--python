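# Methods

## The paradigm the generator emulates

A cued stimulus–response mapping task. On each trial a visual stimulus
appears in one of four positions — two per hemifield (left/right), at an
inner and an outer eccentricity — and the colour of the fixation square
cues one of two stimulus→button mapping rules (four cue colours, two per
rule, so rule cannot be read off a single colour). The participant presses
one of four buttons with four fingers; buttons 2 and 3 are the "inner"
response group, 1 and 4 the "outer" group. Sessions have 12 blocks of 80
trials; within a block every (cue colour × stimulus position) configuration
occurs exactly 5 times in shuffled order.

Four binary information types are analysed throughout:

| info type  | distinction                              |
|------------|------------------------------------------|
| `across`   | left vs right hemifield                  |
| `within`   | inner vs outer eccentricity              |
| `rule`     | rule 1 vs rule 2                         |
| `response` | inner vs outer response fingers          |

Behaviour defaults are the empirical session-level values: accuracy 80.78%,
omissions 2.6%, correct RT mean 1692 ms / sd 284 ms. RTs are drawn from a
log-normal moment-matched to that mean/sd (strictly positive,
right-skewed — the standard choice where no distributional form is given).
Error trials press a uniformly random non-target button; omitted trials
press nothing. Error and omitted trials are excluded from every analysis
stage, matching standard practice.

The two rule permutations' exact stimulus→button assignments are a
counterbalancing detail with no analysis consequence; the defaults are the
identity layout (rule 1) and its reversal (rule 2), and both are
configurable.

## Condition schemes

Each information type gets its own 4-condition scheme so its RDM isolates
that feature: `across` uses hemifield × rule, `within` eccentricity × rule,
`rule` the four cue colours, and `response` two response-group conditions
plus two cue-colour conditions (one colour from each rule, to balance cue
identity out of the response contrast). For trial-level (MEG) analyses the
response scheme must partition trials; this package assigns trials carrying
one of the two selected colours to that colour condition and splits the
remaining trials by response group. This is a design choice: the original
regressor formulation lets one trial load on two regressors, which has no
unique trial-level analogue.

## Synthetic signal model

Both generators plant effects the same way. Each information type carries a
fixed latent pattern (i.i.d. standard normal over voxels or sensors, drawn
once per dataset and Gram–Schmidt-orthogonalised across information types
so planted contrasts never alias). The two feature levels sit at
±effect_size/2 × noise_sd along that pattern, on top of i.i.d. Gaussian
noise of sd `noise_sd`. `effect_size` is therefore a per-feature amplitude
in noise-SD units; multivariate separability grows with the square root of
the number of features, so effect size 2 with ~30 voxels is already close
to decoding ceiling, while 0 is exactly chance.

fMRI betas are generated at condition level: one (condition × block ×
voxel) array per ROI, 12 patterns per condition in the full design. ROIs
not named in any effect spec carry pure noise. A first-level GLM route is
also provided for testing the estimation chain: trial epochs (duration =
RT, onset at the stimulus) convolved with the canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6, no derivatives), one regressor per
condition × block plus block constants, ordinary least squares with a
minimum-norm fallback (with warning) for rank-deficient designs.

MEG epochs are (trial × sensor × time) at 200 Hz by default, stimulus-
aligned −200…+2500 ms or response-aligned −2500…+500 ms. Effects are
confined to a window in stimulus time, with 20 ms raised-cosine on/off
ramps to avoid spectral ringing at the decoding onset. Noise is drawn per
trial on a master stimulus-time grid whose extent does not depend on the
requested alignment, so the stimulus- and response-aligned versions of one
dataset (same seed) are sample-for-sample consistent; response alignment
shifts each trial by its RT quantised to the sampling grid (as any real
epoching at fixed rate does), which makes the consistency exact rather than
interpolation-approximate. Omitted trials are dropped from response-aligned
epochs.

What the generator does *not* emulate: fMRI spatial autocorrelation,
physiological/motion confounds, MEG forward physics (no leadfields),
inter-participant variability, or temporal autocorrelation of sensor noise.
A green recovery test therefore establishes that the analysis chain detects
the planted representational structure at the stated SNR — not that it
would behave identically on real recordings.

## Decoding

Linear SVM, C = 1, no class weighting — the field-standard MVPA default.
Features are z-scored with training-fold statistics only (no leakage).
fMRI: leave-one-block-out over (condition, block) patterns. MEG: one
stratified k-fold partition (default k = 10) drawn per dataset and reused
at every time sample, so the accuracy trace is comparable across time; for
pairwise condition decoding the majority class is subsampled to the
minority size within each training fold (seeded). Decision values of
exactly zero go to the class with the lower label index. Permutation nulls
shuffle at the unit of exchangeability: condition labels within blocks for
fMRI, trial labels for MEG. Empirical p-values use the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm), which can never return 0.

The implementation calls scikit-learn's liblinear solver directly (the
exact code path behind `LinearSVC`, with a pinned `random_state`) because
the fusion permutation test refits the classifier thousands of times and
estimator-object overhead would otherwise dominate the runtime; the public
estimator is the automatic fallback.

## RDMs and the commonality index

Neural RDM cells hold the pairwise decoding result mapped to dissimilarity.
The default follows the printed convention `1 − accuracy`; the alternative
`accuracy` convention (chance 0.5 = low, perfect 1 = high, matching the
binary model RDMs' direction) is available via `convention="accuracy"`.
The commonality index is invariant to this choice when it is applied to
both neural RDVs — flipping both negates the two neural–model Spearman
correlations jointly, and only their product enters the partialling — so
fusion results are identical either way; only the sign of the stored
neural–model audit correlations differs. RDVs are the lower triangle,
column-major, diagonal excluded (6 elements for 4 conditions); the order is
arbitrary but fixed package-wide, which is all rank correlation requires.

Model RDMs are binary: 1 where the two conditions differ on the coded
feature, 0.5 where they do not (configurable; Spearman-based quantities are
invariant to the actual two values). In the response model, cells pairing a
response condition with a cue-colour condition take the low value by
default — an assumption exposed as a parameter because the condition set
mixes two factors.

Commonality = ρ(fMRI, MEG) − ρ(fMRI, MEG | model), all Spearman
(Pearson on average ranks, midranks for ties). Degenerate cases return
missing (NaN), never ±∞ or a clipped value: a constant RDV makes ρ
undefined, and |ρ(neural, model)| within 1e-10 of 1 zeroes the partialling
denominator. Planting very strong effects can drive a neural RDV
rank-identical to the model, which is the honest "undefined" case.

## Inference

Permutation test: the fMRI condition labels are shuffled within blocks, the
pairwise decoding and fMRI RDM rebuilt, and the full commonality time
course recomputed, 1000 times by default (the MEG RDMs stay fixed — only
the fMRI labels are stated to be shuffled). One-tailed add-one p per time
point; Storey q-values across time within each (ROI × model × alignment)
trace; significant = q < α and commonality > 0. Negative commonalities are
reported but can never be significant.

Storey FDR uses the fixed-λ estimator π₀ = min(1, #{p > λ}/((1−λ)m)) with
λ = 0.5 (reproducibility over adaptivity; a λ-grid smoother would add a
tuning dimension with no benefit at trace lengths of a few hundred). π₀ is
floored at 1/m so a fully saturated trace cannot zero out every q-value.
Families smaller than 10 p-values fall back to Benjamini–Hochberg with a
warning, since π₀ estimation is meaningless there.

Temporal metrics per trace: time to first significant commonality (earliest
significant point at t ≥ 0 for stimulus-aligned traces; NaN when the trace
never reaches significance — reported as "no data point"), time to maximum
(argmax of the trace, flagged unreliable when nothing is significant), and
time from maximum to the response, defined as `response_ref − t_max` so a
maximum *before* the response is positive (the source convention is
internally inconsistent; this package fixes one direction and documents
it). For response-aligned traces the reference defaults to 0 (the button
press).

## Bayes factors

JZS one-sample/paired t-tests: H1 places a Cauchy prior (default scale
r = √2/2, the conventional default of the implementation family this
follows) on the standardised effect size. BF10 is computed by adaptive
quadrature of the noncentral-t marginal likelihood over the prior
(tolerance 1e-8); a one-sided variant integrates the doubled half-Cauchy
for directional above-chance tests; the default for difference tests is
two-sided. Thresholds: BF10 > 3 evidence for the alternative, < 1/3 for
the null, otherwise insufficient (boundaries inclusive to insufficient).
The test suite cross-checks against an independent g-space (inverse-gamma
mixture) quadrature to 1e-6 relative error. The chance reference for
above-chance decoding tests defaults to the theoretical 0.5, with the
empirical null mean available to the caller.

## Numerical and scaling choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte-for-byte.
- The calibration-style tests (type-I error over 200 null datasets,
  planted-structure recovery over 50 replicates) run at reduced world size
  — 4–8 blocks, 10–30 voxels, 6–16 sensors, 25–40 Hz MEG grids, n_perm at
  the documented floors of 100/200 — so the suite fits a single-CPU budget.
  Thresholds are unchanged; only the worlds are smaller.
- Pipeline CLI: `validate`, `simulate`, `run-all`, plus artifact-level
  `decode`, `fuse`, `stats` on a run directory. RDM construction happens
  inside `fuse`, which writes the RDM-derived traces as artifacts.

## Known limitations

- Single-"participant" worlds: group-level aggregation (`aggregate_rdms`)
  is implemented and tested, but the pipeline demo fuses one synthetic
  dataset per modality, mirroring the group-averaged fusion design.
- The Bayes-factor stage of the demo pipeline tests per-fold accuracies
  against chance; folds are not independent, so those BFs illustrate the
  machinery rather than a calibrated group inference.
- Storey adaptivity buys power inside a true effect window at the price of
  slightly elevated borderline false positives on the same trace when the
  effect is strong (π₀ shrinks); the recovery tests bound this at 10% of
  outside-window time points.
- Per-time-point fusion significance on single synthetic datasets has
  structurally limited power and, in one regime, a miscalibrated null.
  With 4 conditions an RDV has 6 cells, so every correlation in the index
  is a 6-element rank correlation with heavy quantisation and spread.
  Two consequences:
  1. A *pure* planted effect makes the neural RDV rank-degenerate with its
     own binary model in expectation (all cross-feature cells structurally
     tied above the same-feature cells, |ρ(neural, model)| → 1). The
     permutation null shuffles only fMRI labels, so at time points where
     the MEG RDV is noise it never reproduces the variance amplification
     coming through the near-unit fMRI–model correlation in the
     partialling denominator — the observed commonality there has several
     times the null's spread, and apparent "detections" (including
     onsets at 0 ms) are artifacts. Planting realistic concurrent
     information (e.g. rule structure alongside stimulus structure, as
     these regions actually show) keeps ρ(fMRI, model) moderate and the
     null calibrated.
  2. In the calibrated regime, the observed commonality is bounded near
     ρ(fMRI, model)·ρ(MEG, model), while the null's upper quantiles scale
     the same way through the discrete atoms of a random 6-element rank
     correlation against the model (a permuted RDV lands at |ρ| ≥ 0.87
     with probability ≈ 1/15). Per-point permutation p-values therefore
     have a floor of roughly 0.03–0.07, and FDR across a trace can push q
     below 0.05 only when several points beat essentially the entire null
     sample — so single-dataset detection of a moderate planted effect is
     a borderline event (observed ~20–30% of replicates at pattern
     amplitude 2), not a near-certainty. Group-averaged multi-participant
     RDMs with graded multi-feature structure (the setting this analysis
     was designed for) soften both issues but are not reproducible at
     desk scale.
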