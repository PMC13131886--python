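# Methods

`dualpath` implements a dual-branch spatiotemporal classifier for ROI-level
fMRI time series together with the full analysis chain around it:
quality control and signal conditioning, nested cross-validated evaluation,
attribution-based interpretation of both branches, event detection from
frame-wise attention, and multivariate brain-behavior mapping.  A synthetic
cohort generator with planted ground truth provides the test bed: every
stage of the chain can be scored against what was planted.

## The classifier

The input is one matrix per subject, `R x T` (246 Brainnetome parcels by
`T` acquisition frames at repetition time `tr` seconds), plus a metadata
vector (sex one-hot, site one-hot, age standardized with training-fold
statistics).

A shared temporal-convolution backbone applies three blocks of
(1-D convolution along time -> batch normalization -> ReLU -> dropout) with
kernel sizes 7, 7, 5, stride 1 and symmetric zero padding, so the temporal
length is preserved and frame-wise features stay aligned with stimulus
time.  Channel widths default to (128, 64, 64) and are configurable; the
tests and bundled analysis configurations use (32, 32, 32), which trains in
seconds on one CPU core and loses nothing at the planted effect sizes.

Two branches consume the feature maps `h_t`:

* **Global temporal-pooling branch** — features averaged over time,
  metadata concatenated, linear head to 2 logits.  Averaging discards all
  information about *when* signal occurred; this branch models stable,
  trait-like spatial patterns.
* **Attention-based multiple-instance branch** — a tanh-gated scorer
  `s_t = u . tanh(V h_t)` produces frame-wise attention
  `a_t = softmax(s)_t` (nonnegative, summing to 1 per subject); the bag
  representation `sum_t a_t h_t` is concatenated with metadata and fed to
  its own linear head.  The attention profile is the interpretable output:
  it says when the model found diagnostic information.

The branch logits are fused convexly, `alpha * global + (1-alpha) * MIL`,
with `alpha` a searched hyperparameter, and the class is the argmax (ties
resolve to class 0).  Training minimizes mean cross-entropy with Adam,
mini-batches, and early stopping on a held-out split; one integer seed
controls initialization, dropout, the holdout split and batch order.

A note on permutation symmetry: attention aggregation is itself a symmetric
set function, so with *fixed* per-frame embeddings both branches are
invariant to reordering frames.  Temporal sensitivity of the MIL branch
enters through the convolutional embeddings (kernels span neighboring
frames) and through which frames receive attention mass.  The testable
contrast is therefore: equalizing the temporal distribution of features
while preserving their time-mean leaves the global branch unchanged and
moves the MIL branch.

The network and its gradients are implemented directly in numpy
(im2col convolutions, explicit backward passes).  This keeps the package
dependency-light, makes the gradient flow fully inspectable, and gives
attribution code first-class access to input gradients; backward passes are
verified against finite differences in the test suite.

## Evaluation protocol

Outer evaluation is stratified group 5-fold cross-validation: all samples
of a subject share a fold and per-fold label proportions match the cohort.
Within each outer training fold, random search (log-uniform learning rate,
batch size choice, dropout and fusion-alpha ranges) is scored by mean
validation accuracy over an inner stratified group 3-fold split; the winner
is retrained on the full outer training fold with a 10% stratified internal
holdout for early stopping (patience 10 by default; stopping cannot fire
before a minimum epoch count, because holdout accuracy is a noisy step
function that sits at chance for the first few epochs of slow-starting
runs) and scored once on the outer test fold.  The search range for the
learning rate is log-uniform on [3e-4, 1e-2]: lower rates do not converge
within the desk-scale epoch caps.  Reported metrics: accuracy, precision and recall (case
class and macro), macro-F1, as mean +/- sd over outer folds.  Age
standardization for the metadata vector is always computed from the
training portion in play — the leakage test asserts that changing the
training fold changes the encoding.

Inner fold count (3), search budget, patience, epoch caps and the holdout
fraction are configuration with documented defaults; they are not dictated
by the method.

## Signal conditioning

* Band-pass: zero-phase (forward-backward) Butterworth, 0.008–0.09 Hz,
  order 4 per direction.  At this order in-band content is attenuated
  < 0.1% while 0.2 Hz is suppressed by roughly 40 dB; a lower order leaves
  so much transition-band leakage that refiltering changes signal energy
  appreciably, which breaks the idempotency property the pipeline relies
  on.  Strictly band-limited idempotency (for in-band content) is tested.
* Nuisance regression: per-region OLS residuals on [intercept, confounds];
  collinear confound columns are dropped with a warning.  Order relative
  to filtering is configurable; the default applies regression after
  filtering and is an assumption, not a claim about any particular
  acquisition pipeline.
* Hemodynamic alignment: stimulus index `t` is paired with the brain
  sample at `t + round(delay/tr)` (ties toward the larger shift; default
  delay 4 s), cropping the uncovered tail.
* Segment slicing: half-open TR windows `[start, end)`; the three
  narrative segments of the long movie stimulus ship as configuration
  defaults (0–243, 372–543, 547–end).
* QC: subjects are excluded for mean framewise displacement > 0.5 mm,
  > 10% repaired volumes, NaNs, or a shape differing from the cohort mode;
  inequalities are strict (FD = 0.5 mm is retained), rules are
  order-independent, and every exclusion is reported with its triggering
  rule.  Volume repair itself is out of scope; the repaired fraction is
  consumed as a phenotype field.
* Model input scaling: per-region z-scoring across time is available but
  off by default.  Within-subject demeaning would erase exactly the stable
  spatial offsets the pooled branch is designed to detect, so the default
  feeds conditioned amplitudes to the network unchanged.

## Attribution and event chain

* **Integrated Gradients** on the model input, midpoint-quadrature
  approximation of the path integral from a baseline (all-zeros by
  default; configurable) to the input, targeting a chosen branch logit
  (fused / global / MIL) of the predicted class.  Completeness — the
  attributions sum to `F(input) - F(baseline)` — is tested per branch at
  128 steps with a < 1% gap; the linear-model closed form (`w_i x_i`) is
  exact.  Time-resolved maps target the MIL logit; the pooled spatial map
  targets the global logit and is summed over time.
* **Ensemble attribution.**  When several discriminative signals are
  redundant, a single fit may classify perfectly while representing only
  one of them, and its attribution map inherits that arbitrariness.  The
  chain therefore averages attribution magnitudes (|IG|) and attention
  profiles over a small ensemble of fits differing only in seed (default
  4).  Group-level maps computed from the ensemble are stable across
  seeds; all downstream consumers (top-region selection, saliency indices,
  concordance) operate on magnitudes anyway.
* **Event detection**: per-timepoint two-sample Mann–Whitney test between
  the groups' attention weights; timepoints with p < 0.05 merge into
  maximal runs; runs shorter than 3 TRs are discarded; windows are indexed
  E1..Ek in temporal order with the direction of the group difference.  No
  correction across timepoints by default (a Benjamini–Hochberg mode is
  available).  The false-event rate under exchangeable groups is tested to
  stay below 5%.  Because attention is compositional (sums to one per
  subject), a genuine group difference inside an event window necessarily
  induces opposite-signed differences elsewhere; side-lobe windows flagged
  "control" adjacent to strong "case" windows are expected behavior, not
  false positives of the test.
* **Top-region selection**: k = round(0.05 * R) regions (12 at R = 246) by
  absolute attribution, ties to the lower region index.  Event-level
  scores use the median |IG| over the event window per subject, averaged
  over case-group subjects.
* **Core presence matrix**: boolean ROI-by-event membership in the
  per-event top sets; core regions appear in at least a majority threshold
  of events (e.g. 3 of 6, or 3 of 4), event-specific regions in exactly
  one.
* **Saliency indices**: per subject, mean |IG| over the global top set
  (global index) and over each event's top set within its window (event
  indices).
* **Network assignment**: each atlas ROI maps to the network parcel with
  maximal voxel-overlap proportion; exact ties break to the lower network
  id with a flag; zero overlap yields "unassigned".

## Brain-behavior mapping

The global saliency index is related to behavior by partial Pearson
correlation: both variables are residualized on covariates (age, sex and
site dummies), the residuals correlated, and p computed from the t
distribution with `n - c - 2` degrees of freedom; missing pairs are
dropped listwise.

Event indices enter a partial PLSC: rank-based inverse normal
transformation (Blom offset 3/8) of each brain column, residualization of
both blocks on covariates (single-block mode available), column
standardization, then SVD of the cross-covariance `X'Y/(n-1)`.  The
first-nonzero-positive sign convention makes weights deterministic.
Significance: behavior rows are permuted (5,000 by default) and each latent
variable's singular value is compared with the permuted distribution of the
same-index singular value — a standard approximation for non-leading
components, recorded as such.  Stability: subjects are resampled with
replacement (5,000 by default), each bootstrap SVD is aligned to the
original weights by maximal absolute agreement in sign and order, and the
bootstrap ratio is the original weight over the bootstrap standard
deviation, flagged at |BSR| > 1.96.  Permutations use batched SVDs of the
small cross-covariance matrices, so large iteration counts cost seconds.

## The synthetic cohort generator

Each subject's series is built as

    site offset + shared stimulus component + AR(1) noise
    + (case) x subject trait amplitude x trait offset on trait ROIs
    + sum over events: subject event amplitude x response(t) on event ROIs

with behavior scores loaded linearly on the event amplitudes.

Defaults (60 subjects per group, 246 ROIs, 250 TRs at 0.8 s) and the
reasoning behind the effect structure:

* **Noise**: AR(1) with rho = 0.3, marginal sd 1 — the natural unit of all
  effect sizes.  A shared `R x T` smoothed component (sd 0.5) is added to
  every subject, inducing the positive inter-subject correlation that
  naturalistic viewing produces; disabling it removes that correlation.
* **Trait signal**: +0.5 sd stable offset on a compact set of 3 regions in
  cases, scaled per subject by 1 + Normal(0, 0.5) jitter.  Trait-like
  differences concentrated in a handful of regions mirror how such
  analyses report stable group signatures; the subject-level jitter keeps
  the signal from being trivially separable, so training pressure remains
  on the transient signals too.
* **Events**: three 30-TR windows on disjoint 12-region sets.  The
  response is a boxcar convolved with a canonical double-gamma hemodynamic
  response (pure boxcar mode available for exact-window unit tests) and
  then demeaned over the run: transient responses fluctuate around
  baseline rather than shifting the run mean, which is also what band-pass
  filtered BOLD looks like.  This makes the stable and transient planted
  signals separable by construction — the time-averaged pathway can only
  exploit the trait offset, the windows only carry the events.  Subject
  amplitudes are `effect x (group_gain if case else 1) + Normal(0, 0.4)`
  with effect 1.5 and gain 2.0.  The ground truth records both the planted
  boxcar window and the effective response window (regressor above half
  maximum), which is what detection should be scored against under the
  hemodynamic lag.
* **Demographics**: cases ~85% male vs controls ~61%, ages Normal(11, 1.5)
  truncated above 5 years, three sites with small additive offsets, mean
  FD |Normal(0.13, 0.05)| mm — the magnitudes a developmental cohort of
  this kind exhibits.
* **Behavior**: all scores share one loading vector over event amplitudes
  (rank-1 brain-behavior cross-covariance) plus noise at half the signal
  sd; score scales imitate SRS/RBS/CBCL totals.  Within one diagnostic
  group the amplitude jitter is isotropic, so the planted loading vector
  is exactly the first PLSC brain component there — brain-behavior
  analyses are therefore run within the case group, as symptom-severity
  analyses are.

What the generator does *not* emulate: spatial autocorrelation between
parcels, scanner drifts and physiological rhythms, heavy-tailed motion
artifacts, heterogeneous site covariance, label noise, and any nonlinearity
in the brain-behavior link.  Passing recovery tests on this generator shows
the chain is correct and well-calibrated — not that comparable accuracy or
effect sizes would be obtained on real cohorts.

## Numerical choices and problem sizes

* Network arithmetic is float32; losses and attributions accumulate in
  float64.  Argmax ties go to class 0; top-k ties to the lower region
  index; `k = round(fraction x R)` uses round-half-even.
* Conv biases receive exactly zero gradient through the following
  batch-norm (mean subtraction); the dead-path test exempts them.
* Tests and the acceptance script run the desk-scale configuration:
  channels (32, 32, 32), random-search budget 2–3 configurations, inner
  k = 3, attribution ensembles of 2–4 fits at 16–32 IG steps, null
  calibrations at 30/group with T = 150, and permutation calibration at
  n_perm = 500 over 200 repetitions.  These sizes are the package's choice
  of a configuration that a laptop reproduces in minutes; every protocol
  element is identical at larger sizes.

## Known limitations

* The MIL attention is a single softmax over time: two simultaneous
  discriminative processes in one window are not separable.
* Attribution ensembling stabilizes group-level maps but roughly
  multiplies attribution cost by the ensemble size.
* Permutation p-values for non-leading latent variables are approximate
  (same-index comparison).
* The image-space preprocessing that produces ROI series (realignment,
  normalization, smoothing, atlas extraction) and stimulus annotation
  pipelines are out of scope; the package starts from extracted ROI
  matrices and treats annotation windows as configuration.
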