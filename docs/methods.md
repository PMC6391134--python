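# Methods

`isidecode` implements a trial-by-trial, spike-timing-based decoding
framework for cortical spike trains recorded in a go/no-go task, together
with the controls and statistics needed to interpret it: a rate-modulated
Poisson baseline decoder, two shuffle null models, classical-responsiveness
tests, and ensemble LLR-consensus metrics.  This note records the model,
the numerical choices, and what the synthetic benchmarks do and do not
establish.

## The decoding model

**Observation model.** The elementary observation is the interspike
interval (ISI).  For each unit, ISIs from training trials are sorted into
four libraries by the trial's stimulus category (target / non-target) and
behavioral choice (go / no-go).  Each library yields a conditional density
p(ISI | c, t) estimated by Gaussian-kernel KDE on log(ISI) — the log maps
the positive ISI axis to the real line — in 1 s sliding windows
recalculated every 100 ms to absorb within-trial non-stationarity.  An ISI
is always assessed with the window whose center is closest to its final
spike; ties go to the earlier window, and out-of-range times clamp.

**Inference.** Each trial starts from the agnostic prior
p(target) = p(non-target) = 0.5.  Every ISI, in order of its closing
spike, updates the posterior by Bayes' rule with the window-assigned
likelihoods.  ISIs are treated as independent, so the end-of-trial
posterior equals the normalized product of per-ISI likelihoods — the
implementation accumulates log-likelihood ratios, making order-invariance
and normalization exact to machine precision.  The per-trial *decoding
performance* is the posterior mass on the true condition at trial end
(certainty-weighted; chance 0.5); thresholded accuracy (ties scored 0.5)
is reported alongside.  Ensembles share one posterior per variable,
updated by every member's ISIs chronologically; per-member likelihoods are
fitted independently.

**Cross-validation.** Trials are stratified over the four
(stimulus x choice) categories into 10 folds; the fold split is redrawn
for each of 124 bootstrap repetitions (defaults).  If the smallest
category has fewer trials than folds, the fold count is reduced to that
size (with a warning) so every training set spans both conditions.

**Trial window.** A trial runs from tone onset (time 0) to the behavioral
response; no-go trials, having no response, end at the mean response time
of *correct* go trials (configurable to all go trials — the reference set
is genuinely ambiguous and the choice moves the window end by a few
percent at realistic false-alarm rates).  ISIs are included when their
final spike falls in [start, end); the first spike of the pair may precede
the window, which maximizes data use and matches the final-spike window
assignment.

## Bandwidth selection and density evaluation

The kernel bandwidth is chosen per window from 30 log-spaced candidates in
[0.01, 1.5] log-ISI units by 10-fold cross-validation on the mean held-out
log-density; ties take the smaller bandwidth.  For speed, the CV score is
computed on at most 300 randomly subsampled observations (the final
density uses all of them); the bandwidth estimate is insensitive to this
cap well before 300 samples.  Windows holding fewer observations than CV
folds are pooled symmetrically with neighboring time ranges; if the whole
library is still too small, one whole-trial density is shared by all
windows.  Densities are renormalized to the support (1 ms – 10 s by
default) so they integrate to one, and floored at 1e-9 per log-ISI unit at
evaluation time so no single ISI can produce an infinite log-likelihood
ratio.  All LLR and consensus quadrature uses a 512-point log-spaced ISI
grid with trapezoidal integration over the log-ISI coordinate; because
every density lives on log-ISI, Jacobians cancel in all ratios.

## The rate-modulated Poisson baseline

The conventional alternative assumes spikes arise from an inhomogeneous
Poisson process with per-condition rate r_c(t), estimated from the
training PSTH by Gaussian KDE (CV bandwidth over 5–500 ms) on a 1 ms
grid.  Because trials end at variable response times, the smoothed spike
density is divided by the number of trials still active at t; each
kernel is renormalized to its mass inside the session span, so per-trial
integrals of the fitted rate average to the mean spike count.  The rate
is floored at 0.01 spikes/s.  Decoding uses the whole-trial likelihood
(1/n!) Π r(t_i) exp(−∫r); the implementation also provides the
ISI-factorized form with explicit boundary terms (agreement to 1e-9 is a
test oracle) and the window-normalized ISI density the Poisson model
predicts, for direct comparison with the nonparametric densities.

Agreement between decoders is summarized by the Matthews correlation of
per-trial correctness, and by that correlation divided by the maximum MCC
attainable with both decoders' accuracies held fixed (computed by scanning
every feasible overlap of the two correct sets; verified against
enumeration).

## Null models and significance

Two shuffles: (1) *ISI resampling* — per trial, ISIs drawn with
replacement from the unit's pooled, condition-agnostic library and laid
down from the trial's first observed spike (configurable to 0) until the
trial end; lengths and labels preserved.  (2) *condition permutation* —
spikes untouched, (stimulus, choice) label pairs permuted jointly
(independently via a flag); outcomes recomputed, windows frozen to the
original trials.  Each of (default) 1240 repetitions regenerates the null
and runs the identical decoding pipeline.  The p-value compares the median
of the observed bootstrap repetitions to the null distribution,
p = (1 + #{null ≥ observed}) / (1 + N); at the default 1240 repetitions
the floor is 1/1241.

## Responsiveness statistics

*Tone modulation*: per trial, spike-count changes of the 100 ms tone and
post-tone windows against three sequential 100 ms pre-onset baselines are
pooled; 5000 subsampled (90%) means are formed, and the unit is sensory
non-classically responsive only if ≥95% of means lie within ±0.1 spikes
for **both** windows (the conservative reading).  Note the band is an
absolute criterion: on stationary cells its false-positive rate depends on
baseline count noise — about 1% at 2 Hz spontaneous rate with 300 trials,
but large at high rates or short sessions.  *Ramp index*: the maximum
slope of a linear regression in a 500 ms window sliding over the
response-aligned, 50 ms-binned rate starting 850 ms before the response.
Taking a maximum biases the index upward by roughly one window-noise
standard deviation, which shrinks as 1/sqrt(trials); the calibration
benchmarks therefore size sessions inversely with the slope being
recovered.  A cell ramps when the implied change (|slope| x 0.5 s)
exceeds 50% of its mean rate in ≥95% of trial-subsampled bootstraps and
the best window's Pearson r exceeds 0.5.  Also provided: the evoked
z-score mu/sigma of per-trial count changes, receptive-field best
frequency and half-height bandwidth on a log2-frequency axis, and
logistic-link (binomial GLM) stimulus/choice selectivity indices with the
orthogonal-projection uniplexing axis.

## Consensus metrics

For an ensemble of weighted LLR curves, consensus is the l1 norm (absolute
area, integrated over log-ISI) of the sum divided by the sum of the norms:
1 for members that agree in sign everywhere, 0 for exact sign reversals.
The unsigned consensus maximizes consensus over all 2^(n−1) member sign
assignments up to a global sign — exhaustively enumerated, capped at
n = 16.  Time courses re-estimate per-member weighted LLRs from the ISIs
whose final spike falls in a 750 ms window sliding every 100 ms
(stimulus- or response-aligned) and assign each value to the window
center; spline interpolation is presentation-only.

## The synthetic-data generator

Sessions mirror trained-animal behavior: stimulus Bernoulli(0.5), hits at
88%, false alarms at 7%, log-normal go response times around 1.5 s, no-go
trials truncated at the mean correct-go response time, pre-onset baseline
retained to 0.3 s.  Conditional ISI distributions are two-component
log-normal mixtures; the "distinct" presets match the mean ISI across
conditions (bimodal 30/240 ms vs. a mean-matched unimodal mixture,
sigma 0.35 log units, ~7 spikes/s) so the mean rate carries no
information.  The model-cell presets reproduce the canonical
dissociations: `fig2a` (evoked + distinct ISIs), `fig2b` (evoked +
identical ISIs), `fig2c` (no evoked response, distinct ISIs).

Two construction details matter and were chosen deliberately:

- **Evoked responses are circular rotations of circularly generated
  trials.**  The evoked construction rotates a trial's spike pattern so
  the spike nearest a drawn time t ~ N(30 ms, 10 ms) lands exactly on it
  ("variance of 10 ms" is read as SD = 10 ms; a variance of 10 ms is
  dimensionally a duration).  A rotation only preserves ISI statistics
  exactly when the pattern is stationary on a circle, so evoked cells are
  generated as circular renewal patterns (uniform phase); the circle-cut
  artifact is then identical across conditions.  With linear generation
  the wrap interval and the broken pre-onset continuation appear on
  target trials only, and the ISI decoder detects that asymmetry — a real
  leak, not a decoder bug.  Pre-onset baselines are independent
  stationary segments.
- **Model-cell preset sessions use fixed 1.5 s trials**
  (`preset_session`).  With variable response times, either decoder can
  read the stimulus out of the trial *duration* through the
  stimulus-choice correlation; fixing the length isolates what the spike
  train itself encodes.  Behavioral-realism sessions (`SessionSpec`
  defaults) keep variable lengths.

What the generator does not emulate: spike-history dependence beyond the
renewal structure (real neurons have refractoriness and burst
correlations the independence assumption ignores), correlated noise
across ensemble members, drift across a session, and spike-sorting
contamination.  Passing benchmarks on these cells therefore shows the
pipeline is correct and calibrated under its own assumptions, not that
real cortical data satisfy them.

In-trial ISIs are right-censored at the trial end (an interval is
observed only if it fits), so the empirical ISI distribution of short
trials is slightly shifted toward short intervals relative to the
generating mixture; distribution-recovery tests use long trials where the
censoring is negligible.

## Benchmark problem sizes

The shipped test suite runs the full pipeline at desk scale: 100–200
trial sessions, 20 decoding repetitions, 39–50 null repetitions (p-value
floor 1/40), 200 simulated units for the tone-modulation calibration, and
3000–30000-trial sessions for ramp-index recovery (larger for smaller
slopes, per the bias argument above).  Defaults in `RunConfig` remain the
published full-scale parameters (124 repetitions, 1240 nulls).

## Known limitations

- Error prediction (train on correct trials, flag held-out trials whose
  decoded choice contradicts the choice their stimulus demands, balanced
  accuracy over correct/error) is an interpretation; the original
  procedure is not fully specified.
- The p-value aggregation compares the *median* of the observed bootstrap
  values to the null; other summaries are defensible.
- Bandwidth CV folds are unstratified random splits with a recorded seed.
- The consensus l1 norm integrates over log-ISI; any fixed coordinate
  gives the same worked-example values because the metric is a ratio.
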