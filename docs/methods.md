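# Methods

## Task model

A trial runs on a clock with t = 0 at target onset. Two colored targets
appear 567 ms after fixation; 533 ms later six stimuli are shown
sequentially, each visible 333 ms and followed by a 133-ms gap (466-ms
pitch), then a variable end delay of 433/533/633 ms precedes the go cue.
The model window is target onset → go cue, discretized into 10-ms bins;
event times are floored onto the bin grid (the first stimulus lands in bin
53). Each stimulus is drawn i.i.d. uniformly from a pool of six shapes and
colored red or green with equal probability. Shape `i` carries an assigned
weight `W_i` (base-10 log odds); the default synthetic pool is
{−0.9, −0.5, −0.3, +0.3, +0.5, +0.9} — symmetric and spanning weak to
strong cues; it is a simulation convention, configurable via YAML.

Reward: the probability that a target pays the large reward is the base-10
logistic of its same-color summed weights, computed independently per
color (the two probabilities need not sum to 1). Two schemes are
implemented: *probabilistic* (the chosen target's lottery always runs) and
*better_only* (the lottery runs only when the weakly better target was
chosen; otherwise no reward, or optionally the small one). A tie counts as
choosing the better target.

Per-stimulus variables, with red = +1 and configuration = +1 when the
in-field target is red: consistency = color × configuration; evidence =
SW × consistency; color evidence = SW × color; SW_in/SW_out route the
weight to the in-field/out-field target and satisfy SW_in + SW_out = SW,
SW_in·SW_out = 0. Because color and configuration are exactly ±1, the
identities evidence = SW × consistency = color_evidence × configuration
hold bit-exactly in floating point. The reference frame of "color
evidence" (here: evidence for the red target) is one consistent reading;
the alternative (evidence for the stimulus-colored target) differs only by
relabeling.

## Behavioral analyses

Choices are modeled as Bernoulli with a base-10 logit link,
`P(red) = 1/(1+10^−Q)`. For subjective weights, Q is linear in how often
each shape appeared in red minus in green (one coefficient per shape,
shared across colors); for epoch leverage, Q is linear in the epoch
stimulus's subjective weight signed by its color (one coefficient per
epoch). The fit is an in-house Newton/IRLS on the base-10 likelihood with
Wald standard errors from the observed information; coefficients equal
natural-log logistic estimates divided by ln 10, which the test suite
verifies against statsmodels to 1e−8. No regularization is applied;
perfect separation and rank deficiency raise errors rather than shrink
silently. Psychometric curves use nine equal-count bins of net assigned
evidence (binning granularity was not externally constrained; nine is the
default).

## Encoding model

Spike counts `r_t` in 10-ms bins are Poisson with
`λ_t = exp(b0 + Σ_i (k_i ∗ f(x_i))(t))` (λ in spikes/s, exposure
Δ = 0.01 s). Two regressor semantics are provided because the published
description ("a boxcar lasting 1500 ms" convolved with a kernel) and the
plotted per-lag kernels cannot both be literal:

* **impulse** (default): `f(x_i)` is an impulse of amplitude `x_i` at the
  event-onset bin and the kernel has one free weight per 10-ms lag over
  the full support (150 lags for stimulus variables, 300 for target
  variables). The kernel then *is* the plotted response function.
* **boxcar**: the amplitude is held for the support duration from onset
  and convolved with a shorter free kernel (default 50 lags).

Contributions extending past the go cue are truncated: design rows simply
end at the trial's last bin, which the suite verifies equals masking a
padded design. A global intercept is always included (the baseline rate is
otherwise unidentified); note the stimulus-onset and target-onset kernels
overlap heavily with the intercept over the stimulus period, which
inflates their per-lag variance — visible in the null-neuron recovery
bounds used by the tests.

The negative log-likelihood `Σ_t [Δλ_t − r_t log(Δλ_t)]` (log r_t!
dropped) is minimized by damped Newton iterations: the exact Hessian
`XᵀWX` is assembled from the sparse design, solved by Cholesky with
Levenberg damping only if numerically singular (lags with no data), and
steps are halved until the NLL decreases. The objective is convex, so the
optimum is unique and start-independent; shuffle and CPD refits therefore
warm-start from the observed fit purely to save iterations. Convergence:
relative NLL change < 1e−9 or gradient norm < 1e−6; init is zero kernels
with the intercept at the log mean rate. Datasets with zero spikes raise a
degenerate-data error (the log-rate is unbounded below). Cross-validation
is five-fold over trials with a seeded shuffle, reporting train/test NLL
against an intercept-only reference.

## Shuffle-null inference

For a variable's significance, its per-trial values are permuted across
trials (event times kept) and the full model refit; 100 shuffles by
default. Per lag, the observed kernel weight is compared to the shuffle
distribution with a t statistic (df = n_shuffles − 1, two-tailed,
p < 0.01) — the shuffles are the only replicate structure available for a
single neuron. Lags whose null variance is at rounding level are marked
non-testable. The neuron-level gate: each shuffle's kernel is tested
leave-one-out against the remaining shuffles and its longest significant
run recorded; the neuron encodes the variable only if its observed longest
run strictly exceeds the 95th percentile of those null runs (computed
within the one shuffle set rather than with fresh nested shuffles, which
would square the refit cost). Latency is the start of the first run whose
duration itself exceeds the threshold — the first *significant encoding
duration*, not the first stretch of per-lag hits; isolated false-positive
lags (expected at ~1% of lags by construction) would otherwise capture the
latency and bias late onsets severely early. The encoding sign is the sign
of the mean kernel weight over that run. No multiple-comparison correction
is applied beyond the longest-run gate.

Two properties of this procedure are worth knowing. First, the gate is
**conservative**: the longest run is a small discrete statistic (under the
null almost always 0 or 1 bins at α = 0.01), so "strictly above the 95th
percentile" occurs in roughly 1–3% of null neurons rather than 5% —
measured here both on simulated null neurons and in an abstract
Monte-Carlo of the procedure, and insensitive to the quantile convention.
Second, the latency **overestimates** the true onset by roughly half a
rise time: a qualifying run begins where the kernel becomes reliably
detectable, somewhat after it starts rising (the validation cohort's
planted 200/350/680 ms onsets are recovered near 260/410/790 ms). The
*ordering* of latencies across variables is preserved much more faithfully
than their absolute values.

CPD uses the same shuffles: per repetition the variable is shuffled, the
model refit, and `CPD = (SSE_reduced − SSE_full)/SSE_reduced` computed on
expected counts, averaged over repetitions (100 by default). Population
kernel summaries use uncorrected per-lag one-sample t tests across
neurons. SW_in/SW_out selectivity is the mean kernel weight over a late
window; neurons selective for both are called "equal and opposite" when
the sum of the two selectivities does not differ from its shuffle null.
Model-II (reduced-major-axis) regression uses slope = sign(r)·sd(y)/sd(x);
its significance comes from a permutation test of y against x — the named
procedure in the source literature is not fully specified, so a
permutation test stands in and is labeled as such.

## Synthetic data

The generator is the analyses' inverse. Choices come from a base-10
logistic agent whose per-shape leverages play the role of subjective
weights. Spikes are inhomogeneous Poisson with log rate built through the
*same* regressor code path the GLM fits, from named kernel templates:
a negative transient on weight (onset 200 ms, peak ~300 ms, gone by
1000 ms), a later negative transient on consistency or color evidence
(onset 350 ms), a sustained positive ramp on evidence (onset 680 ms), or
silence (null). Template onsets echo the latency cascade the pipeline is
meant to resolve; they are fixtures, not measurements. Baseline rates
default to 10–40 sp/s (a conventional range; the source data's rate
distribution is not public), and the simulated rate is capped at
1000 sp/s with a warning so degenerate amplitudes cannot overflow.

What the generator does *not* emulate: refractoriness, adaptation,
spike-history effects, across-neuron noise correlations, non-Poisson
dispersion, eye-movement covariates, and session nonstationarity. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to real-data violations of
them.

## Validation studies and problem sizes

`lipglm.validation` packages four studies, run by both the test suite and
`scripts/acceptance.py`:

* behavioral recovery — 50,000 trials; subjective weights recovered within
  2 SE; an agent ignoring epoch 6 yields a null epoch-6 leverage with all
  other epochs clearly positive;
* kernel recovery — 10 neurons × 1000 trials at 30 sp/s, full 8-variable
  model; fitted weight and evidence kernels correlate > 0.8 with ground
  truth per neuron;
* null calibration — 200 homogeneous neurons × 200 trials, 20 shuffles,
  compact {stimulus onset, weight} model; reports the flagged fraction
  (expected ~1–2.5%, see above);
* latency ordering — 30 neurons × 150 trials planted with the
  200/350/680 ms cascade at amplitude 0.5; mean latencies preserve
  weight < consistency < evidence with pooled two-sample t tests.

Cohort and shuffle sizes are the package's validation defaults, chosen so
each study finishes in minutes on one CPU while its statistical assertion
retains power; all randomness flows from a single seed through
`numpy.random.SeedSequence`, making every study bit-reproducible.

## Numerical choices and degenerate inputs

Quantile groups use stable argsort with `array_split` (sizes within one;
ties broken by trial order). The 300–800-ms rate window is applied
literally even where it crosses into the next epoch. Per-bin PSTH standard
errors are across neurons. Zero-variance latency sets, all-identical
choice vectors, rank-deficient designs, zero-spike neurons, negative or
fractional spike counts, and out-of-support selectivity windows all raise
explicit errors. Trial CSVs are written at %.17g and read with
round-trip float parsing so write → read is lossless.
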