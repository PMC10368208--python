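# Methods

This note documents the models implemented in `ssdmodels`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical and
design choices that were genuinely open.

## Task and synthetic sessions

The saccadic-suppression-of-displacement (SSD) task asks an observer to judge
whether a target moved while their eyes were in flight. On each simulated
trial a cue signals the prior probability of a jump, P(J); the displacement is
drawn from a broad Gaussian on jump trials and a narrow Gaussian on no-jump
trials (both zero-mean), and sensory uncertainty is set by the width of the
Gaussian-blob target, sigma_t. The generator (`ssdmodels.design`) builds five
session layouts:

- `human_categorical` — 1300 trials: a 100-trial neutral baseline block, then
  six 100-trial blocks per cued prior (0.9 and 0.1). 70% of prior-block
  trials are low-noise (0.1 deg) training trials whose jump probability
  matches the cue; 30% are testing trials at 0.25/0.5 deg with a veridical
  jump probability of 0.5. Per prior this yields 420/1300 = 32.3% training
  trials and 90/1300 = 6.9% per testing cell. Displacement widths 1.5 /
  0.017 deg (jump / no-jump).
- `monkey_categorical` — same layout with priors 0.8/0.2, blob widths
  0.5/1.25/2.0 deg, displacement widths 2.5 / 0.2 deg.
- `monkey_control` — as above but the jump probability matches the cue at
  every noise level.
- `continuous` — 600 training + 400 testing trials; displacements from the
  continuous prior N(0, 1 deg); noise levels 0.1/0.5/1.0 deg plus a
  target-absent ("infinite noise") condition making up 20% of trials. The
  testing split across the three finite levels (107/107/106) keeps counts
  exact.
- `motor_noise` — six interleaved trial types (priors 0.2/0.5/0.8 by
  saccade/no-saccade), lowest blob width throughout, veridical cues;
  1000 trials per type by default.

Two generator conventions matter for testing. First, per-(prior, noise,
phase) cell counts are exact — only trial order and displacement draws are
random — so realized proportions can be asserted without tolerance. Second,
the target-absent condition is carried as the string sentinel `"infinite"`
rather than a float infinity, so accidental arithmetic on it fails loudly.

Each trial also carries a synthetic jump-command-to-saccade-end latency,
Gaussian with mean −17.25 ms, SD 1.80 ms for human-style sessions and
−7.63 / 5.07 ms for macaque-style sessions. These exist purely to exercise
the timing-exclusion filter (`filter_by_timing`, which drops trials whose
jump command preceded saccade end by more than one display frame); no eye
traces are modeled, and participant-level exclusion is left to the caller.

What the generator does **not** emulate: sequential dependencies, learning
within a session (responses come from a fixed observer), lapses of attention
beyond the observer's lapse parameter, saccade kinematics, and any
veridical-feedback dynamics. Tests passing on these sessions show the
estimators are consistent for data generated by their own model class, not
that the models describe real observers.

## Categorical Bayesian ideal observer

The observer reports "jumped" when P(J | x_hat) > P(not-J | x_hat) for the
perceived displacement x_hat ~ N(x, sigma_t^2). With Gaussian likelihoods the
log-odds condition is quadratic in x_hat; with both likelihood means at zero
it reduces to a threshold on x_hat^2,

    crit = [log((sJ^2 + st^2)/(sNJ^2 + st^2)) + 2 log((1 - P(J))/P(J))]
           / [1/(sNJ^2 + st^2) - 1/(sJ^2 + st^2)],

and because x_hat^2 / st^2 is noncentral chi-square (df 1, noncentrality
x^2/st^2), the report probability at a true displacement x is the survivor
function of that distribution at crit/st^2 (`decision_curve`). Corner cases
are made explicit rather than left to floating point: a non-positive crit
means "always report jumped"; equal effective variances make the decision
prior-only (sentinel with a warning); sigma_t = 0 degenerates to the
noiseless indicator. For non-zero likelihood means the quadratic region is
found by a bracketing root finder and the curve is evaluated by Monte Carlo
(`mc_decision_oracle`), which doubles as the independent cross-check of the
closed form (agreement within 3 MC standard errors at 10^6 samples is
asserted on a 45-point grid).

`CategoricalBayesObserver.fit` is a 14-parameter Bernoulli maximum-likelihood
fit for a 3-prior x 3-noise session: three priors, three sensory-noise SDs,
shared jump/no-jump widths, and a lower bound and lapse rate per noise level
scaling the curve into [lower, 1 − lapse]. The NLL surface is multimodal, so
the optimizer (L-BFGS-B, SDs log-transformed, priors logit-transformed,
lapse/lower bounded to [0, 0.5]) is multi-started: one data-informed anchor
(empirical response rates seed the priors, the condition's blob widths seed
the noise SDs), jittered local restarts, and wide random restarts, 10 by
default. Recovery on synthetic sessions (5000 trials/condition, lapse 0.05)
returns priors within ±0.1 and the correct noise ordering; with fewer trials
the prior–lapse trade-off widens, which is a property of the model, not the
optimizer.

The simulation default for decision-curve predictions uses the
mixture-corrected priors 0.22/0.78 — the cue says 0.9/0.1 but only 70% of
trials follow it, the rest being neutral — with likelihood widths 2 and
0.017 deg. Simulated curves carry no lapse scaling (lapse parameters exist
for fitting real responses).

## Continuous reliability-weighted observer

For continuous reports the posterior mean under Gaussian prior and likelihood
is the precision-weighted average; its deviation from the presented
displacement is linear with slope w_prior = sigma_L^2/(sigma_L^2 +
sigma_prior^2), so deviation slopes order by noise level. In the
target-absent condition the report reverts to the presaccadic location
(deviation equals the displacement); this is treated as a strategy change and
excluded from fitting rather than modeled as an extreme prior. All continuous
quantities are coded relative to the saccade direction (positive =
with-saccade); a prior bias opposite to the saccade is a negative fitted
`mu_prior_`, reported also as `bias_opposite_saccade_` with the opposite
sign. `ContinuousBayesObserver.fit` jointly fits the prior mean and one
likelihood SD per noise level (prior SD fixed at the experiment's 1 deg) by
bounded least squares on the noiseless posterior mean, multi-started with
log-transformed SDs; report noise belongs to the synthetic generator, not the
fitted model.

## Discriminative (delta-rule) network

The network codes absolute displacement over 75 input units (0–7.5 deg in
0.1-deg bins). Sensory noise spreads input activation as the Gaussian
probability mass per bin, truncated to the range and renormalized to sum to
one; zero noise is a one-hot input. Two output units ("jump", "no jump")
receive weighted sums of the inputs; outputs are rectified at zero and
normalized to sum to one, with a (0.5, 0.5) guard when both are zero. Weights
update by the delta rule dw = beta * a * (d − o), beta = 0.5, toward desired
state (1, 0) on jump trials and (0, 1) otherwise, in the cue-defined context
only: each prior cue has its own weight matrix, which is what lets the
expressed psychometric curve differ across cues at the same training stage.

Three details are interpretations the source description leaves open, fixed
here as package design decisions:

- **Initialization**: all weights start at zero (symmetric; the output guard
  defines the first response).
- **Non-negative weights**: updates are clipped at zero. Without this,
  no-jump weights at large-displacement bins are driven negative, the
  rectified output stage saturates, and the prior separation *grows* with
  input noise instead of collapsing; with excitatory-only weights the
  network reproduces the documented behavior (separation shrinking with
  noise, early overweighting, late parallelism). A raw (unrectified)
  normalization is not viable at all: with zero initialization the two
  output columns always sum to the same value, so the denominator stays
  zero forever.
- **Out-of-range displacements** (about 0.3% of draws at jump width 2.5 deg)
  clamp to the top bin.

The training protocol mirrors the categorical sessions: a 100-trial neutral
baseline block (its size is not specified by the behavioral protocol for
simulations; the session's baseline block size is used), then 600-trial
blocks at priors 0.8 and 0.2; 70% of block trials are low-noise (0.1 deg)
training trials at the cued jump probability, 30% are medium/high-noise
(1/2 deg) testing trials at a neutral 0.5 — updating weights on every trial,
since the behavioral task gives feedback on every trial. Jump/no-jump widths
are 2.5/0.5 deg. Late-training snapshots extend the prior blocks to 5000
trials and read out trials 3000–5000. The trainer is vectorized across
ensemble runs (each run draws its own trial order and displacements), so
thousand-run ensembles used for percentile confidence bands are cheap; the
default ensemble in the acceptance computations is 1000 runs, a deliberate
scale-down from the 10,000 used for publication-quality bands.

## Combined model

The combined report probability is O_C = w_B O_B + w_P O_P with w_B = 0.1,
w_P = 0.9 fixed (a fitting hook is deliberately absent). The division of
labor follows the source of uncertainty: the Bayesian component carries
motor-driven noise — its no-jump width is set to 1.5 deg, triple the
simulated experimental width, to mimic saccadic suppression, while its visual
noise stays at the lowest level (0.1 deg) — and the discriminative component
carries the visual noise through its input encoding. The Bayesian component
uses the block priors 0.8/0.2 (matching the contexts the network trains
under). Intercepts are measured behaviorally: the mean combined output on a
block's own trials with |x| < 0.5 deg at each noise level, per run, averaged
over the ensemble. Under this configuration the high-minus-low prior
intercept difference decreases monotonically over input noise
{0.1, 1, 2} deg — prior use shrinking as uncertainty grows, the opposite of
the ideal-observer prediction — while a pure Bayesian allocation of the same
noise (w_B = 1, noise in sigma_t) increases it.

The motor-noise-only contrast evaluates the categorical observer at jump
width 5 deg, priors {0.2, 0.5, 0.8}, sigma_t = 0.5 deg (the lowest blob
width, since the probe is unblurred in those sessions), with no-jump width
1 deg in the with-saccade condition versus 0.25 deg without. The with-saccade
intercept difference exceeds the no-saccade difference. The difference is
not globally monotone in the no-jump width: grid evaluation shows a shallow
dip between 0.25 and 0.5 deg before the rise (and saturation at 1 once the
high-prior criterion collapses to "always jump"); only the published
two-condition contrast is asserted.

## Psychometric analysis layer

Binary responses are summarized by the four-parameter logistic in |x|,
y = max + (min − max)/(1 + (x/thresh)^slope), fit by minimizing mean squared
error against the raw binary responses (the stated convention; a Bernoulli
likelihood loss is available as an option), with slope constrained positive
so y(0) = min. The intercept — the bias measure throughout — is the fitted
`min` for continuous-displacement designs and the raw proportion of "jumped"
reports at displacement = 0 for discretized designs. SDT measures use
d' = Z(hit) − Z(FA) and Criterion C = −0.5 [Z(hit) + Z(FA)]; rates of 0 or 1
are clamped to 1/(2N) and 1 − 1/(2N) before the inverse normal (the simplest
standard correction; log-linear alternatives were rejected for simplicity).
Bootstrap confidence intervals are percentile intervals over trial-level
resamples; 95% intervals on Bernoulli means calibrate to 95% ± 3% coverage
in a 1000-replicate check. Summary curves bin displacements at 0.5 deg.

## Problem sizes and tolerances

The Monte-Carlo cross-check uses 10^6 samples and a 3-SE band. MLE recovery
uses 5000 trials/condition; continuous recovery 400 trials x 20 seeds with
0.3 deg report noise. Combined-model ensembles default to 1000 runs;
late-training snapshots to 100 runs x 5000 trials/block. Optimizer bounds:
SDs in [10^-3, 20] deg (log scale), lapse/lower bound in [0, 0.5], priors in
[10^-3, 1 − 10^-3] (logit scale).

## Known limitations

- The categorical closed form covers only zero-mean likelihoods; non-zero
  means fall back to Monte Carlo (the region machinery exists but no closed
  survivor form is claimed).
- The 14-parameter fit's prior and lapse parameters trade off; recovery
  tolerances hold at the stated sample sizes, not for small sessions.
- The perceptron's non-negativity constraint is an interpretation; other
  resolutions of the unstated details (e.g. small positive initialization)
  were not explored beyond what the tests require.
- Group-level inference on real data (ANOVA-style machinery) is out of
  scope; ensemble summaries use the bootstrap only.
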