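# Methods

## Task environment

Each trial is an episode through five temporal stages: initial → cue →
action → outcome → end. Four cue states encode the condition (speaker
location × sound frequency), eight action states the condition × chosen
side, eight outcome states the condition × obtained outcome, giving 22
states with one initial and one terminal end state. Entering the reward
outcome state yields r = +1, the no-reward state r = −1; all other
transitions are unrewarded. Only the cue state admits a real left/right
action; every other state takes a dummy action and keeps both of its
action-value slots equal after updates. The probabilistic variant flips
the outcome of the chosen action with probability 0.1, independently per
trial.

Two trial-sequence modes are provided and used for different purposes:
agent simulation draws the condition uniformly i.i.d. from the
environment RNG stream, matching the generative model of the episodes;
behavior-like logs use pseudorandomized 32-trial blocks in which each
condition appears exactly 8 times (drawn without replacement). When a
requested schedule length is not a multiple of the block size, whole
blocks are generated and the tail truncated, so only full blocks
guarantee exact balance. Miss trials are not modeled: every scheduled
trial yields a response.

## TD agents

Tabular state-action values are updated online, `Q(s,a) ← Q(s,a) + α δ`,
with the TD error computed on entering each state:

* SARSA (on-policy): `δ = r' + γ Q(s', a') − Q(s, a)`, bootstrapping from
  the action actually selected in the next state;
* Q-learning (off-policy): bootstrap `max_a Q(s', a)`;
* state-value learner: `V(s) ← V(s) + α_v δ`, `δ = r' + γ V(s') − V(s)`.

The state-value learner runs passively alongside the behaving
state-action agent on the same state sequence, so both RPE families are
available from a single simulation. RPEs are defined as the TD error on
entering a state; the cue-epoch RPE reported by default is the error on
entering the cue state (the action-entry error is logged as well, since
the mapping of "cue response" onto state entries is a modeling choice).
Because SARSA needs the next action, the action is selected immediately
on entering the cue state, before the initial-state update uses it.

The terminal end state is pinned at value 0; attempted updates to it are
counted and ignored. With γ = 1 the four TD errors of one episode
telescope exactly to (total reward − initial-state prediction), which the
test suite asserts to 1e−12 — a useful integrity check on the update
order.

Action selection is a softmax over the cue-state values plus a side
bias: `P(left) = exp[β(Q_L + b_L)] / (exp[β(Q_L + b_L)] + exp[β(Q_R +
b_R)])`, computed with max-subtraction as the overflow guard. The bias
is applied to one side only (configurable left/right, or drawn at random
per agent from a dedicated RNG stream) and decays across sessions within
a rule as `b(k) = β_bias0 · exp(−λ_bias · k)`; the exponential form is
the default because the decay parameter is a rate constant, and a
geometric alternative (`β_bias0 (1 − λ_bias)^k`) is available behind a
switch. The bias is active during initial learning (location rule) and
after the within-dimension reversal (frequency-reversed rule), where
perseveration necessarily drops performance below chance from the first
session — at session granularity, enabling it from the first
post-switch session is the non-circular reading of a "below chance"
trigger. It is inactive during the frequency rule.

Default parameters (used for all simulations unless stated): α = 0.003
for state-action values, α_v = 0.015 for state values, γ = 1, β = 6,
β_bias0 = 0.4, λ_bias = 0.4, 300 trials per session.

### Protocol and resets

Rules advance (location → frequency → frequency-reversed) after two
consecutive sessions at criterion — ≥80% correct overall and ≥60% in
each condition, evaluated over the 300-trial session, the same
thresholds as the behavioral criterion. At each switch the values are
reset per the configured mode: `none` (identity), `complete` (all
values zeroed), or `partial` (everything zeroed except the cue-state
action values, i.e. outcome expectations are discarded while
choice-guiding associations survive). An agent that exhausts
`max_sessions` without criterion is flagged non-convergent and its
protocol stops with a partial log.

Each agent owns two RNG streams (policy sampling and environment draws)
spawned from a per-agent seed, itself spawned from the master seed, so
environment randomness is reproducible independently of the policy and
identical seeds give bit-identical logs.

## Behavioral metrics

Accuracy is the fraction of correct trials over any exact label
selection; empty selections are NaN, never 0. The response-bias index is
computed from fcl and fcr, the accuracies among left-cued and right-cued
trials. The primary form is `bias = fcl / (fcl + fcr)` — 0.5 when
unbiased — so that the absolute bias `|bias − 0.5|` spans 0 (unbiased)
to 0.5 (one-sided responder) as the staging analyses require. A variant
form `(fcl − fcr) / fcl` is retained behind a flag for reference; it
does not respect that range and is not used by any other code.

Stages: novice < 60% overall; expert requires ≥80% overall *and* ≥60%
in every condition (identical to the acquisition criterion, so
criterion ⇒ expert holds at the boundary); everything else, including
sessions above 80% overall that fail a condition clause, is
intermediate.

Learning rate is the least-squares slope of the per-session accuracy
curve from the first session to the first criterion session. For the
location rule two slopes are fitted — first session to last novice
session, and first intermediate session to first criterion session —
because the early strong-bias phase flattens the initial segment.
Segments shorter than two sessions yield NaN.

Session truncation drops trials from the first miss after 90% of the
session, then removes a trailing stretch of the last 15% whose running
performance falls below the session mean minus 1.5 standard deviations.
The running performance is the fraction correct in 20-trial windows, and
the mean/s.d. are taken over all windows of the session; the 20-trial
window is this package's operationalization (any fixed window of similar
scale behaves the same on the test fixtures). The cut never removes more
than a further 15%.

## Choice model

The session-based model is an unregularized logistic regression of the
binary choice (0 = left, 1 = right): ŷ = 1/(1 + e^(−z)) with
z = Σ_p β_p x_p + β_0. All predictors are coded in [−1, +1] and not
standardized, so weights are interpretable deviations from zero. The
ΔReward-rate predictor is the difference of per-spout exponentially
weighted reward averages (smoothing factor 2/(10+1), i.e. a ten-trial
memory) over an indicator that is 1 when that spout was chosen and
rewarded on a trial and 0 otherwise — trials where the spout was not
chosen count as zeros rather than being excluded, which is flagged here
as a modeling choice. The predictor value for trial t uses rewards up to
and including trial t − 1; history predictors are 0 wherever the lag
reaches before the session start.

Fitting minimizes the mean negative log-likelihood
`J = −(1/m) Σ [y log ŷ + (1−y) log(1−ŷ)]` (evaluated in the
numerically stable log-sum-exp form) by batch gradient descent from
zero-initialized weights, with a fixed step that backtracks (halves) on
any loss increase and re-grows by 1.1× after accepted steps. Iteration
stops when J < 1e−4, when an accepted step improves J by less than
1e−12, or at 50,000 iterations. Single-class sessions are flagged
degenerate and produce an intercept-driven fit. Under perfect
separation the loss threshold terminates the fit with large but finite
weights. The test suite checks the fit against an independent
maximum-likelihood solver (statsmodels Logit) on random fixtures to
|Δβ| < 1e−3; the solver is never used as the implementation.

Binary predictions round ŷ at 0.5, with ŷ = 0.5 assigned to class 1
(an arbitrary, seed-independent convention). Cross-validation uses ten
folds stratified by response class (plain K-fold when a class is rarer
than the fold count), each trial tested exactly once, accuracy pooled
over test folds. Model comparison reports the per-session accuracy
difference between the base model and removal/addition/replacement
variants.

## Photometry

The 1-kHz trace is smoothed with a 50-sample (50-ms) running average —
centered, with shrinking windows at the edges, both unstated details
chosen here — and decimated by keeping every 20th sample (50 Hz).
Per-trial ΔF/F uses the mean of the 500 ms before trial start as
baseline B: (F − B)/B, with trials flagged invalid when B ≤ 0.
Alternative baselining (polynomial/low-pass detrending of the whole
session) is a documented option. Session normalization is a robust z
score, (x − median)/MAD, with the statistics taken from the
concatenated analyzed trial segments by default (baseline-only and
whole-session references are options); MAD = 0 flags the session
degenerate and only the median is subtracted.

Epoch amplitudes are extracted per trial in region-specific windows:
cue, 1,000 ms from cue onset (all regions); spouts, 340 ms from cue
offset; outcome, starting 160 ms (VS, DMS) or 140 ms (DLS) after the
instrumental lick and lasting 840 ms (VS), 740 ms (DMS) or 380 ms
(DLS). Within a window the most prominent local peak competes with the
most prominent local valley (prominences computed on the sign-inverted
segment); the winner's signed sample value and latency are reported,
ties going to the peak, with no minimum prominence threshold. Windows
with no interior local extremum fall back to the largest-magnitude
sample. Plain window means are available as the cross-check variant.
Because ΔF/F and the robust z are both scale-free, the whole chain is
exactly invariant to positive rescaling of the raw trace, which the
tests assert.

## Synthetic data

The photometry generator places impulses at cue onset, spout
presentation and outcome (150 ms after the lick, inside every region's
outcome window once sensor rise time is added), scaled by the logged TD
errors (the spout impulse adds a fixed Pavlovian component so
early-learning spout signals have a synthetic analogue), convolves them
with a unit-peak double-exponential kernel, and adds a constant
baseline (1.0), slow sinusoidal drift (amplitude 0.05, period 120 s)
and white noise (s.d. 0.02 by default, in raw fluorescence units where
the kernel gain is 1). Trial timing follows the task: cue onset 1,000 ms
after trial start, 1,000-ms cue, lick 300 ms after cue offset, 4,000-ms
intertrial interval. Kernel defaults (rise/decay 40/400 ms VS, 40/350 ms
DMS, 25/150 ms DLS) are chosen so the transient has decayed
substantially by the end of each region's outcome window — motivated
by, not fitted to, the window table. The ground-truth table records the
noise-free ΔF/F peak and latency inside each analysis window, computed
directly from the clean signal rather than through the measurement
pipeline, so recovery tests score the pipeline against an independent
forward computation.

The behavior generator draws choices from
`P(right) = lapse + (1 − 2·lapse)·σ(z)` with
z = cue weight × correct-side sign + bias + history weight × previous
choice, so accuracy saturates at 1 − lapse. Defaults (2,000 trials, cue
weight 1.5, lapse 0.02) put weight recovery comfortably inside the
25%-magnitude check while keeping the data non-separable.

What the generators deliberately do not emulate: photobleaching,
hemodynamic or movement artifacts, sensor nonlinearity, lick-by-lick
timing variability, and miss trials (beyond the planted misses used to
test truncation). Passing recovery tests therefore demonstrates the
correctness of the analysis chain on data that satisfy its assumptions,
not robustness to every artifact of real recordings.

## Problem sizes and runtime choices

Simulations in the tests and the acceptance script use the standard 300
trials/session; property checks over agent populations use 5–20 agents,
convergence checks 5,000–40,000 trials, and the probabilistic-rate check
10,000 trials — sizes at which the binomial confidence intervals and
stationary-value fluctuations quoted in the tests are comfortably
discriminating. Synthetic traces for recovery tests use 40–60 trials per
session at the full 1-kHz rate.

## Known limitations

* Agents are not fitted to data; parameters are fixed at the standard
  values and the claims are qualitative signatures, not quantitative fits.
* The criterion-stopped protocol ends long before value convergence
  (α = 0.003), so "expert" outcome RPEs in protocol logs are small but
  clearly positive; near-zero outcome RPEs require extended training,
  which the convergence tests exercise separately.
* The trial-based fluctuating-weight choice model and eligibility-trace
  or actor-critic agent variants are out of scope.
* `truncate_session` is idempotent on realistic sessions (asserted on
  the fixtures) but its two-pass statistics are recomputed per call, so
  pathological performance curves could in principle truncate twice.
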