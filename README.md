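# striatd

Temporal-difference (TD) learning models of striatal dopamine in an
auditory rule-switch task, with the full analysis chain needed to study
them: task simulation, behavioral metrics, a session-based logistic
choice model, and fiber-photometry amplitude extraction — all exercisable
on synthetic data with known ground truth.

## The problem

Head-fixed mice learn to lick a left or right spout after an auditory cue
that varies in *location* (left/right speaker) and *frequency* (low/high
band), giving four cue conditions. Which cue dimension instructs the
rewarded side is an implicit rule that changes across training:
**location** (lick the side the sound came from), then **frequency**
(low → left, high → right), then **frequency-reversed** (high → left,
low → right). Striatal dopamine transients recorded during this task
behave like reward prediction errors (RPEs), but their coupling between
cue and outcome depends on the animal's current strategy — in particular,
rule switches appear to make animals discard learned outcome expectations
while keeping cue–action associations.

`striatd` implements the computational core of that account:

* **Task environment** (`striatd.task_env`) — the task unrolled as a
  22-state episode graph (initial → cue → action → outcome → end; 4 cue,
  8 action and 8 outcome states), deterministic or with a 10% outcome
  flip, plus balanced 32-trial pseudorandom schedules.
* **TD agents** (`striatd.rl_agents`) — tabular SARSA and off-policy
  Q-learning with `Q(s,a) ← Q(s,a) + αδ`, where for SARSA
  `δ = r' + γ Q(s',a') − Q(s,a)` and for Q-learning the bootstrap is
  `max_a Q(s',a)`; a parallel state-value learner `V(s) ← V(s) + α_v δ`;
  softmax action selection with an exponentially decaying side bias;
  criterion-driven rule switching with none/partial/complete value
  resets. RPEs are the TD errors logged on entering each state.
  Defaults: α = 0.003, α_v = 0.015, γ = 1, β = 6, β_bias0 = 0.4,
  λ_bias = 0.4, 300 trials/session.
* **Behavior metrics** (`striatd.behavior_metrics`) — session accuracy,
  response-bias index, novice/intermediate/expert staging (<60%, 60–80%,
  ≥80% overall and ≥60% per condition), acquisition criterion,
  learning-rate slopes, post-hoc session truncation, stay/switch splits.
* **Choice model** (`striatd.choice_model`) — logistic regression of
  choice with ŷ = 1/(1+e^(−z)), z = Σ_p β_p x_p + β_0, fit by gradient
  descent on the mean negative log-likelihood with no regularization;
  tenfold cross-validated accuracy and model comparison. Predictors
  include current cue location/frequency and a ten-trial exponentially
  weighted per-spout reward-rate difference, plus alternative history
  codings (win-stay/lose-switch, choice lags, …).
* **Photometry** (`striatd.photometry`) — 50-ms running average and
  downsampling to 50 Hz, per-trial ΔF/F against a 500-ms pre-trial
  baseline, robust z-scoring (median/MAD), and signed prominence-based
  peak extraction in region-specific epoch windows (VS/DMS/DLS).
* **Synthetic data** (`striatd.synthetic_data`) — RPE-driven synthetic
  fluorescence with known injected transients, and parametric behavior
  with known generative weights, for closed-loop validation.

## Worked example

Train five SARSA agents with a partial value reset (cue-state Q values
kept at the rule switch) through the location and frequency rules, then
look at the first session after the switch:

```python
from striatd import AgentParams, run_protocol, extract_rpes

params = AgentParams(algorithm="sarsa", reset_mode="partial")
log = run_protocol(params, rule_sequence=("location", "frequency"),
                   n_agents=5, max_sessions=40, seed=1)

print(log.sessions.groupby(["rule", "session_in_rule"])["fraction_correct"]
      .mean().round(3).to_string())
for epoch in ("cue", "outcome"):
    for cls in ("stay", "switch"):
        d = extract_rpes(log, epoch=epoch, correct=True, stay_switch=cls,
                         rule="frequency", session_in_rule=0)
        print(f"{epoch} RPE, correct {cls} trials: {d['delta'].mean():+.3f}")
```

Output:

```
rule       session_in_rule
frequency  0                  0.493
           1                  0.524
           ...
           7                  0.910
location   0                  0.515
           ...
           6                  0.881

cue RPE, correct stay trials:     +0.187
cue RPE, correct switch trials:   -0.162
outcome RPE, correct stay trials:  +0.907
outcome RPE, correct switch trials: +0.989
```

Agents start near chance (the decaying side bias mimics the animals'
early spout preference), reach the ≥80%/≥60% criterion in about seven
sessions, and drop back to chance when the rule switches. In the first
post-switch session, outcome RPEs on correct trials re-emerge near +1
*equally* for stay and switch conditions (the partial reset wiped the
outcome expectations), while cue RPEs *separate*: positive for stay
conditions (the retained cue values still favor the chosen action) and
negative for switch conditions (a correct choice under the new rule was
a devalued action under the old one). This uncoupling is the on-policy
(SARSA) signature; Q-learning agents do not show it.

A thin CLI wraps the same functionality: `striatd simulate`,
`striatd fit-choice`, `striatd process-photometry`,
`striatd make-fixtures` (see `--help`).

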