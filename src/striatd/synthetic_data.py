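"""Synthetic ground-truth generators for every pipeline stage.

Two generators close the loop between the models and the analysis code:

* :func:`simulate_photometry` renders an agent's logged TD errors as a
  1-kHz fluorescence trace — impulses at cue onset, spout presentation
  and outcome, convolved with a region-specific double-exponential sensor
  kernel, on top of a constant baseline, slow sinusoidal drift and white
  noise — together with a table of the injected transients so recovery
  can be scored exactly.
* :func:`simulate_behavior_parametric` draws choices from a lapse-mixed
  logistic policy with known cue, bias and choice-history weights, so the
  session-based choice model can be validated by parameter recovery.

Trial timing follows the task: the trial starts 1,000 ms before the
1,000-ms auditory cue; the spouts arrive at cue offset; the response lick
follows shortly after; the intertrial interval is 4,000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rl_agents
from .photometry import RawTrace, epoch_windows
from .task_env import (
    CONDITIONS,
    RULES,
    TrialSchedule,
    correct_action,
    generate_schedule,
)

#: trial event layout, seconds from trial start
CUE_ONSET_S = 1.0
CUE_DURATION_S = 1.0
LICK_LATENCY_S = 0.3       # first lick after spout arrival
OUTCOME_DELAY_S = 0.15     # reward delivery after the lick
ITI_S = 4.0
TRIAL_PERIOD_S = CUE_ONSET_S + CUE_DURATION_S + LICK_LATENCY_S + OUTCOME_DELAY_S + ITI_S
LEAD_IN_S = 1.0            # head room so the first trial has a baseline window


@dataclass(frozen=True)
class SensorKernel:
    """Double-exponential impulse response of the fluorescent sensor.

    ``k(t) = gain * (exp(-t / decay) - exp(-t / rise)) / peak`` so a unit
    impulse produces a transient of peak height ``gain``.  Region defaults
    decay fastest in the DLS and slowest in the VS, consistent with the
    shorter outcome analysis window used there.
    """

    region: str = "VS"
    rise_s: float = 0.040
    decay_s: float = 0.400
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_s <= 0 or self.decay_s <= self.rise_s:
            raise ValueError("time constants must satisfy 0 < rise < decay")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def peak_time_s(self) -> float:
        r, d = self.rise_s, self.decay_s
        return r * d / (d - r) * np.log(d / r)

    def sample(self, fs: float, duration_s: float = 3.0) -> np.ndarray:
        t = np.arange(0.0, duration_s, 1.0 / fs)
        raw = np.exp(-t / self.decay_s) - np.exp(-t / self.rise_s)
        return self.gain * raw / raw.max()


DEFAULT_KERNELS = {
    "VS": SensorKernel("VS", rise_s=0.040, decay_s=0.400),
    "DMS": SensorKernel("DMS", rise_s=0.040, decay_s=0.350),
    "DLS": SensorKernel("DLS", rise_s=0.025, decay_s=0.150),
}


def simulate_photometry(episode_logs: pd.DataFrame, region: str = "VS",
                        kernel: SensorKernel | None = None, noise_sd: float = 0.02,
                        drift_amplitude: float = 0.05, drift_period_s: float = 120.0,
                        baseline_level: float = 1.0, pavlovian_coef: float = 0.2,
                        seed: int = 0, fs: float = 1000.0,
                        ) -> tuple[RawTrace, pd.DataFrame]:
    """Render logged per-trial TD errors as a raw fluorescence session.

    ``episode_logs`` needs columns ``delta_cue``, ``delta_action`` and
    ``delta_outcome`` (one row per trial).  Impulse amplitudes are
    ``gain * delta`` at cue onset and outcome, and ``gain * (pavlovian_coef
    + delta_action)`` at spout presentation (the spouts initially act as a
    Pavlovian reward cue).  The returned ground-truth table holds, per
    trial and epoch, the injected impulse, and the noise-free dF/F peak
    amplitude and latency inside that region's analysis window, computed
    directly from the clean signal.
    """
    if kernel is None:
        kernel = DEFAULT_KERNELS[region]
    n_trials = len(episode_logs)
    rng = np.random.default_rng(seed)
    t_start = LEAD_IN_S + TRIAL_PERIOD_S * np.arange(n_trials)
    t_cue = t_start + CUE_ONSET_S
    t_cue_off = t_cue + CUE_DURATION_S
    t_lick = t_cue_off + LICK_LATENCY_S
    t_outcome = t_lick + OUTCOME_DELAY_S
    duration = t_start[-1] + TRIAL_PERIOD_S if n_trials else LEAD_IN_S
    n = int(round(duration * fs))

    amp_cue = kernel.gain * episode_logs["delta_cue"].to_numpy(dtype=float)
    amp_spout = kernel.gain * (pavlovian_coef
                               + episode_logs["delta_action"].to_numpy(dtype=float))
    amp_out = kernel.gain * episode_logs["delta_outcome"].to_numpy(dtype=float)

    impulses = np.zeros(n)
    for times, amps in ((t_cue, amp_cue), (t_cue_off, amp_spout), (t_outcome, amp_out)):
        idx = np.round(times * fs).astype(int)
        if np.any(idx >= n):
            raise ValueError("trial timing conflict: events fall outside the trace")
        np.add.at(impulses, idx, amps)
    # impulse amplitudes already carry the gain; convolve with the
    # unit-peak kernel so a lone impulse of amplitude a peaks at a
    transients = np.convolve(impulses, kernel.sample(fs) / kernel.gain)[:n]

    t = np.arange(n) / fs
    drift = drift_amplitude * np.sin(2.0 * np.pi * t / drift_period_s)
    clean = baseline_level + drift + transients
    values = clean + rng.normal(0.0, noise_sd, size=n)

    events = {"trial_start": t_start, "cue_onset": t_cue, "cue_offset": t_cue_off,
              "lick": t_lick}
    trace = RawTrace(values=values, events=events, fs=fs)

    # noise-free ground truth in dF/F units, per analysis window
    win = epoch_windows(region)
    nb = int(round(0.5 * fs))
    rows = []
    for i in range(n_trials):
        s = int(round(t_start[i] * fs))
        b = float(np.mean(clean[max(0, s - nb): s]))
        clean_dff = (clean - b) / b
        row = {"trial": i, "t_trial_start": t_start[i], "t_cue_onset": t_cue[i],
               "t_cue_offset": t_cue_off[i], "t_lick": t_lick[i],
               "impulse_cue": amp_cue[i], "impulse_spouts": amp_spout[i],
               "impulse_outcome": amp_out[i], "baseline": b}
        spans = {"cue": (t_cue[i], win.cue_s),
                 "spouts": (t_cue_off[i], win.spouts_s),
                 "outcome": (t_lick[i] + win.outcome_latency_s, win.outcome_len_s)}
        for name, (w0, length) in spans.items():
            i0, i1 = int(round(w0 * fs)), int(round((w0 + length) * fs))
            window = clean_dff[i0:i1]
            sign = np.sign(row[f"impulse_{name}"]) or 1.0
            j = int(np.argmax(sign * window))
            row[f"true_{name}_amp"] = float(window[j])
            row[f"true_{name}_latency"] = j / fs
        rows.append(row)
    return trace, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parametric behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGenParams:
    """Generative policy weights for synthetic sessions.

    The policy is P(right) = lapse + (1 - 2 lapse) * sigmoid(z) with
    z = cue_weight * s_cue + bias + history_weight * previous choice,
    where s_cue is the sign (+1 right) of the correct side under the
    active rule.  Accuracy therefore saturates at 1 - lapse for a
    cue-dominated policy.
    """

    n_trials: int = 2000
    cue_weight: float = 1.5
    bias_weight: float = 0.0
    bias_side: str = "right"
    history_weight: float = 0.0
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.bias_side not in ("left", "right"):
            raise ValueError("bias_side must be left or right")


def simulate_behavior_parametric(params: BehaviorGenParams,
                                 schedule: TrialSchedule | None = None,
                                 rule: str = "location") -> pd.DataFrame:
    """Draw a synthetic session from the parametric policy; outcomes follow ``rule``."""
    if schedule is None:
        schedule = generate_schedule(params.n_trials, seed=params.seed + 1)
    rng = np.random.default_rng(params.seed)
    bias = params.bias_weight * (1.0 if params.bias_side == "right" else -1.0)
    prev_choice_sign = 0.0
    rows = []
    for i, cond in enumerate(schedule.conditions[: params.n_trials]):
        target = correct_action(rule, cond)
        s_cue = 1.0 if target == "right" else -1.0
        z = params.cue_weight * s_cue + bias + params.history_weight * prev_choice_sign
        p_right = params.lapse + (1.0 - 2.0 * params.lapse) / (1.0 + np.exp(-z))
        choice = "right" if rng.random() < p_right else "left"
        correct = choice == target
        rows.append({
            "trial": i, "block": i // schedule.block_size, "rule": rule,
            "cue_location": cond.cue_location, "cue_frequency": cond.cue_frequency,
            "choice": choice, "correct": correct, "r": 1.0 if correct else -1.0,
            "miss": False,
        })
        prev_choice_sign = 1.0 if choice == "right" else -1.0
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureDataset:
    """A full multi-rule run with matching synthetic traces for all regions."""

    protocol: rl_agents.ProtocolLog
    traces: dict[str, RawTrace]
    ground_truth: dict[str, pd.DataFrame]
    trace_trials: pd.DataFrame


def make_fixture_dataset(seed: int = 0, n_trace_trials: int = 40,
                         max_sessions: int = 40) -> FixtureDataset:
    """SARSA partial-reset protocol plus per-region traces for its first session.

    One agent is trained through all three rules; the first
    ``n_trace_trials`` trials of the first location session (where RPEs
    are large and untrained) are rendered as raw photometry for each
    striatal subregion.  Deterministic given the seed.
    """
    params = rl_agents.AgentParams(algorithm="sarsa", reset_mode="partial")
    protocol = rl_agents.run_protocol(params, rule_sequence=RULES, n_agents=1,
                                      max_sessions=max_sessions, seed=seed)
    first = protocol.trials
    first = first[(first["session"] == 0)].head(n_trace_trials).reset_index(drop=True)
    traces, truths = {}, {}
    for i, region in enumerate(("VS", "DMS", "DLS")):
        trace, truth = simulate_photometry(first, region=region, seed=seed * 7 + i)
        traces[region] = trace
        truths[region] = truth
    return FixtureDataset(protocol=protocol, traces=traces, ground_truth=truths,
                          trace_trials=first)
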