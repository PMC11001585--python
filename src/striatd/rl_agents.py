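"""Temporal-difference agents whose TD errors model striatal dopamine RPEs.

Agents learn the 22-state rule-switch task (:mod:`striatd.task_env`) with
tabular state-action values updated by ``Q(s,a) <- Q(s,a) + alpha * delta``.
Two bootstrapping variants are provided: on-policy SARSA, which evaluates
the action it actually takes next, and off-policy Q-learning, which
evaluates the best available next action.  A pure state-value learner
(``V(s) <- V(s) + alpha_v * delta``) is tracked alongside the behaving
agent; its TD errors model outcome predictions that are blind to the
agent's own actions.

Reward prediction errors are the TD errors logged on *entering* each
temporal state (cue, action, outcome, end).  Action selection is a softmax
over cue-state values plus a session-wise exponentially decaying side bias
that models the animals' early response bias.  Rules switch after two
consecutive criterion sessions, optionally resetting learned values
(complete reset, or a partial reset that keeps only the choice-guiding
cue-state values).

Default parameters: alpha = 0.003 (state-action), alpha_v = 0.015 (state
value), gamma = 1, beta = 6, beta_bias0 = 0.4, lambda_bias = 0.4, 300
trials per session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior_metrics
from .task_env import (
    ACTIONS,
    CONDITIONS,
    RULES,
    STATE_END,
    STATE_INITIAL,
    Environment,
    TrialCondition,
    action_state,
    all_states,
    classify_stay_switch,
    correct_action,
    cue_state,
    outcome_state,
)

ALGORITHMS = ("sarsa", "qlearning", "state_value")
RESET_MODES = ("none", "partial", "complete")
BIAS_SIDES = ("left", "right", "random")

#: rules during which the softmax side bias is active: initial learning
#: (location) and the perseveration-driven performance collapse after the
#: within-dimension reversal (frequency_reversed)
BIAS_ACTIVE_RULES = frozenset({"location", "frequency_reversed"})

DEFAULT_ALPHA = 0.003
DEFAULT_ALPHA_STATE = 0.015


@dataclass(frozen=True)
class AgentParams:
    """Agent configuration; defaults are the standard simulation settings."""

    algorithm: str = "sarsa"
    alpha: float | None = None  # default depends on algorithm
    gamma: float = 1.0
    beta: float = 6.0
    beta_bias0: float = 0.4
    lambda_bias: float = 0.4
    reset_mode: str = "partial"
    bias_side: str = "random"
    bias_decay: str = "exponential"  # or "geometric"
    alpha_v: float = DEFAULT_ALPHA_STATE

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.reset_mode not in RESET_MODES:
            raise ValueError(f"unknown reset mode {self.reset_mode!r}")
        if self.bias_side not in BIAS_SIDES:
            raise ValueError(f"unknown bias side {self.bias_side!r}")
        if self.bias_decay not in ("exponential", "geometric"):
            raise ValueError(f"unknown bias decay form {self.bias_decay!r}")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.beta < 0 or self.beta_bias0 < 0 or self.lambda_bias < 0:
            raise ValueError("beta, beta_bias0 and lambda_bias must be non-negative")

    @property
    def effective_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        return DEFAULT_ALPHA_STATE if self.algorithm == "state_value" else DEFAULT_ALPHA


# ---------------------------------------------------------------------------
# Value table
# ---------------------------------------------------------------------------

class ValueTable:
    """Tabular Q(s, a) and V(s), all zero-initialised.

    Non-cue states admit only a dummy action, so both of their action slots
    are kept equal after every update.  The terminal end state is pinned to
    zero; attempted updates to it are counted and ignored.
    """

    __slots__ = ("q", "v", "ignored_terminal_updates")

    def __init__(self) -> None:
        self.q: dict[str, list[float]] = {s: [0.0, 0.0] for s in all_states()}
        self.v: dict[str, float] = {s: 0.0 for s in all_states()}
        self.ignored_terminal_updates = 0

    def value(self, state: str, action: str) -> float:
        return self.q[state][0 if action == "left" else 1]

    def max_value(self, state: str) -> float:
        qs = self.q[state]
        return qs[0] if qs[0] >= qs[1] else qs[1]

    def copy(self) -> "ValueTable":
        new = ValueTable()
        new.q = {s: list(v) for s, v in self.q.items()}
        new.v = dict(self.v)
        return new

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "q_left": qs[0], "q_right": qs[1], "v": self.v[s]}
            for s, qs in self.q.items()
        ]
        return pd.DataFrame(rows)


def update_values(table: ValueTable, state: str, action: str | None, delta: float,
                  alpha: float) -> ValueTable:
    """Apply ``Q(s,a) += alpha * delta`` in place (and equalise dummy-action states)."""
    if state == STATE_END:
        table.ignored_terminal_updates += 1
        return table
    qs = table.q[state]
    if state.startswith("cue:"):
        if action not in ACTIONS:
            raise ValueError("cue-state updates require a left/right action")
        qs[0 if action == "left" else 1] += alpha * delta
    else:
        qs[0] += alpha * delta
        qs[1] = qs[0]
    return table


def apply_reset(table: ValueTable, mode: str) -> ValueTable:
    """Value reset at a rule switch.

    "partial" keeps only the cue-state action values Q_L/Q_R (the
    choice-guiding associations) and zeroes everything else, including all
    outcome predictions; "complete" restores a fresh table; "none" is the
    identity.
    """
    if mode == "none":
        return table
    if mode == "complete":
        for qs in table.q.values():
            qs[0] = qs[1] = 0.0
        table.v = {s: 0.0 for s in table.v}
        return table
    if mode == "partial":
        for s, qs in table.q.items():
            if not s.startswith("cue:"):
                qs[0] = qs[1] = 0.0
        for s in table.v:
            if not s.startswith("cue:"):
                table.v[s] = 0.0
        return table
    raise ValueError(f"unknown reset mode {mode!r}")


# ---------------------------------------------------------------------------
# Elementary computations
# ---------------------------------------------------------------------------

def softmax_choice(q_left: float, q_right: float, beta: float, bias_left: float = 0.0,
                   bias_right: float = 0.0, rng: np.random.Generator | None = None,
                   ) -> tuple[str, float]:
    """Softmax over biased action values; returns (sampled action, P(left)).

    P(left) = exp[beta (Q_L + b_L)] / (exp[beta (Q_L + b_L)] + exp[beta (Q_R + b_R)]).
    The shared maximum is subtracted before exponentiation (overflow guard).
    """
    p_left = _p_left(q_left, q_right, beta, bias_left, bias_right)
    if rng is None:
        rng = np.random.default_rng()
    action = "left" if rng.random() < p_left else "right"
    return action, p_left


def _p_left(q_left: float, q_right: float, beta: float, bias_left: float,
            bias_right: float) -> float:
    zl = beta * (q_left + bias_left)
    zr = beta * (q_right + bias_right)
    m = zl if zl >= zr else zr
    el = math.exp(zl - m)
    er = math.exp(zr - m)
    return el / (el + er)


def bias_magnitude(session_index: int, beta_bias0: float, lambda_bias: float,
                   active: bool = True, form: str = "exponential") -> float:
    """Session-wise decaying softmax bias applied to the preferred side only.

    Exponential form (default): ``beta_bias0 * exp(-lambda_bias * k)`` with
    k the number of sessions elapsed within the current rule.  The
    geometric alternative multiplies by ``(1 - lambda_bias)`` per session.
    """
    if session_index < 0:
        raise ValueError("session index must be non-negative")
    if not active:
        return 0.0
    if form == "exponential":
        return beta_bias0 * math.exp(-lambda_bias * session_index)
    if form == "geometric":
        return beta_bias0 * (1.0 - lambda_bias) ** session_index
    raise ValueError(f"unknown bias decay form {form!r}")


def td_error_sarsa(r_next: float, q_next: float, q_current: float, gamma: float) -> float:
    """On-policy TD error: bootstraps from the value of the action taken next."""
    return r_next + gamma * q_next - q_current


def td_error_qlearning(r_next: float, q_next_max: float, q_current: float,
                       gamma: float) -> float:
    """Off-policy TD error: bootstraps from the best next-state action value."""
    return r_next + gamma * q_next_max - q_current


def td_error_state(r_next: float, v_next: float, v_current: float, gamma: float) -> float:
    """State-value TD error, blind to which action produced the transition."""
    return r_next + gamma * v_next - v_current


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------

@dataclass
class EpisodeLog:
    """One trial: choice, outcome and TD error per state entry."""

    condition: TrialCondition
    choice: str
    correct: bool
    reward: float
    deltas: dict[str, float]          # state-action TD errors, keyed by epoch
    state_deltas: dict[str, float]    # state-value TD errors, keyed by epoch
    p_left: float


# state labels are interned once; episode code runs on indices
_CUE = [cue_state(c) for c in CONDITIONS]
_ACT = [[action_state(c, a) for a in ACTIONS] for c in CONDITIONS]
_OUT = [[outcome_state(c, False), outcome_state(c, True)] for c in CONDITIONS]
_CORRECT_IDX = {
    rule: [0 if correct_action(rule, c) == "left" else 1 for c in CONDITIONS]
    for rule in RULES
}


def _run_episode(table: ValueTable, rule: str, cond_idx: int, params: AgentParams,
                 bias_left: float, bias_right: float, u_action: float,
                 flip: bool, forced_action_idx: int | None = None,
                 ) -> tuple[int, bool, float, float, float, float, float,
                            float, float, float, float, float]:
    """Run one episode in place; returns the flat trial record.

    ``u_action`` is a uniform variate from the policy stream; ``flip``
    states whether the probabilistic environment inverts this outcome.
    """
    q = table.q
    v = table.v
    alpha = params.effective_alpha
    gamma = params.gamma
    s_cue = _CUE[cond_idx]
    qc = q[s_cue]

    p_left = _p_left(qc[0], qc[1], params.beta, bias_left, bias_right)
    if forced_action_idx is not None:
        ai = forced_action_idx
    else:
        ai = 0 if u_action < p_left else 1

    correct = ai == _CORRECT_IDX[rule][cond_idx]
    if flip:
        correct = not correct
    s_act = _ACT[cond_idx][ai]
    s_out = _OUT[cond_idx][1 if correct else 0]
    r = 1.0 if correct else -1.0
    qi = q[STATE_INITIAL]
    qa = q[s_act]
    qo = q[s_out]

    # entering the cue state: SARSA bootstraps from the chosen action,
    # Q-learning from the best one (identical elsewhere: dummy-action
    # states keep both slots equal)
    boot = qc[ai] if params.algorithm != "qlearning" else (qc[0] if qc[0] >= qc[1] else qc[1])
    d_cue = gamma * boot - qi[0]
    qi[0] += alpha * d_cue
    qi[1] = qi[0]
    # entering the action state
    d_act = gamma * qa[0] - qc[ai]
    qc[ai] += alpha * d_act
    # entering the outcome state: the only rewarded transition
    d_out = r + gamma * qo[0] - qa[0]
    qa[0] += alpha * d_out
    qa[1] = qa[0]
    # entering the terminal end state (value pinned at 0)
    d_end = -qo[0]
    qo[0] += alpha * d_end
    qo[1] = qo[0]

    # parallel state-value learner (passive outcome prediction)
    av = params.alpha_v
    vi = v[STATE_INITIAL]
    vc = v[s_cue]
    va = v[s_act]
    vo = v[s_out]
    dv_cue = gamma * vc - vi
    v[STATE_INITIAL] = vi + av * dv_cue
    dv_act = gamma * va - vc
    v[s_cue] = vc + av * dv_act
    dv_out = r + gamma * vo - va
    v[s_act] = va + av * dv_out
    dv_end = -vo
    v[s_out] = vo + av * dv_end

    return ai, correct, r, p_left, d_cue, d_act, d_out, d_end, dv_cue, dv_act, dv_out, dv_end


@dataclass
class Agent:
    """A behaving TD learner bound to independent policy and environment RNG streams."""

    params: AgentParams = field(default_factory=AgentParams)
    seed: int | np.random.SeedSequence = 0
    table: ValueTable = field(default_factory=ValueTable)

    def __post_init__(self) -> None:
        ss = self.seed if isinstance(self.seed, np.random.SeedSequence) else np.random.SeedSequence(self.seed)
        policy_ss, env_ss, side_ss = ss.spawn(3)
        self.rng_policy = np.random.default_rng(policy_ss)
        self.rng_env = np.random.default_rng(env_ss)
        if self.params.bias_side == "random":
            self.bias_side = ACTIONS[np.random.default_rng(side_ss).integers(2)]
        else:
            self.bias_side = self.params.bias_side

    def bias_terms(self, rule: str, session_in_rule: int) -> tuple[float, float]:
        mag = bias_magnitude(
            session_in_rule, self.params.beta_bias0, self.params.lambda_bias,
            active=rule in BIAS_ACTIVE_RULES, form=self.params.bias_decay,
        )
        return (mag, 0.0) if self.bias_side == "left" else (0.0, mag)


def run_trial(agent: Agent, env: Environment, condition: TrialCondition | None = None,
              forced_action: str | None = None, session_in_rule: int = 0) -> EpisodeLog:
    """Run one full episode (initial -> cue -> action -> outcome -> end).

    Values are updated online; the returned log holds one TD error per
    state entered beyond the initial state, for both the state-action and
    the state-value learner.
    """
    if condition is None:
        condition = env.draw_condition(agent.rng_env)
    cond_idx = CONDITIONS.index(condition)
    flip = bool(env.probabilistic and agent.rng_env.random() < env.p_flip)
    bias_left, bias_right = agent.bias_terms(env.rule, session_in_rule)
    forced_idx = None if forced_action is None else (0 if forced_action == "left" else 1)
    u = float(agent.rng_policy.random())
    ai, correct, r, p_left, d_cue, d_act, d_out, d_end, dv_cue, dv_act, dv_out, dv_end = _run_episode(
        agent.table, env.rule, cond_idx, agent.params, bias_left, bias_right, u,
        flip, forced_idx)
    return EpisodeLog(
        condition=condition,
        choice=ACTIONS[ai],
        correct=correct,
        reward=r,
        deltas={"cue": d_cue, "action": d_act, "outcome": d_out, "end": d_end},
        state_deltas={"cue": dv_cue, "action": dv_act, "outcome": dv_out, "end": dv_end},
        p_left=p_left,
    )


# ---------------------------------------------------------------------------
# Multi-session protocol
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "agent", "rule", "rule_index", "session", "session_in_rule", "trial",
    "cue_location", "cue_frequency", "stay_switch", "choice", "correct",
    "r", "delta_cue", "delta_action", "delta_outcome", "delta_end",
    "delta_v_cue", "delta_v_action", "delta_v_outcome", "delta_v_end", "p_left",
]


@dataclass
class ProtocolLog:
    """Full simulation record: per-trial table, per-session summaries, metadata."""

    trials: pd.DataFrame
    sessions: pd.DataFrame
    params: AgentParams
    seed: int
    converged: dict[int, bool]
    reset_events: list[dict]

    def manifest(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in (
                "algorithm", "alpha", "gamma", "beta", "beta_bias0", "lambda_bias",
                "reset_mode", "bias_side", "bias_decay", "alpha_v")},
            "seed": self.seed,
            "converged": {str(k): bool(v) for k, v in self.converged.items()},
            "n_reset_events": len(self.reset_events),
        }


def run_protocol(params: AgentParams, rule_sequence: Sequence[str] = RULES,
                 n_trials_per_session: int = 300, n_agents: int = 5,
                 max_sessions: int = 50, seed: int = 0,
                 probabilistic: bool = False) -> ProtocolLog:
    """Simulate agents through the full multi-rule training protocol.

    Each rule is trained until two consecutive sessions meet the behavioral
    criterion (>= 80% correct overall and >= 60% in each condition over the
    session), then the rule advances and values are reset per
    ``params.reset_mode``.  An agent that exhausts ``max_sessions`` on a
    rule is flagged non-convergent and its protocol stops there (partial
    log).  Conditions are drawn uniformly i.i.d. from the environment RNG
    stream; action sampling uses the independent policy stream.
    """
    master = np.random.SeedSequence(seed)
    records: list[tuple] = []
    session_rows: list[dict] = []
    converged: dict[int, bool] = {}
    reset_events: list[dict] = []

    for agent_idx, agent_ss in enumerate(master.spawn(n_agents)):
        agent = Agent(params=params, seed=agent_ss)
        converged[agent_idx] = True
        global_session = 0
        prev_rule: str | None = None
        for rule_index, rule in enumerate(rule_sequence):
            env = Environment(rule, probabilistic=probabilistic)
            if prev_rule is not None:
                apply_reset(agent.table, params.reset_mode)
                reset_events.append({
                    "agent": agent_idx, "rule": rule, "session": global_session,
                    "mode": params.reset_mode,
                })
            stay_switch = {
                i: (classify_stay_switch(prev_rule, rule, c) if prev_rule else "")
                for i, c in enumerate(CONDITIONS)
            }
            consecutive = 0
            advanced = False
            for session_in_rule in range(max_sessions):
                bias_left, bias_right = agent.bias_terms(rule, session_in_rule)
                cond_draws = agent.rng_env.integers(4, size=n_trials_per_session)
                u_actions = agent.rng_policy.random(n_trials_per_session)
                flips = (
                    agent.rng_env.random(n_trials_per_session) < env.p_flip
                    if probabilistic else np.zeros(n_trials_per_session, dtype=bool)
                )
                n_corr = 0
                cond_n = [0, 0, 0, 0]
                cond_corr = [0, 0, 0, 0]
                side_n = [0, 0]
                side_corr = [0, 0]
                for t in range(n_trials_per_session):
                    ci = int(cond_draws[t])
                    out = _run_episode(
                        agent.table, rule, ci, params, bias_left, bias_right,
                        float(u_actions[t]), bool(flips[t]))
                    ai, correct = out[0], out[1]
                    cond = CONDITIONS[ci]
                    records.append((
                        agent_idx, rule, rule_index, global_session, session_in_rule,
                        t, cond.cue_location, cond.cue_frequency, stay_switch[ci],
                        ACTIONS[ai], correct, out[2], out[4], out[5], out[6], out[7],
                        out[8], out[9], out[10], out[11], out[3],
                    ))
                    n_corr += correct
                    cond_n[ci] += 1
                    cond_corr[ci] += correct
                    si = 0 if cond.cue_location == "left" else 1
                    side_n[si] += 1
                    side_corr[si] += correct
                overall = n_corr / n_trials_per_session
                per_cond = [cond_corr[i] / cond_n[i] if cond_n[i] else np.nan
                            for i in range(4)]
                crit = behavior_metrics.meets_criterion_fractions(overall, per_cond)
                fcl = side_corr[0] / side_n[0] if side_n[0] else np.nan
                fcr = side_corr[1] / side_n[1] if side_n[1] else np.nan
                bias = fcl / (fcl + fcr) if (fcl + fcr) > 0 else np.nan
                session_rows.append({
                    "agent": agent_idx, "rule": rule, "rule_index": rule_index,
                    "session": global_session, "session_in_rule": session_in_rule,
                    "n_trials": n_trials_per_session,
                    "fraction_correct": overall,
                    "min_condition_correct": float(np.nanmin(per_cond)),
                    "criterion": crit,
                    "stage": behavior_metrics.stage_from_fractions(overall, per_cond),
                    "response_bias": bias,
                    "abs_response_bias": abs(bias - 0.5) if np.isfinite(bias) else np.nan,
                    "bias_magnitude": bias_left + bias_right,
                })
                global_session += 1
                consecutive = consecutive + 1 if crit else 0
                if consecutive >= 2:
                    advanced = True
                    break
            if not advanced:
                converged[agent_idx] = False
                break
            prev_rule = rule

    trials = pd.DataFrame.from_records(records, columns=_TRIAL_COLUMNS)
    sessions = pd.DataFrame(session_rows)
    return ProtocolLog(trials=trials, sessions=sessions, params=params, seed=seed,
                       converged=converged, reset_events=reset_events)


def extract_rpes(log: ProtocolLog, epoch: str = "cue", correct: bool | None = None,
                 stay_switch: str | None = None, stage: str | None = None,
                 rule: str | None = None, session_in_rule: int | None = None,
                 value_type: str = "state_action") -> pd.DataFrame:
    """Select the per-trial TD-error series for one epoch under exact label filters.

    ``epoch`` is one of cue/action/outcome/end; ``value_type``
    "state_action" reads the behaving agent's deltas, "state" the parallel
    state-value learner's.  Averaging is left to the caller.
    """
    if epoch not in ("cue", "action", "outcome", "end"):
        raise ValueError(f"unknown epoch {epoch!r}")
    if value_type == "state_action":
        col = f"delta_{epoch}"
    elif value_type == "state":
        col = f"delta_v_{epoch}"
    else:
        raise ValueError(f"unknown value type {value_type!r}")
    df = log.trials
    mask = np.ones(len(df), dtype=bool)
    if correct is not None:
        mask &= df["correct"].to_numpy() == correct
    if stay_switch is not None:
        mask &= df["stay_switch"].to_numpy() == stay_switch
    if rule is not None:
        mask &= df["rule"].to_numpy() == rule
    if session_in_rule is not None:
        mask &= df["session_in_rule"].to_numpy() == session_in_rule
    out = df.loc[mask, ["agent", "rule", "session", "session_in_rule", "trial", col]]
    out = out.rename(columns={col: "delta"})
    if stage is not None:
        stages = log.sessions.set_index(["agent", "session"])["stage"]
        keys = pd.MultiIndex.from_frame(out[["agent", "session"]])
        out = out[stages.reindex(keys).to_numpy() == stage]
    return out.reset_index(drop=True)
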