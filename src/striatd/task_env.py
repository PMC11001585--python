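"""Auditory rule-switch task: conditions, rules, schedules and the TD state space.

The task is a head-fixed two-alternative auditory decision task.  On each
trial a cue is played from the left or right speaker at a low or high
frequency, giving four conditions (location x frequency).  Which cue
dimension instructs the rewarded lick side is set by an implicit rule that
changes over training: first *location* (lick the side the sound came
from), then *frequency* (low -> left, high -> right), then
*frequency_reversed* (high -> left, low -> right).

For the learning agents the task is unrolled into a 22-state episode graph
with five temporal stages (initial, cue, action, outcome, end): 1 initial
state, 4 cue states (one per condition), 8 action states (condition x
chosen side), 8 outcome states (condition x correct/false) and 1 terminal
end state.  Entering the reward outcome state yields +1, the no-reward
state -1.  A probabilistic variant flips the outcome on a configurable
fraction of trials (10% in the probabilistic sessions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

LOCATIONS = ("left", "right")
FREQUENCIES = ("low", "high")
ACTIONS = ("left", "right")
RULES = ("location", "frequency", "frequency_reversed")

#: reward on entering the rewarded / unrewarded outcome state
REWARD_CORRECT = 1.0
REWARD_FALSE = -1.0

#: outcome flip probability in the probabilistic task variant
DEFAULT_P_FLIP = 0.1


@dataclass(frozen=True)
class TrialCondition:
    """One of the four cue conditions (speaker location x sound frequency)."""

    cue_location: str
    cue_frequency: str

    def __post_init__(self) -> None:
        if self.cue_location not in LOCATIONS:
            raise ValueError(f"unknown cue location {self.cue_location!r}")
        if self.cue_frequency not in FREQUENCIES:
            raise ValueError(f"unknown cue frequency {self.cue_frequency!r}")

    @property
    def label(self) -> str:
        return f"{self.cue_location}-{self.cue_frequency}"


#: the four conditions, in a fixed canonical order
CONDITIONS: tuple[TrialCondition, ...] = tuple(
    TrialCondition(loc, freq) for loc in LOCATIONS for freq in FREQUENCIES
)


def correct_action(rule: str, condition: TrialCondition) -> str:
    """Rewarded lick side for ``condition`` under task ``rule``.

    location: lick the side the sound came from; frequency: low -> left,
    high -> right; frequency_reversed: high -> left, low -> right.
    """
    if rule == "location":
        return condition.cue_location
    if rule == "frequency":
        return "left" if condition.cue_frequency == "low" else "right"
    if rule == "frequency_reversed":
        return "right" if condition.cue_frequency == "low" else "left"
    raise ValueError(f"unknown task rule {rule!r}")


def classify_stay_switch(prev_rule: str, new_rule: str, condition: TrialCondition) -> str:
    """Label a condition "stay" if its correct response survives the rule switch.

    After the location -> frequency switch two conditions stay and two
    switch; after frequency -> frequency_reversed all four switch.
    """
    if prev_rule == new_rule:
        raise ValueError("stay/switch is defined only across a rule change")
    same = correct_action(prev_rule, condition) == correct_action(new_rule, condition)
    return "stay" if same else "switch"


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSchedule:
    """Ordered condition sequence organised in balanced pseudorandom blocks."""

    conditions: tuple[TrialCondition, ...]
    block_size: int

    def __len__(self) -> int:
        return len(self.conditions)

    def to_frame(self, rule: str | None = None, prev_rule: str | None = None) -> pd.DataFrame:
        """Tabulate the schedule (tab-separated friendly trial log skeleton)."""
        rows = []
        for i, cond in enumerate(self.conditions):
            row = {
                "trial": i,
                "block": i // self.block_size,
                "cue_location": cond.cue_location,
                "cue_frequency": cond.cue_frequency,
            }
            if rule is not None:
                row["rule"] = rule
                if prev_rule is not None:
                    row["stay_switch"] = classify_stay_switch(prev_rule, rule, cond)
            rows.append(row)
        return pd.DataFrame(rows)


def generate_schedule(n_trials: int, block_size: int = 32, seed: int | np.random.Generator = 0) -> TrialSchedule:
    """Pseudorandomised condition schedule: balanced blocks, drawn without replacement.

    Each block holds every condition exactly ``block_size / 4`` times in a
    seed-determined random order.  If ``n_trials`` is not a multiple of
    ``block_size`` the final block is truncated, so only full blocks
    guarantee exact balance.
    """
    if block_size % 4 != 0:
        raise ValueError("block_size must be divisible by 4")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_cond = block_size // 4
    n_blocks = -(-n_trials // block_size)
    seq: list[TrialCondition] = []
    for _ in range(n_blocks):
        block = list(CONDITIONS) * per_cond
        order = rng.permutation(len(block))
        seq.extend(block[i] for i in order)
    return TrialSchedule(conditions=tuple(seq[:n_trials]), block_size=block_size)


# ---------------------------------------------------------------------------
# Episode state space
# ---------------------------------------------------------------------------

STATE_INITIAL = "initial"
STATE_END = "end"


def cue_state(condition: TrialCondition) -> str:
    return f"cue:{condition.label}"


def action_state(condition: TrialCondition, action: str) -> str:
    return f"action:{condition.label}:{action}"


def outcome_state(condition: TrialCondition, correct: bool) -> str:
    return f"outcome:{condition.label}:{'correct' if correct else 'false'}"


def all_states() -> list[str]:
    """The 22 labelled states of one task environment."""
    states = [STATE_INITIAL]
    states += [cue_state(c) for c in CONDITIONS]
    states += [action_state(c, a) for c in CONDITIONS for a in ACTIONS]
    states += [outcome_state(c, f) for c in CONDITIONS for f in (True, False)]
    states.append(STATE_END)
    return states


@dataclass
class Environment:
    """One task rule unrolled as an episodic state graph.

    Episodes run initial -> cue -> action -> outcome -> end.  The cue state
    is drawn uniformly from the four conditions; the chosen action selects
    the action state; the outcome is determined by the rule (and flipped
    with probability ``p_flip`` when ``probabilistic``).
    """

    rule: str
    probabilistic: bool = False
    p_flip: float = DEFAULT_P_FLIP
    states: tuple[str, ...] = field(default_factory=lambda: tuple(all_states()), repr=False)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown task rule {self.rule!r}")
        if not 0.0 <= self.p_flip <= 1.0:
            raise ValueError("p_flip must be a probability")

    # -- transition model ---------------------------------------------------

    def draw_condition(self, rng: np.random.Generator) -> TrialCondition:
        """Uniform condition draw used for agent simulation."""
        return CONDITIONS[rng.integers(4)]

    def step(self, state: str, action: str | None, rng: np.random.Generator,
             condition: TrialCondition | None = None) -> tuple[str, float]:
        """Advance one temporal state; returns (next_state, reward).

        ``action`` must be a lick side in cue states and None (dummy)
        elsewhere.  ``condition`` fixes the cue drawn from the initial
        state; omitted, it is drawn uniformly.
        """
        if state == STATE_END:
            raise ValueError("end state is terminal")
        if state == STATE_INITIAL:
            self._check_dummy(action, state)
            cond = condition if condition is not None else self.draw_condition(rng)
            return cue_state(cond), 0.0
        kind, _, rest = state.partition(":")
        if kind == "cue":
            if action not in ACTIONS:
                raise ValueError(f"a left/right action is required in cue state {state!r}")
            cond = _condition_from_label(rest)
            return action_state(cond, action), 0.0
        if kind == "action":
            self._check_dummy(action, state)
            label, _, side = rest.partition(":")
            cond = _condition_from_label(label)
            correct = side == correct_action(self.rule, cond)
            if self.probabilistic and rng.random() < self.p_flip:
                correct = not correct
            reward = REWARD_CORRECT if correct else REWARD_FALSE
            return outcome_state(cond, correct), reward
        if kind == "outcome":
            self._check_dummy(action, state)
            return STATE_END, 0.0
        raise ValueError(f"unknown state {state!r}")

    @staticmethod
    def _check_dummy(action: str | None, state: str) -> None:
        if action is not None:
            raise ValueError(f"only the dummy action is allowed in state {state!r}")

    # -- config round-trip --------------------------------------------------

    def to_config(self) -> dict:
        return {"rule": self.rule, "probabilistic": self.probabilistic, "p_flip": self.p_flip}

    @classmethod
    def from_config(cls, cfg: dict | str) -> "Environment":
        """Build from a dict or a YAML/JSON config string."""
        if isinstance(cfg, str):
            cfg = yaml.safe_load(cfg)
        return cls(rule=cfg["rule"], probabilistic=bool(cfg.get("probabilistic", False)),
                   p_flip=float(cfg.get("p_flip", DEFAULT_P_FLIP)))


def _condition_from_label(label: str) -> TrialCondition:
    loc, _, freq = label.partition("-")
    return TrialCondition(loc, freq)


# ---------------------------------------------------------------------------
# Trial-table I/O
# ---------------------------------------------------------------------------

def write_trial_table(frame: pd.DataFrame, path) -> None:
    """Serialize a trial log as a tab-separated table with a one-line header."""
    frame.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=str)
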