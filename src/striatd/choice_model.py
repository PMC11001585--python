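"""Session-based logistic regression of trial-by-trial choice.

Models the probability of a right-side choice as a logistic function of
trial predictors, y_hat = 1 / (1 + exp(-z)) with z = sum_p beta_p x_p +
beta_0.  Weights minimise the mean negative log-likelihood by plain
gradient descent with no regularization; model quality is the tenfold
cross-validated prediction accuracy, and models are compared by the
per-session accuracy difference.

All predictors are coded in [-1, +1] and deliberately not standardized,
so a weight of 0 is interpretable as "no influence".  The full model uses
the current cue location, current cue frequency and the difference of
ten-trial exponentially weighted per-spout reward rates; the alternative
history codings (per-spout rates, choice lags, win-stay/lose-switch,
previous choice/outcome and interactions, cue history) are available for
model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

#: predictors of the final session-based model
FULL_MODEL = ("cue_location", "cue_frequency", "delta_reward_rate")

#: named alternative/reduced models compared against the full model
ALTERNATIVE_MODELS: dict[str, tuple[str, ...]] = {
    "spout_reward_rates": ("cue_location", "cue_frequency",
                           "reward_rate_left", "reward_rate_right"),
    "choice_history": ("cue_location", "cue_frequency",
                       "choice_hist_1", "choice_hist_2", "choice_hist_3"),
    "win_stay_lose_switch": ("cue_location", "cue_frequency", "win_stay", "lose_switch"),
    "previous_choice": ("cue_location", "cue_frequency", "prev_choice"),
}

_PM1 = {"left": -1.0, "right": 1.0, "low": -1.0, "high": 1.0}


@dataclass
class DesignMatrix:
    """Per-trial predictor matrix and binary response (0 = left, 1 = right)."""

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y are inconsistent")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


@dataclass
class FitResult:
    weights: np.ndarray
    intercept: float
    names: tuple[str, ...]
    loss: float
    n_iter: int
    converged: bool
    degenerate: bool = False

    def coef(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])


# ---------------------------------------------------------------------------
# Regressor construction
# ---------------------------------------------------------------------------

def delta_reward_rate(trials: pd.DataFrame, memory: int = 10) -> np.ndarray:
    """Left-minus-right exponentially weighted reward rate, in [-1, 1].

    Each spout carries an exponentially weighted average (smoothing factor
    2 / (memory + 1)) of a per-trial reward indicator: 1 when that spout
    was chosen and rewarded, else 0.  The value assigned to trial t uses
    rewards up to and including trial t - 1; the first trial gets 0.
    """
    a = 2.0 / (memory + 1.0)
    chosen_right = _choice_signs(trials) > 0
    rewarded = _rewarded(trials)
    out = np.zeros(len(trials))
    s_left = s_right = 0.0
    for t in range(len(trials)):
        out[t] = s_left - s_right
        xl = float(rewarded[t] and not chosen_right[t])
        xr = float(rewarded[t] and chosen_right[t])
        s_left = a * xl + (1.0 - a) * s_left
        s_right = a * xr + (1.0 - a) * s_right
    return out


def _spout_reward_rate(trials: pd.DataFrame, spout: str, memory: int = 10) -> np.ndarray:
    a = 2.0 / (memory + 1.0)
    chosen = _choice_signs(trials) > 0 if spout == "right" else _choice_signs(trials) < 0
    rewarded = _rewarded(trials)
    out = np.zeros(len(trials))
    s = 0.0
    for t in range(len(trials)):
        out[t] = s
        s = a * float(rewarded[t] and chosen[t]) + (1.0 - a) * s
    return out


def _choice_signs(trials: pd.DataFrame) -> np.ndarray:
    return np.array([_PM1[c] for c in trials["choice"]])


def _rewarded(trials: pd.DataFrame) -> np.ndarray:
    if "r" in trials.columns:
        return trials["r"].to_numpy(dtype=float) > 0
    return trials["correct"].to_numpy(dtype=bool)


def _lagged(values: np.ndarray, lag: int) -> np.ndarray:
    """Shift by ``lag`` trials; unavailable history is coded 0."""
    out = np.zeros_like(values, dtype=float)
    if lag < len(values):
        out[lag:] = values[: len(values) - lag]
    return out


def build_regressors(trials: pd.DataFrame,
                     predictors: Sequence[str] = FULL_MODEL) -> DesignMatrix:
    """Assemble the design matrix for the named predictors.

    Codings: cue_location / choice -1 left, +1 right; cue_frequency -1
    low, +1 high; outcome -1 unrewarded, +1 rewarded; win_stay is the
    previous choice sign after a rewarded previous trial and 0 otherwise,
    lose_switch the previous choice sign after an unrewarded previous
    trial and 0 otherwise.  History predictors are 0 where the lag reaches
    before the session start.
    """
    trials = trials.reset_index(drop=True)
    cue_loc = np.array([_PM1[v] for v in trials["cue_location"]])
    cue_freq = np.array([_PM1[v] for v in trials["cue_frequency"]])
    choice = _choice_signs(trials)
    outcome = np.where(_rewarded(trials), 1.0, -1.0)

    def column(name: str) -> np.ndarray:
        if name == "cue_location":
            return cue_loc
        if name == "cue_frequency":
            return cue_freq
        if name == "cue_interaction":
            return cue_loc * cue_freq
        if name == "delta_reward_rate":
            return delta_reward_rate(trials)
        if name in ("reward_rate_left", "reward_rate_right"):
            return _spout_reward_rate(trials, name.removeprefix("reward_rate_"))
        if name == "prev_choice":
            return _lagged(choice, 1)
        if name == "prev_outcome":
            return _lagged(outcome, 1)
        if name == "win_stay":
            return _lagged(np.where(outcome > 0, choice, 0.0), 1)
        if name == "lose_switch":
            return _lagged(np.where(outcome < 0, choice, 0.0), 1)
        if name.startswith("choice_hist_"):
            return _lagged(choice, int(name.rsplit("_", 1)[1]))
        if name.startswith("outcome_hist_"):
            return _lagged(outcome, int(name.rsplit("_", 1)[1]))
        if name.startswith("choice_outcome_"):
            lag = int(name.rsplit("_", 1)[1])
            return _lagged(choice * outcome, lag)
        if name.startswith("cue_location_hist_"):
            return _lagged(cue_loc, int(name.rsplit("_", 1)[1]))
        if name.startswith("cue_frequency_hist_"):
            return _lagged(cue_freq, int(name.rsplit("_", 1)[1]))
        raise ValueError(f"unknown predictor {name!r}")

    X = np.column_stack([column(p) for p in predictors]) if predictors else np.empty((len(trials), 0))
    y = (choice > 0).astype(float)
    return DesignMatrix(X=X, y=y, names=tuple(predictors))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _loss_and_grad(theta: np.ndarray, Xb: np.ndarray, y: np.ndarray):
    z = Xb @ theta
    # J = mean[log(1 + e^z) - y z], numerically stable cross-entropy
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = Xb.T @ (p - y) / len(y)
    return loss, grad


def fit_logistic(design: DesignMatrix, tol: float = 1e-4, max_iter: int = 50000,
                 step0: float = 1.0) -> FitResult:
    """Gradient-descent fit of the unregularized logistic model.

    Fixed step with backtracking halving on loss increase (and mild
    re-growth after accepted steps).  Stops when the loss falls below
    ``tol``, when an accepted step no longer decreases the loss by more
    than 1e-12, or at ``max_iter``.  Sessions with a single response class
    are flagged degenerate and yield an intercept-driven fit.
    """
    X, y = design.X, design.y
    degenerate = len(np.unique(y)) < 2
    Xb = np.column_stack([X, np.ones(len(y))])
    theta = np.zeros(Xb.shape[1])
    loss, grad = _loss_and_grad(theta, Xb, y)
    step = step0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        while True:
            cand = theta - step * grad
            new_loss, new_grad = _loss_and_grad(cand, Xb, y)
            if new_loss <= loss or step < 1e-14:
                break
            step *= 0.5
        decrease = loss - new_loss
        theta, loss, grad = cand, new_loss, new_grad
        step = min(step * 1.1, 1e6)
        if loss < tol or decrease < 1e-12:
            converged = True
            break
    return FitResult(weights=theta[:-1], intercept=float(theta[-1]),
                     names=design.names, loss=loss, n_iter=it,
                     converged=converged, degenerate=degenerate)


def predict(fit: FitResult, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Model choice probabilities and binary predictions (y_hat >= 0.5 -> 1)."""
    z = design.X @ fit.weights + fit.intercept
    prob = 1.0 / (1.0 + np.exp(-z))
    return prob, (prob >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Cross-validation and model comparison
# ---------------------------------------------------------------------------

def crossval_accuracy(design: DesignMatrix, folds: int = 10, seed: int = 0,
                      tol: float = 1e-4, max_iter: int = 50000) -> float:
    """Tenfold cross-validated prediction accuracy over pooled test folds.

    Folds are stratified by response class (plain K-fold when a class is
    rarer than the fold count) so short sessions do not produce empty-class
    training sets; every trial is tested exactly once.
    """
    X, y = design.X, design.y
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    correct = 0
    for train, test in splits:
        sub = DesignMatrix(X=X[train], y=y[train], names=design.names)
        fit = fit_logistic(sub, tol=tol, max_iter=max_iter)
        _, pred = predict(fit, DesignMatrix(X=X[test], y=y[test], names=design.names))
        correct += int(np.sum(pred == y[test]))
    return correct / len(y)


def compare_models(trials: pd.DataFrame, base_spec: Sequence[str] = FULL_MODEL,
                   variant_specs: Mapping[str, Sequence[str]] | None = None,
                   folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Cross-validated accuracy of the base model against named variants.

    Returns one row per variant with base accuracy, variant accuracy and
    their difference (positive = the base model predicts better).
    """
    if variant_specs is None:
        variant_specs = ALTERNATIVE_MODELS
    base_acc = crossval_accuracy(build_regressors(trials, base_spec), folds=folds, seed=seed)
    rows = []
    for name, spec in variant_specs.items():
        acc = crossval_accuracy(build_regressors(trials, spec), folds=folds, seed=seed)
        rows.append({"variant": name, "accuracy_base": base_acc,
                     "accuracy_variant": acc, "delta_accuracy": base_acc - acc})
    return pd.DataFrame(rows)
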