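"""Elo-style rating engines: standard (unidimensional) ERS and M-ERS.

The standard ERS tracks a single ability on the Rasch scale,

    theta <- theta + K(t) * (Y - P),       P = logistic(theta - beta_j),

while the multidimensional extension (M-ERS) tracks an M-vector under the
compensatory working model (slopes fixed at 1),

    P = logistic( sum_{m : item loads on m} theta_m - beta_j ),
    theta_m <- theta_m + D_m * K(t) * (Y - P),

where D_m is 1 on loaded dimensions and (by default) 0 elsewhere.  In
speed-accuracy (HSHS) mode the binary innovation Y - P is replaced by the
score innovation S - E(S), with E(S) the closed-form expected trade-off
score; this is exact stochastic-gradient ascent on the tilted score
log-likelihood, just as Y - P is for the Bernoulli likelihood.

The step size K decays linearly in the learner's own number of answered
items, from ``k_max`` at t = 0 to ``k_min`` at t = horizon - 1, and is
clamped at ``k_min`` thereafter.  Item difficulties come from a calibrated
bank and are not updated by default (the ``update_difficulty`` flag enables
the classic symmetric item-side update for completeness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .item_bank import Item, ItemBank
from .scores import mean_score

__all__ = [
    "StepSchedule",
    "EngineConfig",
    "RatingState",
    "step_size",
    "init_state",
    "predict",
    "update",
    "replay_arrays",
    "state_to_json",
    "state_from_json",
]


@dataclass(frozen=True)
class StepSchedule:
    """Linearly decaying step size, k_max -> k_min over ``horizon`` occasions."""

    k_max: float = 0.4
    k_min: float = 0.1
    horizon: int = 200

    def __post_init__(self):
        if not (self.k_max >= self.k_min > 0):
            raise ValueError("need k_max >= k_min > 0")
        if self.horizon < 2:
            raise ValueError("horizon must be >= 2")


def step_size(schedule: StepSchedule, n_answered: int) -> float:
    """K(t) = k_max - (k_max - k_min) * min(t, horizon-1)/(horizon-1)."""
    if n_answered < 0:
        raise ValueError("n_answered must be >= 0")
    h = schedule.horizon - 1
    frac = min(n_answered, h) / h
    return schedule.k_max - (schedule.k_max - schedule.k_min) * frac


@dataclass(frozen=True)
class EngineConfig:
    """Configuration of a rating engine.

    mode: 'uni' (scalar Rasch ability) or 'multi' (M-dimensional).
    outcome: 'accuracy' (binary Y) or 'hshs' (trade-off score S).
    d_weights_off: update weight D_m applied to dimensions the item does
        NOT load on (loaded dimensions always get weight 1); default 0.
    time_limit: the HSHS time limit d (scores live on (-d, d)).
    update_difficulty: enable the symmetric item-side Elo update (off in
        all reproduction experiments; difficulties are treated as known).
    """

    mode: str = "multi"
    outcome: str = "accuracy"
    n_dims: int = 3
    schedule: StepSchedule = field(default_factory=StepSchedule)
    d_weights_off: float = 0.0
    time_limit: float = 1.0
    update_difficulty: bool = False

    def __post_init__(self):
        if self.mode not in ("uni", "multi"):
            raise ValueError(f"mode must be 'uni'|'multi', got {self.mode!r}")
        if self.outcome not in ("accuracy", "hshs"):
            raise ValueError(f"outcome must be 'accuracy'|'hshs', got {self.outcome!r}")
        if not 0.0 <= self.d_weights_off <= 1.0:
            raise ValueError("d_weights_off must lie in [0, 1]")

    @property
    def state_dims(self) -> int:
        return 1 if self.mode == "uni" else self.n_dims


@dataclass
class RatingState:
    """Mutable per-learner rating state theta_hat(t)."""

    learner_id: int
    theta_hat: np.ndarray
    n_answered: int = 0

    def copy(self) -> "RatingState":
        return RatingState(self.learner_id, self.theta_hat.copy(), self.n_answered)


def init_state(config: EngineConfig, learner_id: int = 0,
               theta0: np.ndarray | None = None) -> RatingState:
    """Fresh state at the origin of the ability scale (theta_hat = 0)."""
    m = config.state_dims
    if m < 1:
        raise ValueError("need at least one dimension")
    theta = np.zeros(m) if theta0 is None else np.asarray(theta0, float).copy()
    if theta.shape != (m,):
        raise ValueError(f"theta0 must have shape ({m},)")
    return RatingState(learner_id=learner_id, theta_hat=theta)


def _weights(config: EngineConfig, item: Item) -> np.ndarray:
    """Update weights D: 1 on loaded dimensions, d_weights_off elsewhere."""
    load = np.asarray(item.loadings, dtype=float)
    return np.where(load == 1.0, 1.0, config.d_weights_off)


def _eta(config: EngineConfig, state: RatingState, item: Item) -> float:
    if config.mode == "uni":
        return float(state.theta_hat[0]) - item.difficulty
    load = np.asarray(item.loadings, dtype=float)
    if load.shape != state.theta_hat.shape:
        raise ValueError("item dimensionality does not match engine state")
    return float(load @ state.theta_hat) - item.difficulty


def predict(config: EngineConfig, state: RatingState, item: Item) -> float:
    """Model expectation for the next outcome, computed before the update.

    Accuracy mode: P(Y=1) = logistic(eta).  HSHS mode: E(S) on (-d, d).
    Only loaded dimensions enter eta in multi mode.
    """
    eta = _eta(config, state, item)
    if config.outcome == "accuracy":
        return float(expit(eta))
    return float(mean_score(eta, config.time_limit))


def update(config: EngineConfig, state: RatingState, item: Item, outcome: float,
           bank: ItemBank | None = None) -> RatingState:
    """One Elo update; mutates and returns ``state``.

    ``outcome`` is Y in {0, 1} for accuracy mode, or S in [-d, d] for HSHS
    mode.  The innovation (outcome minus its pre-update expectation) is
    scaled by K(t) and the per-dimension weights D.
    """
    d = config.time_limit
    if config.outcome == "accuracy":
        if outcome not in (0, 1, 0.0, 1.0):
            raise ValueError(f"accuracy outcome must be 0/1, got {outcome!r}")
    elif not -d <= outcome <= d:
        raise ValueError(f"HSHS score must lie in [-{d}, {d}], got {outcome!r}")

    expected = predict(config, state, item)
    k = step_size(config.schedule, state.n_answered)
    innov = k * (outcome - expected)
    if config.mode == "uni":
        state.theta_hat[0] += innov
    else:
        state.theta_hat += _weights(config, item) * innov
    state.n_answered += 1
    if config.update_difficulty and bank is not None:
        idx = next(i for i, it in enumerate(bank.items) if it.item_id == item.item_id)
        new_item = replace(item, difficulty=item.difficulty - innov)
        bank.items[idx] = new_item
    return state


# ----------------------------------------------------------------------
# Vectorised replay over a logged outcome stream
# ----------------------------------------------------------------------

def replay_arrays(
    config: EngineConfig,
    item_idx: np.ndarray,
    outcomes: np.ndarray,
    difficulties: np.ndarray,
    loadings: np.ndarray,
    theta0: np.ndarray | None = None,
):
    """Score an (n_learners, n_occasions) outcome stream through the engine.

    Learners are independent, so the occasion loop is vectorised across
    them; the result is identical to running :func:`update` per learner in
    chronological order.  Returns ``(predictions, trajectories)`` where
    ``predictions[i, t]`` is the pre-update expectation and
    ``trajectories[i, t]`` the post-update theta_hat at occasion t.
    """
    item_idx = np.asarray(item_idx)
    outcomes = np.asarray(outcomes, dtype=float)
    n, t_max = item_idx.shape
    m = config.state_dims
    theta = np.zeros((n, m)) if theta0 is None else np.array(theta0, float)
    preds = np.empty((n, t_max))
    traj = np.empty((n, t_max, m))
    for t in range(t_max):
        j = item_idx[:, t]
        beta = difficulties[j]
        if config.mode == "uni":
            eta = theta[:, 0] - beta
            w = np.ones((n, 1))
        else:
            load = loadings[j]
            eta = np.einsum("ij,ij->i", load, theta) - beta
            w = np.where(load == 1.0, 1.0, config.d_weights_off)
        if config.outcome == "accuracy":
            p = expit(eta)
        else:
            p = mean_score(eta, config.time_limit)
        k = step_size(config.schedule, t)
        theta = theta + w * (k * (outcomes[:, t] - p))[:, None]
        preds[:, t] = p
        traj[:, t] = theta
    return preds, traj


# ----------------------------------------------------------------------
# State serialisation (streaming / real-time use)
# ----------------------------------------------------------------------

def state_to_json(state: RatingState) -> str:
    return json.dumps(
        {
            "learner_id": state.learner_id,
            "theta_hat": state.theta_hat.tolist(),
            "n_answered": state.n_answered,
        }
    )


def state_from_json(payload: str) -> RatingState:
    obj = json.loads(payload)
    return RatingState(
        learner_id=int(obj["learner_id"]),
        theta_hat=np.asarray(obj["theta_hat"], dtype=float),
        n_answered=int(obj["n_answered"]),
    )
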