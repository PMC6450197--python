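"""Learner populations, generating models, and practice-session simulation.

True abilities are drawn from a multivariate normal N(mu, Sigma); in the
study design mu = (1, 1, 1)' and Sigma is an equicorrelation matrix with
unit variances and common correlation rho in {0.0, 0.2, 0.5}.  Accuracy
outcomes follow the compensatory MIRT generating model

    P(Y = 1) = logistic( sum_m alpha_jm * theta_im - beta_j ),

with the item's generating slopes (zero off the loaded dimensions).  In
speed-accuracy mode the HSHS score S is drawn from the exponential-tilted
density on (-d, d) at the true logit, and (Y, T) are derived from it; the
implied accuracy marginal is exactly the logistic above (at d = 1), so the
two modes agree in accuracy distribution.

Each simulated practice session presents every learner a fresh uniformly
random permutation of the full bank.  Item selection is non-adaptive, so
outcomes never depend on the rating engine's state; sessions are therefore
simulated as an outcome stream first and scored through an engine second,
which also lets several engines consume an identical stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import engine as _engine
from .item_bank import Item, ItemBank
from .scores import sample_score

__all__ = [
    "PopulationSpec",
    "LearnerAbility",
    "SessionStream",
    "equicorrelation",
    "sample_abilities",
    "response_probability",
    "sample_accuracy",
    "sample_hshs",
    "simulate_stream",
    "run_session",
]


def equicorrelation(rho: float, n_dims: int = 3) -> np.ndarray:
    """Unit-variance covariance with a common off-diagonal correlation."""
    cov = np.full((n_dims, n_dims), float(rho))
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass(frozen=True)
class PopulationSpec:
    """N learners with abilities ~ N(mean, cov)."""

    n_learners: int = 250
    mean: np.ndarray = field(default_factory=lambda: np.ones(3))
    cov: np.ndarray = field(default_factory=lambda: np.eye(3))
    seed: int | None = None

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("cov shape must match mean length")
        if not np.allclose(cov, cov.T):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("cov must be positive semi-definite")

    @property
    def n_dims(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class LearnerAbility:
    learner_id: int
    theta_true: np.ndarray


def sample_abilities(spec: PopulationSpec,
                     rng: np.random.Generator | None = None) -> list[LearnerAbility]:
    """Draw the true ability vectors; reproducible under ``spec.seed``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(spec.mean, spec.cov, size=spec.n_learners,
                                    method="cholesky")
    return [LearnerAbility(i, draws[i]) for i in range(spec.n_learners)]


def response_probability(theta_true, item: Item) -> float:
    """Generating-model probability of a correct answer (overflow-safe)."""
    theta = np.asarray(theta_true, dtype=float)
    slopes = np.asarray(item.gen_slopes, dtype=float)
    if theta.shape != slopes.shape:
        raise ValueError("theta dimensionality does not match item")
    return float(expit(slopes @ theta - item.difficulty))


def sample_accuracy(theta_true, item: Item, rng: np.random.Generator) -> int:
    """Bernoulli draw from the generating model."""
    return int(rng.random() < response_probability(theta_true, item))


def sample_hshs(theta_true, item: Item, d: float = 1.0,
                rng: np.random.Generator | None = None):
    """Joint draw of (Y, T, S) under the HSHS score model.

    S is drawn from the tilted density at the true logit; Y = 1{S > 0} and
    T = d - |S|, so S = (2Y - 1)(d - T) holds by construction.
    """
    if d <= 0:
        raise ValueError("time limit d must be positive")
    theta = np.asarray(theta_true, dtype=float)
    eta = float(np.asarray(item.gen_slopes) @ theta - item.difficulty)
    s = float(sample_score(eta, rng.random(), d))
    y = int(s > 0)
    t = d - abs(s)
    return y, t, s


@dataclass
class SessionStream:
    """Engine-independent outcome stream for one simulated condition.

    Arrays are (n_learners, n_occasions); ``item_idx`` holds 0-based
    positions into the bank's item list.  ``score``/``t_resp`` are None in
    accuracy mode.
    """

    bank: ItemBank
    theta_true: np.ndarray
    item_idx: np.ndarray
    y: np.ndarray
    t_resp: np.ndarray | None
    score: np.ndarray | None
    mode: str
    time_limit: float


def simulate_stream(
    bank: ItemBank,
    learners: list[LearnerAbility],
    mode: str = "accuracy",
    seed=None,
    time_limit: float = 1.0,
    hshs_accuracy: str = "joint",
) -> SessionStream:
    """Simulate full sessions (one bank permutation per learner).

    Per-learner randomness comes from independent child generators spawned
    from ``seed``, so the stream is invariant to learner processing order.
    ``hshs_accuracy='joint'`` derives Y from the sampled score (the
    default); ``'marginal'`` redraws Y from the accuracy model with times
    attached from an independent score draw.
    """
    if mode not in ("accuracy", "hshs"):
        raise ValueError(f"mode must be 'accuracy'|'hshs', got {mode!r}")
    n = len(learners)
    t_max = len(bank)
    theta = np.stack([l.theta_true for l in learners])
    beta = bank.difficulties
    slopes = bank.gen_slopes

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n)

    item_idx = np.empty((n, t_max), dtype=np.int64)
    u_out = np.empty((n, t_max))
    u_acc = np.empty((n, t_max))
    for i in range(n):
        rng = np.random.default_rng(children[i])
        item_idx[i] = rng.permutation(t_max)
        u_out[i] = rng.random(t_max)
        u_acc[i] = rng.random(t_max)

    # true logit per (learner, occasion)
    eta = (theta @ slopes.T)[np.arange(n)[:, None], item_idx] - beta[item_idx]

    if mode == "accuracy":
        y = (u_out < expit(eta)).astype(np.int8)
        return SessionStream(bank, theta, item_idx, y, None, None, mode, time_limit)

    s = sample_score(eta, u_out, time_limit)
    if hshs_accuracy == "joint":
        y = (s > 0).astype(np.int8)
        s = np.where(y == 1, np.abs(s), -np.abs(s))  # no-op; keeps identity explicit
    elif hshs_accuracy == "marginal":
        y = (u_acc < expit(eta * time_limit)).astype(np.int8)
        s = np.where(y == 1, np.abs(s), -np.abs(s))
    else:
        raise ValueError(f"hshs_accuracy must be 'joint'|'marginal', got {hshs_accuracy!r}")
    t_resp = time_limit - np.abs(s)
    return SessionStream(bank, theta, item_idx, y, t_resp, s, mode, time_limit)


def stream_outcomes(stream: SessionStream, outcome: str) -> np.ndarray:
    """The outcome array an engine of the given kind consumes."""
    if outcome == "accuracy":
        return stream.y.astype(float)
    if stream.score is None:
        raise ValueError("stream has no scores; simulate with mode='hshs'")
    return stream.score


def run_session(
    bank: ItemBank,
    learners: list[LearnerAbility],
    config: _engine.EngineConfig,
    mode: str | None = None,
    seed=None,
    time_limit: float = 1.0,
) -> pd.DataFrame:
    """Simulate sessions and score them through one engine.

    Returns the chronological interaction log (sorted by learner, then
    occasion) with the engine's pre-update prediction attached.  Columns:
    learner_id, item_id, occasion (1-based), y, t_resp, score, predicted,
    mode.
    """
    if config.n_dims != bank.n_dims and config.mode == "multi":
        raise ValueError("engine dimensionality does not match bank")
    stream_mode = mode or ("hshs" if config.outcome == "hshs" else "accuracy")
    if config.outcome == "hshs" and stream_mode != "hshs":
        raise ValueError("an HSHS engine needs an HSHS stream")
    stream = simulate_stream(bank, learners, stream_mode, seed, time_limit)
    preds, _ = _engine.replay_arrays(
        config,
        stream.item_idx,
        stream_outcomes(stream, config.outcome),
        bank.difficulties,
        bank.loadings,
    )
    n, t_max = stream.item_idx.shape
    item_ids = np.array([it.item_id for it in bank.items])
    frame = pd.DataFrame(
        {
            "learner_id": np.repeat([l.learner_id for l in learners], t_max),
            "item_id": item_ids[stream.item_idx].ravel(),
            "occasion": np.tile(np.arange(1, t_max + 1), n),
            "y": stream.y.ravel(),
            "t_resp": np.nan if stream.t_resp is None else stream.t_resp.ravel(),
            "score": np.nan if stream.score is None else stream.score.ravel(),
            "predicted": preds.ravel(),
            "mode": f"{config.mode}-{config.outcome}",
        }
    )
    return frame
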