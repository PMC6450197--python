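"""Elo update machinery: step schedule, predictions, updates, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from mers.engine import (
    EngineConfig,
    StepSchedule,
    init_state,
    predict,
    replay_arrays,
    state_from_json,
    state_to_json,
    step_size,
    update,
)
from mers.item_bank import Item
from mers.scores import mean_score, sample_score

from conftest import make_item

LOGISTIC_1 = 0.7310585786300049


@pytest.mark.parametrize(
    "t, expected", [(0, 0.4), (199, 0.1), (500, 0.1), (99, 0.4 - 0.3 * 99 / 199)]
)
def test_step_size_linear_decay_with_clamp(t, expected):
    sched = StepSchedule(0.4, 0.1, 200)
    assert step_size(sched, t) == pytest.approx(expected)


def test_step_schedule_validation():
    with pytest.raises(ValueError):
        StepSchedule(0.1, 0.4, 200)
    with pytest.raises(ValueError):
        StepSchedule(0.4, 0.1, 1)


def test_predict_uni_logistic():
    cfg = EngineConfig(mode="uni", n_dims=1)
    state = init_state(cfg)
    assert predict(cfg, state, Item(1, 0.0, (1,), (1.0,))) == pytest.approx(0.5)
    state.theta_hat[0] = 1.0
    assert predict(cfg, state, Item(1, 0.0, (1,), (1.0,))) == pytest.approx(LOGISTIC_1)
    # monotone in theta_hat
    probs = []
    for th in np.linspace(-3, 3, 13):
        state.theta_hat[0] = th
        probs.append(predict(cfg, state, Item(1, 0.3, (1,), (1.0,))))
    assert np.all(np.diff(probs) > 0)


def test_predict_multi_only_loaded_dimensions_enter():
    cfg = EngineConfig(mode="multi", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array([0.5, -0.5, 9.0])
    # dim 3 is excluded; 0.5 - 0.5 - 0 = 0
    assert predict(cfg, state, make_item(0.0, (1, 1, 0))) == pytest.approx(0.5)
    state.theta_hat = np.array([1.0, 1.0, 1.0])
    assert predict(cfg, state, make_item(3.0, (1, 1, 1))) == pytest.approx(0.5)


def test_single_loading_item_reduces_to_uni():
    multi = EngineConfig(mode="multi", n_dims=3)
    uni = EngineConfig(mode="uni", n_dims=1)
    sm = init_state(multi)
    sm.theta_hat = np.array([9.0, 0.7, -3.0])
    su = init_state(uni)
    su.theta_hat = np.array([0.7])
    item_m = make_item(0.4, (0, 1, 0))
    item_u = Item(1, 0.4, (1,), (1.0,))
    assert predict(multi, sm, item_m) == pytest.approx(predict(uni, su, item_u))


def test_expected_hshs_values_and_limits():
    cfg = EngineConfig(mode="multi", outcome="hshs", n_dims=3)
    state = init_state(cfg)
    item = make_item(0.0, (1, 1, 1))
    assert predict(cfg, state, item) == pytest.approx(0.0)
    state.theta_hat = np.array([1.0, 1.0, 0.0])  # eta = 2
    assert predict(cfg, state, item) == pytest.approx(0.5373147207, abs=1e-9)
    state.theta_hat = np.array([20.0, 20.0, 20.0])
    assert 0.98 < predict(cfg, state, item) < 1.0


def test_update_hand_computed_example():
    """Y=1 against P=logistic(1): each loaded dimension moves by K(Y-P)."""
    cfg = EngineConfig(mode="multi", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array([0.5, 0.5, 0.0])  # eta = 1 for a (1,1,0) item
    update(cfg, state, make_item(0.0, (1, 1, 0)), 1)
    delta = state.theta_hat - np.array([0.5, 0.5, 0.0])
    expected = 0.4 * (1 - LOGISTIC_1)  # 0.10758
    assert delta == pytest.approx([expected, expected, 0.0], abs=1e-9)
    assert expected == pytest.approx(0.10758, abs=5e-6)
    assert state.n_answered == 1


def test_zero_innovation_is_noop_hshs():
    cfg = EngineConfig(mode="multi", outcome="hshs", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array([0.8, 0.2, -0.4])
    item = make_item(0.3, (1, 1, 0))
    s_expected = predict(cfg, state, item)
    update(cfg, state, item, s_expected)
    assert state.theta_hat == pytest.approx([0.8, 0.2, -0.4], abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    theta=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    beta=st.floats(-5, 5),
    y=st.integers(0, 1),
    t=st.integers(0, 400),
    loadings=st.sampled_from([(1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1)]),
)
def test_bounded_innovation_accuracy(theta, beta, y, t, loadings):
    """|delta theta_m| <= K(t) for every accuracy update."""
    cfg = EngineConfig(mode="multi", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array(theta)
    state.n_answered = t
    k = step_size(cfg.schedule, t)
    before = state.theta_hat.copy()
    update(cfg, state, make_item(beta, loadings), y)
    assert np.all(np.abs(state.theta_hat - before) <= k + 1e-12)


@settings(max_examples=200, deadline=None)
@given(
    theta=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    beta=st.floats(-5, 5),
    u=st.floats(0, 0.999999),
    t=st.integers(0, 400),
)
def test_bounded_innovation_hshs(theta, beta, u, t):
    """|delta theta_m| <= 2 d K(t) for every score update."""
    cfg = EngineConfig(mode="multi", outcome="hshs", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array(theta)
    state.n_answered = t
    k = step_size(cfg.schedule, t)
    s = float(sample_score(np.array(theta)[:2].sum() - beta, u))
    before = state.theta_hat.copy()
    update(cfg, state, make_item(beta, (1, 1, 0)), s)
    assert np.all(np.abs(state.theta_hat - before) <= 2 * cfg.time_limit * k + 1e-12)


def test_update_direction_follows_gradient_sign():
    """Accuracy updates move along the single-observation likelihood gradient."""
    cfg = EngineConfig(mode="multi", n_dims=3)
    for y in (0, 1):
        state = init_state(cfg)
        state.theta_hat = np.array([0.2, -0.1, 0.0])
        item = make_item(0.5, (1, 1, 0))
        p = predict(cfg, state, item)
        before = state.theta_hat.copy()
        update(cfg, state, item, y)
        delta = state.theta_hat - before
        assert np.sign(delta[0]) == np.sign(y - p)
        assert np.sign(delta[1]) == np.sign(y - p)
        assert delta[2] == 0.0


def test_martingale_calibration(rng):
    """Outcomes drawn from the engine's own prediction give mean-zero updates."""
    cfg = EngineConfig(mode="multi", n_dims=3)
    state = init_state(cfg)
    state.theta_hat = np.array([0.4, -0.2, 0.0])
    item = make_item(0.3, (1, 1, 0))
    p = predict(cfg, state, item)
    n = 100_000
    ys = (rng.random(n) < p).astype(float)
    deltas = 0.4 * (ys - p)
    assert abs(deltas.mean()) < 3 * deltas.std() / np.sqrt(n)


def test_convergence_with_more_items():
    """Estimates after 200 updates beat estimates after 20 in >=90% of runs.

    One learner per replication, true ability 3 (far from the origin), item
    difficulties spanning the scale.
    """
    cfg = EngineConfig(mode="uni", n_dims=1)
    theta_true = 3.0
    wins = 0
    for rep in range(100):
        rng = np.random.default_rng(rep)
        state = init_state(cfg)
        for t, beta in enumerate(rng.uniform(-4, 4, 200)):
            item = Item(1, float(beta), (1,), (1.0,))
            p = predict(cfg, state, item)
            y = int(rng.random() < expit(theta_true - beta))
            update(cfg, state, item, y)
            if t == 19:
                err20 = abs(state.theta_hat[0] - theta_true)
        wins += abs(state.theta_hat[0] - theta_true) < err20
    assert wins >= 90


def test_init_states_are_independent():
    cfg = EngineConfig(mode="multi", n_dims=3)
    a = init_state(cfg)
    b = init_state(cfg)
    a.theta_hat[0] = 5.0
    assert b.theta_hat[0] == 0.0
    assert a.n_answered == 0


def test_outcome_validation():
    cfg = EngineConfig(mode="multi", n_dims=3)
    with pytest.raises(ValueError, match="0/1"):
        update(cfg, init_state(cfg), make_item(), 0.5)
    cfg_h = EngineConfig(mode="multi", outcome="hshs", n_dims=3)
    with pytest.raises(ValueError, match="score"):
        update(cfg_h, init_state(cfg_h), make_item(), 1.5)


def test_state_json_round_trip():
    cfg = EngineConfig(mode="multi", n_dims=3)
    state = init_state(cfg, learner_id=42)
    update(cfg, state, make_item(0.1, (1, 0, 1)), 1)
    restored = state_from_json(state_to_json(state))
    assert restored.learner_id == 42
    assert restored.n_answered == 1
    assert restored.theta_hat == pytest.approx(state.theta_hat)


def test_spillover_weights_update_unloaded_dimensions():
    cfg = EngineConfig(mode="multi", n_dims=3, d_weights_off=0.5)
    state = init_state(cfg)
    item = make_item(0.0, (1, 0, 0))
    update(cfg, state, item, 1)
    full = state.theta_hat[0]
    assert state.theta_hat[1] == pytest.approx(0.5 * full)
    assert state.theta_hat[2] == pytest.approx(0.5 * full)


def test_replay_matches_sequential_updates(bank1, rng):
    """The vectorised replay equals per-interaction updates, per learner."""
    cfg = EngineConfig(mode="multi", n_dims=3)
    n, t_max = 4, 30
    item_idx = np.stack([rng.permutation(len(bank1))[:t_max] for _ in range(n)])
    outcomes = rng.integers(0, 2, size=(n, t_max)).astype(float)
    preds, traj = replay_arrays(
        cfg, item_idx, outcomes, bank1.difficulties, bank1.loadings
    )
    for i in range(n):
        state = init_state(cfg, learner_id=i)
        for t in range(t_max):
            item = bank1.items[item_idx[i, t]]
            assert predict(cfg, state, item) == pytest.approx(preds[i, t])
            update(cfg, state, item, outcomes[i, t])
            assert state.theta_hat == pytest.approx(traj[i, t])
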