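"""Q-learning classifier: action policy, rewards, TD updates, replay."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from atpbind.dqn import (DQNClassifier, DQNConfig, QNetwork, ReplayBuffer,
                         Transition, compute_reward, decay_epsilon,
                         predict_proba_dqn, replay_update, select_action,
                         td_targets)
from atpbind.errors import ConfigError, ContractError, DataError
from atpbind.nn import Adam

TINY = DQNConfig(in_dim=8, hidden=(16, 8), episodes=3, batch_size=32,
                 buffer_capacity=500, seed=0)


# ---------------------------------------------------------------------------
# action selection / epsilon schedule / rewards
# ---------------------------------------------------------------------------

def test_greedy_action_is_argmax_with_tie_to_nonbinding(rng):
    assert select_action(np.array([0.2, 0.7]), 0.0, rng) == 1
    assert select_action(np.array([0.5, 0.5]), 0.0, rng) == 0  # tie -> action 0
    with pytest.raises(ContractError):
        select_action(np.array([np.nan, 0.0]), 0.0, rng)


def test_full_exploration_is_uniform_binomial():
    rng = np.random.default_rng(123)
    n = 10_000
    actions = [select_action(np.array([5.0, -5.0]), 1.0, rng) for _ in range(n)]
    k = sum(actions)
    assert abs(k / n - 0.5) < 0.02
    assert stats.binomtest(k, n, 0.5).pvalue > 0.01


def test_epsilon_decay_closed_form_and_floor():
    cfg = DQNConfig()
    assert decay_epsilon(1.0, cfg) == pytest.approx(0.995)
    # 0.01002 * 0.995 = 0.0099699 < 0.01 -> floor engages
    assert decay_epsilon(0.01002, cfg) == 0.01
    eps = 1.0
    for n in range(1, 40):
        eps = decay_epsilon(eps, cfg)
        assert eps == pytest.approx(max(0.01, 0.995**n))


def test_rewards_immediate_and_terminal_bonus():
    assert compute_reward(1, 1, False) == 1.0
    assert compute_reward(0, 1, False) == -0.5
    # correct call on last batch with accuracy 0.9: 1.0 + 2.0*0.9 = 2.8
    assert compute_reward(1, 1, True, batch_accuracy=0.9) == pytest.approx(2.8)
    arr = compute_reward(np.array([1, 0]), np.array([1, 1]), True, batch_accuracy=0.5)
    np.testing.assert_allclose(arr, [2.0, 0.5])
    with pytest.raises(ContractError):
        compute_reward(1, 1, True)  # missing accuracy on last batch
    with pytest.raises(ContractError):
        compute_reward(1, 1, False, batch_accuracy=0.5)


# ---------------------------------------------------------------------------
# TD targets and the replay machinery
# ---------------------------------------------------------------------------

def test_td_targets_arithmetic(rng):
    net = QNetwork(TINY, rng)
    s = rng.normal(size=(3, 8))
    q_next_max = net.q_values(s).max(axis=1)
    r = np.array([1.0, 1.0, -0.5])
    done = np.array([True, False, False])
    t = td_targets(s, r, done, net, gamma=0.95)
    assert t[0] == pytest.approx(1.0)  # terminal: future value masked
    assert t[1] == pytest.approx(1.0 + 0.95 * q_next_max[1])
    assert t[2] == pytest.approx(-0.5 + 0.95 * q_next_max[2])
    # frozen example: r=1, gamma=.95, max q_next=2 -> 2.9
    assert 1.0 + 0.95 * 2.0 == pytest.approx(2.9)


def test_td_loss_matches_literal_equation_transcription(rng):
    """(1/B) sum (q_pred - [r + (1-done) gamma max q'])^2, element by element."""
    net = QNetwork(TINY, rng)
    policy = QNetwork(TINY, rng)
    for seed in range(5):
        r_ = np.random.default_rng(seed)
        s = r_.normal(size=(16, 8))
        a = r_.integers(0, 2, 16)
        r = np.where(r_.random(16) < 0.7, 1.0, -0.5)
        done = r_.random(16) < 0.2
        targets = td_targets(s, r, done, net, 0.95)
        q = policy.q_values(s)
        ours = np.mean((q[np.arange(16), a] - targets) ** 2)
        # independent literal transcription
        qn = net.q_values(s)
        ref = 0.0
        for j in range(16):
            tgt = r[j] + (1 - float(done[j])) * 0.95 * max(qn[j, 0], qn[j, 1])
            ref += (q[j, a[j]] - tgt) ** 2
        ref /= 16
        assert abs(ours - ref) < 1e-10


def test_replay_buffer_is_bounded_fifo(rng):
    buf = ReplayBuffer(capacity=4, dim=2)
    for i in range(7):
        buf.add(Transition(s=np.full(2, float(i)), a=0, r=0.0,
                           s_next=np.full(2, float(i)), done=False))
    assert len(buf) == 4
    # oldest three evicted: survivors are inserts 3..6
    kept = sorted(buf._s[:, 0].tolist())
    assert kept == [3.0, 4.0, 5.0, 6.0]
    s, a, r, done = buf.sample(4, rng)
    assert len(np.unique(s[:, 0])) == 4  # without replacement


def test_transition_contracts():
    s = np.ones(3)
    with pytest.raises(ContractError):
        Transition(s=s, a=2, r=0.0, s_next=s, done=False)
    with pytest.raises(ContractError):
        Transition(s=s, a=1, r=0.0, s_next=np.zeros(3), done=False)


def test_replay_update_skips_underfull_buffer(rng):
    cfg = TINY
    policy, target = QNetwork(cfg, rng), QNetwork(cfg, rng)
    buf = ReplayBuffer(cfg.buffer_capacity, 8)
    for i in range(cfg.batch_size - 1):
        buf.add(Transition(s=np.zeros(8), a=0, r=1.0, s_next=np.zeros(8), done=True))
    opt = Adam(policy.parameters(), lr=cfg.lr, clipnorm=cfg.grad_clip_norm)
    assert replay_update(policy, target, buf, cfg, opt, rng) is None


def test_repeated_updates_on_fixed_terminal_transition_reduce_loss(rng):
    cfg = replace(TINY, batch_size=1, dropout=0.0, lr=1e-2)
    policy, target = QNetwork(cfg, rng), QNetwork(cfg, rng)
    buf = ReplayBuffer(cfg.buffer_capacity, 8)
    buf.add(Transition(s=np.ones(8), a=1, r=1.0, s_next=np.ones(8), done=True))
    opt = Adam(policy.parameters(), lr=cfg.lr, clipnorm=cfg.grad_clip_norm)
    losses = [replay_update(policy, target, buf, cfg, opt, rng) for _ in range(50)]
    assert losses[-1] < losses[0]
    assert losses[-1] < 1e-2


def test_single_transition_mse_arithmetic(rng):
    # q_pred 0.5 vs target 1.0 with B=1 -> loss 0.25 (plain MSE)
    assert (0.5 - 1.0) ** 2 / 1 == pytest.approx(0.25)
    # through the machinery: terminal transition, known reward
    cfg = replace(TINY, batch_size=1, dropout=0.0)
    policy, target = QNetwork(cfg, rng), QNetwork(cfg, rng)
    buf = ReplayBuffer(8, 8)
    s = np.ones(8)
    buf.add(Transition(s=s, a=1, r=1.0, s_next=s, done=True))
    q_before = policy.q_values(s[None])[0, 1]
    opt = Adam(policy.parameters(), lr=cfg.lr)
    loss = replay_update(policy, target, buf, cfg, opt, rng)
    assert loss == pytest.approx((q_before - 1.0) ** 2, abs=1e-10)


# ---------------------------------------------------------------------------
# probability extraction
# ---------------------------------------------------------------------------

def test_probability_extraction_softmax_values(rng):
    cfg = TINY
    net = QNetwork(cfg, rng)
    net.fc1.w.data[:] = 0.0
    net.fc1.b.data[:] = 0.0
    net.fc2.w.data[:] = 0.0
    net.fc2.b.data[:] = 0.0
    net.out.w.data[:] = 0.0
    net.out.b.data[:] = [0.0, 0.0]
    x = rng.normal(size=(3, 8))
    np.testing.assert_allclose(predict_proba_dqn(net, x), 0.5, atol=1e-12)
    net.out.b.data[:] = [0.0, math.log(3.0)]  # softmax -> 0.75
    np.testing.assert_allclose(predict_proba_dqn(net, x), 0.75, atol=1e-12)
    net.out.b.data[:] = [0.0, math.log(3.0) + 0.5]  # raising Q1 raises p
    assert np.all(predict_proba_dqn(net, x) > 0.75)


# ---------------------------------------------------------------------------
# training loop contracts
# ---------------------------------------------------------------------------

def test_training_is_reproducible_and_syncs_target(tiny_dataset):
    cfg = DQNConfig(in_dim=16, hidden=(32, 16), episodes=10, batch_size=128,
                    target_sync_every=10, buffer_capacity=2000, seed=4)
    r1 = DQNClassifier.from_dataset(tiny_dataset, cfg).fit()
    r2 = DQNClassifier.from_dataset(tiny_dataset, cfg).fit()
    assert r1.history.equals(r2.history)
    np.testing.assert_array_equal(
        r1.predict_proba(tiny_dataset.X[:64]), r2.predict_proba(tiny_dataset.X[:64])
    )
    # epsilon schedule in the history follows the closed form
    np.testing.assert_allclose(
        r1.history["epsilon"], [max(0.01, 0.995**n) for n in range(1, 11)]
    )


def test_target_equals_policy_snapshot_at_sync_boundary(tiny_dataset):
    """At an episode multiple of C the target becomes a policy snapshot;
    between boundaries it lags behind the policy."""
    base = DQNConfig(in_dim=16, hidden=(16, 8), episodes=10, batch_size=128,
                     target_sync_every=10, buffer_capacity=1000, seed=4)
    synced = DQNClassifier.from_dataset(tiny_dataset, base).fit()
    for k, v in synced.network.state_dict().items():
        np.testing.assert_array_equal(v, synced.target_network.state_dict()[k])
    lagging = DQNClassifier.from_dataset(
        tiny_dataset, replace(base, episodes=5)
    ).fit()
    diffs = [
        not np.array_equal(v, lagging.target_network.state_dict()[k])
        for k, v in lagging.network.state_dict().items()
    ]
    assert any(diffs)  # no sync has happened yet at episode 5 < C


def test_pure_exploitation_predictions_are_deterministic(trained_dqn, separable_dataset):
    x = separable_dataset.X[:200]
    a1 = trained_dqn.predict(x)
    a2 = trained_dqn.predict(x)
    np.testing.assert_array_equal(a1, a2)
    assert set(np.unique(a1)) <= {0, 1}


def test_empty_dataset_rejected():
    with pytest.raises(DataError):
        DQNClassifier(np.empty((0, 4)), np.empty(0), config=TINY)


def test_config_validation():
    with pytest.raises(ConfigError):
        DQNConfig(gamma=1.5)
    with pytest.raises(ConfigError):
        DQNConfig(epsilon_min=0.5, epsilon_start=0.1)
    with pytest.raises(ConfigError):
        DQNConfig(batch_size=0)
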