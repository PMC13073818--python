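"""Deep Q-network residue classifier.

Residue-level binary classification framed as a one-step decision process:
the state is a residue's embedding, the action is the predicted class
(0 = non-binding, 1 = binding). Action selection is epsilon-greedy with a
multiplicative epsilon decay per episode; rewards are +1.0 for a correct
call and -0.5 for a wrong one, plus a terminal bonus of 2.0 x batch
accuracy added to every transition of an episode's last batch. Transitions
(s, a, r, s' = s, done) go to a bounded FIFO replay buffer; the policy
network is trained on uniformly sampled mini-batches against a target
network (synchronised every C episodes) with the squared temporal-
difference error

    L = mean( (Q(s, a) - [r + (1 - done) * gamma * max_a' Qhat(s', a')])^2 ).

The policy/target architecture is a feedforward map in_dim -> 512 -> 256
-> 2 with ReLU activations, dropout 0.3 during updates, Glorot-uniform
initialisation and a linear output (two Q-values). For ensembling, the
probability of the binding class is the softmax over the two Q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, DataError
from .evaluation import optimal_threshold_by_mcc
from .features import FeatureStandardizer
from .nn import Adam, Linear, Module, Tensor, as_tensor
from .nn.layers import dropout as _dropout

__all__ = [
    "DQNConfig",
    "QNetwork",
    "Transition",
    "ReplayBuffer",
    "select_action",
    "compute_reward",
    "decay_epsilon",
    "td_targets",
    "replay_update",
    "predict_proba_dqn",
    "DQNClassifier",
    "DQNResults",
]


@dataclass(frozen=True)
class DQNConfig:
    """Hyperparameters of the Q-learning classifier (published defaults)."""

    in_dim: int = 1280
    hidden: tuple[int, int] = (512, 256)
    dropout: float = 0.3
    gamma: float = 0.95
    lr: float = 1e-4
    grad_clip_norm: float = 1.0
    epsilon_start: float = 1.0
    epsilon_min: float = 0.01
    epsilon_decay: float = 0.995
    target_sync_every: int = 10  # C episodes
    reward_correct: float = 1.0
    reward_wrong: float = -0.5
    terminal_coeff: float = 2.0
    buffer_capacity: int = 50_000
    batch_size: int = 256
    episodes: int = 50
    oversample: bool = False  # natural class frequencies by default
    standardize: bool = True
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ConfigError("gamma must be in (0, 1)")
        if not 0.0 <= self.epsilon_min <= self.epsilon_start <= 1.0:
            raise ConfigError("need 0 <= epsilon_min <= epsilon_start <= 1")
        if min(self.buffer_capacity, self.batch_size, self.episodes,
               self.target_sync_every, *self.hidden) <= 0:
            raise ConfigError("all sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")


class QNetwork(Module):
    """Feedforward in_dim -> 512 -> 256 -> 2, ReLU, linear Q-value output."""

    def __init__(self, config: DQNConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h1, h2 = config.hidden
        self.fc1 = self.add_module("fc1", Linear(rng, config.in_dim, h1))
        self.fc2 = self.add_module("fc2", Linear(rng, h1, h2))
        self.out = self.add_module("out", Linear(rng, h2, 2))
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x, training: bool = False) -> Tensor:
        x = as_tensor(x)
        if x.shape[-1] != self.config.in_dim:
            raise ContractError(
                f"input dim {x.shape[-1]} != configured {self.config.in_dim}"
            )
        h = self.fc1(x).relu()
        h = _dropout(h, self.config.dropout, self._dropout_rng, training)
        h = self.fc2(h).relu()
        h = _dropout(h, self.config.dropout, self._dropout_rng, training)
        return self.out(h)

    def q_values(self, x: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Inference-mode Q-values, chunked over rows."""
        from .nn.autodiff import no_grad

        x = np.asarray(x, dtype=np.float64)
        if len(x) == 0:
            return np.empty((0, 2))
        with no_grad():
            return np.concatenate(
                [self.forward(x[i : i + chunk]).data for i in range(0, len(x), chunk)]
            )


@dataclass(frozen=True)
class Transition:
    """One stored decision: (s, a, r, s' = s, done)."""

    s: np.ndarray
    a: int
    r: float
    s_next: np.ndarray
    done: bool

    def __post_init__(self):
        if self.a not in (0, 1):
            raise ContractError(f"action must be 0 or 1, got {self.a}")
        if self.s_next is not self.s and not np.array_equal(self.s_next, self.s):
            raise ContractError("s_next must be identical to s by construction")


class ReplayBuffer:
    """Bounded FIFO transition store with uniform mini-batch sampling."""

    def __init__(self, capacity: int, dim: int):
        if capacity <= 0:
            raise ConfigError("capacity must be positive")
        self.capacity = capacity
        self._s = np.empty((capacity, dim))
        self._a = np.empty(capacity, dtype=np.int64)
        self._r = np.empty(capacity)
        self._done = np.empty(capacity, dtype=bool)
        self._pos = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def add(self, transition: Transition) -> None:
        i = self._pos
        self._s[i] = transition.s
        self._a[i] = transition.a
        self._r[i] = transition.r
        self._done[i] = transition.done
        self._pos = (self._pos + 1) % self.capacity  # strict FIFO eviction
        self._size = min(self._size + 1, self.capacity)

    def add_batch(self, s: np.ndarray, a: np.ndarray, r: np.ndarray,
                  done: bool) -> None:
        for row, ai, ri in zip(s, a, r):
            self.add(Transition(s=row, a=int(ai), r=float(ri), s_next=row, done=done))

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform sample without replacement within the mini-batch."""
        if batch_size > self._size:
            raise ContractError(f"buffer holds {self._size} < batch {batch_size}")
        idx = rng.choice(self._size, size=batch_size, replace=False)
        return self._s[idx], self._a[idx], self._r[idx], self._done[idx]


def select_action(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy over two Q-values; greedy ties resolve to action 0."""
    q = np.asarray(q, dtype=float)
    if q.shape != (2,) or not np.all(np.isfinite(q)):
        raise ContractError("q must be two finite action values")
    if not 0.0 <= epsilon <= 1.0:
        raise ContractError(f"epsilon {epsilon} outside [0, 1]")
    if rng.random() < epsilon:
        return int(rng.integers(0, 2))
    return int(np.argmax(q))  # argmax returns the first maximum -> tie = 0


def _select_actions_batch(q: np.ndarray, epsilon: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Vectorised epsilon-greedy with the same semantics as select_action."""
    if not np.all(np.isfinite(q)):
        raise ContractError("non-finite Q-values")
    explore = rng.random(len(q)) < epsilon
    random_a = rng.integers(0, 2, size=len(q))
    greedy = np.argmax(q, axis=1)
    return np.where(explore, random_a, greedy).astype(np.int64)


def compute_reward(a, y, is_last_batch: bool,
                   batch_accuracy: float | None = None):
    """Immediate +1.0 / -0.5 reward, plus 2.0 x batch accuracy on the last batch."""
    a = np.asarray(a)
    y = np.asarray(y)
    r = np.where(a == y, 1.0, -0.5)
    if is_last_batch:
        if batch_accuracy is None or not 0.0 <= batch_accuracy <= 1.0:
            raise ContractError("last batch requires batch_accuracy in [0, 1]")
        r = r + 2.0 * batch_accuracy
    elif batch_accuracy is not None:
        raise ContractError("batch_accuracy is only supplied on the last batch")
    return r if r.ndim else float(r)


def decay_epsilon(epsilon: float, config: DQNConfig) -> float:
    """Multiplicative decay floored at epsilon_min: max(eps_min, eps * rate)."""
    return max(config.epsilon_min, epsilon * config.epsilon_decay)


def td_targets(s_next: np.ndarray, r: np.ndarray, done: np.ndarray,
               target_net: QNetwork, gamma: float) -> np.ndarray:
    """Per-sample targets r + (1 - done) * gamma * max_a Qhat(s', a).

    No gradient flows through the target network (plain arrays in, plain
    arrays out).
    """
    if len(r) == 0:
        raise ContractError("empty transition batch")
    q_next = target_net.q_values(s_next)
    return r + (1.0 - done.astype(float)) * gamma * q_next.max(axis=1)


def replay_update(policy_net: QNetwork, target_net: QNetwork,
                  buffer: ReplayBuffer, config: DQNConfig,
                  optimizer: Adam, rng: np.random.Generator) -> float | None:
    """One gradient step on the squared TD error; None if the buffer is underfull."""
    if len(buffer) < config.batch_size:
        return None  # Algorithm guard: skip until the buffer can fill a batch
    s, a, r, done = buffer.sample(config.batch_size, rng)
    targets = td_targets(s, r, done, target_net, config.gamma)
    q = policy_net.forward(s, training=True)
    onehot = np.zeros((len(a), 2))
    onehot[np.arange(len(a)), a] = 1.0
    q_pred = (q * Tensor(onehot)).sum(axis=1)
    loss = ((q_pred - Tensor(targets)) ** 2).mean()
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item()


def predict_proba_dqn(policy_net: QNetwork, features: np.ndarray,
                      temperature: float = 1.0) -> np.ndarray:
    """P(binding) = softmax over the two Q-values (temperature 1 by default)."""
    q = policy_net.q_values(features) / temperature
    shifted = q - q.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e[:, 1] / e.sum(axis=1)


# ---------------------------------------------------------------------------
# model / results (fit interface)
# ---------------------------------------------------------------------------

class DQNResults:
    """Fitted Q-learning classifier with its per-episode history."""

    def __init__(self, network, standardizer, history, train_accuracy, validation,
                 config, target_network=None):
        self.network = network
        self.target_network = target_network
        self.standardizer = standardizer
        self.history = history
        self.train_accuracy = train_accuracy
        self.validation = validation
        self.config = config

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.standardizer is not None:
            x = self.standardizer.transform(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return predict_proba_dqn(self.network, self._prepare(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Greedy (pure-exploitation) class decisions."""
        q = self.network.q_values(self._prepare(x))
        return np.argmax(q, axis=1)

    def summary(self) -> str:
        lines = [
            "Deep Q-network classifier",
            f"  episodes: {len(self.history)}  final epsilon "
            f"{self.history['epsilon'].iloc[-1]:.4f}",
            f"  greedy training accuracy: {self.train_accuracy:.3f}",
        ]
        if self.validation is not None:
            lines.append(f"  validation: {self.validation.summary()}")
        return "\n".join(lines)


class DQNClassifier:
    """Model object: per-residue features + labels -> fitted Q-network."""

    def __init__(self, X, y, groups=None, config: DQNConfig | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y).astype(int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ContractError("X must be (n, dim) aligned with y")
        if self.y.size == 0:
            raise DataError("empty dataset")
        self.groups = groups
        cfg = config or DQNConfig()
        if cfg.in_dim != self.X.shape[1]:
            cfg = replace(cfg, in_dim=self.X.shape[1])
        self.config = cfg

    @classmethod
    def from_dataset(cls, dataset, config: DQNConfig | None = None):
        return cls(dataset.X, dataset.y, groups=dataset.groups, config=config)

    def fit(self, verbose: bool = False) -> DQNResults:
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        rng_init, rng_shuffle, rng_explore, rng_replay = (
            np.random.default_rng(s) for s in ss.spawn(4)
        )

        x, y = self.X, self.y
        standardizer = None
        if cfg.standardize:
            standardizer = FeatureStandardizer().fit(x)
            x = standardizer.transform(x)

        policy = QNetwork(cfg, rng_init)
        target = QNetwork(cfg, rng_init)
        target.load_state_dict(policy.state_dict())
        optimizer = Adam(policy.parameters(), lr=cfg.lr,
                         clipnorm=cfg.grad_clip_norm)
        buffer = ReplayBuffer(cfg.buffer_capacity, x.shape[1])

        n = len(y)
        b = min(cfg.batch_size, n)
        epsilon = cfg.epsilon_start
        rows = []
        pos_idx = np.flatnonzero(y == 1)
        for episode in range(1, cfg.episodes + 1):
            epsilon = decay_epsilon(epsilon, cfg)
            order = rng_shuffle.permutation(n)
            if cfg.oversample and pos_idx.size:
                extra = rng_shuffle.choice(pos_idx, size=pos_idx.size, replace=True)
                order = rng_shuffle.permutation(np.concatenate([order, extra]))
            batches = [order[i : i + b] for i in range(0, len(order), b)]
            rewards, accs, losses = [], [], []
            for k, idx in enumerate(batches):
                s_batch, y_batch = x[idx], y[idx]
                q = policy.q_values(s_batch)
                a = _select_actions_batch(q, epsilon, rng_explore)
                acc = float(np.mean(a == y_batch))
                is_last = k == len(batches) - 1
                r = compute_reward(a, y_batch, is_last,
                                   batch_accuracy=acc if is_last else None)
                buffer.add_batch(s_batch, a, r, done=is_last)
                loss = replay_update(policy, target, buffer, cfg, optimizer,
                                     rng_replay)
                rewards.append(float(np.mean(r)))
                accs.append(acc)
                if loss is not None:
                    losses.append(loss)
            if episode % cfg.target_sync_every == 0:
                target.load_state_dict(policy.state_dict())
            rows.append({
                "episode": episode, "epsilon": epsilon,
                "mean_reward": float(np.mean(rewards)),
                "batch_accuracy": float(np.mean(accs)),
                "td_loss": float(np.mean(losses)) if losses else np.nan,
            })
            if verbose:  # pragma: no cover
                print(f"episode {episode}: eps {epsilon:.3f} "
                      f"acc {rows[-1]['batch_accuracy']:.3f}")

        greedy = np.argmax(policy.q_values(x), axis=1)
        train_accuracy = float(np.mean(greedy == y))
        validation = None
        scores = predict_proba_dqn(policy, x)
        if y.min() != y.max():
            _, validation = optimal_threshold_by_mcc(scores, y)
        return DQNResults(
            network=policy, standardizer=standardizer,
            history=pd.DataFrame(rows), train_accuracy=train_accuracy,
            validation=validation, config=cfg, target_network=target,
        )
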