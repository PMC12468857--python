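"""Deep Q-Network training harness.

Standard deep Q-learning with experience replay and a hard-updated target
network, written directly on NumPy:

* Q-network: fully connected MLP, two hidden layers of 64 ReLU units,
  linear output head over the 4 discrete actions;
* epsilon-greedy behaviour policy with a linear schedule;
* Huber (smooth-L1) temporal-difference loss, Adam optimizer, global
  gradient-norm clipping;
* a checkpoint is snapshotted periodically and evaluated greedily on a
  fixed set of randomized episodes; the best checkpoint by mean episode
  reward is selected after training.

Default hyperparameters follow the widely used library defaults for DQN on
low-dimensional inputs (learning rate 1e-4, buffer 1e6, batch 32,
gamma 0.99, train frequency 4, target update every 10k steps, epsilon
1.0 -> 0.05 over the first 10% of training).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:  # compiled kernels for the two-hidden-layer fast path
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco(args[0]) if args and callable(args[0]) else deco

from .evaluation import mse_from_cooling

__all__ = [
    "DQNConfig",
    "QNetwork",
    "QPolicy",
    "ReplayBuffer",
    "Checkpoint",
    "train",
    "evaluate_checkpoint",
    "select_best",
]


# -- compiled kernels (two-hidden-layer fast path) --------------------------


@_njit(cache=False)
def _q2_single(x, W0, b0, W1, b1, W2, b2):
    h0 = np.dot(x, W0) + b0
    h0 = np.maximum(h0, 0.0)
    h1 = np.dot(h0, W1) + b1
    h1 = np.maximum(h1, 0.0)
    return np.dot(h1, W2) + b2


@_njit(cache=False)
def _q2_batch_max(x, W0, b0, W1, b1, W2, b2):
    B = x.shape[0]
    h0 = np.dot(x, W0)
    for i in range(B):
        for j in range(h0.shape[1]):
            h0[i, j] += b0[j]
            if h0[i, j] < 0.0:
                h0[i, j] = 0.0
    h1 = np.dot(h0, W1)
    for i in range(B):
        for j in range(h1.shape[1]):
            h1[i, j] += b1[j]
            if h1[i, j] < 0.0:
                h1[i, j] = 0.0
    q = np.dot(h1, W2)
    out = np.empty(B, dtype=np.float64)
    for i in range(B):
        m = q[i, 0] + b2[0]
        for a in range(1, q.shape[1]):
            v = q[i, a] + b2[a]
            if v > m:
                m = v
        out[i] = m
    return out


@_njit(cache=False)
def _huber2_backward(obs, actions, targets, W0, b0, W1, b1, W2, b2, grad, clip):
    B = obs.shape[0]
    a0 = np.dot(obs, W0)
    for i in range(B):
        for j in range(a0.shape[1]):
            a0[i, j] += b0[j]
            if a0[i, j] < 0.0:
                a0[i, j] = 0.0
    a1 = np.dot(a0, W1)
    for i in range(B):
        for j in range(a1.shape[1]):
            a1[i, j] += b1[j]
            if a1[i, j] < 0.0:
                a1[i, j] = 0.0
    q = np.dot(a1, W2)
    loss = 0.0
    dq = np.zeros_like(q)
    for i in range(B):
        a = actions[i]
        d = q[i, a] + b2[a] - targets[i]
        ad = abs(d)
        loss += 0.5 * d * d if ad < 1.0 else ad - 0.5
        g = d
        if g > 1.0:
            g = 1.0
        elif g < -1.0:
            g = -1.0
        dq[i, a] = g / B
    loss /= B

    gW2 = np.dot(a1.T.copy(), dq)
    gb2 = np.sum(dq, axis=0)
    d1 = np.dot(dq, W2.T.copy())
    for i in range(B):
        for j in range(d1.shape[1]):
            if a1[i, j] <= 0.0:
                d1[i, j] = 0.0
    gW1 = np.dot(a0.T.copy(), d1)
    gb1 = np.sum(d1, axis=0)
    d0 = np.dot(d1, W1.T.copy())
    for i in range(B):
        for j in range(d0.shape[1]):
            if a0[i, j] <= 0.0:
                d0[i, j] = 0.0
    gW0 = np.dot(obs.T.copy(), d0)
    gb0 = np.sum(d0, axis=0)

    o = 0
    for arr in (gW0.ravel(), gb0, gW1.ravel(), gb1, gW2.ravel(), gb2):
        grad[o : o + arr.shape[0]] = arr
        o += arr.shape[0]
    norm = np.sqrt(np.dot(grad, grad))
    if norm > clip:
        grad *= clip / (norm + 1e-6)
    return loss


@_njit(cache=False)
def _adam_kernel(theta, m, v, grad, lr, b1, b2, eps, b1t, b2t):
    for i in range(theta.shape[0]):
        g = grad[i]
        m[i] = b1 * m[i] + (1.0 - b1) * g
        v[i] = b2 * v[i] + (1.0 - b2) * g * g
        theta[i] -= lr * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + eps)


@dataclass(frozen=True)
class DQNConfig:
    """Learning hyperparameters (library-default DQN settings)."""

    learning_rate: float = 1e-4
    buffer_size: int = 1_000_000
    learning_starts: int = 100
    batch_size: int = 32
    tau: float = 1.0
    gamma: float = 0.99
    train_freq: int = 4
    gradient_steps: int = 1
    target_update_interval: int = 10_000
    exploration_fraction: float = 0.1
    epsilon_initial: float = 1.0
    epsilon_final: float = 0.05
    max_grad_norm: float = 10.0
    hidden_layers: tuple[int, ...] = (64, 64)
    total_steps: int = 10_000_000
    checkpoint_interval: int = 50_000
    eval_episodes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon_final > self.epsilon_initial:
            raise ValueError("epsilon_final must not exceed epsilon_initial")
        if self.checkpoint_interval > self.total_steps:
            raise ValueError("checkpoint_interval must not exceed total_steps")
        for name in ("learning_rate", "buffer_size", "batch_size", "total_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class QNetwork:
    """Fully connected ReLU MLP with a linear output layer.

    All parameters live in one flat vector (``theta``); the per-layer
    weight matrices and bias vectors are views into it, so snapshots,
    target-network updates and the optimizer work on a single contiguous
    array.
    """

    def __init__(self, n_in: int, n_out: int, hidden: tuple[int, ...], rng: np.random.Generator):
        sizes = (n_in, *hidden, n_out)
        self.sizes = sizes
        n_params = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
        self.theta = np.empty(n_params, dtype=np.float64)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        off = 0
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            W = self.theta[off : off + fan_in * fan_out].reshape(fan_in, fan_out)
            off += fan_in * fan_out
            b = self.theta[off : off + fan_out]
            off += fan_out
            bound = 1.0 / np.sqrt(fan_in)
            W[...] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            b[...] = rng.uniform(-bound, bound, size=fan_out)
            self.W.append(W)
            self.b.append(b)

    def forward(self, x: np.ndarray, keep: bool = False):
        """Q-values for a batch of observations (B, n_in) -> (B, n_out)."""
        acts = [x]
        h = x
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            if keep:
                acts.append(h)
        q = h @ self.W[-1] + self.b[-1]
        return (q, acts) if keep else q

    def q_single(self, obs: np.ndarray) -> np.ndarray:
        if len(self.W) == 3 and _HAVE_NUMBA:
            return _q2_single(obs, self.W[0], self.b[0], self.W[1], self.b[1],
                              self.W[2], self.b[2])
        h = obs
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.W[-1] + self.b[-1]

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def unflatten(self, vec: np.ndarray) -> list[np.ndarray]:
        """Split a flat vector into arrays matching ``parameters()``."""
        out_W, out_b = [], []
        off = 0
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            out_W.append(vec[off : off + fan_in * fan_out].reshape(fan_in, fan_out))
            off += fan_in * fan_out
            out_b.append(vec[off : off + fan_out])
            off += fan_out
        return out_W + out_b

    def copy_weights(self) -> np.ndarray:
        return self.theta.copy()

    def load_weights(self, weights) -> None:
        if isinstance(weights, np.ndarray):
            self.theta[...] = weights
            return
        n = len(self.W)
        for i in range(n):
            self.W[i][...] = weights[i]
            self.b[i][...] = weights[n + i]

    def soft_update_from(self, other: "QNetwork", tau: float) -> None:
        if tau == 1.0:
            self.theta[...] = other.theta
        else:
            self.theta *= 1.0 - tau
            self.theta += tau * other.theta


class QPolicy:
    """Greedy policy wrapper around a Q-network snapshot."""

    def __init__(self, net: QNetwork, meta: dict | None = None):
        self.net = net
        self.meta = dict(meta or {})

    def predict(self, obs: np.ndarray) -> int:
        return int(np.argmax(self.net.q_single(np.asarray(obs, dtype=np.float64))))

    def q_values(self, obs: np.ndarray) -> np.ndarray:
        return self.net.q_single(np.asarray(obs, dtype=np.float64))

    def save(self, path: str | Path) -> None:
        """Persist as .npz weights plus a JSON metadata sidecar."""
        path = Path(path)
        arrays = {f"W{i}": W for i, W in enumerate(self.net.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.b)})
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2, default=float))

    @classmethod
    def load(cls, path: str | Path) -> "QPolicy":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        W = [data[f"W{i}"] for i in range(n_layers)]
        hidden = tuple(w.shape[1] for w in W[:-1])
        net = QNetwork(W[0].shape[0], W[-1].shape[1], hidden, np.random.default_rng(0))
        net.load_weights(W + [data[f"b{i}"] for i in range(n_layers)])
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(net, meta)


class ReplayBuffer:
    """Fixed-capacity uniform-sampling transition store."""

    def __init__(self, capacity: int, obs_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.next_obs = np.zeros((capacity, obs_dim), dtype=np.float32)
        self.action = np.zeros(capacity, dtype=np.int64)
        self.reward = np.zeros(capacity, dtype=np.float32)
        self.done = np.zeros(capacity, dtype=np.float32)
        self.pos = 0
        self.full = False

    def __len__(self) -> int:
        return self.capacity if self.full else self.pos

    def add(self, obs, action, reward, next_obs, done) -> None:
        i = self.pos
        self.obs[i] = obs
        self.action[i] = action
        self.reward[i] = reward
        self.next_obs[i] = next_obs
        self.done[i] = done
        self.pos += 1
        if self.pos == self.capacity:
            self.pos = 0
            self.full = True

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self), size=batch_size)
        return (
            self.obs[idx].astype(np.float64),
            self.action[idx],
            self.reward[idx].astype(np.float64),
            self.next_obs[idx].astype(np.float64),
            self.done[idx].astype(np.float64),
        )


class _Adam:
    """Adam on a single flat parameter vector."""

    def __init__(self, theta: np.ndarray, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.theta = theta
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros_like(theta)
        self.v = np.zeros_like(theta)
        self.t = 0

    def step(self, grad: np.ndarray) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        if _HAVE_NUMBA:
            _adam_kernel(self.theta, self.m, self.v, grad,
                         self.lr, self.b1, self.b2, self.eps, b1t, b2t)
        else:
            self.m *= self.b1
            self.m += (1.0 - self.b1) * grad
            self.v *= self.b2
            self.v += (1.0 - self.b2) * grad * grad
            self.theta -= self.lr * (self.m / b1t) / (np.sqrt(self.v / b2t) + self.eps)


@dataclass
class Checkpoint:
    """Policy snapshot with its fixed-seed evaluation statistics."""

    step: int
    policy: QPolicy
    mean_reward: float
    min_reward: float
    max_reward: float
    mean_mse: float

    def stats(self) -> dict:
        return {
            "step": self.step,
            "mean_reward": self.mean_reward,
            "min_reward": self.min_reward,
            "max_reward": self.max_reward,
            "mean_mse": self.mean_mse,
        }


def _huber_backward(net: QNetwork, obs, actions, targets, max_grad_norm: float):
    """Flat gradient of the mean smooth-L1 TD loss, clipped by global norm."""
    if len(net.W) == 3 and _HAVE_NUMBA:
        grad = np.empty_like(net.theta)
        loss = _huber2_backward(
            np.ascontiguousarray(obs, dtype=np.float64),
            np.ascontiguousarray(actions, dtype=np.int64),
            np.ascontiguousarray(targets, dtype=np.float64),
            net.W[0], net.b[0], net.W[1], net.b[1], net.W[2], net.b[2],
            grad, float(max_grad_norm),
        )
        return grad, loss
    B = obs.shape[0]
    rows = np.arange(B)
    q, acts = net.forward(obs, keep=True)
    delta = q[rows, actions] - targets
    loss = float(np.mean(np.where(np.abs(delta) < 1.0, 0.5 * delta**2, np.abs(delta) - 0.5)))
    dq = np.zeros_like(q)
    dq[rows, actions] = np.clip(delta, -1.0, 1.0) / B  # mean reduction

    flat = np.empty_like(net.theta)
    views = net.unflatten(flat)
    n = len(net.W)
    grad = dq
    for layer in range(n - 1, -1, -1):
        views[layer][...] = acts[layer].T @ grad
        views[n + layer][...] = grad.sum(axis=0)
        if layer > 0:
            grad = (grad @ net.W[layer].T) * (acts[layer] > 0.0)
    norm = float(np.sqrt(flat @ flat))
    if norm > max_grad_norm:
        flat *= max_grad_norm / (norm + 1e-6)
    return flat, loss


def _epsilon(step: int, cfg: DQNConfig) -> float:
    horizon = max(1.0, cfg.exploration_fraction * cfg.total_steps)
    frac = min(step / horizon, 1.0)
    return cfg.epsilon_initial + frac * (cfg.epsilon_final - cfg.epsilon_initial)


def evaluate_checkpoint(policy: QPolicy, env, seeds: list[int]) -> dict:
    """Greedy evaluation on a fixed seed list; identical seeds give every
    checkpoint the same randomized-episode set."""
    if not seeds:
        raise ValueError("seed list must be non-empty")
    rewards, mses = [], []
    for s in seeds:
        obs, _ = env.reset(seed=int(s))
        done = False
        while not done:
            obs, _, term, trunc, _ = env.step(policy.predict(obs))
            done = term or trunc
        rewards.append(env.log.agent_reward)
        try:
            mses.append(mse_from_cooling(env.log))
        except ValueError:
            # episode truncated before the cooling window; metric undefined
            mses.append(float("nan"))
    finite = [m for m in mses if not np.isnan(m)]
    return {
        "mean_reward": float(np.mean(rewards)),
        "min_reward": float(np.min(rewards)),
        "max_reward": float(np.max(rewards)),
        "mean_mse": float(np.mean(finite)) if finite else float("nan"),
        "rewards": rewards,
        "mses": mses,
    }


def select_best(checkpoints: list[Checkpoint]) -> QPolicy:
    """Best checkpoint by mean episode reward; ties go to the later step."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    best = checkpoints[0]
    for ck in checkpoints[1:]:
        if ck.mean_reward >= best.mean_reward:
            best = ck
    return best.policy


def train(
    config: DQNConfig,
    env_factory,
    seed: int | None = None,
    verbose: bool = False,
) -> tuple[list[Checkpoint], list[dict]]:
    """Run deep Q-learning against environments from ``env_factory``.

    Returns the checkpoint list and a per-episode training log
    (episode index, global step at episode end, agent/supervisor step
    counts, cumulative agent reward and total logged reward).

    The step count refers to *agent* decisions; supervisor-governed plant
    steps advance inside the environment and carry no learning signal.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    net_ss, act_ss, buf_ss, env_ss, eval_ss = ss.spawn(5)
    rng_act = np.random.default_rng(act_ss)
    rng_buf = np.random.default_rng(buf_ss)
    rng_env = np.random.default_rng(env_ss)
    eval_seeds = list(np.random.default_rng(eval_ss).integers(2**31, size=config.eval_episodes))

    env = env_factory()
    eval_env = env_factory()
    obs_dim = env.observation_size
    n_actions = env.action_space_n

    net = QNetwork(obs_dim, n_actions, config.hidden_layers, np.random.default_rng(net_ss))
    target = QNetwork(obs_dim, n_actions, config.hidden_layers, np.random.default_rng(0))
    target.load_weights(net.copy_weights())
    opt = _Adam(net.theta, config.learning_rate)
    buffer = ReplayBuffer(min(config.buffer_size, config.total_steps), obs_dim)

    checkpoints: list[Checkpoint] = []
    training_log: list[dict] = []
    episode = 0
    t0 = time.time()

    obs, _ = env.reset(seed=int(rng_env.integers(2**31)))
    for step in range(1, config.total_steps + 1):
        if rng_act.random() < _epsilon(step - 1, config):
            action = int(rng_act.integers(n_actions))
        else:
            action = int(np.argmax(net.q_single(obs)))
        next_obs, reward, term, trunc, _ = env.step(action)
        buffer.add(obs, action, reward, next_obs, float(term))
        obs = next_obs

        if term or trunc:
            log = env.log
            n_agent = sum(1 for s in log.source if s == "agent")
            training_log.append(
                {
                    "episode": episode,
                    "end_step": step,
                    "agent_steps": n_agent,
                    "plant_steps": len(log) - 1,
                    "reward_agent": log.agent_reward,
                    "reward_total": log.total_reward,
                }
            )
            episode += 1
            obs, _ = env.reset(seed=int(rng_env.integers(2**31)))

        if step >= config.learning_starts and step % config.train_freq == 0:
            for _ in range(config.gradient_steps):
                b_obs, b_act, b_rew, b_next, b_done = buffer.sample(config.batch_size, rng_buf)
                if len(target.W) == 3 and _HAVE_NUMBA:
                    q_next = _q2_batch_max(
                        b_next, target.W[0], target.b[0], target.W[1],
                        target.b[1], target.W[2], target.b[2],
                    )
                else:
                    q_next = target.forward(b_next).max(axis=1)
                targets = b_rew + config.gamma * (1.0 - b_done) * q_next
                grads, loss = _huber_backward(net, b_obs, b_act, targets, config.max_grad_norm)
                if not np.isfinite(loss):
                    raise RuntimeError(f"divergent TD loss at step {step}: {loss}")
                opt.step(grads)

        if step % config.target_update_interval == 0:
            target.soft_update_from(net, config.tau)

        if step % config.checkpoint_interval == 0:
            policy = QPolicy(
                QNetwork(obs_dim, n_actions, config.hidden_layers, np.random.default_rng(0)),
                meta={"step": step, "seed": seed},
            )
            policy.net.load_weights(net.copy_weights())
            stats = evaluate_checkpoint(policy, eval_env, eval_seeds)
            policy.meta.update({k: stats[k] for k in ("mean_reward", "min_reward", "max_reward", "mean_mse")})
            checkpoints.append(
                Checkpoint(
                    step=step,
                    policy=policy,
                    mean_reward=stats["mean_reward"],
                    min_reward=stats["min_reward"],
                    max_reward=stats["max_reward"],
                    mean_mse=stats["mean_mse"],
                )
            )
            if verbose:
                el = time.time() - t0
                print(
                    f"[train] step {step}/{config.total_steps} "
                    f"eps={_epsilon(step, config):.3f} "
                    f"eval mean_reward={stats['mean_reward']:.1f} "
                    f"mean_mse={stats['mean_mse']:.4f} ({el:.0f}s)",
                    flush=True,
                )
    return checkpoints, training_log


def save_training_log(training_log: list[dict], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        if not training_log:
            fh.write("episode,end_step,agent_steps,plant_steps,reward_agent,reward_total\n")
            return
        w = csv.DictWriter(fh, fieldnames=list(training_log[0].keys()))
        w.writeheader()
        w.writerows(training_log)
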