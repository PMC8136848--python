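"""Reward, Gaussian head-control policy, and natural actor-critic learning.

The agent's reward at each iteration is the negative reconstruction
error of the received echo, averaged over all scales, aural streams and
window indices:  r(t) = -(1/(6N)) sum_s sum_e sum_i E_{s,e,i}(t).
Coding efficiency is thus the sole training signal; no ground-truth
target direction is ever used (active efficient coding).

The actor is a one-hidden-layer tanh network mapping the pooled feature
vector to the means of the yaw/pitch commands; during training actions
are drawn from an isotropic Gaussian around the mean with exploration
std sigma_e = 10 deg, during testing the greedy mean is used.  The
critic is a single linear layer estimating the state value.  Updates
follow a natural actor-critic scheme with compatible features: the
critic is trained by TD(0), and the actor takes a step along the natural
gradient, which for the Gaussian output layer reduces to the TD error
times the exploration residual (a - mu) back-propagated through the mean
network (the Fisher preconditioning cancels the 1/sigma_e^2 factor of
the vanilla score function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Action",
    "NacConfig",
    "PolicyNet",
    "CriticNet",
    "TrainingDiverged",
    "compute_reward",
    "act",
    "nac_update",
]


class TrainingDiverged(RuntimeError):
    """Network weights exceeded the divergence threshold."""


@dataclass(frozen=True)
class Action:
    """Incremental yaw/pitch head command in degrees (already clipped)."""

    dyaw: float
    dpitch: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dyaw, self.dpitch])


@dataclass(frozen=True)
class NacConfig:
    """Actor-critic hyperparameters.

    discount 0.3 suits the short-horizon episodic task; learning rates
    anneal by ``anneal_factor`` over ``total_steps`` updates.  Actions
    are clipped to +/- ``action_clip`` deg per iteration for stability.
    """

    discount: float = 0.3
    critic: str = "rls"  # "rls" (least-squares TD) or "lms"
    lr_critic: float = 1e-3  # used by the lms critic
    lr_actor: float = 1e-3  # hidden-layer (vanilla) learning rate
    natural_lr: float = 0.3  # output-layer natural-gradient step
    nat_forgetting: float = 0.995  # RLS forgetting of the advantage fit
    nat_update_every: int = 20  # apply the natural gradient every N steps
    anneal_factor: float = 0.1
    total_steps: int = 3000
    sigma_explore: float = 10.0
    action_clip: float = 30.0
    weight_norm_limit: float = 1e4


def compute_reward(stream_errors) -> float:
    """Reward r(t) from the per-window reconstruction errors.

    ``stream_errors`` maps each of the six streams (or any iterable of
    streams) to the 1-D array of per-window errors E_{s,e,i}(t).  The
    reward is the negative mean over streams of the per-stream mean
    error, which equals -(1/(6N)) of the grand sum when every stream has
    the same window count N.
    """
    if hasattr(stream_errors, "values"):
        arrays = list(stream_errors.values())
    else:
        arrays = list(stream_errors)
    if not arrays:
        raise ValueError("no error streams given")
    means = []
    for arr in arrays:
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            raise ValueError("empty error stream")
        means.append(arr.mean())
    return float(-np.mean(means))


class PolicyNet:
    """Gaussian policy: tanh hidden layer -> linear yaw/pitch means."""

    def __init__(self, input_dim: int, hidden: int = 500, seed=0,
                 config: NacConfig | None = None):
        self.config = config or NacConfig()
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(input_dim), (hidden, input_dim))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1e-3, (2, hidden))
        self.b2 = np.zeros(2)
        self.step = 0
        # compatible-feature natural-gradient state for the output layer:
        # RLS fit of the advantage onto psi = dlogpi/dmu-parameters
        nat_dim = 2 * (hidden + 1)
        self._nat_P = np.eye(nat_dim) * 100.0
        self._nat_w = np.zeros(nat_dim)

    @property
    def sigma_explore(self) -> float:
        return self.config.sigma_explore

    def mean(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Action mean and hidden activations for a feature vector."""
        f = np.asarray(f, dtype=float)
        h = np.tanh(self.W1 @ f + self.b1)
        return self.W2 @ h + self.b2, h

    def lr(self) -> float:
        cfg = self.config
        frac = min(self.step / max(cfg.total_steps, 1), 1.0)
        return cfg.lr_actor * cfg.anneal_factor**frac

    def weight_norm(self) -> float:
        return float(
            np.sqrt(sum(np.sum(np.square(w)) for w in
                        (self.W1, self.b1, self.W2, self.b2)))
        )

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "nat_P": self._nat_P, "nat_w": self._nat_w}


class CriticNet:
    """Linear state-value estimator V(f) = w . f + b.

    Trained by recursive-least-squares TD(0) (the least-squares critic of
    the natural actor-critic family): the inverse feature covariance P is
    tracked with a forgetting factor so the value fit follows the slowly
    changing representation.  ``lr_critic`` > 0 switches to plain LMS
    TD(0) with the annealed rate (used by small closed-form test cases).
    """

    def __init__(self, input_dim: int, config: NacConfig | None = None):
        self.config = config or NacConfig()
        self.w = np.zeros(input_dim)
        self.b = 0.0
        self.P = np.eye(input_dim + 1) * 100.0  # inverse covariance (w, b)
        self.forgetting = 0.999
        self.step = 0

    def value(self, f: np.ndarray) -> float:
        return float(self.w @ np.asarray(f, dtype=float) + self.b)

    def rls_update(self, f: np.ndarray, target: float) -> float:
        """RLS step fitting V(f) toward a (bootstrapped) target."""
        x = np.r_[np.asarray(f, dtype=float), 1.0]
        lam = self.forgetting
        Px = self.P @ x
        g = Px / (lam + x @ Px)
        err = target - (x[:-1] @ self.w + self.b * x[-1])
        self.w = self.w + g[:-1] * err
        self.b = self.b + float(g[-1]) * err
        self.P = (self.P - np.outer(g, Px)) / lam
        self.step += 1
        return float(err)

    def lr(self) -> float:
        cfg = self.config
        frac = min(self.step / max(cfg.total_steps, 1), 1.0)
        return cfg.lr_critic * cfg.anneal_factor**frac

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": np.array([self.b]), "P": self.P}


def act(policy: PolicyNet, f: np.ndarray, mode: str = "greedy", rng=None) -> Action:
    """Sample (train) or return (greedy) the head command for a state.

    Train mode draws from N(pi(f), sigma_e^2 I); both modes clip each
    component to +/- action_clip deg.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("feature vector contains non-finite entries")
    mu, _ = policy.mean(f)
    if mode == "train":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        a = mu + policy.sigma_explore * rng.standard_normal(2)
    elif mode == "greedy":
        a = mu
    else:
        raise ValueError(f"unknown mode {mode!r}")
    clip = policy.config.action_clip
    a = np.clip(a, -clip, clip)
    return Action(float(a[0]), float(a[1]))


def nac_update(
    policy: PolicyNet,
    critic: CriticNet,
    transition: tuple,
    done: bool = False,
) -> dict:
    """One natural actor-critic update from a transition (f, a, r, f_next).

    The TD error ``delta = r + gamma V(f') - V(f)`` (no bootstrap when
    ``done``, i.e. at episode boundaries) drives the least-squares TD
    critic.  The actor follows the episodic natural gradient with
    compatible features: delta is regressed (recursive least squares,
    with forgetting) onto ``psi = dlog pi / d(mean parameters)`` of the
    output layer, and the fitted coefficient vector — which by the
    compatible-function-approximation theorem IS the natural gradient of
    the mean parameters — is applied to W2/b2 every
    ``nat_update_every`` steps.  The hidden layer follows the vanilla
    back-propagated gradient at ``lr_actor``.

    Returns diagnostics (td_error, gradient norms).  Raises
    :class:`TrainingDiverged` if weights blow past the configured limit.
    """
    f, a, r, f_next = transition
    f = np.asarray(f, dtype=float)
    a = np.asarray(a.as_array() if isinstance(a, Action) else a, dtype=float)
    if not (np.all(np.isfinite(f)) and np.isfinite(r)):
        raise ValueError("non-finite transition")
    cfg = policy.config
    gamma = critic.config.discount
    v = critic.value(f)
    v_next = 0.0 if done else critic.value(f_next)
    delta = r + gamma * v_next - v

    if critic.config.critic == "rls":
        critic.rls_update(f, r + gamma * v_next)
    else:
        lr_c = critic.lr()
        critic.w = critic.w + lr_c * delta * f
        critic.b = critic.b + lr_c * delta
        critic.step += 1

    mu, h = policy.mean(f)
    if cfg.natural_lr > 0:
        s2 = max(cfg.sigma_explore, 1e-6) ** 2
        hb = np.r_[h, 1.0]
        psi = np.concatenate([((a[k] - mu[k]) / s2) * hb for k in range(2)])
        # RLS fit of the advantage onto the compatible features
        lam = cfg.nat_forgetting
        Pp = policy._nat_P @ psi
        gain = Pp / (lam + psi @ Pp)
        policy._nat_w = policy._nat_w + gain * (delta - psi @ policy._nat_w)
        policy._nat_P = (policy._nat_P - np.outer(gain, Pp)) / lam

    g = delta * (a - mu)  # instantaneous score direction (hidden layer)
    lr_a = policy.lr()
    back = (policy.W2.T @ g) * (1.0 - h * h)
    gW1 = np.outer(back, f)
    policy.W1 = policy.W1 + lr_a * gW1
    policy.b1 = policy.b1 + lr_a * back
    policy.step += 1

    applied = 0.0
    warmed_up = policy.step >= 2 * len(policy._nat_w)
    if cfg.natural_lr > 0 and warmed_up and policy.step % cfg.nat_update_every == 0:
        nh = len(h)
        w = cfg.natural_lr * policy._nat_w.reshape(2, nh + 1)
        # trust region: cap the induced change of the action mean
        # (||h|| <= sqrt(nh), so the mean moves at most ~cap degrees)
        cap = 1.0
        scale = np.linalg.norm(w) * np.sqrt(nh)
        if scale > cap:
            w = w * (cap / scale)
        policy.W2 = policy.W2 + w[:, :nh]
        policy.b2 = policy.b2 + w[:, nh]
        applied = float(np.linalg.norm(w))

    wn = policy.weight_norm()
    if wn > policy.config.weight_norm_limit or not np.isfinite(wn):
        raise TrainingDiverged(f"policy weight norm {wn:.3g} exceeds limit")
    return {
        "td_error": float(delta),
        "critic_grad_norm": float(np.abs(delta) * np.sqrt(f @ f + 1.0)),
        "actor_grad_norm": float(np.linalg.norm(policy._nat_w)),
        "natural_step_norm": applied,
        "value": float(v),
    }
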