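"""State-to-action mapping network (SAMNN) and its exact gradients.

A three-layer fully connected network maps the 152-dim mental-state
vector to a categorical distribution over 4 dimensionless speed levels:
softmax(W2 @ tanh(W1 @ s + b1) + b2). Gradients of the log action
probability are computed analytically (no autodiff) so they can be
validated against finite differences. The same network is pre-trained
as a 4-way classifier on valence/arousal quadrant labels before
reinforcement learning, and updated by ADAM in both phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    InvalidDistributionError,
    InvalidInputError,
    ShapeError,
)
from .features import STATE_DIM

N_ACTIONS = 4
HIDDEN_DIM = 80

#: Dimensionless speed multipliers for levels 0..3.
DEFAULT_MULTIPLIERS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8
LEARNING_RATE = 1e-3

PARAM_KEYS = ("W1", "b1", "W2", "b2")


@dataclass
class SpeedAction:
    """A discrete speed level and its multiplier applied to the robot."""

    level: int
    multiplier: float

    @classmethod
    def from_level(
        cls, level: int, multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    ) -> "SpeedAction":
        return cls(level=int(level), multiplier=multipliers[int(level)])


@dataclass
class PolicyParameters:
    """Weights/biases theta plus ADAM moment accumulators."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    step: int = 0

    def __post_init__(self) -> None:
        if not self.m:
            self.m = {k: np.zeros_like(getattr(self, k)) for k in PARAM_KEYS}
            self.v = {k: np.zeros_like(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        input_dim: int = STATE_DIM,
        hidden_dim: int = HIDDEN_DIM,
        n_actions: int = N_ACTIONS,
    ) -> "PolicyParameters":
        """Symmetric uniform initialization scaled by fan-in."""
        s1 = 1.0 / np.sqrt(input_dim)
        s2 = 1.0 / np.sqrt(hidden_dim)
        return cls(
            W1=rng.uniform(-s1, s1, size=(input_dim, hidden_dim)),
            b1=np.zeros(hidden_dim),
            W2=rng.uniform(-s2, s2, size=(hidden_dim, n_actions)),
            b2=np.zeros(n_actions),
        )

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def n_actions(self) -> int:
        return self.W2.shape[1]

    def copy(self) -> "PolicyParameters":
        return PolicyParameters(
            self.W1.copy(),
            self.b1.copy(),
            self.W2.copy(),
            self.b2.copy(),
            {k: a.copy() for k, a in self.m.items()},
            {k: a.copy() for k, a in self.v.items()},
            self.step,
        )

    def equals(self, other: "PolicyParameters") -> bool:
        return all(
            np.array_equal(getattr(self, k), getattr(other, k)) for k in PARAM_KEYS
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def policy_forward(theta: PolicyParameters, s: np.ndarray) -> np.ndarray:
    """Action probabilities softmax(W2 @ tanh(W1 @ s + b1) + b2).

    Accepts a single state vector or a batch (n, input_dim).
    """
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != theta.input_dim:
        raise ShapeError(
            f"state dim {s.shape[-1]} does not match input layer {theta.input_dim}"
        )
    h = np.tanh(s @ theta.W1 + theta.b1)
    return _softmax(h @ theta.W2 + theta.b2)


def sample_action(
    probs: np.ndarray,
    rng: np.random.Generator,
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS,
) -> SpeedAction:
    """Draw a speed level from the categorical action distribution."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or abs(probs.sum() - 1.0) > 1e-6 or (probs < 0).any():
        raise InvalidDistributionError(f"invalid action distribution {probs}")
    level = int(rng.choice(len(probs), p=probs / probs.sum()))
    return SpeedAction.from_level(level, multipliers)


def grad_log_prob(
    theta: PolicyParameters, s: np.ndarray, a: int | SpeedAction
) -> dict[str, np.ndarray]:
    """Exact gradient of ln p_theta(a|s) with respect to every parameter.

    Backpropagation through the softmax (output-bias gradient is
    one_hot(a) - probs) and the tanh hidden layer.
    """
    level = a.level if isinstance(a, SpeedAction) else int(a)
    s = np.asarray(s, dtype=float)
    h = np.tanh(s @ theta.W1 + theta.b1)
    probs = _softmax(h @ theta.W2 + theta.b2)
    dlogits = -probs
    dlogits[level] += 1.0
    dh = theta.W2 @ dlogits
    dz1 = (1.0 - h**2) * dh
    return {
        "W1": np.outer(s, dz1),
        "b1": dz1,
        "W2": np.outer(h, dlogits),
        "b2": dlogits,
    }


def log_prob(theta: PolicyParameters, s: np.ndarray, a: int | SpeedAction) -> float:
    level = a.level if isinstance(a, SpeedAction) else int(a)
    return float(np.log(policy_forward(theta, s)[level]))


def adam_update(
    theta: PolicyParameters,
    grad: dict[str, np.ndarray],
    lr: float = LEARNING_RATE,
    beta1: float = ADAM_BETA1,
    beta2: float = ADAM_BETA2,
    eps: float = ADAM_EPS,
    maximize: bool = True,
) -> PolicyParameters:
    """One bias-corrected ADAM step in place; ascent when maximizing."""
    for k in PARAM_KEYS:
        g = grad[k]
        if not np.all(np.isfinite(g)):
            raise InvalidInputError(f"non-finite gradient for {k}")
    theta.step += 1
    t = theta.step
    sign = 1.0 if maximize else -1.0
    for k in PARAM_KEYS:
        g = grad[k]
        theta.m[k] = beta1 * theta.m[k] + (1 - beta1) * g
        theta.v[k] = beta2 * theta.v[k] + (1 - beta2) * g**2
        m_hat = theta.m[k] / (1 - beta1**t)
        v_hat = theta.v[k] / (1 - beta2**t)
        setattr(
            theta,
            k,
            getattr(theta, k) + sign * lr * m_hat / (np.sqrt(v_hat) + eps),
        )
    return theta


def pretrain(
    theta: PolicyParameters,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 10_000,
    batch_size: int = 50,
    lr: float = LEARNING_RATE,
    rng: np.random.Generator | None = None,
) -> tuple[PolicyParameters, list[float]]:
    """Supervised 4-class pretraining of the network by cross-entropy.

    Class indices map directly onto action indices, so the pre-trained
    classifier seeds the speed policy. Returns the updated parameters
    and the per-epoch mean training loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != theta.input_dim:
        raise ShapeError(f"pretraining data shape {X.shape} incompatible")
    if y.min() < 0 or y.max() >= theta.n_actions:
        raise InvalidInputError(
            f"class labels must lie in 0..{theta.n_actions - 1}"
        )
    rng = rng or np.random.default_rng()
    n = X.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            h = np.tanh(xb @ theta.W1 + theta.b1)
            probs = _softmax(h @ theta.W2 + theta.b2)
            losses.append(float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-300))))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            dh = dlogits @ theta.W2.T
            dz1 = (1.0 - h**2) * dh
            grad = {
                "W1": xb.T @ dz1,
                "b1": dz1.sum(axis=0),
                "W2": h.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            adam_update(theta, grad, lr=lr, maximize=False)
        history.append(float(np.mean(losses)))
    return theta, history


# ------------------------------------------------------------ checkpoints

def save_checkpoint(theta: PolicyParameters, path: str | Path) -> Path:
    """Write parameters + moments as .npz with a JSON manifest."""
    path = Path(path)
    arrays = {k: getattr(theta, k) for k in PARAM_KEYS}
    arrays |= {f"m_{k}": theta.m[k] for k in PARAM_KEYS}
    arrays |= {f"v_{k}": theta.v[k] for k in PARAM_KEYS}
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {
        "shapes": {k: list(getattr(theta, k).shape) for k in PARAM_KEYS},
        "step": theta.step,
        "format": "psa-checkpoint-v1",
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> PolicyParameters:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        theta = PolicyParameters(
            z["W1"], z["b1"], z["W2"], z["b2"],
            {k: z[f"m_{k}"] for k in PARAM_KEYS},
            {k: z[f"v_{k}"] for k in PARAM_KEYS},
            int(manifest["step"]),
        )
    return theta
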