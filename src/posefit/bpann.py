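"""First-stage classifier: a 9–15–5 sigmoid network over waist features.

The input is the flattened rotation matrix of the waist orientation in
the animation frame (nine components), the output one independent
sigmoid unit per waist-orientation category.  The cost is the mean of
per-output binary cross-entropies with an L2 penalty on non-bias
weights,

    J(θ) = -1/m Σᵢ Σₖ [ yₖ log oₖ + (1-yₖ) log(1-oₖ) ] + λ/(2m) Σ θ²,

minimised by full-batch gradient descent with a backtracking (Armijo)
line search, which keeps J monotonically non-increasing.  Note the
outputs are independent sigmoids, not a softmax, so prediction is
argmax-with-threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .body import WAIST
from .quat import quat_to_matrix

N_INPUT, N_HIDDEN, N_OUTPUT = 9, 15, 5
_CLIP = 1e-12  # keeps log arguments finite


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def extract_waist_features(anim_quats: np.ndarray) -> np.ndarray:
    """Row-major waist rotation-matrix components, shape ``(..., 9)``.

    *anim_quats* are animation-frame quaternions of shape ``(..., 11, 4)``.
    """
    anim_quats = np.asarray(anim_quats, dtype=float)
    R = quat_to_matrix(anim_quats[..., WAIST, :])
    return R.reshape(R.shape[:-2] + (9,))


@dataclass
class AnnConfig:
    """Training hyper-parameters (λ, step, stopping rule, seed)."""

    lam: float = 0.01
    learning_rate: float = 0.5
    max_epochs: int = 5000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class AnnModel:
    """Weights of the 9–15–5 network (bias column first in each matrix)."""

    theta2: np.ndarray  # (15, 10)
    theta3: np.ndarray  # (5, 16)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta2 = np.asarray(self.theta2, dtype=float)
        self.theta3 = np.asarray(self.theta3, dtype=float)
        if self.theta2.shape != (N_HIDDEN, N_INPUT + 1) or self.theta3.shape != (N_OUTPUT, N_HIDDEN + 1):
            raise ValueError(
                f"weight shapes must be ({N_HIDDEN},{N_INPUT + 1}) and ({N_OUTPUT},{N_HIDDEN + 1}), "
                f"got {self.theta2.shape} and {self.theta3.shape}"
            )
        if not (np.all(np.isfinite(self.theta2)) and np.all(np.isfinite(self.theta3))):
            raise ValueError("non-finite network weights")

    def to_json(self, path) -> None:
        doc = {
            "format": "posefit-bpann-v1",
            "layers": [N_INPUT, N_HIDDEN, N_OUTPUT],
            "theta2": self.theta2.tolist(),
            "theta3": self.theta3.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        doc = json.loads(Path(path).read_text())
        return cls(theta2=np.array(doc["theta2"]), theta3=np.array(doc["theta3"]), meta=doc.get("meta", {}))


def _with_bias(X: np.ndarray) -> np.ndarray:
    return np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)


def forward(model: AnnModel, X: np.ndarray, return_hidden: bool = False):
    """Category scores in (0, 1), shape ``(m, 5)``.

    *X* is the ``(m, 9)`` waist feature matrix (a single feature vector
    is also accepted).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT}-dimensional waist features, got {X.shape[1]}")
    H = sigmoid(_with_bias(X) @ model.theta2.T)          # (m, 15)
    O = sigmoid(_with_bias(H) @ model.theta3.T)          # (m, 5)
    return (O, H) if return_hidden else O


def one_hot(categories: np.ndarray) -> np.ndarray:
    """Category ids 1–5 → ``(m, 5)`` one-hot targets."""
    categories = np.asarray(categories, dtype=int)
    if np.any((categories < 1) | (categories > N_OUTPUT)):
        raise ValueError("category ids must lie in 1..5")
    Y = np.zeros((categories.size, N_OUTPUT))
    Y[np.arange(categories.size), categories - 1] = 1.0
    return Y


def cost(model: AnnModel, X: np.ndarray, Y: np.ndarray, lam: float) -> float:
    """Regularized cross-entropy cost J(θ) of a batch."""
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    m = X.shape[0]
    O = np.clip(forward(model, X), _CLIP, 1.0 - _CLIP)
    ce = -np.sum(Y * np.log(O) + (1.0 - Y) * np.log(1.0 - O)) / m
    reg = (lam / (2.0 * m)) * (np.sum(model.theta2[:, 1:] ** 2) + np.sum(model.theta3[:, 1:] ** 2))
    return float(ce + reg)


def gradients(model: AnnModel, X: np.ndarray, Y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`cost` w.r.t. (θ⁽²⁾, θ⁽³⁾)."""
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    m = X.shape[0]
    O, H = forward(model, X, return_hidden=True)
    O = np.clip(O, _CLIP, 1.0 - _CLIP)
    delta3 = (O - Y) / m                                     # (m, 5)
    g3 = delta3.T @ _with_bias(H)                            # (5, 16)
    delta2 = (delta3 @ model.theta3[:, 1:]) * H * (1.0 - H)  # (m, 15)
    g2 = delta2.T @ _with_bias(X)                            # (15, 10)
    g3[:, 1:] += (lam / m) * model.theta3[:, 1:]
    g2[:, 1:] += (lam / m) * model.theta2[:, 1:]
    return g2, g3


def train(X: np.ndarray, categories: np.ndarray, config: AnnConfig | None = None) -> AnnModel:
    """Fit the network on waist features and category labels (1–5).

    Full-batch gradient descent with a growing/backtracking Armijo line
    search; deterministic given ``config.seed``.  Raises if any category
    is absent from the training data.
    """
    config = config or AnnConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    categories = np.asarray(categories, dtype=int)
    missing = sorted(set(range(1, N_OUTPUT + 1)) - set(categories.tolist()))
    if missing:
        raise ValueError(f"training data lacks categories {missing}")
    Y = one_hot(categories)
    rng = np.random.default_rng(config.seed)
    lim2 = np.sqrt(6.0 / (N_INPUT + 1 + N_HIDDEN))
    lim3 = np.sqrt(6.0 / (N_HIDDEN + 1 + N_OUTPUT))
    model = AnnModel(
        theta2=rng.uniform(-lim2, lim2, size=(N_HIDDEN, N_INPUT + 1)),
        theta3=rng.uniform(-lim3, lim3, size=(N_OUTPUT, N_HIDDEN + 1)),
    )
    J = cost(model, X, Y, config.lam)
    history = [J]
    step = config.learning_rate
    epochs = 0
    for epoch in range(config.max_epochs):
        g2, g3 = gradients(model, X, Y, config.lam)
        gsq = float(np.sum(g2 ** 2) + np.sum(g3 ** 2))
        if gsq == 0.0:
            break
        # Armijo backtracking; step grows between epochs for speed
        accepted = False
        for _ in range(60):
            trial = AnnModel(theta2=model.theta2 - step * g2, theta3=model.theta3 - step * g3)
            J_trial = cost(trial, X, Y, config.lam)
            if J_trial <= J - 1e-4 * step * gsq:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        dJ = J - J_trial
        model, J = trial, J_trial
        history.append(J)
        epochs = epoch + 1
        step = min(step * 2.0, 1e3)
        if dJ < config.tol:
            break
    model.meta = {"seed": config.seed, "lam": config.lam, "epochs": epochs,
                  "final_cost": J, "cost_history": history}
    return model


def predict_category(model: AnnModel, X: np.ndarray, t1: float = 0.5) -> np.ndarray:
    """Category id (1–5) per row, or 0 where no score exceeds *t1*.

    Ties at the maximum resolve to the lowest category index.
    """
    O = forward(model, X)
    best = np.argmax(O, axis=1)
    scores = O[np.arange(O.shape[0]), best]
    return np.where(scores > t1, best + 1, 0)


__all__ = [
    "N_INPUT", "N_HIDDEN", "N_OUTPUT", "sigmoid", "extract_waist_features",
    "AnnConfig", "AnnModel", "forward", "one_hot", "cost", "gradients",
    "train", "predict_category",
]
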