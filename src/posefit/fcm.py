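"""Second-stage classifier: per-category fuzzy C-means over body features.

The 90-dimensional body feature stacks, for each of the ten non-waist
segments, the nine row-major rotation-matrix components of the segment's
orientation relative to the waist.  One FCM model is fitted per posture
category, with as many clusters as the category has postures.

Memberships follow the standard fuzzy C-means rule with weight index
``b`` (2 unless configured otherwise),

    μ_j(x) = ‖x − m_j‖^(−2/(b−1)) / Σ_s ‖x − m_s‖^(−2/(b−1)),

and centers are the μ^b-weighted sample means.  Alternating the two
updates never increases the objective J_f = ΣΣ μ^b ‖x − m‖².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .body import NONWAIST, relative_to_waist
from .data import POSTURES_IN_CATEGORY
from .quat import quat_to_matrix

N_FEATURES = 90


def extract_body_features(anim_quats: np.ndarray) -> np.ndarray:
    """Waist-relative rotation-matrix features, shape ``(..., 90)``.

    Blocks are ordered by IMU index skipping the waist
    (:data:`posefit.body.NONWAIST`); each 9-block is the row-major
    rotation matrix of ``q_i-6``.
    """
    rel = relative_to_waist(anim_quats)                  # (..., 10, 4)
    R = quat_to_matrix(rel)                              # (..., 10, 3, 3)
    return R.reshape(R.shape[:-3] + (N_FEATURES,))


def _sq_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(X)
    return np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=-1)


def membership(X: np.ndarray, centers: np.ndarray, b: float = 2.0) -> np.ndarray:
    """Fuzzy memberships, shape ``(m, K)``; rows sum to one.

    A sample coinciding with a center takes crisp membership 1 there
    (the singular limit of the update rule).
    """
    if b <= 1:
        raise ValueError("weight index b must exceed 1")
    centers = np.atleast_2d(centers)
    d2 = _sq_distances(X, centers)
    at_center = d2 < 1e-24
    U = np.empty_like(d2)
    sing = at_center.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d2[~sing] ** (-1.0 / (b - 1.0))
    U[~sing] = w / np.sum(w, axis=1, keepdims=True)
    if np.any(sing):
        rows = at_center[sing].astype(float)
        U[sing] = rows / np.sum(rows, axis=1, keepdims=True)
    return U


def update_centers(X: np.ndarray, U: np.ndarray, b: float = 2.0) -> np.ndarray:
    """μ^b-weighted means; a cluster with no weight restarts at the sample
    farthest from the existing centers."""
    X = np.atleast_2d(X)
    W = U ** b                                            # (m, K)
    tot = W.sum(axis=0)                                   # (K,)
    centers = np.empty((U.shape[1], X.shape[1]))
    dead = tot <= 1e-300
    live = ~dead
    centers[live] = (W[:, live].T @ X) / tot[live, None]
    for k in np.flatnonzero(dead):
        d2 = _sq_distances(X, centers[live]).min(axis=1) if live.any() else np.full(X.shape[0], np.inf)
        centers[k] = X[int(np.argmax(d2))]
    return centers


def objective(X: np.ndarray, centers: np.ndarray, U: np.ndarray, b: float = 2.0) -> float:
    return float(np.sum(U ** b * _sq_distances(X, centers)))


def fcm_fit(X: np.ndarray, K2: int, b: float = 2.0, seed: int = 0,
            tol: float = 1e-8, max_iter: int = 500,
            init: np.ndarray | str = "random") -> tuple[np.ndarray, list[float]]:
    """Alternate membership/center updates until J_f converges.

    *init* may be ``"random"`` (K2 distinct samples, seeded) or an
    explicit ``(K2, d)`` array of starting centers.  Returns the centers
    and the (non-increasing) J_f history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if K2 < 2:
        raise ValueError("K2 must be >= 2")
    n_distinct = np.unique(X, axis=0).shape[0]
    if K2 > n_distinct:
        raise ValueError(f"K2 = {K2} exceeds the {n_distinct} distinct samples")
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be 'random' or an array of centers")
        rng = np.random.default_rng(seed)
        # draw until the K2 picks are distinct points
        while True:
            centers = X[rng.choice(X.shape[0], size=K2, replace=False)]
            if np.unique(centers, axis=0).shape[0] == K2:
                break
    else:
        centers = np.array(init, dtype=float)
        if centers.shape != (K2, X.shape[1]):
            raise ValueError(f"init centers must have shape ({K2}, {X.shape[1]})")
    history: list[float] = []
    for _ in range(max_iter):
        U = membership(X, centers, b)
        centers = update_centers(X, U, b)
        J = objective(X, centers, U, b)
        history.append(J)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol:
            break
    return centers, history


@dataclass
class FcmModel:
    """A fitted, labelled FCM classifier for one posture category."""

    category: int
    centers: np.ndarray                 # (K2, 90)
    cluster_to_posture: dict[int, int]  # cluster index → posture id
    b: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        K2 = self.centers.shape[0]
        if K2 < 2:
            raise ValueError("an FCM model needs at least two clusters")
        postures = sorted(self.cluster_to_posture.values())
        if sorted(self.cluster_to_posture) != list(range(K2)) or len(set(postures)) != K2:
            raise ValueError("cluster→posture map must be a bijection over the clusters")

    @property
    def K2(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "b": self.b,
            "centers": self.centers.tolist(),
            "cluster_to_posture": {str(k): v for k, v in self.cluster_to_posture.items()},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FcmModel":
        return cls(
            category=int(doc["category"]), b=float(doc["b"]),
            centers=np.array(doc["centers"], dtype=float),
            cluster_to_posture={int(k): int(v) for k, v in doc["cluster_to_posture"].items()},
            meta=doc.get("meta", {}),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"format": "posefit-fcm-v1", **self.to_dict()}))

    @classmethod
    def from_json(cls, path) -> "FcmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def assign_labels(centers: np.ndarray, X: np.ndarray, labels: np.ndarray,
                  b: float = 2.0) -> dict[int, int]:
    """Greedy bijective cluster→posture map by total membership mass.

    Repeatedly matches the (cluster, posture) pair with the largest
    remaining mass; any clusters left without a clear posture are matched
    by exclusion with a warning.
    """
    import warnings

    X = np.atleast_2d(X)
    labels = np.asarray(labels, dtype=int)
    postures = sorted(set(labels.tolist()))
    K2 = centers.shape[0]
    if len(postures) != K2:
        raise ValueError(f"samples cover {len(postures)} postures but the model has {K2} clusters")
    U = membership(X, centers, b)
    mass = np.stack([U[labels == p].sum(axis=0) for p in postures], axis=1)  # (K2, P)
    mapping: dict[int, int] = {}
    used_k, used_p = set(), set()
    work = mass.copy()
    for _ in range(K2):
        k, j = np.unravel_index(int(np.argmax(work)), work.shape)
        if work[k, j] <= 0:
            break
        mapping[int(k)] = postures[int(j)]
        used_k.add(int(k)); used_p.add(int(j))
        work[k, :] = -np.inf
        work[:, j] = -np.inf
    left_k = [k for k in range(K2) if k not in used_k]
    left_p = [postures[j] for j in range(K2) if j not in used_p]
    if left_k:
        warnings.warn("clusters without dominant posture matched by exclusion", stacklevel=2)
        for k, p in zip(left_k, left_p):
            mapping[k] = p
    return mapping


def fit_category_model(X: np.ndarray, labels: np.ndarray, category: int,
                       b: float = 2.0, seed: int = 0, tol: float = 1e-8,
                       max_iter: int = 500, init: str = "labelled") -> FcmModel:
    """Fit and label the FCM model of one category.

    With ``init="labelled"`` (default) centers start at the per-posture
    labelled means, which also makes the cluster→posture assignment
    near-trivial; ``init="random"`` keeps the classic seeded start.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    expected = set(POSTURES_IN_CATEGORY[category])
    present = set(labels.tolist())
    if present - expected:
        raise ValueError(f"labels {sorted(present - expected)} do not belong to category {category}")
    if expected - present:
        raise ValueError(f"category {category} is missing postures {sorted(expected - present)} in the samples")
    K2 = len(expected)
    if init == "labelled":
        start = np.stack([X[labels == p].mean(axis=0) for p in sorted(expected)])
        centers, history = fcm_fit(X, K2, b=b, seed=seed, tol=tol, max_iter=max_iter, init=start)
    else:
        centers, history = fcm_fit(X, K2, b=b, seed=seed, tol=tol, max_iter=max_iter, init="random")
    mapping = assign_labels(centers, X, labels, b=b)
    return FcmModel(category=category, centers=centers, cluster_to_posture=mapping, b=b,
                    meta={"iterations": len(history), "final_Jf": history[-1], "seed": seed, "init": init})


def predict_posture(model: FcmModel, X: np.ndarray, t2: float = 0.5) -> np.ndarray:
    """Posture id per row, or 0 where the best membership is ≤ *t2*.

    Ties at the maximum resolve to the lowest cluster index.
    """
    U = membership(X, model.centers, model.b)
    best = np.argmax(U, axis=1)
    scores = U[np.arange(U.shape[0]), best]
    postures = np.array([model.cluster_to_posture[k] for k in range(model.K2)])
    return np.where(scores > t2, postures[best], 0)


__all__ = [
    "N_FEATURES", "extract_body_features", "membership", "update_centers",
    "objective", "fcm_fit", "FcmModel", "assign_labels", "fit_category_model",
    "predict_posture",
]
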