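"""Per-posture conditional-Gaussian network scoring segment standard degree.

Every body part is modelled as a 4-D Gaussian over its quaternion
relative to the waist (the waist root itself over its animation-frame
quaternion, since its waist-relative quaternion is identically the
identity).  For each edge (child s, parent t) of the body tree the joint
8-D Gaussian is fitted by population moments,

    μ_s,t = Σ z⁽ⁱ⁾ / m,     Σ_s,t(p,q) = Σ (z⁽ⁱ⁾_p − μ_p)(z⁽ⁱ⁾_q − μ_q) / m,

with a small ridge added before inversion (unit-norm quaternion data
makes Σ rank-deficient).  Partitioning the precision Σ⁻¹ into 4×4 blocks
B11, B12, B21, B22 gives the conditional

    s | t  ~  N( μ_s − B11⁻¹ B12 (t − μ_t),  B11⁻¹ ).

A segment observation s is scored by the probability that a random draw
S from this conditional lies *farther* from the conditional mean than s
does, measured in the Mahalanobis norm: with d² the squared Mahalanobis
distance, the score is the χ²₄ survival function at d².  Standard
segments thus score near 1 and deviated segments near 0; parts scoring
below the threshold (0.3 by default) are flagged nonstandard.

Quaternions are treated as unconstrained 4-vectors after hemisphere
canonicalization and alignment to the per-edge mean direction — Gaussian
statistics are meaningless across the double cover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .body import (BodyTopology, CalibrationSet, N_SEGMENTS, NONWAIST, SEGMENTS,
                   WAIST, calibrate_to_animation, relative_to_waist)
from .data import PostureInstance
from .quat import canonicalize

# Unit-norm quaternion data leaves the covariance near-singular along the
# mean direction, where the residual variance is second order, ~(σ²/2)² —
# about 2.5e-5 at a typical 0.1 rad angular spread.  The ridge must dominate
# that scale while staying well below the informative variances (>= ~3e-4).
DEFAULT_RIDGE = 1e-4
DEFAULT_THRESHOLD = 0.3
_CHI2_DF = 4


def _align_hemisphere(Q: np.ndarray) -> np.ndarray:
    """Canonicalize, then flip rows against the mean direction."""
    Q = canonicalize(np.asarray(Q, dtype=float))
    mean = Q.mean(axis=0)
    n = np.linalg.norm(mean)
    if n > 1e-12:
        flip = (Q @ mean) < 0
        Q = np.where(flip[:, None], -Q, Q)
    return Q


@dataclass
class EdgeGaussian:
    """Joint child–parent Gaussian of one body-tree edge."""

    child: int
    parent: int
    mu: np.ndarray        # (8,) = [μ_s, μ_t]
    cov: np.ndarray       # (8, 8), ridge already added
    ridge: float = DEFAULT_RIDGE

    B11: np.ndarray = field(init=False, repr=False)
    B12: np.ndarray = field(init=False, repr=False)
    B21: np.ndarray = field(init=False, repr=False)
    B22: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mu.shape != (8,) or self.cov.shape != (8, 8):
            raise ValueError("edge Gaussian needs an 8-vector mean and 8x8 covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        P = np.linalg.inv(self.cov)
        self.B11, self.B12 = P[:4, :4], P[:4, 4:]
        self.B21, self.B22 = P[4:, :4], P[4:, 4:]

    @property
    def mu_child(self) -> np.ndarray:
        return self.mu[:4]

    @property
    def mu_parent(self) -> np.ndarray:
        return self.mu[4:]


@dataclass
class ConditionalGaussian:
    """Conditional child distribution evaluated at a parent observation."""

    mu: np.ndarray   # (4,)
    cov: np.ndarray  # (4, 4) = B11⁻¹

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mu.shape != (4,) or self.cov.shape != (4, 4):
            raise ValueError("conditional Gaussian needs a 4-vector mean and 4x4 covariance")


def fit_joint_gaussian(child: np.ndarray, parent: np.ndarray,
                       child_idx: int = -1, parent_idx: int = -1,
                       ridge: float = DEFAULT_RIDGE) -> EdgeGaussian:
    """Population-moment fit of the joint child–parent Gaussian.

    Requires at least two samples; quaternion samples are hemisphere-
    aligned before the moments are taken, and ``ridge · I`` is added to
    the covariance before any inversion.
    """
    child = np.atleast_2d(np.asarray(child, dtype=float))
    parent = np.atleast_2d(np.asarray(parent, dtype=float))
    if child.shape != parent.shape or child.shape[1] != 4:
        raise ValueError("child and parent must be matching (m, 4) sample arrays")
    m = child.shape[0]
    if m < 2:
        raise ValueError("need at least two samples to fit an edge Gaussian")
    if not (np.all(np.isfinite(child)) and np.all(np.isfinite(parent))):
        raise ValueError("non-finite samples")
    Z = np.concatenate([_align_hemisphere(child), _align_hemisphere(parent)], axis=1)
    mu = Z.mean(axis=0)
    Zc = Z - mu
    cov = (Zc.T @ Zc) / m + ridge * np.eye(8)
    return EdgeGaussian(child=child_idx, parent=parent_idx, mu=mu, cov=cov, ridge=ridge)


def conditional_params(edge: EdgeGaussian, t_obs: np.ndarray) -> ConditionalGaussian:
    """Conditional child Gaussian given one parent observation."""
    t_obs = np.asarray(t_obs, dtype=float)
    if t_obs.shape != (4,):
        raise ValueError("parent observation must be a 4-vector")
    B11_inv = np.linalg.inv(edge.B11)
    mu = edge.mu_child - B11_inv @ edge.B12 @ (t_obs - edge.mu_parent)
    return ConditionalGaussian(mu=mu, cov=B11_inv)


def standard_degree(cond: ConditionalGaussian, s_obs: np.ndarray,
                    norm: str = "mahalanobis", n_draws: int = 100_000,
                    rng: np.random.Generator | None = None) -> float:
    """Probability that a conditional draw is farther from the mean than
    *s_obs* — near 1 for standard observations, near 0 for deviated ones.

    Under the Mahalanobis norm (default) this is the χ²₄ survival
    function at the squared Mahalanobis distance; ``norm="euclidean"``
    estimates the same exceedance probability for the Euclidean norm by
    Monte Carlo.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    if s_obs.shape != (4,):
        raise ValueError("segment observation must be a 4-vector")
    # score is hemisphere-insensitive: compare on the mean's side
    if float(s_obs @ cond.mu) < 0:
        s_obs = -s_obs
    diff = s_obs - cond.mu
    if norm == "mahalanobis":
        d2 = float(diff @ np.linalg.solve(cond.cov, diff))
        return float(stats.chi2.sf(d2, _CHI2_DF))
    if norm == "euclidean":
        rng = rng or np.random.default_rng(0)
        draws = rng.multivariate_normal(cond.mu, cond.cov, size=n_draws, method="cholesky")
        r2 = np.sum((draws - cond.mu) ** 2, axis=1)
        return float(np.mean(r2 > float(diff @ diff)))
    raise ValueError("norm must be 'mahalanobis' or 'euclidean'")


def _part_samples(anim: np.ndarray) -> dict[int, np.ndarray]:
    """Per-part 4-D sample arrays from (T, 11, 4) animation-frame quats."""
    rel = relative_to_waist(anim)  # (T, 10, 4) in NONWAIST order
    out = {seg: rel[:, k, :] for k, seg in enumerate(NONWAIST)}
    out[WAIST] = canonicalize(anim[:, WAIST, :])
    return out


@dataclass
class BayesNetModel:
    """Fitted evaluation network of one posture."""

    posture: int
    topology: BodyTopology
    edges: dict[int, EdgeGaussian]       # child segment → edge Gaussian
    root_mu: np.ndarray                  # (4,) waist marginal mean
    root_cov: np.ndarray                 # (4, 4) waist marginal covariance (ridged)
    ridge: float = DEFAULT_RIDGE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = sorted(i for i in range(N_SEGMENTS) if i != WAIST)
        if sorted(self.edges) != expected:
            raise ValueError("need one edge Gaussian per non-waist segment (10 edges + root marginal)")

    def to_json(self, path) -> None:
        doc = {
            "format": "posefit-bayesnet-v1",
            "posture": self.posture,
            "ridge": self.ridge,
            "topology": {SEGMENTS[c]: SEGMENTS[p] for c, p in self.topology.edges()},
            "root": {"mu": self.root_mu.tolist(), "cov": self.root_cov.tolist()},
            "edges": {
                SEGMENTS[c]: {"parent": SEGMENTS[e.parent], "mu": e.mu.tolist(), "cov": e.cov.tolist()}
                for c, e in self.edges.items()
            },
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "BayesNetModel":
        doc = json.loads(Path(path).read_text())
        topo = BodyTopology(parent=tuple(sorted(
            (SEGMENTS.index(c), SEGMENTS.index(p)) for c, p in doc["topology"].items()
        )))
        edges = {
            SEGMENTS.index(c): EdgeGaussian(
                child=SEGMENTS.index(c), parent=SEGMENTS.index(d["parent"]),
                mu=np.array(d["mu"]), cov=np.array(d["cov"]), ridge=doc["ridge"],
            )
            for c, d in doc["edges"].items()
        }
        return cls(posture=int(doc["posture"]), topology=topo, edges=edges,
                   root_mu=np.array(doc["root"]["mu"]), root_cov=np.array(doc["root"]["cov"]),
                   ridge=float(doc["ridge"]), meta=doc.get("meta", {}))


def fit_network(instances: list[PostureInstance], cal: CalibrationSet,
                topology: BodyTopology | None = None,
                ridge: float = DEFAULT_RIDGE) -> BayesNetModel:
    """Fit the per-posture network from training instances of one posture."""
    if not instances:
        raise ValueError("no training instances")
    postures = {inst.label for inst in instances}
    if len(postures) != 1:
        raise ValueError(f"training instances mix postures {sorted(postures)}")
    anim = np.concatenate([calibrate_to_animation(inst.quats, cal) for inst in instances])
    if anim.shape[0] < 2:
        raise ValueError("need at least two training frames")
    samples = _part_samples(anim)
    topology = topology or BodyTopology()
    edges = {
        child: fit_joint_gaussian(samples[child], samples[parent],
                                  child_idx=child, parent_idx=parent, ridge=ridge)
        for child, parent in topology.edges()
    }
    W = _align_hemisphere(samples[WAIST])
    root_mu = W.mean(axis=0)
    Wc = W - root_mu
    root_cov = (Wc.T @ Wc) / W.shape[0] + ridge * np.eye(4)
    return BayesNetModel(posture=instances[0].label, topology=topology, edges=edges,
                         root_mu=root_mu, root_cov=root_cov, ridge=ridge,
                         meta={"n_frames": int(anim.shape[0]), "n_instances": len(instances)})


def score_frames(model: BayesNetModel, quats: np.ndarray, cal: CalibrationSet) -> np.ndarray:
    """Standard-degree scores for every segment of every frame.

    *quats* is ``(T, 11, 4)`` raw data; returns ``(T, 11)`` scores in
    [0, 1], column-aligned with :data:`posefit.body.SEGMENTS`.
    Vectorized over frames.
    """
    quats = np.asarray(quats, dtype=float)
    if quats.ndim == 2:
        quats = quats[None]
    anim = calibrate_to_animation(quats, cal)
    samples = _part_samples(anim)
    T = anim.shape[0]
    scores = np.empty((T, N_SEGMENTS))
    # root: marginal Mahalanobis
    W = samples[WAIST]
    W = np.where((W @ model.root_mu < 0)[:, None], -W, W)
    diff = W - model.root_mu
    d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(model.root_cov, diff.T).T)
    scores[:, WAIST] = stats.chi2.sf(d2, _CHI2_DF)
    for child, edge in model.edges.items():
        S = samples[child]
        Tp = samples[edge.parent]
        B11_inv = np.linalg.inv(edge.B11)
        K = B11_inv @ edge.B12
        mu_cond = edge.mu_child[None, :] - (Tp - edge.mu_parent[None, :]) @ K.T  # (T, 4)
        S = np.where((np.einsum("ij,ij->i", S, mu_cond) < 0)[:, None], -S, S)
        diff = S - mu_cond
        P = np.linalg.inv(B11_inv)  # precision of the conditional
        d2 = np.einsum("ij,jk,ik->i", diff, P, diff)
        scores[:, child] = stats.chi2.sf(d2, _CHI2_DF)
    return scores


@dataclass
class EvaluationReport:
    """Per-segment standard-degree summary of an evaluated recording."""

    posture: int
    scores: np.ndarray          # (T, 11) per-frame scores
    threshold: float
    mean_scores: np.ndarray = field(init=False)
    nonstandard: list[int] = field(init=False)

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.mean_scores = self.scores.mean(axis=0)
        self.nonstandard = [int(i) for i in np.flatnonzero(self.mean_scores < self.threshold)]

    def as_dict(self) -> dict:
        return {
            "posture": self.posture,
            "threshold": self.threshold,
            "mean_scores": {SEGMENTS[i]: float(s) for i, s in enumerate(self.mean_scores)},
            "nonstandard": [SEGMENTS[i] for i in self.nonstandard],
        }


def evaluate_posture(model: BayesNetModel, quats: np.ndarray, cal: CalibrationSet,
                     threshold: float = DEFAULT_THRESHOLD,
                     posture: int | None = None) -> EvaluationReport:
    """Score a recording against the model and flag nonstandard parts.

    If *posture* is given it must match the model's posture (guards
    against evaluating a recording with the wrong network).
    """
    if posture is not None and posture != model.posture:
        raise ValueError(f"model is for posture {model.posture}, recording labelled {posture}")
    scores = score_frames(model, quats, cal)
    return EvaluationReport(posture=model.posture, scores=scores, threshold=threshold)


__all__ = [
    "DEFAULT_RIDGE", "DEFAULT_THRESHOLD", "EdgeGaussian", "ConditionalGaussian",
    "fit_joint_gaussian", "conditional_params", "standard_degree",
    "BayesNetModel", "fit_network", "score_frames", "EvaluationReport",
    "evaluate_posture",
]
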