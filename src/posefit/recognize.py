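"""Two-stage frame classification and cumulative-likelihood recognition.

Per frame, the waist feature is scored by the BP-ANN; if the best
category clears threshold ``t1`` the frame is routed to that category's
FCM model, whose best membership must clear ``t2`` to yield a posture.
Frames failing either stage are "noisy" (encoded as posture 0).

A posture *instance* is recognized by streaming its frames through a
per-posture likelihood vector initialised to zero: a recognized frame
adds ``τ`` to its posture and subtracts ``τ`` from every other posture,
with the vector clipped to [0, 1]; noisy frames leave it unchanged (a
configurable decay is available).  The first posture whose likelihood
strictly exceeds ``t3`` is emitted as the final result, which makes the
decision robust to isolated misclassified frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bpann, fcm
from .body import CalibrationSet, calibrate_to_animation
from .data import (CATEGORY_OF, N_CATEGORIES, N_POSTURES, PostureDatabase,
                   PostureInstance)

NOISY = 0  # frame-level "no decision" marker


@dataclass
class RecognizerConfig:
    """Thresholds of both stages plus the likelihood update step τ."""

    t1: float = 0.5
    t2: float = 0.5
    t3: float = 0.5
    tau: float = 0.1
    noisy_decay: bool = False  # if True, noisy frames subtract τ everywhere

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("t1", "t2", "t3"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.t3 < self.tau:
            raise ValueError("t3 must be >= tau")


@dataclass
class RecognitionState:
    """Per-posture cumulative likelihoods for one instance."""

    likelihoods: np.ndarray = field(default_factory=lambda: np.zeros(N_POSTURES))
    emitted: int | None = None

    def reset(self) -> None:
        self.likelihoods = np.zeros(N_POSTURES)
        self.emitted = None


@dataclass
class TwoStageModel:
    """BP-ANN category stage plus one labelled FCM model per category."""

    ann: bpann.AnnModel
    fcms: dict[int, fcm.FcmModel]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if sorted(self.fcms) != list(range(1, N_CATEGORIES + 1)):
            raise ValueError("need exactly one FCM model per category 1..5")
        covered = sorted(p for m in self.fcms.values() for p in m.cluster_to_posture.values())
        if covered != list(range(1, N_POSTURES + 1)):
            raise ValueError("FCM label maps must cover the 18 postures exactly once")

    def to_json(self, path) -> None:
        doc = {
            "format": "posefit-two-stage-v1",
            "ann": {"theta2": self.ann.theta2.tolist(), "theta3": self.ann.theta3.tolist(),
                    "meta": self.ann.meta},
            "fcms": {str(c): m.to_dict() for c, m in self.fcms.items()},
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "TwoStageModel":
        doc = json.loads(Path(path).read_text())
        ann = bpann.AnnModel(theta2=np.array(doc["ann"]["theta2"]),
                             theta3=np.array(doc["ann"]["theta3"]),
                             meta=doc["ann"].get("meta", {}))
        fcms = {int(c): fcm.FcmModel.from_dict(d) for c, d in doc["fcms"].items()}
        return cls(ann=ann, fcms=fcms, meta=doc.get("meta", {}))


def _subsample_indices(T: int, k: int) -> np.ndarray:
    if k >= T:
        return np.arange(T)
    return np.unique(np.linspace(0, T - 1, k).round().astype(int))


def train_two_stage(train_db: PostureDatabase, cal: CalibrationSet,
                    ann_config: bpann.AnnConfig | None = None,
                    b: float = 2.0, fcm_seed: int = 0, fcm_tol: float = 1e-8,
                    frames_per_instance: int = 20) -> TwoStageModel:
    """Train both stages on a labelled database.

    Static postures make consecutive frames near-duplicates, so training
    uses ``frames_per_instance`` evenly spaced frames of each instance
    (all frames if the instance is shorter).
    """
    ann_config = ann_config or bpann.AnnConfig()
    X1, X2, labels = [], [], []
    for inst in train_db.instances:
        idx = _subsample_indices(len(inst), frames_per_instance)
        anim = calibrate_to_animation(inst.quats[idx], cal)
        X1.append(bpann.extract_waist_features(anim))
        X2.append(fcm.extract_body_features(anim))
        labels.append(np.full(len(idx), inst.label))
    X1 = np.concatenate(X1)
    X2 = np.concatenate(X2)
    labels = np.concatenate(labels)
    categories = np.array([CATEGORY_OF[p] for p in labels])
    ann = bpann.train(X1, categories, ann_config)
    fcms = {}
    for c in range(1, N_CATEGORIES + 1):
        mask = categories == c
        fcms[c] = fcm.fit_category_model(X2[mask], labels[mask], category=c, b=b,
                                         seed=fcm_seed, tol=fcm_tol)
    return TwoStageModel(ann=ann, fcms=fcms,
                         meta={"n_train_instances": len(train_db), "frames_per_instance": frames_per_instance})


def classify_frames(model: TwoStageModel, quats: np.ndarray, cal: CalibrationSet,
                    config: RecognizerConfig | None = None) -> np.ndarray:
    """Frame-level posture labels for raw quaternions ``(T, 11, 4)``.

    Returns an int array with posture ids (1–18) and :data:`NOISY` (0)
    where either stage withholds a decision.
    """
    config = config or RecognizerConfig()
    quats = np.asarray(quats, dtype=float)
    single = quats.ndim == 2
    if single:
        quats = quats[None]
    anim = calibrate_to_animation(quats, cal)
    cats = bpann.predict_category(model.ann, bpann.extract_waist_features(anim), config.t1)
    out = np.zeros(len(cats), dtype=int)
    X2 = None
    for c in range(1, N_CATEGORIES + 1):
        mask = cats == c
        if not mask.any():
            continue
        if X2 is None:
            X2 = fcm.extract_body_features(anim)
        out[mask] = fcm.predict_posture(model.fcms[c], X2[mask], config.t2)
    return int(out[0]) if single else out


def update_likelihoods(state: RecognitionState, frame_result: int,
                       config: RecognizerConfig) -> RecognitionState:
    """Apply one frame's ±τ update (in place) and return the state.

    A recognized posture gains τ while every other posture loses τ; the
    vector is clipped to [0, 1].  Noisy frames change nothing unless
    ``noisy_decay`` is enabled, in which case all likelihoods decay by τ.
    """
    L = state.likelihoods
    if frame_result == NOISY:
        if config.noisy_decay:
            L -= config.tau
    else:
        L -= config.tau
        L[frame_result - 1] += 2 * config.tau
    np.clip(L, 0.0, 1.0, out=L)
    return state


def recognize_instance(model: TwoStageModel, instance: PostureInstance,
                       cal: CalibrationSet, config: RecognizerConfig | None = None,
                       return_frames: bool = False):
    """Stream an instance through the recognizer.

    The likelihood vector starts at zero; the first posture whose
    likelihood strictly exceeds ``t3`` is emitted and frozen.  Returns
    the emitted posture id (or ``None``), optionally with the per-frame
    labels.
    """
    config = config or RecognizerConfig()
    frame_labels = classify_frames(model, instance.quats, cal, config)
    result = accumulate_stream(frame_labels, config)
    return (result, frame_labels) if return_frames else result


def accumulate_stream(frame_labels, config: RecognizerConfig) -> int | None:
    """Run the cumulative-likelihood rule over a stream of frame labels.

    Returns the first posture whose likelihood strictly exceeds ``t3``,
    or ``None`` if the stream ends without an emission.  A (guarded) tie
    at the crossing resolves to the lowest posture id.
    """
    state = RecognitionState()
    for res in frame_labels:
        update_likelihoods(state, int(res), config)
        # strict crossing; the epsilon keeps accumulated tau steps that land
        # exactly on t3 (up to float error) from emitting early
        above = np.flatnonzero(state.likelihoods > config.t3 + 1e-9)
        if above.size:
            state.emitted = int(above[0]) + 1
            break
    return state.emitted


def accuracy_report(truth: np.ndarray, predicted: np.ndarray) -> pd.DataFrame:
    """Per-posture and total recognition accuracy table.

    *truth* holds posture ids 1–18; *predicted* the matching decisions
    (0/None/NaN count as incorrect).  The ``Total`` row sums counts
    before dividing; percentages are rounded to two decimals.
    """
    truth = np.asarray(truth)
    pred = np.array([0 if p is None else int(p) for p in np.ravel(predicted)])
    if truth.size == 0:
        raise ValueError("cannot build an accuracy report from empty results")
    if truth.shape != pred.shape:
        raise ValueError("truth and predictions must align")
    counts = {}
    for p in sorted(set(truth.tolist())):
        mask = truth == p
        counts[int(p)] = (int(np.sum(pred[mask] == p)), int(mask.sum()))
    return report_from_counts(counts)


def report_from_counts(counts: dict[int, tuple[int, int]]) -> pd.DataFrame:
    """Accuracy table from per-posture (correct, total) count pairs."""
    if not counts:
        raise ValueError("cannot build an accuracy report from empty results")
    rows, c_sum, t_sum = [], 0, 0
    for p in sorted(counts):
        c, t = counts[p]
        rows.append({"posture": p, "correct": c, "total": t,
                     "accuracy_pct": round(100.0 * c / t, 2) if t else float("nan")})
        c_sum += c
        t_sum += t
    rows.append({"posture": "Total", "correct": c_sum, "total": t_sum,
                 "accuracy_pct": round(100.0 * c_sum / t_sum, 2)})
    return pd.DataFrame(rows).set_index("posture")


def evaluate_recognizer(model: TwoStageModel, test_db: PostureDatabase,
                        cal: CalibrationSet, config: RecognizerConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frame-level and instance-level accuracy tables over a test set."""
    config = config or RecognizerConfig()
    f_true, f_pred, i_true, i_pred = [], [], [], []
    for inst in test_db.instances:
        emitted, frames = recognize_instance(model, inst, cal, config, return_frames=True)
        f_true.append(np.full(len(inst), inst.label))
        f_pred.append(frames)
        i_true.append(inst.label)
        i_pred.append(emitted)
    frame_report = accuracy_report(np.concatenate(f_true), np.concatenate(f_pred))
    instance_report = accuracy_report(np.array(i_true), np.array(i_pred))
    return frame_report, instance_report


__all__ = [
    "NOISY", "RecognizerConfig", "RecognitionState", "TwoStageModel",
    "train_two_stage", "classify_frames", "update_likelihoods",
    "accumulate_stream", "recognize_instance", "accuracy_report", "report_from_counts",
    "evaluate_recognizer",
]
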