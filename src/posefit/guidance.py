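"""Corrective guidance: deviation angles and orientation words.

Once the evaluation network flags a segment, its observed waist-relative
quaternion is compared with the conditional-model mean: the deviation
rotation is ``q_dev = μ_s|t⁻¹ ⊗ q_s-6``, whose rotation matrix R yields
signed planar angle differences

    d_fore-and-back = sign(−R21) · arccos( R11 / √(R11² + R21²) )
    d_up-and-down   = sign(−R31) · arccos( R11 / √(R11² + R31²) )

(the azimuth/elevation of the segment's longitudinal local x-axis).  For
elbow and knee segments the bend–stretch difference compares the child's
x-axis direction in the parent frame between model and observation:

    d_bend-and-stretch = arccos((V_model)_x) − arccos((V_actual)_x),
    V = Im{ (q_p⁻¹ ⊗ q_c) ⊗ (0,1,0,0) ⊗ (q_p⁻¹ ⊗ q_c)⁻¹ }.

Words follow the sign rules: d_fore-and-back ≥ 0 → "backward" (else
forward), d_up-and-down ≥ 0 → "downward" (else upward), left–right ≥ 0 →
"rightward" (else leftward, a symmetric reconstruction for head/thighs),
and d_bend-and-stretch ≥ 0 → "bend" (else stretch).  The guidance extent
is |d| in radians.  For non-stand categories the deviation is conjugated
by the category's nominal waist rotation before word selection, mapping
directions into the trainer's own perspective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import BayesNetModel, EvaluationReport, evaluate_posture
from .body import (CalibrationSet, HEAD, LFARM, LSHANK, LTHIGH, LUARM, RFARM,
                   RSHANK, RTHIGH, RUARM, SEGMENTS, WAIST,
                   calibrate_to_animation, relative_to_waist, NONWAIST)
from .quat import (normalize, qinv, qmul, quat_to_matrix, require_unit,
                   rotate_vector)

#: segments guided by planar (azimuth/elevation) differences
PLANAR_SEGMENTS = {LUARM, RUARM, HEAD, LTHIGH, RTHIGH}
#: segments guided by the joint bend–stretch difference
BEND_SEGMENTS = {LFARM, RFARM, LSHANK, RSHANK}
GUIDABLE = PLANAR_SEGMENTS | BEND_SEGMENTS

_PHRASE = {
    HEAD: "your head",
    LUARM: "your left arm", RUARM: "your right arm",
    LFARM: "your left forearm", RFARM: "your right forearm",
    LTHIGH: "your left leg", RTHIGH: "your right leg",
    LSHANK: "your left knee", RSHANK: "your right knee",
}

_TEMPLATES = {
    "upward": "lift up {seg}",
    "downward": "lower {seg}",
    "forward": "put {seg} forward",
    "backward": "put {seg} backward",
    "leftward": "put {seg} to left",
    "rightward": "put {seg} to right",
    "bend": "bend {seg}",
    "stretch": "straighten {seg}",
}


@dataclass
class GuidanceConfig:
    """Evaluation threshold, suppression band, and perspective handling."""

    score_threshold: float = 0.3
    acceptable_range: float = 0.1   # rad; smaller deviations produce no item
    category: int = 1               # posture category, for perspective remapping


@dataclass
class GuidanceItem:
    """One corrective instruction for one segment."""

    segment: int
    word: str
    extent: float
    d_fore_back: float | None = None
    d_second: float | None = None       # up–down or left–right
    d_bend_stretch: float | None = None
    sentence: str = ""

    def __post_init__(self):
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if not self.sentence:
            self.sentence = _TEMPLATES[self.word].format(seg=_PHRASE[self.segment]) + f" ({self.extent:.2f} rad)"


@dataclass
class GuidanceReport:
    """Evaluation scores plus ordered corrective items and sentences."""

    posture: int
    evaluation: EvaluationReport
    items: list[GuidanceItem] = field(default_factory=list)

    @property
    def sentences(self) -> list[str]:
        if not self.items:
            return ["posture standard"]
        return [item.sentence for item in self.items]


def deviation_matrix(mu_cond: np.ndarray, q_rel: np.ndarray) -> np.ndarray:
    """Rotation matrix of the actual-vs-model deviation ``μ⁻¹ ⊗ q``.

    *mu_cond* is the (unnormalized) conditional mean 4-vector, *q_rel*
    the observed waist-relative quaternion.
    """
    mu_cond = np.asarray(mu_cond, dtype=float)
    n = np.linalg.norm(mu_cond)
    if n < 1e-8:
        raise ValueError("conditional mean has near-zero norm")
    mu = mu_cond / n
    q = require_unit(np.asarray(q_rel, dtype=float))
    if float(q @ mu) < 0:  # same-hemisphere comparison
        q = -q
    return quat_to_matrix(normalize(qmul(qinv(mu), q)))


def planar_diffs(R: np.ndarray) -> tuple[float, float]:
    """Signed fore–back and up–down angle differences of a deviation matrix."""
    R = np.asarray(R, dtype=float)
    r11, r21, r31 = R[0, 0], R[1, 0], R[2, 0]
    if abs(r11) < 1e-12 and abs(r21) < 1e-12:
        warnings.warn("degenerate fore-and-back projection; reporting 0", stacklevel=2)
        d_fb = 0.0
    else:
        d_fb = float(np.sign(-r21) * np.arccos(np.clip(r11 / np.hypot(r11, r21), -1, 1)))
    if abs(r11) < 1e-12 and abs(r31) < 1e-12:
        warnings.warn("degenerate up-and-down projection; reporting 0", stacklevel=2)
        d_ud = 0.0
    else:
        d_ud = float(np.sign(-r31) * np.arccos(np.clip(r11 / np.hypot(r11, r31), -1, 1)))
    return d_fb, d_ud


def bend_stretch_diff(q_parent_rel: np.ndarray, q_child_rel: np.ndarray,
                      mu_child_cond: np.ndarray) -> float:
    """Signed bend–stretch difference of an elbow/knee segment."""
    mu = np.asarray(mu_child_cond, dtype=float)
    n = np.linalg.norm(mu)
    if n < 1e-8:
        raise ValueError("conditional mean has near-zero norm")
    x = np.array([1.0, 0.0, 0.0])
    inv_p = qinv(q_parent_rel)
    v_model = rotate_vector(normalize(qmul(inv_p, mu / n)), x)
    v_actual = rotate_vector(normalize(qmul(inv_p, q_child_rel)), x)
    return float(np.arccos(np.clip(v_model[0], -1, 1)) - np.arccos(np.clip(v_actual[0], -1, 1)))


def orientation_word(segment, d_first: float, d_second: float | None,
                     category: int = 1) -> tuple[str, float]:
    """Dominant orientation word and extent for a segment's signed diffs.

    For planar segments ``d_first`` is the fore–back difference and
    ``d_second`` the up–down (arms) or left–right (head/thighs)
    difference; the axis with the larger magnitude wins.  For bend
    segments ``d_first`` is the bend–stretch difference.
    """
    from .body import segment_index

    seg = segment_index(segment)
    if seg in BEND_SEGMENTS:
        word = "bend" if d_first >= 0 else "stretch"
        return word, abs(d_first)
    if seg not in PLANAR_SEGMENTS:
        raise ValueError(f"segment {SEGMENTS[seg]} has no guidance vocabulary")
    if d_second is None:
        raise ValueError("planar segments need both signed differences")
    if abs(d_first) >= abs(d_second):
        word = "backward" if d_first >= 0 else "forward"
        return word, abs(d_first)
    if seg in (LUARM, RUARM):
        word = "downward" if d_second >= 0 else "upward"
    else:
        word = "rightward" if d_second >= 0 else "leftward"
    return word, abs(d_second)


def _category_matrix(category: int) -> np.ndarray:
    from .synth import CATEGORY_WAIST_QUAT

    return quat_to_matrix(CATEGORY_WAIST_QUAT[category])


def segment_differences(model: BayesNetModel, quats: np.ndarray, cal: CalibrationSet,
                        category: int = 1) -> dict[int, dict[str, float]]:
    """Frame-averaged signed guidance differences for every guidable segment.

    Returns ``{segment: {"d_fore_back":…, "d_second":…}}`` for planar
    segments and ``{"d_bend_stretch":…}`` for elbow/knee segments.
    """
    quats = np.asarray(quats, dtype=float)
    if quats.ndim == 2:
        quats = quats[None]
    anim = calibrate_to_animation(quats, cal)
    rel = relative_to_waist(anim)                      # (T, 10, 4)
    col = {seg: k for k, seg in enumerate(NONWAIST)}
    M = _category_matrix(category)
    out: dict[int, dict[str, float]] = {}
    T = anim.shape[0]
    for seg in sorted(GUIDABLE):
        edge = model.edges[seg]
        B11_inv = np.linalg.inv(edge.B11)
        K = B11_inv @ edge.B12
        parent = edge.parent
        if parent == WAIST:
            from .quat import canonicalize
            p_obs = canonicalize(anim[:, WAIST, :])
        else:
            p_obs = rel[:, col[parent], :]
        mu_cond = edge.mu_child[None, :] - (p_obs - edge.mu_parent[None, :]) @ K.T
        s_obs = rel[:, col[seg], :]
        if seg in PLANAR_SEGMENTS:
            d1 = np.empty(T)
            d2 = np.empty(T)
            for t in range(T):
                R = deviation_matrix(mu_cond[t], s_obs[t])
                if category != 1:
                    R = M @ R @ M.T
                d1[t], d2[t] = planar_diffs(R)
            out[seg] = {"d_fore_back": float(d1.mean()), "d_second": float(d2.mean())}
        else:
            d = np.empty(T)
            for t in range(T):
                d[t] = bend_stretch_diff(p_obs[t], s_obs[t], mu_cond[t])
            out[seg] = {"d_bend_stretch": float(d.mean())}
    return out


def analyze_posture(model: BayesNetModel, quats: np.ndarray, cal: CalibrationSet,
                    config: GuidanceConfig | None = None) -> GuidanceReport:
    """Full evaluation + guidance pass over a recording of one posture.

    Flags segments scoring below the threshold, computes their deviation
    differences, and renders one imperative sentence per flagged
    guidable segment whose extent exceeds the acceptable range.
    """
    config = config or GuidanceConfig()
    evaluation = evaluate_posture(model, quats, cal, threshold=config.score_threshold)
    diffs = segment_differences(model, quats, cal, category=config.category)
    items: list[GuidanceItem] = []
    for seg in evaluation.nonstandard:
        if seg not in GUIDABLE:
            continue
        d = diffs[seg]
        if seg in PLANAR_SEGMENTS:
            word, extent = orientation_word(seg, d["d_fore_back"], d["d_second"], config.category)
            if extent < config.acceptable_range:
                continue
            items.append(GuidanceItem(segment=seg, word=word, extent=extent,
                                      d_fore_back=d["d_fore_back"], d_second=d["d_second"]))
        else:
            word, extent = orientation_word(seg, d["d_bend_stretch"], None, config.category)
            if extent < config.acceptable_range:
                continue
            items.append(GuidanceItem(segment=seg, word=word, extent=extent,
                                      d_bend_stretch=d["d_bend_stretch"]))
    return GuidanceReport(posture=model.posture, evaluation=evaluation, items=items)


def render_report(report: GuidanceReport) -> list[str]:
    """Plain-text lines: per-segment scores then the guidance sentences."""
    lines = [f"posture {report.posture}: segment standard-degree scores"]
    for i, s in enumerate(report.evaluation.mean_scores):
        flag = "  NONSTANDARD" if i in report.evaluation.nonstandard else ""
        lines.append(f"  {SEGMENTS[i]:<7s} {s:0.3f}{flag}")
    lines.extend(report.sentences)
    return lines


__all__ = [
    "PLANAR_SEGMENTS", "BEND_SEGMENTS", "GUIDABLE",
    "GuidanceConfig", "GuidanceItem", "GuidanceReport",
    "deviation_matrix", "planar_diffs", "bend_stretch_diff",
    "orientation_word", "segment_differences", "analyze_posture", "render_report",
]
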