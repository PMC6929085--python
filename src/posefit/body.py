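"""Body segment map, sensor-to-animation calibration, and waist-relative frames.

Eleven IMUs are strapped to the body; by convention segment ``i`` carries
a fixed index:

====== ========  ====== ========
index  segment   index  segment
====== ========  ====== ========
0      head      6      waist
1      breast    7      LThigh
2      LUArm     8      LShank
3      LFArm     9      RThigh
4      RUArm     10     RShank
====== ========  ====== ========

Each IMU reports the orientation of its (remapped) local frame in the
global frame as a quaternion.  A one-off calibration posture anchors the
map from sensor frames into the common *animation frame* of the virtual
skeleton: with the calibration reading ``q_cali,i`` recorded, a live
reading ``q_i`` maps to

    ``q_i-interface = q_init ⊗ q_cali,i⁻¹ ⊗ q_i``

where ``q_init`` is the constant quaternion placing the segment group's
local axes in the animation frame.  Two groups exist: the trunk/leg/head
sensors (O1) and the arm sensors (O2), with distinct constants.

Downstream features use orientations *relative to the waist*,
``q_i-6 = q_6-interface⁻¹ ⊗ q_i-interface``, which removes the trainer's
global heading and makes features waist-centric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quat import canonicalize, qinv, qmul, require_unit, rotate_vector

SEGMENTS: tuple[str, ...] = (
    "head", "breast", "LUArm", "LFArm", "RUArm", "RFArm",
    "waist", "LThigh", "LShank", "RThigh", "RShank",
)
N_SEGMENTS = 11

HEAD, BREAST, LUARM, LFARM, RUARM, RFARM, WAIST, LTHIGH, LSHANK, RTHIGH, RSHANK = range(11)

#: indices whose sensors share the trunk-style local frame O1 / arm-style O2
O1_GROUP: tuple[int, ...] = (0, 1, 6, 7, 8, 9, 10)
O2_GROUP: tuple[int, ...] = (2, 3, 4, 5)

#: non-waist indices in feature order (used for the 90-D body feature)
NONWAIST: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 7, 8, 9, 10)

_S2 = np.sqrt(2.0) / 2.0
#: constant mapping the O1 sensor frame into the animation frame
Q_INIT1 = np.array([0.0, _S2, _S2, 0.0])
#: constant mapping the O2 sensor frame into the animation frame
Q_INIT2 = np.array([0.5, -0.5, -0.5, -0.5])


def segment_index(name_or_index) -> int:
    """Resolve a segment given its name or integer index."""
    if isinstance(name_or_index, str):
        try:
            return SEGMENTS.index(name_or_index)
        except ValueError:
            raise KeyError(f"unknown segment name {name_or_index!r}") from None
    i = int(name_or_index)
    if not 0 <= i < N_SEGMENTS:
        raise KeyError(f"segment index {i} out of range 0..10")
    return i


@dataclass(frozen=True)
class BodyTopology:
    """Rooted tree over the 11 segments used by the evaluation network.

    The waist is the unique root; the trunk chain runs waist→breast→head,
    arms hang off the breast and legs off the waist.  The head's parent is
    configurable (``head_parent="breast"`` by default, ``"waist"`` as the
    alternative reading of the guidance rule).
    """

    parent: tuple[tuple[int, int], ...] = field(default=(
        (HEAD, BREAST), (BREAST, WAIST),
        (LUARM, BREAST), (LFARM, LUARM), (RUARM, BREAST), (RFARM, RUARM),
        (LTHIGH, WAIST), (LSHANK, LTHIGH), (RTHIGH, WAIST), (RSHANK, RTHIGH),
    ))

    def __post_init__(self):
        pm = dict(self.parent)
        if WAIST in pm:
            raise ValueError("waist must be the root (it cannot have a parent)")
        if sorted(pm) != [i for i in range(N_SEGMENTS) if i != WAIST]:
            raise ValueError("parent map must cover every non-waist segment exactly once")
        # acyclicity / connectivity: every chain must terminate at the waist
        for child in pm:
            seen, node = set(), child
            while node != WAIST:
                if node in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(node)
                node = pm[node]

    @classmethod
    def default(cls, head_parent: str = "breast") -> "BodyTopology":
        hp = segment_index(head_parent)
        if hp not in (BREAST, WAIST):
            raise ValueError("head parent must be 'breast' or 'waist'")
        edges = tuple((c, hp if c == HEAD else p) for c, p in cls().parent)
        return cls(parent=edges)

    @property
    def parent_map(self) -> dict[int, int]:
        return dict(self.parent)

    def edges(self) -> list[tuple[int, int]]:
        """(child, parent) pairs ordered by child index."""
        return sorted(self.parent, key=lambda e: e[0])

    @staticmethod
    def init_group(i: int) -> int:
        """1 or 2: which init constant applies to segment *i*."""
        return 1 if i in O1_GROUP else 2


@dataclass
class CalibrationSet:
    """Per-subject calibration readings plus the two init constants.

    ``cali`` holds the 11 sensor quaternions recorded while the subject
    holds the calibration posture, index-aligned with :data:`SEGMENTS`.
    """

    cali: np.ndarray
    init1: np.ndarray = field(default_factory=lambda: Q_INIT1.copy())
    init2: np.ndarray = field(default_factory=lambda: Q_INIT2.copy())

    def __post_init__(self):
        self.cali = require_unit(np.asarray(self.cali, dtype=float))
        if self.cali.shape != (N_SEGMENTS, 4):
            raise ValueError(f"calibration set needs exactly {N_SEGMENTS} quaternions, got shape {self.cali.shape}")
        self.init1 = require_unit(np.asarray(self.init1, dtype=float))
        self.init2 = require_unit(np.asarray(self.init2, dtype=float))

    @classmethod
    def trivial(cls) -> "CalibrationSet":
        """Calibration under which raw data *is* animation-frame data.

        Setting ``q_cali,i = q_init`` of the segment's group makes
        ``q_init ⊗ q_cali,i⁻¹`` the identity, so calibration passes raw
        quaternions through unchanged.  Synthetic databases are generated
        directly in the animation frame and use this set.
        """
        cali = np.empty((N_SEGMENTS, 4))
        for i in range(N_SEGMENTS):
            cali[i] = Q_INIT1 if i in O1_GROUP else Q_INIT2
        return cls(cali=cali)

    # -- prefix q_init ⊗ q_cali⁻¹, one per segment -------------------------
    def _prefix(self) -> np.ndarray:
        pre = np.empty((N_SEGMENTS, 4))
        for i in range(N_SEGMENTS):
            init = self.init1 if i in O1_GROUP else self.init2
            pre[i] = qmul(init, qinv(self.cali[i]))
        return pre

    def to_json(self, path) -> None:
        doc = {
            "format": "posefit-calibration-v1",
            "order": "scalar-first (w, x, y, z)",
            "init1": self.init1.tolist(),
            "init2": self.init2.tolist(),
            "cali": {SEGMENTS[i]: self.cali[i].tolist() for i in range(N_SEGMENTS)},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationSet":
        doc = json.loads(Path(path).read_text())
        missing = [s for s in SEGMENTS if s not in doc["cali"]]
        if missing:
            raise ValueError(f"calibration file missing segments: {missing}")
        cali = np.array([doc["cali"][s] for s in SEGMENTS], dtype=float)
        return cls(cali=cali, init1=np.asarray(doc["init1"], float), init2=np.asarray(doc["init2"], float))


def calibrate_to_animation(raw, cal: CalibrationSet) -> np.ndarray:
    """Map raw sensor quaternions into the animation frame.

    Parameters
    ----------
    raw
        Array of shape ``(..., 11, 4)`` of unit quaternions, index-aligned
        with :data:`SEGMENTS`.
    cal
        The subject's :class:`CalibrationSet`.

    Returns
    -------
    ``(..., 11, 4)`` animation-frame quaternions
    ``q_i-interface = q_init ⊗ q_cali,i⁻¹ ⊗ q_i``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-2:] != (N_SEGMENTS, 4):
        got = raw.shape[-2] if raw.ndim >= 2 and raw.shape[-1] == 4 else "?"
        raise ValueError(
            f"expected quaternions for all {N_SEGMENTS} segments {SEGMENTS}, got {got} "
            f"(array shape {raw.shape})"
        )
    require_unit(raw)
    return qmul(cal._prefix(), raw)


def relative_to_waist(frame) -> np.ndarray:
    """Waist-relative quaternions ``q_i-6 = q_6⁻¹ ⊗ q_i`` for the 10
    non-waist segments, canonical hemisphere, ordered as :data:`NONWAIST`.

    *frame* is an animation-frame array of shape ``(..., 11, 4)``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-2:] != (N_SEGMENTS, 4):
        raise ValueError(f"expected (..., 11, 4) frames, got {frame.shape}")
    inv_waist = qinv(frame[..., WAIST, :])
    rel = qmul(inv_waist[..., None, :], frame[..., list(NONWAIST), :])
    return canonicalize(rel)


def inter_segment_angle(qa, qb, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Angle (rad, in ``[0, π]``) between the images of *axis* under two
    segment orientations expressed in a common frame.

    The default axis is the segment's longitudinal local x-axis.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("axis must be nonzero")
    u = axis / n
    va = rotate_vector(qa, u)
    vb = rotate_vector(qb, u)
    dot = np.sum(va * vb, axis=-1)
    return np.arccos(np.clip(dot, -1.0, 1.0))


__all__ = [
    "SEGMENTS", "N_SEGMENTS", "NONWAIST", "O1_GROUP", "O2_GROUP",
    "HEAD", "BREAST", "LUARM", "LFARM", "RUARM", "RFARM", "WAIST",
    "LTHIGH", "LSHANK", "RTHIGH", "RSHANK",
    "Q_INIT1", "Q_INIT2", "segment_index",
    "BodyTopology", "CalibrationSet",
    "calibrate_to_animation", "relative_to_waist", "inter_segment_angle",
]
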