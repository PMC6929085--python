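"""Quaternion algebra for body-segment orientations.

All quaternions are Hamilton, scalar-first ``(w, x, y, z)`` and encode
*active* rotations.  Every function broadcasts over leading axes, so a
single quaternion has shape ``(4,)`` while a 40 Hz stream of 11-segment
frames is simply an array of shape ``(T, 11, 4)``.

Because ``q`` and ``-q`` encode the same rotation (double cover),
:func:`canonicalize` maps quaternions onto the hemisphere with
``w >= 0`` (ties broken on the first nonzero component).  Any code that
does statistics on quaternion components must canonicalize first.
"""

from __future__ import annotations

import numpy as np

#: tolerance within which an input must be unit-norm to be accepted
UNIT_TOL = 1e-6

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _asq(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion array must have last axis of size 4, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite quaternion components")
    return q


def qnorm(q) -> np.ndarray:
    """Euclidean norm of the 4-vector(s)."""
    return np.linalg.norm(_asq(q), axis=-1)


def normalize(q) -> np.ndarray:
    """Rescale to unit norm; rejects (near-)zero quaternions."""
    q = _asq(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def require_unit(q, tol: float = UNIT_TOL) -> np.ndarray:
    """Validate unit norm within *tol* and return the array unchanged."""
    q = _asq(q)
    err = np.abs(np.linalg.norm(q, axis=-1) - 1.0)
    if np.any(err > tol):
        raise ValueError(f"expected unit quaternions (max |norm-1| = {float(np.max(err)):.3g} > {tol:g})")
    return q


def qmul(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (apply *b* first, then *a*)."""
    a, b = _asq(a), _asq(b)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q) -> np.ndarray:
    """Conjugate ``(w, -x, -y, -z)``."""
    return _asq(q) * np.array([1.0, -1.0, -1.0, -1.0])


def qinv(q) -> np.ndarray:
    """Inverse of a unit quaternion (equal to its conjugate).

    Zero quaternions are rejected; inputs must be unit within
    :data:`UNIT_TOL`.
    """
    q = _asq(q)
    if np.any(np.linalg.norm(q, axis=-1) < 1e-12):
        raise ValueError("zero quaternion has no inverse")
    return qconj(require_unit(q))


def canonicalize(q) -> np.ndarray:
    """Map onto the canonical hemisphere: ``w >= 0``, first nonzero
    component positive when ``w == 0``."""
    q = _asq(q)
    # lexicographic sign decision: first strictly nonzero of (w, x, y, z)
    sign = np.zeros(q.shape[:-1])
    for k in range(4):
        undecided = sign == 0
        sign = np.where(undecided, np.sign(q[..., k]), sign)
    return np.where((sign < 0)[..., None], -q, q)


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a unit Hamilton quaternion, shape ``(..., 3, 3)``.

    Rejects inputs whose norm is off by more than :data:`UNIT_TOL`.
    Invariant under ``q -> -q``.
    """
    q = require_unit(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def matrix_to_quat(R) -> np.ndarray:
    """Unit quaternion of a rotation matrix (Shepperd's method), canonical
    hemisphere.  Broadcasts over leading axes."""
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) rotation matrices, got {R.shape}")
    lead = R.shape[:-2]
    Rf = R.reshape((-1, 3, 3))
    out = np.empty((Rf.shape[0], 4))
    for n, M in enumerate(Rf):
        tr = np.trace(M)
        # pick the largest of the four squared components for stability
        cand = np.array([tr, M[0, 0], M[1, 1], M[2, 2]])
        i = int(np.argmax(cand))
        if i == 0:
            s = np.sqrt(tr + 1.0) * 2
            q = np.array([0.25 * s, (M[2, 1] - M[1, 2]) / s, (M[0, 2] - M[2, 0]) / s, (M[1, 0] - M[0, 1]) / s])
        elif i == 1:
            s = np.sqrt(1.0 + M[0, 0] - M[1, 1] - M[2, 2]) * 2
            q = np.array([(M[2, 1] - M[1, 2]) / s, 0.25 * s, (M[0, 1] + M[1, 0]) / s, (M[0, 2] + M[2, 0]) / s])
        elif i == 2:
            s = np.sqrt(1.0 + M[1, 1] - M[0, 0] - M[2, 2]) * 2
            q = np.array([(M[0, 2] - M[2, 0]) / s, (M[0, 1] + M[1, 0]) / s, 0.25 * s, (M[1, 2] + M[2, 1]) / s])
        else:
            s = np.sqrt(1.0 + M[2, 2] - M[0, 0] - M[1, 1]) * 2
            q = np.array([(M[1, 0] - M[0, 1]) / s, (M[0, 2] + M[2, 0]) / s, (M[1, 2] + M[2, 1]) / s, 0.25 * s])
        out[n] = q
    return canonicalize(normalize(out.reshape(lead + (4,))))


def rotate_vector(q, v) -> np.ndarray:
    """Rotate 3-vector(s) *v* by unit quaternion(s) *q*:
    ``Im{ q ⊗ (0, v) ⊗ q⁻¹ }``."""
    q = require_unit(q)
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError(f"expected 3-vectors, got shape {v.shape}")
    pure = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return qmul(qmul(q, pure), qconj(q))[..., 1:]


def from_axis_angle(axis, angle) -> np.ndarray:
    """Unit quaternion rotating by *angle* (rad) about *axis*."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("rotation axis must be nonzero")
    u = axis / n
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * u], axis=-1
    )


def from_rotvec(v) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle) to unit quaternion."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v, axis=-1)
    small = angle < 1e-12
    axis = np.where(small[..., None], np.array([1.0, 0.0, 0.0]), v / np.where(small, 1.0, angle)[..., None])
    return from_axis_angle(axis, angle)


def to_axis_angle(q) -> tuple[np.ndarray, np.ndarray]:
    """Axis and angle in ``[0, π]`` of a unit quaternion."""
    q = canonicalize(require_unit(q))
    w = np.clip(q[..., 0], -1.0, 1.0)
    angle = 2.0 * np.arccos(w)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    axis = np.where(
        (s < 1e-12)[..., None], np.array([1.0, 0.0, 0.0]), q[..., 1:] / np.where(s < 1e-12, 1.0, s)[..., None]
    )
    return axis, angle


def rotation_angle_between(a, b) -> np.ndarray:
    """Geodesic rotation angle (rad, in ``[0, π]``) between two unit
    quaternions, insensitive to hemisphere."""
    a, b = require_unit(a), require_unit(b)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def _shape_tuple(shape) -> tuple:
    return (shape,) if isinstance(shape, int) else tuple(shape)


def random_unit(rng: np.random.Generator, shape=()) -> np.ndarray:
    """Uniformly distributed unit quaternions (canonical hemisphere)."""
    q = rng.standard_normal(_shape_tuple(shape) + (4,))
    return canonicalize(normalize(q))


def small_rotation(rng: np.random.Generator, sigma: float, shape=()) -> np.ndarray:
    """Isotropic axis-angle Gaussian perturbation quaternions.

    The rotation vector is drawn from ``N(0, sigma² I₃)``, so *sigma* is
    the per-axis angular scale in radians.  ``sigma = 0`` returns exact
    identities.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    shp = _shape_tuple(shape)
    if sigma == 0:
        return np.broadcast_to(IDENTITY, shp + (4,)).copy()
    return from_rotvec(rng.normal(scale=sigma, size=shp + (3,)))
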