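"""Synthetic 11-IMU posture database generator.

No public corpus of full-body yoga quaternion streams exists, so this
module emulates the statistical structure the recognizer and evaluator
assume:

* 18 static posture templates in the five fixed waist-orientation
  categories — the five category waist rotations are mutually separated
  by at least 60° so the first-stage classifier has something real to
  learn, and postures within a category differ by at least 20° on some
  limb so the second stage does too;
* per-subject systematic offsets (axis-angle, default scale 0.15 rad,
  capped at 0.3 rad) standing in for body-shape and flexibility
  differences between trainers;
* per-instance repetition jitter (default 0.08 rad): the same subject
  does not reproduce a posture exactly across repetitions, a feature
  clearly visible in the between-instance ranges of the reference
  corpus's angle statistics;
* slow postural sway within an instance (default 0.05 rad, ~1 s time
  constant): a person holding a static pose wobbles continuously, which
  is what gives real recordings their within-instance variance;
* per-frame isotropic axis-angle sensor noise (default 0.02 rad);
* instance durations of 6–10 s sampled at 40 Hz;
* deliberately nonstandard instances with known per-segment angular
  deviations, for evaluating the scoring and guidance stages against
  ground truth.

Perturbations are *joint-level and anatomical*: each segment's offset,
jitter and noise quaternions are right-composed at its joint and
propagate to every descendant along the body tree (rotating an upper
arm carries the forearm with it), i.e. for segment ``i`` with parent
``p``

    ``q_i = q_p ⊗ (template_p⁻¹ ⊗ template_i) ⊗ ε_i``,
    ``ε_i = offset_i ⊗ jitter_i ⊗ sway_i(t) ⊗ noise_i(t)``,

with the waist as root.  This is what couples connected segments and
what makes conditioning a child on its parent informative downstream.
All randomness flows through a single seeded
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyTopology, N_SEGMENTS, WAIST, segment_index
from .data import (CATEGORY_OF, N_POSTURES, PostureDatabase, PostureInstance,
                   POSTURES_IN_CATEGORY)
from .quat import (canonicalize, from_axis_angle, qmul, rotation_angle_between,
                   small_rotation)

#: nominal waist rotation of each category in the animation frame
#: (x forward, y left, z up; lean = roll about x, lie = pitch about y)
CATEGORY_WAIST_QUAT: dict[int, np.ndarray] = {
    1: np.array([1.0, 0.0, 0.0, 0.0]),
    2: from_axis_angle((1, 0, 0), 1.3),
    3: from_axis_angle((1, 0, 0), -1.3),
    4: from_axis_angle((0, 1, 0), np.pi / 2),
    5: from_axis_angle((0, 1, 0), -np.pi / 2),
}

#: required separation between category waist rotations (rad)
MIN_CATEGORY_SEPARATION = np.deg2rad(60.0)
#: required worst-segment separation between postures of one category (rad)
MIN_POSTURE_SEPARATION = np.deg2rad(20.0)


@dataclass(frozen=True)
class PostureTemplate:
    """Nominal animation-frame geometry of one posture."""

    posture: int
    category: int
    quats: np.ndarray  # (11, 4), animation frame

    def waist_relative(self) -> np.ndarray:
        """(11, 4) quaternions relative to the template waist (waist row = identity)."""
        from .quat import qinv
        return canonicalize(qmul(qinv(self.quats[WAIST]), self.quats))


@dataclass
class SubjectProfile:
    """Systematic per-segment deviation of one subject from the templates."""

    subject: int
    offsets: np.ndarray  # (11, 4) unit quaternions
    flexibility: float = 1.0

    @classmethod
    def sample(cls, subject: int, spec: "PerturbationSpec", rng: np.random.Generator) -> "SubjectProfile":
        flexibility = float(np.exp(rng.normal(scale=0.2)))
        rotvec = rng.normal(scale=spec.sigma_subject, size=(N_SEGMENTS, 3)) * flexibility
        mag = np.linalg.norm(rotvec, axis=-1, keepdims=True)
        over = mag > spec.max_subject_offset
        rotvec = np.where(over, rotvec * spec.max_subject_offset / np.where(mag == 0, 1, mag), rotvec)
        from .quat import from_rotvec
        return cls(subject=subject, offsets=from_rotvec(rotvec), flexibility=flexibility)

    @classmethod
    def reference(cls, subject: int = 0) -> "SubjectProfile":
        """A subject with zero systematic offset (performs templates exactly)."""
        offsets = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (N_SEGMENTS, 1))
        return cls(subject=subject, offsets=offsets, flexibility=1.0)


@dataclass
class PerturbationSpec:
    """Noise and timing parameters of the generator.

    ``sigma_subject``, ``sigma_instance``, ``sigma_sway`` and
    ``sigma_frame`` are per-axis axis-angle scales in radians
    (``sway_time`` is the sway time constant in seconds);
    ``duration_range`` in seconds; ``rate`` in Hz.
    """

    sigma_subject: float = 0.15
    sigma_instance: float = 0.08
    sigma_sway: float = 0.05
    sway_time: float = 1.0
    sigma_frame: float = 0.02
    duration_range: tuple[float, float] = (6.0, 10.0)
    rate: float = 40.0
    max_subject_offset: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_subject, self.sigma_instance, self.sigma_sway, self.sigma_frame) < 0:
            raise ValueError("noise scales must be >= 0")
        if self.sway_time <= 0:
            raise ValueError("sway time constant must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("duration range must be positive and ordered")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")


def make_templates(seed: int = 0) -> list[PostureTemplate]:
    """Generate the 18 posture templates (deterministic given *seed*).

    Waist orientations are the fixed category rotations; limb segments
    get seeded random orientations re-drawn until the within-category
    separation invariant holds.
    """
    rng = np.random.default_rng(seed)
    # category invariant is structural — assert it once anyway
    cats = list(CATEGORY_WAIST_QUAT)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            sep = rotation_angle_between(CATEGORY_WAIST_QUAT[a], CATEGORY_WAIST_QUAT[b])
            if sep < MIN_CATEGORY_SEPARATION:
                raise AssertionError(f"category waist rotations {a},{b} separated by only {sep:.2f} rad")
    templates: list[PostureTemplate] = []
    for cat in range(1, 6):
        q_waist = CATEGORY_WAIST_QUAT[cat]
        done: list[np.ndarray] = []  # (11,4) relative geometries accepted so far
        for posture in POSTURES_IN_CATEGORY[cat]:
            while True:
                rel = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (N_SEGMENTS, 1))
                for i in range(N_SEGMENTS):
                    if i == WAIST:
                        continue
                    axis = rng.standard_normal(3)
                    axis /= np.linalg.norm(axis)
                    angle = rng.uniform(0.7, 2.2)
                    rel[i] = from_axis_angle(axis, angle)
                ok = all(
                    max(rotation_angle_between(rel[i], other[i])
                        for i in range(N_SEGMENTS) if i != WAIST) >= MIN_POSTURE_SEPARATION
                    for other in done
                )
                if ok:
                    break
            done.append(rel)
            quats = canonicalize(qmul(q_waist, rel))
            templates.append(PostureTemplate(posture=posture, category=cat, quats=quats))
    templates.sort(key=lambda t: t.posture)
    return templates


def coaching_template(posture: int = 1) -> PostureTemplate:
    """A stand-category template with controlled elbow/knee geometry.

    Forearm-in-upper-arm and shank-in-thigh rotations are pure 0.9 rad
    bends about the local z-axis, so bend–stretch differences measured by
    the guidance stage map one-to-one onto injected deviation angles.
    Used by the guidance-recovery scenarios and their tests.
    """
    rel = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (N_SEGMENTS, 1))
    bend = from_axis_angle((0, 0, 1), 0.9)
    rel[segment_index("head")] = from_axis_angle((0, 1, 0), 0.2)
    rel[segment_index("breast")] = from_axis_angle((0, 1, 0), 0.1)
    rel[segment_index("LUArm")] = from_axis_angle((0, 1, 0), -0.6)
    rel[segment_index("RUArm")] = from_axis_angle((0, 1, 0), -0.6)
    rel[segment_index("LFArm")] = qmul(rel[segment_index("LUArm")], bend)
    rel[segment_index("RFArm")] = qmul(rel[segment_index("RUArm")], bend)
    rel[segment_index("LThigh")] = from_axis_angle((0, 0, 1), 0.15)
    rel[segment_index("RThigh")] = from_axis_angle((0, 0, 1), -0.15)
    rel[segment_index("LShank")] = qmul(rel[segment_index("LThigh")], bend)
    rel[segment_index("RShank")] = qmul(rel[segment_index("RThigh")], bend)
    q_waist = CATEGORY_WAIST_QUAT[1]
    return PostureTemplate(posture=posture, category=CATEGORY_OF[posture],
                           quats=canonicalize(qmul(q_waist, rel)))


def generate_instance(template: PostureTemplate, subject: SubjectProfile,
                      spec: PerturbationSpec, rng: np.random.Generator,
                      instance_id: int = 0,
                      joint_deviations: np.ndarray | None = None) -> PostureInstance:
    """One noisy posture instance with anatomically propagated noise.

    Per-segment joint perturbations ``offset ⊗ jitter ⊗ noise`` are
    composed along the body tree (see module docstring), so a deviation
    at a joint carries every descendant segment with it.
    """
    duration = rng.uniform(*spec.duration_range)
    T = max(1, int(round(duration * spec.rate)))
    times = np.arange(T) / spec.rate
    jitter = small_rotation(rng, spec.sigma_instance, (N_SEGMENTS,))
    const = qmul(subject.offsets, jitter)
    if joint_deviations is not None:
        const = qmul(np.asarray(joint_deviations, dtype=float), const)
    wobble = qmul(_sway_rotations(rng, spec, T),
                  small_rotation(rng, spec.sigma_frame, (T, N_SEGMENTS)))
    eps = qmul(const[None, :, :], wobble)
    quats = compose_chain(template.quats, eps)
    return PostureInstance(subject=subject.subject, label=template.posture,
                           instance_id=instance_id, times=times, quats=quats)


def _sway_rotations(rng: np.random.Generator, spec: PerturbationSpec, T: int) -> np.ndarray:
    """Slow postural sway: a stationary AR(1) rotation-vector process per
    joint with sd ``sigma_sway`` and time constant ``sway_time``."""
    from .quat import from_rotvec
    if spec.sigma_sway == 0:
        return np.broadcast_to(np.array([1.0, 0.0, 0.0, 0.0]), (T, N_SEGMENTS, 4)).copy()
    rho = float(np.exp(-1.0 / (spec.rate * spec.sway_time)))
    innov = rng.normal(scale=spec.sigma_sway, size=(T, N_SEGMENTS, 3))
    v = np.empty_like(innov)
    v[0] = innov[0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, T):
        v[t] = rho * v[t - 1] + scale * innov[t]
    return from_rotvec(v)


def compose_chain(template_quats: np.ndarray, joint_perturbs: np.ndarray,
                  topology: BodyTopology | None = None) -> np.ndarray:
    """Propagate joint-level perturbations along the body tree.

    ``template_quats`` is the ``(11, 4)`` nominal geometry and
    ``joint_perturbs`` a ``(..., 11, 4)`` array of per-joint rotations;
    returns the perturbed absolute orientations, canonical hemisphere.
    """
    from .quat import qinv
    topology = topology or BodyTopology()
    parent = topology.parent_map
    tpl = np.asarray(template_quats, dtype=float)
    eps = np.asarray(joint_perturbs, dtype=float)
    out = np.empty(np.broadcast_shapes(eps.shape, (11, 4)), dtype=float)
    out[..., WAIST, :] = qmul(tpl[WAIST], eps[..., WAIST, :])
    # children in order of increasing tree depth
    pending = [c for c, _ in topology.edges()]
    done = {WAIST}
    while pending:
        c = next(i for i in pending if parent[i] in done)
        pending.remove(c)
        joint = qmul(qinv(tpl[parent[c]]), tpl[c])
        out[..., c, :] = qmul(qmul(out[..., parent[c], :], joint), eps[..., c, :])
        done.add(c)
    return canonicalize(out)


def generate_database(n_subjects: int = 11, instances_per_posture: int = 10,
                      spec: PerturbationSpec | None = None,
                      templates: list[PostureTemplate] | None = None,
                      seed: int | None = None) -> PostureDatabase:
    """A full labelled database: subjects × 18 postures × repetitions."""
    spec = spec or PerturbationSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    templates = templates if templates is not None else make_templates(int(rng.integers(2**31)))
    if len(templates) != N_POSTURES:
        raise ValueError(f"need {N_POSTURES} templates, got {len(templates)}")
    subjects = [SubjectProfile.sample(s + 1, spec, rng) for s in range(n_subjects)]
    instances, iid = [], 0
    for subj in subjects:
        for tpl in templates:
            for _ in range(instances_per_posture):
                instances.append(generate_instance(tpl, subj, spec, rng, instance_id=iid))
                iid += 1
    return PostureDatabase(instances=instances)


@dataclass
class DeviationRecord:
    """Ground truth of a deliberately nonstandard instance."""

    posture: int
    deviations: dict[int, tuple[np.ndarray, float]]  # segment → (axis, angle)
    root_deviated: bool = False

    @property
    def segments(self) -> list[int]:
        return sorted(self.deviations)


def generate_nonstandard(template: PostureTemplate,
                         deviations: dict[int | str, tuple] ,
                         subject: SubjectProfile, spec: PerturbationSpec,
                         rng: np.random.Generator, instance_id: int = 0
                         ) -> tuple[PostureInstance, DeviationRecord]:
    """A nonstandard instance with known per-segment deviations.

    *deviations* maps segment (name or index) to ``(axis, angle_rad)``;
    each deviation quaternion is right-composed at the segment's joint,
    so descendants are carried along anatomically while the deviated
    joint itself carries the whole ground-truth angle.  Deviating the
    waist root is allowed but flagged: the root moves the entire body,
    so only its own (animation-frame) score reflects it.
    """
    joint_dev = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (N_SEGMENTS, 1))
    record: dict[int, tuple[np.ndarray, float]] = {}
    root = False
    for key, (axis, angle) in deviations.items():
        i = segment_index(key)
        axis = np.asarray(axis, dtype=float)
        joint_dev[i] = from_axis_angle(axis, angle)
        record[i] = (axis / np.linalg.norm(axis), float(angle))
        if i == WAIST:
            root = True
    inst = generate_instance(template, subject, spec, rng, instance_id=instance_id,
                             joint_deviations=joint_dev)
    return inst, DeviationRecord(posture=template.posture, deviations=record, root_deviated=root)


__all__ = [
    "CATEGORY_WAIST_QUAT", "MIN_CATEGORY_SEPARATION", "MIN_POSTURE_SEPARATION",
    "PostureTemplate", "SubjectProfile", "PerturbationSpec", "DeviationRecord",
    "make_templates", "coaching_template", "generate_instance",
    "generate_database", "generate_nonstandard",
]
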