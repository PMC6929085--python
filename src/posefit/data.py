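"""Posture dataset containers, file I/O, splitting, and angle statistics.

A *posture instance* is one contiguous performance (6–10 s at 40 Hz) of a
single static posture by one subject.  A database is a bag of labelled
instances plus the fixed posture→category map: the 18 postures partition
into five waist-orientation categories

    1 "stand"          postures 1–5
    2 "lean left"      postures 6–7
    3 "lean right"     postures 8–9
    4 "lie on stomach" postures 10–13
    5 "lie on back"    postures 14–18

On disk a database is one row per frame (CSV or JSONL) carrying subject,
posture label, instance id, timestamp, and the 44 quaternion components
(scalar-first) of the 11 segments.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body import N_SEGMENTS, SEGMENTS, segment_index, inter_segment_angle
from .quat import require_unit

logger = logging.getLogger(__name__)

N_POSTURES = 18
N_CATEGORIES = 5

#: posture id (1–18) → category id (1–5)
CATEGORY_OF: dict[int, int] = {
    **{p: 1 for p in range(1, 6)},
    **{p: 2 for p in (6, 7)},
    **{p: 3 for p in (8, 9)},
    **{p: 4 for p in range(10, 14)},
    **{p: 5 for p in range(14, 19)},
}

CATEGORY_NAMES: dict[int, str] = {
    1: "stand", 2: "lean left", 3: "lean right", 4: "lie on stomach", 5: "lie on back",
}

#: category id → tuple of posture ids
POSTURES_IN_CATEGORY: dict[int, tuple[int, ...]] = {
    c: tuple(p for p, cc in CATEGORY_OF.items() if cc == c) for c in range(1, 6)
}

_QCOLS = [f"{SEGMENTS[i]}_{c}" for i in range(N_SEGMENTS) for c in "wxyz"]


@dataclass
class PostureFrame:
    """One 40 Hz sample: timestamp, 11 unit quaternions, optional label."""

    time: float
    quats: np.ndarray  # (11, 4)
    label: int | None = None

    def __post_init__(self):
        self.quats = require_unit(np.asarray(self.quats, dtype=float))
        if self.quats.shape != (N_SEGMENTS, 4):
            raise ValueError(f"a frame needs {N_SEGMENTS} quaternions, got shape {self.quats.shape}")


@dataclass
class PostureInstance:
    """One contiguous performance of a single posture.

    Frames are stored columnar for speed: ``times`` has shape ``(T,)``
    (strictly increasing) and ``quats`` shape ``(T, 11, 4)``.
    """

    subject: int
    label: int
    instance_id: int
    times: np.ndarray
    quats: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        if len(self.times) == 0:
            raise ValueError("a posture instance must contain at least one frame")
        if self.quats.shape != (len(self.times), N_SEGMENTS, 4):
            raise ValueError(f"quats shape {self.quats.shape} inconsistent with {len(self.times)} timestamps")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"timestamps must be strictly increasing within instance {self.instance_id}")
        require_unit(self.quats)

    def __len__(self) -> int:
        return len(self.times)

    def frames(self):
        for t, q in zip(self.times, self.quats):
            yield PostureFrame(time=float(t), quats=q, label=self.label)


@dataclass
class PostureDatabase:
    """A labelled collection of posture instances from several subjects."""

    instances: list[PostureInstance]
    category_map: dict[int, int] = field(default_factory=lambda: dict(CATEGORY_OF))

    def __post_init__(self):
        cats = sorted(set(self.category_map.values()))
        if sorted(self.category_map) != list(range(1, N_POSTURES + 1)) or cats != list(range(1, N_CATEGORIES + 1)):
            raise ValueError("category map must send postures 1–18 onto categories 1–5")
        if self.category_map != CATEGORY_OF:
            raise ValueError("category map must match the fixed five-category partition of the 18 postures")

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def subjects(self) -> list[int]:
        return sorted({inst.subject for inst in self.instances})

    @property
    def n_frames(self) -> int:
        return sum(len(inst) for inst in self.instances)

    def by_label(self, label: int) -> list[PostureInstance]:
        return [inst for inst in self.instances if inst.label == label]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _db_to_dataframe(db: PostureDatabase) -> pd.DataFrame:
    parts = []
    for inst in db.instances:
        T = len(inst)
        block = pd.DataFrame(inst.quats.reshape(T, 44), columns=_QCOLS)
        block.insert(0, "time", inst.times)
        block.insert(0, "instance", inst.instance_id)
        block.insert(0, "posture", inst.label)
        block.insert(0, "subject", inst.subject)
        parts.append(block)
    if not parts:
        return pd.DataFrame(columns=["subject", "posture", "instance", "time", *_QCOLS])
    return pd.concat(parts, ignore_index=True)


def _db_from_dataframe(df: pd.DataFrame) -> PostureDatabase:
    if df.empty:
        warnings.warn("empty posture database file", stacklevel=3)
        return PostureDatabase(instances=[])
    missing = [c for c in ("subject", "posture", "instance", "time", *_QCOLS) if c not in df.columns]
    if missing:
        raise ValueError(f"malformed database: missing columns {missing[:6]}{'...' if len(missing) > 6 else ''}")
    quats = df[_QCOLS].to_numpy(dtype=float).reshape(len(df), N_SEGMENTS, 4)
    norms = np.linalg.norm(quats, axis=-1)
    bad = np.argwhere(np.abs(norms - 1.0) > 1e-6)
    if bad.size:
        r, s = bad[0]
        raise ValueError(
            f"non-unit quaternion at data row {int(r) + 1} (segment {SEGMENTS[int(s)]}, |q| = {norms[r, s]:.6f})"
        )
    instances = []
    for (subj, post, iid), g in df.groupby(["subject", "posture", "instance"], sort=True):
        order = np.argsort(g["time"].to_numpy())
        idx = g.index.to_numpy()[order]
        instances.append(PostureInstance(
            subject=int(subj), label=int(post), instance_id=int(iid),
            times=df.loc[idx, "time"].to_numpy(dtype=float),
            quats=quats[df.index.get_indexer(idx)],
        ))
    return PostureDatabase(instances=instances)


def write_database(db: PostureDatabase, path) -> None:
    """Write a database to ``.csv`` or ``.jsonl`` (chosen by extension)."""
    path = Path(path)
    df = _db_to_dataframe(db)
    if path.suffix == ".csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif path.suffix == ".jsonl":
        with path.open("w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unsupported database extension {path.suffix!r} (use .csv or .jsonl)")


def read_database(path) -> PostureDatabase:
    """Read a database written by :func:`write_database` (lossless)."""
    path = Path(path)
    if path.suffix == ".csv":
        if path.stat().st_size == 0:
            warnings.warn(f"empty posture database file {path}", stacklevel=2)
            return PostureDatabase(instances=[])
        df = pd.read_csv(path, float_precision="round_trip")
    elif path.suffix == ".jsonl":
        rows = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"malformed JSONL at line {lineno}: {exc}") from None
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unsupported database extension {path.suffix!r} (use .csv or .jsonl)")
    return _db_from_dataframe(df)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_database(db: PostureDatabase, train_fraction: float, seed: int) -> tuple[PostureDatabase, PostureDatabase]:
    """Instance-level train/test split, stratified per (subject, posture).

    Within each (subject, posture) cell, ``round(train_fraction * n)``
    instances are drawn at random into the training set — e.g. 3 of 10 at
    a 30 % fraction — and the remainder go to test.  Deterministic given
    *seed*.  Cells with no instances are skipped with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, int], list[PostureInstance]] = {}
    for inst in db.instances:
        cells.setdefault((inst.subject, inst.label), []).append(inst)
    for subject in db.subjects:
        for posture in range(1, N_POSTURES + 1):
            if (subject, posture) not in cells:
                logger.warning("subject %d has no instances of posture %d; cell skipped", subject, posture)
    train, test = [], []
    for key in sorted(cells):
        group = sorted(cells[key], key=lambda i: i.instance_id)
        n_train = int(np.clip(round(train_fraction * len(group)), 0, len(group)))
        picked = set(rng.choice(len(group), size=n_train, replace=False).tolist())
        for i, inst in enumerate(group):
            (train if i in picked else test).append(inst)
    return PostureDatabase(instances=train), PostureDatabase(instances=test)


# ---------------------------------------------------------------------------
# descriptive angle statistics
# ---------------------------------------------------------------------------

def angle_statistics(db: PostureDatabase, posture: int, seg_a, seg_b, axis=(1.0, 0.0, 0.0)) -> pd.DataFrame:
    """Per-subject mean/sd/range of the inter-segment angle for a posture.

    For every subject, the angle between segments *seg_a* and *seg_b*
    (longitudinal-axis angle, rad) is computed over all frames of the
    requested posture; the table reports its mean, population standard
    deviation and range, with a final ``"all"`` row whose ``mean`` entry
    is the across-subject range of per-subject means.
    """
    a, b = segment_index(seg_a), segment_index(seg_b)
    insts = db.by_label(posture)
    if not insts:
        raise ValueError(f"posture {posture} not present in database")
    per_subject: dict[int, list[np.ndarray]] = {}
    for inst in insts:
        ang = inter_segment_angle(inst.quats[:, a, :], inst.quats[:, b, :], axis)
        per_subject.setdefault(inst.subject, []).append(ang)
    rows = []
    for subj in sorted(per_subject):
        ang = np.concatenate(per_subject[subj])
        rows.append({"subject": subj, "mean": float(ang.mean()),
                     "sd": float(ang.std()), "range": float(ang.max() - ang.min())})
    tbl = pd.DataFrame(rows).set_index("subject")
    range_of_means = float(tbl["mean"].max() - tbl["mean"].min())
    tbl.loc["all"] = [range_of_means, np.nan, np.nan]
    tbl.attrs["range_of_means"] = range_of_means
    return tbl


__all__ = [
    "N_POSTURES", "N_CATEGORIES", "CATEGORY_OF", "CATEGORY_NAMES", "POSTURES_IN_CATEGORY",
    "PostureFrame", "PostureInstance", "PostureDatabase",
    "read_database", "write_database", "split_database", "angle_statistics",
]
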