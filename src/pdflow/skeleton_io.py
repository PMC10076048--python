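"""Reading NTU-style ``.skeleton`` files and persisting sequence datasets.

The NTU RGB+D text dialect stores, per recording: a frame count; for every
frame a body count; and for every tracked body a header line, a joint-count
line (25 for Kinect V2) and one line per joint whose first three whitespace
separated fields are the x, y, z coordinates in metres.  Only those three
fields feed the pose sequence; the remaining columns (depth/colour image
coordinates, orientation quaternion, tracking state) are parsed and kept as
per-joint tracking flags where present but otherwise ignored.

Datasets of variable-length sequences are persisted losslessly to HDF5 (one
dataset per sequence, so ragged lengths survive) with a JSON metadata
attribute block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

from .errors import ContainerError, EmptySequenceError, SkeletonFormatError, SkeletonParseError

__all__ = [
    "BodyTrack",
    "PoseSequence",
    "DatasetHandle",
    "read_ntu_skeleton",
    "select_main_actor",
    "save_dataset",
    "load_dataset",
]

NTU_JOINT_COUNT = 25


@dataclass
class PoseSequence:
    """One body's pose signal: ``coords[t, n]`` is joint *n* at frame *t* (metres)."""

    coords: np.ndarray  # (T, J, 3) float64
    label: int | None = None
    seq_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (T, J, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 2:
            raise ValueError("need T >= 1 frames and J >= 2 joints")

    @property
    def num_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def num_joints(self) -> int:
        return self.coords.shape[1]


@dataclass
class BodyTrack:
    """Raw per-body track from one recording; absent frames are all-zero (null)."""

    body_id: str
    coords: np.ndarray  # (T, J, 3)
    tracking: np.ndarray  # (T, J) int

    @property
    def num_frames(self) -> int:
        return self.coords.shape[0]

    def null_mask(self) -> np.ndarray:
        """Boolean (T,): True where the frame is null (all coordinates zero)."""
        return ~np.any(self.coords != 0.0, axis=(1, 2))


@dataclass
class DatasetHandle:
    """In-memory dataset: sequences plus aligned integer labels."""

    sequences: list[PoseSequence]
    labels: np.ndarray
    split_tag: str = "train"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences must align")
        if len(self.labels) and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[PoseSequence]:
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# NTU .skeleton parsing


class _Lines:
    def __init__(self, path: Path):
        self.path = path
        with open(path, "r") as fh:
            self.lines = fh.read().splitlines()
        self.pos = 0

    def next(self) -> str:
        while self.pos < len(self.lines):
            line = self.lines[self.pos]
            self.pos += 1
            if line.strip():
                return line
        raise SkeletonParseError(f"{self.path}: truncated file at line {self.pos + 1}")

    @property
    def lineno(self) -> int:
        return self.pos


def _int_field(lines: _Lines, what: str) -> int:
    line = lines.next()
    try:
        return int(line.split()[0])
    except (ValueError, IndexError) as e:
        raise SkeletonParseError(
            f"{lines.path}: expected {what} on line {lines.lineno}, got {line!r}"
        ) from e


def read_ntu_skeleton(path) -> list[BodyTrack]:
    """Parse one ``.skeleton`` file into per-body tracks.

    Returns one :class:`BodyTrack` per distinct body id, with frames aligned
    to the file's frame order; frames where a body is absent are recorded as
    null (all-zero) frames.
    """
    path = Path(path)
    lines = _Lines(path)
    num_frames = _int_field(lines, "frame count")
    if num_frames < 1:
        raise SkeletonFormatError(f"{path}: nonpositive frame count {num_frames}")

    coords: dict[str, np.ndarray] = {}
    tracking: dict[str, np.ndarray] = {}

    for t in range(num_frames):
        num_bodies = _int_field(lines, f"body count of frame {t}")
        for _ in range(num_bodies):
            header = lines.next()
            body_id = header.split()[0]
            num_joints = _int_field(lines, "joint count")
            if body_id not in coords:
                coords[body_id] = np.zeros((num_frames, num_joints, 3))
                tracking[body_id] = np.zeros((num_frames, num_joints), dtype=np.int64)
            elif coords[body_id].shape[1] != num_joints:
                raise SkeletonFormatError(
                    f"{path}: body {body_id} changes joint count at line {lines.lineno}"
                )
            for n in range(num_joints):
                line = lines.next()
                fields = line.split()
                if len(fields) < 3:
                    raise SkeletonParseError(
                        f"{path}: joint line {lines.lineno} has fewer than 3 fields"
                    )
                try:
                    xyz = [float(fields[k]) for k in range(3)]
                except ValueError as e:
                    raise SkeletonParseError(
                        f"{path}: non-numeric coordinate on line {lines.lineno}"
                    ) from e
                coords[body_id][t, n] = xyz
                # trailing integer column, when present, is the tracking state
                try:
                    tracking[body_id][t, n] = int(float(fields[-1])) if len(fields) > 3 else 1
                except ValueError:
                    tracking[body_id][t, n] = 1
                if not np.all(np.isfinite(coords[body_id][t, n])):
                    raise SkeletonParseError(
                        f"{path}: non-finite coordinate on line {lines.lineno}"
                    )

    return [BodyTrack(b, coords[b], tracking[b]) for b in sorted(coords)]


def select_main_actor(tracks: list[BodyTrack]) -> PoseSequence:
    """Reduce a multi-body recording to the single most active body.

    Motion energy of a track is the sum over joints and axes of the temporal
    variance of its coordinates over non-null frames.  Ties break to the
    lowest body id, so the reduction is deterministic and permutation
    invariant over track order.
    """
    if not tracks:
        raise EmptySequenceError("no body tracks to select from")

    best: tuple[float, str] | None = None
    best_track: BodyTrack | None = None
    for track in tracks:
        valid = ~track.null_mask()
        if not valid.any():
            continue
        pts = track.coords[valid]  # (T_valid, J, 3)
        energy = float(pts.var(axis=0).sum())
        key = (-energy, track.body_id)
        if best is None or key < best:
            best = key
            best_track = track
    if best_track is None:
        raise EmptySequenceError("all candidate tracks are entirely null")
    return PoseSequence(coords=best_track.coords.copy(), seq_id=best_track.body_id)


# ---------------------------------------------------------------------------
# HDF5 container

_FORMAT_VERSION = 1


def save_dataset(data: DatasetHandle, path) -> None:
    """Persist a dataset losslessly (per-sequence datasets allow ragged T)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["split_tag"] = data.split_tag
        f.attrs["meta_json"] = json.dumps(data.meta)
        f.create_dataset("labels", data=data.labels)
        grp = f.create_group("sequences")
        for i, seq in enumerate(data.sequences):
            d = grp.create_dataset(f"{i:06d}", data=seq.coords)
            d.attrs["seq_id"] = seq.seq_id


def load_dataset(path) -> DatasetHandle:
    """Inverse of :func:`save_dataset`; coordinates round-trip bit-exactly."""
    with h5py.File(path, "r") as f:
        if "labels" not in f or "sequences" not in f:
            raise ContainerError(f"{path}: missing 'labels' or 'sequences'")
        labels = np.asarray(f["labels"], dtype=np.int64)
        grp = f["sequences"]
        keys = sorted(grp.keys())
        if len(keys) != len(labels):
            raise ContainerError(
                f"{path}: {len(keys)} sequences but {len(labels)} labels"
            )
        sequences = []
        for i, key in enumerate(keys):
            arr = np.asarray(grp[key], dtype=np.float64)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ContainerError(f"{path}: sequence {key} has shape {arr.shape}")
            sequences.append(
                PoseSequence(
                    coords=arr,
                    label=int(labels[i]),
                    seq_id=str(grp[key].attrs.get("seq_id", key)),
                )
            )
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        split_tag = str(f.attrs.get("split_tag", "train"))
    return DatasetHandle(sequences=sequences, labels=labels, split_tag=split_tag, meta=meta)
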