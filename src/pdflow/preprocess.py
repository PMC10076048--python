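"""Pose-sequence normalization.

The recipe removes nuisance variation before representation learning:

1. null frames (all-zero, i.e. missed body detections) are padded with the
   nearest preceding valid frame;
2. the spine-centre joint of every frame is moved to the origin, removing
   global translation;
3. a single body-frame rotation, built from one reference frame, makes the
   hip->spine bone parallel to the z axis and the right->left shoulder line
   parallel to the x axis, removing camera viewpoint;
4. sequences are resampled/padded to a fixed frame count so batches are
   rectangular.

The rotation is computed once per sequence (from the first valid frame) by
default rather than per frame: a per-frame rotation would cancel the body's
orientation changes over time, which is exactly the motion signal the
orientation flow is meant to expose.  Per-frame mode is available for
ablation via ``rotation_reference="per_frame"``.

Joint-index defaults follow the Kinect V2 convention used by NTU RGB+D
(0 spine-base, 1 spine-mid, 4 left shoulder, 8 right shoulder), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, EmptySequenceError
from .skeleton_io import DatasetHandle, PoseSequence

__all__ = [
    "NormalizationConfig",
    "pad_null_frames",
    "center_spine",
    "align_axes",
    "temporal_resample",
    "normalize",
    "normalize_dataset",
]


@dataclass(frozen=True)
class NormalizationConfig:
    spine_center_index: int = 1     # spine mid: moved to the origin
    hip_index: int = 0              # spine base: tail of the z-defining bone
    spine_index_for_axis: int = 1   # head of the z-defining bone
    left_shoulder_index: int = 4
    right_shoulder_index: int = 8
    max_frames: int = 50
    rotation_reference: str = "first_valid_frame"  # or "per_frame"

    def validate(self, num_joints: int) -> None:
        idx = [
            self.spine_center_index,
            self.hip_index,
            self.left_shoulder_index,
            self.right_shoulder_index,
        ]
        if any(i < 0 or i >= num_joints for i in idx + [self.spine_index_for_axis]):
            raise ConfigError(f"joint index out of range for J={num_joints}: {idx}")
        if self.hip_index == self.spine_index_for_axis:
            raise ConfigError("hip and spine axis indices must differ")
        if self.left_shoulder_index == self.right_shoulder_index:
            raise ConfigError("shoulder indices must differ")
        if self.max_frames < 1:
            raise ConfigError(f"max_frames must be >= 1, got {self.max_frames}")
        if self.rotation_reference not in ("first_valid_frame", "per_frame"):
            raise ConfigError(f"unknown rotation_reference {self.rotation_reference!r}")


def _null_mask(coords: np.ndarray) -> np.ndarray:
    return ~np.any(coords != 0.0, axis=(1, 2))


def pad_null_frames(seq: PoseSequence) -> PoseSequence:
    """Replace null (all-zero) frames with the nearest preceding valid frame.

    Leading nulls take the first valid frame. Sequence length is unchanged.
    """
    coords = seq.coords
    null = _null_mask(coords)
    if null.all():
        raise EmptySequenceError(f"sequence {seq.seq_id!r}: every frame is null")
    if not null.any():
        return seq
    out = coords.copy()
    first_valid = int(np.flatnonzero(~null)[0])
    out[:first_valid] = coords[first_valid]
    for t in range(first_valid + 1, len(out)):
        if null[t]:
            out[t] = out[t - 1]
    return replace(seq, coords=out)


def center_spine(seq: PoseSequence, cfg: NormalizationConfig | None = None) -> PoseSequence:
    """Translate each frame so the spine-centre joint sits at the origin."""
    cfg = cfg or NormalizationConfig()
    cfg.validate(seq.num_joints)
    centred = seq.coords - seq.coords[:, cfg.spine_center_index : cfg.spine_center_index + 1, :]
    return replace(seq, coords=centred)


def _frame_basis(frame: np.ndarray, cfg: NormalizationConfig, label: str) -> np.ndarray:
    """Orthonormal body basis (rows x', y', z') from one frame's bones."""
    spine = frame[cfg.spine_index_for_axis] - frame[cfg.hip_index]
    shoulder = frame[cfg.left_shoulder_index] - frame[cfg.right_shoulder_index]
    ns = np.linalg.norm(spine)
    if ns < 1e-12:
        raise DegenerateGeometryError(f"{label}: hip->spine bone has zero length")
    z = spine / ns
    x = shoulder - np.dot(shoulder, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise DegenerateGeometryError(
            f"{label}: shoulder line is zero or collinear with the spine"
        )
    x = x / nx
    y = np.cross(z, x)
    return np.stack([x, y, z])  # rows form a right-handed orthonormal basis


def align_axes(seq: PoseSequence, cfg: NormalizationConfig | None = None) -> PoseSequence:
    """Rotate the sequence into the body frame (hip->spine // z, shoulders // x)."""
    cfg = cfg or NormalizationConfig()
    cfg.validate(seq.num_joints)
    coords = seq.coords
    if cfg.rotation_reference == "per_frame":
        out = np.empty_like(coords)
        for t in range(len(coords)):
            basis = _frame_basis(coords[t], cfg, f"frame {t}")
            out[t] = coords[t] @ basis.T
        return replace(seq, coords=out)

    null = _null_mask(coords)
    if null.all():
        raise EmptySequenceError(f"sequence {seq.seq_id!r}: every frame is null")
    ref = int(np.flatnonzero(~null)[0])
    basis = _frame_basis(coords[ref], cfg, f"reference frame {ref}")
    return replace(seq, coords=coords @ basis.T)


def temporal_resample(seq: PoseSequence, max_frames: int = 50) -> PoseSequence:
    """Force the sequence to exactly `max_frames` frames.

    Longer sequences keep frames at evenly spaced indices; shorter ones are
    padded by repeating the last frame.
    """
    if max_frames < 1:
        raise ConfigError(f"max_frames must be >= 1, got {max_frames}")
    T = seq.num_frames
    if T == max_frames:
        return seq
    if T > max_frames:
        idx = np.round(np.linspace(0, T - 1, max_frames)).astype(int)
        return replace(seq, coords=seq.coords[idx])
    pad = np.repeat(seq.coords[-1:], max_frames - T, axis=0)
    return replace(seq, coords=np.concatenate([seq.coords, pad], axis=0))


def normalize(seq: PoseSequence, cfg: NormalizationConfig | None = None) -> PoseSequence:
    """Full recipe: pad nulls -> centre spine -> align axes -> fixed length.

    Idempotent on its own output (up to float rounding) and invariant to any
    global translation or proper rotation of the input.
    """
    cfg = cfg or NormalizationConfig()
    seq = pad_null_frames(seq)
    seq = center_spine(seq, cfg)
    seq = align_axes(seq, cfg)
    return temporal_resample(seq, cfg.max_frames)


def normalize_dataset(data: DatasetHandle, cfg: NormalizationConfig | None = None) -> DatasetHandle:
    """Normalize every sequence in a dataset (labels and metadata preserved)."""
    cfg = cfg or NormalizationConfig()
    return DatasetHandle(
        sequences=[normalize(s, cfg) for s in data.sequences],
        labels=data.labels.copy(),
        split_tag=data.split_tag,
        meta={**data.meta, "normalized": True, "max_frames": cfg.max_frames},
    )
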