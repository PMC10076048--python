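"""Pose-flow supervision signals and their magnitude/orientation decoupling.

A pose flow F is a per-frame, per-joint 3D displacement field derived from a
pose sequence P:

* **CPF** (consecutive pose flow): frame-to-frame differences, the skeleton
  analogue of optical flow, F_t = P_{t+1} - P_t.
* **RPF** (reference pose flow): each frame minus the *reference pose* — the
  temporal mean of the sequence — F_t = P_t - (1/T) sum_s P_s.  RPF compares
  one noisy frame against a time-averaged (hence more stable) reference, so
  it is less noise-amplifying than CPF.

Either flow factorises entrywise into a nonnegative **magnitude field**
M = {alpha_t^n} (Euclidean norms, metres) and a unit-vector **orientation
field** O with F = M * O.  Where a displacement is (numerically) zero its
orientation is undefined; those entries carry a zero vector and a False
validity flag, and downstream losses exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .skeleton_io import PoseSequence

__all__ = [
    "PoseFlow",
    "MagnitudeFlow",
    "OrientationFlow",
    "reference_pose",
    "compute_rpf",
    "compute_cpf",
    "decouple",
    "recompose",
    "pdf_of_sequence",
    "DEFAULT_EPS",
]

DEFAULT_EPS = 1e-8


@dataclass
class PoseFlow:
    """Displacement field, same (T, J, 3) shape as its source sequence."""

    vectors: np.ndarray
    kind: str = "rpf"  # "cpf" | "rpf"


@dataclass
class MagnitudeFlow:
    """Scalar field alpha >= 0 of per-entry displacement norms, (T, J)."""

    alpha: np.ndarray


@dataclass
class OrientationFlow:
    """Unit-vector field (T, J, 3); `valid_mask` is False where alpha ~ 0."""

    units: np.ndarray
    valid_mask: np.ndarray


def reference_pose(seq: PoseSequence) -> np.ndarray:
    """Temporal mean pose, (J, 3): the stable anchor RPF compares against.

    Computed as first_frame + mean(coords - first_frame): the shift improves
    conditioning and makes the mean of a temporally constant sequence exact,
    so its flow is exactly zero rather than summation noise.
    """
    first = seq.coords[0]
    return first + (seq.coords - first).mean(axis=0)


def compute_rpf(seq: PoseSequence) -> PoseFlow:
    """Reference pose flow: F_t = P_t - mean_t(P).  Sums to zero over time."""
    return PoseFlow(vectors=seq.coords - reference_pose(seq), kind="rpf")


def compute_cpf(seq: PoseSequence) -> PoseFlow:
    """Consecutive pose flow: F_t = P_{t+1} - P_t, last row repeated.

    The repeat keeps the flow the same length as the sequence, so all
    supervision signals share one decoder output shape.
    """
    if seq.num_frames < 2:
        raise ShapeError("CPF needs at least 2 frames")
    diff = np.diff(seq.coords, axis=0)
    return PoseFlow(vectors=np.concatenate([diff, diff[-1:]], axis=0), kind="cpf")


def decouple(flow: PoseFlow, eps: float = DEFAULT_EPS) -> tuple[MagnitudeFlow, OrientationFlow]:
    """Split F into magnitudes alpha = ||F|| and unit orientations F/alpha.

    Entries with alpha <= eps keep their (tiny) magnitude but get a zero
    orientation vector and a False validity flag.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    vec = np.asarray(flow.vectors, dtype=np.float64)
    alpha = np.linalg.norm(vec, axis=-1)
    valid = alpha > eps
    units = np.zeros_like(vec)
    np.divide(vec, alpha[..., None], out=units, where=valid[..., None])
    return MagnitudeFlow(alpha=alpha), OrientationFlow(units=units, valid_mask=valid)


def recompose(m: MagnitudeFlow, o: OrientationFlow) -> PoseFlow:
    """Entrywise product F = M * O, the inverse of :func:`decouple`."""
    alpha = np.asarray(m.alpha)
    units = np.asarray(o.units)
    if alpha.shape != units.shape[:-1] or units.shape[-1] != 3:
        raise ShapeError(
            f"magnitude {alpha.shape} and orientation {units.shape} do not agree"
        )
    return PoseFlow(vectors=alpha[..., None] * units, kind="rpf")


def pdf_of_sequence(
    seq: PoseSequence, eps: float = DEFAULT_EPS
) -> tuple[MagnitudeFlow, OrientationFlow]:
    """Pose decoupled flow of a sequence: decouple(RPF(seq)).

    This is the default supervision-signal pair (magnitude, orientation) used
    to train the decoupled-flow networks.
    """
    return decouple(compute_rpf(seq), eps=eps)
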