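"""Reconstruction losses and their adaptive multi-task combination.

Four training objectives are supported, one per network variant:

* baseline:     L = mean of the two decoders' pose-reconstruction MSEs
* explicit:     L_e = w1 * MSE(M, M^) + w2 * cos_dist(O, O^)
* implicit:     L_i = L_e-style flow terms + w3 * MSE(P^_M, P^_O)
* generalized:  L_g = flow terms + w3 * MSE(P^_M, P) + w4 * MSE(P^_O, P)

The orientation term is the normalized cosine distance (1 - O.O^)/2, which
lies in [0, 1]; entries whose target orientation is undefined (zero motion)
are excluded from its mean.  "MSE" is the mean of squared element
differences, so printed loss magnitudes are comparable across batch sizes
and sequence lengths.

Instead of hand-tuning the w_k, the homoscedastic-uncertainty strategy
treats each task as a Gaussian likelihood with learnable observation noise
delta_k and minimizes

    sum_k [ L_k / (2 delta_k^2) ] + log prod_k delta_k .

We parameterize s_k = log delta_k^2 (unconstrained), giving the equivalent
form sum_k [ exp(-s_k) L_k / 2 + s_k / 2 ].

Every function here accepts either plain NumPy arrays or autograd
:class:`~pdflow.autograd.Tensor` values for the *predicted* quantities, so
the exact same loss code is differentiated during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .errors import ConfigError, ShapeError, UndefinedLossError
from .flows import MagnitudeFlow, OrientationFlow, PoseFlow

__all__ = [
    "LossWeights",
    "UncertaintyParams",
    "LossBreakdown",
    "mse",
    "orientation_distance",
    "loss_pose",
    "loss_flow",
    "loss_baseline",
    "loss_explicit",
    "loss_implicit",
    "loss_generalized",
    "adaptive_combine",
]


@dataclass(frozen=True)
class LossWeights:
    """Fixed task weights w1..w4 (all default 1)."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ConfigError("loss weights must be nonnegative")


@dataclass
class UncertaintyParams:
    """Learnable log-variances s_k = log delta_k^2, one per weighted term."""

    s: object  # ndarray or autograd Tensor, shape (K,)

    @classmethod
    def zeros(cls, k: int, learnable: bool = True) -> "UncertaintyParams":
        return cls(s=ag.Tensor(np.zeros(k), requires_grad=learnable))

    @property
    def num_terms(self) -> int:
        return int(np.asarray(self.s.data if isinstance(self.s, ag.Tensor) else self.s).shape[0])

    def deltas(self) -> np.ndarray:
        """Current delta_k = exp(s_k / 2) values, as plain floats."""
        s = self.s.data if isinstance(self.s, ag.Tensor) else np.asarray(self.s)
        return np.exp(0.5 * s)


@dataclass
class LossBreakdown:
    """A total loss plus its named unweighted terms and the weights applied."""

    total: object  # scalar (float or Tensor)
    terms: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def term_floats(self) -> dict:
        out = {}
        for k, v in self.terms.items():
            out[k] = float(v.data) if isinstance(v, ag.Tensor) else float(v)
        return out

    def total_float(self) -> float:
        return float(self.total.data) if isinstance(self.total, ag.Tensor) else float(self.total)


def _shape_of(x) -> tuple:
    return x.shape


def _raw(x):
    """Underlying array of a PoseFlow / MagnitudeFlow / array / Tensor."""
    if isinstance(x, PoseFlow):
        return x.vectors
    if isinstance(x, MagnitudeFlow):
        return x.alpha
    return x


def mse(a, b):
    """Mean of squared element differences (symmetric, zero iff a == b)."""
    a, b = _raw(a), _raw(b)
    if _shape_of(a) != _shape_of(b):
        raise ShapeError(f"mse shapes differ: {_shape_of(a)} vs {_shape_of(b)}")
    d = a - b
    return (d * d).mean()


def orientation_distance(o: OrientationFlow, o_hat: OrientationFlow):
    """Normalized cosine distance (1 - O.O^)/2 averaged over valid entries.

    `o` is the target; entries where its orientation is undefined
    (`valid_mask` False) are excluded.  Result lies in [0, 1].
    """
    mask = np.asarray(o.valid_mask, dtype=np.float64)
    count = mask.sum()
    if count == 0:
        raise UndefinedLossError("orientation target has no valid entries")
    if _shape_of(o.units) != _shape_of(o_hat.units):
        raise ShapeError(
            f"orientation shapes differ: {_shape_of(o.units)} vs {_shape_of(o_hat.units)}"
        )
    dot = (o.units * o_hat.units).sum(axis=-1)
    dist = (1.0 - dot) * 0.5
    return (dist * mask).sum() * (1.0 / count)


def loss_pose(p, p_hat):
    """Pose-reconstruction MSE (flattened elementwise)."""
    return mse(p, p_hat)


def loss_flow(f, f_hat):
    """Pose-flow reconstruction MSE (flattened elementwise)."""
    return mse(f, f_hat)


def loss_baseline(p, p_hat_a, p_hat_b) -> LossBreakdown:
    """Baseline autoencoder: mean of the two decoders' pose MSEs."""
    la = loss_pose(p, p_hat_a)
    lb = loss_pose(p, p_hat_b)
    total = (la + lb) * 0.5
    return LossBreakdown(
        total=total,
        terms={"pose_M": la, "pose_O": lb},
        weights={"pose_M": 0.5, "pose_O": 0.5},
    )


def loss_explicit(
    m: MagnitudeFlow, o: OrientationFlow, m_hat, o_hat, w: LossWeights | None = None
) -> LossBreakdown:
    w = w or LossWeights()
    lm = mse(m, m_hat)
    lo = orientation_distance(o, o_hat)
    return LossBreakdown(
        total=w.w1 * lm + w.w2 * lo,
        terms={"magnitude": lm, "orientation": lo},
        weights={"magnitude": w.w1, "orientation": w.w2},
    )


def loss_implicit(
    m: MagnitudeFlow,
    o: OrientationFlow,
    m_hat_m,
    o_hat_o,
    p_hat_m,
    p_hat_o,
    w: LossWeights | None = None,
) -> LossBreakdown:
    """Implicit variant: flow terms plus the decoder-agreement constraint."""
    w = w or LossWeights()
    lm = mse(m, m_hat_m)
    lo = orientation_distance(o, o_hat_o)
    lc = mse(p_hat_m, p_hat_o)
    return LossBreakdown(
        total=w.w1 * lm + w.w2 * lo + w.w3 * lc,
        terms={"magnitude": lm, "orientation": lo, "constraint": lc},
        weights={"magnitude": w.w1, "orientation": w.w2, "constraint": w.w3},
    )


def loss_generalized(
    m: MagnitudeFlow,
    o: OrientationFlow,
    m_hat_m,
    o_hat_o,
    p_hat_m,
    p_hat_o,
    p,
    w: LossWeights | None = None,
) -> LossBreakdown:
    """Generalized variant: both decoder outputs must also rebuild the pose."""
    w = w or LossWeights()
    lm = mse(m, m_hat_m)
    lo = orientation_distance(o, o_hat_o)
    lpm = mse(p_hat_m, p)
    lpo = mse(p_hat_o, p)
    return LossBreakdown(
        total=w.w1 * lm + w.w2 * lo + w.w3 * lpm + w.w4 * lpo,
        terms={"magnitude": lm, "orientation": lo, "pose_M": lpm, "pose_O": lpo},
        weights={"magnitude": w.w1, "orientation": w.w2, "pose_M": w.w3, "pose_O": w.w4},
    )


def adaptive_combine(term_values, u: UncertaintyParams):
    """Homoscedastic-uncertainty combination of task losses.

    ``sum_k [ exp(-s_k) L_k / 2 + s_k / 2 ]`` with s_k = log delta_k^2; for
    two terms and delta = 1 this reduces to half the unweighted sum.  Term
    order follows dict/sequence order of `term_values`.
    """
    if isinstance(term_values, dict):
        values = list(term_values.values())
    else:
        values = list(term_values)
    if len(values) != u.num_terms:
        raise ConfigError(
            f"{len(values)} loss terms but {u.num_terms} uncertainty parameters"
        )
    s = u.s
    tensor_mode = isinstance(s, ag.Tensor) or any(isinstance(v, ag.Tensor) for v in values)
    if tensor_mode:
        s = s if isinstance(s, ag.Tensor) else ag.Tensor(s)
        total = None
        for k, lk in enumerate(values):
            sk = s[k]
            contrib = ag.exp(-sk) * lk * 0.5 + sk * 0.5
            total = contrib if total is None else total + contrib
        return total
    s = np.asarray(s, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    return float(np.sum(0.5 * np.exp(-s) * values + 0.5 * s))
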