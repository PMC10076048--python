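"""Recurrent encoder / dual-decoder networks for the four model variants.

All variants share one topology: a (1- or 2-layer) LSTM encoder reads the
per-frame flattened pose sequence (T x J*3) and its last-step output, a
length-C vector Z (C = 256 by default), is the action representation.  Two
decoders each tile Z to every time step, run a single-layer LSTM over the
tiled input, and map each step through a shared linear layer:

* ``baseline``  — both decoders emit pose reconstructions (T x J*3).
* ``pdf_e``     — explicit: decoder D_M emits raw magnitudes (T x J), D_O
  emits vectors (T x J x 3) that are normalized to unit length, so the
  cosine loss is bounded and well-defined.
* ``pdf_i``     — implicit: both decoders emit pose-like variables; the
  magnitude / orientation of their *derived* reference pose flow are the
  trained outputs, and an agreement constraint couples the decoders.
* ``pdf_g``     — generalized: same forward pass as ``pdf_i``, but the pose
  variables are additionally constrained to rebuild the input pose, so the
  code carries both motion and shape.

The networks are built on the package's own float64 autograd engine, which
keeps runs bit-reproducible for a fixed seed on one device.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor, sigmoid, stack, tanh
from .errors import ConfigError, ShapeError
from .flows import DEFAULT_EPS, MagnitudeFlow, OrientationFlow
from .skeleton_io import PoseSequence

__all__ = [
    "EncoderSpec",
    "DecoderSpec",
    "VARIANTS",
    "PDFModel",
    "encode",
    "decode",
    "tile_latent",
    "forward_baseline",
    "forward_explicit",
    "forward_implicit",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("baseline", "pdf_e", "pdf_i", "pdf_g")


@dataclass(frozen=True)
class EncoderSpec:
    input_dim: int
    hidden_dim: int = 256
    num_layers: int = 1

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.input_dim < 1:
            raise ConfigError("encoder dimensions must be positive")
        if self.num_layers not in (1, 2):
            raise ConfigError("num_layers must be 1 (default) or 2 (enhanced)")


@dataclass(frozen=True)
class DecoderSpec:
    hidden_dim: int
    output_dim: int
    out_frames: int = 50

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.output_dim, self.out_frames) < 1:
            raise ConfigError("decoder dimensions must be positive")


def _init_lstm(params: dict, prefix: str, in_dim: int, hidden: int, rng) -> None:
    k = 1.0 / np.sqrt(hidden)
    params[f"{prefix}.Wx"] = Tensor(rng.uniform(-k, k, (in_dim, 4 * hidden)), requires_grad=True)
    params[f"{prefix}.Wh"] = Tensor(rng.uniform(-k, k, (hidden, 4 * hidden)), requires_grad=True)
    b = rng.uniform(-k, k, 4 * hidden)
    b[hidden : 2 * hidden] += 1.0  # forget-gate bias offset for stable early training
    params[f"{prefix}.b"] = Tensor(b, requires_grad=True)


def _lstm_run(params: dict, prefix: str, inputs, batch: int, hidden: int):
    """Run an LSTM over a list of per-step inputs; returns the output list."""
    Wx, Wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    h = Tensor(np.zeros((batch, hidden)))
    c = Tensor(np.zeros((batch, hidden)))
    outs = []
    for xt in inputs:
        z = xt @ Wx + h @ Wh + b
        i = sigmoid(z[:, :hidden])
        f = sigmoid(z[:, hidden : 2 * hidden])
        g = tanh(z[:, 2 * hidden : 3 * hidden])
        o = sigmoid(z[:, 3 * hidden :])
        c = f * c + i * g
        h = o * tanh(c)
        outs.append(h)
    return outs


def _tensor_rpf_decouple(p: Tensor, eps: float) -> tuple[Tensor, Tensor]:
    """Differentiable RPF + decoupling of a (B, T, J, 3) pose tensor.

    Magnitudes use the smooth surrogate sqrt(||F||^2 + eps^2), which equals
    the exact norm to within eps and keeps gradients finite at zero motion.
    """
    f = p - p.mean(axis=1, keepdims=True)
    sq = (f * f).sum(axis=-1)
    alpha = ag.sqrt(sq + eps * eps)
    b, t, j = alpha.shape
    units = f / alpha.reshape(b, t, j, 1)
    return alpha, units


class PDFModel:
    """One encoder + two decoders; behaviour switches on `variant`."""

    def __init__(
        self,
        variant: str,
        num_joints: int = 25,
        num_frames: int = 50,
        hidden_dim: int = 256,
        num_layers: int = 1,
        seed: int = 0,
        eps: float = DEFAULT_EPS,
    ):
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.variant = variant
        self.num_joints = num_joints
        self.num_frames = num_frames
        self.eps = eps
        self.seed = seed
        in_dim = num_joints * 3
        self.encoder_spec = EncoderSpec(in_dim, hidden_dim, num_layers)
        if variant == "pdf_e":
            out_m, out_o = num_joints, num_joints * 3  # magnitudes / orientation vectors
        else:
            out_m = out_o = num_joints * 3  # pose-shaped outputs
        self.decoder_specs = (
            DecoderSpec(hidden_dim, out_m, num_frames),
            DecoderSpec(hidden_dim, out_o, num_frames),
        )

        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        _init_lstm(self.params, "enc.l0", in_dim, hidden_dim, rng)
        if num_layers == 2:
            _init_lstm(self.params, "enc.l1", hidden_dim, hidden_dim, rng)
        for name, spec in zip(("dec_m", "dec_o"), self.decoder_specs):
            _init_lstm(self.params, f"{name}.lstm", hidden_dim, hidden_dim, rng)
            k = 1.0 / np.sqrt(hidden_dim)
            self.params[f"{name}.fc.W"] = Tensor(
                rng.uniform(-k, k, (hidden_dim, spec.output_dim)), requires_grad=True
            )
            self.params[f"{name}.fc.b"] = Tensor(
                rng.uniform(-k, k, spec.output_dim), requires_grad=True
            )

    # ---- plumbing -------------------------------------------------------
    @property
    def hidden_dim(self) -> int:
        return self.encoder_spec.hidden_dim

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def _as_batch(self, x) -> np.ndarray:
        """Coerce input to (B, T, J*3) float64."""
        if isinstance(x, PoseSequence):
            x = x.coords
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3 and x.shape[-1] == 3:  # (T, J, 3)
            x = x[None]
        if x.ndim == 2:  # (T, D)
            x = x[None]
        if x.ndim == 4:  # (B, T, J, 3)
            x = x.reshape(x.shape[0], x.shape[1], -1)
        if x.ndim != 3:
            raise ShapeError(f"cannot interpret input of shape {x.shape}")
        if x.shape[-1] != self.encoder_spec.input_dim:
            raise ShapeError(
                f"per-frame width {x.shape[-1]} != encoder input_dim "
                f"{self.encoder_spec.input_dim}"
            )
        return x

    # ---- forward passes -------------------------------------------------
    def encode(self, x) -> Tensor:
        """Latent codes Z, shape (B, C): the last-step encoder output."""
        xb = self._as_batch(x)
        batch, t_steps = xb.shape[0], xb.shape[1]
        hidden = self.hidden_dim
        inputs = [Tensor(xb[:, t, :]) for t in range(t_steps)]
        outs = _lstm_run(self.params, "enc.l0", inputs, batch, hidden)
        if self.encoder_spec.num_layers == 2:
            outs = _lstm_run(self.params, "enc.l1", outs, batch, hidden)
        return outs[-1]

    def decode(self, z: Tensor, which: str) -> Tensor:
        """Tile z over time, run one decoder; (B, T, output_dim)."""
        if which not in ("dec_m", "dec_o"):
            raise ConfigError(f"unknown decoder {which!r}")
        spec = self.decoder_specs[0 if which == "dec_m" else 1]
        if z.shape[-1] != spec.hidden_dim:
            raise ShapeError(f"latent width {z.shape[-1]} != {spec.hidden_dim}")
        batch = z.shape[0]
        inputs = [z] * spec.out_frames  # latent tiling: Z repeated at every step
        outs = _lstm_run(self.params, f"{which}.lstm", inputs, batch, spec.hidden_dim)
        W, b = self.params[f"{which}.fc.W"], self.params[f"{which}.fc.b"]
        return stack([h @ W + b for h in outs], axis=1)

    def forward(self, x) -> dict[str, Tensor]:
        """Variant-dependent outputs as autograd tensors (training path)."""
        xb = self._as_batch(x)
        z = self.encode(xb)
        out_m = self.decode(z, "dec_m")
        out_o = self.decode(z, "dec_o")
        b, t = xb.shape[0], xb.shape[1]
        j = self.num_joints
        if self.variant == "baseline":
            return {"pose_a": out_m, "pose_b": out_o, "z": z}
        if self.variant == "pdf_e":
            vec = out_o.reshape(b, t, j, 3)
            sq = (vec * vec).sum(axis=-1)
            norm = ag.sqrt(sq + self.eps * self.eps)
            units = vec / norm.reshape(b, t, j, 1)
            return {"magnitude": out_m, "orientation": units, "z": z}
        # pdf_i / pdf_g: flows derived from pose-like decoder variables
        p_m = out_m.reshape(b, t, j, 3)
        p_o = out_o.reshape(b, t, j, 3)
        alpha, _ = _tensor_rpf_decouple(p_m, self.eps)
        _, units = _tensor_rpf_decouple(p_o, self.eps)
        return {
            "pose_M": out_m,
            "pose_O": out_o,
            "magnitude": alpha,
            "orientation": units,
            "z": z,
        }


# ---------------------------------------------------------------------------
# Functional wrappers (inference: NumPy in, NumPy/domain types out)


def tile_latent(z: np.ndarray, out_frames: int) -> np.ndarray:
    """Repeat a latent vector at every decoder time step: (C,) -> (T, C)."""
    z = np.asarray(z, dtype=np.float64)
    return np.tile(z.reshape(1, -1), (out_frames, 1))


def encode(seq, model: PDFModel) -> np.ndarray:
    """Action representation Z of one sequence (or batch) as an array."""
    z = model.encode(seq)
    out = z.data
    return out[0] if _is_single(seq) else out


def decode(z, model: PDFModel, which: str = "dec_m") -> np.ndarray:
    zt = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
    return model.decode(zt, which).data


def _is_single(x) -> bool:
    if isinstance(x, PoseSequence):
        return True
    x = np.asarray(x)
    return (x.ndim == 3 and x.shape[-1] == 3) or x.ndim == 2


def _squeeze(arr: np.ndarray, single: bool) -> np.ndarray:
    return arr[0] if single else arr


def forward_baseline(seq, model: PDFModel) -> tuple[np.ndarray, np.ndarray]:
    if model.variant != "baseline":
        raise ConfigError(f"forward_baseline called on variant {model.variant!r}")
    out = model.forward(seq)
    single = _is_single(seq)
    return _squeeze(out["pose_a"].data, single), _squeeze(out["pose_b"].data, single)


def forward_explicit(seq, model: PDFModel) -> tuple[MagnitudeFlow, OrientationFlow]:
    if model.variant != "pdf_e":
        raise ConfigError(f"forward_explicit called on variant {model.variant!r}")
    out = model.forward(seq)
    single = _is_single(seq)
    units = _squeeze(out["orientation"].data, single)
    return (
        MagnitudeFlow(alpha=_squeeze(out["magnitude"].data, single)),
        OrientationFlow(units=units, valid_mask=np.ones(units.shape[:-1], dtype=bool)),
    )


def forward_implicit(
    seq, model: PDFModel
) -> tuple[np.ndarray, np.ndarray, MagnitudeFlow, OrientationFlow]:
    if model.variant not in ("pdf_i", "pdf_g"):
        raise ConfigError(f"forward_implicit called on variant {model.variant!r}")
    out = model.forward(seq)
    single = _is_single(seq)
    alpha = _squeeze(out["magnitude"].data, single)
    units = _squeeze(out["orientation"].data, single)
    return (
        _squeeze(out["pose_M"].data, single),
        _squeeze(out["pose_O"].data, single),
        MagnitudeFlow(alpha=alpha),
        OrientationFlow(units=units, valid_mask=alpha > model.eps),
    )


def count_parameters(model: PDFModel) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.size for p in model.params.values()))


# ---------------------------------------------------------------------------
# Checkpoints


def _ckpt_base(path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix in (".npz", ".json") else path


def save_checkpoint(model: PDFModel, path) -> None:
    """Weights to `<path>.npz` plus a `<path>.json` architecture sidecar."""
    base = _ckpt_base(path)
    np.savez(str(base) + ".npz", **{k: v.data for k, v in model.params.items()})
    meta = {
        "variant": model.variant,
        "num_joints": model.num_joints,
        "num_frames": model.num_frames,
        "hidden_dim": model.hidden_dim,
        "num_layers": model.encoder_spec.num_layers,
        "seed": model.seed,
        "eps": model.eps,
        "encoder_spec": asdict(model.encoder_spec),
        "num_parameters": count_parameters(model),
    }
    with open(str(base) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path) -> PDFModel:
    base = _ckpt_base(path)
    with open(str(base) + ".json") as fh:
        meta = json.load(fh)
    model = PDFModel(
        meta["variant"],
        num_joints=meta["num_joints"],
        num_frames=meta["num_frames"],
        hidden_dim=meta["hidden_dim"],
        num_layers=meta["num_layers"],
        seed=meta["seed"],
        eps=meta["eps"],
    )
    with np.load(str(base) + ".npz") as arrs:
        for k in model.params:
            model.params[k].data = np.asarray(arrs[k], dtype=np.float64)
    return model
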