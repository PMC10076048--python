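"""Training loop, representation extraction, and the 1-NN cosine protocol.

Optimization follows the standard schedule for this family of models: Adam
with a learning rate starting at 1e-3, decayed by 0.1 after every 80 epochs,
batch size 128, up to 100 epochs.  All randomness (weight init, shuffling)
derives from ``TrainConfig.seed``, so a run is bit-reproducible on one
device.

Evaluation is fully unsupervised: the trained encoder embeds every train and
test sequence; each test representation is assigned the label of its most
cosine-similar training representation (k-NN with k = 1).  Ties break to the
lowest training index; representations are used raw, since cosine similarity
is already scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import objectives as obj
from .autograd import Tensor
from .errors import ConfigError, ShapeError, UndefinedSimilarityError
from .flows import DEFAULT_EPS, MagnitudeFlow, OrientationFlow
from .networks import PDFModel, save_checkpoint
from .objectives import LossWeights, UncertaintyParams
from .skeleton_io import DatasetHandle

__all__ = [
    "TrainConfig",
    "Adam",
    "effective_lr",
    "train",
    "overfit",
    "RepresentationMatrix",
    "extract_representations",
    "knn1_classify",
    "EvalResult",
    "evaluate",
    "run_ablation",
    "summarize_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    variant: str = "pdf_g"
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 80
    lr_decay_unit: str = "epoch"  # or "step"
    batch_size: int = 128
    max_epochs: int = 100
    seed: int = 0
    adaptive: bool = True  # uncertainty weighting for the multi-task variants
    weights: LossWeights = field(default_factory=LossWeights)
    hidden_dim: int = 256
    num_layers: int = 1
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 0 or self.lr_decay_every < 1:
            raise ConfigError("invalid batch_size / max_epochs / lr_decay_every")
        if self.lr_decay_unit not in ("epoch", "step"):
            raise ConfigError("lr_decay_unit must be 'epoch' or 'step'")


def effective_lr(cfg: TrainConfig, epoch: int = 0, step: int = 0) -> float:
    """Learning rate in force at a (0-based) epoch or optimizer step.

    The rate is multiplied by `lr_decay_factor` after every `lr_decay_every`
    units, so with the defaults (1e-3, 0.1, every 80 epochs) epochs 0..79 run
    at 1e-3 and epoch 80 (the 81st) onward at 1e-4.
    """
    unit = epoch if cfg.lr_decay_unit == "epoch" else step
    return cfg.learning_rate * cfg.lr_decay_factor ** (unit // cfg.lr_decay_every)


class Adam:
    """Adam optimizer over a list of autograd tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Target preparation and per-batch loss


def _stack_coords(data: DatasetHandle) -> np.ndarray:
    lengths = {s.num_frames for s in data.sequences}
    joints = {s.num_joints for s in data.sequences}
    if len(lengths) != 1 or len(joints) != 1:
        raise ShapeError(
            "training requires sequences normalized to one (T, J); "
            f"got T in {sorted(lengths)}, J in {sorted(joints)}"
        )
    return np.stack([s.coords for s in data.sequences])


def _make_targets(x: np.ndarray, variant: str, eps: float) -> dict:
    """Precompute supervision signals for a (n, T, J, 3) coordinate block."""
    n, t, j, _ = x.shape
    targets: dict = {"pose": x.reshape(n, t, j * 3)}
    if variant != "baseline":
        f = x - x.mean(axis=1, keepdims=True)  # reference pose flow
        alpha = np.linalg.norm(f, axis=-1)
        valid = alpha > eps
        units = np.zeros_like(f)
        np.divide(f, alpha[..., None], out=units, where=valid[..., None])
        targets.update(alpha=alpha, units=units, valid=valid)
    return targets


def _batch_loss(model: PDFModel, xb: np.ndarray, tb: dict, cfg: TrainConfig,
                u: UncertaintyParams | None):
    """Forward + loss for one batch; returns (total Tensor, LossBreakdown)."""
    out = model.forward(xb)
    if model.variant == "baseline":
        bd = obj.loss_baseline(tb["pose"], out["pose_a"], out["pose_b"])
        return bd.total, bd
    o_target = OrientationFlow(units=tb["units"], valid_mask=tb["valid"])
    m_target = MagnitudeFlow(alpha=tb["alpha"])
    o_pred = OrientationFlow(units=out["orientation"], valid_mask=tb["valid"])
    if model.variant == "pdf_e":
        bd = obj.loss_explicit(m_target, o_target, out["magnitude"], o_pred, cfg.weights)
    elif model.variant == "pdf_i":
        bd = obj.loss_implicit(
            m_target, o_target, out["magnitude"], o_pred,
            out["pose_M"], out["pose_O"], cfg.weights,
        )
    else:  # pdf_g
        bd = obj.loss_generalized(
            m_target, o_target, out["magnitude"], o_pred,
            out["pose_M"], out["pose_O"], tb["pose"], cfg.weights,
        )
    if u is not None:
        total = obj.adaptive_combine(bd.terms, u)
        return total, bd
    return bd.total, bd


def _num_adaptive_terms(variant: str) -> int:
    return {"pdf_e": 2, "pdf_i": 3, "pdf_g": 4}.get(variant, 0)


def _check_finite(total: Tensor, bd: obj.LossBreakdown) -> None:
    if np.isfinite(total.data):
        return
    bad = [k for k, v in bd.term_floats().items() if not np.isfinite(v)]
    raise FloatingPointError(
        f"non-finite training loss; offending term(s): {bad or ['combined total']}"
    )


def train(
    data: DatasetHandle,
    cfg: TrainConfig,
    checkpoint_path=None,
    log_path=None,
) -> tuple[PDFModel, list[dict]]:
    """Train one variant on a normalized dataset.

    Returns the trained model and a per-epoch history of term values
    (columns: epoch, each loss term, total, and the uncertainty log-variances
    when adaptive weighting is active).  ``max_epochs = 0`` returns the
    freshly initialized model with an empty history.
    """
    x = _stack_coords(data)
    n, t, j, _ = x.shape
    model = PDFModel(
        cfg.variant, num_joints=j, num_frames=t,
        hidden_dim=cfg.hidden_dim, num_layers=cfg.num_layers,
        seed=cfg.seed, eps=cfg.eps,
    )
    targets = _make_targets(x, cfg.variant, cfg.eps)

    u = None
    if cfg.adaptive and _num_adaptive_terms(cfg.variant) > 0:
        u = UncertaintyParams.zeros(_num_adaptive_terms(cfg.variant))
    opt_params = list(model.params.values()) + ([u.s] if u is not None else [])
    opt = Adam(opt_params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    history: list[dict] = []
    step = 0
    for epoch in range(cfg.max_epochs):
        if cfg.lr_decay_unit == "epoch":
            opt.lr = effective_lr(cfg, epoch=epoch)
        perm = rng.permutation(n)
        epoch_terms: dict[str, list[float]] = {}
        totals: list[float] = []
        for start in range(0, n, cfg.batch_size):
            if cfg.lr_decay_unit == "step":
                opt.lr = effective_lr(cfg, step=step)
            idx = perm[start : start + cfg.batch_size]
            tb = {k: v[idx] for k, v in targets.items()}
            total, bd = _batch_loss(model, x[idx], tb, cfg, u)
            _check_finite(total, bd)
            opt.zero_grad()
            total.backward()
            opt.step()
            step += 1
            totals.append(float(total.data))
            for k, v in bd.term_floats().items():
                epoch_terms.setdefault(k, []).append(v)
        row = {"epoch": epoch, "total": float(np.mean(totals))}
        row.update({k: float(np.mean(v)) for k, v in epoch_terms.items()})
        if u is not None:
            for i, s_val in enumerate(np.atleast_1d(u.s.data)):
                row[f"s{i}"] = float(s_val)
        history.append(row)

    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    if log_path is not None and history:
        pd.DataFrame(history).to_csv(log_path, index=False)
    return model, history


def overfit(
    data: DatasetHandle,
    variant: str,
    steps: int = 500,
    seed: int = 0,
    hidden_dim: int = 64,
    learning_rate: float = 1e-3,
    adaptive: bool = False,
) -> tuple[float, float, PDFModel]:
    """Full-batch capacity check: drive one variant onto a tiny dataset.

    Runs `steps` Adam updates at a fixed learning rate (no decay — the point
    is memorization capacity, not the schedule) and returns
    (initial_loss, final_loss, model).  Losses are the fixed-weight totals so
    initial and final values are on the same scale even when adaptive
    weighting is used for the updates.
    """
    cfg = TrainConfig(
        variant=variant, seed=seed, hidden_dim=hidden_dim,
        learning_rate=learning_rate, adaptive=adaptive,
        batch_size=len(data), max_epochs=0,
    )
    x = _stack_coords(data)
    n, t, j, _ = x.shape
    model = PDFModel(variant, num_joints=j, num_frames=t,
                     hidden_dim=hidden_dim, seed=seed, eps=cfg.eps)
    targets = _make_targets(x, variant, cfg.eps)
    u = UncertaintyParams.zeros(_num_adaptive_terms(variant)) if (
        adaptive and _num_adaptive_terms(variant) > 0) else None
    opt = Adam(list(model.params.values()) + ([u.s] if u is not None else []),
               lr=learning_rate)
    initial = None
    for _ in range(steps):
        total, bd = _batch_loss(model, x, targets, cfg, u)
        _check_finite(total, bd)
        if initial is None:
            initial = bd.total_float()
        opt.zero_grad()
        total.backward()
        opt.step()
    _, bd = _batch_loss(model, x, targets, cfg, None)
    if initial is None:
        initial = bd.total_float()
    return float(initial), bd.total_float(), model


# ---------------------------------------------------------------------------
# Representations and the 1-NN cosine protocol


@dataclass
class RepresentationMatrix:
    rows: np.ndarray  # (n, C)
    labels: np.ndarray  # (n,)
    ids: list[str]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("representation matrix contains non-finite rows")
        if len(self.rows) != len(self.labels):
            raise ValueError("rows and labels must align")


def extract_representations(
    model: PDFModel, data: DatasetHandle, batch_size: int = 64
) -> RepresentationMatrix:
    """Encode every sequence; row i is the representation of sequence i."""
    x = _stack_coords(data)
    rows = []
    for start in range(0, len(x), batch_size):
        rows.append(model.encode(x[start : start + batch_size]).data)
    return RepresentationMatrix(
        rows=np.concatenate(rows, axis=0) if rows else np.zeros((0, model.hidden_dim)),
        labels=data.labels.copy(),
        ids=[s.seq_id for s in data.sequences],
    )


def _unit_rows(rows: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        raise UndefinedSimilarityError(f"zero-norm row in {what} representations")
    return rows / norms[:, None]


def knn1_classify(
    train: RepresentationMatrix, test: RepresentationMatrix
) -> np.ndarray:
    """Label of the most cosine-similar training row, per test row.

    Ties break to the lowest training index (argmax returns the first
    maximum), making the protocol deterministic.
    """
    if len(train.rows) == 0:
        raise ValueError("empty training representation matrix")
    if train.rows.shape[1] != test.rows.shape[1]:
        raise ShapeError("train/test representation widths differ")
    sim = _unit_rows(test.rows, "test") @ _unit_rows(train.rows, "train").T
    return train.labels[np.argmax(sim, axis=1)]


@dataclass
class EvalResult:
    accuracy: float
    confusion: np.ndarray  # (K, K), rows = true class, columns = predicted
    per_class_recall: np.ndarray  # (K,)
    classes: np.ndarray  # label values indexing the confusion axes

    def to_csv(self, path) -> None:
        pd.DataFrame(self.confusion, index=self.classes, columns=self.classes).to_csv(path)


def evaluate(train: RepresentationMatrix, test: RepresentationMatrix) -> EvalResult:
    """Run the 1-NN cosine protocol and tabulate a confusion matrix."""
    if not np.intersect1d(train.labels, test.labels).size:
        warnings.warn("train and test label sets are disjoint; accuracy will be 0")
    pred = knn1_classify(train, test)
    classes = np.unique(np.concatenate([train.labels, test.labels]))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), dtype=np.int64)
    for true, p in zip(test.labels, pred):
        confusion[index[true], index[p]] += 1
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, np.diag(confusion) / row_sums, np.nan)
    accuracy = float(np.mean(pred == test.labels)) if len(test.labels) else float("nan")
    return EvalResult(accuracy=accuracy, confusion=confusion,
                      per_class_recall=recall, classes=classes)


# ---------------------------------------------------------------------------
# Ablation harness


def run_ablation(
    train_data: DatasetHandle,
    test_data: DatasetHandle,
    variants: list[str],
    seeds: list[int],
    base_cfg: TrainConfig | None = None,
    out_csv=None,
) -> pd.DataFrame:
    """Train/evaluate every (variant, seed) pair on one dataset split.

    Returns a tidy DataFrame with one row per run (variant, seed, accuracy);
    `summarize_ablation` aggregates it to mean +/- sd per variant, which is
    also what gets written to `out_csv`.
    """
    if not variants or not seeds:
        raise ConfigError("need at least one variant and one seed")
    base_cfg = base_cfg or TrainConfig()
    rows = []
    for variant in variants:
        for seed in seeds:
            cfg = replace(base_cfg, variant=variant, seed=int(seed))
            model, _ = train(train_data, cfg)
            reps_tr = extract_representations(model, train_data)
            reps_te = extract_representations(model, test_data)
            result = evaluate(reps_tr, reps_te)
            rows.append({"variant": variant, "seed": int(seed),
                         "accuracy": result.accuracy})
    runs = pd.DataFrame(rows)
    if out_csv is not None:
        summarize_ablation(runs).to_csv(out_csv, index=False)
    return runs


def summarize_ablation(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of accuracy per variant."""
    summary = (
        runs.groupby("variant", sort=False)["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy="std", n_runs="count")
        .reset_index()
    )
    summary["sd_accuracy"] = summary["sd_accuracy"].fillna(0.0)
    return summary
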