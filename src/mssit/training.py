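"""Losses, balanced sampling, AdamW + cosine schedule, training and evaluation.

The training recipe: AdamW with a cosine-decay learning-rate schedule, MSE
loss for regression and an equally weighted Dice + cross-entropy loss for
segmentation; surface augmentation applied per training sample with
probability 0.8 (rotation or elastic warp, 50/50); and, for regression, a
balancing sampler that equalises the expected sampling mass across target
bins.  Per-channel z-scoring statistics are computed on the training split
and stored in the checkpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .icosphere import build_icosphere
from .model import MSSiT, MSSiTConfig, MSSiTUNet, build_model, save_checkpoint
from .resample import AugmentationConfig, augment
from .surface_io import SurfaceSignal, read_labels, read_metric

__all__ = [
    "TrainConfig",
    "EvalReport",
    "mse_loss",
    "dice_ce_loss",
    "soft_dice",
    "dice_scores",
    "balanced_sample_weights",
    "cosine_decay_lr",
    "AdamW",
    "load_manifest_data",
    "train",
    "evaluate",
]


@dataclass
class TrainConfig:
    task: str = "regression"
    lr_max: float = 1e-3
    lr_min: float = 0.0
    weight_decay: float = 0.01
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0
    val_fraction: float = 0.2
    balance_bin_width: float = 1.0  # regression target units (1 week for age tasks)
    dice_weight: float = 0.5
    ce_weight: float = 0.5
    patience: int = 20
    warmup_fraction: float = 0.15  # share of total steps spent in linear lr warmup
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must be <= lr_max")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class EvalReport:
    """Per-subject predictions plus the task metric."""

    task: str
    subject_ids: list[str]
    predictions: np.ndarray
    mae: float | None = None
    dice_per_region: np.ndarray | None = None
    mean_dice: float | None = None


# --------------------------------------------------------------------- losses
def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64).reshape(pred.shape))
    return (diff * diff).mean()


def soft_dice(logits: Tensor, labels: np.ndarray, num_classes: int, smooth: float = 1e-5) -> Tensor:
    """Mean soft Dice over classes: 2*sum(p*y) / (sum(p) + sum(y)), smoothed."""
    probs = logits.softmax(-1)
    onehot = np.zeros(labels.shape + (num_classes,))
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    axes = tuple(range(probs.ndim - 1))
    inter = (probs * Tensor(onehot)).sum(axis=axes)  # (K,)
    denom = probs.sum(axis=axes) + onehot.sum(axis=axes)
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    return dice.mean()


def dice_ce_loss(
    logits: Tensor,
    labels: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
    smooth: float = 1e-5,
) -> Tensor:
    """``dice_w * (1 - mean soft Dice) + ce_w * cross-entropy`` over all vertices."""
    labels = np.asarray(labels)
    num_classes = logits.shape[-1]
    if num_classes < 2:
        raise ValueError("need at least 2 classes")
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels out of range [0, {num_classes})")
    dice_w, ce_w = weights
    logp = logits.log_softmax(-1)
    onehot = np.zeros(labels.shape + (num_classes,))
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    ce = -(logp * Tensor(onehot)).sum(axis=-1).mean()
    return (1.0 - soft_dice(logits, labels, num_classes, smooth)) * dice_w + ce * ce_w


def dice_scores(pred_labels: np.ndarray, true_labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Hard per-class Dice 2|A∩B|/(|A|+|B|); empty-empty classes score 1."""
    pred_labels = np.asarray(pred_labels).ravel()
    true_labels = np.asarray(true_labels).ravel()
    out = np.zeros(num_classes)
    for k in range(num_classes):
        p = pred_labels == k
        t = true_labels == k
        denom = p.sum() + t.sum()
        out[k] = 1.0 if denom == 0 else 2.0 * (p & t).sum() / denom
    return out


# ------------------------------------------------------------------- sampling
def balanced_sample_weights(targets, bin_width: float) -> np.ndarray:
    """Per-sample weights proportional to 1/bin count, normalised to sum 1."""
    targets = np.asarray(targets, dtype=np.float64)
    if targets.size == 0:
        raise ValueError("targets must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins = np.floor(targets / bin_width).astype(np.int64)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inverse]
    return w / w.sum()


def cosine_decay_lr(step: int, config) -> float:
    """lr(step) = lr_min + (lr_max - lr_min) * (1 + cos(pi * step / total_steps)) / 2."""
    total = config.total_steps if hasattr(config, "total_steps") else config["total_steps"]
    lr_max = config.lr_max if hasattr(config, "lr_max") else config["lr_max"]
    lr_min = config.lr_min if hasattr(config, "lr_min") else config["lr_min"]
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * step / total))


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


# --------------------------------------------------------------------- data
@dataclass
class _Dataset:
    subject_ids: list[str]
    values: np.ndarray  # (N, V, C) raw (not normalised)
    targets: np.ndarray | None  # (N,) regression
    labels: np.ndarray | None  # (N, V) segmentation
    mesh_order: int


def load_manifest_data(manifest: str | Path | pd.DataFrame, task: str) -> _Dataset:
    """Load a CSV manifest (subject_id, metric_path, target | label_path) into memory."""
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        df = pd.read_csv(manifest)
    else:
        base = Path(".")
        df = manifest
    need = {"subject_id", "metric_path"}
    need |= {"target"} if task == "regression" else {"label_path"}
    missing_cols = need - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest lacks columns {sorted(missing_cols)}")
    values, labels, targets, ids = [], [], [], []
    for _, row in df.iterrows():
        p = Path(row["metric_path"])
        if not p.is_absolute():
            p = base / p
        sig = read_metric(p)
        values.append(sig.values)
        ids.append(str(row["subject_id"]))
        if task == "regression":
            targets.append(float(row["target"]))
        else:
            lp = Path(row["label_path"])
            if not lp.is_absolute():
                lp = base / lp
            labels.append(read_labels(lp).labels)
    values = np.stack(values)
    n_vert = values.shape[1]
    order = int(round(math.log((n_vert - 2) / 10, 4)))
    if 10 * 4**order + 2 != n_vert:
        raise ValueError(f"{n_vert} vertices is not an icosphere vertex count")
    return _Dataset(
        subject_ids=ids,
        values=values,
        targets=np.array(targets) if targets else None,
        labels=np.stack(labels) if labels else None,
        mesh_order=order,
    )


def _split(n: int, val_fraction: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]


# ------------------------------------------------------------------- training
def train(
    manifest: str | Path | pd.DataFrame,
    model_config: MSSiTConfig,
    train_config: TrainConfig,
    checkpoint_path: str | Path | None = None,
    val_indices: np.ndarray | None = None,
):
    """Train an MS-SiT on a manifest dataset; returns (model, history, info).

    Deterministic for a fixed seed under single-threaded execution.  The
    best-validation parameters are restored before returning (and saved to
    ``checkpoint_path`` when given, together with normalisation statistics).
    """
    task = train_config.task
    data = load_manifest_data(manifest, task)
    if data.mesh_order != model_config.input_order:
        raise ValueError(
            f"data on ico{data.mesh_order} but model expects ico{model_config.input_order}"
        )
    rng = np.random.default_rng(train_config.seed)
    n = len(data.subject_ids)
    if val_indices is None:
        tr_idx, va_idx = _split(n, train_config.val_fraction, rng)
    else:
        va_idx = np.asarray(val_indices)
        tr_idx = np.setdiff1d(np.arange(n), va_idx)

    mu = data.values[tr_idx].mean(axis=(0, 1))
    sd = data.values[tr_idx].std(axis=(0, 1))
    sd[sd == 0] = 1.0
    if task == "regression":
        t_mu = float(data.targets[tr_idx].mean())
        t_sd = float(data.targets[tr_idx].std()) or 1.0
    else:
        t_mu, t_sd = 0.0, 1.0

    model = build_model(model_config, np.random.default_rng(train_config.seed + 1))
    opt = AdamW(model.parameters(), lr=train_config.lr_max,
                weight_decay=train_config.weight_decay)
    mesh = build_icosphere(data.mesh_order)
    steps_per_epoch = max(1, len(tr_idx) // train_config.batch_size)
    total_steps = steps_per_epoch * train_config.epochs
    warmup_steps = int(round(train_config.warmup_fraction * total_steps))

    class _Sched:
        lr_max = train_config.lr_max
        lr_min = train_config.lr_min
    _Sched.total_steps = max(1, total_steps - warmup_steps)

    def lr_at(step: int) -> float:
        # linear warmup into the cosine decay; warmup stabilises the early
        # AdamW updates that otherwise stall the transformer on a plateau
        if step < warmup_steps:
            return train_config.lr_max * (step + 1) / warmup_steps
        return cosine_decay_lr(step - warmup_steps, _Sched)

    aug = train_config.augmentation
    history: list[dict] = []
    best_metric = math.inf
    best_state = model.state_dict()
    bad_epochs = 0
    step = 0

    def forward_batch(idx: np.ndarray, training: bool):
        vals = []
        labs = [] if task == "segmentation" else None
        for i in idx:
            v = data.values[i]
            lab = data.labels[i] if task == "segmentation" else None
            if training and aug is not None and aug.apply_probability > 0:
                sig = SurfaceSignal(v, mesh_order=data.mesh_order)
                res = augment(sig, aug, rng, mesh=mesh, labels=lab)
                if lab is None:
                    v = res.values
                else:
                    v, lab = res[0].values, res[1]
            vals.append((v - mu) / sd)
            if labs is not None:
                labs.append(lab)
        batch = np.stack(vals)
        out = model(batch, training=training, rng=rng)
        return out, (np.stack(labs) if labs is not None else None)

    def validate() -> float:
        errs = []
        for start in range(0, len(va_idx), train_config.batch_size):
            idx = va_idx[start:start + train_config.batch_size]
            out, labs = forward_batch(idx, training=False)
            if task == "regression":
                pred = out.data[:, 0] * t_sd + t_mu
                errs.append(np.abs(pred - data.targets[idx]))
            else:
                pred = out.data.argmax(-1)
                for b, i in enumerate(idx):
                    errs.append(
                        [1.0 - dice_scores(pred[b], data.labels[i], model_config.num_outputs).mean()]
                    )
        return float(np.concatenate([np.atleast_1d(e) for e in errs]).mean())

    for epoch in range(train_config.epochs):
        if task == "regression":
            w = balanced_sample_weights(data.targets[tr_idx], train_config.balance_bin_width)
            order = rng.choice(len(tr_idx), size=len(tr_idx), replace=True, p=w)
        else:
            order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, steps_per_epoch * train_config.batch_size, train_config.batch_size):
            idx = tr_idx[order[start:start + train_config.batch_size]]
            opt.lr = lr_at(step)
            out, labs = forward_batch(idx, training=True)
            if task == "regression":
                tgt = (data.targets[idx] - t_mu) / t_sd
                loss = mse_loss(out, tgt[:, None])
            else:
                loss = dice_ce_loss(out, labs, (train_config.dice_weight, train_config.ce_weight))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (lr={opt.lr:.3e})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
        val_metric = validate()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_metric": val_metric, "lr": opt.lr}
        )
        if val_metric < best_metric - 1e-12:
            best_metric = val_metric
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > train_config.patience:
                break

    model.load_state_dict(best_state)
    info = {
        "norm_mu": mu, "norm_sd": sd, "target_mu": t_mu, "target_sd": t_sd,
        "val_indices": va_idx, "train_indices": tr_idx, "best_val_metric": best_metric,
    }
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, extra={
            "norm_mu": mu, "norm_sd": sd,
            "target_mu": np.array(t_mu), "target_sd": np.array(t_sd),
        })
    return model, history, info


def evaluate(
    model: MSSiT | MSSiTUNet,
    manifest: str | Path | pd.DataFrame,
    norm: dict | None = None,
    batch_size: int = 16,
    indices: np.ndarray | None = None,
) -> EvalReport:
    """Evaluate a trained model on a manifest; MAE for regression, Dice for segmentation."""
    task = model.config.task
    task_key = "regression" if task in ("regression", "classification") else "segmentation"
    data = load_manifest_data(manifest, task_key)
    idx_all = np.arange(len(data.subject_ids)) if indices is None else np.asarray(indices)
    mu = norm.get("norm_mu", 0.0) if norm else 0.0
    sd = norm.get("norm_sd", 1.0) if norm else 1.0
    t_mu = float(norm.get("target_mu", 0.0)) if norm else 0.0
    t_sd = float(norm.get("target_sd", 1.0)) if norm else 1.0
    preds = []
    for start in range(0, len(idx_all), batch_size):
        idx = idx_all[start:start + batch_size]
        batch = (data.values[idx] - mu) / sd
        out = model(batch).data
        preds.append(out)
    out = np.concatenate(preds)
    ids = [data.subject_ids[i] for i in idx_all]
    if task_key == "regression":
        pred = out[:, 0] * t_sd + t_mu
        mae = float(np.abs(pred - data.targets[idx_all]).mean())
        return EvalReport(task=task, subject_ids=ids, predictions=pred, mae=mae)
    pred_labels = out.argmax(-1)
    K = model.config.num_outputs
    per_subject = np.stack(
        [dice_scores(pred_labels[j], data.labels[i], K) for j, i in enumerate(idx_all)]
    )
    dice_region = per_subject.mean(axis=0)
    return EvalReport(
        task=task, subject_ids=ids, predictions=pred_labels,
        dice_per_region=dice_region, mean_dice=float(dice_region.mean()),
    )
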