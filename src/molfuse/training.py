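"""Losses, learning-rate schedule, hyperparameter sampling, training loop.

Two optimizer parameter groups are used: the language encoder at ``lr_lang``
and everything else (graph layers, projections, head — the "coder") at
``lr_coder``. Both follow the same per-epoch schedule — linear warmup to the
base rate over ``warmup_epochs`` then inverse-square-root decay:
``lr(e) = lr_base * min(e / w, sqrt(w / e))``, continuous and maximal at
``e = w``. The training loss is the literal reported metric (RMSE, MAE or
BCE); regression targets are z-scored on each training fold and predictions
un-scaled before any metric is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._tensor import Adam, Tensor
from .data_splits import TaskSpec
from .exceptions import DomainError, NonFiniteLossError
from .fusion import Batch, FusionModel, Mode, PreparedMolecule, collate

__all__ = ["TrainConfig", "HyperparameterSpace", "lr_schedule",
           "compute_loss", "freeze_layers", "sample_hyperparameters",
           "train_model", "TrainResult", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the benchmark protocol:
    Adam, 50 epochs, batch 16, 32-bit parameters)."""

    lr_coder: float = 1e-3
    lr_lang: float = 1e-3
    warmup_epochs: int = 2
    freeze_layer_count: int = 0
    dense_dropout: float = 0.2
    epochs: int = 50
    batch_size: int = 16
    precision: int = 32
    optimizer: str = "adam"
    seed: int = 0
    standardize_targets: bool = True
    use_mse: bool = False            # train on MSE instead of literal RMSE

    def __post_init__(self):
        if self.lr_coder <= 0 or self.lr_lang <= 0:
            raise DomainError("learning rates must be positive")
        if not (0.0 < self.dense_dropout < 1.0):
            raise DomainError("dropout must lie in (0, 1)")
        if self.epochs < 1 or self.warmup_epochs < 1:
            raise DomainError("epochs and warmup_epochs must be >= 1")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class HyperparameterSpace:
    """Sampling bounds for random hyperparameter search."""

    lr_coder_bounds: tuple[float, float] = (1e-5, 1e-2)
    lr_lang_bounds: tuple[float, float] = (1e-9, 1e-6)
    warmup_bounds: tuple[int, int] = (1, 5)
    freeze_bounds: tuple[int, int] = (0, 3)
    dropout_bounds: tuple[float, float] = (0.1, 0.5)


def lr_schedule(epoch: int, warmup: int, lr_max: float) -> float:
    """Linear warmup then inverse-square-root decay.

    ``lr = lr_max * min(epoch/warmup, sqrt(warmup/epoch))`` for 1-based
    epochs; the two branches meet at ``epoch == warmup`` where the rate is
    exactly ``lr_max``.
    """
    if epoch < 1:
        raise DomainError(f"epoch must be >= 1, got {epoch}")
    if warmup < 1:
        raise DomainError(f"warmup must be >= 1, got {warmup}")
    return lr_max * min(epoch / warmup, math.sqrt(warmup / epoch))


_EPS = 1e-7


def compute_loss(predictions, targets, task: TaskSpec) -> float:
    """The literal training loss on NumPy arrays (float64).

    RMSE = sqrt(mean squared error); MAE = mean absolute error;
    BCE = -mean[y log p + (1-y) log(1-p)] with probabilities clamped to
    [1e-7, 1-1e-7].
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise DomainError(f"length mismatch: {p.shape} vs {t.shape}")
    loss = task.training_loss
    if loss == "rmse":
        return float(np.sqrt(np.mean((p - t) ** 2)))
    if loss == "mae":
        return float(np.mean(np.abs(p - t)))
    if loss == "bce":
        if not np.isin(t, (0.0, 1.0)).all():
            raise DomainError("classification targets must be in {0,1}")
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        return float(-np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc)))
    raise DomainError(f"unknown loss {loss!r}")


def _loss_tensor(pred: Tensor, targets: np.ndarray, task: TaskSpec,
                 use_mse: bool) -> Tensor:
    """Differentiable counterpart of :func:`compute_loss`."""
    t = Tensor(targets.astype(pred.data.dtype))
    loss = task.training_loss
    if loss in ("rmse",):
        mse = ((pred - t) ** 2).mean()
        return mse if use_mse else (mse + 1e-12) ** 0.5
    if loss == "mae":
        diff = pred - t
        return ((diff * diff + 1e-12) ** 0.5).mean()  # smooth |x|
    if loss == "bce":
        p = pred.clip(_EPS, 1.0 - _EPS)
        return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    raise DomainError(f"unknown loss {loss!r}")


def freeze_layers(encoder, n: int):
    """Freeze the embedding tables and first ``n`` transformer blocks."""
    if n < 0 or n > encoder.layer_count:
        raise DomainError(
            f"freeze count {n} outside [0, {encoder.layer_count}]")
    if n >= 0:
        encoder.freeze(n)
    return encoder


def sample_hyperparameters(space: HyperparameterSpace, seed: int,
                           **fixed) -> TrainConfig:
    """One seeded draw from the search space (loguniform rates, inclusive
    integer ranges, uniform dropout)."""
    rng = np.random.default_rng(seed)
    lo, hi = space.lr_coder_bounds
    lr_coder = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = space.lr_lang_bounds
    lr_lang = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    warmup = int(rng.integers(space.warmup_bounds[0],
                              space.warmup_bounds[1] + 1))
    freeze = int(rng.integers(space.freeze_bounds[0],
                              space.freeze_bounds[1] + 1))
    drop = float(rng.uniform(*space.dropout_bounds))
    return TrainConfig(lr_coder=lr_coder, lr_lang=lr_lang,
                       warmup_epochs=warmup, freeze_layer_count=freeze,
                       dense_dropout=drop, seed=seed, **fixed)


@dataclass
class TrainResult:
    model: FusionModel
    history: pd.DataFrame
    best_epoch: int
    best_metric: float
    target_mean: float = 0.0
    target_std: float = 1.0


def predict(model: FusionModel, records: list[PreparedMolecule],
            pad_id: int, batch_size: int = 64,
            target_mean: float = 0.0, target_std: float = 1.0) -> np.ndarray:
    """Deterministic evaluation-mode predictions, order preserved."""
    was_training = model.training
    model.eval()
    out = []
    for i in range(0, len(records), batch_size):
        batch = collate(records[i:i + batch_size], pad_id, mode=model.mode,
                        readout=model.arch.readout)
        out.append(model(batch).data.astype(np.float64))
    if was_training:
        model.train()
    preds = np.concatenate(out)
    if model.task.task_type == "regression":
        preds = preds * target_std + target_mean
    return preds


def train_model(model: FusionModel, train_records: list[PreparedMolecule],
                valid_records: list[PreparedMolecule], config: TrainConfig,
                pad_id: int) -> TrainResult:
    """Train a fusion model and return the epoch-best weights.

    Selection follows the task's metric (lowest RMSE/MAE, highest ROC-AUC) on
    the validation records; the full per-epoch history (train loss, valid
    metric, both learning rates) is returned.
    """
    from .evaluation import compute_metric

    task = model.task
    if config.dense_dropout != model.arch.dropout:
        model.arch = replace(model.arch, dropout=config.dense_dropout)
    if model.encoder is not None:
        freeze_layers(model.encoder, min(config.freeze_layer_count,
                                         model.encoder.layer_count))
    model.reseed_dropout(config.seed + 7919)
    rng = np.random.default_rng(config.seed)

    mu, sd = 0.0, 1.0
    labels = np.asarray([r.label for r in train_records], dtype=np.float64)
    if task.task_type == "regression" and config.standardize_targets:
        mu = float(labels.mean())
        sd = float(labels.std())
        if sd == 0.0:
            sd = 1.0

    groups = []
    coder = [p for p in model.coder_parameters()]
    if coder:
        groups.append({"params": coder, "lr": config.lr_coder})
    enc = model.encoder_parameters()
    if enc:
        groups.append({"params": enc, "lr": config.lr_lang})
    opt = Adam(groups)

    n = len(train_records)
    history = []
    best_metric = None
    best_epoch = -1
    best_state = None
    direction = task.selection_direction
    model.train()
    for epoch in range(1, config.epochs + 1):
        scale_c = lr_schedule(epoch, config.warmup_epochs, config.lr_coder)
        scale_l = lr_schedule(epoch, config.warmup_epochs, config.lr_lang)
        if coder:
            opt.groups[0]["lr"] = scale_c
        if enc:
            opt.groups[-1]["lr"] = scale_l
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            recs = [train_records[i] for i in idx]
            batch = collate(recs, pad_id, mode=model.mode,
                            readout=model.arch.readout)
            targets = batch.labels
            if task.task_type == "regression":
                targets = (targets - mu) / sd
            pred = model(batch)
            loss = _loss_tensor(pred, targets, task, config.use_mse)
            if not np.isfinite(loss.data):
                raise NonFiniteLossError(
                    f"loss became {loss.data} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_pred = predict(model, valid_records, pad_id,
                           target_mean=mu, target_std=sd)
        val_labels = np.asarray([r.label for r in valid_records],
                                dtype=np.float64)
        metric = compute_metric(val_pred, val_labels, task.selection_metric)
        history.append((epoch, float(np.mean(epoch_losses)), metric,
                        scale_c, scale_l))
        better = (best_metric is None
                  or (direction == "min" and metric < best_metric)
                  or (direction == "max" and metric > best_metric))
        if better:
            best_metric = metric
            best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    hist = pd.DataFrame(history, columns=["epoch", "train_loss",
                                          "valid_metric", "lr_coder",
                                          "lr_lang"])
    return TrainResult(model=model, history=hist, best_epoch=best_epoch,
                       best_metric=float(best_metric), target_mean=mu,
                       target_std=sd)
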