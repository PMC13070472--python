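"""Training loop, augmentation, hyperparameter search, and metrics.

Training minimizes mean-squared error on ΔΔG with Adam.  The learning rate
is halved on plateau: at every 100-epoch checkpoint, if the best training
loss has not improved within the last ten recorded epoch losses, the rate
is cut in half.  Runs are exactly reproducible for a fixed seed.

Reverse-mutation augmentation appends, for every record, its reverse
(wild type and mutant swapped, codes inverted, label negated), so the label
distribution the model trains on has mean exactly zero.  Because the
prediction head is antisymmetric by construction, augmented pairs are
predicted as exact negations.

Metrics follow the field's standard trio — Pearson correlation (Rp), RMSE
and MAE in kcal/mol — plus the optimization ratio: among samples predicted
affinity-enhancing (ΔΔG < 0), the fraction whose experimental label is also
negative; undefined when nothing is predicted enhancing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._autodiff import Adam, concat
from .config import ModelConfig
from .predictor import IGMIModel, SampleFeatures, residue_ddg_core, stack_pathways
from .structure import SampleRecord

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainingDiverged",
    "reverse_augment",
    "train",
    "evaluate",
    "compute_metrics",
    "optimization_ratio",
    "default_grid",
    "expand_grid",
    "grid_search",
    "retrain_full",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    dropout: float = 0.0
    batch_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 300
    seed: int = 0
    augment: bool = True
    weight_decay: float = 0.0   # decoupled L2, applied at the Adam step
    lr_check_every: int = 100   # plateau checkpoints, in epochs
    lr_patience: int = 10       # recorded epoch losses without improvement


@dataclass
class MetricsReport:
    """Standard evaluation metrics; ``opt_ratio`` is None when undefined."""

    rp: float
    rmse: float
    mae: float
    opt_ratio: float | None
    n: int


def reverse_augment(dataset: list[SampleRecord]) -> list[SampleRecord]:
    """Originals followed by their reverses; output size is 2x input."""
    return list(dataset) + [s.reversed() for s in dataset]


def compute_metrics(pred, label) -> MetricsReport:
    """Pearson Rp, RMSE, MAE (kcal/mol) and optimization ratio."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if pred.shape != label.shape:
        raise ValueError("prediction and label vectors must align")
    if pred.size < 2:
        raise ValueError("Pearson correlation needs at least two samples")
    rp = float(stats.pearsonr(pred, label).statistic)
    err = pred - label
    return MetricsReport(
        rp=rp,
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        opt_ratio=optimization_ratio(pred, label),
        n=int(pred.size),
    )


def optimization_ratio(pred, label) -> float | None:
    """Fraction of predicted affinity-enhancing mutations that truly are.

    Enhancing means ΔΔG < 0.  Returns None (undefined) when no sample is
    predicted enhancing.
    """
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    predicted_enhancing = pred < 0
    if not predicted_enhancing.any():
        return None
    correct = predicted_enhancing & (label < 0)
    return float(correct.sum() / predicted_enhancing.sum())


# -- internal batched training machinery -----------------------------------

@dataclass
class _PreparedData:
    """Featurized dataset: unique pathway features + (wt, mut, y) items."""

    paths: dict[str, np.ndarray]          # stacked pathway features
    masks: np.ndarray                     # (n_structures//2, n_max) per sample
    items: np.ndarray                     # (n_items, 2) pathway indices
    labels: np.ndarray                    # (n_items,)
    sample_mask_idx: np.ndarray           # (n_items,) -> per-sample mask row


def _prepare(model: IGMIModel, dataset: list[SampleRecord],
             augment: bool) -> _PreparedData:
    feats: list[SampleFeatures] = [model.featurize(s) for s in dataset]
    paths = stack_pathways(
        [f for sf in feats for f in (sf.wt, sf.mut)])
    masks = np.stack([sf.selection.mask for sf in feats])
    items, labels, midx = [], [], []
    for i, (sf, s) in enumerate(zip(feats, dataset)):
        items.append((2 * i, 2 * i + 1))
        labels.append(s.ddg)
        midx.append(i)
    if augment:
        for i, (sf, s) in enumerate(zip(feats, dataset)):
            items.append((2 * i + 1, 2 * i))
            labels.append(-s.ddg)
            midx.append(i)
    return _PreparedData(paths, masks, np.array(items),
                         np.array(labels, dtype=float), np.array(midx))


def _batch_predictions(model: IGMIModel, data: _PreparedData,
                       item_ids: np.ndarray, training: bool,
                       rng: np.random.Generator | None):
    """Predictions (Tensor) for a set of items, encoding each pathway once."""
    used = np.unique(data.items[item_ids].reshape(-1))
    remap = {p: k for k, p in enumerate(used)}
    sub = {k: v[used] for k, v in data.paths.items()}
    u, _, _ = model.encode_batch(sub, training=training, rng=rng)
    wt_rows = np.array([remap[p] for p in data.items[item_ids, 0]])
    mut_rows = np.array([remap[p] for p in data.items[item_ids, 1]])
    contrib = residue_ddg_core(u[wt_rows], u[mut_rows], model.head)
    m = data.masks[data.sample_mask_idx[item_ids]]
    return (contrib * m.astype(contrib.data.dtype)).sum(axis=-1)


def train(model: IGMIModel, dataset: list[SampleRecord],
          config: TrainConfig = TrainConfig(),
          val_dataset: list[SampleRecord] | None = None
          ) -> tuple[IGMIModel, pd.DataFrame]:
    """Fit the model in place; returns (model, per-epoch history).

    History columns: epoch, loss, lr (plus val_loss when a validation set
    is given; validation uses the original, un-augmented records).
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    model.config = model.config.replace(dropout=config.dropout)
    rng = np.random.default_rng(config.seed)
    data = _prepare(model, dataset, config.augment)
    val_data = (_prepare(model, val_dataset, augment=False)
                if val_dataset else None)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    n_items = len(data.labels)
    history = []
    losses: list[float] = []
    n_samples = len(dataset)
    per_batch = (max(config.batch_size // 2, 1) if config.augment
                 else config.batch_size)
    n_batches = max(1, int(np.ceil(n_samples / per_batch)))
    for epoch in range(1, config.epochs + 1):
        # One permuted copy of the pathway arrays per epoch; batches are
        # then contiguous views.  With augmentation each sample travels
        # with its reverse: the head is antisymmetric by construction, so
        # reverse predictions are exact negations of the forward ones and
        # the augmented loss needs no extra forward passes.
        sample_order = rng.permutation(n_samples)
        rows = np.empty(2 * n_samples, dtype=int)
        rows[0::2] = data.items[sample_order, 0]
        rows[1::2] = data.items[sample_order, 1]
        paths_epoch = {k: v[rows] for k, v in data.paths.items()}
        labels_epoch = data.labels[sample_order]
        masks_epoch = data.masks[data.sample_mask_idx[sample_order]]
        bounds = np.linspace(0, n_samples, n_batches + 1).astype(int)
        epoch_loss = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sub = {k: v[2 * lo:2 * hi] for k, v in paths_epoch.items()}
            u, _, _ = model.encode_batch(sub, training=True, rng=rng,
                                         pair_shared_dropout=True)
            contrib = residue_ddg_core(u[0::2], u[1::2], model.head,
                                       dropout=config.dropout, rng=rng)
            m = masks_epoch[lo:hi].astype(contrib.data.dtype)
            preds = (contrib * m).sum(axis=-1)
            y = labels_epoch[lo:hi].astype(preds.data.dtype)
            if config.augment:
                preds = concat([preds, -preds], axis=0)
                y = np.concatenate([y, -y])
            diff = preds - y
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(y)
        epoch_loss /= n_items
        if not np.isfinite(epoch_loss):
            raise TrainingDiverged(f"loss became {epoch_loss} at epoch {epoch}")
        losses.append(epoch_loss)
        row = {"epoch": epoch, "loss": epoch_loss, "lr": opt.lr}
        if val_data is not None:
            vp = _batch_predictions(model, val_data,
                                    np.arange(len(val_data.labels)), False, None)
            row["val_loss"] = float(np.mean((vp.data - val_data.labels) ** 2))
        history.append(row)
        # plateau rule: at each checkpoint, halve LR if the best loss did not
        # improve within the last `lr_patience` recorded epoch losses
        if epoch % config.lr_check_every == 0 and len(losses) > config.lr_patience:
            recent = min(losses[-config.lr_patience:])
            before = min(losses[:-config.lr_patience])
            if recent >= before:
                opt.lr *= 0.5
    return model, pd.DataFrame(history)


def evaluate(model: IGMIModel, dataset: list[SampleRecord],
             batch_size: int = 64) -> np.ndarray:
    """Predicted ΔΔG for every record (kcal/mol)."""
    data = _prepare(model, dataset, augment=False)
    out = np.empty(len(dataset))
    for start in range(0, len(dataset), batch_size):
        ids = np.arange(start, min(start + batch_size, len(dataset)))
        out[ids] = _batch_predictions(model, data, ids, False, None).data
    return out


# -- hyperparameter search -------------------------------------------------

def default_grid() -> dict[str, list]:
    return {"dropout": [0.0, 0.3, 0.5, 0.7],
            "batch_size": [32, 64, 128],
            "learning_rate": [5e-5, 1e-5, 1e-4]}


def expand_grid(grid: dict[str, list] | None = None,
                base: TrainConfig = TrainConfig()) -> list[TrainConfig]:
    """All grid combinations as TrainConfig objects (4x3x3 = 36 default)."""
    grid = grid or default_grid()
    keys = list(grid)
    combos = itertools.product(*(grid[k] for k in keys))
    return [replace(base, **dict(zip(keys, combo))) for combo in combos]


def grid_search(model_config: ModelConfig,
                train_samples: list[SampleRecord],
                val_samples: list[SampleRecord],
                grid: dict[str, list] | None = None,
                epochs: int = 50,
                seed: int = 0) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive grid search; returns the config with lowest val loss.

    Each candidate trains a freshly initialized model for a reduced number
    of epochs; the full log (config + validation loss) is returned.
    """
    if not val_samples:
        raise ValueError("validation set is empty")
    rows = []
    best: tuple[float, TrainConfig] | None = None
    for cand in expand_grid(grid, TrainConfig(epochs=epochs, seed=seed)):
        model = IGMIModel(model_config, seed=seed)
        _, hist = train(model, train_samples, cand, val_dataset=val_samples)
        val_loss = float(hist["val_loss"].iloc[-1])
        rows.append({"dropout": cand.dropout, "batch_size": cand.batch_size,
                     "learning_rate": cand.learning_rate,
                     "val_loss": val_loss})
        if best is None or val_loss < best[0]:
            best = (val_loss, cand)
    return best[1], pd.DataFrame(rows)


def retrain_full(model_config: ModelConfig,
                 full_dataset: list[SampleRecord],
                 selected_epoch: int,
                 config: TrainConfig = TrainConfig(),
                 seed: int = 0) -> tuple[IGMIModel, pd.DataFrame]:
    """Retrain from scratch on train+val for exactly ``selected_epoch`` epochs."""
    model = IGMIModel(model_config, seed=seed)
    cfg = replace(config, epochs=int(selected_epoch), seed=seed)
    return train(model, full_dataset, cfg)
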