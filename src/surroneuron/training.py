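"""Training loop: loss/optimizer configuration, curriculum staging, early
stopping on validation loss, and partial retraining with frozen feature
layers.

The default optimizer is Adam with Nesterov momentum and global-norm
gradient clipping at 1.  Mean absolute error suffices for passive
(subthreshold) corpora; active corpora use mean squared error to emphasize
the rare action-potential samples.  Learning rates and batch size are
package defaults (1e-3 / 2e-3 for the Adam family / Adamax, batch 256).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from surroneuron.architectures import SurrogateModel
from surroneuron.data import TRAIN, VAL, CurriculumBatches, WindowedDataset
from surroneuron.nn import make_optimizer, get_loss
from surroneuron.nn.layers import Conv1D, Flatten, LSTM, RepeatVector, TakeLast

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    optimizer: str = "adam_nesterov"  # adam | adam_nesterov | adamax
    lr: Optional[float] = None
    clipnorm: float = 1.0
    loss: str = "mse"  # mse for active corpora, mae acceptable for passive
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    curriculum: bool = False
    mix_fraction: float = 0.3
    max_batches_per_epoch: Optional[int] = None
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.clipnorm <= 0:
            raise ValueError("gradient clip norm must be positive")


def early_stop_epoch(val_losses: Sequence[float], patience: int) -> Optional[int]:
    """Index of the epoch at which training stops (the first epoch after
    ``patience`` epochs without improvement), or None if it never stops."""
    best = np.inf
    best_epoch = -1
    for epoch, loss in enumerate(val_losses):
        if loss < best:
            best, best_epoch = loss, epoch
        elif epoch - best_epoch >= patience:
            return epoch
    return None


def _step(net, X, y, loss_fn, optimizer) -> float:
    out = net.forward(X, training=True)
    loss, dy = loss_fn(out, y)
    loss += net.regularization_loss()
    if not np.isfinite(loss):
        raise RuntimeError("training loss diverged (non-finite); aborting")
    net.backward(dy)
    params: Dict[str, np.ndarray] = {}
    grads: Dict[str, np.ndarray] = {}
    for key, p, g in net.trainable_params():
        if g is not None:
            params[key] = p
            grads[key] = g
    optimizer.step(params, grads)
    return loss


def evaluate_loss(model: SurrogateModel, ds: WindowedDataset, loss_name: str,
                  which: int = VAL, batch_size: int = 4096) -> float:
    loss_fn = get_loss(loss_name)
    idx = ds.split_indices(which)
    if len(idx) == 0:
        raise ValueError("dataset has no samples in the requested split")
    total = 0.0
    for start in range(0, len(idx), batch_size):
        X, y = ds.gather(idx[start : start + batch_size])
        out = model.net.forward(X, training=False)
        loss, _ = loss_fn(out, y)
        total += loss * len(X)
    return total / len(idx)


def train(
    model: SurrogateModel,
    dataset: WindowedDataset | Dict[str, WindowedDataset],
    config: TrainingConfig,
) -> Tuple[SurrogateModel, pd.DataFrame]:
    """Fit the model; returns (model, per-epoch history).

    ``dataset`` is either one normalized windowed dataset or, with
    ``config.curriculum``, a dict of stage corpora (resting ->
    subthreshold -> suprathreshold) trained sequentially with replay.
    Early stopping monitors validation loss with the configured patience and
    restores the best weights.  Deterministic under a fixed seed in
    single-threaded execution.
    """
    optimizer = make_optimizer(config.optimizer, config.lr, config.clipnorm)
    loss_fn = get_loss(config.loss)
    history: List[dict] = []

    if config.curriculum:
        if not isinstance(dataset, dict):
            raise ValueError("curriculum training expects a dict of stage datasets")
        plan = CurriculumBatches(
            dataset,
            mix_fraction=config.mix_fraction,
            batch_size=config.batch_size,
            seed=config.seed,
        )
        for stage in plan.stage_names:
            _fit_stage(
                model, plan, stage, optimizer, loss_fn, config, history,
                val_ds=dataset[stage],
            )
        if model.norm is None:
            model.norm = next(iter(dataset.values())).norm
        return model, pd.DataFrame(history)

    ds: WindowedDataset = dataset
    if not ds.normalized:
        logger.warning("training on an unnormalized dataset")
    rng = np.random.default_rng(config.seed)
    train_idx = ds.split_indices(TRAIN)
    best_val = np.inf
    best_weights = None
    best_epoch = -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx) if config.shuffle else train_idx
        n_batches = 0
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            X, y = ds.gather(order[start : start + config.batch_size])
            epoch_loss += _step(model.net, X, y, loss_fn, optimizer)
            n_batches += 1
            if config.max_batches_per_epoch and n_batches >= config.max_batches_per_epoch:
                break
        val = evaluate_loss(model, ds, config.loss)
        history.append(
            {"epoch": epoch, "stage": "all", "train_loss": epoch_loss / max(n_batches, 1),
             "val_loss": val}
        )
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_weights = {k: v.copy() for k, v in model.net.weights_flat().items()}
        elif epoch - best_epoch >= config.patience:
            break
    if best_weights is not None:
        model.net.set_weights(best_weights)
    if model.norm is None:
        model.norm = ds.norm
    return model, pd.DataFrame(history)


def _fit_stage(model, plan, stage, optimizer, loss_fn, config, history, val_ds):
    best_val = np.inf
    best_weights = None
    best_epoch = -1
    for epoch in range(config.max_epochs):
        n_batches = 0
        epoch_loss = 0.0
        for X, y in plan.epoch(stage, epoch_seed=epoch):
            epoch_loss += _step(model.net, X, y, loss_fn, optimizer)
            n_batches += 1
            if config.max_batches_per_epoch and n_batches >= config.max_batches_per_epoch:
                break
        val = evaluate_loss(model, val_ds, config.loss)
        history.append(
            {"epoch": epoch, "stage": stage, "train_loss": epoch_loss / max(n_batches, 1),
             "val_loss": val}
        )
        if val < best_val:
            best_val, best_epoch = val, epoch
            best_weights = {k: v.copy() for k, v in model.net.weights_flat().items()}
        elif epoch - best_epoch >= config.patience:
            break
    if best_weights is not None:
        model.net.set_weights(best_weights)


def head_only_predicate(index: int, layer) -> bool:
    """Freeze predicate selecting everything below the fully connected head.

    Layers up to and including the last feature layer (convolution, LSTM,
    flatten/repeat plumbing) are frozen; the dense head stays trainable.
    """
    return getattr(layer, "_freeze_below_head", False)


def mark_head(net) -> None:
    last_feature = -1
    for i, layer in enumerate(net.layers):
        if isinstance(layer, (Conv1D, LSTM, Flatten, RepeatVector, TakeLast)):
            last_feature = i
    for i, layer in enumerate(net.layers):
        layer._freeze_below_head = i <= last_feature


def partial_retrain(
    model: SurrogateModel,
    new_dataset: WindowedDataset,
    config: TrainingConfig,
    predicate: Optional[Callable] = None,
) -> Tuple[SurrogateModel, pd.DataFrame]:
    """Retrain only the fully connected head on a new corpus (for adapting a
    trained surrogate to an altered biophysical condition).  Frozen weights
    are bit-identical before and after."""
    if predicate is None:
        mark_head(model.net)
        predicate = head_only_predicate
    model.net.freeze(predicate)
    try:
        return train(model, new_dataset, config)
    finally:
        model.net.freeze(lambda i, l: False)
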