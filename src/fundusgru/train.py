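"""Training loop: Adam + binary cross-entropy, plateau learning-rate
decay, early stopping, and best-checkpoint selection on validation loss.

The schedule mirrors a common clinical-imaging recipe: Adam starting at
1e-4; if the validation loss has not improved for ``lr_patience`` epochs
the learning rate is multiplied by ``lr_factor`` (default two-thirds);
training stops after ``early_stop_patience`` epochs without improvement;
the returned model is the checkpoint with the minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyCohortError
from .nn.autograd import Tensor, bce_with_logits
from .nn.optim import Adam
from .model import PrognosticModel

__all__ = ["TrainSchedule", "SequenceDataset", "train"]


@dataclass(frozen=True)
class TrainSchedule:
    initial_lr: float = 1e-4
    lr_patience: int = 10
    lr_factor: float = 2.0 / 3.0
    early_stop_patience: int = 25
    max_epochs: int = 100
    min_epochs: int = 1            # no early stop before this many epochs
    batch_size: int = 16
    class_weight: float | None = None  # optional positive-class weight
    prior_bias_init: bool = True   # start the head at the train-set log-odds
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.lr_factor < 1.0):
            raise ConfigError("lr_factor must lie in (0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ConfigError("patience values must be >= 1")
        if self.initial_lr <= 0:
            raise ConfigError("initial_lr must be > 0")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass
class SequenceDataset:
    """Preprocessed tensors for a set of eyes.

    images: (N, T, side, side, 3) in [0,1]; times: (N, T) months;
    prediction_time: (N,); labels: (N,) binary.
    """

    images: np.ndarray
    times: np.ndarray
    prediction_time: np.ndarray
    labels: np.ndarray
    eye_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "SequenceDataset":
        ids = [self.eye_ids[i] for i in idx] if self.eye_ids else []
        return SequenceDataset(self.images[idx], self.times[idx],
                               self.prediction_time[idx], self.labels[idx], ids)


def _epoch_loss(model: PrognosticModel, ds: SequenceDataset,
                batch: int) -> float:
    """Mean BCE over a dataset, forward only."""
    total, n = 0.0, 0
    for lo in range(0, len(ds), batch):
        sl = slice(lo, min(lo + batch, len(ds)))
        z = model.logits(ds.images[sl], ds.times[sl], ds.prediction_time[sl])
        loss = bce_with_logits(z, ds.labels[sl])
        total += float(loss.data) * (sl.stop - sl.start)
        n += sl.stop - sl.start
    return total / n


def train(model: PrognosticModel, train_set: SequenceDataset,
          val_set: SequenceDataset, schedule: TrainSchedule,
          verbose: bool = False):
    """Fit the model; returns ``(model, history)``.

    The model is left holding the parameters of the epoch with minimum
    validation loss.  ``history`` is a dict of per-epoch lists:
    ``train_loss``, ``val_loss``, ``lr``.  Learning-rate reductions
    multiply by exactly ``lr_factor`` after ``lr_patience`` epochs
    without validation improvement (zero min-delta).
    """
    schedule.validate()
    if len(train_set) == 0:
        raise EmptyCohortError("training set is empty")
    if len(val_set) == 0:
        raise EmptyCohortError("validation set is empty")
    rng = np.random.default_rng(schedule.seed)
    if schedule.prior_bias_init and getattr(model, "head", None) is not None:
        # start the output at the empirical event rate so early epochs are
        # spent on discrimination rather than on matching the prior
        p = float(np.clip(train_set.labels.mean(), 1e-3, 1 - 1e-3))
        model.head.b.data[:] = np.log(p / (1 - p))
    opt = Adam(model.parameters(), lr=schedule.initial_lr)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = model.get_state()
    stale = 0
    pos_w = schedule.class_weight
    for epoch in range(schedule.max_epochs):
        idx = rng.permutation(len(train_set))
        run_loss, seen = 0.0, 0
        model.set_training(True)
        for lo in range(0, len(idx), schedule.batch_size):
            sub = train_set.subset(idx[lo:lo + schedule.batch_size])
            model.zero_grad()
            z = model.logits(sub.images, sub.times, sub.prediction_time)
            if pos_w is not None:
                w = np.where(sub.labels == 1, pos_w, 1.0).astype(np.float32)
                loss = _weighted_bce(z, sub.labels, w)
            else:
                loss = bce_with_logits(z, sub.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            run_loss += float(loss.data) * len(sub)
            seen += len(sub)
        model.set_training(False)
        val_loss = _epoch_loss(model, val_set, schedule.batch_size)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(run_loss / seen)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch:3d}  train {run_loss / seen:.4f}  "
                  f"val {val_loss:.4f}  lr {opt.lr:.2e}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale % schedule.lr_patience == 0:
                opt.lr *= schedule.lr_factor
            if (stale >= schedule.early_stop_patience
                    and epoch + 1 >= schedule.min_epochs):
                break
    model.set_state(best_state)
    model.set_training(False)
    return model, history


def _weighted_bce(logits: Tensor, targets, weights) -> Tensor:
    z = logits.data
    y = np.asarray(targets, dtype=np.float32).reshape(z.shape)
    w = np.asarray(weights, dtype=np.float32).reshape(z.shape)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    denom = w.sum()

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accum(g * w * (p - y) / denom)

    return logits._make(np.float32((per * w).sum() / denom), (logits,), backward)
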