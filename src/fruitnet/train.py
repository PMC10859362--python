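"""Cross-entropy training with Adam, plus evaluation and checkpointing.

Training follows the original recipe: Adam with library-default
hyperparameters, categorical cross-entropy, a fixed number of epochs with
no early stopping, and per-epoch reshuffling under a seed derived from the
run seed.  Because the whole stack is single-threaded NumPy, identical
seeds reproduce identical loss traces bit for bit.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import no_grad
from .data import LabeledImageSet
from .metrics import ConfusionMatrix, MetricsReport, confusion_matrix, metric_report
from .model import ArchitectureTable, ModelHandle, build_model
from .nn import Adam, cross_entropy_logits

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "TrainResult", "train", "evaluate",
           "recalibrate_batchnorm", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3   # Adam default; remaining moments at defaults
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(self)):
                w.writerow([i + 1, self.train_loss[i], self.train_acc[i],
                            self.val_loss[i], self.val_acc[i]])


@dataclass
class TrainResult:
    history: TrainHistory
    model: ModelHandle            # final-epoch model (mutated in place)
    best_state: dict              # parameters at the best validation accuracy
    best_epoch: int
    best_val_acc: float


def _as_batch(ds, input_size: int):
    if isinstance(ds, LabeledImageSet):
        if len(ds) == 0:
            return (np.zeros((0, input_size, input_size, 3), np.float32),
                    np.zeros(0, np.int64))
        return ds.preprocessed(input_size)
    X, y = ds
    return np.asarray(X, dtype=np.float32), np.asarray(y, dtype=np.int64)


def _eval_pass(model: ModelHandle, X, y, batch_size: int):
    losses, correct = 0.0, 0
    with no_grad():
        for i in range(0, len(X), batch_size):
            xb, yb = X[i : i + batch_size], y[i : i + batch_size]
            logits = model.logits(xb, training=False)
            losses += float(cross_entropy_logits(logits, yb).data) * len(xb)
            correct += int((np.argmax(logits.data, axis=1) == yb).sum())
    return losses / len(X), correct / len(X)


def train(model: ModelHandle, train_set, val_set, cfg: TrainConfig,
          optimizer: Adam | None = None) -> TrainResult:
    """Run ``cfg.epochs`` epochs to completion (no early stopping).

    Training accuracy is accumulated from the training passes themselves;
    validation is a separate inference pass per epoch.  Pass ``optimizer``
    to continue a previous run with its Adam moments intact.
    """
    size = model.table.input_size[0]
    Xtr, ytr = _as_batch(train_set, size)
    Xva, yva = _as_batch(val_set, size)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("empty training or validation set")
    K = model.table.num_classes
    for name, y in (("train", ytr), ("val", yva)):
        if y.min() < 0 or y.max() >= K:
            raise ValueError(
                f"{name} labels span [{y.min()}, {y.max()}] but the model has {K} classes"
            )

    opt = optimizer or Adam(model.network.parameters(), lr=cfg.learning_rate)
    hist = TrainHistory()
    best_state, best_epoch, best_acc = model.network.state_dict(), 0, -1.0

    for epoch in range(1, cfg.epochs + 1):
        rng = np.random.default_rng([cfg.seed, epoch])  # per-epoch derived seed
        order = rng.permutation(len(Xtr))
        run_loss, run_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.logits(xb, training=True)
            loss = cross_entropy_logits(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            run_loss += float(loss.data) * len(idx)
            run_correct += int((np.argmax(logits.data, axis=1) == yb).sum())
        tr_loss, tr_acc = run_loss / len(Xtr), run_correct / len(Xtr)
        va_loss, va_acc = _eval_pass(model, Xva, yva, cfg.batch_size)
        hist.train_loss.append(tr_loss)
        hist.train_acc.append(tr_acc)
        hist.val_loss.append(va_loss)
        hist.val_acc.append(va_acc)
        if va_acc > best_acc:
            best_acc, best_epoch = va_acc, epoch
            best_state = model.network.state_dict()
        log.info("epoch %d/%d loss=%.4f acc=%.4f val_loss=%.4f val_acc=%.4f",
                 epoch, cfg.epochs, tr_loss, tr_acc, va_loss, va_acc)
    return TrainResult(history=hist, model=model, best_state=best_state,
                       best_epoch=best_epoch, best_val_acc=best_acc)


def recalibrate_batchnorm(model: ModelHandle, data, batch_size: int = 32) -> None:
    """Replace BN running statistics by dataset statistics (one forward pass).

    Short runs leave the exponential running averages far from the data's
    real activation moments; a single cumulative-average pass fixes
    inference-mode behavior after fixture-scale training.
    """
    from .nn import BatchNorm2d

    X, _ = _as_batch(data, model.table.input_size[0])
    bns = [m for m in model.network.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    try:
        with no_grad():
            for t, i in enumerate(range(0, len(X), batch_size)):
                for bn in bns:
                    bn.momentum = t / (t + 1.0)  # cumulative mean of batch stats
                model.logits(X[i : i + batch_size], training=True)
    finally:
        for bn, mom in zip(bns, saved):
            bn.momentum = mom


def evaluate(model: ModelHandle, test_set, batch_size: int = 32
             ) -> tuple[MetricsReport, ConfusionMatrix]:
    """Argmax predictions over the test set, reduced by the metrics module."""
    size = model.table.input_size[0]
    X, y = _as_batch(test_set, size)
    if len(X) == 0:
        raise ValueError("empty test set")
    K = model.table.num_classes
    if y.min() < 0 or y.max() >= K:
        raise ValueError(
            f"test labels span [{y.min()}, {y.max()}] but the model has {K} classes"
        )
    preds = np.concatenate([
        model.predict(X[i : i + batch_size]) for i in range(0, len(X), batch_size)
    ])
    cm = confusion_matrix(y, preds, K)
    return metric_report(cm), cm


def save_checkpoint(model: ModelHandle, path, state: dict | None = None) -> None:
    """Write parameters (+ BN statistics) and the architecture table to .npz."""
    payload = {f"state/{k}": v for k, v in (state or model.network.state_dict()).items()}
    payload["__architecture__"] = np.frombuffer(
        model.table.to_json().encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> ModelHandle:
    with np.load(path) as z:
        table = ArchitectureTable.from_json(bytes(z["__architecture__"]).decode("utf-8"))
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    model = build_model(table, seed=0)
    model.network.load_state_dict(state)
    return model
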