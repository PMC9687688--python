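"""Dataset splitting, training loop and confusion-matrix evaluation.

Training follows a fixed protocol: mini-batches of 8 images, a bounded
number of steps per epoch, and *early stop by valid loss* — training halts
the first epoch whose validation loss J = (1/N) sum_i L(y_hat_i, y_i)
(mean binary cross-entropy over the validation set) falls below a fixed
threshold (default 0.4).  This rule halts on success rather than on
stagnation; a conventional patience-based stop is available via
``TrainConfig.patience``.

Evaluation treats Parkinson's disease as the positive class throughout:
sensitivity is the fraction of PD images detected, specificity the
fraction of healthy images detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.model import Adam, Sequential, predict_proba, softmax_cross_entropy
from .tappy_io import HEALTHY, PARKINSON

__all__ = [
    "ImageDataset",
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "train",
    "evaluate",
]

#: Class-index convention everywhere in the package: 0 = healthy, 1 = PD.
CLASS_INDEX = {HEALTHY: 0, PARKINSON: 1}


@dataclass
class ImageDataset:
    """Labeled RGB image set held in memory (N, H, W, 3) uint8."""

    images: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be (N, H, W, 3)")
        n = self.images.shape[0]
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.provenance is None:
            self.provenance = np.asarray(["real"] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            provenance=self.provenance[idx],
        )

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_batch(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, 3, H, W) float32 in [0, 1] plus integer class targets."""
        x = self.images.astype(np.float32).transpose(0, 3, 1, 2) / 255.0
        y = np.array([CLASS_INDEX[str(l)] for l in self.labels], dtype=np.int64)
        return x, y


@dataclass
class TrainConfig:
    """Training protocol parameters."""

    batch_size: int = 8
    steps_per_epoch: int = 20
    max_epochs: int = 35
    early_stop_valid_loss: float = 0.4
    learning_rate: float = 1e-3
    image_size: tuple[int, int, int] = (240, 240, 3)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    patience: int | None = None  # alternative stagnation-based stop

    def __post_init__(self) -> None:
        f = self.split_fractions
        if len(f) != 3 or any(v <= 0 for v in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


def split_dataset(
    dataset: ImageDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[ImageDataset, ImageDataset, ImageDataset]:
    """Stratified train/test/valid partition, reproducible given the seed.

    Every image is assigned to exactly one split; within each class the
    train and test counts are rounded from the fractions and the remainder
    goes to the validation split.
    """
    if len(fractions) != 3 or any(v <= 0 for v in fractions) or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    labels = dataset.labels.astype(str)
    tr_idx, te_idx, va_idx = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(fractions[0] * n))
        n_te = int(round(fractions[1] * n))
        if n_tr < 1 or n_te < 1 or n - n_tr - n_te < 1:
            raise ValueError(
                f"class {cls!r} has {n} images; fractions {fractions} leave an empty split"
            )
        tr_idx.append(idx[:n_tr])
        te_idx.append(idx[n_tr : n_tr + n_te])
        va_idx.append(idx[n_tr + n_te :])
    return (
        dataset.subset(np.concatenate(tr_idx)),
        dataset.subset(np.concatenate(te_idx)),
        dataset.subset(np.concatenate(va_idx)),
    )


def _dataset_loss_acc(model: Sequential, x: np.ndarray, y: np.ndarray, batch: int = 32):
    losses, hits, n = 0.0, 0, x.shape[0]
    for lo in range(0, n, batch):
        xb, yb = x[lo : lo + batch], y[lo : lo + batch]
        proba = predict_proba(model, xb)
        logp = np.log(np.clip(proba, 1e-12, 1.0))
        losses += -float(logp[np.arange(len(yb)), yb].sum())
        hits += int((proba.argmax(axis=1) == yb).sum())
    return losses / n, hits / n


def train(
    model: Sequential,
    train_set: ImageDataset,
    valid_set: ImageDataset,
    config: TrainConfig | None = None,
) -> tuple[Sequential, pd.DataFrame]:
    """Train in place; returns the model and a per-epoch history table.

    History columns: epoch, train_loss (mean over the epoch's steps),
    valid_loss, train_accuracy, valid_accuracy.  Stops the first epoch
    whose validation loss falls below ``early_stop_valid_loss`` (or by
    patience on the validation loss if ``patience`` is set), never
    exceeding ``max_epochs``.
    """
    config = config or TrainConfig()
    if len(train_set) == 0 or len(valid_set) == 0:
        raise ValueError("train and valid sets must be non-empty")
    x_tr, y_tr = train_set.to_batch()
    x_va, y_va = valid_set.to_batch()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.learning_rate)
    history: list[dict] = []
    best_valid = np.inf
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        epoch_losses = []
        for _ in range(config.steps_per_epoch):
            idx = rng.choice(len(x_tr), size=min(config.batch_size, len(x_tr)), replace=False)
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        valid_loss, valid_acc = _dataset_loss_acc(model, x_va, y_va)
        _, train_acc = _dataset_loss_acc(model, x_tr, y_tr)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "valid_loss": valid_loss,
                "train_accuracy": train_acc,
                "valid_accuracy": valid_acc,
            }
        )
        if config.patience is None:
            if valid_loss < config.early_stop_valid_loss:
                break
        else:
            if valid_loss < best_valid - 1e-12:
                best_valid, stale = valid_loss, 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    return model, pd.DataFrame(history)


@dataclass
class EvalReport:
    """Confusion matrix (PD positive) and derived metrics.

    ``undefined_metrics`` lists metrics whose denominator was zero; such
    metrics are reported as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    valid_loss: float
    per_class: dict[str, dict[str, float]]
    undefined_metrics: list[str] = field(default_factory=list)

    @property
    def confusion(self) -> np.ndarray:
        """2x2 matrix [[TP, FN], [FP, TN]], rows = true PD / true healthy."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=int)

    @property
    def sensitivity(self) -> float:
        return self.recall

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=["true_parkinson", "true_healthy"],
            columns=["pred_parkinson", "pred_healthy"],
        )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int, valid_loss: float = 0.0) -> EvalReport:
    """Derive the standard binary metrics from confusion counts."""
    flags: list[str] = []
    total = tp + fp + fn + tn
    accuracy = _safe_div(tp + tn, total, "accuracy", flags)
    precision = _safe_div(tp, tp + fp, "precision", flags)
    recall = _safe_div(tp, tp + fn, "recall", flags)
    specificity = _safe_div(tn, tn + fp, "specificity", flags)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", flags)
    healthy_precision = _safe_div(tn, tn + fn, "healthy_precision", flags)
    per_class = {
        PARKINSON: {"precision": precision, "recall": recall, "support": tp + fn},
        HEALTHY: {"precision": healthy_precision, "recall": specificity, "support": tn + fp},
    }
    return EvalReport(
        tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn),
        accuracy=accuracy, precision=precision, recall=recall,
        specificity=specificity, f1=f1, valid_loss=valid_loss,
        per_class=per_class, undefined_metrics=flags,
    )


def evaluate(model: Sequential, test_set: ImageDataset) -> EvalReport:
    """Argmax predictions over a labeled image set -> :class:`EvalReport`."""
    if len(test_set) == 0:
        raise ValueError("test set must be non-empty")
    x, y = test_set.to_batch()
    preds = np.empty_like(y)
    losses = 0.0
    for lo in range(0, len(y), 32):
        proba = predict_proba(model, x[lo : lo + 32])
        preds[lo : lo + 32] = proba.argmax(axis=1)
        logp = np.log(np.clip(proba, 1e-12, 1.0))
        losses += -float(logp[np.arange(len(proba)), y[lo : lo + 32]].sum())
    pos = CLASS_INDEX[PARKINSON]
    tp = int(np.sum((y == pos) & (preds == pos)))
    fn = int(np.sum((y == pos) & (preds != pos)))
    fp = int(np.sum((y != pos) & (preds == pos)))
    tn = int(np.sum((y != pos) & (preds != pos)))
    return metrics_from_confusion(tp, fp, fn, tn, valid_loss=losses / len(y))
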