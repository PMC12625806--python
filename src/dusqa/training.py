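"""Balanced-batch SGD training and recording-stratified cross-validation.

Class imbalance is handled by random oversampling into balanced mini-batches
of 128: every batch holds an (almost) equal share of each class -
(26, 26, 26, 25, 25) with the extra slots rotating - where the largest class
cycles through a seeded shuffle and smaller classes are drawn with
replacement.  One epoch shows each majority-class item roughly once.

Cross-validation folds are recording-disjoint: each recording is summarised
by the mode of its window classes and recordings are dealt round-robin into
k folds per mode class, so every fold sees all classes and no recording ever
straddles a train/test boundary.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import CLASS_NAMES, MODEL_CLASSES, QualityClass, QualityWindow
from .evaluation import ConfusionMatrix5, MetricsReport, confusion, metrics_report
from .layers import SGD, cross_entropy
from .network import ModelConfig, QualityModel, build_model

logger = logging.getLogger(__name__)

N_CLASSES = 5


@dataclass(frozen=True)
class Dataset:
    """Scalogram stack with aligned labels and recording ids."""

    scalograms: np.ndarray  # (n, 250, 40)
    labels: np.ndarray  # (n,) int in 0..4
    recording_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.scalograms, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        if len(x) == 0 or len(x) != len(y) or len(y) != len(self.recording_ids):
            raise ValueError("scalograms, labels and recording_ids must align, non-empty")
        if y.min() < 0 or y.max() >= N_CLASSES:
            raise ValueError("labels must lie in 0..4")
        object.__setattr__(self, "scalograms", x)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "recording_ids", tuple(self.recording_ids))

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "Dataset":
        idx = np.flatnonzero(mask)
        return Dataset(
            self.scalograms[idx],
            self.labels[idx],
            tuple(self.recording_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Recording -> fold map for k-fold cross-validation."""

    k: int
    fold_of: dict[str, int]
    seed: int

    def recordings_in(self, fold: int) -> set[str]:
        return {r for r, f in self.fold_of.items() if f == fold}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < N_CLASSES:
            raise ValueError("batch size must be at least the number of classes")


def mode_class(windows: list[QualityWindow] | list[QualityClass] | np.ndarray) -> QualityClass:
    """Most frequent window class; ties break to the lowest class index."""
    if len(windows) == 0:
        raise ValueError("mode_class of an empty collection")
    labels = [
        w.label if isinstance(w, QualityWindow) else QualityClass(int(w))
        for w in windows
    ]
    counts = Counter(labels)
    best = max(counts.items(), key=lambda kv: (kv[1], -int(kv[0])))
    return best[0]


def assign_folds(
    recording_modes: dict[str, QualityClass], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Deal recordings into k folds, stratified by per-recording mode class.

    Within each mode class the recordings are shuffled (seeded) and dealt
    round-robin onto a fold cursor that carries across classes, so per-class
    fold counts differ by at most one and fold sizes stay balanced.
    """
    if len(recording_modes) < k:
        raise ValueError(f"need at least {k} recordings for {k} folds")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    cursor = 0
    for cls in MODEL_CLASSES:
        members = sorted(r for r, m in recording_modes.items() if m == cls)
        rng.shuffle(members)
        for rid in members:
            fold_of[rid] = cursor % k
            cursor += 1
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def balanced_batches(
    labels: np.ndarray, batch_size: int = 128, seed: int = 0, n_batches: int | None = None
):
    """Yield index arrays for balanced oversampled mini-batches.

    Per-batch class counts differ by at most one (a permutation of
    (26, 26, 26, 25, 25) at batch size 128), with the classes receiving the
    extra slot rotating between batches.  The majority class is cycled
    through a seeded shuffle; all other classes are sampled with
    replacement.  The default epoch length is
    ceil(majority_count * 5 / batch_size).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    per_class = {c: np.flatnonzero(labels == int(c)) for c in MODEL_CLASSES}
    for c, idx in per_class.items():
        if len(idx) == 0:
            raise ValueError(f"class {CLASS_NAMES[int(c)]} has no training items")
    majority = max(per_class, key=lambda c: len(per_class[c]))
    if n_batches is None:
        n_batches = math.ceil(len(per_class[majority]) * N_CLASSES / batch_size)

    maj_pool = rng.permutation(per_class[majority])
    maj_pos = 0
    base, rem = divmod(batch_size, N_CLASSES)
    for b in range(n_batches):
        quotas = np.full(N_CLASSES, base, dtype=int)
        for j in range(rem):
            quotas[(b + j) % N_CLASSES] += 1
        batch = []
        for c in MODEL_CLASSES:
            q = quotas[int(c)]
            if c == majority:
                take = []
                while q > 0:
                    if maj_pos == len(maj_pool):
                        maj_pool = rng.permutation(per_class[majority])
                        maj_pos = 0
                    grab = min(q, len(maj_pool) - maj_pos)
                    take.append(maj_pool[maj_pos : maj_pos + grab])
                    maj_pos += grab
                    q -= grab
                batch.append(np.concatenate(take))
            else:
                batch.append(rng.choice(per_class[c], size=q, replace=True))
        idx = np.concatenate(batch)
        rng.shuffle(idx)
        yield idx


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _eval_loss(model: QualityModel, x: np.ndarray, y: np.ndarray, chunk: int = 256) -> float:
    total, n = 0.0, len(y)
    for i in range(0, n, chunk):
        logits = model.forward(x[i : i + chunk], train=False)
        loss, _ = cross_entropy(logits, y[i : i + chunk])
        total += loss * len(y[i : i + chunk])
    return total / n


def predict_labels(model: QualityModel, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(x), chunk):
        out.append(model.predict_proba(x[i : i + chunk]).argmax(axis=1))
    return np.concatenate(out)


def train_fold(
    model: QualityModel,
    train: Dataset,
    val: Dataset,
    cfg: TrainConfig,
) -> TrainHistory:
    """Fit with categorical cross-entropy + momentum SGD on balanced batches.

    Early-stops when validation loss has not improved for ``patience``
    epochs and restores the best-epoch weights in place.
    """
    if set(train.recording_ids) & set(val.recording_ids):
        raise ValueError("train and validation sets share recordings")
    opt = SGD(model.layers, lr=cfg.learning_rate, momentum=cfg.momentum)
    history = TrainHistory()
    best_loss, best_weights, stale = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        epoch_loss, seen = 0.0, 0
        batches = balanced_batches(
            train.labels, cfg.batch_size, seed=cfg.seed * 10007 + epoch
        )
        for idx in batches:
            logits = model.forward(train.scalograms[idx], train=True)
            loss, dlogits = cross_entropy(logits, train.labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}"
                )
            opt.zero_grads()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        vloss = _eval_loss(model, val.scalograms, val.labels)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(vloss)
        logger.info("epoch %d: train %.4f val %.4f", epoch, epoch_loss / seen, vloss)
        if vloss < best_loss - 1e-6:
            best_loss, best_weights, stale = vloss, model.get_weights(), 0
            history.best_epoch = epoch
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def cross_validate(
    dataset: Dataset,
    folds: FoldAssignment,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[list[MetricsReport], ConfusionMatrix5]:
    """Train/evaluate one model per fold; returns per-fold reports and the
    cumulative confusion matrix over all held-out windows."""
    ids = np.asarray(dataset.recording_ids)
    missing = set(ids) - set(folds.fold_of)
    if missing:
        raise ValueError(f"recordings without fold assignment: {sorted(missing)[:3]}")
    reports = []
    cumulative = ConfusionMatrix5(np.zeros((5, 5), dtype=np.int64))
    for fold in range(folds.k):
        test_recs = folds.recordings_in(fold)
        # early stopping watches a held-out training fold, never the test fold
        val_recs = folds.recordings_in((fold + 1) % folds.k)
        test_mask = np.isin(ids, sorted(test_recs))
        val_mask = np.isin(ids, sorted(val_recs))
        test = dataset.subset(test_mask)
        val = dataset.subset(val_mask)
        train = dataset.subset(~(test_mask | val_mask))
        assert not (set(train.recording_ids) & set(test.recording_ids))
        model = build_model(replace(model_cfg, seed=model_cfg.seed * 1009 + fold))
        fold_cfg = replace(train_cfg, seed=train_cfg.seed * 1013 + fold)
        train_fold(model, train, val, fold_cfg)
        y_pred = predict_labels(model, test.scalograms)
        cm = confusion(test.labels, y_pred)
        reports.append(metrics_report(cm))
        cumulative = cumulative + cm
        logger.info("fold %d: micro F1 %.2f%%", fold, reports[-1].micro_f1)
    return reports, cumulative
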