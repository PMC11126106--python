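"""Training loop, cross-validation, test-time crop averaging and metrics.

The positive class throughout is *malignant*: TP counts malignant blocks
predicted malignant, TN benign predicted benign.  Reported metrics are
percentages rounded to two decimals (half away from zero):

    ACC = (TP+TN) / (TP+TN+FP+FN)        SEN = TP / (TP+FN)
    PRE = TP / (TP+FP)                   F1  = 2*PRE*SEN / (PRE+SEN)
    Type-I error = FP / (FP+TN)          (benign misclassified malignant)

F1 is computed from the two-decimal SEN and PRE percentages, matching the
precision at which the intermediate metrics are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from thyrospec import nn
from thyrospec.blockset import Block, BlockDataset, class_weights
from thyrospec.errors import LeakageError
from thyrospec.v3dnet import BlockClassifier, PredictionRecord


@dataclass
class TrainConfig:
    """SGD training hyperparameters (defaults follow the full-scale recipe)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 150
    momentum: float = 0.0
    lr_decay: float = 1.0          # multiplicative per-epoch decay
    clip_norm: float | None = None  # global gradient-norm clip
    class_weighting: bool = True
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate >= 0, batch_size >= 1, epochs >= 1")


@dataclass
class ConfusionCounts:
    """Two-class confusion counts; positive class = malignant."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def _round2_via3(x: float) -> float:
    """Round half-away to three decimals, then truncate to two.

    The published Type-I error tables follow this display convention (it is
    the only deterministic two-decimal rule consistent with every printed
    value); the other metric tables use plain half-away rounding.
    """
    d3 = Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                          rounding=ROUND_HALF_UP)
    return float(d3.quantize(Decimal("0.01"), rounding="ROUND_DOWN"))


@dataclass
class MetricsReport:
    """ACC/SEN/PRE/F1/Type-I percentages; undefined metrics are None."""

    acc: float | None
    sen: float | None
    pre: float | None
    f1: float | None
    type1: float | None

    def as_dict(self) -> dict:
        return {"ACC": self.acc, "SEN": self.sen, "PRE": self.pre,
                "F1": self.f1, "TypeI": self.type1}


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the percentage metrics from confusion counts.

    A metric whose denominator is zero is returned as None (flagged
    undefined) rather than silently zero.
    """
    if c.total == 0:
        raise ValueError("no evaluated blocks")
    acc = _round2(100.0 * (c.tp + c.tn) / c.total)
    sen = _round2(100.0 * c.tp / (c.tp + c.fn)) if c.tp + c.fn else None
    pre = _round2(100.0 * c.tp / (c.tp + c.fp)) if c.tp + c.fp else None
    if sen is not None and pre is not None and (sen + pre) > 0:
        f1 = _round2(2.0 * pre * sen / (pre + sen))
    else:
        f1 = None
    type1 = _round2_via3(100.0 * c.fp / (c.fp + c.tn)) if c.fp + c.tn else None
    return MetricsReport(acc=acc, sen=sen, pre=pre, f1=f1, type1=type1)


def confusion(preds: list[PredictionRecord] | list[int],
              truths: list[int] | np.ndarray) -> ConfusionCounts:
    """Tally confusion counts from predictions and true labels (malignant=1)."""
    pred_labels = [p.predicted if isinstance(p, PredictionRecord) else int(p)
                   for p in preds]
    truths = [int(t) for t in truths]
    if len(pred_labels) != len(truths):
        raise ValueError(f"{len(pred_labels)} predictions vs {len(truths)} truths")
    tp = sum(1 for p, t in zip(pred_labels, truths) if p == 1 and t == 1)
    fn = sum(1 for p, t in zip(pred_labels, truths) if p == 0 and t == 1)
    fp = sum(1 for p, t in zip(pred_labels, truths) if p == 1 and t == 0)
    tn = sum(1 for p, t in zip(pred_labels, truths) if p == 0 and t == 0)
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def predict_blocks(model: BlockClassifier, blocks: list[Block],
                   batch_size: int = 64) -> list[PredictionRecord]:
    """Deterministic, order-preserving batch inference over a block list."""
    records: list[PredictionRecord] = []
    for start in range(0, len(blocks), batch_size):
        chunk = blocks[start:start + batch_size]
        x = np.stack([b.data for b in chunk]).astype(np.float32)
        probs = model.predict_proba(x)
        for b, p in zip(chunk, probs):
            records.append(PredictionRecord(prob=p, predicted=int(np.argmax(p)),
                                            case_id=b.case_id, origin=b.origin))
    return records


def ordered_crop_predict(model: BlockClassifier, region: np.ndarray,
                         size: int, stride: int | None = None
                         ) -> PredictionRecord:
    """Classify a region by averaging softmax outputs over ordered crops.

    Crops are enumerated row-major on the stride grid; their probability
    vectors are averaged and the argmax of the mean is the decision.
    """
    region = np.asarray(region, dtype=np.float32)
    rows, cols = region.shape[:2]
    if stride is None:
        stride = size
    if size > rows or size > cols:
        raise ValueError(f"region {(rows, cols)} smaller than crop size {size}")
    crops = [region[r:r + size, c:c + size]
             for r in range(0, rows - size + 1, stride)
             for c in range(0, cols - size + 1, stride)]
    probs = model.predict_proba(np.stack(crops))
    mean = probs.mean(axis=0)
    return PredictionRecord(prob=mean, predicted=int(np.argmax(mean)))


def train(model: BlockClassifier, train_set: BlockDataset,
          val_set: BlockDataset | None, cfg: TrainConfig) -> dict:
    """Train with class-weighted cross-entropy SGD; returns the history.

    Hard-fails if any case id appears in both the training and validation
    sets (patient-level leakage).  Shuffles each epoch with a seeded
    generator; history records per-epoch mean train loss, train accuracy and
    validation accuracy.  Training always runs the full epoch budget (no
    early stopping); alongside the final parameters, the checkpoint with the
    best validation accuracy is kept in ``model.best_state`` (with its epoch
    in ``history["best_val_epoch"]``) for model selection.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if val_set is not None and len(val_set) > 0:
        overlap = train_set.case_ids & val_set.case_ids
        if overlap:
            raise LeakageError(f"cases in both train and val: {sorted(overlap)}")
    x_train, y_train = train_set.stacked()
    if cfg.class_weighting and min(train_set.class_counts) > 0:
        cw = class_weights(train_set.class_counts)
    else:
        cw = np.ones(2)
    opt = nn.SGD(model.net, lr=cfg.learning_rate, momentum=cfg.momentum,
                 clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_val, best_epoch, best_state = -1.0, -1, None
    n = len(y_train)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.logits(x_train[idx], train=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, y_train[idx], cw)
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == y_train[idx]).sum())
        opt.lr *= cfg.lr_decay
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / n)
        if val_set is not None and len(val_set) > 0:
            va = evaluate_accuracy(model, val_set)
            history["val_acc"].append(va)
            if va > best_val:
                best_val = va
                best_epoch = _epoch
                best_state = {k: v.copy()
                              for k, v in model.net.state_dict().items()}
        else:
            history["val_acc"].append(float("nan"))
    model.final_state = model.net.state_dict()
    model.best_state = best_state if best_state is not None \
        else model.final_state
    history["best_val_epoch"] = best_epoch
    return history


def evaluate_accuracy(model: BlockClassifier, dataset: BlockDataset,
                      batch_size: int = 64) -> float:
    """Plain block accuracy of a model on a dataset."""
    x, y = dataset.stacked()
    hits = 0
    for start in range(0, len(y), batch_size):
        probs = model.predict_proba(x[start:start + batch_size])
        hits += int((probs.argmax(axis=1) == y[start:start + batch_size]).sum())
    return hits / len(y)


def evaluate(model: BlockClassifier, dataset: BlockDataset) -> tuple[ConfusionCounts, MetricsReport]:
    preds = predict_blocks(model, dataset.blocks)
    truths = [b.label for b in dataset.blocks]
    c = confusion(preds, truths)
    return c, metrics(c)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics with mean and standard deviation per metric."""

    folds: list[MetricsReport]
    fold_test_ids: list[list[str]]
    k: int
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = ("ACC", "SEN", "PRE", "F1", "TypeI")
        for key in keys:
            vals = [m.as_dict()[key] for m in self.folds
                    if m.as_dict()[key] is not None]
            if vals:
                self.mean[key] = float(np.mean(vals))
                self.std[key] = float(np.std(vals))


def _stratified_folds(cases, k: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for case in cases:
        strata.setdefault(case.diagnosis, []).append(case.case_id)
    folds: list[list[str]] = [[] for _ in range(k)]
    for diag in sorted(strata):
        ids = sorted(strata[diag])
        rng.shuffle(ids)
        for i, cid in enumerate(ids):
            folds[i % k].append(cid)
    return folds


def kfold_cv(cases, model_builder, cfg: TrainConfig, prepare,
             k: int = 10, seed: int = 0) -> CVResult:
    """Case-level stratified k-fold cross-validation.

    ``prepare(train_cases, test_cases)`` must return a
    ``(train_set, test_set)`` pair of block datasets (fitting any
    data-driven transforms such as PCA on the training side only);
    ``model_builder(fold_index)`` returns a fresh classifier.
    """
    cases = list(cases)
    if len(cases) < k:
        raise ValueError(f"need >= {k} cases, got {len(cases)}")
    by_id = {c.case_id: c for c in cases}
    folds = _stratified_folds(cases, k, seed)
    reports: list[MetricsReport] = []
    for i, test_ids in enumerate(folds):
        train_cases = [by_id[cid] for cid in sorted(by_id) if cid not in test_ids]
        test_cases = [by_id[cid] for cid in test_ids]
        train_set, test_set = prepare(train_cases, test_cases)
        model = model_builder(i)
        train(model, train_set, None, cfg)
        _, report = evaluate(model, test_set)
        reports.append(report)
    return CVResult(folds=reports, fold_test_ids=folds, k=k)


def blocksize_report(results: dict[int, ConfusionCounts]) -> tuple[list[dict], dict]:
    """Per-block-size metric rows plus per-metric series for plotting."""
    if not results:
        raise ValueError("no entries")
    rows = []
    for size in sorted(results):
        m = metrics(results[size]).as_dict()
        rows.append({"size": size, **m})
    series = {key: [(row["size"], row[key]) for row in rows]
              for key in ("ACC", "SEN", "PRE", "F1", "TypeI")}
    return rows, series
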