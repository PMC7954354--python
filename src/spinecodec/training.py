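"""Training protocol: BCE loss, Adam optimisation, splits, k-fold CV,
and the evaluation loop.

Defaults follow the published protocol: Adam with learning rate 2e-3 and
betas (0.5, 0.999), binary cross-entropy loss, up to 300 epochs, and an
8:1:1 train/validation/test split.  Every source of randomness (data order,
splits, folds) is derived from the seed, so two CPU runs with one seed give
identical loss curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError
from .metrics import BFConfig, MetricsReport, REPORT_FIELDS, evaluate_pair, mean_report
from .models import SegmentationModel, count_parameters
from .nn import functional as F

__all__ = ["TrainSpec", "SplitPlan", "History", "bce_loss", "split_dataset",
           "kfold", "train", "evaluate", "TrainingDivergedError",
           "TABLE_COLUMNS", "reports_table"]

# column order of the published evaluation tables
TABLE_COLUMNS = ["Accuracy", "Sensitivity", "Specificity", "Precision",
                 "Dice Coefficient", "Jaccard", "BF-Score", "Parameters"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 2e-3
    beta1: float = 0.5
    beta2: float = 0.999
    max_epochs: int = 300
    batch_size: int = 4
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigurationError("betas must lie in [0, 1)")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass(frozen=True)
class SplitPlan:
    train: tuple
    val: tuple
    test: tuple
    ratio: tuple = (8, 1, 1)
    seed: int = 0


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    val_metrics: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_jsonl(self, path) -> None:
        """One JSON record per epoch."""
        with open(path, "w") as fh:
            for i, loss in enumerate(self.train_loss):
                record = {"epoch": i + 1, "train_loss": loss}
                if i < len(self.val_metrics):
                    record["val"] = self.val_metrics[i].as_dict()
                fh.write(json.dumps(record) + "\n")


def bce_loss(pred, target):
    """Mean binary cross-entropy.  On autodiff tensors this participates in
    the graph; on plain arrays it returns a float."""
    if isinstance(pred, nn.Tensor):
        return F.bce_loss(pred, target)
    return float(F.bce_loss(nn.Tensor(pred), target).data)


def split_dataset(n: int, ratio=(8, 1, 1), seed: int = 0) -> SplitPlan:
    """Deterministic shuffled partition; remainder indices go to train."""
    parts = tuple(int(r) for r in ratio)
    total = sum(parts)
    if n < total:
        raise ValueError(f"need at least {total} samples for a "
                         f"{':'.join(map(str, parts))} split, got {n}")
    n_val = n * parts[1] // total
    n_test = n * parts[2] // total
    perm = np.random.default_rng(seed).permutation(n)
    n_train = n - n_val - n_test
    return SplitPlan(train=tuple(int(i) for i in perm[:n_train]),
                     val=tuple(int(i) for i in perm[n_train:n_train + n_val]),
                     test=tuple(int(i) for i in perm[n_train + n_val:]),
                     ratio=parts, seed=seed)


def kfold(n: int, k: int = 5, seed: int = 0):
    """k disjoint, exhaustive folds (sizes differ by at most one);
    returns a list of (train_indices, test_indices) pairs."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    test_folds = np.array_split(perm, k)
    pairs = []
    for i in range(k):
        test = test_folds[i]
        train = np.concatenate([f for j, f in enumerate(test_folds) if j != i])
        pairs.append((tuple(int(x) for x in train),
                      tuple(int(x) for x in test)))
    return pairs


def _stack(dataset):
    xs = np.stack([np.asarray(p.image, dtype=np.float32) for p in dataset])
    ys = np.stack([np.asarray(p.mask, dtype=np.float32) for p in dataset])
    return xs[:, None], ys[:, None]


def train(model: SegmentationModel, dataset, spec: TrainSpec = TrainSpec(),
          val_dataset=None, bf_config: BFConfig = BFConfig(),
          keep_best: bool = True):
    """Minimise BCE with Adam for ``spec.max_epochs`` epochs.

    When a validation set is given, per-epoch validation metrics are logged
    and (with ``keep_best``) the weights with the best validation Dice are
    restored at the end.  Returns ``(model, History)``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    xs, ys = _stack(dataset)
    rng = np.random.default_rng(spec.seed)
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate,
                  betas=(spec.beta1, spec.beta2))
    history = History()
    best_dice, best_state = -1.0, None
    n = len(dataset)
    for epoch in range(1, spec.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            out = model(nn.Tensor(xs[idx]))
            loss = F.bce_loss(out, ys[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += value * len(idx)
            count += len(idx)
        history.train_loss.append(total / count)
        if val_dataset:
            _, mean = evaluate(model, val_dataset, threshold=spec.threshold,
                               cfg=bf_config)
            history.val_metrics.append(mean)
            if keep_best and mean.dice is not None and mean.dice > best_dice:
                best_dice = mean.dice
                best_state = {name: p.data.copy()
                              for name, p in model.named_parameters()}
                best_state["__buffers__"] = {
                    name: b.copy() for name, b in model.named_buffers()}
    if best_state is not None:
        buffers = best_state.pop("__buffers__")
        for name, p in model.named_parameters():
            p.data[...] = best_state[name]
        for name, b in model.named_buffers():
            b[...] = buffers[name]
    return model, history


def evaluate(model, dataset, threshold: float = 0.5,
             cfg: BFConfig = BFConfig()):
    """Forward every image and score it; returns (per-image reports, mean).

    ``model`` may be any object with ``predict(batch) -> probabilities``
    (NCHW in, NCHW out)."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty evaluation dataset")
    reports = []
    for pair in dataset:
        prob = model.predict(pair.image[None, None].astype(np.float32))[0, 0]
        reports.append(evaluate_pair(prob, pair.mask, threshold, cfg))
    return reports, mean_report(reports)


def reports_table(reports, mean: MetricsReport, ids=None,
                  parameters: int | None = None) -> pd.DataFrame:
    """Per-image metric table in the published column order, with a trailing
    mean row and a parameter-count column."""
    rows = []
    key_map = dict(zip(TABLE_COLUMNS[:-1], ["accuracy", "sensitivity",
                                            "specificity", "precision",
                                            "dice", "jaccard", "bf_score"]))
    items = list(reports) + [mean]
    labels = (list(ids) if ids is not None
              else [str(i) for i in range(len(reports))]) + ["mean"]
    for label, rep in zip(labels, items):
        row = {"id": label}
        for col, attr in key_map.items():
            row[col] = getattr(rep, attr)
        row["Parameters"] = parameters
        rows.append(row)
    return pd.DataFrame(rows, columns=["id"] + TABLE_COLUMNS)
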