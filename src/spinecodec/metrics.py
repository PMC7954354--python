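"""Segmentation evaluation: six region scores plus the boundary F1-score.

Region scores follow the usual pixel confusion-matrix definitions
(accuracy, sensitivity, specificity, precision, Jaccard, Dice).  The
BF-score extracts the inner boundary of each mask (foreground pixels with a
background 4-neighbour, the image border counting as background), then
scores a boundary pixel as matched when the nearest opposite-boundary pixel
lies within a Euclidean distance threshold (theta, default 2 px, inclusive);
the score is the harmonic mean of boundary precision and recall.

Degenerate ratios: any 0/0 is 1 when the corresponding sets are empty on
both sides (a perfect empty prediction stays perfect) and 0 otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ShapeError

__all__ = ["BFConfig", "ConfusionCounts", "MetricsReport", "binarize",
           "confusion_counts", "region_metrics", "extract_boundary",
           "bf_score", "evaluate_pair", "mean_report", "score_mask_folders",
           "REPORT_FIELDS"]

REPORT_FIELDS = ("accuracy", "sensitivity", "specificity", "precision",
                 "dice", "jaccard", "bf_score")


@dataclass(frozen=True)
class BFConfig:
    theta: float = 2.0
    connectivity: int = 4

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    dice: float
    jaccard: float
    bf_score: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must contain only {0, 1}")
    return arr.astype(bool)


def binarize(prob, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    arr = np.asarray(prob, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (arr >= threshold).astype(np.uint8)


def confusion_counts(pred, truth) -> ConfusionCounts:
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def region_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six confusion-matrix scores (bf_score left unset)."""
    if c.total <= 0:
        raise ValueError("empty confusion counts")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    return MetricsReport(
        accuracy=(tp + tn) / c.total,
        # truth foreground empty: perfect iff prediction is empty too
        sensitivity=_ratio(tp, tp + fn, fp == 0),
        # truth background empty: perfect iff prediction has no background
        specificity=_ratio(tn, tn + fp, fn == 0),
        # predicted foreground empty: perfect iff truth is empty too
        precision=_ratio(tp, tp + fp, fn == 0),
        dice=_ratio(2 * tp, 2 * tp + fp + fn, True),
        jaccard=_ratio(tp, tp + fp + fn, True),
    )


def extract_boundary(mask, connectivity: int = 4) -> np.ndarray:
    """Inner boundary: foreground pixels with a background pixel (or the
    image border) in their 4- (default) or 8-neighbourhood.  Returns a
    boolean array of the mask's shape."""
    m = _as_binary(mask)
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        structure = ndimage.generate_binary_structure(2, 2)
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return m & ~interior


def bf_score(pred, truth, cfg: BFConfig = BFConfig()) -> float:
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    bp = extract_boundary(p, cfg.connectivity)
    bt = extract_boundary(t, cfg.connectivity)
    np_, nt = int(bp.sum()), int(bt.sum())
    if np_ == 0 and nt == 0:
        return 1.0
    if np_ == 0 or nt == 0:
        return 0.0
    # exact Euclidean distance to the nearest boundary pixel of the other mask
    dist_to_t = ndimage.distance_transform_edt(~bt)
    dist_to_p = ndimage.distance_transform_edt(~bp)
    precision = float(np.count_nonzero(dist_to_t[bp] <= cfg.theta)) / np_
    recall = float(np.count_nonzero(dist_to_p[bt] <= cfg.theta)) / nt
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_pair(prob, truth, threshold: float = 0.5,
                  cfg: BFConfig = BFConfig()) -> MetricsReport:
    """Binarise a probability map and score it against the ground truth."""
    pred = binarize(prob, threshold)
    report = region_metrics(confusion_counts(pred, truth))
    report.bf_score = bf_score(pred, truth, cfg)
    return report


def mean_report(reports) -> MetricsReport:
    """Unweighted (macro) mean of per-image reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to average")
    values = {}
    for name in REPORT_FIELDS:
        vals = [getattr(r, name) for r in reports]
        values[name] = None if any(v is None for v in vals) else float(np.mean(vals))
    return MetricsReport(**values)


def _load_binary_png(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 0).astype(np.uint8)


def score_mask_folders(pred_dir, truth_dir, out_csv=None, out_json=None,
                       threshold: float = 0.5,
                       cfg: BFConfig = BFConfig()) -> pd.DataFrame:
    """Score matching-stem PNG masks (0/255) from two folders.

    Returns a per-image table with a trailing ``mean`` row; optionally
    writes it as CSV and JSON.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    rows = []
    pred_files = sorted(pred_dir.glob("*.png"))
    if not pred_files:
        raise FileNotFoundError(f"no PNG masks found in {pred_dir}")
    for pf in pred_files:
        tf = truth_dir / pf.name
        if not tf.exists():
            raise FileNotFoundError(f"no ground-truth mask for {pf.name}")
        pred = _load_binary_png(pf)
        truth = _load_binary_png(tf)
        report = evaluate_pair(pred.astype(float), truth, threshold, cfg)
        rows.append({"id": pf.stem, **report.as_dict()})
    table = pd.DataFrame(rows)
    mean_row = {"id": "mean", **{k: table[k].mean() for k in REPORT_FIELDS}}
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(table.to_dict("records"), indent=2))
    return table
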