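"""Segmentation evaluation: pixel metrics, region Dice, instance counts.

Two metric families are deliberately kept distinct:

* pixel-based precision/recall/F1 are *pooled* over all test pixels
  (one-vs-rest per class), and
* the region-based Dice similarity coefficient (DSC) is computed per image
  and then averaged over images.

This is the only convention under which pooled F1 and per-image DSC can
legitimately differ for the same class.  Instance-level behaviour is
assessed by counting connected components of the nuclei class
(8-connectivity, i.e. closed external contours) and reporting the percent
deviation from the ground-truth count per cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BACKGROUND, BORDER, NUCLEI, HsinucdbError, validate_segmap

CLASS_NAMES = {BACKGROUND: "background", BORDER: "border", NUCLEI: "nuclei"}
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# pixel-based metrics (pooled)
# --------------------------------------------------------------------------

def pixel_metrics(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    classes: Sequence[int] = (BACKGROUND, BORDER, NUCLEI),
) -> dict[int, dict[str, float]]:
    """Per-class precision/recall/F1 in percent, pooled over all pixels."""
    if len(preds) != len(gts):
        raise HsinucdbError("need one ground truth per prediction")
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    for pred, gt in zip(preds, gts):
        pred = validate_segmap(pred)
        gt = validate_segmap(gt)
        if pred.shape != gt.shape:
            raise HsinucdbError("prediction and ground truth shapes differ")
        for c in classes:
            p = pred == c
            g = gt == c
            tp[c] += int((p & g).sum())
            fp[c] += int((p & ~g).sum())
            fn[c] += int((~p & g).sum())
    out: dict[int, dict[str, float]] = {}
    for c in classes:
        prec = 100.0 * tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        rec = 100.0 * tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = {"precision": prec, "recall": rec, "f1": f1}
    return out


# --------------------------------------------------------------------------
# region-based Dice (per-image averaged)
# --------------------------------------------------------------------------

def region_dsc(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    classes: Sequence[int] = (BACKGROUND, BORDER, NUCLEI),
) -> dict[int, float]:
    """Per-class Dice in percent, computed per image and averaged.

    A class absent from both maps of an image scores Dice 1 for that image
    (empty agreement, e.g. no border pixels on a healthy cube).
    """
    if len(preds) != len(gts):
        raise HsinucdbError("need one ground truth per prediction")
    per_class: dict[int, list[float]] = {c: [] for c in classes}
    for pred, gt in zip(preds, gts):
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise HsinucdbError("prediction and ground truth shapes differ")
        for c in classes:
            p = pred == c
            g = gt == c
            denom = int(p.sum() + g.sum())
            dice = 2.0 * int((p & g).sum()) / denom if denom else 1.0
            per_class[c].append(dice)
    return {c: 100.0 * float(np.mean(v)) for c, v in per_class.items()}


def macro_main_classes(per_class_values: dict[int, float]) -> float:
    """Average over the main classes (background and nuclei) only.

    The border class is auxiliary — it exists to teach networks the nucleus
    boundaries — and is excluded from macro averages.
    """
    missing = {BACKGROUND, NUCLEI} - set(per_class_values)
    if missing:
        raise HsinucdbError(f"missing main classes {missing}")
    return float(np.mean([per_class_values[BACKGROUND], per_class_values[NUCLEI]]))


# --------------------------------------------------------------------------
# instance counting
# --------------------------------------------------------------------------

def count_instances(seg: np.ndarray) -> int:
    """Number of closed nucleus contours = 8-connected nuclei components.

    Border and background pixels are ignored, so a 1-px border band
    between two nuclei keeps them as two separate instances.
    """
    seg = validate_segmap(seg)
    _, n = ndimage.label(seg == NUCLEI, structure=EIGHT_CONNECTED)
    return int(n)


def count_deviation(pred_count: int, gt_count: int) -> float:
    """Percent deviation of a predicted instance count from ground truth."""
    if gt_count <= 0:
        raise HsinucdbError("ground-truth count must be positive")
    return round((pred_count - gt_count) / gt_count * 100.0, 2)


# --------------------------------------------------------------------------
# combined report
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    class_metrics: pd.DataFrame  # rows: classes (+ macro), cols: P/R/F1/DSC
    count_report: pd.DataFrame  # rows: cubes (+ average), cols: gt/pred/delta

    def to_csv(self, metrics_path, counts_path) -> None:
        self.class_metrics.to_csv(metrics_path)
        self.count_report.to_csv(counts_path)

    def __str__(self) -> str:
        return (
            "Pixel/region metrics (%):\n"
            + self.class_metrics.to_string(float_format=lambda v: f"{v:.2f}")
            + "\n\nInstance counts:\n"
            + self.count_report.to_string(float_format=lambda v: f"{v:.2f}")
        )


def evaluation_report(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    instance_gt_counts: Optional[Sequence[int]] = None,
    cube_ids: Optional[Sequence[str]] = None,
    classes: Sequence[int] = (BACKGROUND, BORDER, NUCLEI),
) -> EvaluationReport:
    """Build the per-class metric table and the per-cube count table.

    ``instance_gt_counts`` are ground-truth nucleus counts (from instance
    maps); predicted counts are closed-contour counts of each predicted
    map's nuclei class.
    """
    pm = pixel_metrics(preds, gts, classes)
    dsc = region_dsc(preds, gts, classes)
    rows = {}
    for c in classes:
        rows[CLASS_NAMES[c]] = {
            "precision": pm[c]["precision"],
            "recall": pm[c]["recall"],
            "f1": pm[c]["f1"],
            "dsc": dsc[c],
        }
    rows["macro_main"] = {
        "precision": macro_main_classes({c: pm[c]["precision"] for c in pm}),
        "recall": macro_main_classes({c: pm[c]["recall"] for c in pm}),
        "f1": macro_main_classes({c: pm[c]["f1"] for c in pm}),
        "dsc": macro_main_classes(dsc),
    }
    class_df = pd.DataFrame(rows).T

    if cube_ids is None:
        cube_ids = [f"cube{i}" for i in range(len(preds))]
    count_rows = []
    if instance_gt_counts is not None:
        for cid, pred, gt_count in zip(cube_ids, preds, instance_gt_counts):
            pred_count = count_instances(pred)
            count_rows.append(
                {
                    "cube": cid,
                    "gt_count": int(gt_count),
                    "pred_count": pred_count,
                    "delta_percent": count_deviation(pred_count, gt_count),
                }
            )
        avg = float(np.mean([r["delta_percent"] for r in count_rows]))
        count_rows.append(
            {"cube": "average", "gt_count": np.nan, "pred_count": np.nan,
             "delta_percent": round(avg, 2)}
        )
    count_df = pd.DataFrame(count_rows).set_index("cube") if count_rows else pd.DataFrame()
    return EvaluationReport(class_metrics=class_df, count_report=count_df)


def average_count_deviation(deltas: Sequence[float]) -> float:
    """Arithmetic mean of per-cube percent deviations, to 2 decimals."""
    return round(float(np.mean(list(deltas))), 2)
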