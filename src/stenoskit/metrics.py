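"""Detection evaluation: greedy IoU matching, precision/recall/F1, AP and mAP.

Matching follows standard detection practice: detections are processed in
descending score order and each one claims the unmatched same-class ground
truth with the highest IoU, provided that IoU reaches the threshold (0.5 by
default — the usual choice for stenosis detection).  AP integrates the
precision envelope over recall (all-point interpolation as in VOC2010 and
modern detection tooling; 11-point interpolation is available behind a flag),
and mAP averages AP over classes that have at least one ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxloss import Box, iou

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "GroundTruth",
    "MatchCounts",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "map_over_classes",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_detections",
    "write_detections",
    "evaluation_report",
]


@dataclass(frozen=True)
class Detection:
    box: Box
    class_id: int = 0
    score: float = 1.0


@dataclass(frozen=True)
class GroundTruth:
    box: Box
    class_id: int = 0


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_thresh: float = 0.5) -> tuple[MatchCounts, list[bool]]:
    """Greedy one-to-one matching of same-class detections to ground truths.

    Returns the TP/FP/FN counts and a per-detection TP flag (in the original
    input order).  Score ties keep input order; IoU ties go to the lowest
    ground-truth index.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(gts)
    flags = [False] * len(dets)
    for i in order:
        best_j, best_iou = -1, iou_thresh
        for j, g in enumerate(gts):
            if taken[j] or g.class_id != dets[i].class_id:
                continue
            v = iou(dets[i].box, g.box)
            if v > best_iou or (best_j < 0 and v == best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            flags[i] = True
    tp = sum(flags)
    return MatchCounts(tp=tp, fp=len(dets) - tp,
                       fn=len(gts) - sum(taken)), flags


def precision_recall_f1(c: MatchCounts) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), and their harmonic mean.

    Each value is defined as 0 when its denominator is 0.
    """
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    rec = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def _flatten(per_image: dict) -> list[tuple]:
    out = []
    for img_id, items in per_image.items():
        out.extend((img_id, it) for it in items)
    return out


def _pr_curve(dets_by_image: dict, gts_by_image: dict,
              iou_thresh: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Cumulative precision/recall arrays over the global score sweep."""
    n_gt = sum(len(v) for v in gts_by_image.values())
    flat = _flatten(dets_by_image)
    flat.sort(key=lambda t: -t[1].score)  # stable: ties keep input order
    taken = {img: [False] * len(gts) for img, gts in gts_by_image.items()}
    tps = np.zeros(len(flat), dtype=bool)
    for k, (img_id, det) in enumerate(flat):
        gts = gts_by_image.get(img_id, [])
        used = taken.setdefault(img_id, [False] * len(gts))
        best_j, best_iou = -1, iou_thresh
        for j, g in enumerate(gts):
            if used[j] or g.class_id != det.class_id:
                continue
            v = iou(det.box, g.box)
            if v > best_iou or (best_j < 0 and v == best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            used[best_j] = True
            tps[k] = True
    cum_tp = np.cumsum(tps)
    prec = cum_tp / np.arange(1, len(flat) + 1) if len(flat) else np.array([])
    rec = cum_tp / n_gt if n_gt else np.zeros(len(flat))
    return prec, rec, n_gt


def average_precision(dets_by_image: dict, gts_by_image: dict,
                      iou_thresh: float = 0.5,
                      interpolation: str = "all") -> float:
    """AP of a single class: area under the precision envelope.

    ``dets_by_image`` / ``gts_by_image`` map an image id to that image's
    detections / ground truths (one class; group by class first — see
    :func:`map_over_classes`).
    """
    prec, rec, n_gt = _pr_curve(dets_by_image, gts_by_image, iou_thresh)
    if n_gt == 0:
        raise ValueError("average_precision undefined without ground truths")
    if len(prec) == 0:
        return 0.0
    if interpolation == "11point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = rec >= r
            ap += (prec[mask].max() if mask.any() else 0.0) / 11
        return float(ap)
    mrec = np.concatenate([[0.0], rec, [1.0]])
    mpre = np.concatenate([[0.0], prec, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]  # precision envelope
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map_over_classes(dets_by_image: dict, gts_by_image: dict,
                     iou_thresh: float = 0.5,
                     interpolation: str = "all") -> float:
    """Unweighted mean of per-class APs; classes without ground truth are
    excluded (a warning is logged if they carry detections)."""
    classes = sorted({g.class_id for gts in gts_by_image.values() for g in gts})
    det_classes = {d.class_id for ds in dets_by_image.values() for d in ds}
    for c in sorted(det_classes - set(classes)):
        logger.warning("class %d has detections but no ground truth; "
                       "its AP is undefined and excluded from mAP", c)
    if not classes:
        return 0.0
    aps = []
    for c in classes:
        dbi = {img: [d for d in ds if d.class_id == c]
               for img, ds in dets_by_image.items()}
        gbi = {img: [g for g in gs if g.class_id == c]
               for img, gs in gts_by_image.items()}
        aps.append(average_precision(dbi, gbi, iou_thresh, interpolation))
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# file formats: YOLO labels and detection lists
# ---------------------------------------------------------------------------

def read_yolo_labels(path) -> list[GroundTruth]:
    """One `class cx cy w h` line per object, coordinates normalized to [0,1]."""
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        out.append(GroundTruth(Box(cx, cy, w, h), class_id=cls))
    return out


def write_yolo_labels(path, gts: list[GroundTruth]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{g.class_id} {g.box.cx:.6f} {g.box.cy:.6f} "
             f"{g.box.w:.6f} {g.box.h:.6f}" for g in gts]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections(path) -> list[Detection]:
    """One `class score cx cy w h` line per detection."""
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls = int(parts[0])
        score, cx, cy, w, h = map(float, parts[1:6])
        out.append(Detection(Box(cx, cy, w, h), class_id=cls, score=score))
    return out


def write_detections(path, dets: list[Detection]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{d.class_id} {d.score:.6f} {d.box.cx:.6f} {d.box.cy:.6f} "
             f"{d.box.w:.6f} {d.box.h:.6f}" for d in dets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def evaluation_report(dets_by_image: dict, gts_by_image: dict,
                      iou_thresh: float = 0.5) -> dict:
    """Pooled precision/recall/F1 over all images plus mAP at the threshold."""
    total = MatchCounts()
    for img_id, gts in gts_by_image.items():
        c, _ = match_detections(dets_by_image.get(img_id, []), gts, iou_thresh)
        total.tp += c.tp
        total.fp += c.fp
        total.fn += c.fn
    for img_id, dets in dets_by_image.items():
        if img_id not in gts_by_image:
            total.fp += len(dets)
    prec, rec, f1 = precision_recall_f1(total)
    return {"precision": prec, "recall": rec, "f1": f1,
            "map50": map_over_classes(dets_by_image, gts_by_image, iou_thresh),
            "tp": total.tp, "fp": total.fp, "fn": total.fn}
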