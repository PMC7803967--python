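"""Detection scoring: IoU matching, precision-recall curves, AP and mAP.

Matching follows the standard protocol at a fixed IoU threshold: detections
are processed in descending confidence and greedily matched to the
highest-IoU unmatched ground-truth box of the same class.  AP integrates
the precision envelope over recall ("all-point" interpolation); mAP is the
unweighted mean over classes with at least one ground-truth box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BBox",
    "ScoredDetection",
    "iou",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate",
    "load_coco_ground_truth",
    "load_coco_detections",
]

BBox = tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)


@dataclass
class ScoredDetection:
    label: str
    box: BBox
    score: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise ValueError("box must have positive width and height")
        if not np.isfinite(self.score):
            raise ValueError("confidence must be finite")


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    if inter <= 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def match_detections(
    dets: list[ScoredDetection],
    gts: list[tuple[str, BBox]],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], list[int], list[bool]]:
    """Greedy confidence-ordered matching.

    Returns ``(tp_flags, order, gt_matched)``: ``order`` indexes ``dets``
    in descending confidence (ties broken by input position, stable),
    ``tp_flags[i]`` says whether ``dets[order[i]]`` is a true positive, and
    ``gt_matched[j]`` whether ground truth ``j`` was claimed.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gt_matched = [False] * len(gts)
    tp_flags = []
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, 0.0
        for j, (label, box) in enumerate(gts):
            if gt_matched[j] or label != det.label:
                continue
            v = iou(det.box, box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_matched[best_j] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    return tp_flags, order, gt_matched


def pr_curve(tp_flags: list[bool], n_gt: int) -> list[tuple[float, float]]:
    """Cumulative (recall, precision) points over descending-confidence prefixes."""
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    points = []
    tp = 0
    for k, flag in enumerate(tp_flags, start=1):
        tp += bool(flag)
        points.append((tp / n_gt, tp / k))
    return points


def average_precision(
    curve: list[tuple[float, float]], interpolation: str = "all"
) -> float:
    """Area under the precision-envelope / recall curve.

    ``interpolation='all'`` integrates the running-maximum precision over
    every recall step; ``'101'`` samples the envelope at 101 evenly spaced
    recall levels (COCO-style).
    """
    if not curve:
        return 0.0
    recalls = np.array([r for r, _ in curve])
    precisions = np.array([p for _, p in curve])
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    if interpolation == "101":
        levels = np.linspace(0.0, 1.0, 101)
        vals = np.zeros_like(levels)
        for i, lv in enumerate(levels):
            ok = recalls >= lv
            vals[i] = env[ok].max() if ok.any() else 0.0
        return float(vals.mean())
    if interpolation != "all":
        raise ValueError("interpolation must be 'all' or '101'")
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_ap(per_class_ap: dict[str, float]) -> float:
    """Unweighted mean AP over classes (caller excludes zero-gt classes)."""
    if not per_class_ap:
        raise ValueError("no class with ground truth")
    return float(np.mean(list(per_class_ap.values())))


def evaluate(
    dets_by_image: dict[object, list[ScoredDetection]],
    gts_by_image: dict[object, list[tuple[str, BBox]]],
    iou_threshold: float = 0.5,
    interpolation: str = "all",
) -> dict:
    """Per-class AP and mAP over a set of images.

    Matching runs per image; flags are pooled per class in global
    descending-confidence order.  Classes with zero ground truth are
    skipped.
    """
    classes = sorted({lbl for gts in gts_by_image.values() for lbl, _ in gts})
    per_class = {}
    curves = {}
    for cls in classes:
        scored: list[tuple[float, int, bool]] = []  # (score, tiebreak, tp)
        n_gt = 0
        tiebreak = 0
        for img, gts in gts_by_image.items():
            gts_c = [(l, b) for l, b in gts if l == cls]
            n_gt += len(gts_c)
            dets_c = [d for d in dets_by_image.get(img, []) if d.label == cls]
            flags, order, _ = match_detections(dets_c, gts_c, iou_threshold)
            for flag, i in zip(flags, order):
                scored.append((dets_c[i].score, tiebreak, flag))
                tiebreak += 1
        if n_gt == 0:
            continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        flags = [f for _, _, f in scored]
        curve = pr_curve(flags, n_gt)
        per_class[cls] = average_precision(curve, interpolation)
        curves[cls] = curve
    return {
        "per_class_ap": per_class,
        "mAP": mean_ap(per_class),
        "curves": curves,
        "iou_threshold": iou_threshold,
    }


# --- COCO-format IO --------------------------------------------------------


def load_coco_ground_truth(path: str | Path) -> dict[int, list[tuple[str, BBox]]]:
    with open(path) as fh:
        coco = json.load(fh)
    names = {c["id"]: c["name"] for c in coco["categories"]}
    gts: dict[int, list] = {img["id"]: [] for img in coco["images"]}
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        gts[ann["image_id"]].append((names[ann["category_id"]], (x, y, x + w, y + h)))
    return gts


def load_coco_detections(
    path: str | Path, categories: dict[int, str]
) -> dict[int, list[ScoredDetection]]:
    with open(path) as fh:
        results = json.load(fh)
    dets: dict[int, list] = {}
    for r in results:
        x, y, w, h = r["bbox"]
        dets.setdefault(r["image_id"], []).append(
            ScoredDetection(categories[r["category_id"]], (x, y, x + w, y + h), r["score"])
        )
    return dets
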