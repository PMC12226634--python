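"""Temporal-consistency and per-frame detection/segmentation metrics.

Temporal consistency of a predicted mask sequence is measured two ways:

* flow-aware: warp mask m_t by the optical flow between frames t and t+1
  and score its macro Dice/IoU against m_{t+1} (Dice_OF / IoU_OF) — high
  values mean the masks move with the image content;
* content-free: contour distance and macro IoU between subsequent masks
  (CD_T / IoU_T) — these reward smooth masks regardless of image motion.

Per-frame detection quality follows standard practice: greedy
score-ordered matching at a 50% box-IoU threshold gives Class F1, the
mean box IoU over true positives (BB IoU), the mean instance-mask Dice
over true positives whose mask IoU >= 50% (Mask Dice), and macro Dice of
the rendered semantic maps (Semantic Dice).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk

from .overseer import Detection, DetectionSet, semantic_mask_from_detections
from .video_io import FrameSequence, LabelSchema, MaskSequence

IOU_MATCH_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Optical flow
# ---------------------------------------------------------------------------

def compute_flow(frame_t: np.ndarray, frame_next: np.ndarray, method: str = "ilk") -> np.ndarray:
    """Dense flow (H, W, 2) = (drow, dcol) mapping frame t to frame t+1."""
    if frame_t.shape != frame_next.shape:
        raise ValueError(
            f"shape mismatch: {frame_t.shape} vs {frame_next.shape}"
        )
    if method != "ilk":
        raise ValueError(f"unknown flow method {method!r}")
    g0 = rgb2gray(frame_t) if frame_t.ndim == 3 else frame_t.astype(float)
    g1 = rgb2gray(frame_next) if frame_next.ndim == 3 else frame_next.astype(float)
    # estimator is backward (t+1 -> t); negate for forward displacement
    v, u = optical_flow_ilk(g0, g1, radius=7)
    return np.stack([-v, -u], axis=-1)


class GroundTruthFlowProvider:
    """Flow source backed by a synthetic bundle's exact fields."""

    def __init__(self, gt_flow: np.ndarray | None) -> None:
        if gt_flow is None:
            raise ValueError("no ground-truth flow available")
        self.gt_flow = np.asarray(gt_flow)

    def __call__(self, t: int) -> np.ndarray:
        return self.gt_flow[t]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def warp_mask(mask: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Warp a label map by a flow field with nearest-neighbour sampling.

    Implemented as a forward splat of the integer-rounded flow; collisions
    resolve to the highest class id and pixels receiving no source become
    background. Exact for integer flows.
    """
    if flow.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs flow {flow.shape[:2]}")
    H, W = mask.shape
    rr, cc = np.mgrid[0:H, 0:W]
    dr = _round_half_away(flow[..., 0]).astype(np.int64)
    dc = _round_half_away(flow[..., 1]).astype(np.int64)
    tr, tc = rr + dr, cc + dc
    inside = (tr >= 0) & (tr < H) & (tc >= 0) & (tc < W)
    out = np.zeros_like(mask)
    np.maximum.at(out, (tr[inside], tc[inside]), mask[inside])
    return out


# ---------------------------------------------------------------------------
# Overlap and contour metrics
# ---------------------------------------------------------------------------

def macro_overlap(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    schema: LabelSchema | None = None,
    all_classes: bool = False,
) -> tuple[float, float]:
    """Macro-averaged (Dice, IoU) over classes, background included.

    By default only classes present in either mask contribute (a class
    absent from both would trivially score 1); ``all_classes=True`` scores
    every schema class instead.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    if all_classes:
        if schema is None:
            raise ValueError("all_classes mode requires a schema")
        universe = schema.class_ids
    else:
        universe = sorted(set(np.unique(mask_a)) | set(np.unique(mask_b)))
    dices, ious = [], []
    for c in universe:
        a = mask_a == c
        b = mask_b == c
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
        union = na + nb - inter
        if na + nb == 0:
            dices.append(1.0)
            ious.append(1.0)
        else:
            dices.append(2.0 * inter / (na + nb))
            ious.append(inter / union)
    return float(np.mean(dices)), float(np.mean(ious))


def _boundary(binary: np.ndarray) -> np.ndarray:
    """Pixels of the region 4-adjacent to a different label or the frame edge."""
    interior = ndimage.binary_erosion(
        binary, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return binary & ~interior


def contour_distance(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    schema: LabelSchema | None = None,
    flicker_penalty: bool = True,
) -> float:
    """Macro-averaged mean symmetric contour distance over foreground classes.

    A class present in exactly one mask contributes the frame diagonal as a
    flicker penalty (disable with ``flicker_penalty=False`` to skip such
    classes). Returns NaN ("no contours") when no foreground class is
    present in either mask.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    H, W = mask_a.shape
    diagonal = math.hypot(H, W)
    present = (set(np.unique(mask_a)) | set(np.unique(mask_b))) - {0}
    dists = []
    for c in sorted(present):
        a = mask_a == c
        b = mask_b == c
        if not (a.any() and b.any()):
            if flicker_penalty:
                dists.append(diagonal)
            continue
        ba, bb = _boundary(a), _boundary(b)
        dist_to_b = ndimage.distance_transform_edt(~bb)
        dist_to_a = ndimage.distance_transform_edt(~ba)
        d_ab = dist_to_b[ba].mean()
        d_ba = dist_to_a[bb].mean()
        dists.append(0.5 * (d_ab + d_ba))
    if not dists:
        return float("nan")
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Sequence-level temporal consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Per-frame-pair temporal-consistency values and their means.

    ``cd_t`` entries may be NaN ("no contours"); NaNs are excluded from the
    sequence mean.
    """

    dice_of: list[float]
    iou_of: list[float]
    cd_t: list[float]
    iou_t: list[float]

    @property
    def mean_dice_of(self) -> float:
        return float(np.mean(self.dice_of))

    @property
    def mean_iou_of(self) -> float:
        return float(np.mean(self.iou_of))

    @property
    def mean_cd_t(self) -> float:
        vals = [v for v in self.cd_t if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_iou_t(self) -> float:
        return float(np.mean(self.iou_t))

    def summary(self) -> dict[str, float]:
        return {
            "dice_of": self.mean_dice_of,
            "iou_of": self.mean_iou_of,
            "cd_t": self.mean_cd_t,
            "iou_t": self.mean_iou_t,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.with_suffix(".json").write_text(
            json.dumps(
                {"summary": self.summary(), "per_pair": self.__dict__},
                indent=2,
                allow_nan=True,
            )
        )
        lines = [f"{k}: {v:.6f}" for k, v in self.summary().items()]
        path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def temporal_consistency_report(
    frames: FrameSequence,
    masks: MaskSequence,
    flow_source: GroundTruthFlowProvider | str = "ilk",
    schema: LabelSchema | None = None,
) -> ConsistencyReport:
    """Score a mask sequence's temporal consistency over all T-1 frame pairs.

    ``flow_source`` is either a :class:`GroundTruthFlowProvider` or the name
    of a dense estimator run on the frames themselves.
    """
    if len(frames) != len(masks):
        raise ValueError(
            f"length mismatch: {len(frames)} frames vs {len(masks)} masks"
        )
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    rep = ConsistencyReport([], [], [], [])
    for t in range(len(frames) - 1):
        if isinstance(flow_source, GroundTruthFlowProvider):
            flow = flow_source(t)
        else:
            flow = compute_flow(frames[t], frames[t + 1], method=flow_source)
        warped = warp_mask(masks[t], flow)
        dice, iou = macro_overlap(warped, masks[t + 1], schema)
        rep.dice_of.append(dice)
        rep.iou_of.append(iou)
        rep.cd_t.append(contour_distance(masks[t], masks[t + 1], schema))
        rep.iou_t.append(macro_overlap(masks[t], masks[t + 1], schema)[1])
    return rep


# ---------------------------------------------------------------------------
# Detection matching and per-frame reports
# ---------------------------------------------------------------------------

def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def mask_overlap(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(dice, iou) of two binary masks; empty-vs-empty scores 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = int((a & b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0, 1.0
    return 2.0 * inter / (sa + sb), inter / (sa + sb - inter)


@dataclass
class Matching:
    tp: list[tuple[int, int, float]]  # (pred index, gt index, box IoU)
    fp: list[int]
    fn: list[int]


def match_detections(
    preds: DetectionSet, gts: DetectionSet, iou_threshold: float = IOU_MATCH_THRESHOLD
) -> Matching:
    """Greedy same-class matching at a box-IoU threshold.

    Candidate pairs are taken in order of descending prediction score, then
    descending IoU; each prediction and ground truth matches at most once.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    cands = []
    for pi, p in enumerate(preds):
        for gi, g in enumerate(gts):
            if p.class_id != g.class_id:
                continue
            iou = box_iou(p.box, g.box)
            if iou >= iou_threshold:
                cands.append((pi, gi, iou))
    cands.sort(key=lambda c: (-preds.detections[c[0]].score, -c[2], c[0], c[1]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = []
    for pi, gi, iou in cands:
        if pi in used_p or gi in used_g:
            continue
        tp.append((pi, gi, iou))
        used_p.add(pi)
        used_g.add(gi)
    fp = [i for i in range(len(preds)) if i not in used_p]
    fn = [i for i in range(len(gts)) if i not in used_g]
    return Matching(tp=tp, fp=fp, fn=fn)


@dataclass
class DetectionReport:
    class_f1: float
    bb_iou: float
    mask_dice: float
    semantic_dice: float
    counts: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        return {
            "class_f1": self.class_f1,
            "bb_iou": self.bb_iou,
            "mask_dice": self.mask_dice,
            "semantic_dice": self.semantic_dice,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.with_suffix(".json").write_text(
            json.dumps({"summary": self.summary(), "counts": self.counts}, indent=2)
        )
        lines = [f"{k}: {v:.6f}" for k, v in self.summary().items()]
        path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def detection_report(
    preds: Sequence[DetectionSet],
    gts: Sequence[DetectionSet],
    schema: LabelSchema,
    iou_threshold: float = IOU_MATCH_THRESHOLD,
) -> DetectionReport:
    """Pooled per-frame detection/segmentation quality at 50% IoU."""
    if len(preds) != len(gts):
        raise ValueError(f"length mismatch: {len(preds)} pred vs {len(gts)} gt frames")
    n_tp = n_fp = n_fn = 0
    box_ious: list[float] = []
    mask_dices: list[float] = []
    sem_dices: list[float] = []
    any_objects = False
    for ps, gs in zip(preds, gts):
        if len(ps) or len(gs):
            any_objects = True
        m = match_detections(ps, gs, iou_threshold)
        n_tp += len(m.tp)
        n_fp += len(m.fp)
        n_fn += len(m.fn)
        for pi, gi, iou in m.tp:
            box_ious.append(iou)
            dice, miou = mask_overlap(
                ps.detections[pi].binary_mask, gs.detections[gi].binary_mask
            )
            if miou >= iou_threshold:
                mask_dices.append(dice)
        sem_dices.append(
            macro_overlap(
                semantic_mask_from_detections(ps, schema),
                semantic_mask_from_detections(gs, schema),
                schema,
            )[0]
        )
    if not any_objects:
        warnings.warn("no ground truths and no predictions: vacuous perfection")
        return DetectionReport(1.0, 1.0, 1.0, 1.0, {"tp": 0, "fp": 0, "fn": 0})
    denom = 2 * n_tp + n_fp + n_fn
    return DetectionReport(
        class_f1=2 * n_tp / denom if denom else 0.0,
        bb_iou=float(np.mean(box_ious)) if box_ious else 0.0,
        mask_dice=float(np.mean(mask_dices)) if mask_dices else 0.0,
        semantic_dice=float(np.mean(sem_dices)),
        counts={"tp": n_tp, "fp": n_fp, "fn": n_fn},
    )
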