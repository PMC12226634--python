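"""The frame-wise Overseer: detection types, an oracle implementation, and
the detector's multi-task training loss as pure operations.

An *overseer* is any per-frame detector-segmenter exposing
``detect(frame, frame_id) -> DetectionSet``. It monitors which semantic
classes are present so the orchestrator can re-prompt the video tracker
when the scene constellation changes. The shipped
:class:`OracleOverseer` is backed by synthetic ground truth plus a
configurable noise model; adapters for real detectors (Mask R-CNN, DETR,
Mask2Former, ...) only need to satisfy the same contract.

The loss operations implement the standard detection multi-task objective:
cross-entropy over class probabilities, smooth-L1 over normalized box
coordinates, and per-pixel binary cross-entropy over instance masks, each
averaged over its own object count (N_cls, N_bb, N_mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .video_io import LabelSchema

EPS = 1e-7  # probability clipping before logs

DEFAULT_SCORE_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Detection containers
# ---------------------------------------------------------------------------

@dataclass
class Detection:
    """One detected object instance.

    box is normalized ``(x_min, y_min, x_max, y_max)`` in [0,1], half-open;
    instance_mask is a full-frame binary (or probability) map.
    """

    class_id: int
    score: float
    box: tuple[float, float, float, float]
    instance_mask: np.ndarray  # (H, W) bool or float in [0, 1]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if self.class_id < 1:
            raise ValueError("detections carry foreground classes (id >= 1)")

    @property
    def binary_mask(self) -> np.ndarray:
        m = self.instance_mask
        return m if m.dtype == bool else m >= 0.5


@dataclass
class DetectionSet:
    """All detections of one frame; carries (H, W) so empty sets keep shape."""

    frame_id: int
    frame_shape: tuple[int, int]
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.instance_mask.shape != tuple(self.frame_shape):
                raise ValueError(
                    f"instance mask shape {d.instance_mask.shape} != "
                    f"frame shape {self.frame_shape}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


def class_set(
    dets: DetectionSet, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> frozenset[int]:
    """Deduplicated class ids with score >= threshold (presence, not count)."""
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must lie in [0, 1]")
    return frozenset(d.class_id for d in dets if d.score >= score_threshold)


def semantic_mask_from_detections(
    dets: DetectionSet, schema: LabelSchema
) -> np.ndarray:
    """Render a semantic label map from instance detections.

    Pixels covered by no instance are background; overlaps go to the
    highest-score instance (ties: lower list index wins).
    """
    out = np.zeros(dets.frame_shape, dtype=np.uint8)
    claimed = np.zeros(dets.frame_shape, dtype=bool)
    order = sorted(range(len(dets.detections)),
                   key=lambda i: (-dets.detections[i].score, i))
    for i in order:
        d = dets.detections[i]
        schema.validate_labels(np.array([d.class_id], dtype=np.int64))
        fp = d.binary_mask & ~claimed
        out[fp] = d.class_id
        claimed |= fp
    return out


# ---------------------------------------------------------------------------
# Overseer contract and the ground-truth-backed oracle
# ---------------------------------------------------------------------------

class Overseer(Protocol):
    """Contract for frame-wise detectors driving re-prompting."""

    def detect(self, frame: np.ndarray, frame_id: int) -> DetectionSet: ...


class OracleOverseer:
    """Overseer backed by a synthetic scene's ground truth plus noise.

    With a zero/absent noise model, ``detect`` returns exactly the
    connected-component detections of the ground-truth mask; a
    :class:`~repromptseg.synthetic_scenes.NoiseConfig` injects missed
    detections, spurious class blips, boundary jitter and score noise,
    deterministically per seed.
    """

    def __init__(self, bundle, schema: LabelSchema, noise=None) -> None:
        from .synthetic_scenes import perturb_detections  # circular at module level

        self.schema = schema
        self._shape = bundle.frames.shape
        dets = bundle.gt_detections
        if noise is not None:
            dets, self.noise_log = perturb_detections(
                dets, noise, schema, return_log=True
            )
        else:
            self.noise_log = []
        self._dets = dets

    def detect(self, frame: np.ndarray, frame_id: int) -> DetectionSet:
        if not 0 <= frame_id < len(self._dets):
            raise ValueError(f"unknown frame {frame_id}")
        if frame.shape[:2] != self._shape:
            raise ValueError(
                f"frame shape {frame.shape[:2]} != configured {self._shape}"
            )
        return self._dets[frame_id]


# ---------------------------------------------------------------------------
# Multi-task detection loss
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossBreakdown:
    loss_cls: float
    loss_box: float
    loss_mask: float

    @property
    def total(self) -> float:
        return self.loss_cls + self.loss_box + self.loss_mask


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def loss_cls(p: np.ndarray, c_star: np.ndarray) -> float:
    """Mean cross-entropy over objects: (1/N) sum_i -sum_k c*_ik log p_ik."""
    p = np.asarray(p, dtype=float)
    c_star = np.asarray(c_star, dtype=float)
    if p.shape != c_star.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs targets {c_star.shape}")
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("no objects to score")
    return float(np.mean(-np.sum(c_star * np.log(_clip(p)), axis=1)))


def smooth_l1(d: np.ndarray) -> np.ndarray:
    """Huber-style smooth L1 with transition at |d| = 1."""
    d = np.abs(np.asarray(d, dtype=float))
    return np.where(d < 1.0, 0.5 * d * d, d - 0.5)


def loss_box(t_pred: np.ndarray, t_star: np.ndarray) -> float:
    """Smooth-L1 box loss, summed over the 4 coords, averaged over objects."""
    t_pred = np.atleast_2d(np.asarray(t_pred, dtype=float))
    t_star = np.atleast_2d(np.asarray(t_star, dtype=float))
    if t_pred.shape != t_star.shape or t_pred.shape[-1] != 4:
        raise ValueError(
            f"shape mismatch: boxes {t_pred.shape} vs targets {t_star.shape}"
        )
    if t_pred.shape[0] == 0:
        raise ValueError("no objects to score")
    return float(np.mean(np.sum(smooth_l1(t_pred - t_star), axis=1)))


def loss_mask(m: np.ndarray, m_star: np.ndarray) -> float:
    """Per-pixel BCE averaged over H*W per object, then over objects."""
    m = np.asarray(m, dtype=float)
    m_star = np.asarray(m_star, dtype=float)
    if m.ndim == 2:
        m, m_star = m[None], m_star[None]
    if m.shape != m_star.shape:
        raise ValueError(f"shape mismatch: masks {m.shape} vs targets {m_star.shape}")
    if m.shape[0] == 0:
        raise ValueError("no objects to score")
    mc = _clip(m)
    bce = -(m_star * np.log(mc) + (1.0 - m_star) * np.log(1.0 - mc))
    return float(np.mean(bce.reshape(m.shape[0], -1).mean(axis=1)))


def multitask_loss(
    p: np.ndarray,
    c_star: np.ndarray,
    t_pred: np.ndarray,
    t_star: np.ndarray,
    m: np.ndarray,
    m_star: np.ndarray,
) -> LossBreakdown:
    """Total detection loss: class CE + box smooth-L1 + mask BCE.

    Predictions and targets arrive already matched; the matching policy is
    the caller's (per-head object counts may differ).
    """
    return LossBreakdown(
        loss_cls=loss_cls(p, c_star),
        loss_box=loss_box(t_pred, t_star),
        loss_mask=loss_mask(m, m_star),
    )


# ---------------------------------------------------------------------------
# Text serialization (inspection / fixtures)
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> str:
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return "-"
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.uint8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    return ",".join(f"{s}:{e - s}" for s, e in zip(starts, ends))


def _rle_decode(rle: str, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    if rle != "-":
        for run in rle.split(","):
            s, n = (int(v) for v in run.split(":"))
            flat[s : s + n] = True
    return flat.reshape(shape)


def write_detection_sets(dets: Sequence[DetectionSet], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for ds in dets:
        h, w = ds.frame_shape
        lines.append(f"frame {ds.frame_id} {h} {w}")
        for d in ds:
            x0, y0, x1, y1 = d.box
            lines.append(
                f"det {d.class_id} {d.score:.6f} "
                f"{x0:.6f} {y0:.6f} {x1:.6f} {y1:.6f} {_rle_encode(d.binary_mask)}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_detection_sets(path: str | Path) -> list[DetectionSet]:
    out: list[DetectionSet] = []
    cur: DetectionSet | None = None
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "frame":
            cur = DetectionSet(int(parts[1]), (int(parts[2]), int(parts[3])))
            out.append(cur)
        elif parts[0] == "det":
            assert cur is not None, "det line before frame header"
            mask = _rle_decode(parts[7], cur.frame_shape)
            cur.detections.append(
                Detection(
                    class_id=int(parts[1]),
                    score=float(parts[2]),
                    box=tuple(float(v) for v in parts[3:7]),
                    instance_mask=mask,
                )
            )
    return out
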