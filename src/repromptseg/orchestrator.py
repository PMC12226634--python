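"""Re-prompting orchestration: overseer-monitored video segmentation.

The orchestrator runs a memory-based tracker over a video while a
frame-wise overseer watches the scene constellation. Per frame the
overseer's detected class set c_t is appended to a buffer B and compared
with the *reference set* — the classes active at the last prompt. When
the sets disagree on more than n_t consecutive frames (n_t + 1 frames,
default n_t = 4, which suppresses short spurious blips), the orchestrator

1. takes the trigger frame t' and back-tracks to t' - n_t, the first
   frame of the discrepancy run;
2. renders the overseer's semantic mask there and samples one (or more)
   anchor points per connected component as the most interior pixels of
   the component (distance-transform maxima);
3. rewinds the tracker's memory to just before t' - n_t and re-prompts it
   with the mask and anchors;
4. re-segments frames t' - n_t .. t', overwriting the earlier outputs
   (this also smooths out the tracker's mistakes over the latency window),
   then continues forward with the new reference set.

The result is a complete mask sequence over all T frames plus a log of
every triggered re-prompt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .overseer import (
    DEFAULT_SCORE_THRESHOLD,
    DetectionSet,
    Overseer,
    class_set,
    semantic_mask_from_detections,
)
from .synthetic_scenes import EIGHT_CONN
from .tracker import PromptEntity, PromptSet, Tracker
from .video_io import FrameSequence, LabelSchema, MaskSequence

logger = logging.getLogger(__name__)

DEFAULT_PERSISTENCE = 4  # n_t: frames a class-set change must persist


@dataclass(frozen=True)
class RepromptConfig:
    """Orchestration knobs.

    n_t — persistence threshold in frames; a discrepancy must hold for
    n_t + 1 consecutive frames before a re-prompt fires (default 4).
    score_threshold — overseer confidence cutoff for class presence.
    anchors_per_component — positive clicks sampled per mask component.
    """

    n_t: int = DEFAULT_PERSISTENCE
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    anchors_per_component: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        if self.anchors_per_component < 1:
            raise ValueError("anchors_per_component must be >= 1")


@dataclass
class ClassBuffer:
    """Per-frame class sets since the last prompt, plus the reference set."""

    reference_set: frozenset[int] = frozenset()
    reference_frame: int = -1
    entries: list[tuple[int, frozenset[int]]] = field(default_factory=list)

    def append(self, frame_id: int, classes: frozenset[int]) -> None:
        if self.entries and frame_id != self.entries[-1][0] + 1:
            raise ValueError("buffer entries must be contiguous in frame_id")
        self.entries.append((frame_id, classes))

    def rebase(self, frame_id: int, classes: frozenset[int]) -> None:
        """Adopt a new reference (after a prompt) and clear the run."""
        self.reference_set = classes
        self.reference_frame = frame_id
        self.entries = []


@dataclass(frozen=True)
class RepromptRecord:
    trigger_frame: int  # t'
    reprompt_frame: int  # t' - n_t
    old_classes: frozenset[int]
    new_classes: frozenset[int]


@dataclass
class RepromptLog:
    initial_prompt_frame: int | None = None
    records: list[RepromptRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"initial_prompt {self.initial_prompt_frame}"]
        for r in self.records:
            old = ",".join(map(str, sorted(r.old_classes))) or "-"
            new = ",".join(map(str, sorted(r.new_classes))) or "-"
            lines.append(f"reprompt {r.trigger_frame} {r.reprompt_frame} {old} {new}")
        for w in self.warnings:
            lines.append(f"warning {w}")
        path.write_text("\n".join(lines) + "\n")
        return path


def sample_anchor_points(
    mask: np.ndarray, k_per_component: int = 1
) -> dict[int, list[tuple[tuple[int, int], ...]]]:
    """Most-interior anchor points per (class, 8-connected component).

    The first anchor of a component is the argmax of its interior distance
    transform (ties row-major); further anchors are the remaining
    distance-transform local maxima in decreasing depth order. Returns
    ``{class_id: [anchors of component 0, anchors of component 1, ...]}``
    with components ordered by first pixel in row-major order.
    """
    result: dict[int, list[tuple[tuple[int, int], ...]]] = {}
    for cid in sorted(np.unique(mask)):
        if cid == 0:
            continue
        labelled, n = ndimage.label(mask == cid, structure=EIGHT_CONN)
        comps = []
        for comp in range(1, n + 1):
            fp = labelled == comp
            dist = ndimage.distance_transform_edt(fp)
            # local maxima under 8-neighbourhood (plateaus included)
            local_max = fp & (dist == ndimage.maximum_filter(dist, size=3))
            rows, cols = np.nonzero(local_max)
            depth = dist[rows, cols]
            order = np.lexsort((cols, rows, -depth))  # depth desc, then row-major
            anchors = tuple(
                (int(rows[i]), int(cols[i])) for i in order[:k_per_component]
            )
            comps.append(anchors)
        result[int(cid)] = comps
    return result


def detect_persistent_change(
    buffer: ClassBuffer, n_t: int, current_frame: int
) -> tuple[int, int] | None:
    """Return (t', t'-n_t) iff the class set disagreed with the reference on
    every one of the last n_t + 1 frames ending at current_frame.

    The discrepant sets need not be identical across the window; only the
    disagreement with the reference must persist.
    """
    window = [e for e in buffer.entries if current_frame - n_t <= e[0] <= current_frame]
    if len(window) < n_t + 1:
        return None
    if all(classes != buffer.reference_set for _, classes in window):
        return current_frame, current_frame - n_t
    return None


def _build_prompt(
    dets: DetectionSet,
    schema: LabelSchema,
    config: RepromptConfig,
    log: RepromptLog,
    frame_id: int,
) -> PromptSet | None:
    """Render the overseer mask and package it as a mask+anchors prompt."""
    confident = DetectionSet(
        dets.frame_id,
        dets.frame_shape,
        [d for d in dets if d.score >= config.score_threshold],
    )
    sem = semantic_mask_from_detections(confident, schema)
    anchors_by_class = sample_anchor_points(sem, config.anchors_per_component)
    entities = []
    for d in confident:
        fp = d.binary_mask & (sem == d.class_id)
        if not fp.any():
            msg = (
                f"frame {frame_id}: class {d.class_id} has an empty overseer "
                "mask; dropped from prompt"
            )
            logger.warning(msg)
            log.warnings.append(msg)
            continue
        pts = []
        for comps in anchors_by_class.get(d.class_id, []):
            for r, c in comps:
                if fp[r, c]:
                    pts.append((r, c))
        if not pts:  # anchor landed in another instance of the class
            dist = ndimage.distance_transform_edt(fp)
            idx = int(np.argmax(dist))
            pts = [(idx // fp.shape[1], idx % fp.shape[1])]
        entities.append(
            PromptEntity(class_id=d.class_id, mask=fp, anchors=tuple(pts))
        )
    if not entities:
        return None
    return PromptSet(frame_id=frame_id, entities=tuple(entities))


def segment_video(
    frames: FrameSequence,
    overseer: Overseer,
    tracker: Tracker,
    config: RepromptConfig | None = None,
    schema: LabelSchema | None = None,
) -> tuple[MaskSequence, RepromptLog]:
    """Segment a full video with overseer-monitored tracker re-prompting.

    Returns the complete per-frame mask sequence (always T frames) and the
    log of the initial prompt plus every triggered re-prompt.
    """
    config = config or RepromptConfig()
    T = len(frames)
    H, W = frames.shape
    if schema is None:
        schema = getattr(overseer, "schema", None)
    if schema is None:
        raise ValueError("a label schema is required")

    outputs = np.zeros((T, H, W), dtype=np.uint8)
    log = RepromptLog()
    buffer = ClassBuffer()
    det_cache: dict[int, DetectionSet] = {}

    def detect(t: int) -> DetectionSet:
        if t not in det_cache:
            det_cache[t] = overseer.detect(frames[t], t)
        return det_cache[t]

    # --- initial prompt: first frame with usable detections ---------------
    start = 0
    prompt = None
    while start < T:
        prompt = _build_prompt(detect(start), schema, config, log, start)
        if prompt is not None:
            break
        msg = f"frame {start}: overseer returned no detections; prompt deferred"
        logger.warning(msg)
        log.warnings.append(msg)
        start += 1
    if prompt is None:  # nothing detectable anywhere: all background
        return MaskSequence(outputs), log

    tracker.prompt(prompt, frame=frames[start])
    outputs[start] = tracker.output(start)
    log.initial_prompt_frame = start
    buffer.rebase(start, class_set(detect(start), config.score_threshold))

    # --- forward pass with monitoring --------------------------------------
    for t in range(start + 1, T):
        outputs[t] = tracker.propagate(frames[t])
        buffer.append(t, class_set(detect(t), config.score_threshold))
        trig = detect_persistent_change(buffer, config.n_t, t)
        if trig is None:
            continue
        t_prime, r = trig
        new_prompt = _build_prompt(detect(r), schema, config, log, r)
        if new_prompt is None:
            msg = f"frame {r}: re-prompt skipped, no usable overseer mask"
            logger.warning(msg)
            log.warnings.append(msg)
            buffer.rebase(r, buffer.reference_set)
            continue
        old_ref = buffer.reference_set
        tracker.reset_to(max(r - 1, 0))
        tracker.prompt(new_prompt, frame=frames[r])
        outputs[r] = tracker.output(r)
        for u in range(r + 1, t_prime + 1):  # overwrite the latency window
            outputs[u] = tracker.propagate(frames[u])
        new_ref = class_set(detect(r), config.score_threshold)
        buffer.rebase(r, new_ref)
        log.records.append(
            RepromptRecord(
                trigger_frame=t_prime,
                reprompt_frame=r,
                old_classes=old_ref,
                new_classes=new_ref,
            )
        )

    return MaskSequence(outputs), log
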