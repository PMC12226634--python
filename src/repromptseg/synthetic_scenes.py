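"""Synthetic video scenes with scripted object entry/exit events.

Generates the kind of footage the re-prompting pipeline targets in
miniature: static textured background regions ("anatomy") and moving
foreground shapes ("instruments") that appear and disappear at scripted
frames. Alongside the rendered frames the generator emits exact ground
truth — label masks, per-pixel optical flow, per-frame detections and an
event log — so every downstream component can be tested against a crisp
oracle.

Velocities are integer-valued by default, which makes the ground-truth
flow field exact under nearest-neighbour warping: warping mask t by
flow t reproduces mask t+1 wherever no entry/exit occurs and objects do
not overlap. Background texture is seeded smooth value noise so dense
optical-flow estimators have gradients to lock onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .overseer import Detection, DetectionSet
from .video_io import FrameSequence, LabelSchema, MaskSequence

EIGHT_CONN = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectSpec:
    """A moving foreground shape present on frames [entry_frame, exit_frame).

    ``size``: disk -> (radius,); rectangle -> (height, width);
    capsule -> (length, radius), a horizontal stadium.
    ``start`` is the center (row, col) at entry_frame; the center advances
    by ``velocity`` (drow, dcol) pixels per frame.
    """

    class_id: int
    shape: Literal["disk", "rectangle", "capsule"]
    size: tuple[int, ...]
    start: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    entry_frame: int = 0
    exit_frame: int | None = None  # None -> present to the end

    def footprint(self, center: tuple[float, float], H: int, W: int) -> np.ndarray:
        r0, c0 = center
        rr, cc = np.mgrid[0:H, 0:W]
        if self.shape == "disk":
            (radius,) = self.size
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        if self.shape == "rectangle":
            h, w = self.size
            return (np.abs(rr - r0) <= h / 2) & (np.abs(cc - c0) <= w / 2)
        if self.shape == "capsule":
            length, radius = self.size
            half = length / 2
            dc = np.clip(cc - c0, -half, half)
            return (rr - r0) ** 2 + (cc - (c0 + dc)) ** 2 <= radius**2
        raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class BackgroundRegion:
    """A static labelled region (r0, c0, r1, c1), half-open, painted in order."""

    class_id: int
    rect: tuple[int, int, int, int]


@dataclass(frozen=True)
class SceneConfig:
    H: int
    W: int
    T: int
    objects: tuple[ObjectSpec, ...] = ()
    background_regions: tuple[BackgroundRegion, ...] = ()
    texture_seed: int = 0
    noise_seed: int = 0
    pixel_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("a scene needs T >= 2 frames")
        objs = tuple(
            o if o.exit_frame is not None else replace(o, exit_frame=self.T)
            for o in self.objects
        )
        object.__setattr__(self, "objects", objs)
        for o in self.objects:
            if not 0 <= o.entry_frame < o.exit_frame <= self.T:
                raise ValueError(
                    f"object entry/exit ({o.entry_frame}, {o.exit_frame}) "
                    f"must satisfy 0 <= entry < exit <= T={self.T}"
                )
            if o.class_id < 1:
                raise ValueError("object class ids must be >= 1")

    @property
    def num_classes(self) -> int:
        ids = [o.class_id for o in self.objects]
        ids += [b.class_id for b in self.background_regions]
        return max(ids, default=1)

    def default_schema(self) -> LabelSchema:
        names = {0: "background"}
        for i in range(1, self.num_classes + 1):
            names[i] = f"class_{i}"
        return LabelSchema(names)


@dataclass(frozen=True)
class NoiseConfig:
    """Overseer imperfection model (all effects deterministic per seed)."""

    miss_prob: float = 0.0
    spurious_prob: float = 0.0
    spurious_duration: tuple[int, int] = (1, 3)
    jitter_radius: tuple[int, int] = (0, 0)
    score_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.spurious_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spurious_duration[0] < 1:
            raise ValueError("blip durations must be >= 1")


@dataclass
class SceneBundle:
    """A generated scene plus its complete ground truth."""

    config: SceneConfig
    frames: FrameSequence
    gt_masks: MaskSequence
    gt_flow: np.ndarray  # (T-1, H, W, 2) float (drow, dcol)
    gt_detections: list[DetectionSet]
    events: list[tuple[int, int, int, int]]  # (object_id, class_id, entry, exit)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _value_noise(rng: np.random.Generator, H: int, W: int, cell: int = 8) -> np.ndarray:
    """Smooth seeded texture in [0, 1] via spline-upsampled coarse noise."""
    coarse = rng.random((H // cell + 2, W // cell + 2))
    zoom = ndimage.zoom(coarse, cell, order=3)
    return np.clip(zoom[:H, :W], 0.0, 1.0)


def _class_base_color(class_id: int, rng: np.random.Generator) -> np.ndarray:
    # widely separated base intensities per class so regions are distinguishable
    return rng.integers(60, 200, size=3).astype(float)


def _object_center(o: ObjectSpec, t: int) -> tuple[float, float]:
    dt = t - o.entry_frame
    return (o.start[0] + o.velocity[0] * dt, o.start[1] + o.velocity[1] * dt)


def generate_scene(config: SceneConfig, schema: LabelSchema | None = None) -> SceneBundle:
    """Render frames, masks, exact flow, detections and the event log.

    Deterministic given ``texture_seed``/``noise_seed``. Later-listed
    objects are painted on top. Raises if an object's footprint leaves the
    frame interior during its lifetime.
    """
    H, W, T = config.H, config.W, config.T
    schema = schema or config.default_schema()
    tex_rng = np.random.default_rng(config.texture_seed)
    noise_rng = np.random.default_rng(config.noise_seed)

    # static background: label map + textured image
    bg_labels = np.zeros((H, W), dtype=np.uint8)
    base = np.empty((H, W, 3), dtype=float)
    texture = _value_noise(tex_rng, H, W)
    bg_color = _class_base_color(0, tex_rng)
    base[:] = bg_color
    for region in config.background_regions:
        r0, c0, r1, c1 = region.rect
        bg_labels[r0:r1, c0:c1] = region.class_id
        base[r0:r1, c0:c1] = _class_base_color(region.class_id, tex_rng)
    base += (texture[..., None] - 0.5) * 80.0

    # per-object appearance: a textured patch that translates with the object
    obj_colors = [_class_base_color(o.class_id, tex_rng) for o in config.objects]
    obj_textures = [_value_noise(tex_rng, H, W, cell=4) for _ in config.objects]

    masks = np.zeros((T, H, W), dtype=np.uint8)
    frames = np.zeros((T, H, W, 3), dtype=np.uint8)
    flow = np.zeros((max(T - 1, 0), H, W, 2), dtype=float)

    footprints: list[list[np.ndarray | None]] = [[None] * T for _ in config.objects]
    for i, o in enumerate(config.objects):
        for t in range(o.entry_frame, o.exit_frame):
            fp = o.footprint(_object_center(o, t), H, W)
            # the footprint must stay clear of the frame border (fully inside)
            if fp[0, :].any() or fp[-1, :].any() or fp[:, 0].any() or fp[:, -1].any():
                raise ValueError(f"object {i} exits bounds at frame {t}")
            if not fp.any():
                raise ValueError(f"object {i} has an empty footprint at frame {t}")
            footprints[i][t] = fp

    for t in range(T):
        masks[t] = bg_labels
        img = base.copy()
        for i, o in enumerate(config.objects):
            fp = footprints[i][t]
            if fp is None:
                continue
            masks[t][fp] = o.class_id
            # translate the object's texture with its integer displacement
            dt = t - o.entry_frame
            dr = int(round(o.velocity[0] * dt))
            dc = int(round(o.velocity[1] * dt))
            tex = np.roll(obj_textures[i], (dr, dc), axis=(0, 1))
            img[fp] = obj_colors[i] + (tex[fp, None] - 0.5) * 80.0
        if config.pixel_noise_sigma > 0:
            img = img + noise_rng.normal(0.0, config.pixel_noise_sigma, img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    for t in range(T - 1):
        for i, o in enumerate(config.objects):
            fp = footprints[i][t]
            if fp is None or footprints[i][t + 1] is None:
                continue  # exiting objects carry no defined motion
            flow[t][fp] = o.velocity

    gt_masks = MaskSequence(masks)
    gt_dets = [detections_from_mask(masks[t], schema, frame_id=t) for t in range(T)]
    events = [
        (i, o.class_id, o.entry_frame, o.exit_frame)
        for i, o in enumerate(config.objects)
    ]
    return SceneBundle(
        config=config,
        frames=FrameSequence(frames),
        gt_masks=gt_masks,
        gt_flow=flow,
        gt_detections=gt_dets,
        events=events,
    )


# ---------------------------------------------------------------------------
# Masks -> detections, and the overseer noise model
# ---------------------------------------------------------------------------

def detections_from_mask(
    mask: np.ndarray, schema: LabelSchema, frame_id: int = 0
) -> DetectionSet:
    """One detection per 8-connected component per non-background class.

    Boxes are the tight component extents, normalized to [0,1] half-open;
    scores are 1.0.
    """
    schema.validate_labels(mask)
    H, W = mask.shape
    dets = DetectionSet(frame_id, (H, W))
    for cid in range(1, schema.num_classes + 1):
        binary = mask == cid
        if not binary.any():
            continue
        labelled, n = ndimage.label(binary, structure=EIGHT_CONN)
        for comp in range(1, n + 1):
            fp = labelled == comp
            rows, cols = np.nonzero(fp)
            box = (
                cols.min() / W,
                rows.min() / H,
                (cols.max() + 1) / W,
                (rows.max() + 1) / H,
            )
            dets.detections.append(
                Detection(class_id=cid, score=1.0, box=box, instance_mask=fp)
            )
    return dets


def _box_from_mask(fp: np.ndarray, fallback) -> tuple[float, float, float, float]:
    if not fp.any():
        return fallback
    H, W = fp.shape
    rows, cols = np.nonzero(fp)
    return (cols.min() / W, rows.min() / H, (cols.max() + 1) / W, (rows.max() + 1) / H)


def perturb_detections(
    dets: list[DetectionSet],
    noise: NoiseConfig,
    schema: LabelSchema,
    return_log: bool = False,
):
    """Apply the overseer imperfection model to per-frame detections.

    Misses drop whole detections; spurious blips insert a small random disk
    of a random class for a contiguous run of frames; jitter dilates/erodes
    instance masks (boxes recomputed); score noise perturbs confidences.
    Deterministic given ``noise.seed``. With ``return_log=True`` also
    returns the realized noise events
    (``("miss"|"blip", frame/start, ..., class_id)``).
    """
    rng = np.random.default_rng(noise.seed)
    T = len(dets)
    log: list[tuple] = []
    out: list[DetectionSet] = []

    # pass 1: misses + jitter + score noise
    for t, ds in enumerate(dets):
        new = DetectionSet(ds.frame_id, ds.frame_shape)
        for d in ds:
            if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
                log.append(("miss", t, d.class_id))
                continue
            mask = d.binary_mask
            box = d.box
            lo, hi = noise.jitter_radius
            if hi > 0:
                radius = int(rng.integers(lo, hi + 1))
                if radius > 0:
                    op = ndimage.binary_dilation if rng.random() < 0.5 else ndimage.binary_erosion
                    mask = op(mask, structure=EIGHT_CONN, iterations=radius)
                    box = _box_from_mask(mask, fallback=d.box)
            score = d.score
            if noise.score_noise > 0:
                score = float(np.clip(score + rng.normal(0.0, noise.score_noise), 0.0, 1.0))
            new.detections.append(
                Detection(class_id=d.class_id, score=score, box=box, instance_mask=mask)
            )
        out.append(new)

    # pass 2: spurious class blips (contiguous runs)
    if noise.spurious_prob > 0:
        H, W = dets[0].frame_shape
        active_until = {c: -1 for c in range(1, schema.num_classes + 1)}
        for t in range(T):
            for cid in range(1, schema.num_classes + 1):
                if t <= active_until[cid]:
                    continue
                if rng.random() >= noise.spurious_prob:
                    continue
                lo, hi = noise.spurious_duration
                dur = int(rng.integers(lo, hi + 1))
                end = min(t + dur, T)  # frames [t, end)
                radius = int(rng.integers(2, max(3, min(H, W) // 8)))
                r0 = int(rng.integers(radius + 1, H - radius - 1))
                c0 = int(rng.integers(radius + 1, W - radius - 1))
                rr, cc = np.mgrid[0:H, 0:W]
                fp = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
                box = _box_from_mask(fp, fallback=(0.0, 0.0, 1.0, 1.0))
                for u in range(t, end):
                    out[u].detections.append(
                        Detection(class_id=cid, score=0.9, box=box, instance_mask=fp)
                    )
                active_until[cid] = end - 1
                log.append(("blip", t, end, cid))

    return (out, log) if return_log else out


# ---------------------------------------------------------------------------
# Event-log I/O
# ---------------------------------------------------------------------------

def write_events(events: list[tuple[int, int, int, int]], path: str | Path) -> Path:
    path = Path(path)
    lines = ["# object_id\tclass_id\tentry\texit"]
    lines += [f"{o}\t{c}\t{e}\t{x}" for o, c, e, x in events]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_events(path: str | Path) -> list[tuple[int, int, int, int]]:
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        o, c, e, x = (int(v) for v in line.split("\t"))
        events.append((o, c, e, x))
    return events
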