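"""Frame/mask sequence I/O and the label schema.

Conventions used throughout the package:

* arrays are row-major with origin at the top-left; a pixel is addressed as
  ``(row, col)``, 0-based;
* bounding boxes are normalized ``(x_min, y_min, x_max, y_max)`` in
  ``[0, 1]`` and half-open (``x = col / W``, ``y = row / H``);
* frames are indexed ``0 .. T-1``.

Masks are stored as palette-indexed PNGs whose palette index *is* the class
id, which keeps labels bit-exact on disk, together with a plain-text schema
sidecar (id, name, palette color).
"""

from __future__ import annotations

import colorsys
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

FRAME_PATTERN = "frame_%06d.png"
SCHEMA_FILENAME = "schema.txt"

_NUM_RE = re.compile(r"(\d+)")


def _default_color(class_id: int) -> tuple[int, int, int]:
    """Deterministic, well-separated palette color for a class id."""
    if class_id == 0:
        return (0, 0, 0)
    hue = (class_id * 0.6180339887498949) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 0.95)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


@dataclass(frozen=True)
class LabelSchema:
    """Mapping of contiguous class ids ``0..C`` to names; id 0 is background."""

    classes: dict[int, str]
    palette: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(self.classes)
        if ids != list(range(len(ids))) or len(ids) < 2:
            raise ValueError(
                "schema ids must be contiguous from 0 with at least one "
                f"foreground class, got {ids}"
            )
        names = list(self.classes.values())
        if len(set(names)) != len(names):
            raise ValueError("schema names must be unique")
        if not self.palette:
            object.__setattr__(
                self, "palette", {i: _default_color(i) for i in ids}
            )

    @property
    def background_id(self) -> int:
        return 0

    @property
    def num_classes(self) -> int:
        """C: the largest class id (foreground classes are ``1..C``)."""
        return len(self.classes) - 1

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.classes)

    def validate_labels(self, mask: np.ndarray) -> None:
        bad = mask.max(initial=0)
        if bad > self.num_classes:
            raise ValueError(
                f"label outside schema: value {int(bad)} exceeds C={self.num_classes}"
            )


@dataclass
class FrameSequence:
    """Ordered RGB frames ``v_0 .. v_{T-1}`` of uniform shape (H, W, 3)."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if len(self.frames) < 1:
            raise ValueError("no frames found")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.frames))
        self.frame_ids = np.asarray(self.frame_ids)
        if np.any(np.diff(self.frame_ids) <= 0):
            raise ValueError("frame_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of every frame."""
        return self.frames.shape[1:3]


@dataclass
class MaskSequence:
    """Per-frame semantic label maps aligned with a :class:`FrameSequence`."""

    masks: np.ndarray  # (T, H, W) uint8
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(f"masks must be (T, H, W), got {self.masks.shape}")
        if self.masks.dtype != np.uint8:
            if self.masks.min(initial=0) < 0 or self.masks.max(initial=0) > 255:
                raise ValueError("mask labels must fit in uint8 (0..255)")
            self.masks = self.masks.astype(np.uint8)
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.masks))
        self.frame_ids = np.asarray(self.frame_ids)

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, t: int) -> np.ndarray:
        return self.masks[t]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:3]


def _numbered_pngs(path: Path) -> list[Path]:
    files = [p for p in sorted(path.iterdir()) if p.suffix.lower() == ".png"]

    def key(p: Path) -> int:
        m = _NUM_RE.findall(p.stem)
        return int(m[-1]) if m else -1

    return sorted(files, key=key)


def read_frame_sequence(path: str | Path) -> FrameSequence:
    """Read a directory of numbered PNGs into a :class:`FrameSequence`."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no frames found: {path} is not a directory")
    files = _numbered_pngs(path)
    if not files:
        raise ValueError(f"no frames found in {path}")
    frames = []
    shape = None
    for k, f in enumerate(files):
        arr = np.asarray(Image.open(f).convert("RGB"))
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"shape mismatch at frame {k}: {arr.shape} != {shape}"
            )
        frames.append(arr)
    return FrameSequence(np.stack(frames))


def write_frame_sequence(frames: FrameSequence, path: str | Path) -> list[Path]:
    """Write frames as ``frame_%06d.png``; returns the written paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for t in range(len(frames)):
        out = path / (FRAME_PATTERN % t)
        Image.fromarray(frames[t], mode="RGB").save(out)
        written.append(out)
    return written


def write_label_schema(schema: LabelSchema, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# id\tname\tR,G,B"]
    for i in schema.class_ids:
        r, g, b = schema.palette[i]
        lines.append(f"{i}\t{schema.classes[i]}\t{r},{g},{b}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_label_schema(path: str | Path) -> LabelSchema:
    classes: dict[int, str] = {}
    palette: dict[int, tuple[int, int, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, name, rgb = line.split("\t")
        r, g, b = (int(v) for v in rgb.split(","))
        classes[int(sid)] = name
        palette[int(sid)] = (r, g, b)
    return LabelSchema(classes, palette)


def _flat_palette(schema: LabelSchema) -> list[int]:
    flat = []
    for i in range(256):
        flat.extend(schema.palette.get(i, (0, 0, 0)))
    return flat


def write_mask_sequence(
    masks: MaskSequence, schema: LabelSchema, path: str | Path
) -> list[Path]:
    """Write one palette-indexed PNG per frame plus the schema sidecar.

    The palette index of every pixel equals its class id, so the round trip
    through :func:`read_mask_sequence` is exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    flat = _flat_palette(schema)
    written = []
    for t in range(len(masks)):
        schema.validate_labels(masks[t])
        img = Image.fromarray(masks[t], mode="P")
        img.putpalette(flat)
        out = path / (FRAME_PATTERN % t)
        img.save(out)
        written.append(out)
    written.append(write_label_schema(schema, path / SCHEMA_FILENAME))
    return written


def read_mask_sequence(path: str | Path, schema: LabelSchema) -> MaskSequence:
    """Read palette-indexed mask PNGs; values are the stored palette indices."""
    path = Path(path)
    files = _numbered_pngs(path)
    if not files:
        raise ValueError(f"no frames found in {path}")
    masks = []
    for k, f in enumerate(files):
        try:
            img = Image.open(f)
            img.load()
        except OSError as exc:
            raise ValueError(f"failed to decode mask frame {k} ({f.name}): {exc}")
        if img.mode != "P":
            raise ValueError(f"mask not palette-indexed: frame {k} has mode {img.mode}")
        arr = np.asarray(img, dtype=np.uint8)
        schema.validate_labels(arr)
        masks.append(arr)
    return MaskSequence(np.stack(masks))
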