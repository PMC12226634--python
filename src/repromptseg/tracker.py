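"""The video Tracker contract and a flow-propagation reference tracker.

A *tracker* is a memory-based video segmentation engine: it is prompted
with instance masks and positive anchor points at one frame, propagates
the tracked entities forward frame by frame, and can rewind its memory to
an earlier frame so a new prompt can overwrite recent history. SAM2 is
the canonical real implementation; the contract here is the abstraction
the orchestrator programs against.

:class:`FlowPropagationTracker` is a deliberately simple reference
implementation that warps its previous output mask along the optical flow
between frames. By construction it reproduces the failure mode that
motivates re-prompting: classes that were never in the prompt can never
appear in its output, so objects entering the scene after the prompt
frame are invisible to it until it is re-prompted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .metrics import compute_flow, warp_mask


@dataclass(frozen=True)
class PromptEntity:
    """One tracked entity: its class, instance mask and positive clicks."""

    class_id: int
    mask: np.ndarray  # (H, W) bool
    anchors: tuple[tuple[int, int], ...]  # (row, col) points inside the mask

    def __post_init__(self) -> None:
        for r, c in self.anchors:
            if not self.mask[r, c]:
                raise ValueError(
                    f"anchor point ({r}, {c}) lies outside its entity mask"
                )


@dataclass(frozen=True)
class PromptSet:
    frame_id: int
    entities: tuple[PromptEntity, ...]

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("nothing to track: prompt has no entities")

    @property
    def class_ids(self) -> frozenset[int]:
        return frozenset(e.class_id for e in self.entities)

    def render(self) -> np.ndarray:
        """Semantic label map of the prompt; later entities paint on top."""
        out = np.zeros(self.entities[0].mask.shape, dtype=np.uint8)
        for e in self.entities:
            out[e.mask] = e.class_id
        return out


class Tracker(Protocol):
    """Contract: prompt, propagate one frame, rewind memory."""

    @property
    def horizon(self) -> int: ...

    def prompt(self, prompts: PromptSet, frame: np.ndarray | None = None) -> None: ...

    def propagate(self, frame: np.ndarray) -> np.ndarray: ...

    def reset_to(self, frame_id: int) -> None: ...


@dataclass
class FlowPropagationTracker:
    """Reference tracker: nearest-neighbour warp of the previous mask.

    With ``gt_flow`` (a (T-1, H, W, 2) array of exact fields) propagation
    is exact for integer motion; without it, flow is estimated densely from
    the frames, which requires the prompt call to supply the prompt frame's
    image.
    """

    gt_flow: np.ndarray | None = None
    flow_method: str = "ilk"
    _masks: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _frames: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _horizon: int = -1
    _last_prompt: PromptSet | None = None

    @property
    def horizon(self) -> int:
        """Last frame id with an output mask; -1 before any prompt."""
        return self._horizon

    def prompt(self, prompts: PromptSet, frame: np.ndarray | None = None) -> None:
        # a fresh tracker may be prompted at any frame (that becomes frame 0
        # of its memory); afterwards prompts must stay within horizon+1
        if self._last_prompt is not None and prompts.frame_id > self._horizon + 1:
            raise ValueError(
                f"prompt frame {prompts.frame_id} is beyond horizon+1 "
                f"({self._horizon + 1})"
            )
        fid = prompts.frame_id
        self._masks = {k: v for k, v in self._masks.items() if k < fid}
        self._masks[fid] = prompts.render()
        if frame is not None:
            self._frames[fid] = np.asarray(frame)
        self._horizon = fid
        self._last_prompt = prompts

    def output(self, frame_id: int) -> np.ndarray:
        return self._masks[frame_id]

    def propagate(self, frame: np.ndarray) -> np.ndarray:
        if self._last_prompt is None:
            raise RuntimeError("tracker not prompted")
        cur = self._horizon + 1
        prev_mask = self._masks[self._horizon]
        if self.gt_flow is not None:
            flow = self.gt_flow[self._horizon]
        else:
            prev_frame = self._frames.get(self._horizon)
            if prev_frame is None:
                raise RuntimeError(
                    f"no stored image for frame {self._horizon}; "
                    "pass frames to prompt() when estimating flow"
                )
            flow = compute_flow(prev_frame, np.asarray(frame), self.flow_method)
        out = warp_mask(prev_mask, flow)
        self._masks[cur] = out
        self._frames[cur] = np.asarray(frame)
        self._horizon = cur
        return out

    def reset_to(self, frame_id: int) -> None:
        """Discard memory for frames > frame_id (back-tracking support)."""
        if frame_id < 0:
            raise ValueError(f"invalid reset target {frame_id}")
        if frame_id > self._horizon:
            raise ValueError(
                f"reset target {frame_id} is beyond horizon {self._horizon}"
            )
        self._masks = {k: v for k, v in self._masks.items() if k <= frame_id}
        self._frames = {k: v for k, v in self._frames.items() if k <= frame_id}
        self._horizon = frame_id
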