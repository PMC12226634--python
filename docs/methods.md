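# Methods

## The re-prompting procedure

The pipeline couples two components through minimal contracts:

* an **overseer** — any frame-wise detector-segmenter exposing
  `detect(frame, frame_id) -> DetectionSet`, where a detection carries a
  class id, a confidence score, a normalized half-open box
  `(x_min, y_min, x_max, y_max)` and a full-frame instance mask;
* a **tracker** — any memory-based video segmenter exposing
  `prompt(PromptSet)`, `propagate(frame)` and `reset_to(frame_id)`, with
  the invariants that the prompt frame's output equals the rendered
  prompt mask, propagation is valid only at `horizon + 1`, and
  `reset_to(k)` discards all memory beyond frame `k` (after which
  prompting at `k` or `k + 1` behaves exactly like a freshly constructed
  tracker — the Markov-after-reset property, asserted bit-exactly in the
  tests).

At the first frame with usable detections the overseer's mask is rendered
(overlaps go to the highest-score instance, ties to the lower list
index), anchor points are sampled, and the tracker is prompted. From then
on the tracker propagates forward while the overseer's thresholded class
set `c_t` (score ≥ 0.5 by default) is appended to a buffer and compared
with the reference set — the class set observed at the last prompt frame.
A re-prompt fires at frame `t'` iff `c_t` differed from the reference on
all of the last `n_t + 1` frames; the discrepant sets need not be equal
to each other, only persistently different from the reference, which
keeps the trigger robust to noisy class labels while still catching
genuine constellation changes. The tracker is rewound to `t' − n_t − 1`,
re-prompted from the overseer's mask at `t' − n_t` (the first discrepant
frame), and frames `t' − n_t .. t'` are re-segmented, overwriting the
earlier outputs. The prompt replaces the full entity set rather than
adding entities incrementally, because the re-prompt is built from the
complete overseer mask. After a trigger the buffer is cleared and the
reference becomes the class set at the re-prompt frame, so a still-ongoing
change can re-trigger no earlier than `n_t + 1` frames later.

Consequences worth knowing:

* a spurious class that persists longer than the window is *adopted* at
  its onset and then *corrected* by a second re-prompt once it vanishes —
  two triggers for one transient. This is the intended self-healing
  behaviour, not a defect; "exactly one trigger" holds for genuine
  (persistent) constellation changes.
* changes in instance count within a class do not trigger, because the
  buffer stores class presence, not instance identity. This is a known
  limitation of set semantics.
* if the overseer reports a class whose mask is empty at the re-prompt
  frame (e.g. erased by boundary jitter), that class is dropped from the
  prompt with a logged warning.
* if the first frames have no detections at all, the initial prompt is
  deferred to the first frame that does; earlier frames are emitted as
  background.

### Anchor sampling

For each 8-connected component of each non-background class in the
overseer mask, the first anchor is the argmax of the interior Euclidean
distance transform (the most interior pixel; ties broken row-major by
`argmax` order). Additional anchors (`anchors_per_component > 1`) are the
remaining distance-transform local maxima in decreasing depth order. This
is deterministic and places clicks where a promptable segmenter is least
likely to bleed across boundaries.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_t` | 4 frames | persistence a class-set change must show before re-prompting; larger values suppress longer detector blips at the cost of later recovery |
| `score_threshold` | 0.5 | overseer confidence cutoff for a class to count as present (detectors rarely publish a canonical cutoff; 0.5 is the conventional operating point) |
| `anchors_per_component` | 1 | positive clicks per mask component |
| smooth-L1 transition | 1.0 | standard Huber-style switch point, applied to normalized box coordinates |
| probability clip ε | 1e−7 | applied before logs in the cross-entropy losses so saturated predictions stay finite |

## The reference implementations

**OracleOverseer** returns the connected-component detections of the
synthetic ground-truth mask, optionally degraded by a seeded noise model:
per-detection misses, spurious class blips (a small disk of a random
class inserted for a contiguous run of frames), boundary jitter
(morphological dilation/erosion with box recomputation) and Gaussian
score noise. The blip mechanism is what the persistence threshold is
designed to reject.

**FlowPropagationTracker** warps its previous output mask along the
optical flow between frames using nearest-neighbour (forward-splat)
sampling. It deliberately reproduces the failure mode that motivates
re-prompting: a class never present in the prompt can never appear in its
output. With ground-truth flow its propagation is exact for integer
motion, which is what makes the end-to-end recovery tests bit-exact; with
estimated flow (iterative Lucas–Kanade from scikit-image) it behaves like
a realistic, slightly leaky propagator. It is a reference implementation
of the tracker contract, not a model of SAM2's internals.

## The synthetic scene generator

Scenes are textured value-noise backgrounds (seeded, smooth — flat
backgrounds would make flow estimation degenerate) with optional static
labelled regions, plus moving disk/rectangle/capsule objects that enter
and leave at scripted frames. Object textures translate rigidly with the
object. The generator emits exact ground truth: label masks, per-pixel
flow (the object's velocity on its pixels, zero on background), per-frame
connected-component detections, and an event log.

What it emulates: the statistical structure the method cares about —
scene-constellation changes at known frames, rigid per-object motion,
detector imperfection via the noise model. What it does not: deformation,
occlusion ordering changes, camera motion, specularities, motion blur,
or anything photometrically surgical. Passing tests therefore demonstrate
the *mechanism* (monitoring, triggering, back-tracking, metric
correctness), not performance on real endoscopic footage, which depends
on the quality of the real overseer and tracker plugged into the
contracts.

### Numerical and degenerate-case choices

* **Warping.** `warp_mask` forward-splats each pixel by its
  integer-rounded flow (half away from zero); destination collisions
  resolve to the highest class id; pixels with no source become
  background (id 0). Label maps need nearest-neighbour handling, and the
  fixed collision order makes results deterministic.
* **Exactness domain.** Warping mask `t` by the exact flow reproduces
  mask `t+1` bit-for-bit when velocities are integer, objects do not
  overlap, no entry/exit happens at `t+1`, *and moving objects travel
  over label-0 background*: pixels disoccluded behind a moving object
  have no source by definition, so they resolve to id 0. Scenes that
  assert exactness are constructed within this domain; sub-pixel motion
  is permitted but waives it.
* **Macro averaging** runs over classes present in either mask,
  background included; classes absent from both are excluded (they would
  trivially score 1). An all-classes mode exists behind a flag.
* **Contour distance** is the symmetric mean boundary distance
  (boundaries: pixels 4-adjacent to a different label or the frame edge),
  macro-averaged over foreground classes; background is excluded, since
  its "contour" is an artifact of the other classes. A class present in
  exactly one mask contributes the frame diagonal `√(H² + W²)` — the
  flicker penalty that gives the metric its sensitivity to dropped
  objects (a skip mode exists behind a flag). Two all-background masks
  have no contours and yield NaN, excluded from sequence means.
* **Matching** is greedy by descending prediction score, then descending
  IoU, then list index — standard detection-evaluation practice and
  deterministic; optimal assignment was deliberately not used.
* **BB IoU** averages over true positives only; all `T − 1` frame pairs
  enter the consistency means, including pairs spanning re-prompts.
* Losses require at least one matched object ("no objects to score");
  the matching of predictions to targets is the caller's input, since
  per-head object counts (`N_cls`, `N_bb`, `N_mask`) may differ across
  detector architectures.

## Problem sizes

Tests and the acceptance script run on 64×64 (and smaller) scenes of
20–60 frames — large enough that every mechanism (entry, exit, blips,
back-tracking, metric exactness) is exercised with non-trivial geometry,
while the whole suite completes in seconds. The mechanism contains no
resolution-dependent logic; only the dense flow estimator benefits from
more texture at larger scales.

## Known limitations

* Instance-level changes within a class are invisible to the trigger.
* The contour-distance flicker penalty saturates per class; a single
  1-pixel flicker and a whole-object flicker pay the same diagonal.
* The reference tracker cannot model occlusion recovery: once a pixel run
  is lost off-frame it never returns.
* Real-detector and SAM2 adapters are contracts only; nothing here
  validates GPU inference.
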