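# Methods

This note documents the models, parameters and design choices behind
`rtrepp`, and what the synthetic test bed does and does not establish about
behavior on real endoscopy video.

## Detection linking

A detector emits, per frame, boxes `{x, y, w, h}` (upper-left corner,
continuous pixel coordinates, area `w·h`), a class-confidence vector
`cc ∈ [0,1]^C` (C = 1 for pure polyp detection) and optionally an
L2-normalized appearance embedding. Two detections in consecutive frames are
scored with

```
LS = fsem · σ(b + Σ_f w_f · x_f),   fsem = cc_t · cc_{t+1}
```

over the features IoU, normalized center distance, width/height ratios and
(optionally) embedding distance. Design choices where the formulation was
genuinely open:

* **Center-distance normalizer.** The "relative" center distance is
  normalized by the frame diagonal, making the feature resolution-independent
  and ≤ 1 whenever both centers are inside the frame. Width- or
  height-normalization would make the feature anisotropic for 4:3 frames.
* **Ratio orientation.** Size ratios are `min/max`, so they are symmetric in
  their arguments and bounded in (0, 1], matching the intent that the
  feature be high when the boxes are similar in size.
* **`fsem` stays outside the regression.** Semantic similarity multiplies
  the logistic output rather than entering the linear term, so detections
  with zero class confidence can never link regardless of geometry.
* **Default weights.** When no trained scorer is supplied, the package uses
  `iou: +12, dcenters: −10, ratio_w: +2, ratio_h: +2, intercept: −9`. With
  these, near-identical boxes (IoU ≈ 0.9, center offset under a percent of
  the diagonal) score close to `fsem`, while boxes overlapping less than
  roughly half fall below the 0.2 linking threshold even at full semantic
  similarity. `fit_link_scorer` (scikit-learn logistic regression, lbfgs,
  fixed seed) replaces these with weights trained on labeled pairs; on
  simulator-labeled pairs the fitted and default scorers behave near
  identically.
* **Assignment.** Pairing per frame transition is a maximum-total-score
  one-to-one assignment (`scipy.optimize.linear_sum_assignment`), with
  below-threshold pairs treated as infeasible (contributing zero, i.e. no
  better than leaving both unmatched). Optimal assignment is deterministic
  and matches exhaustive enumeration; a purely greedy matcher would be
  order-dependent.
* **No gap bridging.** Only consecutive frames link; a single missed frame
  terminates a tubelet. This is faithful to the linking rule as stated and
  is what makes one-frame false positives removable, but it also means a
  detector miss splits a true track in two.

## Refinement

Batch refinement (`repp`) runs, in order: prefilter below
`prefilter_confidence` (default 0.01), link, build tubelets, rescore each
tubelet to its mean confidence vector, optionally smooth coordinates, drop
singleton tubelets (`drop_unmatched`, default on), drop tubelets whose
rescored confidence is below `final_score_threshold` (default 0.2), and
flatten back to per-frame lists. Rescoring is an arithmetic mean, hence
idempotent and confidence-conserving within a tubelet. The final threshold
is applied after rescoring, as the pipeline order lists it.

Coordinate smoothing convolves the four series center-x, center-y, width,
height — the same position/geometry decomposition the link features use —
with a normalized 1-D Gaussian (`scipy.ndimage.gaussian_filter1d`,
reflective boundary, kernel truncated at 4σ). Smoothing therefore never
leaves the per-series min/max envelope, preserves constants, and degenerates
to the identity when the truncated kernel radius reaches zero (σ below about
0.125 frames). The default `smoothing_sigma` of 1.5 frames (60 ms at
25 fps) suppresses single-frame box jitter without visibly lagging real
motion; it is config-exposed.

The linking threshold (0.2) is applied both at pairing time and, as
`final_score_threshold`, to rescored confidences — the two are independent
configuration values that happen to share a default.

## Streaming variant

The real-time variant holds the `window_size` (default 300) most recent
**raw** frames in a ring buffer; each pushed frame evicts the oldest once
the buffer is full and reruns the batch pipeline on the buffer, emitting
only the newest frame's refined detections. During warm-up the pipeline runs
on the partial buffer from the very first frame, so the stream starts
producing output immediately (the first frame necessarily emits nothing when
singletons are dropped, since nothing can have linked yet). By construction
the streaming output at frame *t* equals the batch result on the trailing
window restricted to frame *t*; the test suite asserts this equality
exactly, per frame, on randomized streams. A 300-frame buffer covers 12 s at
25 fps; since only past frames ever enter the buffer, streaming and
whole-video batch output coincide frame-by-frame only in the limit where
the window reaches back to frame 0 and the batch pipeline is restricted to
the same causal window — at the final frame of a video shorter than the
window, the two are identical.

## Evaluation protocol

"Overlap at least 50%" is read as IoU ≥ 0.5, the standard interpretation
and the one consistent with PR-curve conventions; an alternative
`gt_coverage` mode (intersection ≥ 50% of the annotated box) is available
for sensitivity analysis. Frame matching is greedy by confidence, one to
one. Zero-denominator metrics report 0. mAP uses all-point interpolation
with right-monotonized precision (an 11-point mode is available), and is
reported both with detections pooled across videos and as the unweighted
mean of per-video APs, since the pooling is a genuine degree of freedom.
FDT for a multi-polyp video aggregates per-track latencies by mean
(max by flag); a never-detected track is reported as a distinct sentinel
(`None`), not as a number. The false-positive rate per video is the
percentage of annotation-free frames containing at least one detection; a
second mode counts frames containing a false positive over all frames.
Neither definition is canonical in the literature, so both are exposed and
the choice is recorded in the report.

## Synthetic streams

The generator emulates the statistics the post-processing relies on:
polyp tracks appearing within the first 30% of a 200-frame, 640×480,
25 fps clip, moving as a clipped random walk (2 px center step, 0.5 px size
step, sizes 60–120 px); detector jitter (σ = 2 px per coordinate), 10%
frame-wise miss rate, true-detection confidence 0.8 ± 0.1; short-lived
false positives spawning with probability 0.3 per frame with geometric
lifetimes of mean 1.5 frames and confidence 0.5 ± 0.15; rare persistent
false positives (rate 0.005 per frame, mean lifetime 100 frames) that sit
nearly still — the static, high-confidence failure mode that temporal
linking deliberately retains; and 16-dimensional embeddings drawn as
unit-normalized perturbations (noise scale 0.15) of a per-object template,
giving within-object cosine similarity around 0.7 against near 0 across
objects. These values were chosen as a plausible regime for 25 fps
colonoscopy detector output: misses and jitter small enough that tracks
mostly survive linking, false positives frequent enough to dominate the
error budget, mirroring the qualitative failure modes reported for polyp
detectors.

All randomness flows through one PCG64 generator
(`numpy.random.default_rng`) seeded once, with draws in a fixed documented
order (per frame: track emissions by ascending id, then false-positive
spawning, then false-positive emissions in spawn order), so a (config,
seed) pair reproduces a stream bit for bit across platforms.

What the simulator does **not** model: correlated detector failures
(blur, occlusion spanning many frames), confidence drift within a track,
non-box annotation geometry, multiple polyps overlapping each other, and
any appearance statistics of real tissue. Passing tests therefore
demonstrate the pipeline's algebraic and statistical behavior under the
stated noise model — not clinical performance, which requires trained
detector weights and annotated video.

## Problem sizes and numerics

The test suite and the acceptance script use 200-frame streams (ten seeds
for the suppression and headline figures), 1000-frame streams for scorer
training (2000 balanced pairs, held-out accuracy measured on an independent
stream), and exhaustive streaming/batch equivalence checks over twenty
randomized streams of 40–200 frames with window sizes from 5 to 300.
Assignment is validated against brute-force enumeration on matrices up to
5×5 (1000 instances); smoothing against an independently coded discrete
convolution at 1e-10; AP against a direct staircase integration at 1e-12.

Known numerical details: IoU is clamped to 1 against floating-point
round-off for identical boxes; assignment ties between equal-total
matchings resolve deterministically via the Hungarian implementation
(random-real scores make ties measure-zero); smoothing casts coordinate
series to float before filtering.

## File formats

* **Detections** — JSON with `video` metadata (width, height, fps,
  n_frames), an `images` list mapping image id → frame number, and
  `annotations` records `{image_id, category_id, bbox: [x, y, w, h], score,
  cc, objectness, embedding?}`. Round trips are lossless.
* **Ground truth** — JSON with `video` metadata and `tracks`
  (`{id, first_frame, boxes: {frame: [x, y, w, h]}}`); `first_frame` is
  validated against the box keys on load.
* **Scorer** — JSON `{features, coefficients: {name: weight}, intercept}`.
* **Config** — YAML whose keys mirror the `ReppConfig` /
  `SimulationConfig` field names exactly; unknown keys are rejected.

## Known limitations

* A one-frame detector miss splits a tubelet; recall of heavily flickering
  detectors degrades accordingly (no gap bridging).
* Persistent, confident false positives are retained by design; the method
  trades them for the removal of short distracting ones.
* The streaming variant recomputes the batch pipeline over the whole buffer
  each frame (O(ws) per push at typical densities); an incremental
  implementation would be needed for very large windows.
* Single-video CLI: the library evaluates multi-video datasets, but the
  `evaluate` verb operates on one detections/ground-truth pair at a time.
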