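# Methods

## AOI construction from head keypoints

A pose detector reports five head landmarks per person per frame: nose,
left/right eye, left/right ear. A landmark is treated as *visible* when its
detector confidence is at or above `confidence_threshold` (default 0.1;
pose detectors emit a confidence per keypoint, and very low-confidence
points are effectively absent). Orientation is decided purely by the
visibility count: 5 visible → frontal, 2–4 → profile, ≤ 1 → undetected (no
AOI for that head in that frame).

The AOI is an axis-aligned rectangle (or its inscribed ellipse):

- `width  = W · margin(orientation)` where `W` is the largest pairwise
  Euclidean distance between the visible landmarks;
- `height = W · aspect_ratio(orientation) · margin(orientation)`;
- centre = centroid of the visible landmarks, shifted vertically by
  `center_offset(orientation) · height` (positive = downward, toward the
  chin; pixel coordinates have y increasing downward).

Parameters, with defaults: `aspect_ratio_frontal = 1.4`,
`aspect_ratio_profile = 1.2` (faces are taller than the eye–ear span is
wide; profile spans are shorter so need less vertical stretch),
`margin_frontal = margin_profile = 1.2` (the five landmarks do not cover
the chin or hairline, and human coders include a small margin around the
face), `center_offset_* = 0`, `shape = rectangle`. These are placeholders
of plausible magnitude, not fitted values: in a real study they should be
calibrated to a sample of manual annotations (e.g. mean manual-box
dimensions relative to landmark spans). All tests parameterise them
explicitly. No head rotation is modelled beyond the frontal/profile
dichotomy, and the AOI is never rotated.

Degenerate input: if all visible landmarks coincide (`W = 0`) no
positive-area AOI exists and the head is treated as undetected (`None`),
mirroring the ≤ 1-visible case rather than raising.

A note on a tempting invariant: with the centroid-centred design, a margin
of 1 does **not** guarantee the box contains every visible landmark (the
centroid of n points can sit up to (n−1)/n of the diameter away from one of
them). Margin ≥ 1.6 does guarantee containment for ≤ 5 points, and margin 1
suffices in the two-point case; the property tests assert exactly that.

## Gaze-to-frame assignment and hit testing

The annotation grain is the 25 Hz video frame (40 ms); a duration of `d`
seconds spans `round(25·d)` frames. Eye trackers sample gaze faster than
25 Hz, so each frame's half-open window `[40f, 40f+40)` ms may hold several
samples: the valid sample nearest the frame midpoint (`40f + 20` ms)
represents the frame, ties broken toward the earlier sample. Both choices
are arbitrary but deterministic, which matters more than the choice itself.
Raw gaze coordinates are used — no fixation or attention filter, no
smoothing.

Hit testing is boundary-inclusive (rectangle: `|x−cx| ≤ w/2 ∧ |y−cy| ≤ h/2`;
oval: `((x−cx)/(w/2))² + ((y−cy)/(h/2))² ≤ 1`): manual coders deliberately
draw generous boxes, so an edge hit counts as a hit. A frame with no valid
gaze sample is labelled 0 — the output spreadsheet is strictly 0/1 (or
0/identity) with no third state; the count of missing-gaze frames is
reported in the run log instead. When a gaze point falls inside several
overlapping AOIs, the AOI with the nearest centre wins (stable under margin
changes, unlike smallest-area); ties on that distance resolve by identity
label order. The single-class annotation of a scene always equals its
multiple-class annotation with identities collapsed to 1 — this is enforced
as an oracle-equivalence test, not assumed.

## Re-identification

Each detected person per frame carries a 128-dimensional appearance
embedding produced upstream. Identity = label of the Euclidean-nearest
entry in a labelled gallery, taking the per-entry minimum (not a
per-identity mean: a mean of two wardrobe states is a point in between that
may resemble neither). There is no rejection threshold by default
(`reid_max_distance = ∞`): every detection is assigned some identity, with
`unknown` available for robustness when a threshold is configured. Distance
ties resolve lexicographically by label, then insertion order, so gallery
insertion order never changes results. Appending gallery entries is
monotone: the minimum distance to any query can only shrink.

## Agreement scoring

Cohen's kappa is computed from the frame-wise observed agreement and the
chance agreement implied by both raters' marginal label frequencies,
unweighted, over the full label set including 0. The degenerate case where
both timelines are constant and identical (p_e = 1) returns 1.0 with a
warning — the raters agree on every frame, and any other convention would
report spurious disagreement. Accuracy is the percentage of agreeing
frames; it equals the confusion-matrix diagonal share, which doubles as the
re-identification accuracy for identity-labelled timelines.

The duration difference Δ is the **net** difference of face-gaze totals
(a − b), and the normalised difference is |Δ| / video duration × 100. An
alternative frame-wise convention (disagreeing frames × 0.04 s, an upper
bound on |Δ|) is flag-selectable (`--convention framewise`); the net
convention is the default because it is the one under which the bundled
validation tables are internally consistent. Duration arithmetic is exposed
at the summary level (`duration_difference`) as well as the timeline level,
because published per-video durations are sometimes rounded to values that
are not whole multiples of 40 ms and thus cannot be rebuilt as timelines.

### Bundled validation summaries

`facegaze.datasets` ships the per-video duration summaries of a validation
study on seven clinical-consultation recordings (single-class minutes,
per-identity minutes, and two long recordings annotated with both AOI
shapes). Only the raw durations are stored; Δ, normalised Δ, means and
totals are always recomputed. One internal inconsistency in the source
material is worth noting: the prose total for manual patient face-gaze
(192.52 s) differs from the sum of the per-video column (193.38 s); the
per-video values are stored verbatim and sums are computed from them.

## Synthetic scenes

The generator emulates the study conditions the pipeline is meant for: a
full-HD (1920×1080) 25-fps scene camera, two interactors (configurable),
heads spanning ~120 px (ear-to-ear), Gaussian random-walk head motion of
2 px/frame, a 30 % chance per frame of a profile pose (nose + one ear, the
near eye dropped with probability 0.25, leaving 2–3 visible landmarks),
embedding clusters 10 apart with configurable isotropic noise, and gaze on
a face 50 % of frames. Landmarks sit at fixed canonical offsets of the head
centre; undetected landmarks carry no coordinates.

Each head walks inside its own horizontal band of the frame, with padding
chosen so AOIs can never overlap or leave the frame; a configuration whose
heads cannot fit raises a config error. Disjoint AOIs make the generative
identity of an on-face gaze point unambiguous. On-face gaze points are
drawn uniformly strictly inside the target AOI and off-face points strictly
outside all AOIs, each with a 2-px buffer, so no boundary-inclusion
convention can flip the ground truth. Ground-truth timelines are recorded
from the generative draws themselves, never by re-running the annotation —
recovery checks are therefore true oracle comparisons, and with zero
embedding noise and zero gaze jitter recovery is exact by construction
(kappa = 1, Re-ID accuracy = 100 %).

`gaze_jitter_sd` adds measurement noise after the label is fixed and
`embedding_noise_sd` widens the identity clusters; the test suite checks
that mean kappa and mean Re-ID accuracy are non-increasing along seeded
grids of these knobs (20 replicates per point, 10-s scenes — sizes chosen
to keep the whole suite fast while leaving the Monte-Carlo error an order
of magnitude below the between-level gaps). All randomness derives from a
single master seed via independent substreams (motion, pose, embeddings,
gaze), so identical configurations produce byte-identical scene files.

What the generator does **not** emulate: pose-detector localisation error
(landmarks are exact when visible), motion blur, camera/lens distortion,
AOI overlap between interactors, gaze-sample dropout, and asynchronous
gaze/video clocks. Passing recovery tests therefore demonstrates the
correctness of the AOI/annotation/re-identification logic, not the
field performance of any upstream detector.

## File formats and reproducibility

All files are plain text, UTF-8, "." decimal separator: a tab-separated
gaze file (`timestamp_ms, x_px, y_px, valid`, timestamps non-decreasing),
and comma-separated keypoint, embedding, gallery and timeline files (see
`facegaze.io`). Writers and readers round-trip losslessly; malformed input
raises a format error naming the offending line (CLI exit code 2; invalid
configuration exits 3). Timeline files round-trip bit-exactly, so a
re-annotation can be diffed against a stored one.

The acceptance script simulates a 400-s (10,000-frame) scene for the
noiseless-recovery check — long enough that any systematic geometry or
bookkeeping error would surface, short enough to run in seconds.
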