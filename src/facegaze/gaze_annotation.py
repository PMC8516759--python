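"""Per-frame gaze-to-AOI annotation at the 25 Hz spreadsheet grain.

The annotation timeline mirrors the spreadsheet a human coder produces in an
eye-tracking analysis suite: one label per 40-ms video frame. A single-class
timeline records 1 when the wearer's gaze fell inside any face AOI and 0
otherwise; a multiple-class timeline records the identity of the gazed-at
face (or 0). Raw gaze screen coordinates are used directly, without any
fixation or attention filter.

Conventions (deterministic by design):

* frame windows are half-open ``[f*40, (f+1)*40)`` ms; the sample nearest
  the frame midpoint represents the frame, ties going to the earlier sample;
* frames without a valid gaze sample are labelled 0 (the spreadsheet is
  strictly binary / categorical — missingness is counted separately);
* hit testing is boundary-inclusive;
* when a gaze point lies in several overlapping AOIs, the AOI whose centre
  is nearest wins.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .aoi_geometry import Aoi

__all__ = [
    "FRAME_RATE",
    "FRAME_MS",
    "GazeSample",
    "Timeline",
    "frames_for_duration",
    "gaze_for_frame",
    "hit_test",
    "annotate_single_class",
    "annotate_multi_class",
    "face_gaze_duration",
]

FRAME_RATE = 25          # annotation frames per second
FRAME_MS = 40            # one frame is 40 ms
FRAME_S = FRAME_MS / 1000.0

Label = Union[int, str]  # 0, 1, or an identity string


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: screen coordinates at a timestamp.

    ``valid`` is False when the tracker lost the eyes (blinks, track loss);
    invalid samples never contribute to annotation.
    """

    timestamp_ms: float
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise ValueError("timestamp_ms must be >= 0")


@dataclass(frozen=True)
class Timeline:
    """A per-40-ms label sequence at 25 Hz.

    Labels are 0/1 for a single-class (any-face) timeline, or identity
    strings / 0 for a multiple-class timeline.
    """

    labels: tuple[Label, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / FRAME_RATE

    @property
    def is_binary(self) -> bool:
        return all(lab in (0, 1) for lab in self.labels)

    def collapse_binary(self) -> "Timeline":
        """Collapse identities to 1, keeping 0 as 0 (multi -> single class)."""
        return Timeline(tuple(0 if lab == 0 else 1 for lab in self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def frames_for_duration(duration_s: float) -> int:
    """Number of 40-ms annotation frames in ``duration_s`` seconds.

    >>> frames_for_duration(421.04)
    10526
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    return round(duration_s * FRAME_RATE)


def gaze_for_frame(
    samples: Sequence[GazeSample], frame_index: int
) -> Optional[GazeSample]:
    """The valid sample representing one frame, or ``None``.

    Among the valid samples whose timestamps fall in the half-open window
    ``[frame_index*40, (frame_index+1)*40)`` ms, returns the one nearest the
    frame midpoint (``frame_index*40 + 20`` ms); on a tie the earlier sample
    wins. ``samples`` must be sorted by timestamp.
    """
    t0 = frame_index * FRAME_MS
    t1 = t0 + FRAME_MS
    mid = t0 + FRAME_MS / 2
    ts = [s.timestamp_ms for s in samples]
    lo = bisect_left(ts, t0)
    hi = bisect_right(ts, t1 - 1e-9, lo=lo)
    best: Optional[GazeSample] = None
    best_d = math.inf
    for s in samples[lo:hi]:
        if not s.valid or s.timestamp_ms >= t1:
            continue
        d = abs(s.timestamp_ms - mid)
        if d < best_d:  # strict: ties keep the earlier sample
            best, best_d = s, d
    return best


def hit_test(x: float, y: float, aoi: Aoi) -> bool:
    """Boundary-inclusive point-in-AOI test.

    Rectangle: |x - cx| <= w/2 and |y - cy| <= h/2.
    Oval: ((x - cx)/(w/2))^2 + ((y - cy)/(h/2))^2 <= 1.
    """
    dx = x - aoi.center_x
    dy = y - aoi.center_y
    if aoi.shape == "rectangle":
        return abs(dx) <= aoi.width / 2 and abs(dy) <= aoi.height / 2
    return (dx / (aoi.width / 2)) ** 2 + (dy / (aoi.height / 2)) ** 2 <= 1.0


def _hit_aois(x: float, y: float, aois: Sequence[Aoi]) -> list[Aoi]:
    return [a for a in aois if hit_test(x, y, a)]


def annotate_single_class(
    samples: Sequence[GazeSample],
    aois_by_frame: Mapping[int, Sequence[Aoi]],
    n_frames: int,
) -> Timeline:
    """Binary any-face annotation: 1 iff the frame's gaze hits any AOI.

    Frames with no valid gaze sample, or no AOIs, are 0.
    """
    labels: list[Label] = []
    for f in range(n_frames):
        g = gaze_for_frame(samples, f)
        if g is None:
            labels.append(0)
            continue
        labels.append(1 if _hit_aois(g.x, g.y, aois_by_frame.get(f, ())) else 0)
    return Timeline(tuple(labels))


def annotate_multi_class(
    samples: Sequence[GazeSample],
    aois_by_frame: Mapping[int, Sequence[Aoi]],
    n_frames: int,
) -> Timeline:
    """Identity annotation: the label of the gazed-at face AOI, or 0.

    Every AOI must carry an identity. When the gaze point lies in several
    AOIs, the one whose centre is nearest the gaze point is chosen.
    """
    labels: list[Label] = []
    for f in range(n_frames):
        g = gaze_for_frame(samples, f)
        if g is None:
            labels.append(0)
            continue
        hits = _hit_aois(g.x, g.y, aois_by_frame.get(f, ()))
        if not hits:
            labels.append(0)
            continue
        for a in hits:
            if a.identity is None:
                raise ValueError(
                    f"frame {f}: AOI without identity in multi-class annotation"
                )
        nearest = min(
            hits,
            key=lambda a: ((a.center_x - g.x) ** 2 + (a.center_y - g.y) ** 2,
                           a.identity),
        )
        labels.append(nearest.identity)
    return Timeline(tuple(labels))


def face_gaze_duration(timeline: Timeline, identity: Optional[str] = None) -> float:
    """Cumulative face-gaze time in seconds (non-zero frames x 0.04 s).

    With ``identity`` given, counts only frames labelled with that identity.
    """
    if identity is None:
        n = sum(1 for lab in timeline if lab != 0)
    else:
        n = sum(1 for lab in timeline if lab == identity)
    return n * FRAME_S
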