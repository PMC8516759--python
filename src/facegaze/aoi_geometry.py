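"""Face area-of-interest construction from head keypoints.

A pose detector (e.g. OpenPose) reports five head landmarks per detected
person: the nose, both eyes and both ears. From the subset of landmarks that
are actually visible in a frame we decide the face orientation, measure the
head span, and inflate it into a rectangular or oval area-of-interest (AOI)
that covers the whole face.

Orientation rule
----------------
* all five landmarks visible  -> frontal face
* two to four visible         -> profile face
* one or none visible         -> head undetected (no AOI)

The AOI width is the largest pairwise Euclidean distance between the visible
landmarks, scaled by a margin factor; the height is width times an
orientation-specific aspect ratio (height/width), scaled by the same margin.
The AOI is centred on the centroid of the visible landmarks, optionally
shifted vertically by a fraction of the AOI height (faces extend further
below the eye line than above it).

Coordinates are pixels, origin top-left, y increasing downward. AOIs are
axis-aligned; the oval variant is the ellipse inscribed in the rectangle.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "LANDMARK_NAMES",
    "HeadKeypoints",
    "FaceOrientation",
    "AoiParams",
    "Aoi",
    "UndetectedHeadError",
    "classify_orientation",
    "head_width",
    "build_aoi",
]

#: The five head landmarks, in canonical order.
LANDMARK_NAMES = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")


class UndetectedHeadError(ValueError):
    """Raised when an operation needs a detected head (>= 2 visible points)."""


class FaceOrientation(enum.Enum):
    FRONTAL = "frontal"
    PROFILE = "profile"
    UNDETECTED = "undetected"


@dataclass(frozen=True)
class HeadKeypoints:
    """The five head landmarks of one person in one frame.

    All five named slots are always present; absence of a landmark is
    expressed through its ``visible`` flag, never by dropping the slot.

    Parameters
    ----------
    frame_index : int
        Zero-based video frame index.
    person_index : int
        Zero-based detection index within the frame.
    xs, ys : tuple of 5 floats
        Pixel coordinates in ``LANDMARK_NAMES`` order. Coordinates of
        invisible landmarks are ignored (conventionally 0).
    visible : tuple of 5 bools
        Visibility flag per landmark.
    """

    frame_index: int
    person_index: int
    xs: tuple[float, ...]
    ys: tuple[float, ...]
    visible: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.xs) == len(self.ys) == len(self.visible) == 5):
            raise ValueError("exactly five landmarks required")
        if self.frame_index < 0 or self.person_index < 0:
            raise ValueError("frame_index and person_index must be >= 0")
        for x, y, v in zip(self.xs, self.ys, self.visible):
            if v and not (math.isfinite(x) and math.isfinite(y) and x >= 0 and y >= 0):
                raise ValueError("visible landmark coordinates must be finite and >= 0")

    @property
    def n_visible(self) -> int:
        return sum(self.visible)

    def visible_points(self) -> list[tuple[float, float]]:
        """(x, y) pairs of the visible landmarks, in canonical order."""
        return [
            (x, y) for x, y, v in zip(self.xs, self.ys, self.visible) if v
        ]

    @classmethod
    def from_named(
        cls,
        frame_index: int,
        person_index: int,
        points: dict[str, Optional[tuple[float, float]]],
    ) -> "HeadKeypoints":
        """Build from a name -> (x, y) mapping; ``None`` marks an invisible landmark."""
        xs, ys, vis = [], [], []
        for name in LANDMARK_NAMES:
            p = points.get(name)
            if p is None:
                xs.append(0.0)
                ys.append(0.0)
                vis.append(False)
            else:
                xs.append(float(p[0]))
                ys.append(float(p[1]))
                vis.append(True)
        return cls(frame_index, person_index, tuple(xs), tuple(ys), tuple(vis))


@dataclass(frozen=True)
class AoiParams:
    """Tunable AOI construction parameters.

    Aspect ratios are height/width; margins are multiplicative inflation
    factors applied to both width and height; centre offsets are signed
    fractions of the final AOI height added to the centroid y (positive =
    downward). The shipped defaults are plausible placeholders for adult
    faces and should be fitted to each study's footage.
    """

    aspect_ratio_frontal: float = 1.4
    aspect_ratio_profile: float = 1.2
    margin_frontal: float = 1.2
    margin_profile: float = 1.2
    center_offset_frontal: float = 0.0
    center_offset_profile: float = 0.0
    shape: str = "rectangle"

    def __post_init__(self) -> None:
        for name in ("aspect_ratio_frontal", "aspect_ratio_profile",
                     "margin_frontal", "margin_profile"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("center_offset_frontal", "center_offset_profile"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.shape not in ("rectangle", "oval"):
            raise ValueError("shape must be 'rectangle' or 'oval'")

    def aspect_ratio(self, orientation: FaceOrientation) -> float:
        return (self.aspect_ratio_frontal if orientation is FaceOrientation.FRONTAL
                else self.aspect_ratio_profile)

    def margin(self, orientation: FaceOrientation) -> float:
        return (self.margin_frontal if orientation is FaceOrientation.FRONTAL
                else self.margin_profile)

    def center_offset(self, orientation: FaceOrientation) -> float:
        return (self.center_offset_frontal if orientation is FaceOrientation.FRONTAL
                else self.center_offset_profile)


@dataclass(frozen=True)
class Aoi:
    """One face area-of-interest in pixel space.

    ``shape`` is ``"rectangle"`` or ``"oval"``; the oval is the axis-aligned
    ellipse inscribed in the same width x height box, so both shapes share
    centre and extents.
    """

    frame_index: int
    shape: str
    center_x: float
    center_y: float
    width: float
    height: float
    identity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("AOI width and height must be > 0")
        if self.shape not in ("rectangle", "oval"):
            raise ValueError("shape must be 'rectangle' or 'oval'")

    def with_identity(self, identity: str) -> "Aoi":
        return Aoi(self.frame_index, self.shape, self.center_x, self.center_y,
                   self.width, self.height, identity)


def classify_orientation(kp: HeadKeypoints) -> FaceOrientation:
    """Decide frontal / profile / undetected from landmark visibility.

    Frontal needs all five landmarks; two to four visible landmarks mean the
    face is turned (profile); with fewer than two the head is undetected.
    Total function: never raises.
    """
    n = kp.n_visible
    if n == 5:
        return FaceOrientation.FRONTAL
    if n >= 2:
        return FaceOrientation.PROFILE
    return FaceOrientation.UNDETECTED


def head_width(kp: HeadKeypoints) -> float:
    """Largest pairwise distance between the visible landmarks, in pixels.

    Raises
    ------
    UndetectedHeadError
        If fewer than two landmarks are visible.
    """
    pts = kp.visible_points()
    if len(pts) < 2:
        raise UndetectedHeadError(
            f"frame {kp.frame_index} person {kp.person_index}: "
            f"{len(pts)} visible landmark(s), head undetected"
        )
    return max(
        math.hypot(ax - bx, ay - by)
        for i, (ax, ay) in enumerate(pts)
        for bx, by in pts[i + 1:]
    )


def build_aoi(kp: HeadKeypoints, params: AoiParams) -> Optional[Aoi]:
    """Construct the face AOI for one head, or ``None`` if undetected.

    width  = head_width * margin(orientation)
    height = head_width * aspect_ratio(orientation) * margin(orientation)
    centre = centroid of visible landmarks, y shifted by
             center_offset(orientation) * height.

    A degenerate detection whose visible landmarks all coincide (zero head
    width) also yields ``None``: it cannot support a positive-area AOI.
    """
    orientation = classify_orientation(kp)
    if orientation is FaceOrientation.UNDETECTED:
        return None
    w0 = head_width(kp)
    if w0 == 0:
        return None
    margin = params.margin(orientation)
    width = w0 * margin
    height = w0 * params.aspect_ratio(orientation) * margin
    pts = kp.visible_points()
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)
    cy += params.center_offset(orientation) * height
    return Aoi(kp.frame_index, params.shape, cx, cy, width, height)
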