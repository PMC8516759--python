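"""Synthetic dyadic/triadic interaction scenes with known ground truth.

Emulates what the pipeline consumes from a wearable eye tracker and a pose
detector — per-frame head keypoints of several interactors, raw gaze
samples, appearance embeddings and a labelled gallery — together with the
ground-truth per-frame annotation timelines, so every stage is testable
without any video.

Generative model
----------------
* Each identity is one head following a bounded Gaussian random walk inside
  its own horizontal band of the frame (bands keep face AOIs disjoint, so
  the ground-truth identity of an on-face gaze point is unambiguous).
* Per frame a head is frontal (all five landmarks visible) with probability
  ``1 - profile_prob``, otherwise profile: one side of the face (nose, one
  eye, one ear) with the eye further dropped with ``dropout_prob``, leaving
  2-3 visible landmarks. Landmarks sit at fixed canonical offsets scaled by
  ``head_scale``; the ear-to-ear span of a frontal face equals
  ``head_scale`` pixels.
* One gaze sample per 40-ms frame, at the frame midpoint. With probability
  ``gaze_on_face_prob`` it targets a uniformly chosen face, drawn strictly
  inside that face's AOI with a 2-pixel buffer; otherwise strictly outside
  every AOI (same buffer), so boundary conventions can never flip the
  ground truth. ``gaze_jitter_sd`` adds measurement noise after the ground
  truth label is fixed.
* Embeddings are identity-specific Gaussian clusters: centroids pairwise
  ``embedding_centroid_separation`` apart in 128 dimensions, isotropic
  noise ``embedding_noise_sd`` per component. The gallery holds one
  noiseless centroid entry per identity.

Ground-truth timelines come from the generative choices themselves, never
from re-running the annotation pipeline, which makes recovery checks a true
oracle comparison. Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .agreement import cohens_kappa, confusion_matrix
from .aoi_geometry import Aoi, AoiParams, HeadKeypoints, build_aoi
from .config import ConfigError
from .gaze_annotation import (
    FRAME_MS,
    GazeSample,
    Timeline,
    annotate_multi_class,
    annotate_single_class,
    frames_for_duration,
)
from .io import EmbeddingRecord
from .reid import Gallery, assign_identity

__all__ = [
    "SceneConfig",
    "SimulatedScene",
    "RecoveryResult",
    "simulate_scene",
    "pipeline_recovery_check",
    "write_scene",
]

#: Strict interior/exterior buffer (pixels) between generated gaze points
#: and AOI boundaries.
BUFFER_PX = 2.0

# Canonical landmark offsets (x, y) in units of head_scale, relative to the
# head centre: nose, left_eye, right_eye, left_ear, right_ear. Ear-to-ear
# span = 1.0 head_scale.
_CANON = np.array([
    (0.00, 0.10),
    (-0.18, -0.12),
    (0.18, -0.12),
    (-0.50, 0.00),
    (0.50, 0.00),
])


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated interaction scene.

    Defaults emulate a one-minute dyadic consultation filmed by a
    full-HD 25-fps scene camera: two interactors whose faces span about
    120 px, moderate head motion, occasional profile turns with landmark
    dropout, well-separated appearance clusters, and gaze that is on a face
    about half the time.
    """

    n_identities: int = 2
    duration_s: float = 60.0
    frame_width: int = 1920
    frame_height: int = 1080
    head_scale: float = 120.0
    motion_step_sd: float = 2.0
    profile_prob: float = 0.3
    dropout_prob: float = 0.25
    embedding_centroid_separation: float = 10.0
    embedding_noise_sd: float = 0.0
    gaze_on_face_prob: float = 0.5
    gaze_jitter_sd: float = 0.0
    seed: int = 0
    aoi: AoiParams = field(default_factory=AoiParams)

    def __post_init__(self) -> None:
        if self.n_identities < 1:
            raise ConfigError("n_identities must be >= 1")
        if self.duration_s <= 0 or self.head_scale <= 0:
            raise ConfigError("duration_s and head_scale must be > 0")
        for name in ("profile_prob", "dropout_prob", "gaze_on_face_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.motion_step_sd < 0 or self.embedding_noise_sd < 0 \
                or self.gaze_jitter_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")

    @property
    def identity_labels(self) -> tuple[str, ...]:
        return tuple(f"person{i:02d}" for i in range(self.n_identities))


@dataclass(frozen=True)
class SimulatedScene:
    """One simulated scene: pipeline inputs plus ground truth."""

    config: SceneConfig
    keypoints: tuple[HeadKeypoints, ...]
    gaze: tuple[GazeSample, ...]
    embeddings: tuple[EmbeddingRecord, ...]
    gallery: Gallery
    truth_single: Timeline
    truth_multi: Timeline
    #: ground-truth AOIs by frame (identity-tagged), as generated
    truth_aois: dict[int, tuple[Aoi, ...]]

    @property
    def n_frames(self) -> int:
        return len(self.truth_single)


def _pads(cfg: SceneConfig) -> tuple[float, float]:
    s = cfg.head_scale
    p = cfg.aoi
    max_margin = max(p.margin_frontal, p.margin_profile)
    max_aspect = max(p.aspect_ratio_frontal, p.aspect_ratio_profile)
    max_off = max(abs(p.center_offset_frontal), abs(p.center_offset_profile))
    pad_x = s * max_margin / 2 + s / 2 + BUFFER_PX + 2
    pad_y = (s * max_aspect * max_margin / 2 * (1 + 2 * max_off)
             + s / 2 + BUFFER_PX + 2)
    return pad_x, pad_y


def simulate_scene(config: SceneConfig) -> SimulatedScene:
    """Generate one deterministic scene from ``config``.

    Raises
    ------
    ConfigError
        If the requested heads cannot fit in the frame with the configured
        AOI parameters (bands too narrow or frame too low).
    """
    n_frames = frames_for_duration(config.duration_s)
    n = config.n_identities
    pad_x, pad_y = _pads(config)
    band_w = config.frame_width / n
    if band_w <= 2 * pad_x or config.frame_height <= 2 * pad_y:
        raise ConfigError(
            f"{n} head(s) of scale {config.head_scale} px cannot fit in a "
            f"{config.frame_width}x{config.frame_height} frame"
        )

    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_motion = np.random.default_rng(streams[0])
    rng_pose = np.random.default_rng(streams[1])
    rng_emb = np.random.default_rng(streams[2])
    rng_gaze = np.random.default_rng(streams[3])

    labels = config.identity_labels
    s = config.head_scale

    # head-centre random walks, one band per identity
    lo_x = np.array([i * band_w + pad_x for i in range(n)])
    hi_x = np.array([(i + 1) * band_w - pad_x for i in range(n)])
    centers = np.empty((n_frames, n, 2))
    cx = (lo_x + hi_x) / 2 + rng_motion.uniform(-0.1, 0.1, n) * (hi_x - lo_x)
    cy = np.full(n, config.frame_height / 2) \
        + rng_motion.uniform(-0.1, 0.1, n) * (config.frame_height - 2 * pad_y)
    for f in range(n_frames):
        step = rng_motion.normal(0.0, config.motion_step_sd, (n, 2))
        cx = np.clip(cx + step[:, 0], lo_x, hi_x)
        cy = np.clip(cy + step[:, 1], pad_y, config.frame_height - pad_y)
        centers[f, :, 0] = cx
        centers[f, :, 1] = cy

    # keypoints + ground-truth AOIs
    keypoints: list[HeadKeypoints] = []
    truth_aois: dict[int, tuple[Aoi, ...]] = {}
    for f in range(n_frames):
        frame_aois: list[Aoi] = []
        for p in range(n):
            xs = centers[f, p, 0] + _CANON[:, 0] * s
            ys = centers[f, p, 1] + _CANON[:, 1] * s
            if rng_pose.random() < config.profile_prob:
                side = (1, 3) if rng_pose.random() < 0.5 else (2, 4)
                vis = [False] * 5
                vis[0] = True           # nose
                vis[side[1]] = True     # ear
                if rng_pose.random() >= config.dropout_prob:
                    vis[side[0]] = True  # eye
                visible = tuple(vis)
            else:
                visible = (True,) * 5
            # undetected landmarks carry no coordinates
            kp = HeadKeypoints(
                f, p,
                tuple(float(x) if v else 0.0 for x, v in zip(xs, visible)),
                tuple(float(y) if v else 0.0 for y, v in zip(ys, visible)),
                visible,
            )
            keypoints.append(kp)
            aoi = build_aoi(kp, config.aoi)
            assert aoi is not None  # generator always leaves >= 2 visible
            frame_aois.append(aoi.with_identity(labels[p]))
        truth_aois[f] = tuple(frame_aois)

    # embeddings: orthogonal centroids at pairwise distance `separation`
    dim = 128
    centroids = np.zeros((n, dim))
    for i in range(n):
        centroids[i, i] = config.embedding_centroid_separation / math.sqrt(2)
    gallery = Gallery(dim=dim)
    for i, lab in enumerate(labels):
        gallery.add(lab, centroids[i])
    embeddings: list[EmbeddingRecord] = []
    for f in range(n_frames):
        noise = rng_emb.normal(0.0, config.embedding_noise_sd, (n, dim)) \
            if config.embedding_noise_sd > 0 else np.zeros((n, dim))
        for p in range(n):
            embeddings.append(EmbeddingRecord(f, p, centroids[p] + noise[p]))

    # gaze: ground-truth label fixed by the generative draw, then jitter
    gaze: list[GazeSample] = []
    multi: list = []
    for f in range(n_frames):
        t = f * FRAME_MS + FRAME_MS / 2
        if rng_gaze.random() < config.gaze_on_face_prob:
            target = int(rng_gaze.integers(n))
            aoi = truth_aois[f][target]
            x, y = _point_inside(aoi, rng_gaze)
            multi.append(labels[target])
        else:
            x, y = _point_outside(truth_aois[f], config, rng_gaze)
            multi.append(0)
        if config.gaze_jitter_sd > 0:
            x += rng_gaze.normal(0.0, config.gaze_jitter_sd)
            y += rng_gaze.normal(0.0, config.gaze_jitter_sd)
            x = float(np.clip(x, 0, config.frame_width))
            y = float(np.clip(y, 0, config.frame_height))
        gaze.append(GazeSample(t, x, y, True))

    truth_multi = Timeline(tuple(multi))
    return SimulatedScene(
        config=config,
        keypoints=tuple(keypoints),
        gaze=tuple(gaze),
        embeddings=tuple(embeddings),
        gallery=gallery,
        truth_single=truth_multi.collapse_binary(),
        truth_multi=truth_multi,
        truth_aois=truth_aois,
    )


def _point_inside(aoi: Aoi, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point strictly inside the AOI, BUFFER_PX off the boundary."""
    hw = aoi.width / 2 - BUFFER_PX
    hh = aoi.height / 2 - BUFFER_PX
    if hw <= 0 or hh <= 0:
        raise ConfigError("AOI too small for the interior gaze buffer")
    if aoi.shape == "oval":
        r = math.sqrt(rng.random())
        phi = rng.uniform(0, 2 * math.pi)
        return (aoi.center_x + hw * r * math.cos(phi),
                aoi.center_y + hh * r * math.sin(phi))
    return (aoi.center_x + rng.uniform(-hw, hw),
            aoi.center_y + rng.uniform(-hh, hh))


def _point_outside(
    aois: Sequence[Aoi], config: SceneConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform in-frame point strictly outside every AOI's buffered box."""
    for _ in range(1000):
        x = rng.uniform(0, config.frame_width)
        y = rng.uniform(0, config.frame_height)
        if all(
            abs(x - a.center_x) > a.width / 2 + BUFFER_PX
            or abs(y - a.center_y) > a.height / 2 + BUFFER_PX
            for a in aois
        ):
            return x, y
    raise ConfigError("could not place an off-face gaze point (AOIs fill frame)")


@dataclass(frozen=True)
class RecoveryResult:
    """Pipeline-vs-ground-truth scores on one simulated scene."""

    kappa: float
    reid_accuracy_pct: float
    multi_kappa: float


def pipeline_recovery_check(config: SceneConfig) -> RecoveryResult:
    """Run the full pipeline on a simulated scene and score it against truth.

    Rebuilds AOIs from the generated keypoints, annotates the generated gaze
    (single- and multi-class, identities assigned by gallery matching of the
    generated embeddings) and compares against the ground-truth timelines:
    single-class Cohen's kappa, multi-class kappa, and re-identification
    accuracy (confusion-matrix diagonal share). With zero embedding noise
    and zero gaze jitter, recovery is exact by construction.
    """
    scene = simulate_scene(config)
    n_frames = scene.n_frames

    ident_by_fp = {
        (r.frame_index, r.person_index):
            assign_identity(r.vector, scene.gallery)
        for r in scene.embeddings
    }
    aois_by_frame: dict[int, list[Aoi]] = {}
    for kp in scene.keypoints:
        aoi = build_aoi(kp, config.aoi)
        if aoi is None:
            continue
        label = ident_by_fp[(kp.frame_index, kp.person_index)]
        aois_by_frame.setdefault(kp.frame_index, []).append(
            aoi.with_identity(label)
        )

    single = annotate_single_class(scene.gaze, aois_by_frame, n_frames)
    multi = annotate_multi_class(scene.gaze, aois_by_frame, n_frames)
    cm = confusion_matrix(scene.truth_multi, multi)
    return RecoveryResult(
        kappa=cohens_kappa(scene.truth_single, single),
        reid_accuracy_pct=cm.accuracy_pct,
        multi_kappa=cohens_kappa(scene.truth_multi, multi),
    )


def write_scene(scene: SimulatedScene, directory: Union[str, Path]) -> Path:
    """Write a scene as the pipeline's file dialects into ``directory``.

    Emits ``keypoints.csv``, ``gaze.tsv``, ``embeddings.csv``,
    ``gallery.csv``, ``truth_single.csv`` and ``truth_multi.csv``.
    """
    from . import io  # local import to keep module load cheap

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    io.write_keypoints(directory / "keypoints.csv", scene.keypoints)
    io.write_gaze(directory / "gaze.tsv", scene.gaze)
    io.write_embeddings(directory / "embeddings.csv", scene.embeddings)
    io.write_gallery(directory / "gallery.csv", scene.gallery)
    io.write_timeline(directory / "truth_single.csv", scene.truth_single)
    io.write_timeline(directory / "truth_multi.csv", scene.truth_multi)
    return directory
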