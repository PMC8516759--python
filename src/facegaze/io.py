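"""Readers and writers for the pipeline's plain-text file dialects.

All files are UTF-8; CSV files are comma-separated with "." as the decimal
separator; the gaze file is tab-separated (the common wearable-eye-tracker
export dialect). Every writer's output is accepted by the corresponding
reader. Malformed input raises :class:`FormatError` naming the offending
line.

Dialects
--------
gaze (TSV)       ``timestamp_ms  x_px  y_px  valid`` — timestamps must be
                 non-decreasing; ``valid`` is 0/1.
keypoints (CSV)  ``frame,person,<lm>_x,<lm>_y,<lm>_c`` for the five head
                 landmarks ``nose, leye, reye, lear, rear``; a missing
                 landmark is encoded as empty coordinate fields with
                 confidence 0. A landmark counts as visible when its
                 confidence is at or above a threshold (default 0.1).
embeddings (CSV) ``frame,person,e0..e127``.
gallery (CSV)    ``label,e0..e127``.
timeline (CSV)   ``frame,label`` with labels 0/1 or identity strings;
                 round-trips bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .aoi_geometry import HeadKeypoints
from .gaze_annotation import GazeSample, Timeline
from .reid import EMBEDDING_DIM, Gallery

__all__ = [
    "FormatError",
    "EmbeddingRecord",
    "read_gaze", "write_gaze",
    "read_keypoints", "write_keypoints",
    "read_embeddings", "write_embeddings",
    "read_gallery", "write_gallery",
    "read_timeline", "write_timeline",
]

PathLike = Union[str, Path]

_GAZE_HEADER = ["timestamp_ms", "x_px", "y_px", "valid"]
_KP_LANDMARKS = ["nose", "leye", "reye", "lear", "rear"]
_KP_HEADER = ["frame", "person"] + [
    f"{lm}_{suffix}" for lm in _KP_LANDMARKS for suffix in ("x", "y", "c")
]
_EMB_COLS = [f"e{i}" for i in range(EMBEDDING_DIM)]


class FormatError(ValueError):
    """A file does not conform to its dialect; the message names the line."""


def _fail(path: PathLike, line: int, msg: str) -> None:
    raise FormatError(f"{path}:{line}: {msg}")


def _check_header(path: PathLike, row: Optional[list[str]], expected: list[str]) -> None:
    if row is None or [c.strip() for c in row] != expected:
        raise FormatError(
            f"{path}:1: expected header {','.join(expected)!r}, "
            f"got {','.join(row) if row else '<empty file>'!r}"
        )


def _rows(path: PathLike, delimiter: str):
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.reader(fh, delimiter=delimiter)


# ---------------------------------------------------------------- gaze TSV

def read_gaze(path: PathLike) -> list[GazeSample]:
    """Read a gaze TSV; timestamps must be non-decreasing."""
    samples: list[GazeSample] = []
    prev_ts = -np.inf
    rows = _rows(path, "\t")
    _check_header(path, next(rows, None), _GAZE_HEADER)
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != 4:
            _fail(path, lineno, f"expected 4 fields, got {len(row)}")
        try:
            ts, x, y = float(row[0]), float(row[1]), float(row[2])
            valid = bool(int(row[3]))
        except ValueError:
            _fail(path, lineno, f"malformed gaze row: {row!r}")
        if ts < prev_ts:
            _fail(path, lineno, f"timestamp {ts} decreases (previous {prev_ts})")
        prev_ts = ts
        samples.append(GazeSample(ts, x, y, valid))
    return samples


def write_gaze(path: PathLike, samples: Iterable[GazeSample]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_GAZE_HEADER)
        for s in samples:
            w.writerow([_fmt(s.timestamp_ms), _fmt(s.x), _fmt(s.y), int(s.valid)])


# ----------------------------------------------------------- keypoints CSV

def read_keypoints(
    path: PathLike, confidence_threshold: float = 0.1
) -> list[HeadKeypoints]:
    """Read per-frame head keypoints; visibility = confidence >= threshold."""
    out: list[HeadKeypoints] = []
    rows = _rows(path, ",")
    _check_header(path, next(rows, None), _KP_HEADER)
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != len(_KP_HEADER):
            _fail(path, lineno, f"expected {len(_KP_HEADER)} fields, got {len(row)}")
        try:
            frame, person = int(row[0]), int(row[1])
            xs, ys, vis = [], [], []
            for i in range(5):
                fx, fy, fc = row[2 + 3 * i: 5 + 3 * i]
                c = float(fc) if fc.strip() else 0.0
                visible = c >= confidence_threshold and fx.strip() != ""
                xs.append(float(fx) if fx.strip() else 0.0)
                ys.append(float(fy) if fy.strip() else 0.0)
                vis.append(visible)
            out.append(HeadKeypoints(frame, person, tuple(xs), tuple(ys), tuple(vis)))
        except (ValueError, IndexError) as exc:
            if isinstance(exc, FormatError):
                raise
            _fail(path, lineno, f"malformed keypoint row: {row!r}")
    return out


def write_keypoints(path: PathLike, keypoints: Iterable[HeadKeypoints]) -> None:
    """Write keypoints; visible landmarks get confidence 1, invisible empty/0."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_KP_HEADER)
        for kp in keypoints:
            row: list = [kp.frame_index, kp.person_index]
            for x, y, v in zip(kp.xs, kp.ys, kp.visible):
                row += [_fmt(x), _fmt(y), 1] if v else ["", "", 0]
            w.writerow(row)


# ---------------------------------------------------------- embeddings CSV

@dataclass(frozen=True)
class EmbeddingRecord:
    """One appearance embedding for one detected person in one frame."""
    frame_index: int
    person_index: int
    vector: np.ndarray


def read_embeddings(path: PathLike) -> list[EmbeddingRecord]:
    out: list[EmbeddingRecord] = []
    rows = _rows(path, ",")
    _check_header(path, next(rows, None), ["frame", "person"] + _EMB_COLS)
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != 2 + EMBEDDING_DIM:
            _fail(path, lineno,
                  f"expected {2 + EMBEDDING_DIM} fields, got {len(row)}")
        try:
            out.append(EmbeddingRecord(
                int(row[0]), int(row[1]),
                np.array([float(v) for v in row[2:]], dtype=float),
            ))
        except ValueError:
            _fail(path, lineno, "malformed embedding row")
    return out


def write_embeddings(path: PathLike, records: Iterable[EmbeddingRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "person"] + _EMB_COLS)
        for r in records:
            w.writerow([r.frame_index, r.person_index] + [_fmt(v) for v in r.vector])


# ------------------------------------------------------------- gallery CSV

def read_gallery(path: PathLike) -> Gallery:
    gallery = Gallery(dim=EMBEDDING_DIM)
    rows = _rows(path, ",")
    _check_header(path, next(rows, None), ["label"] + _EMB_COLS)
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != 1 + EMBEDDING_DIM:
            _fail(path, lineno,
                  f"expected {1 + EMBEDDING_DIM} embedding components, "
                  f"got {len(row) - 1}")
        if not row[0]:
            _fail(path, lineno, "empty gallery label")
        try:
            gallery.add(row[0], [float(v) for v in row[1:]])
        except ValueError:
            _fail(path, lineno, "malformed gallery row")
    return gallery


def write_gallery(path: PathLike, gallery: Gallery) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label"] + _EMB_COLS)
        for entry in gallery.entries:
            w.writerow([entry.label] + [_fmt(v) for v in entry.vector])


# ------------------------------------------------------------ timeline CSV

def read_timeline(path: PathLike) -> Timeline:
    """Read a per-frame label timeline; frames must be 0..n-1 in order."""
    labels: list = []
    rows = _rows(path, ",")
    _check_header(path, next(rows, None), ["frame", "label"])
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != 2:
            _fail(path, lineno, f"expected 2 fields, got {len(row)}")
        try:
            frame = int(row[0])
        except ValueError:
            _fail(path, lineno, f"malformed frame index {row[0]!r}")
        if frame != len(labels):
            _fail(path, lineno, f"expected frame {len(labels)}, got {frame}")
        lab = row[1]
        labels.append(int(lab) if lab in ("0", "1") else lab)
    return Timeline(tuple(labels))


def write_timeline(path: PathLike, timeline: Timeline) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "label"])
        for f, lab in enumerate(timeline):
            w.writerow([f, lab])


def _fmt(v: float) -> str:
    """Compact, round-trip-exact float formatting (repr semantics)."""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)
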