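"""Agreement scoring between two annotation timelines.

Compares a manual (reference) timeline against an automated one, frame by
frame, the way semi-automated annotation tools are validated:

* Cohen's kappa, chance-corrected agreement
  ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed frame-wise
  agreement and ``p_e`` the chance agreement implied by each rater's
  marginal label frequencies — plain (unweighted) kappa, for binary and
  multi-label timelines alike;
* frame-by-frame accuracy, the percentage of frames on which the two
  timelines agree;
* face-gaze duration difference ``delta = duration_a - duration_b`` and its
  normalised form ``|delta| / total duration x 100`` (percent of the
  video). The default is this net-of-totals convention; a frame-wise
  convention (mismatched frames x 0.04 s) is also available;
* per-identity confusion matrices (manual rows, algorithm columns) with
  re-identification accuracy = diagonal share of frames.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .gaze_annotation import FRAME_S, Timeline, face_gaze_duration

__all__ = [
    "AgreementReport",
    "ConfusionMatrix",
    "cohens_kappa",
    "accuracy",
    "duration_difference",
    "normalized_difference",
    "confusion_matrix",
    "compare_timelines",
]

logger = logging.getLogger(__name__)

Label = Union[int, str]


def _check_equal_length(a: Timeline, b: Timeline) -> int:
    if len(a) != len(b):
        raise ValueError(f"timeline length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("timelines are empty")
    return len(a)


def cohens_kappa(a: Timeline, b: Timeline) -> float:
    """Chance-corrected frame-wise agreement between two timelines.

    Degenerate case: when both raters use a single identical label
    everywhere, chance agreement p_e = 1 and the ratio is undefined; 1.0 is
    returned by convention (and logged), since the raters agree everywhere.
    """
    n = _check_equal_length(a, b)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    ca, cb = Counter(a.labels), Counter(b.labels)
    labels = set(ca) | set(cb)
    p_e = sum((ca.get(lab, 0) / n) * (cb.get(lab, 0) / n) for lab in labels)
    if p_e == 1.0:
        logger.warning(
            "both timelines are constant and identical; kappa undefined, "
            "returning 1.0 by convention"
        )
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def accuracy(a: Timeline, b: Timeline) -> float:
    """Percentage of frames on which the two timelines agree."""
    n = _check_equal_length(a, b)
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / n


def duration_difference(
    duration_a_s: float, duration_b_s: float, total_s: float
) -> tuple[float, float]:
    """Signed duration difference and its normalised percentage.

    Returns ``(delta, normalized_pct)`` with ``delta = a - b`` in seconds
    and ``normalized_pct = |delta| / total_s x 100``. Operates on summary
    durations directly so it applies both to timelines and to published
    per-video duration tables.
    """
    if total_s <= 0:
        raise ValueError("total duration must be > 0")
    delta = duration_a_s - duration_b_s
    return delta, abs(delta) / total_s * 100.0


def normalized_difference(
    a: Timeline, b: Timeline, convention: str = "net"
) -> tuple[float, float]:
    """Face-gaze duration difference between two timelines.

    ``convention="net"`` (default): delta of total face-gaze durations,
    normalised by the video duration. ``convention="framewise"``: delta is
    the (unsigned) disagreement time, mismatched frames x 0.04 s, an upper
    bound on |net delta|.
    """
    n = _check_equal_length(a, b)
    total_s = n * FRAME_S
    if convention == "net":
        return duration_difference(
            face_gaze_duration(a), face_gaze_duration(b), total_s
        )
    if convention == "framewise":
        delta = sum(1 for x, y in zip(a, b) if x != y) * FRAME_S
        return delta, delta / total_s * 100.0
    raise ValueError("convention must be 'net' or 'framewise'")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Frame counts of (manual label, algorithm label) pairs.

    Rows are manual labels, columns algorithm labels, in ``labels`` order
    (0 first, then identities sorted). ``accuracy_pct`` is the diagonal
    share of frames — the re-identification accuracy when both timelines
    are identity-labelled.
    """

    labels: tuple[Label, ...]
    counts: np.ndarray  # shape (n_labels, n_labels), manual rows

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.n_frames

    def per_identity_accuracy(self) -> dict[Label, float]:
        """Row-wise recall per manual label, in percent (NaN for empty rows)."""
        out: dict[Label, float] = {}
        for i, lab in enumerate(self.labels):
            row = self.counts[i].sum()
            out[lab] = 100.0 * self.counts[i, i] / row if row else float("nan")
        return out

    def collapse_binary(self) -> "ConfusionMatrix":
        """Collapse identities to a single face class (0 vs non-zero)."""
        idx = [0 if lab == 0 else 1 for lab in self.labels]
        counts = np.zeros((2, 2), dtype=int)
        for i, ri in enumerate(idx):
            for j, cj in enumerate(idx):
                counts[ri, cj] += self.counts[i, j]
        return ConfusionMatrix((0, 1), counts)


def confusion_matrix(manual: Timeline, algorithm: Timeline) -> ConfusionMatrix:
    """Identity confusion between a manual and an automated timeline."""
    _check_equal_length(manual, algorithm)
    idents = sorted(
        {lab for lab in (*manual.labels, *algorithm.labels) if lab != 0},
        key=str,
    )
    labels: tuple[Label, ...] = (0, *idents)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for m, g in zip(manual, algorithm):
        counts[index[m], index[g]] += 1
    return ConfusionMatrix(labels, counts)


@dataclass(frozen=True)
class AgreementReport:
    """Per-video agreement summary between two timelines.

    ``delta_s`` is signed (a - b); ``normalized_delta_pct`` is
    ``|delta| / video duration x 100``.
    """

    kappa: float
    accuracy_pct: float
    duration_a_s: float
    duration_b_s: float
    delta_s: float
    normalized_delta_pct: float
    n_frames: int
    reid_accuracy_pct: Optional[float] = None


def compare_timelines(
    a: Timeline, b: Timeline, convention: str = "net"
) -> AgreementReport:
    """Full agreement report between two equal-length timelines.

    Re-ID accuracy is included when either timeline carries identity labels
    (it then equals the confusion-matrix diagonal share).
    """
    n = _check_equal_length(a, b)
    delta, norm = normalized_difference(a, b, convention=convention)
    reid_acc = None
    if not (a.is_binary and b.is_binary):
        reid_acc = confusion_matrix(a, b).accuracy_pct
    return AgreementReport(
        kappa=cohens_kappa(a, b),
        accuracy_pct=accuracy(a, b),
        duration_a_s=face_gaze_duration(a),
        duration_b_s=face_gaze_duration(b),
        delta_s=delta,
        normalized_delta_pct=norm,
        n_frames=n,
        reid_accuracy_pct=reid_acc,
    )
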