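"""Bundled per-video face-gaze duration summaries from a clinical validation.

These small tables summarise a validation of the automated pipeline against
manual annotation on seven wearable eye-tracking recordings of clinical
consultations: for each video, the duration and the total face-gaze time
according to the human coder and to the algorithm (single-class any-face,
multiple-class per-identity, and two long recordings annotated with both
rectangular and oval AOIs). They serve as reference inputs for the duration
arithmetic in :mod:`facegaze.agreement` — the signed duration difference and
its video-length-normalised percentage are recomputed from these durations,
not stored.
"""

from __future__ import annotations

import pandas as pd

from .agreement import duration_difference

__all__ = [
    "single_class_minutes",
    "multi_class_minutes",
    "long_videos",
    "single_class_summary",
    "multi_class_summary",
    "long_video_summary",
]

# First minute of each of the seven videos: total any-face gaze (s),
# manual coder vs algorithm.
_SINGLE = [
    # video, duration_s, manual_s, algorithm_s
    (1, 59.84, 30.44, 30.60),
    (2, 60.50, 27.00, 26.60),
    (3, 60.04, 30.08, 31.40),
    (4, 60.46, 35.36, 36.56),
    (5, 60.20, 24.80, 26.00),
    (6, 60.00, 24.64, 26.68),
    (7, 60.00, 34.40, 34.56),
]

# Same minutes, per-identity face-gaze durations (s). Videos show a patient
# and a researcher; video 7 additionally a caregiver.
_MULTI = [
    # video, duration_s, manual (patient, caregiver, researcher),
    #                    algorithm (patient, caregiver, researcher)
    (1, 59.84, 30.16, 0.00, 0.28, 30.44, 0.00, 0.16),
    (2, 60.50, 26.90, 0.00, 0.10, 26.50, 0.00, 0.10),
    (3, 60.04, 28.76, 0.00, 1.32, 30.16, 0.00, 1.24),
    (4, 60.46, 34.20, 0.00, 1.16, 35.72, 0.00, 0.84),
    (5, 60.20, 24.80, 0.00, 0.00, 26.00, 0.00, 0.00),
    (6, 60.00, 24.56, 0.00, 0.08, 26.56, 0.00, 0.12),
    (7, 60.00, 24.00, 10.36, 0.04, 23.68, 10.80, 0.08),
]

# Two full-length recordings, manually annotated twice (rectangular and
# oval AOI shape); the algorithm total is shape-independent here because the
# single-class algorithm ran with its default rectangular AOIs.
_LONG = [
    # video, aoi_shape, duration_s, manual_s, algorithm_s
    (6, "rectangle", 1102.76, 173.92, 183.52),
    (6, "oval", 1102.76, 174.60, 183.52),
    (7, "rectangle", 758.92, 229.16, 239.40),
    (7, "oval", 758.92, 209.24, 239.40),
]


def single_class_minutes() -> pd.DataFrame:
    """Single-class (any-face) durations for the seven one-minute excerpts."""
    return pd.DataFrame(
        _SINGLE, columns=["video", "duration_s", "manual_s", "algorithm_s"]
    )


def multi_class_minutes() -> pd.DataFrame:
    """Per-identity durations for the seven one-minute excerpts."""
    return pd.DataFrame(
        _MULTI,
        columns=[
            "video", "duration_s",
            "manual_patient_s", "manual_caregiver_s", "manual_researcher_s",
            "algo_patient_s", "algo_caregiver_s", "algo_researcher_s",
        ],
    )


def long_videos() -> pd.DataFrame:
    """Full-length durations for the two long recordings, by AOI shape."""
    return pd.DataFrame(
        _LONG,
        columns=["video", "aoi_shape", "duration_s", "manual_s", "algorithm_s"],
    )


def _with_differences(df: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    deltas, norms = [], []
    for _, row in df.iterrows():
        d, n = duration_difference(row[a], row[b], row["duration_s"])
        deltas.append(d)
        norms.append(n)
    out = df.copy()
    out["delta_s"] = deltas
    out["normalized_delta_pct"] = norms
    return out


def single_class_summary() -> pd.DataFrame:
    """Single-class table with recomputed delta_s and normalized_delta_pct."""
    return _with_differences(single_class_minutes(), "manual_s", "algorithm_s")


def multi_class_summary() -> pd.DataFrame:
    """Multi-class table with totals over identities and recomputed differences."""
    df = multi_class_minutes().copy()
    df["manual_total_s"] = (
        df.manual_patient_s + df.manual_caregiver_s + df.manual_researcher_s
    )
    df["algo_total_s"] = (
        df.algo_patient_s + df.algo_caregiver_s + df.algo_researcher_s
    )
    return _with_differences(df, "manual_total_s", "algo_total_s")


def long_video_summary() -> pd.DataFrame:
    """Long-recording table with recomputed differences."""
    return _with_differences(long_videos(), "manual_s", "algorithm_s")
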