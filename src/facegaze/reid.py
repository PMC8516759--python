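"""Person re-identification by Euclidean nearest neighbour in embedding space.

Each detected person carries a 128-dimensional appearance embedding produced
upstream (e.g. by a ResNet re-identification network). Identities are
assigned by comparing the query embedding against a gallery of labelled
embeddings and taking the label of the closest entry (per-entry minimum, not
per-identity average). A few labelled occurrences per person suffice; adding
entries over the course of a recording — for instance after a wardrobe
change — only ever improves the match, since the minimum distance to any
identity can only shrink.

Ties (exactly equal distances) resolve to the lexicographically smallest
label, then the earliest-added entry, so runs are reproducible regardless of
gallery insertion order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EMBEDDING_DIM",
    "Gallery",
    "embedding_distance",
    "assign_identity",
    "update_gallery",
]

EMBEDDING_DIM = 128


def _as_vector(v, dim: Optional[int] = None) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("embedding components must be finite")
    if dim is not None and arr.size != dim:
        raise ValueError(f"embedding has {arr.size} components, expected {dim}")
    return arr


def embedding_distance(a, b) -> float:
    """Euclidean (L2) distance between two embeddings of equal dimension."""
    va = _as_vector(a)
    vb = _as_vector(b, dim=va.size)
    return float(np.linalg.norm(va - vb))


@dataclass
class GalleryEntry:
    label: str
    vector: np.ndarray
    source_frame: Optional[int] = None


class Gallery:
    """Labelled embeddings used for nearest-neighbour identity assignment.

    Entries are kept in insertion order; every entry has exactly one
    non-empty label. The embedding dimensionality is fixed by the first
    entry (128 by convention).
    """

    def __init__(self, dim: Optional[int] = None):
        self._entries: list[GalleryEntry] = []
        self._dim = dim

    @property
    def dim(self) -> Optional[int]:
        return self._dim

    @property
    def entries(self) -> Sequence[GalleryEntry]:
        return tuple(self._entries)

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct identity labels, in first-seen order."""
        seen: dict[str, None] = {}
        for e in self._entries:
            seen.setdefault(e.label, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self._entries)

    def add(self, label: str, vector, source_frame: Optional[int] = None) -> "Gallery":
        """Append one labelled embedding; existing entries are untouched."""
        if not label:
            raise ValueError("gallery label must be non-empty")
        v = _as_vector(vector, dim=self._dim)
        if self._dim is None:
            self._dim = v.size
        self._entries.append(GalleryEntry(str(label), v, source_frame))
        return self


def assign_identity(
    query, gallery: Gallery, max_distance: float = math.inf
) -> Optional[str]:
    """Label of the gallery entry closest to ``query``.

    Returns ``None`` ("unknown") when the minimum distance exceeds
    ``max_distance``; by default there is no rejection threshold, so every
    query receives the nearest identity. Exact distance ties resolve to the
    lexicographically smallest label, then the earliest entry.

    Raises
    ------
    ValueError
        If the gallery is empty or dimensions mismatch.
    """
    if len(gallery) == 0:
        raise ValueError("cannot assign an identity against an empty gallery")
    q = _as_vector(query, dim=gallery.dim)
    best_label: Optional[str] = None
    best_d = math.inf
    for entry in gallery.entries:
        d = float(np.linalg.norm(q - entry.vector))
        if d < best_d or (d == best_d and best_label is not None
                          and entry.label < best_label):
            best_d, best_label = d, entry.label
    if best_d > max_distance:
        return None
    return best_label


def update_gallery(
    gallery: Gallery, embedding, label: str, source_frame: Optional[int] = None
) -> Gallery:
    """Append one labelled embedding to the gallery (in place) and return it.

    New labels create new identities; repeated labels accumulate entries, so
    the nearest-neighbour match for that identity can only improve.
    """
    return gallery.add(label, embedding, source_frame)
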