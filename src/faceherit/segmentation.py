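"""Hierarchical spectral clustering of the co-heritability matrix.

Landmarks with strong co-inheritance are grouped into nested modules by
recursive two-way spectral partitioning of the symmetrized K x K
co-heritability matrix: five levels of bisection give 2^l segments at
level l and 63 segments in total (levels 0-5).  Alternative
segmentations of the same landmarks are compared by normalized mutual
information (NMI).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .heritability import CoheritabilityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# two-way spectral split
# ---------------------------------------------------------------------------


def _normalized_cut(a: np.ndarray, mask: np.ndarray) -> float:
    """Ncut value of the bipartition given by boolean mask (inf if empty side)."""
    if mask.all() or not mask.any():
        return np.inf
    cut = a[np.ix_(mask, ~mask)].sum()
    vol1, vol2 = a[mask].sum(), a[~mask].sum()
    if vol1 <= 0 or vol2 <= 0:
        return np.inf
    return float(cut / vol1 + cut / vol2)


def spectral_bisect(s_sub: np.ndarray, seed: int = 0) -> np.ndarray:
    """Split a symmetric similarity submatrix into two non-empty groups.

    Negative entries are clipped to 0 to form a valid affinity matrix.
    The split is the sign pattern of the second eigenvector of the
    symmetric normalized Laplacian, refined by 2-means on the 2-dim
    spectral embedding (fixed seed) and by a sweep cut along the second
    eigenvector; among these candidates the one with the smallest
    normalized cut is kept.  A disconnected affinity graph is split by
    connected components.  Labels: the lowest-index landmark's group is 0.
    """
    s_sub = np.asarray(s_sub, dtype=float)
    m = s_sub.shape[0]
    if s_sub.ndim != 2 or s_sub.shape[1] != m:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s_sub, s_sub.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if m < 2:
        raise ValueError("cannot bisect fewer than 2 landmarks")

    a = np.maximum(s_sub, 0.0)
    off = a - np.diag(np.diag(a))
    n_comp, comp_labels = connected_components(off > 0, directed=False)
    if n_comp > 1:
        labels = (comp_labels != comp_labels[0]).astype(int)
        return labels

    deg = off.sum(axis=1) + np.diag(a)  # keep self-similarity in the volume
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    lap = np.eye(m) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    lap = (lap + lap.T) / 2.0
    eigval, eigvec = np.linalg.eigh(lap)
    v2 = eigvec[:, 1]
    embedding = eigvec[:, :2] * d_inv_sqrt[:, None]

    candidates = []
    sign_mask = v2 >= 0
    if sign_mask.any() and not sign_mask.all():
        candidates.append(sign_mask)
    if m > 2:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(embedding)
        km_mask = km.labels_.astype(bool)
        if km_mask.any() and not km_mask.all():
            candidates.append(km_mask)
    order = np.argsort(v2, kind="stable")
    for cut_at in range(1, m):
        mask = np.zeros(m, dtype=bool)
        mask[order[:cut_at]] = True
        candidates.append(mask)

    best = min(candidates, key=lambda mask: _normalized_cut(a, mask))
    labels = best.astype(int)
    if labels[0] != 0:
        labels = 1 - labels
    return labels


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


@dataclass
class SegmentationHierarchy:
    """Nested binary partition of landmarks, levels 0..L.

    Segment ids follow the binary-heap convention: the level-l segments
    are ids 2^l .. 2^(l+1)-1, parent(id) = id // 2; with L = 5 the
    registry holds 63 segments.  Undersized segments (< 2 landmarks) are
    carried down unchanged and flagged.
    """

    levels: list[np.ndarray]  # per level, label vector of length K (0..2^l-1)
    segments: dict[int, np.ndarray]  # segment id -> landmark indices
    n_landmarks: int
    undersized: list[int] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels) - 1

    @property
    def segment_count(self) -> int:
        return len(self.segments)

    def labels_at_level(self, level: int) -> np.ndarray:
        return self.levels[level]

    def parent(self, segment_id: int) -> int | None:
        return segment_id // 2 if segment_id > 1 else None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_landmarks": self.n_landmarks,
            "n_levels": self.n_levels,
            "undersized": self.undersized,
            "segments": {str(k): v.tolist() for k, v in self.segments.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationHierarchy":
        payload = json.loads(Path(path).read_text())
        segments = {int(k): np.array(v, dtype=int) for k, v in payload["segments"].items()}
        n_levels = payload["n_levels"]
        k = payload["n_landmarks"]
        levels = []
        for lvl in range(n_levels + 1):
            labels = np.zeros(k, dtype=int)
            for j, sid in enumerate(range(2**lvl, 2 ** (lvl + 1))):
                labels[segments[sid]] = j
            levels.append(labels)
        return cls(levels, segments, k, payload["undersized"])


def build_hierarchy(
    s: CoheritabilityMatrix | np.ndarray, levels: int = 5, seed: int = 0
) -> SegmentationHierarchy:
    """Recursive spectral bisection into 2^l segments per level l.

    The input must be symmetrized; each segment is re-bisected on its
    similarity submatrix with a per-segment seed substream.  Segments
    too small to split pass through unchanged (with a warning) so the
    registry keeps its full 2^(L+1)-1 size.
    """
    if isinstance(s, CoheritabilityMatrix):
        if not s.symmetrized:
            raise ValueError("co-heritability matrix must be symmetrized first")
        values = s.values
    else:
        values = np.asarray(s, dtype=float)
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
    k = values.shape[0]
    segments: dict[int, np.ndarray] = {1: np.arange(k)}
    undersized: list[int] = []
    level_labels = [np.zeros(k, dtype=int)]
    for level in range(levels):
        labels = np.zeros(k, dtype=int)
        for j, sid in enumerate(range(2**level, 2 ** (level + 1))):
            idx = segments[sid]
            left_id, right_id = 2 * sid, 2 * sid + 1
            if idx.size < 2:
                logger.warning("segment %d has < 2 landmarks; carried down unchanged", sid)
                undersized.append(sid)
                segments[left_id] = idx.copy()
                segments[right_id] = np.array([], dtype=int)
            else:
                sub = values[np.ix_(idx, idx)]
                split = spectral_bisect(sub, seed=seed + sid)
                segments[left_id] = idx[split == 0]
                segments[right_id] = idx[split == 1]
            labels[segments[left_id]] = 2 * j
            labels[segments[right_id]] = 2 * j + 1
        level_labels.append(labels)
    return SegmentationHierarchy(
        levels=level_labels, segments=segments, n_landmarks=k, undersized=undersized
    )


# ---------------------------------------------------------------------------
# segmentation comparison
# ---------------------------------------------------------------------------


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information (mean-entropy normalization) in [0, 1].

    1 for identical labelings -- including the degenerate identical
    single-cluster case -- and ~0 for independent ones.
    """
    labels_a = np.asarray(labels_a).reshape(-1)
    labels_b = np.asarray(labels_b).reshape(-1)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(
        normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
    )
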