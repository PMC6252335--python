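"""Generalized Procrustes alignment and bilateral symmetry decomposition.

GPA iteratively removes position, orientation and (optionally) size from
a set of landmark configurations.  The symmetry decomposition runs GPA
on the originals together with their relabeled mirror images: the
average of an aligned original and its aligned reflection is the
symmetric component, the difference the asymmetric component.  Rotations
are solved by SVD-based orthogonal Procrustes with a determinant
correction, so improper rotations never enter; reflection is handled
explicitly by :func:`reflect`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_shapes import TemplateMesh

logger = logging.getLogger(__name__)

_REFLECT_X = np.diag([-1.0, 1.0, 1.0])


@dataclass
class AlignedShapeSet:
    """GPA output: aligned coordinates, centroid sizes and consensus."""

    coords: np.ndarray  # (n, K, 3), centroids at origin
    centroid_sizes: np.ndarray  # (n,) pre-alignment centroid sizes
    consensus: np.ndarray  # (K, 3) arithmetic mean of aligned coords
    scaling_removed: bool


@dataclass
class SymmetryDecomposition:
    """symmetric + asymmetric = aligned original, per subject."""

    symmetric: np.ndarray  # (n, K, 3)
    asymmetric: np.ndarray  # (n, K, 3)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def centroid_size(coords: np.ndarray) -> np.ndarray:
    """Root summed squared deviation from the centroid (batched)."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    arr = coords[None] if single else coords
    centered = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    return sizes[0] if single else sizes


def optimal_rotations(sources: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotations R_i minimizing ||sources_i @ R_i - target|| (batched).

    Determinant-corrected so a reflection is never returned.
    """
    single = sources.ndim == 2
    src = sources[None] if single else sources
    m = np.einsum("nki,kj->nij", src, target)
    u, _, vt = np.linalg.svd(m)
    det = np.linalg.det(np.einsum("nij,njk->nik", u, vt))
    u = u.copy()
    u[:, :, -1] *= np.sign(det)[:, None]
    rot = np.einsum("nij,njk->nik", u, vt)
    return rot[0] if single else rot


def similarity_tangent(coords: np.ndarray, include_scale: bool = True) -> np.ndarray:
    """Orthonormal basis of the similarity directions at a configuration.

    Columns of the returned (3m, d) matrix span translations, infinitesimal
    rotations and (optionally) scaling of the centered (m, 3) configuration
    -- the directions removed by Procrustes superimposition.
    """
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    fields = []
    for ax in range(3):  # translations
        f = np.zeros((m, 3))
        f[:, ax] = 1.0
        fields.append(f)
    gens = [
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
    ]
    for g in gens:  # infinitesimal rotations
        fields.append(centered @ g.T)
    if include_scale:
        fields.append(centered)
    mat = np.stack([f.reshape(-1) for f in fields], axis=1)
    q, r = np.linalg.qr(mat)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def reflect(coords: np.ndarray, template: TemplateMesh) -> np.ndarray:
    """Mirror a configuration: negate x, then swap each bilateral pair.

    Midline landmarks keep their index.  Applying twice is the identity.
    Works on a single (K, 3) configuration or a batch (n, K, 3).
    """
    coords = np.asarray(coords, dtype=float)
    out = coords @ _REFLECT_X
    perm = template.reflection_permutation
    return out[..., perm, :]


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def gpa(
    configs: np.ndarray,
    remove_scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    gauge_align_first: bool = True,
) -> AlignedShapeSet:
    """Generalized Procrustes analysis of an (n, K, 3) configuration stack.

    Iterates rotate-to-consensus / update-consensus until the root mean
    squared consensus displacement falls below ``tol``.  With
    ``remove_scale`` each configuration is first scaled to unit centroid
    size (full Procrustes fit).  The global rotation gauge is fixed by
    rotating the final consensus onto the first (centered) input
    configuration unless ``gauge_align_first`` is False.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("gpa needs at least two (K, 3) configurations")
    x = configs - configs.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0) or np.any(~np.isfinite(sizes)):
        raise ValueError("degenerate configuration with zero centroid size")
    if remove_scale:
        x = x / sizes[:, None, None]
    first_centered = x[0].copy()

    consensus = x[0].copy()
    for _ in range(max_iter):
        rot = optimal_rotations(x, consensus)
        x = np.einsum("nkj,nji->nki", x, rot)
        new_consensus = x.mean(axis=0)
        if remove_scale:
            norm = np.sqrt((new_consensus**2).sum())
            if norm <= 0:
                raise ValueError("degenerate consensus")
            new_consensus = new_consensus / norm
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            break

    if gauge_align_first:
        rot = optimal_rotations(consensus, first_centered)
        x = x @ rot
        consensus = consensus @ rot
    return AlignedShapeSet(
        coords=x,
        centroid_sizes=sizes,
        consensus=x.mean(axis=0),
        scaling_removed=remove_scale,
    )


def _symmetric_frame_rotation(consensus: np.ndarray, template: TemplateMesh) -> np.ndarray:
    """Rotation placing the consensus' symmetry plane at x = 0.

    For a (near-)symmetric consensus C there is a proper rotation Q with
    reflect(C) @ Q ~= C; A = diag(-1,1,1) @ Q is then a symmetric
    orthogonal matrix whose -1-eigenvector is the normal of the symmetry
    plane in the current frame.  Rotating that normal onto the x axis
    restores the sagittal-plane convention.
    """
    mirrored = reflect(consensus, template)
    q = optimal_rotations(mirrored, consensus)
    a = _REFLECT_X @ q
    a = (a + a.T) / 2.0
    eigval, eigvec = np.linalg.eigh(a)
    normal = eigvec[:, np.argmin(eigval)]
    if normal[0] < 0:
        normal = -normal
    # orthonormal completion with det +1
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rot = np.column_stack([normal, u, v])
    if np.linalg.det(rot) < 0:
        rot[:, 2] *= -1
    return rot


def symmetrize(
    configs: np.ndarray,
    template: TemplateMesh,
    remove_scale: bool = True,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[SymmetryDecomposition, AlignedShapeSet]:
    """Symmetric/asymmetric decomposition via GPA of originals + reflections.

    The 2n-set {originals u reflections} is jointly aligned; the frame is
    then rotated so the symmetry plane is x = 0 (with a final in-plane
    gauge fixed against the first subject), and the aligned set is
    refined against the reflection-averaged consensus so that the
    symmetric component is reflection-invariant to numerical precision.

    Returns the decomposition (symmetric_i + asymmetric_i equals the
    aligned original exactly) and the AlignedShapeSet of the 2n-set,
    ordered as originals then reflections.
    """
    configs = np.asarray(configs, dtype=float)
    n = configs.shape[0]
    stack = np.concatenate([configs, reflect(configs, template)], axis=0)
    aligned = gpa(
        stack, remove_scale=remove_scale, tol=tol, max_iter=max_iter, gauge_align_first=False
    )
    x = aligned.coords
    consensus = aligned.consensus

    rot = _symmetric_frame_rotation(consensus, template)
    x = x @ rot
    consensus = consensus @ rot

    # refinement sweeps against the exactly-symmetric consensus
    for _ in range(3):
        target = (consensus + reflect(consensus, template)) / 2.0
        rots = optimal_rotations(x, target)
        x = np.einsum("nkj,nji->nki", x, rots)
        consensus = x.mean(axis=0)

    # in-plane gauge: rotate about x so subject 0 matches its pre-rotation yz frame
    ref = aligned.coords[0] @ rot
    yz_cur, yz_ref = x[0][:, 1:], ref[:, 1:]
    m = yz_cur.T @ yz_ref
    theta = np.arctan2(m[0, 1] - m[1, 0], m[0, 0] + m[1, 1])
    c, s = np.cos(theta), np.sin(theta)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    x = x @ rx
    consensus = consensus @ rx

    sym = (x[:n] + x[n:]) / 2.0
    asym = (x[:n] - x[n:]) / 2.0
    aligned_out = AlignedShapeSet(
        coords=x,
        centroid_sizes=aligned.centroid_sizes,
        consensus=consensus,
        scaling_removed=remove_scale,
    )
    return SymmetryDecomposition(symmetric=sym, asymmetric=asym), aligned_out


# ---------------------------------------------------------------------------
# distances and QC
# ---------------------------------------------------------------------------


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two (K, 3) configurations.

    Both are centered and scaled to unit centroid size; with rho the
    optimal (proper) rotation angle between the preshapes, the full
    Procrustes distance is sin(rho).  Symmetric in its arguments, zero
    exactly on the shape quotient.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share dimensions")
    za = a - a.mean(axis=0)
    zb = b - b.mean(axis=0)
    na, nb = np.sqrt((za**2).sum()), np.sqrt((zb**2).sum())
    if na <= 0 or nb <= 0:
        raise ValueError("degenerate configuration")
    za /= na
    zb /= nb
    u, s, vt = np.linalg.svd(zb.T @ za)
    s = s.copy()
    det_flip = np.linalg.det(u @ vt) < 0
    if det_flip:
        s[-1] *= -1
        u[:, -1] *= -1
    rot = u @ vt  # proper rotation aligning zb to za
    cos_rho = np.clip(s.sum(), -1.0, 1.0)
    # residual form of sqrt(1 - cos^2 rho): numerically exact near zero
    resid = za - cos_rho * (zb @ rot)
    return float(np.sqrt((resid**2).sum()))


def flag_outliers(aligned: AlignedShapeSet, z_max: float = 2.0) -> np.ndarray:
    """Flag atypical shapes by z-scored Procrustes distance to the consensus.

    The per-subject score is the full Procrustes distance to the
    consensus, standardized across subjects; subjects with z >= z_max
    are flagged (boolean array).
    """
    n = aligned.coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects to standardize")
    dists = np.array(
        [procrustes_distance(c, aligned.consensus) for c in aligned.coords]
    )
    sd = dists.std(ddof=1)
    if sd == 0:
        return np.zeros(n, dtype=bool)
    z = (dists - dists.mean()) / sd
    return z >= z_max
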