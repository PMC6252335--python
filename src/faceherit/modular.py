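"""Per-module shape spaces and multivariate modular heritability.

Each co-inheritance module gets its own shape space: the module's
landmarks from fathers and offspring combined are re-aligned by a fresh
GPA (so only the module's own shape information remains), decomposed
into principal components, and truncated by Horn's parallel analysis.
Heritability per module and cohort (sons / daughters) is then the PLSR
estimate on all retained PC scores simultaneously, with significance
from permutation tests (father rows randomized) and a multiple-testing
threshold from the Li-Ji effective number of independent tests computed
on the matrix of pairwise RV coefficients between module score blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heritability import (
    HeritabilityEstimate,
    PLSRModel,
    choose_ncomp,
    estimate_h2,
    plsr_fit,
    r2_to_b,
    shape_r2,
)
from .io_shapes import TemplateMesh
from .procrustes import gpa, similarity_tangent

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# module shape space
# ---------------------------------------------------------------------------


@dataclass
class ModuleShapeSpace:
    """PCA shape space of one module, built on fathers + offspring pooled."""

    module_id: int
    landmark_ids: np.ndarray
    aligned: np.ndarray  # (N, m, 3) module-aligned coordinates
    consensus: np.ndarray  # (m, 3)
    basis: np.ndarray  # (3m, r_full) orthonormal PCs
    eigenvalues: np.ndarray  # (r_full,)
    scores: np.ndarray  # (N, r_full)
    retained: int

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained]


def parallel_analysis(
    centered: np.ndarray,
    eigenvalues: np.ndarray,
    pa_iters: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
    shape_basis: np.ndarray | None = None,
) -> int:
    """Horn's parallel analysis: retained PC count (at least 1).

    Columns of the centered data matrix are permuted independently
    ``pa_iters`` times; a component is retained while its eigenvalue
    exceeds the given percentile of the corresponding permuted
    eigenvalue distribution (leading run).

    For Procrustes-aligned coordinates the data are confined to the
    shape subspace (similarity transforms are removed), while a permuted
    matrix is not; ``shape_basis`` (columns spanning the shape subspace)
    projects each permuted matrix back into it, rescaled to preserve its
    total variance, so the null has the same dimensionality and variance
    budget as the data.  Without this, isotropic noise would spuriously
    pass the threshold in every direction.
    """
    rng = np.random.default_rng(seed)
    n, p = centered.shape
    r = len(eigenvalues)
    null_eigs = np.empty((pa_iters, r))
    work = centered.copy()
    for it in range(pa_iters):
        for j in range(p):
            work[:, j] = work[rng.permutation(n), j]
        if shape_basis is None:
            null = work
        else:
            null = (work @ shape_basis) @ shape_basis.T
            ss_null = (null**2).sum()
            if ss_null > 0:
                null = null * np.sqrt((work**2).sum() / ss_null)
        # eigenvalues of the covariance via the smaller-side Gram matrix
        gram = null @ null.T if n <= p else null.T @ null
        ev = np.linalg.eigvalsh(gram)[::-1] / (n - 1)
        null_eigs[it] = ev[:r] if len(ev) >= r else np.pad(ev, (0, r - len(ev)))
    thresh = np.percentile(null_eigs, percentile, axis=0)
    retained = 0
    for lam, t in zip(eigenvalues, thresh):
        if lam > t:
            retained += 1
        else:
            break
    return max(retained, 1)


def module_shape_space(
    shapes: np.ndarray,
    landmark_ids: np.ndarray,
    module_id: int = 0,
    pa_iters: int = 100,
    seed: int = 0,
    remove_scale: bool = True,
) -> ModuleShapeSpace:
    """Build the PCA shape space of one module from pooled (N, K, 3) shapes.

    Modules with >= 3 landmarks are re-GPA'd independently of the rest
    of the face; smaller modules use the raw (centered) coordinates.
    The retained PC count comes from parallel analysis of the aligned
    coordinate matrix.
    """
    landmark_ids = np.asarray(landmark_ids, dtype=int)
    sub = np.asarray(shapes, dtype=float)[:, landmark_ids, :]
    n = sub.shape[0]
    shape_basis = None
    if landmark_ids.size >= 3:
        aligned_set = gpa(sub, remove_scale=remove_scale)
        aligned = aligned_set.coords
        sim = similarity_tangent(aligned_set.consensus, include_scale=remove_scale)
        full = np.linalg.qr(
            np.concatenate([sim, np.eye(sim.shape[0])], axis=1)
        )[0]
        shape_basis = full[:, sim.shape[1] : sim.shape[0]]  # complement of similarity
    else:
        aligned = sub - sub.mean(axis=1, keepdims=True) if landmark_ids.size > 1 else sub
    flat = aligned.reshape(n, -1)
    consensus_vec = flat.mean(axis=0)
    centered = flat - consensus_vec
    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    keep = svals > max(svals[0], 1.0) * 1e-12 if svals.size else np.array([], bool)
    basis = vt[keep].T
    scores = u[:, keep] * svals[keep]
    eigenvalues = eigenvalues[keep]
    retained = parallel_analysis(
        centered, eigenvalues, pa_iters=pa_iters, seed=seed, shape_basis=shape_basis
    )
    retained = min(retained, basis.shape[1])
    return ModuleShapeSpace(
        module_id=module_id,
        landmark_ids=landmark_ids,
        aligned=aligned,
        consensus=consensus_vec.reshape(-1, 3),
        basis=basis,
        eigenvalues=eigenvalues,
        scores=scores,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# modular heritability + permutation significance
# ---------------------------------------------------------------------------


@dataclass
class ModularHeritabilityResult:
    """Multivariate h2 of one module for one cohort (sons or daughters)."""

    module_id: int
    cohort: str
    h2: float
    p_value: float | None
    mse: float
    n_pairs: int
    retained_pcs: int
    r_squared: float = np.nan
    ncomp: int = 0


def modular_h2(
    space: ModuleShapeSpace,
    father_rows: np.ndarray,
    offspring_rows: np.ndarray,
    cohort: str = "",
    ncomp: int | None = None,
) -> ModularHeritabilityResult:
    """PLSR heritability on all retained PCs simultaneously."""
    x = space.retained_scores[np.asarray(father_rows, dtype=int)]
    y = space.retained_scores[np.asarray(offspring_rows, dtype=int)]
    est = estimate_h2(x, y, ncomp=ncomp)
    return ModularHeritabilityResult(
        module_id=space.module_id,
        cohort=cohort,
        h2=est.h2,
        p_value=None,
        mse=est.mse,
        n_pairs=est.n,
        retained_pcs=space.retained,
        r_squared=est.r_squared,
        ncomp=est.ncomp,
    )


def _h2_fixed(x: np.ndarray, y: np.ndarray, ncomp: int, ss_x: float, ss_y: float) -> float:
    """Lean h2 with a fixed component count (permutation inner loop)."""
    model = plsr_fit(x, y, ncomp)
    r2 = shape_r2(y, model.predict(x))
    return 2.0 * r2_to_b(r2, ss_x, ss_y)


def permutation_test(
    fathers_block: np.ndarray,
    offspring_block: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    ncomp: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for h2 > 0 by randomizing father-offspring pairing.

    Father rows are permuted uniformly at random ``n_perm`` times and
    p = (1 + #{h2_perm >= h2_obs}) / (1 + n_perm), so p >= 1/(n_perm+1).
    The same component count is used for the observed and all permuted
    fits; by default it is the (pairing-independent) full count
    min(15, p, n-1), which keeps the statistic exchangeable under the
    null -- a data-driven choice made on the observed pairing would
    bias the test anti-conservative.

    Returns (h2_obs, p_value); h2_obs is the test statistic, which may
    differ from a cross-validated point estimate.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.atleast_2d(np.asarray(fathers_block, dtype=float))
    y = np.atleast_2d(np.asarray(offspring_block, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("paired rows required")
    n = x.shape[0]
    if ncomp is None:
        ncomp = 15
    ncomp = max(1, min(ncomp, n - 1, x.shape[1]))
    ss_x = float(((x - x.mean(axis=0)) ** 2).sum())
    ss_y = float(((y - y.mean(axis=0)) ** 2).sum())
    h2_obs = _h2_fixed(x, y, ncomp, ss_x, ss_y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        if _h2_fixed(xp, y, ncomp, ss_x, ss_y) >= h2_obs:
            exceed += 1
    return h2_obs, (1.0 + exceed) / (1.0 + n_perm)


def modular_h2_with_significance(
    space: ModuleShapeSpace,
    father_rows: np.ndarray,
    offspring_rows: np.ndarray,
    cohort: str = "",
    n_perm: int = 9999,
    seed: int = 0,
) -> ModularHeritabilityResult:
    """Module h2 (cross-validated estimate) with permutation p-value.

    The p-value comes from the exchangeable full-component statistic;
    the reported h2 stays the cross-validated point estimate.
    """
    result = modular_h2(space, father_rows, offspring_rows, cohort=cohort)
    x = space.retained_scores[np.asarray(father_rows, dtype=int)]
    y = space.retained_scores[np.asarray(offspring_rows, dtype=int)]
    _, p = permutation_test(x, y, n_perm=n_perm, seed=seed)
    result.p_value = p
    return result


# ---------------------------------------------------------------------------
# modular co-heritability and multiple testing
# ---------------------------------------------------------------------------


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """RV coefficient between two centered blocks (rotation-invariant, [0,1])."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxy = xc.T @ yc
    sxx = xc.T @ xc
    syy = yc.T @ yc
    denom = np.sqrt((sxx**2).sum() * (syy**2).sum())
    if denom <= 0:
        raise ValueError("zero-variance block")
    return float((sxy**2).sum() / denom)


def module_correlations(
    spaces: list[ModuleShapeSpace], rows: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise multivariate correlations (RV) of module score blocks.

    By default the pooled subjects are used; ``rows`` restricts to a
    subject subset (e.g. one cohort).  Diagonal is 1.
    """
    blocks = []
    for sp in spaces:
        sc = sp.retained_scores
        blocks.append(sc if rows is None else sc[np.asarray(rows, dtype=int)])
    m = len(blocks)
    corr = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            corr[a, b] = corr[b, a] = rv_coefficient(blocks[a], blocks[b])
    return corr


@dataclass
class MultipleTesting:
    """Li-Ji effective number of tests and the adjusted alpha."""

    module_correlation: np.ndarray
    eigenvalues: np.ndarray = field(init=False)
    m_eff: float = field(init=False)
    alpha_adj: float = field(init=False)
    fwer: float = 0.05

    def __post_init__(self) -> None:
        corr = np.asarray(self.module_correlation, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(corr, corr.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        eigs = np.linalg.eigvalsh((corr + corr.T) / 2.0)[::-1]
        eigs = np.clip(eigs, 0.0, None)
        # snap to integers within float tolerance: the fractional part in the
        # Li-Ji sum is discontinuous at integer eigenvalues
        near = np.round(eigs)
        eigs = np.where(np.abs(eigs - near) < 1e-9, near, eigs)
        self.eigenvalues = eigs
        self.m_eff = float(np.sum((eigs >= 1.0) + (eigs - np.floor(eigs))))
        self.alpha_adj = self.fwer / round(self.m_eff)


def effective_tests(corr: np.ndarray, fwer: float = 0.05) -> MultipleTesting:
    """Effective number of independent tests from the eigenvalues of corr.

    Li-Ji: m_eff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ];
    the Bonferroni-style threshold divides by round(m_eff) (integer
    reporting convention).
    """
    return MultipleTesting(module_correlation=np.asarray(corr, dtype=float), fwer=fwer)


# ---------------------------------------------------------------------------
# latent morphs and stability
# ---------------------------------------------------------------------------


def latent_morphs(
    space: ModuleShapeSpace,
    model: PLSRModel,
    component_index: int,
    sd_multiplier: float = 4.0,
    side: str = "offspring",
    template: TemplateMesh | None = None,
) -> dict:
    """Morphs +- sd_multiplier SDs along one latent pair, in module space.

    The chosen latent component's loading (father or offspring side) is
    mapped through the PC basis into landmark coordinates; morphs are
    the module consensus displaced by +-(sd_multiplier * score SD) along
    that direction.  The per-landmark displacement is also projected on
    the template vertex normals (signed normal displacement map).
    """
    if not 0 <= component_index < model.n_components:
        raise ValueError("component index out of range")
    if side == "offspring":
        loading = model.y_loadings[:, component_index]
        score_sd = float(model.x_scores[:, component_index].std(ddof=1))
    elif side == "father":
        loading = model.x_weights[:, component_index]
        score_sd = float(model.x_scores[:, component_index].std(ddof=1))
    else:
        raise ValueError("side must be 'offspring' or 'father'")
    r = len(loading)
    direction = (space.basis[:, :r] @ loading).reshape(-1, 3)
    nrm = np.linalg.norm(direction)
    if nrm > 0:
        direction = direction / nrm
    offset = sd_multiplier * score_sd * nrm
    plus = space.consensus + offset * direction
    minus = space.consensus - offset * direction

    if template is not None:
        import trimesh

        mesh = trimesh.Trimesh(
            vertices=template.vertices, faces=template.faces, process=False
        )
        normals = np.asarray(mesh.vertex_normals)[space.landmark_ids]
    else:
        disp = plus - minus
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        normals = np.where(norms > 0, disp / np.maximum(norms, 1e-30), 0.0)
    normal_displacement = ((plus - minus) * normals).sum(axis=1)
    return {
        "plus": plus,
        "minus": minus,
        "direction": direction,
        "normal_displacement": normal_displacement,
    }


def subsample_stability(
    fathers_block: np.ndarray,
    offspring_block: np.ndarray,
    sizes: list[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """h2 over random subsamples of different sizes (stability curve).

    Returns a tidy DataFrame (size, rep, h2) plus per-size mean/sd via
    groupby; at size n with a single rep the estimate equals the
    full-sample one.
    """
    x = np.atleast_2d(np.asarray(fathers_block, dtype=float))
    y = np.atleast_2d(np.asarray(offspring_block, dtype=float))
    n = x.shape[0]
    if max(sizes) > n:
        raise ValueError("subsample size exceeds cohort size")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        n_rep = 1 if size == n else reps
        for rep in range(n_rep):
            idx = np.arange(n) if size == n else rng.choice(n, size=size, replace=False)
            est: HeritabilityEstimate = estimate_h2(x[idx], y[idx])
            rows.append({"size": size, "rep": rep, "h2": est.h2})
    return pd.DataFrame(rows)
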