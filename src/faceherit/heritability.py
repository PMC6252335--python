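"""Parent-offspring regression heritability for high-dimensional shape.

The estimator regresses offspring shape on father shape by partial least
squares (PLSR), summarizes fit quality by the multivariate shape
coefficient of determination R2, converts R2 to a multivariate
regression coefficient b = sqrt(R2 * SS_offspring / SS_parent) -- the
unique form reproducing the univariate identity b = r * s_y / s_x -- and
reports h2 = 2 b, as appropriate for a one-parent one-offspring additive
design.  Applied landmark-by-landmark (3-coordinate blocks) it yields a
K x K matrix whose diagonal is per-landmark heritability and whose
off-diagonal entries are pairwise landmark co-heritability.

PLSR is implemented as NIPALS on the cross-covariance: each component's
predictor weight is the dominant left singular vector of X'Y, followed
by rank-one deflation.  Coefficients for any leading subset of
components are recovered from the same fit, which makes nested
cross-validation over the component count cheap.  The component count is
chosen per fit as the minimizer of 5-fold cross-validated MSE; 0
components (mean predictor) is an admissible choice, so a structureless
pairing yields R2 = b = h2 = 0 rather than pure overfit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PLSR core
# ---------------------------------------------------------------------------


def _dominant_left_singular(c: np.ndarray) -> np.ndarray:
    p, q = c.shape
    if min(p, q) <= 64:
        u, _, _ = np.linalg.svd(c, full_matrices=False)
        return u[:, 0]
    # power iteration on C C' for large blocks
    w = c.sum(axis=1)
    nrm = np.linalg.norm(w)
    w = np.ones(p) / np.sqrt(p) if nrm == 0 else w / nrm
    for _ in range(500):
        w_new = c @ (c.T @ w)
        nrm = np.linalg.norm(w_new)
        if nrm == 0:
            return w
        w_new /= nrm
        if np.linalg.norm(w_new - w) < 1e-14:
            w = w_new
            break
        w = w_new
    return w


class PLSRModel:
    """Two-block PLS regression model (centering only, no scaling).

    Successive latent score pairs have non-increasing covariance; with
    ``n_components`` equal to the predictor rank the fitted values equal
    the least-squares projection of Y onto the column space of X.
    """

    def __init__(self, x_mean, y_mean, weights, x_loadings, y_loadings, x_scores, mse_curve):
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.x_weights = weights  # (p, k)
        self.x_loadings = x_loadings  # (p, k)
        self.y_loadings = y_loadings  # (q, k)
        self.x_scores = x_scores  # (n, k), training scores
        self.mse_curve = mse_curve  # training MSE at 0..k components
        self.n_components = weights.shape[1]
        # rotations R with X_c @ R = T; (P'W) is unit upper triangular,
        # so leading sub-blocks give the coefficients for any a <= k.
        ptw = self.x_loadings.T @ self.x_weights
        self._rotations = np.linalg.solve(ptw.T, self.x_weights.T).T

    def coefficients(self, ncomp: int | None = None) -> np.ndarray:
        a = self.n_components if ncomp is None else ncomp
        if not 0 <= a <= self.n_components:
            raise ValueError("ncomp out of fitted range")
        return self._rotations[:, :a] @ self.y_loadings[:, :a].T

    def predict(self, x: np.ndarray, ncomp: int | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.x_mean) @ self.coefficients(ncomp) + self.y_mean


def plsr_fit(x: np.ndarray, y: np.ndarray, ncomp: int) -> PLSRModel:
    """Fit PLSR with up to ``ncomp`` components (NIPALS, deflation).

    Stops early if the residual cross-covariance vanishes (e.g. the
    predictor rank is exhausted); the returned model then has fewer
    components than requested.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    q = y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if ncomp < 1 or ncomp > min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - x_mean, y - y_mean
    ss_y0 = float((yc**2).sum())

    weights = np.zeros((p, ncomp))
    x_loadings = np.zeros((p, ncomp))
    y_loadings = np.zeros((q, ncomp))
    scores = np.zeros((n, ncomp))
    mse_curve = [ss_y0 / (n * q)]
    k = 0
    for a in range(ncomp):
        c = xc.T @ yc
        if np.linalg.norm(c) < 1e-13 * max(1.0, ss_y0):
            break
        w = _dominant_left_singular(c)
        t = xc @ w
        tt = float(t @ t)
        if tt <= 1e-30:
            break
        p_load = (xc.T @ t) / tt
        q_load = (yc.T @ t) / tt
        xc = xc - np.outer(t, p_load)
        yc = yc - np.outer(t, q_load)
        weights[:, a] = w
        x_loadings[:, a] = p_load
        y_loadings[:, a] = q_load
        scores[:, a] = t
        mse_curve.append(float((yc**2).sum()) / (n * q))
        k = a + 1
    if k == 0:
        # X and Y uncorrelated to machine precision: one null component (B = 0)
        weights[:, 0] = 1.0 / np.sqrt(p)
        x_loadings[:, 0] = weights[:, 0]
        k = 1
        mse_curve.append(mse_curve[0])
    return PLSRModel(
        x_mean,
        y_mean,
        weights[:, :k],
        x_loadings[:, :k],
        y_loadings[:, :k],
        scores[:, :k],
        np.array(mse_curve),
    )


def choose_ncomp(
    x: np.ndarray,
    y: np.ndarray,
    max_ncomp: int | None = None,
    n_folds: int = 5,
    allow_zero: bool = True,
) -> int:
    """Component count minimizing K-fold cross-validated prediction MSE.

    Candidates are 0..max_ncomp (0 = mean predictor, admissible only
    with ``allow_zero``); folds are contiguous, so the choice is
    deterministic.  Nested coefficients mean one fit per fold covers all
    candidates.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    n_folds = min(n_folds, n)
    fold_max = n - (n // n_folds + n % n_folds) - 1  # smallest training size - 1
    cap = min(15, p, fold_max)
    if max_ncomp is not None:
        cap = min(cap, max_ncomp)
    cap = max(cap, 1)
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    sse = np.zeros(cap + 1)
    for f in range(n_folds):
        lo, hi = bounds[f], bounds[f + 1]
        mask = np.ones(n, dtype=bool)
        mask[lo:hi] = False
        model = plsr_fit(x[mask], y[mask], cap)
        for a in range(cap + 1):
            aa = min(a, model.n_components)
            pred = model.predict(x[~mask], ncomp=aa)
            sse[a] += float(((y[~mask] - pred) ** 2).sum())
    start = 0 if allow_zero else 1
    return int(start + np.argmin(sse[start:]))


# ---------------------------------------------------------------------------
# R2, transformation, h2
# ---------------------------------------------------------------------------


def shape_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Multivariate shape coefficient of determination.

    1 - sum_i d2(y_i, yhat_i) / sum_i d2(y_i, ybar) with d2 the squared
    deviation in the aligned shape space; negative values (prediction
    worse than the mean) are clipped to 0 with a logged warning.
    """
    y_true = np.asarray(y_true, dtype=float).reshape(len(y_true), -1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(len(y_pred), -1)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    ss_tot = float(((y_true - y_true.mean(axis=0)) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero total shape variance")
    r2 = 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot
    if r2 < 0:
        logger.warning("negative shape R2 (%.3g) clipped to 0", r2)
        return 0.0
    return min(r2, 1.0)


def r2_to_b(r_squared: float, ss_parent: float, ss_offspring: float) -> float:
    """Transform a shape R2 to a multivariate regression coefficient.

    b = sqrt(R2 * SS_offspring / SS_parent), the multivariate
    generalization consistent with the univariate b = r * s_y / s_x;
    the sign is fixed positive.
    """
    if ss_parent <= 0:
        raise ValueError("ss_parent must be positive")
    return float(np.sqrt(max(r_squared, 0.0) * ss_offspring / ss_parent))


@dataclass
class HeritabilityEstimate:
    """PLSR-based parent-offspring heritability: h2 = 2 b (reported raw)."""

    r_squared: float
    b: float
    h2: float
    mse: float
    ncomp: int
    n: int


def estimate_h2(
    fathers_block: np.ndarray,
    offspring_block: np.ndarray,
    ncomp: int | None = None,
    max_ncomp: int = 15,
) -> HeritabilityEstimate:
    """Estimate h2 from paired father/offspring blocks (rows = pairs).

    ``ncomp=None`` selects the component count by 5-fold cross-validated
    MSE (0 allowed); an integer forces that count.  h2 = 2 b may exceed
    1 (or 2 in degenerate cases) and is reported raw.
    """
    x = np.atleast_2d(np.asarray(fathers_block, dtype=float))
    y = np.atleast_2d(np.asarray(offspring_block, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("father and offspring blocks must have paired rows")
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 pairs")
    if ncomp is None:
        ncomp = choose_ncomp(x, y, max_ncomp=max_ncomp)
    ss_x = float(((x - x.mean(axis=0)) ** 2).sum())
    ss_y = float(((y - y.mean(axis=0)) ** 2).sum())
    if ncomp == 0:
        mse = ss_y / y.size
        return HeritabilityEstimate(0.0, 0.0, 0.0, mse, 0, n)
    model = plsr_fit(x, y, min(ncomp, min(n - 1, x.shape[1])))
    y_hat = model.predict(x)
    r2 = shape_r2(y, y_hat)
    b = r2_to_b(r2, ss_x, ss_y)
    mse = float(((y - y_hat) ** 2).mean())
    return HeritabilityEstimate(r2, b, 2.0 * b, mse, model.n_components, n)


# ---------------------------------------------------------------------------
# landmark-level (co-)heritability
# ---------------------------------------------------------------------------


@dataclass
class CoheritabilityMatrix:
    """K x K matrix: diagonal = landmark h2, off-diagonal = co-heritability.

    Entry (i, j) comes from regressing offspring landmark j's 3D
    coordinates on father landmark i's 3D coordinates.
    """

    values: np.ndarray
    symmetrized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("co-heritability matrix must be square")

    @property
    def landmark_h2(self) -> np.ndarray:
        return np.diag(self.values).copy()


def landmark_coheritability(
    fathers: np.ndarray, offspring: np.ndarray, progress: bool = False
) -> CoheritabilityMatrix:
    """All-pairs landmark (co-)heritability from adjusted, symmetrized cohorts.

    Uses the full-rank (3-component) PLSR fit for every (father landmark
    i, offspring landmark j) pair, which coincides with the least-squares
    projection onto the 3-coordinate predictor block and is therefore
    computed by a vectorized normal-equations solve: entry (i, j) =
    2 * sqrt(R2_ij * SS_yj / SS_xi).  Identical to looping
    ``estimate_h2(..., ncomp=3)`` over pairs, and independent of
    execution order.
    """
    f = np.asarray(fathers, dtype=float)
    o = np.asarray(offspring, dtype=float)
    if f.shape != o.shape or f.ndim != 3:
        raise ValueError("expect matching (n, K, 3) father/offspring stacks")
    n, k, _ = f.shape
    fc = f - f.mean(axis=0)
    oc = o - o.mean(axis=0)
    o_flat = oc.reshape(n, 3 * k)
    ss_x = (fc**2).sum(axis=(0, 2))  # (K,)
    ss_y = (oc**2).sum(axis=(0, 2))
    if np.any(ss_y <= 0):
        raise ValueError("offspring landmark with zero variance")
    values = np.zeros((k, k))
    for i in range(k):
        xi = fc[:, i, :]  # (n, 3)
        gram = xi.T @ xi
        cross = xi.T @ o_flat  # (3, 3K)
        beta = np.linalg.pinv(gram, hermitian=True, rcond=1e-12) @ cross
        ss_exp = (beta * cross).sum(axis=0).reshape(k, 3).sum(axis=1)
        r2 = np.clip(ss_exp / ss_y, 0.0, 1.0)
        values[i] = 2.0 * np.sqrt(r2 * ss_y / ss_x[i])
        if progress and (i + 1) % 50 == 0:
            logger.info("landmark co-heritability: %d / %d rows", i + 1, k)
    return CoheritabilityMatrix(values=values, symmetrized=False)


def symmetrize_matrix(m: CoheritabilityMatrix | np.ndarray) -> CoheritabilityMatrix:
    """(M + M') / 2, with the symmetrized flag set."""
    values = m.values if isinstance(m, CoheritabilityMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    return CoheritabilityMatrix(values=(values + values.T) / 2.0, symmetrized=True)
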