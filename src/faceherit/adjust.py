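"""Covariate adjustment of symmetrized shapes before heritability estimation.

Facial shape is confounded by age, sex and BMI; these effects are
removed by regressing vectorized shape on the covariate block with PLSR
and keeping the residuals (consensus added back).  Fathers and offspring
are adjusted in separate fits.  With the component count equal to the
number of covariates the fit is full rank and coincides with ordinary
multivariate least squares, so the adjustment is idempotent and leaves
no linear association between shape coordinates and covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heritability import plsr_fit

logger = logging.getLogger(__name__)


@dataclass
class AdjustedShapes:
    """Residualized configurations (mean shape added back)."""

    coords: np.ndarray  # (n, K, 3)
    covariates_used: list[str]
    cohort_tag: str = ""


def adjust_covariates(
    shapes: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    ncomp: int | None = None,
    cohort_tag: str = "",
) -> AdjustedShapes:
    """Remove linear covariate effects from an (n, K, 3) shape stack.

    Covariates are standardized before the fit; zero-variance columns
    (e.g. sex in a single-sex cohort) are dropped with a warning, and if
    nothing remains the transform is the identity.  ``ncomp`` defaults
    to the number of retained covariates (full rank, OLS-equivalent).
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 3:
        raise ValueError("expect an (n, K, 3) shape stack")
    n, k, _ = shapes.shape
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        names = [f"cov{i}" for i in range(cov.shape[1])]
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match subjects")
    if np.isnan(cov).any():
        raise ValueError("covariates must be complete")

    sd = cov.std(axis=0)
    keep = sd > 0
    dropped = [nm for nm, k_ in zip(names, keep) if not k_]
    if dropped:
        logger.warning("dropping zero-variance covariate(s): %s", dropped)
    used = [nm for nm, k_ in zip(names, keep) if k_]
    flat = shapes.reshape(n, 3 * k)
    consensus = flat.mean(axis=0)
    if not used:
        logger.warning("all covariates dropped; adjustment is the identity")
        return AdjustedShapes(shapes.copy(), [], cohort_tag)

    z = (cov[:, keep] - cov[:, keep].mean(axis=0)) / sd[keep]
    p = z.shape[1]
    if ncomp is None:
        ncomp = p
    if n <= ncomp:
        raise ValueError("need n > ncomp subjects")
    model = plsr_fit(z, flat, ncomp)
    residual = flat - model.predict(z)
    adjusted = (residual - residual.mean(axis=0)) + consensus
    return AdjustedShapes(adjusted.reshape(n, k, 3), used, cohort_tag)
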