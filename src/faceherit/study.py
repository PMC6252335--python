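"""Canonical synthetic-study workflows built from the pipeline primitives.

These helpers chain the standard estimation path -- simulate, jointly
symmetrize fathers and offspring, adjust covariates per cohort, build a
module shape space, estimate h2 -- so that parameter-recovery studies,
the analysis drivers and the acceptance checks all run the exact same
code.
"""

from __future__ import annotations

import numpy as np

from .adjust import adjust_covariates
from .heritability import CoheritabilityMatrix, landmark_coheritability, symmetrize_matrix
from .io_shapes import PairedCohort, TemplateMesh
from .modular import ModularHeritabilityResult, modular_h2, module_shape_space
from .procrustes import symmetrize
from .synthetic import (
    SimulationDesign,
    default_design,
    default_partition,
    make_template,
    simulate_cohort,
)


def symmetrized_adjusted_pairs(
    cohort: PairedCohort, template: TemplateMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Joint GPA + symmetrization, then per-cohort covariate adjustment.

    Returns paired (fathers, offspring) symmetric components as
    (n, K, 3) arrays in pairing order.
    """
    fathers = cohort.father_array()
    offspring = cohort.offspring_array()
    n = cohort.n_pairs
    decomp, _ = symmetrize(np.concatenate([fathers, offspring]), template)
    father_ids = [cohort.pairing[o] for o in cohort.offspring_ids]
    adj_f = adjust_covariates(
        decomp.symmetric[:n], cohort.covariate_matrix(father_ids), cohort_tag="fathers"
    )
    adj_o = adjust_covariates(
        decomp.symmetric[n:], cohort.covariate_matrix(cohort.offspring_ids),
        cohort_tag="offspring",
    )
    return adj_f.coords, adj_o.coords


def recover_module_h2(
    h2_true: float,
    n_pairs: int = 800,
    seed: int = 0,
    grid_shape: tuple[int, int] = (6, 7),
    module_label: int = 1,
    pa_iters: int = 30,
) -> ModularHeritabilityResult:
    """One parameter-recovery run: planted h2 -> estimated module h2.

    All four planted modules carry the same h2; measurement noise is 0
    so the planted truth is exactly Va / (Va + Ve).
    """
    design = default_design(
        grid_shape=grid_shape, n_pairs=n_pairs, seed=seed, h2=(h2_true,) * 4, noise_sd=0.0
    )
    template = make_template(design.grid_shape)
    cohort = simulate_cohort(design, template)
    adj_f, adj_o = symmetrized_adjusted_pairs(cohort, template)
    idx = np.flatnonzero(default_partition(template) == module_label)
    pooled = np.concatenate([adj_f, adj_o])
    n = cohort.n_pairs
    space = module_shape_space(pooled, idx, module_id=module_label, pa_iters=pa_iters, seed=seed)
    return modular_h2(space, np.arange(n), np.arange(n, 2 * n))


def coheritability_study(
    design: SimulationDesign,
) -> tuple[CoheritabilityMatrix, TemplateMesh, np.ndarray]:
    """Simulate a cohort and compute its symmetrized co-heritability matrix.

    Returns (symmetrized matrix, template, planted partition labels).
    """
    template = make_template(design.grid_shape)
    cohort = simulate_cohort(design, template)
    adj_f, adj_o = symmetrized_adjusted_pairs(cohort, template)
    matrix = symmetrize_matrix(landmark_coheritability(adj_f, adj_o))
    partition = (
        default_partition(template) if design.partition is None else design.partition
    )
    return matrix, template, partition
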