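"""Module shape spaces, modular h2, permutation tests, Meff, morphs,
stability curves."""

import numpy as np
import pytest

from faceherit import (
    default_design,
    default_partition,
    effective_tests,
    gpa,
    latent_morphs,
    make_template,
    modular_h2,
    module_correlations,
    module_shape_space,
    permutation_test,
    plsr_fit,
    rv_coefficient,
    simulate_cohort,
    subsample_stability,
    symmetrize,
)


# ---------------------------------------------------------------------------
# parallel analysis / module shape space
# ---------------------------------------------------------------------------


def _shape_factor_basis(base, n_factors, rng):
    """Orthonormal displacement directions surviving Procrustes alignment."""
    from faceherit.procrustes import similarity_tangent

    sim = similarity_tangent(base)
    raw = rng.normal(size=(base.size, n_factors))
    raw -= sim @ (sim.T @ raw)
    return np.linalg.qr(raw)[0]


def test_isotropic_noise_module_retains_at_most_one_pc():
    rng = np.random.default_rng(0)
    base = make_template((3, 2)).vertices
    shapes = base + 0.02 * rng.normal(size=(120, 6, 3))
    space = module_shape_space(shapes, np.arange(6), pa_iters=50, seed=1)
    assert space.retained <= 1


def test_three_planted_factors_retained():
    rng = np.random.default_rng(1)
    n = 300
    base = make_template((4, 2)).vertices
    m = base.shape[0]
    basis = _shape_factor_basis(base, 3, rng)
    scores = rng.normal(size=(n, 3)) * np.array([0.25, 0.2, 0.15])
    shapes = base + (scores @ basis.T).reshape(n, m, 3) + 0.01 * rng.normal(size=(n, m, 3))
    space = module_shape_space(shapes, np.arange(m), pa_iters=50, seed=2)
    assert space.retained == 3


def test_full_landmark_module_matches_global_gpa():
    design = default_design(grid_shape=(5, 5), n_pairs=30, seed=6)
    template = make_template(design.grid_shape)
    cohort = simulate_cohort(design, template)
    coords = cohort.father_array()
    space = module_shape_space(coords, np.arange(25), pa_iters=20, seed=0)
    direct = gpa(coords)
    assert np.allclose(space.aligned, direct.coords, atol=1e-12)


def test_scores_reconstruct_aligned_coords():
    rng = np.random.default_rng(3)
    shapes = rng.normal(size=(40, 5, 3))
    space = module_shape_space(shapes, np.arange(5), pa_iters=20, seed=0, remove_scale=False)
    recon = space.scores @ space.basis.T + space.consensus.reshape(-1)
    flat = space.aligned.reshape(40, -1)
    assert np.abs(recon - flat).max() < 1e-10
    # PCs orthonormal
    assert np.allclose(space.basis.T @ space.basis, np.eye(space.basis.shape[1]), atol=1e-10)


# ---------------------------------------------------------------------------
# modular h2 + permutation test
# ---------------------------------------------------------------------------


def _paired_scores(rng, n, q, h2):
    va = h2
    gf = rng.normal(0, np.sqrt(va), size=(n, q))
    go = 0.5 * gf + np.sqrt(0.75 * va) * rng.normal(size=(n, q))
    x = gf + rng.normal(0, np.sqrt(1 - va), size=(n, q))
    y = go + rng.normal(0, np.sqrt(1 - va), size=(n, q))
    return x, y


def test_identical_scores_give_h2_two():
    rng = np.random.default_rng(4)
    shapes = rng.normal(size=(40, 5, 3))
    space = module_shape_space(shapes, np.arange(5), pa_iters=20, seed=0, remove_scale=False)
    rows = np.arange(20)
    res = modular_h2(space, rows, rows, cohort="sons")
    assert res.h2 == pytest.approx(2.0, abs=1e-8)


def test_permutation_p_floor():
    rng = np.random.default_rng(5)
    x, y = _paired_scores(rng, 200, 3, 0.9)
    h2_obs, p = permutation_test(x, y, n_perm=99, seed=0)
    assert p == pytest.approx(1.0 / 100.0)
    assert h2_obs > 0.5


def test_strong_signal_reaches_min_p():
    rng = np.random.default_rng(6)
    x, y = _paired_scores(rng, 800, 4, 0.8)
    _, p = permutation_test(x, y, n_perm=999, seed=1)
    assert p == pytest.approx(1.0 / 1000.0)


def test_null_p_values_roughly_uniform():
    """KS test over repeated null permutation p-values (alpha = 1%)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(7)
    pvals = []
    for rep in range(100):
        x = rng.normal(size=(60, 3))
        y = rng.normal(size=(60, 3))
        _, p = permutation_test(x, y, n_perm=199, seed=rep)
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_permutation_requires_min_count(rng):
    with pytest.raises(ValueError):
        permutation_test(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)), n_perm=50)


# ---------------------------------------------------------------------------
# RV coefficient and effective tests
# ---------------------------------------------------------------------------


def test_rv_self_and_rotation_invariance(rng):
    x = rng.normal(size=(50, 4))
    assert rv_coefficient(x, x) == pytest.approx(1.0, abs=1e-12)
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    assert rv_coefficient(x, x @ q) == pytest.approx(1.0, abs=1e-10)


def test_rv_independent_blocks_near_zero():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(4000, 3))
    y = rng.normal(size=(4000, 5))
    assert rv_coefficient(x, y) < 0.03


def test_effective_tests_identity_and_rank_one():
    identity = effective_tests(np.eye(63))
    assert identity.m_eff == pytest.approx(63.0)
    assert identity.alpha_adj == pytest.approx(0.05 / 63)
    ones = effective_tests(np.ones((63, 63)))
    assert ones.m_eff == pytest.approx(1.0)
    assert ones.alpha_adj == pytest.approx(0.05)


def test_effective_tests_printed_threshold_convention():
    """36 independent blocks among 63 tests -> alpha = 0.05/36 = 1.3889e-3."""
    blocks = [1] * 27 + [4] * 9
    corr = np.zeros((63, 63))
    start = 0
    for b in blocks:
        corr[start : start + b, start : start + b] = 1.0
        start += b
    mt = effective_tests(corr)
    assert round(mt.m_eff) == 36
    assert mt.alpha_adj == pytest.approx(1.3889e-3, abs=5e-8)


def test_m_eff_bounds_on_random_correlation_matrices():
    rng = np.random.default_rng(10)
    for _ in range(100):
        z = rng.normal(size=(30, 12))
        corr = np.corrcoef(z, rowvar=False)
        mt = effective_tests(corr)
        assert 1.0 - 1e-9 <= mt.m_eff <= 12.0 + 1e-9


def test_effective_tests_rejects_asymmetric(rng):
    with pytest.raises(ValueError):
        effective_tests(rng.normal(size=(5, 5)))


def test_module_correlations_shape_and_diagonal(rng):
    shapes = rng.normal(size=(60, 12, 3))
    spaces = [
        module_shape_space(shapes, np.arange(i * 4, i * 4 + 4), module_id=i,
                           pa_iters=10, seed=i, remove_scale=False)
        for i in range(3)
    ]
    corr = module_correlations(spaces)
    assert corr.shape == (3, 3)
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)


# ---------------------------------------------------------------------------
# latent morphs
# ---------------------------------------------------------------------------


def _space_and_model(rng, planted=None, n=200, grid=(3, 2)):
    base = make_template(grid).vertices
    m = base.shape[0]
    basis = _shape_factor_basis(base, 2, rng) if planted is None else planted
    scores = rng.normal(size=(n, basis.shape[1])) * 0.2
    shapes = base + (scores @ basis.T).reshape(n, m, 3) + 0.005 * rng.normal(size=(n, m, 3))
    space = module_shape_space(shapes, np.arange(m), pa_iters=20, seed=0)
    x = space.retained_scores[: n // 2]
    y = space.retained_scores[n // 2 :]
    model = plsr_fit(x, y, 1)
    return space, model


def test_zero_multiplier_morph_is_consensus(rng):
    space, model = _space_and_model(rng)
    morph = latent_morphs(space, model, 0, sd_multiplier=0.0)
    assert np.allclose(morph["plus"], space.consensus, atol=1e-12)
    assert np.allclose(morph["normal_displacement"], 0.0, atol=1e-12)


def test_plus_minus_morphs_mirror(rng):
    space, model = _space_and_model(rng)
    morph = latent_morphs(space, model, 0, sd_multiplier=4.0)
    assert np.allclose(
        morph["plus"] - space.consensus, -(morph["minus"] - space.consensus), atol=1e-12
    )


def test_morph_direction_recovers_planted_loading():
    rng = np.random.default_rng(11)
    base = make_template((3, 2)).vertices
    planted = _shape_factor_basis(base, 1, rng)
    space, model = _space_and_model(rng, planted=planted, n=400)
    morph = latent_morphs(space, model, 0, sd_multiplier=4.0)
    direction = morph["direction"].reshape(-1)
    cos = abs(direction @ planted[:, 0]) / np.linalg.norm(direction)
    assert cos > 0.9


def test_morph_component_out_of_range(rng):
    space, model = _space_and_model(rng)
    with pytest.raises(ValueError):
        latent_morphs(space, model, 5)


# ---------------------------------------------------------------------------
# subsample stability
# ---------------------------------------------------------------------------


def test_full_size_single_rep_equals_full_sample():
    rng = np.random.default_rng(12)
    x, y = _paired_scores(rng, 120, 3, 0.6)
    from faceherit import estimate_h2

    curve = subsample_stability(x, y, sizes=[60, 120], reps=3, seed=0)
    full = curve[curve["size"] == 120]
    assert len(full) == 1
    assert full["h2"].iloc[0] == pytest.approx(estimate_h2(x, y).h2, abs=1e-12)


def test_stability_curve_deterministic_and_spread_shrinks():
    rng = np.random.default_rng(13)
    x, y = _paired_scores(rng, 400, 3, 0.6)
    a = subsample_stability(x, y, sizes=[40, 120, 300], reps=8, seed=5)
    b = subsample_stability(x, y, sizes=[40, 120, 300], reps=8, seed=5)
    assert a.equals(b)
    spread = a.groupby("size")["h2"].std()
    assert spread.loc[300] < spread.loc[40]


def test_subsample_size_bound(rng):
    x, y = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
    with pytest.raises(ValueError):
        subsample_stability(x, y, sizes=[30])
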