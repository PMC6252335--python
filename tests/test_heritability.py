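"""Core estimator: PLSR, shape R2, the b transform, h2 = 2b, and the
landmark co-heritability matrix."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from faceherit import (
    CoheritabilityMatrix,
    choose_ncomp,
    estimate_h2,
    landmark_coheritability,
    plsr_fit,
    r2_to_b,
    shape_r2,
    symmetrize_matrix,
)


def nipals_reference(x, y, ncomp):
    """Independent textbook NIPALS PLS2 (tight power-iteration tolerance)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean(0)
    yd = y - y.mean(0)
    ws, ps, qs = [], [], []
    for _ in range(ncomp):
        u = yd[:, np.argmax((yd**2).sum(0))]
        for _ in range(10000):
            w = xd.T @ u
            w /= np.linalg.norm(w)
            t = xd @ w
            q = yd.T @ t / (t @ t)
            u_new = yd @ q / (q @ q)
            if np.linalg.norm(u_new - u) < 1e-14 * max(1.0, np.linalg.norm(u)):
                break
            u = u_new
        t = xd @ w
        tt = t @ t
        p = xd.T @ t / tt
        q = yd.T @ t / tt
        xd = xd - np.outer(t, p)
        yd = yd - np.outer(t, q)
        ws.append(w)
        ps.append(p)
        qs.append(q)
    w_, p_, q_ = np.array(ws).T, np.array(ps).T, np.array(qs).T
    b = w_ @ np.linalg.inv(p_.T @ w_) @ q_.T
    return (x - x.mean(0)) @ b + y.mean(0)


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


def test_univariate_collapse_equals_least_squares(rng):
    x = rng.normal(size=(40, 1))
    y = 0.7 * x + 0.2 * rng.normal(size=(40, 1))
    model = plsr_fit(x, y, 1)
    slope = np.polyfit(x.ravel(), y.ravel(), 1)[0]
    fitted_slope = model.coefficients()[0, 0]
    assert fitted_slope == pytest.approx(slope, abs=1e-10)


def test_exact_linear_relation_reaches_r2_one(rng):
    x = rng.normal(size=(20, 4))
    y = x @ rng.normal(size=(4, 3))
    model = plsr_fit(x, y, 4)
    assert shape_r2(y, model.predict(x)) == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("ncomp", [1, 2, 3])
def test_fitted_values_match_independent_nipals(rng, ncomp):
    for _ in range(4):
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 2))
        model = plsr_fit(x, y, ncomp)
        assert np.abs(model.predict(x) - nipals_reference(x, y, ncomp)).max() < 1e-8


def test_full_rank_fit_matches_sklearn(rng):
    x = rng.normal(size=(25, 6))
    y = x @ rng.normal(size=(6, 4)) + 0.2 * rng.normal(size=(25, 4))
    model = plsr_fit(x, y, 6)
    sk = PLSRegression(n_components=6, scale=False).fit(x, y)
    assert np.abs(model.predict(x) - sk.predict(x)).max() < 1e-10


def test_latent_covariances_non_increasing(rng):
    x = rng.normal(size=(50, 8))
    y = x @ rng.normal(size=(8, 5)) + rng.normal(size=(50, 5))
    model = plsr_fit(x, y, 5)
    yc = y - y.mean(0)
    covs = []
    # recompute |cov(t_a, u_a)| from stored scores and loadings
    for a in range(model.n_components):
        t = model.x_scores[:, a]
        covs.append(abs(t @ (yc @ model.y_loadings[:, a])))
        yc = yc - np.outer(t, model.y_loadings[:, a])
    assert all(covs[i] >= covs[i + 1] - 1e-9 for i in range(len(covs) - 1))


def test_nested_coefficients_match_refits(rng):
    x = rng.normal(size=(30, 7))
    y = rng.normal(size=(30, 4))
    model = plsr_fit(x, y, 6)
    for a in (1, 3, 5):
        refit = plsr_fit(x, y, a)
        assert np.abs(model.coefficients(a) - refit.coefficients()).max() < 1e-10


def test_ncomp_bounds_rejected(rng):
    x = rng.normal(size=(10, 3))
    y = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        plsr_fit(x, y, 4)
    with pytest.raises(ValueError):
        plsr_fit(x, y, 0)


def test_mse_curve_is_non_increasing(rng):
    x = rng.normal(size=(30, 6))
    y = x @ rng.normal(size=(6, 3)) + 0.5 * rng.normal(size=(30, 3))
    model = plsr_fit(x, y, 5)
    assert all(np.diff(model.mse_curve) <= 1e-12)


# ---------------------------------------------------------------------------
# shape R2 and the b transform
# ---------------------------------------------------------------------------


def test_shape_r2_identities(rng):
    y = rng.normal(size=(15, 6))
    assert shape_r2(y, y) == 1.0
    assert shape_r2(y, np.tile(y.mean(0), (15, 1))) == 0.0
    with pytest.raises(ValueError):
        shape_r2(np.zeros((5, 3)), np.zeros((5, 3)))


def test_shape_r2_univariate_equals_classical(rng):
    x = rng.normal(size=50)
    y = 1.2 * x + rng.normal(size=50)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    classical = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert shape_r2(y[:, None], pred[:, None]) == pytest.approx(classical, abs=1e-12)


def test_negative_r2_clipped_with_warning(rng, caplog):
    y = rng.normal(size=(10, 2))
    bad = y.mean(0) + 5.0 * rng.normal(size=(10, 2))
    with caplog.at_level("WARNING"):
        assert shape_r2(y, bad) == 0.0
    assert "clipped" in caplog.text


def test_b_transform_identities():
    assert r2_to_b(1.0, 2.0, 2.0) == 1.0
    assert r2_to_b(0.0, 3.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        r2_to_b(0.5, 0.0, 1.0)


def test_b_transform_recovers_ols_slope(rng):
    x = rng.normal(size=100)
    y = 0.45 * x + 0.3 * rng.normal(size=100)
    slope = np.polyfit(x, y, 1)[0]
    est = estimate_h2(x[:, None], y[:, None])
    assert est.b == pytest.approx(slope, abs=1e-6)
    assert est.h2 == 2.0 * est.b


# ---------------------------------------------------------------------------
# estimate_h2
# ---------------------------------------------------------------------------


def test_self_regression_gives_h2_two(rng):
    z = rng.normal(size=(30, 5))
    est = estimate_h2(z, z)
    assert est.h2 == pytest.approx(2.0, abs=1e-8)
    assert est.r_squared == pytest.approx(1.0, abs=1e-10)


def test_broken_pairing_null_mean_near_zero():
    """Re-pairing offspring at random must destroy the h2 signal."""
    rng = np.random.default_rng(99)
    n = 800
    g = rng.normal(size=(n, 3))
    x = g + rng.normal(size=(n, 3))
    y = 0.5 * g + np.sqrt(0.75) * rng.normal(size=(n, 3)) + rng.normal(size=(n, 3))
    h2s = []
    for _ in range(50):
        h2s.append(estimate_h2(x[rng.permutation(n)], y).h2)
    assert abs(np.mean(h2s)) < 0.05


def test_h2_recovery_direct_scores():
    """Score-level oracle: h2 = 2 cov / var recovered within +-0.08."""
    rng = np.random.default_rng(5)
    h2_true, n = 0.6, 800
    ests = []
    for _ in range(20):
        va = h2_true  # Va + Ve = 1, so h2 = Va
        gf = rng.normal(0, np.sqrt(va), size=(n, 4))
        go = 0.5 * gf + np.sqrt(0.75 * va) * rng.normal(size=(n, 4))
        ef = rng.normal(0, np.sqrt(1 - va), size=(n, 4))
        eo = rng.normal(0, np.sqrt(1 - va), size=(n, 4))
        ests.append(estimate_h2(gf + ef, go + eo).h2)
    assert np.mean(ests) == pytest.approx(h2_true, abs=0.08)


def test_estimate_requires_min_pairs(rng):
    with pytest.raises(ValueError, match="10"):
        estimate_h2(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))


def test_cv_choice_prefers_zero_on_noise(rng):
    x = rng.normal(size=(200, 4))
    y = rng.normal(size=(200, 4))
    assert choose_ncomp(x, y) == 0


# ---------------------------------------------------------------------------
# landmark co-heritability matrix
# ---------------------------------------------------------------------------


def test_matrix_equals_looped_estimates(rng):
    n, k = 14, 5
    f = rng.normal(size=(n, k, 3))
    o = 0.5 * f + rng.normal(size=(n, k, 3))
    matrix = landmark_coheritability(f, o)
    for i in range(k):
        for j in range(k):
            est = estimate_h2(f[:, i, :], o[:, j, :], ncomp=3)
            assert matrix.values[i, j] == pytest.approx(est.h2, abs=1e-8)


def test_identical_cohorts_have_diagonal_two(rng):
    f = rng.normal(size=(12, 4, 3))
    matrix = landmark_coheritability(f, f)
    assert np.allclose(np.diag(matrix.values), 2.0, atol=1e-8)


def test_independent_modules_have_low_cross_coheritability():
    rng = np.random.default_rng(21)
    n = 600
    ga, gb = rng.normal(size=(n, 1)), rng.normal(size=(n, 1))
    load_a, load_b = rng.normal(size=(1, 2, 3)), rng.normal(size=(1, 2, 3))
    noise = 0.4
    f = np.concatenate([ga[:, :, None] * load_a, gb[:, :, None] * load_b], axis=1)
    o = np.concatenate(
        [(0.5 * ga + np.sqrt(0.75) * rng.normal(size=(n, 1)))[:, :, None] * load_a,
         (0.5 * gb + np.sqrt(0.75) * rng.normal(size=(n, 1)))[:, :, None] * load_b],
        axis=1,
    )
    f = f + noise * rng.normal(size=f.shape)
    o = o + noise * rng.normal(size=o.shape)
    m = landmark_coheritability(f, o).values
    within = np.concatenate([m[:2, :2].ravel(), m[2:, 2:].ravel()])
    between = np.concatenate([m[:2, 2:].ravel(), m[2:, :2].ravel()])
    assert within.min() > 0.3
    assert between.max() < 0.25


def test_symmetrize_matrix_arithmetic():
    m = symmetrize_matrix(np.array([[0.0, 1.0], [3.0, 0.0]]))
    assert np.array_equal(m.values, [[0.0, 2.0], [2.0, 0.0]])
    assert m.symmetrized
    assert np.array_equal(m.values, m.values.T)
    sym_in = np.array([[1.0, 0.5], [0.5, 1.0]])
    assert np.array_equal(symmetrize_matrix(sym_in).values, sym_in)
    with pytest.raises(ValueError):
        symmetrize_matrix(np.zeros((2, 3)))


def test_matrix_requires_matching_stacks(rng):
    with pytest.raises(ValueError):
        landmark_coheritability(rng.normal(size=(10, 4, 3)), rng.normal(size=(10, 5, 3)))
    with pytest.raises(ValueError):
        CoheritabilityMatrix(np.zeros((3, 4)))
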