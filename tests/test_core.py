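"""Unit and property tests for standardization, thresholding, the NIPALS
loop, deflation and the multi-component / sparsity-path drivers."""

import json
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import toscca
from toscca.core import make_init


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


def test_standardize_centers_and_scales():
    pair = toscca.standardize(
        np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [0.0], [2.0]])
    )
    np.testing.assert_allclose(pair.x1[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
    assert abs(pair.x2[:, 0].mean()) < 1e-12
    assert abs(pair.x2[:, 0].std(ddof=1) - 1.0) < 1e-12


def test_standardize_is_idempotent(rng):
    pair = toscca.standardize(rng.standard_normal((10, 4)), rng.standard_normal((10, 3)))
    again = toscca.standardize(pair.x1, pair.x2)
    np.testing.assert_allclose(again.x1, pair.x1, atol=1e-12)
    np.testing.assert_allclose(again.x2, pair.x2, atol=1e-12)


def test_standardize_rejects_bad_input(rng):
    x = rng.standard_normal((5, 3))
    with pytest.raises(ValueError, match="row count mismatch"):
        toscca.standardize(x, rng.standard_normal((6, 2)))
    xc = x.copy()
    xc[:, 1] = 7.0
    with pytest.raises(ValueError, match="X1_2"):
        toscca.standardize(xc, rng.standard_normal((5, 2)))
    xn = x.copy()
    xn[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        toscca.standardize(xn, rng.standard_normal((5, 2)))


def test_standardized_pair_invariants_enforced(rng):
    x1 = rng.standard_normal((6, 3))  # not standardized
    with pytest.raises(ValueError, match="not centered|not unit-scale"):
        toscca.StandardizedPair(
            x1, x1, [f"s{i}" for i in range(6)], list("abc"), list("abc")
        )


# ---------------------------------------------------------------------------
# soft_threshold_support
# ---------------------------------------------------------------------------


def _threshold_oracle(v, keep):
    """Exhaustive sorting oracle: descending magnitude, index tie-break."""
    a = np.abs(v)
    order = sorted(range(v.size), key=lambda i: (-a[i], i))
    lam = 0.0 if keep == v.size else a[order[keep]]
    w = np.zeros(v.size)
    for i in order[:keep]:
        w[i] = np.sign(v[i]) * (a[i] - lam)
    return w


def test_soft_threshold_shrinks_survivors():
    out = toscca.soft_threshold_support(np.array([3.0, -2.0, 1.0, 0.0]), keep=2)
    np.testing.assert_allclose(out, [2.0, -1.0, 0.0, 0.0])


def test_soft_threshold_keep_all_is_identity():
    v = np.array([3.0, -2.0])
    np.testing.assert_allclose(toscca.soft_threshold_support(v, keep=2), v)


def test_soft_threshold_boundary_tie_shrinks_to_zero():
    with pytest.warns(toscca.ThresholdTieWarning):
        out = toscca.soft_threshold_support(np.array([5.0, 5.0, 1.0]), keep=1)
    np.testing.assert_allclose(out, [0.0, 0.0, 0.0])


def test_soft_threshold_rejects_bad_keep():
    with pytest.raises(ValueError):
        toscca.soft_threshold_support(np.array([1.0, 2.0]), keep=0)
    with pytest.raises(ValueError):
        toscca.soft_threshold_support(np.array([1.0, 2.0]), keep=3)


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.sampled_from([-3.0, -2.0, -1.5, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0]),
        min_size=1,
        max_size=12,
    ),
    st.data(),
)
def test_soft_threshold_matches_sorting_oracle(values, data):
    v = np.array(values)
    keep = data.draw(st.integers(1, v.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", toscca.ThresholdTieWarning)
        out = toscca.soft_threshold_support(v, keep)
    np.testing.assert_allclose(out, _threshold_oracle(v, keep))
    assert np.count_nonzero(out) <= keep


# ---------------------------------------------------------------------------
# nipals_component
# ---------------------------------------------------------------------------


def test_unpenalized_nipals_matches_svd(small_pair, rng):
    """Without thresholding the loop is power iteration on X1'X2, so the
    weights must match the leading singular vector pair up to sign."""
    pair = small_pair
    comp = toscca.nipals_component(
        pair,
        toscca.SparsityLevel(pair.p, pair.q),
        init=rng.uniform(-1, 1, pair.p),
        tol=1e-14,
        max_iter=5000,
    )
    u, s, vt = np.linalg.svd(pair.x1.T @ pair.x2)
    for est, ref in ((comp.alpha, u[:, 0]), (comp.beta, vt[0])):
        err = min(np.abs(est - ref).max(), np.abs(est + ref).max())
        assert err < 1e-6


def test_self_paired_data_has_unit_correlation(rng):
    x = rng.standard_normal((15, 6))
    pair = toscca.standardize(x, x)
    comp = toscca.nipals_component(
        pair, toscca.SparsityLevel(6, 6), init=rng.uniform(-1, 1, 6), tol=1e-12
    )
    assert comp.rho_insample == pytest.approx(1.0, abs=1e-8)


def test_component_invariants(planted, rng):
    pair, _, _ = planted
    comp = toscca.nipals_component(
        pair, toscca.SparsityLevel(15, 12), init=rng.uniform(-1, 1, pair.p)
    )
    assert not comp.degenerate and comp.converged
    assert np.count_nonzero(comp.alpha) == 15
    assert np.count_nonzero(comp.beta) == 12
    assert np.linalg.norm(comp.gamma) == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.norm(comp.zeta) == pytest.approx(1.0, abs=1e-10)
    r = np.corrcoef(comp.gamma, comp.zeta)[0, 1]
    assert comp.rho_insample == pytest.approx(r, abs=1e-10)
    # sign convention: the largest-magnitude alpha entry is positive
    assert comp.alpha[np.argmax(np.abs(comp.alpha))] > 0


def test_rho_trajectory_is_monotone_up_to_tol(planted, rng):
    pair, _, _ = planted
    tol = 1e-6
    comp = toscca.nipals_component(
        pair, toscca.SparsityLevel(20, 15), init=rng.uniform(-1, 1, pair.p), tol=tol
    )
    diffs = np.diff(comp.rho_path)
    # essentially monotone: decreases only as terminal oscillations near
    # the fixed point, orders of magnitude below the correlation scale
    assert (diffs >= -100 * tol).all()
    assert comp.rho_path[-1] >= comp.rho_path.max() - 1e-4


def test_nonconvergence_is_flagged_not_raised(planted, rng):
    pair, _, _ = planted
    comp = toscca.nipals_component(
        pair,
        toscca.SparsityLevel(20, 15),
        init=rng.uniform(-1, 1, pair.p),
        tol=1e-15,
        max_iter=2,
    )
    assert comp.n_iter == 2 and not comp.converged


def test_true_support_recovered_on_planted_data(planted, rng):
    pair, truth, _ = planted
    comp = toscca.nipals_component(
        pair, toscca.SparsityLevel(15, 12), init=rng.uniform(-1, 1, pair.p)
    )
    est = set(np.flatnonzero(comp.alpha))
    true = set(truth.true_supports_1[0])
    assert len(est & true) / len(true) > 0.9


# ---------------------------------------------------------------------------
# deflate
# ---------------------------------------------------------------------------


def test_deflate_removes_basis_coordinate(rng):
    x = rng.standard_normal((6, 4))
    e1 = np.zeros(6)
    e1[0] = 1.0
    out = toscca.deflate(x, e1)
    np.testing.assert_allclose(out[0], 0.0, atol=1e-12)
    np.testing.assert_allclose(out[1:], x[1:], atol=1e-12)


def test_deflate_is_idempotent_and_matches_dense_projector(rng):
    x = rng.standard_normal((10, 4))
    g = rng.standard_normal(10)
    once = toscca.deflate(x, g)
    np.testing.assert_allclose(toscca.deflate(once, g), once, atol=1e-12)
    projector = np.eye(10) - np.outer(g, g) / (g @ g)
    np.testing.assert_allclose(once, projector @ x, atol=1e-10)
    np.testing.assert_allclose(g @ once, 0.0, atol=1e-10)


def test_deflate_rejects_zero_latent(rng):
    with pytest.raises(ValueError, match="zero"):
        toscca.deflate(rng.standard_normal((5, 3)), np.zeros(5))


# ---------------------------------------------------------------------------
# fit_toscca
# ---------------------------------------------------------------------------


def test_single_component_fit_equals_nipals(planted):
    pair, _, _ = planted
    level = toscca.SparsityLevel(15, 12)
    fit = toscca.fit_toscca(pair, level, k=1, seed=3)
    init = make_init("uniform_random", pair.x1, np.random.default_rng(3))
    comp = toscca.nipals_component(pair, level, init=init)
    np.testing.assert_array_equal(fit.components[0].alpha, comp.alpha)
    np.testing.assert_array_equal(fit.components[0].beta, comp.beta)


def test_unpenalized_latents_are_orthogonal_after_deflation(small_pair):
    pair = small_pair
    fit = toscca.fit_toscca(
        pair, toscca.SparsityLevel(pair.p, pair.q), k=2, seed=0, tol=1e-12,
        max_iter=5000,
    )
    g1, g2 = fit.components[0].gamma, fit.components[1].gamma
    z1, z2 = fit.components[0].zeta, fit.components[1].zeta
    assert abs(g1 @ g2) < 1e-8
    assert abs(z1 @ z2) < 1e-8


def test_cpev_curves_are_monotone_and_bounded(planted):
    pair, _, _ = planted
    fit = toscca.fit_toscca(pair, toscca.SparsityLevel(15, 12), k=3, seed=1)
    for curve, adj in ((fit.cpev_1, fit.cpev_adj_1), (fit.cpev_2, fit.cpev_adj_2)):
        assert (np.diff(curve) >= -1e-12).all()
        assert (adj <= curve + 1e-12).all()
        assert (curve >= 0).all() and (curve <= 1 + 1e-12).all()


def test_degenerate_component_truncates_with_warning(rng):
    # x2's two leading columns are identical, so with q_beta=1 the
    # boundary tie shrinks the whole beta vector to zero: signal-free at
    # the requested sparsity
    v = rng.standard_normal(12)
    w = rng.standard_normal(12)
    x1 = rng.standard_normal((12, 4))
    x2 = np.column_stack([v, v, w])
    pair = toscca.standardize(x1, x2)
    with pytest.warns(toscca.DegenerateComponentWarning):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", toscca.ThresholdTieWarning)
            fit = toscca.fit_toscca(pair, toscca.SparsityLevel(4, 1), k=2, seed=0)
    assert fit.k == 0
    assert fit.cpev_1.size == 0

    comp = toscca.nipals_component(
        pair, toscca.SparsityLevel(4, 1), init=rng.uniform(-1, 1, 4)
    )
    assert comp.degenerate and not comp.alpha.any() and not comp.beta.any()


def test_fit_is_deterministic_given_seed(planted):
    pair, _, _ = planted
    fits = [
        toscca.fit_toscca(pair, toscca.SparsityLevel(15, 12), k=2, seed=11)
        for _ in range(2)
    ]
    assert json.dumps(fits[0].to_dict(), sort_keys=True) == json.dumps(
        fits[1].to_dict(), sort_keys=True
    )
    np.testing.assert_array_equal(fits[0].weight_matrix_1(), fits[1].weight_matrix_1())
    np.testing.assert_array_equal(fits[0].weight_matrix_2(), fits[1].weight_matrix_2())


def test_fit_attaches_out_of_sample_correlations(planted):
    pair, _, _ = planted
    fit = toscca.fit_toscca(pair, toscca.SparsityLevel(15, 12), k=2, seed=5, folds=4)
    for comp in fit.components:
        assert comp.rho_oos is not None
        assert -1.0 <= comp.rho_oos <= 1.0
    # sparse in-sample correlations are optimistic relative to held-out data
    assert fit.components[0].rho_oos < fit.components[0].rho_insample


# ---------------------------------------------------------------------------
# fit_sparsity_path
# ---------------------------------------------------------------------------


def test_path_of_length_one_equals_fit(planted):
    pair, _, _ = planted
    level = toscca.SparsityLevel(15, 12)
    path = toscca.fit_sparsity_path(pair, [level], k=2, seed=9, init_mode="uniform_random")
    fit = toscca.fit_toscca(pair, level, k=2, seed=9)
    np.testing.assert_array_equal(path[0].weight_matrix_1(), fit.weight_matrix_1())


def test_path_levels_agree_with_independent_fits(planted):
    pair, _, _ = planted
    levels = [toscca.SparsityLevel(pa, 12) for pa in (8, 15, 30)]
    path = toscca.fit_sparsity_path(pair, levels, k=2, seed=4, init_mode="uniform_random")
    for level, fit in zip(levels, path):
        solo = toscca.fit_toscca(pair, level, k=2, seed=4)
        np.testing.assert_allclose(
            fit.weight_matrix_1(), solo.weight_matrix_1(), atol=1e-10
        )
        np.testing.assert_allclose(
            fit.weight_matrix_2(), solo.weight_matrix_2(), atol=1e-10
        )


def test_supports_nest_along_the_sparsity_grid(planted):
    pair, _, _ = planted
    levels = [toscca.SparsityLevel(pa, 12) for pa in (8, 15, 30)]
    path = toscca.fit_sparsity_path(pair, levels, k=2, seed=4)
    for comp_idx in range(2):
        supports = [
            set(np.flatnonzero(fit.components[comp_idx].alpha)) for fit in path
        ]
        for smaller, larger in zip(supports[:-1], supports[1:]):
            assert smaller <= larger


def test_path_requires_levels(planted):
    pair, _, _ = planted
    with pytest.raises(ValueError):
        toscca.fit_sparsity_path(pair, [], k=1)


def test_sparsity_level_validation():
    with pytest.raises(ValueError):
        toscca.SparsityLevel(0, 5)
    with pytest.raises(ValueError):
        toscca.SparsityLevel(3, -1)
    with pytest.raises(ValueError, match="exceeds"):
        toscca.SparsityLevel(100, 5).validate_for(10, 10)
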