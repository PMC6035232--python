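"""Elastic compensation: basis oracles, update steps, solver behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import profilecomp as pc
from profilecomp.align import AlignmentParams, _f_values
from profilecomp.synthgen import warped_profile_stack


class TestSincBasis:
    def test_node_identity(self):
        L = 8
        delta = 1.0 / (L - 1)
        nodes = np.arange(L) * delta
        B = pc.sinc_basis(nodes, L)
        np.testing.assert_allclose(B, np.eye(L), atol=1e-12)

    def test_L2_closed_form_at_half(self):
        B = pc.sinc_basis(np.array([0.5]), 2)
        np.testing.assert_allclose(B.ravel(), [2 / np.pi, 2 / np.pi], atol=1e-12)

    def test_interpolation_identity(self):
        rng = np.random.default_rng(0)
        L = 12
        c = rng.normal(size=L)
        nodes = np.arange(L) / (L - 1)
        f = pc.sinc_basis(nodes, L).T @ c
        np.testing.assert_allclose(f, c, atol=1e-12)


class TestSincBasisDeriv:
    def test_zero_at_own_node(self):
        L = 10
        delta = 1.0 / (L - 1)
        D = pc.sinc_basis_deriv(np.arange(L) * delta, L)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)

    def test_matches_central_difference(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.02, 0.98, 100)
        L = 14
        h = 1e-6
        num = (pc.sinc_basis(x + h, L) - pc.sinc_basis(x - h, L)) / (2 * h)
        np.testing.assert_allclose(pc.sinc_basis_deriv(x, L), num, atol=1e-5)

    def test_flat_template_has_near_zero_slope_in_node_units(self):
        # truncated sinc summation ripple: the mid-domain slope of a constant
        # template, measured per node spacing, is small relative to the level
        L = 40
        delta = 1.0 / (L - 1)
        c = np.full(L, 3.0)
        x = np.linspace(0.3, 0.7, 50)
        slope = pc.sinc_basis_deriv(x, L).T @ c
        assert np.abs(slope).max() * delta < 0.1 * c[0]


class TestSymmetryMatrix:
    def test_L4_block_pattern(self):
        expected = np.array([[1, 0], [0, 1], [0, 1], [1, 0]], float)
        np.testing.assert_array_equal(pc.symmetry_matrix(4), expected)

    def test_PtP_is_twice_identity(self):
        for L in (4, 8, 20):
            P = pc.symmetry_matrix(L)
            np.testing.assert_array_equal(P.T @ P, 2.0 * np.eye(L // 2))

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_folded_vector_is_mirror_symmetric(self, half, seed):
        rng = np.random.default_rng(seed)
        c = pc.symmetry_matrix(2 * half) @ rng.normal(size=half)
        np.testing.assert_array_equal(c, c[::-1])

    def test_odd_L_rejected(self):
        with pytest.raises(ValueError):
            pc.symmetry_matrix(5)


class TestDifferencePenalty:
    def test_constant_null_space(self):
        psi = pc.difference_penalty(7)
        c = np.full(7, 3.3)
        assert c @ psi @ c == pytest.approx(0.0, abs=1e-12)

    def test_single_difference(self):
        psi = pc.difference_penalty(2)
        c = np.array([0.0, 1.0])
        assert c @ psi @ c == pytest.approx(1.0)

    @given(st.integers(2, 20), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_quadratic_form_matches_brute_force_sum(self, size, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=size)
        psi = pc.difference_penalty(size)
        brute = sum((c[k] - c[k - 1]) ** 2 for k in range(1, size))
        assert c @ psi @ c == pytest.approx(brute, rel=1e-10)


class TestWeights:
    def test_awgn_unit_weights(self):
        X = np.tile(np.linspace(0, 1, 5)[:, None], (1, 3))
        sig = pc.weights(X, np.ones(6), np.ones(3), "awgn")
        np.testing.assert_array_equal(sig, np.ones((5, 3)))

    def test_poisson_zero_template_guard(self):
        X = np.tile(np.linspace(0, 1, 5)[:, None], (1, 2))
        sig = pc.weights(X, np.zeros(6), np.ones(2), "poisson", epsilon=1e-6)
        np.testing.assert_allclose(sig, 1e6)

    def test_outlier_column_zeroed(self):
        X = np.tile(np.linspace(0, 1, 5)[:, None], (1, 3))
        sig = pc.weights(X, np.ones(6), np.array([1.0, 0.0, 1.0]), "awgn")
        assert np.all(sig[:, 1] == 0.0)
        assert np.all(sig[:, [0, 2]] == 1.0)


def band_limited_stack(L=12, N=201, M=4, seed=0):
    rng = np.random.default_rng(seed)
    c_true = rng.uniform(1.0, 5.0, L)
    x = np.linspace(0, 1, N)
    col = pc.sinc_basis(x, L).T @ c_true
    return np.tile(col[:, None], (1, M)), c_true, x


class TestCoefficientUpdate:
    def test_recovers_band_limited_coefficients(self):
        Y, c_true, x = band_limited_stack()
        X = np.tile(x[:, None], (1, Y.shape[1]))
        c, _ = pc.coefficient_update(X, Y, np.ones_like(Y), alpha=1e-12, L=12)
        assert np.abs(c - c_true).max() < 1e-6

    def test_large_alpha_flattens_template(self):
        Y, _, x = band_limited_stack()
        X = np.tile(x[:, None], (1, Y.shape[1]))
        c, _ = pc.coefficient_update(X, Y, np.ones_like(Y), alpha=1e9, L=12)
        assert np.ptp(c) < 1e-3 * np.abs(c).mean()

    def test_symmetric_mode_mirror_exact(self):
        Y, _, x = band_limited_stack()
        X = np.tile(x[:, None], (1, Y.shape[1]))
        P = pc.symmetry_matrix(12)
        c, c_tilde = pc.coefficient_update(X, Y, np.ones_like(Y), 0.5, P=P)
        np.testing.assert_array_equal(c, c[::-1])
        np.testing.assert_array_equal(c, P @ c_tilde)

    def test_gradient_optimality(self):
        """The solve zeroes the energy gradient w.r.t. the coefficients."""
        rng = np.random.default_rng(2)
        N, M, L, alpha = 101, 6, 10, 0.7
        Y = rng.uniform(0, 50, (N, M))
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        sigma = rng.uniform(0.5, 2.0, (N, M))
        c, _ = pc.coefficient_update(X, Y, sigma, alpha, L=L)
        Phi = pc.sinc_basis(X.ravel(), L)
        w = sigma.ravel()
        grad = (Phi * w) @ Phi.T @ c + alpha * pc.difference_penalty(L) @ c - (
            Phi * w
        ) @ Y.ravel()
        assert np.linalg.norm(grad) < 1e-6 * np.linalg.norm(c)

    def test_all_outliers_rejected(self):
        Y, _, x = band_limited_stack()
        X = np.tile(x[:, None], (1, Y.shape[1]))
        with pytest.raises(ValueError, match="no valid profiles"):
            pc.coefficient_update(X, Y, np.zeros_like(Y), 0.5, L=12)


class TestOutlierUpdate:
    def test_identical_columns_all_valid(self):
        Y, c_true, x = band_limited_stack(M=8)
        X = np.tile(x[:, None], (1, 8))
        om = pc.outlier_update(Y, X, c_true)
        np.testing.assert_array_equal(om, np.ones(8))

    def test_garbage_column_flagged(self):
        Y, c_true, x = band_limited_stack(M=12)
        Y[:, 5] = 10.0 * np.abs(Y).max()
        X = np.tile(x[:, None], (1, 12))
        om = pc.outlier_update(Y, X, c_true)
        assert om[5] == 0.0
        assert om.sum() == 11

    def test_readmission_when_distance_drops(self):
        Y, c_true, x = band_limited_stack(M=12)
        Y[:, 5] = 10.0 * np.abs(Y).max()
        X = np.tile(x[:, None], (1, 12))
        assert pc.outlier_update(Y, X, c_true)[5] == 0.0
        Y[:, 5] = _f_values(X, c_true)[:, 5]  # coherent again
        assert pc.outlier_update(Y, X, c_true)[5] == 1.0

    def test_single_column_always_valid(self):
        om = pc.outlier_update(np.ones((5, 1)), np.zeros((5, 1)), np.ones(4))
        np.testing.assert_array_equal(om, [1.0])


class TestLocationUpdate:
    def test_omega_matrix_N4(self):
        expected = np.array(
            [[1, 2, 0, 0], [1, 1, 1, 0], [0, 1, 1, 1], [0, 0, 2, 1]], float
        )
        np.testing.assert_array_equal(pc.omega_matrix(4), expected)

    def test_uniform_locations_fixed_point_when_no_force(self):
        N, M = 21, 3
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        c = np.zeros(8)  # flat template -> z = 0
        Y = np.zeros((N, M))
        Xn = pc.location_update(X, c, Y, beta=10.0, gamma=np.ones((N, M)))
        np.testing.assert_allclose(Xn, X, atol=1e-12)

    def test_flat_template_relaxes_to_uniform_spacing(self):
        rng = np.random.default_rng(0)
        N = 31
        X = np.sort(rng.uniform(0, 1, (N, 2)), axis=0)
        X[0] = 0.0
        X[-1] = 1.0
        c = np.zeros(8)  # flat template: z = 0, pure diffusion
        Y = np.zeros((N, 2))
        for _ in range(3000):
            X = pc.location_update(X, c, Y, beta=10.0, gamma=np.ones((N, 2)))
        uniform = np.tile(np.linspace(0, 1, N)[:, None], (1, 2))
        np.testing.assert_allclose(X, uniform, atol=1e-4)

    def test_projection_enforces_bounds_and_monotonicity(self):
        rng = np.random.default_rng(5)
        N, M = 41, 7
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        c = rng.normal(0, 50, 16)  # violent template
        Y = rng.uniform(0, 100, (N, M))
        Xn = pc.location_update(X, c, Y, beta=0.01, gamma=np.ones((N, M)))
        assert Xn.min() >= 0.0 and Xn.max() <= 1.0
        assert np.all(Xn[0] == 0.0) and np.all(Xn[-1] == 1.0)
        assert np.all(np.diff(Xn, axis=0) >= 0.0)


class TestTotalEnergy:
    def test_perfect_fit_leaves_only_tension(self):
        N, M, L = 51, 4, 8
        params = AlignmentParams(alpha=1.0, beta=2.5, L=L, noise_model="awgn")
        c = np.full(L, 7.0)
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        Y = _f_values(X, c)
        E = pc.total_energy(X, c, Y, params, np.ones(M))
        assert E == pytest.approx(params.beta * M / (N - 1), rel=1e-9)

    def test_reduces_to_weighted_least_squares(self):
        rng = np.random.default_rng(3)
        N, M, L = 31, 5, 8
        params = AlignmentParams(alpha=1e-300, beta=1e-300, L=L, noise_model="awgn")
        c = rng.normal(size=L)
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        Y = rng.uniform(0, 5, (N, M))
        om = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
        E = pc.total_energy(X, c, Y, params, om)
        brute = float(np.sum(om[None, :] * (_f_values(X, c) - Y) ** 2))
        assert E == pytest.approx(brute, rel=1e-9)

    def test_poisson_zero_image_near_zero(self):
        N, M = 21, 3
        params = AlignmentParams(L=8, noise_model="poisson")
        X = np.tile(np.linspace(0, 1, N)[:, None], (1, M))
        E = pc.total_energy(X, np.zeros(8), np.zeros((N, M)), params, np.ones(M))
        # E_Y = sum of epsilon terms plus the tension term
        assert E == pytest.approx(params.beta * M / (N - 1), abs=1e-3)

    def test_poisson_negative_counts_rejected(self):
        params = AlignmentParams(L=8, noise_model="poisson")
        X = np.tile(np.linspace(0, 1, 5)[:, None], (1, 2))
        with pytest.raises(ValueError):
            pc.total_energy(X, np.ones(8), np.full((5, 2), -1.0), params, np.ones(2))


class TestCompensate:
    def test_identical_band_limited_columns_recovered(self):
        Y, c_true, x = band_limited_stack(L=12, N=201, M=5, seed=4)
        params = AlignmentParams(
            alpha=1e-9, beta=10.0, L=12, noise_model="awgn", symmetric=False
        )
        state, ideal = pc.compensate(Y, params)
        np.testing.assert_allclose(ideal(x), Y[:, 0], atol=1e-4)
        uniform = np.tile(x[:, None], (1, 5))
        assert np.abs(state.X - uniform).max() < 1e-3
        np.testing.assert_array_equal(state.omega, np.ones(5))

    def test_noiseless_warped_stack_variance_collapse(self):
        Y, _, _ = warped_profile_stack(seed=6, noise="none", warp_strength=0.4)
        state, _ = pc.compensate(
            Y, AlignmentParams(noise_model="awgn", symmetric=True)
        )
        cmap = pc.compensated_map(state, Y)
        assert cmap.var(axis=1).mean() <= 0.10 * Y.var(axis=1).mean()

    def test_single_column_is_smoothed_fit(self):
        rng = np.random.default_rng(8)
        y = 50 + 40 * np.exp(-0.5 * ((np.linspace(0, 1, 101) - 0.5) / 0.1) ** 2)
        Y = (y + rng.normal(0, 2, 101))[:, None]
        state, ideal = pc.compensate(
            Y, AlignmentParams(noise_model="awgn", symmetric=False)
        )
        np.testing.assert_array_equal(state.omega, [1.0])
        assert np.corrcoef(ideal(np.linspace(0, 1, 101)), y)[0, 1] > 0.97

    def test_locations_valid_at_every_iteration(self):
        Y, _, _ = warped_profile_stack(seed=2, n_profiles=10)
        state, _ = pc.compensate(
            Y, AlignmentParams(noise_model="poisson", symmetric=True),
            keep_history=True,
        )
        assert len(state.X_history) == state.iterations
        for Xh in state.X_history:
            assert Xh.min() >= 0.0 and Xh.max() <= 1.0
            assert np.all(Xh[0] == 0.0) and np.all(Xh[-1] == 1.0)
            assert np.all(np.diff(Xh, axis=0) >= -1e-15)

    def test_symmetric_template_mirror_exact(self):
        Y, _, _ = warped_profile_stack(seed=3, n_profiles=10)
        state, ideal = pc.compensate(
            Y, AlignmentParams(noise_model="poisson", symmetric=True)
        )
        np.testing.assert_array_equal(state.c, state.c[::-1])
        assert ideal.symmetric


class TestCompensatedMap:
    def test_uniform_locations_identity(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(0, 9, (21, 4))
        state = pc.AlignmentState(
            X=np.tile(np.linspace(0, 1, 21)[:, None], (1, 4)),
            c=np.zeros(8), omega=np.ones(4),
            energy_trace=np.zeros(1), iterations=1,
        )
        np.testing.assert_allclose(pc.compensated_map(state, Y), Y, atol=1e-12)

    def test_constant_profiles_stay_constant(self):
        Y = np.full((31, 3), 2.5)
        X = np.tile(np.linspace(0, 1, 31)[:, None] ** 2, (1, 3))
        X[-1] = 1.0
        state = pc.AlignmentState(
            X=X, c=np.zeros(8), omega=np.ones(3),
            energy_trace=np.zeros(1), iterations=1,
        )
        np.testing.assert_allclose(pc.compensated_map(state, Y), 2.5, atol=1e-12)

    def test_known_warp_column_recovers_template(self):
        f = lambda x: 10 + 90 * np.exp(-0.5 * ((x - 0.5) / 0.15) ** 2)
        x = np.linspace(0, 1, 201)
        g = x**2  # monotone warp with g(0)=0, g(1)=1
        Y = f(g)[:, None]
        state = pc.AlignmentState(
            X=g[:, None].copy(), c=np.zeros(8), omega=np.ones(1),
            energy_trace=np.zeros(1), iterations=1,
        )
        out = pc.compensated_map(state, Y).ravel()
        np.testing.assert_allclose(out, f(x), atol=0.05)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"alpha": 0.0},
            {"beta": -1.0},
            {"L": 7},
            {"L": 2},
            {"noise_model": "gamma"},
            {"epsilon": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            AlignmentParams(**kw)

    def test_kind_defaults(self):
        assert AlignmentParams.for_kind("IN").symmetric
        assert not AlignmentParams.for_kind("RD").symmetric
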