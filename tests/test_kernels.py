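import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetblup import (
    AdmixtureMatrix,
    MaternParams,
    interaction_covariance,
    marker_kernel,
    matern_kappa,
    omega_matern,
    omega_mixture,
    omega_ones,
    pc_distances,
)


class TestMaternKappa:
    def test_unit_at_zero_distance(self):
        for nu in (0.3, 0.5, 2.0, 30.0, 1e4):
            assert matern_kappa(0.0, MaternParams(nu=nu, h=1.0)) == 1.0

    def test_exponential_special_case(self):
        """nu = 0.5 is the exponential kernel exp(-d/h) to 1e-10."""
        params = MaternParams(nu=0.5, h=1.0)
        d = np.concatenate([[1e-6], np.linspace(0.01, 50, 50)])
        np.testing.assert_allclose(matern_kappa(d, params), np.exp(-d), atol=1e-10)
        assert matern_kappa(2.0, params) == pytest.approx(np.exp(-2), abs=1e-10)

    def test_gaussian_limit(self):
        """Large nu approaches exp(-d^2 / (2 h^2))."""
        params = MaternParams(nu=1e6, h=1.0)
        d = np.linspace(0.0, 5, 50)
        np.testing.assert_allclose(
            matern_kappa(d, params), np.exp(-0.5 * d**2), atol=1e-6
        )
        assert matern_kappa(1.0, params) == pytest.approx(np.exp(-0.5), abs=1e-6)

    @given(
        nu=st.floats(0.05, 45.0),
        h=st.floats(0.1, 10.0),
        d1=st.floats(0.001, 20.0),
        d2=st.floats(0.001, 20.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_distance(self, nu, h, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        lo, hi = sorted((d1, d2))
        params = MaternParams(nu=nu, h=h)
        k_lo, k_hi = matern_kappa(lo, params), matern_kappa(hi, params)
        # strictly decreasing wherever the correlation has not underflowed
        assert k_lo > k_hi or (k_lo == 0.0 and k_hi == 0.0)

    def test_stable_at_extreme_shape(self):
        val = matern_kappa(1.0, MaternParams(nu=1e4, h=2.0))
        assert 0.0 < val <= 1.0 and np.isfinite(val)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            MaternParams(nu=-1.0, h=1.0)
        with pytest.raises(ValueError):
            matern_kappa(np.nan, MaternParams(nu=0.5, h=1.0))


class TestPCDistances:
    def test_euclidean_hand_case(self):
        D, d_max = pc_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert d_max == pytest.approx(5.0)

    def test_permutation_invariant_max(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(20, 4))
        _, d1 = pc_distances(P)
        _, d2 = pc_distances(P[rng.permutation(20)])
        assert d1 == pytest.approx(d2)

    def test_identical_rows_degenerate(self):
        D, d_max = pc_distances(np.zeros((5, 3)))
        assert d_max == 0.0
        assert np.abs(D).max() == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pc_distances(np.zeros((1, 3)))


class TestOmegaMixture:
    def _admixture(self, coeff):
        return AdmixtureMatrix(coeff=np.asarray(coeff, dtype=float))

    def test_rho_zero_is_all_ones(self):
        A = self._admixture([[1.0, 0.0], [0.0, 1.0]])
        omega = omega_mixture(A, rho=0.0)
        np.testing.assert_allclose(omega.omega, 1.0)

    def test_rho_one_pure_memberships_are_block_indicators(self):
        A = self._admixture([[1, 0], [1, 0], [0, 1]])
        omega = omega_mixture(A, rho=1.0)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(omega.omega, expected)

    def test_uniform_admixture_constant_matrix(self):
        K, rho = 4, 0.6
        A = self._admixture(np.full((5, K), 1.0 / K))
        omega = omega_mixture(A, rho=rho)
        np.testing.assert_allclose(omega.omega, rho / K + (1 - rho))

    def test_linear_in_rho(self, small_sim):
        A = small_sim.A_true
        w0 = omega_mixture(A, 0.0).omega
        w1 = omega_mixture(A, 1.0).omega
        for rho in (0.25, 0.7):
            np.testing.assert_array_equal(
                omega_mixture(A, rho).omega, rho * w1 + (1 - rho) * w0
            )

    def test_rho_out_of_bounds_rejected(self, small_sim):
        with pytest.raises(ValueError, match="rho"):
            omega_mixture(small_sim.A_true, rho=1.5)


class TestOmegaMatern:
    def test_duplicated_coordinates_fully_correlated(self):
        P = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        omega = omega_matern(P, MaternParams(nu=0.5, h=1.0))
        assert omega.omega[0, 1] == pytest.approx(1.0)

    def test_distance_h_at_exponential_shape(self):
        P = np.array([[0.0], [2.0]])
        omega = omega_matern(P, MaternParams(nu=0.5, h=2.0))
        assert omega.omega[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-10)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(50, 4))
        for nu, h in [(0.5, 0.5), (3.0, 2.0), (80.0, 1.0)]:
            omega = omega_matern(P, MaternParams(nu=nu, h=h))
            assert np.linalg.eigvalsh(omega.omega).min() >= -1e-8
            np.testing.assert_array_equal(np.diag(omega.omega), 1.0)


class TestInteractionCovariance:
    def test_all_ones_collapses_to_marker_kernel(self, small_sim):
        C = interaction_covariance(omega_ones(small_sim.X.n), small_sim.X)
        np.testing.assert_array_equal(C.C, marker_kernel(small_sim.X))

    def test_identity_omega_gives_diagonal(self, small_sim):
        n = small_sim.X.n
        omega = omega_ones(n)
        omega.omega = np.eye(n)
        omega.kind = "custom"
        C = interaction_covariance(omega, small_sim.X)
        Xc = small_sim.X.values - small_sim.X.values.mean(axis=0)
        np.testing.assert_allclose(np.diag(C.C), (Xc**2).sum(axis=1))
        off = C.C - np.diag(np.diag(C.C))
        assert np.abs(off).max() == 0.0

    def test_schur_product_stays_psd(self, small_sim, small_structure):
        _, _, P = small_structure
        omega = omega_matern(P.scores, MaternParams(nu=1.0, h=1.0))
        C = interaction_covariance(omega, small_sim.X)
        scale = np.abs(np.linalg.eigvalsh(C.C)).max()
        assert np.linalg.eigvalsh(C.C).min() >= -1e-8 * scale

    def test_dimension_mismatch_rejected(self, small_sim):
        with pytest.raises(ValueError, match="marker kernel"):
            interaction_covariance(omega_ones(5), small_sim.X)
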