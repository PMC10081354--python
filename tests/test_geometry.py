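"""Riemannian primitives: closed-form examples, round trips, metric axioms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spdmean.geometry import (
    check_spd,
    exp_map,
    geodesic_distance,
    geodesic_midpoint,
    log_map,
    matrix_expm,
    matrix_logm,
    riemannian_norm,
    sym,
)
from conftest import random_spd


class TestValidation:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="not symmetric"):
            check_spd(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_rejects_indefinite_and_names_eigenvalue(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            check_spd(np.diag([1.0, -2.0]))

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            check_spd(np.ones((2, 3)))

    def test_accepts_and_symmetrizes(self):
        a = np.array([[2.0, 1e-12], [0.0, 3.0]])
        out = check_spd(a)
        assert np.array_equal(out, out.T)


class TestMatrixFunctions:
    def test_logm_identity_is_zero(self):
        assert np.allclose(matrix_logm(np.eye(3)), 0.0)

    def test_logm_diagonal(self):
        out = matrix_logm(np.diag([np.e, np.e**2]))
        assert np.allclose(out, np.diag([1.0, 2.0]))

    def test_expm_zero_is_identity(self):
        assert np.allclose(matrix_expm(np.zeros((4, 4))), np.eye(4))

    def test_expm_diagonal(self):
        assert np.allclose(matrix_expm(np.diag([1.0, 0.0])), np.diag([np.e, 1.0]))

    def test_logm_rejects_non_pd(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            matrix_logm(np.diag([1.0, 0.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trips(self, seed):
        rng = np.random.default_rng(seed)
        g = random_spd(rng, 5)
        assert np.allclose(matrix_expm(matrix_logm(g)), g, atol=1e-10)
        v = sym(rng.standard_normal((5, 5)))
        assert np.allclose(matrix_logm(matrix_expm(v)), v, atol=1e-10)


class TestMaps:
    def test_exp_map_zero_tangent(self, rng):
        phi = random_spd(rng, 4)
        assert np.allclose(exp_map(phi, np.zeros((4, 4))), phi)

    def test_exp_map_at_identity_is_expm(self, rng):
        v = sym(rng.standard_normal((4, 4)))
        assert np.allclose(exp_map(np.eye(4), v), matrix_expm(v), atol=1e-12)

    def test_log_map_trivials(self, rng):
        phi = random_spd(rng, 4)
        g = random_spd(rng, 4)
        assert np.allclose(log_map(phi, phi), 0.0, atol=1e-10)
        assert np.allclose(log_map(np.eye(4), g), matrix_logm(g), atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exp_log_mutual_inverse(self, seed):
        rng = np.random.default_rng(seed)
        phi, g = random_spd(rng, 6), random_spd(rng, 6)
        assert np.allclose(exp_map(phi, log_map(phi, g)), g, atol=1e-8)

    def test_log_map_norm_matches_distance(self, rng):
        from spdmean.geometry import spd_inv_sqrt

        phi, g = random_spd(rng, 5), random_spd(rng, 5)
        ih = spd_inv_sqrt(phi)
        v = log_map(phi, g)
        assert np.isclose(
            np.linalg.norm(ih @ v @ ih), geodesic_distance(phi, g), atol=1e-8
        )

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            exp_map(np.eye(3), np.zeros((4, 4)))


class TestDistance:
    def test_self_distance_zero(self, rng):
        g = random_spd(rng, 5)
        assert geodesic_distance(g, g) < 1e-12

    def test_closed_form_value(self):
        # logm of diag(e^2, e^2) is diag(2, 2); Frobenius norm 2*sqrt(2)
        d = geodesic_distance(np.eye(2), np.diag([np.e**2, np.e**2]))
        assert np.isclose(d, 2 * np.sqrt(2), atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 11))
        a, b = random_spd(rng, p), random_spd(rng, p)
        dab = geodesic_distance(a, b)
        assert dab >= 0
        assert abs(dab - geodesic_distance(b, a)) < 1e-8
        assert geodesic_distance(a, a) < 1e-10

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 21))
        g1, g2 = random_spd(rng, p), random_spd(rng, p)
        a = rng.standard_normal((p, p))
        while abs(np.linalg.det(a)) < 1e-6:
            a = rng.standard_normal((p, p))
        d0 = geodesic_distance(g1, g2)
        d1 = geodesic_distance(sym(a @ g1 @ a.T), sym(a @ g2 @ a.T))
        assert abs(d0 - d1) < 1e-8 * (1 + d0)

    def test_riemannian_norm(self, rng):
        assert riemannian_norm(np.eye(4)) == 0.0
        assert np.isclose(riemannian_norm(np.diag([np.e, 1 / np.e])), np.sqrt(2))
        g = random_spd(rng, 6)
        assert np.isclose(riemannian_norm(g), geodesic_distance(np.eye(6), g), atol=1e-10)


class TestMidpoint:
    def test_idempotent(self, rng):
        g = random_spd(rng, 4)
        assert np.allclose(geodesic_midpoint(g, g), g, atol=1e-10)

    def test_commuting_case_geometric_mean(self):
        mid = geodesic_midpoint(np.diag([1.0, 1.0]), np.diag([4.0, 16.0]))
        assert np.allclose(mid, np.diag([2.0, 4.0]), atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_equidistant_and_stationary(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = random_spd(rng, 5), random_spd(rng, 5)
        mid = geodesic_midpoint(g1, g2)
        assert abs(geodesic_distance(g1, mid) - geodesic_distance(g2, mid)) < 1e-8
        # first-order optimality: tangent residuals at the midpoint cancel
        from spdmean.geometry import spd_inv_sqrt

        ih = spd_inv_sqrt(mid)
        resid = matrix_logm(sym(ih @ g1 @ ih)) + matrix_logm(sym(ih @ g2 @ ih))
        assert np.abs(resid).max() < 1e-8
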