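"""Mean estimators: network forward/loss identities, convergence, AJD, ALE."""

import numpy as np
import pytest

from spdmean.estimators import (
    ALEMean,
    FrechetMeanGD,
    MSPDNN,
    ajd_pham,
    ale_mean,
    condition_fit,
    gradient_descent_mean,
    mspdnn_fit,
    mspdnn_loss,
    mspdnn_transform,
)
from spdmean.geometry import geodesic_distance, geodesic_midpoint, sym
from spdmean.synthetic import sample_cpc_dataset, theoretical_cpc_mean
from conftest import random_spd, random_spd_stack


class TestTransformAndLoss:
    def test_identity_weights_pass_through(self, rng):
        g = random_spd(rng, 4)
        assert np.allclose(mspdnn_transform(np.eye(4), g, lam=0.0), g, atol=1e-12)

    def test_zero_weights_with_unit_ridge(self, rng):
        g = random_spd(rng, 3)
        assert np.allclose(mspdnn_transform(np.zeros((3, 3)), g, lam=1.0), g, atol=1e-12)

    def test_output_symmetric(self, rng):
        w = rng.standard_normal((5, 5))
        g = random_spd(rng, 5)
        out = mspdnn_transform(w, g, lam=1e-4)
        assert np.abs(out - out.T).max() < 1e-10

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension mismatch"):
            mspdnn_transform(np.eye(3), random_spd(rng, 4))

    def test_loss_zero_at_inverse_sqrt(self, rng):
        g = random_spd(rng, 4)
        w_eig, u = np.linalg.eigh(g)
        v = u @ np.diag(w_eig**-0.25) @ u.T  # V = W W^T = g^{-1/2} for W = g^{-1/4}
        assert mspdnn_loss(v, g[None], lam=0.0) < 1e-20

    def test_loss_hand_computed_diagonal_case(self):
        # V = diag(1/2, 1/2): transformed matrices diag(1/4, 1) and diag(1, 1/4);
        # mean log = diag(-log2, -log2); loss = (1/4) * 2 * (log 2)^2
        coll = np.stack([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        w = np.diag([np.sqrt(0.5), np.sqrt(0.5)])
        expected = 0.5 * np.log(2.0) ** 2
        assert np.isclose(mspdnn_loss(w, coll, lam=0.0), expected, rtol=1e-12)
        assert np.isclose(expected, 0.24022650695910062)

    def test_loss_zero_at_frechet_mean(self, rng):
        from spdmean.geometry import spd_power

        coll = random_spd_stack(rng, 6, 5)
        g = FrechetMeanGD(tol=1e-12).fit(coll).mean_
        w_eig, u = np.linalg.eigh(g)
        w = u @ np.diag(w_eig**-0.25) @ u.T
        assert mspdnn_loss(w, coll, lam=0.0) < 1e-16
        assert spd_power(g, 1.0).shape == (5, 5)


class TestConditionFit:
    def test_single_matrix_zero(self, rng):
        g = random_spd(rng, 4)
        assert condition_fit(g, g[None]) < 1e-20

    def test_hand_computed_value(self):
        # residual logm(diag(e, e)) = I; loss = (1/4) * ||I||_F^2 = 0.5
        assert np.isclose(condition_fit(np.eye(2), np.diag([np.e, np.e])[None]), 0.5)

    def test_midpoint_satisfies_first_order_condition(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        mid = geodesic_midpoint(a, b)
        assert condition_fit(mid, np.stack([a, b])) < 1e-12


class TestGradientDescent:
    def test_duplicate_collection_converges_immediately(self, rng):
        g = random_spd(rng, 4)
        est = FrechetMeanGD().fit(np.stack([g, g]))
        assert geodesic_distance(est.mean_, g) < 1e-10
        assert est.converged_

    def test_commuting_geometric_mean(self):
        est = FrechetMeanGD(step=1.0).fit(np.stack([np.diag([1.0, 1.0]), np.diag([4.0, 4.0])]))
        assert np.abs(est.mean_ - np.diag([2.0, 2.0])).max() < 1e-8

    def test_invalid_step(self, rng):
        with pytest.raises(ValueError, match="step"):
            FrechetMeanGD(step=-1.0).fit(random_spd_stack(rng, 3, 3))

    def test_non_convergence_flag_not_exception(self, rng):
        est = FrechetMeanGD(max_iter=1, tol=1e-14).fit(random_spd_stack(rng, 5, 4))
        assert est.converged_ is False

    def test_matches_midpoint(self, rng):
        a, b = random_spd(rng, 6), random_spd(rng, 6)
        est = FrechetMeanGD(tol=1e-10).fit(np.stack([a, b]))
        assert geodesic_distance(est.mean_, geodesic_midpoint(a, b)) < 1e-8

    def test_weighted_mean_of_pair_slides_along_geodesic(self, rng):
        # weights (3, 1) put the mean at the 1/4 point of the geodesic
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        est = FrechetMeanGD(tol=1e-12).fit(np.stack([a, b]), sample_weight=[3.0, 1.0])
        d_a = geodesic_distance(est.mean_, a)
        d_b = geodesic_distance(est.mean_, b)
        assert np.isclose(d_a / (d_a + d_b), 0.25, atol=1e-6)


class TestMSPDNN:
    def test_duplicate_collection(self, rng):
        g = random_spd(rng, 4)
        est = MSPDNN().fit(np.stack([g, g, g]))
        assert geodesic_distance(est.mean_, g) < 1e-2
        assert est.converged_

    def test_commuting_geometric_mean(self):
        est = MSPDNN().fit(np.stack([np.diag([1.0, 1.0]), np.diag([4.0, 4.0])]))
        assert np.abs(est.mean_ - np.diag([2.0, 2.0])).max() < 1e-2

    def test_agrees_with_gradient_descent(self, rng):
        coll = random_spd_stack(rng, 10, 10)
        nn = MSPDNN().fit(coll)
        gd = FrechetMeanGD(tol=1e-10).fit(coll)
        assert geodesic_distance(nn.mean_, gd.mean_) < 1e-2

    def test_recovers_cpc_mean(self):
        truth, coll = sample_cpc_dataset(10, 10, seed=7)
        est = MSPDNN().fit(coll)
        from spdmean.evaluation import normalized_recovery_error

        assert normalized_recovery_error(est.mean_, theoretical_cpc_mean(truth)) < 1e-3

    def test_equal_weights_match_unweighted(self, rng):
        coll = random_spd_stack(rng, 5, 6)
        a = MSPDNN().fit(coll).mean_
        b = MSPDNN().fit(coll, sample_weight=np.full(5, 2.5)).mean_
        assert geodesic_distance(a, b) < 1e-8

    def test_loss_trace_finite_and_fitted_attributes(self, rng):
        est = MSPDNN(max_epochs=5, tol=1e-20).fit(random_spd_stack(rng, 4, 5))
        assert np.all(np.isfinite(est.loss_trace_))
        assert est.n_iter_ == 5 and est.converged_ is False
        assert est.condition_fit_ >= 0
        assert est.to_estimate().method == "mspdnn"

    def test_invalid_config(self, rng):
        with pytest.raises(ValueError, match="lr"):
            MSPDNN(lr=0.0).fit(random_spd_stack(rng, 3, 3))

    def test_minibatch_mode_runs(self, rng):
        coll = random_spd_stack(rng, 6, 4)
        est = MSPDNN(batch_size=2, max_epochs=30).fit(coll)
        gd = FrechetMeanGD(tol=1e-10).fit(coll)
        assert geodesic_distance(est.mean_, gd.mean_) < 0.2

    def test_sklearn_params_round_trip(self):
        est = MSPDNN(lr=0.02)
        assert MSPDNN(**est.get_params()).lr == 0.02


class TestAJD:
    def test_diagonal_collection_identity(self):
        coll = np.stack([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        b, info = ajd_pham(coll)
        assert info["criterion"] < 1e-10
        off = b - np.diag(np.diag(b))
        assert np.abs(off).max() < 1e-8

    def test_commuting_family_eigenbasis(self, rng):
        g = random_spd(rng, 5)
        coll = np.stack([g, sym(g @ g)])
        _, info = ajd_pham(coll)
        assert info["criterion"] < 1e-10

    def test_recovers_cpc_components(self):
        truth, coll = sample_cpc_dataset(10, 20, seed=3)
        b_hat, info = ajd_pham(coll)
        assert info["converged"]
        m = np.abs(b_hat @ truth.B)
        m = m / m.max(axis=1, keepdims=True)
        # generalized permutation: one unit entry per row/column, rest ~ 0
        assert (m.max(axis=1) == 1.0).all()
        assert np.sort(m, axis=1)[:, :-1].max() < 1e-3

    def test_needs_two_matrices(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            ajd_pham(random_spd(rng, 4)[None])


class TestALE:
    def test_diagonal_collection(self):
        est = ALEMean().fit(np.stack([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])]))
        assert np.abs(est.mean_ - np.diag([2.0, 2.0])).max() < 1e-10

    def test_duplicate_collection(self, rng):
        g = random_spd(rng, 5)
        est = ALEMean().fit(np.stack([g, g]))
        assert geodesic_distance(est.mean_, g) < 1e-8

    def test_exact_cpc_equals_theoretical_mean(self):
        truth, coll = sample_cpc_dataset(8, 12, seed=5)
        est = ALEMean().fit(coll)
        from spdmean.evaluation import normalized_recovery_error

        assert normalized_recovery_error(est.mean_, theoretical_cpc_mean(truth)) < 1e-6


class TestFunctionalWrappers:
    def test_wrappers_return_estimates(self, rng):
        coll = random_spd_stack(rng, 4, 4)
        for fn, name in [
            (mspdnn_fit, "mspdnn"),
            (gradient_descent_mean, "gradient_descent"),
            (ale_mean, "ale"),
        ]:
            est = fn(coll)
            assert est.method == name
            assert est.condition_fit >= 0
            assert est.mean.shape == (4, 4)
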