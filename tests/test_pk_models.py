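"""Model definitions: concentrations, AUC closed forms, sensitivities."""

import math

import numpy as np
import pytest
from scipy.integrate import quad as scipy_quad
from scipy.optimize import brentq

import aucquad as aq
from aucquad.pk_models import ParameterBox, parse_constraint, LN2

from conftest import INTERIOR_THETA, central_diff


class TestConcentration:
    def test_model1_starts_at_zero(self, models):
        assert models[1].conc({"ka": 1.0, "ke": 0.1}, 0.0)[0] == pytest.approx(0.0)

    def test_model3_initial_concentration_is_total_amplitude(self, models):
        c0 = models[3].conc({"k1": 1.0, "k2": 0.1, "alpha": 1.25}, 0.0)[0]
        assert c0 == pytest.approx(22.5)

    def test_model4_implicit_solution_matches_bisection_oracle(self, models):
        KM, Vm, C0, t = 20.0, 0.2, 10.0, 24.0
        oracle = brentq(
            lambda C: KM * math.log(C / C0) + (C - C0) + Vm * t, 1e-12, C0,
            xtol=1e-14)
        ours = models[4].conc({"KM": KM, "Vm": Vm}, t)[0]
        assert ours == pytest.approx(oracle, rel=1e-10)
        assert ours == pytest.approx(8.49, abs=0.01)

    def test_conc_many_matches_scalar_path(self, models):
        times = np.array([0.5, 3.0, 12.0, 24.0])
        for mid, model in models.items():
            theta = INTERIOR_THETA[mid]
            batch = model.conc_many(np.stack([theta, theta * 1.1]), times)
            np.testing.assert_allclose(batch[0], model.conc(theta, times),
                                       rtol=1e-7)
            np.testing.assert_allclose(batch[1], model.conc(theta * 1.1, times),
                                       rtol=1e-7)

    def test_rejects_nonpositive_parameters(self, models):
        with pytest.raises(ValueError):
            models[1].conc([1.0, -0.1], 2.0)

    def test_unknown_model_id(self):
        with pytest.raises(ValueError):
            aq.get_model(7)


class TestAUC:
    def test_model2_closed_form(self, models):
        auc = models[2].auc({"ka": 3 * LN2, "ke": LN2 / 12})
        assert auc == pytest.approx(336.63, abs=0.01)

    def test_model1_closed_form(self, models):
        auc = models[1].auc({"ka": 3 * LN2, "ke": LN2 / 12})
        assert auc == pytest.approx(250.07, abs=0.01)

    def test_model4_table_minimum_corner(self, models):
        assert models[4].auc({"KM": 2.0, "Vm": 1.0}) == pytest.approx(70.0, abs=0.1)

    @pytest.mark.parametrize("mid", [1, 2, 3])
    def test_closed_form_equals_numeric_integral(self, models, mid):
        theta = INTERIOR_THETA[mid]
        model = models[mid]
        numeric, _ = scipy_quad(lambda t: model.conc(theta, t)[0], 0.0, 24.0,
                                epsabs=1e-12, epsrel=1e-12, limit=200)
        assert model.auc(theta) == pytest.approx(numeric, abs=1e-9)

    def test_model4_ode_agrees_with_closed_form_identity(self, models):
        model = models[4]
        for KM in np.linspace(2, 20, 10):
            for Vm in np.linspace(0.2, 1.0, 10):
                closed = model.auc([KM, Vm])
                _, ode_auc = model.conc_ode([KM, Vm], [24.0])
                assert ode_auc == pytest.approx(closed, rel=1e-6)

    def test_model4_linear_limit(self, models):
        # KM >> C0 with Vm/KM fixed degenerates to first-order elimination
        k = 0.1
        KM = 1e3 * 10.0
        auc_mm = models[4].auc([KM, k * KM])
        auc_lin = 10.0 * (1 - math.exp(-k * 24.0)) / k
        assert auc_mm == pytest.approx(auc_lin, rel=1e-2)

    def test_model5_auc_matches_batch_path(self, models):
        theta = INTERIOR_THETA[5]
        scalar = models[5].auc(theta)
        batch = models[5].auc_many(theta[None, :])[0]
        assert batch == pytest.approx(scalar, rel=1e-6)


class TestSensitivities:
    def test_model1_ke_derivative_closed_form(self, models):
        t = np.array([2.0, 10.0])
        theta = INTERIOR_THETA[1]
        grad = models[1].conc_grad(theta, t)
        np.testing.assert_allclose(grad[:, 1], -20.0 * t * np.exp(-theta[1] * t),
                                   rtol=1e-12)

    def test_model3_auc_linear_in_alpha(self, models):
        theta = INTERIOR_THETA[3]
        expected = 10.0 * (1 - math.exp(-24 * theta[1])) / theta[1]
        assert models[3].auc_grad(theta)[2] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mid", [1, 2, 3, 4, 5])
    def test_gradients_match_finite_differences(self, models, mid):
        model = models[mid]
        theta = INTERIOR_THETA[mid]
        times = np.array([1.0, 6.0, 18.0, 24.0])
        bundle = model.sensitivities(theta, times)
        for i in range(theta.size):
            fd_c = central_diff(lambda th: model.conc(th, times), theta, i)
            np.testing.assert_allclose(
                bundle.conc_grad[:, i], fd_c, rtol=1e-5,
                atol=1e-5 * np.max(np.abs(bundle.conc_grad)))
            fd_a = central_diff(lambda th: model.auc(th), theta, i)
            assert bundle.auc_grad[i] == pytest.approx(
                float(fd_a), rel=1e-5, abs=1e-5 * abs(bundle.auc))

    @pytest.mark.parametrize("mid", [1, 2, 3, 4])
    def test_hessians_match_finite_differences_of_gradient(self, models, mid):
        model = models[mid]
        theta = INTERIOR_THETA[mid]
        times = np.array([2.0, 12.0])
        H = model.conc_hess(theta, times)
        Ha = model.auc_hess(theta)
        for i in range(theta.size):
            fd_c = central_diff(lambda th: model.conc_grad(th, times), theta, i)
            np.testing.assert_allclose(
                H[:, :, i], fd_c, rtol=1e-4, atol=1e-4 * np.max(np.abs(H)) + 1e-10)
            fd_a = central_diff(lambda th: model.auc_grad(th), theta, i)
            np.testing.assert_allclose(
                Ha[:, i], fd_a, rtol=1e-4, atol=1e-4 * np.max(np.abs(Ha)))

    def test_knots_outside_interval_rejected(self, models):
        with pytest.raises(ValueError):
            models[1].sensitivities(INTERIOR_THETA[1], [30.0])


class TestParameterBox:
    def test_parse_constraint_roundtrip(self):
        a, b = parse_constraint("ka >= 2*ke", ("ka", "ke"))
        np.testing.assert_allclose(a, [1.0, -2.0])
        assert b == 0.0
        a2, b2 = parse_constraint("ke <= 0.5*ka", ("ka", "ke"))
        np.testing.assert_allclose(a2, [0.5, -1.0])
        assert b2 == 0.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterBox(names=("a",), lower=np.array([2.0]), upper=np.array([1.0]))

    def test_constrained_sampling_respects_constraint(self, boxes):
        rng = np.random.default_rng(0)
        draws = boxes[1].sample(rng, 500)
        assert np.all(draws[:, 0] >= 2 * draws[:, 1])

    def test_corners_filter_infeasible(self, boxes):
        corners = boxes[1].corners()
        assert all(boxes[1].contains(c) for c in corners)
        # (ka_min, ke_max) violates ka >= 2 ke and must be dropped
        assert len(corners) == 3


class TestAUCRange:
    def test_degenerate_box(self, models):
        theta = INTERIOR_THETA[1]
        box = ParameterBox(names=("ka", "ke"), lower=theta, upper=theta)
        lo, hi = aq.auc_range(models[1], box, grid_density=3)
        expected = models[1].auc(theta)
        assert lo == pytest.approx(expected, rel=1e-12)
        assert hi == pytest.approx(expected, rel=1e-12)

    def test_model2_published_range(self, models, boxes):
        lo, hi = aq.auc_range(models[2], boxes[2])
        assert round(lo) == 58
        assert round(hi) == 337
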