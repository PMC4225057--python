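"""Nested minimax search: inner maximization, envelope gradients, optimizers."""

import numpy as np
import pytest

import aucquad as aq
from aucquad.pk_models import ParameterBox
from aucquad.quadrature import Quadrature, gauss_legendre, clenshaw_curtis, trapezoid_weights

from conftest import INTERIOR_THETA

QUICK = aq.OptimizerSettings(seed=7, outer_starts=3, max_iterations=12,
                             inner_starts=6)


@pytest.fixture(scope="module")
def quick_trap(models, boxes):
    return aq.optimize_trapezoid(models[1], boxes[1], aq.NoiseModel(0.10), 4,
                                 settings=QUICK)


@pytest.fixture(scope="module")
def quick_lc(models, boxes):
    return aq.optimize_lc(models[1], boxes[1], aq.NoiseModel(0.10), 2,
                          settings=QUICK)


class TestMaxRisk:
    def test_degenerate_box_returns_point_risk(self, models):
        theta = INTERIOR_THETA[1]
        box = ParameterBox(names=("ka", "ke"), lower=theta, upper=theta)
        q = gauss_legendre(3)
        th, obj = aq.max_risk(q, models[1], box, aq.NoiseModel(0.05),
                              grid_density=2)
        np.testing.assert_allclose(th, theta)
        assert obj == pytest.approx(
            aq.relative_risk(q, models[1], theta, aq.NoiseModel(0.05)).value,
            rel=1e-12)

    @pytest.mark.parametrize("mid,cv", [(1, 0.05), (4, 0.05)])
    def test_grid_oracle_agreement(self, models, boxes, mid, cv):
        # brute-force 200x200 scan must not beat the multistart ascent
        q = gauss_legendre(4)
        noise = aq.NoiseModel(cv)
        th, obj = aq.max_risk(q, models[mid], boxes[mid], noise)
        grid = boxes[mid].grid(200)
        grid_max = float(np.max(
            aq.relative_risk_many(q, models[mid], grid, noise)))
        assert obj >= grid_max - 1e-8
        assert obj == pytest.approx(grid_max, rel=1e-4)

    def test_monotone_in_cv_for_fixed_design(self, models, boxes):
        q = gauss_legendre(4)
        objs = [aq.max_risk(q, models[1], boxes[1], aq.NoiseModel(cv))[1]
                for cv in (0.0, 0.05, 0.10)]
        assert objs[0] <= objs[1] <= objs[2]


class TestOuterGradient:
    def test_weight_partial_closed_form(self, models):
        theta = INTERIOR_THETA[1]
        model = models[1]
        noise = aq.NoiseModel(0.08)
        k = np.array([2.0, 8.0, 16.0, 24.0])
        w = np.array([3.0, 6.0, 7.0, 5.0])
        q = Quadrature(k, w)
        _, d_w = aq.outer_gradient(q, model, theta, noise)
        C = model.conc(theta, k)
        A = model.auc(theta)
        B = A - w @ C
        expected = (2 * noise.cv**2 * w * C**2 - 2 * B * C) / A**2
        np.testing.assert_allclose(d_w, expected, rtol=1e-12)

    @pytest.mark.parametrize("mid", [1, 2, 3, 4, 5])
    def test_matches_finite_differences(self, models, mid):
        theta = INTERIOR_THETA[mid]
        model = models[mid]
        noise = aq.NoiseModel(0.06)
        k = np.array([1.5, 7.0, 15.0, 22.0])
        w = np.array([4.0, 6.0, 7.0, 6.0])
        d_t, d_w = aq.outer_gradient(Quadrature(k, w), model, theta, noise)
        h = 1e-6
        for i in range(4):
            for (vec, grad) in ((k, d_t), (w, d_w)):
                vp, vm = vec.copy(), vec.copy()
                vp[i] += h
                vm[i] -= h
                if vec is k:
                    fd = (aq.relative_risk(Quadrature(vp, w), model, theta, noise).value
                          - aq.relative_risk(Quadrature(vm, w), model, theta, noise).value) / (2 * h)
                else:
                    fd = (aq.relative_risk(Quadrature(k, vp), model, theta, noise).value
                          - aq.relative_risk(Quadrature(k, vm), model, theta, noise).value) / (2 * h)
                assert grad[i] == pytest.approx(
                    fd, rel=2e-5, abs=2e-5 * max(np.max(np.abs(d_t)),
                                                 np.max(np.abs(d_w))))


class TestOptimizeTrapezoid:
    def test_knot_constraints(self, quick_trap):
        k = quick_trap.quadrature.knots
        assert np.all(np.diff(k) > 0)
        assert k[-1] == pytest.approx(24.0)
        assert quick_trap.quadrature.kind == "trapezoid"

    def test_beats_equispaced_schedule(self, models, boxes, quick_trap):
        eq = np.linspace(6.0, 24.0, 4)
        q = Quadrature(eq, trapezoid_weights(eq), kind="trapezoid")
        _, obj_eq = aq.max_risk(q, models[1], boxes[1], aq.NoiseModel(0.10))
        assert quick_trap.objective <= obj_eq * (1 + 1e-9)

    def test_objective_consistent_with_theta_star(self, models, quick_trap):
        recomputed = aq.relative_risk(
            quick_trap.quadrature, models[1], quick_trap.theta_star,
            aq.NoiseModel(0.10)).value
        assert quick_trap.objective == pytest.approx(recomputed, abs=1e-10)

    def test_reproducible_bit_identical(self, models, boxes):
        kw = dict(settings=aq.OptimizerSettings(seed=3, outer_starts=2,
                                                max_iterations=6))
        a = aq.optimize_trapezoid(models[1], boxes[1], aq.NoiseModel(0.1), 3, **kw)
        b = aq.optimize_trapezoid(models[1], boxes[1], aq.NoiseModel(0.1), 3, **kw)
        np.testing.assert_array_equal(a.quadrature.knots, b.quadrature.knots)
        np.testing.assert_array_equal(a.quadrature.weights, b.quadrature.weights)
        assert a.objective == b.objective

    def test_extrapolated_kind_for_positive_c0(self, models, boxes):
        res = aq.optimize_trapezoid(models[2], boxes[2], aq.NoiseModel(0.1), 2,
                                    settings=QUICK)
        assert res.quadrature.kind == "trapezoid_extrapolated"

    def test_rejects_single_knot(self, models, boxes):
        with pytest.raises(ValueError):
            aq.optimize_trapezoid(models[1], boxes[1], aq.NoiseModel(0.1), 1)


class TestOptimizeLC:
    def test_beats_all_baselines_in_cell(self, models, boxes, quick_lc):
        noise = aq.NoiseModel(0.10)
        others = []
        for q in (gauss_legendre(2), clenshaw_curtis(2)):
            others.append(aq.max_risk(q, models[1], boxes[1], noise)[1])
        assert quick_lc.objective <= min(others) * (1 + 1e-9)

    def test_theta_star_inside_box(self, boxes, quick_lc):
        assert boxes[1].contains(quick_lc.theta_star, tol=1e-9)

    def test_result_serialization_roundtrip(self, models, quick_lc, tmp_path):
        payload = quick_lc.to_dict(models[1])
        assert set(payload) >= {"knots", "weights", "objective", "theta_star"}
        q = Quadrature.from_dict(payload)
        np.testing.assert_array_equal(q.knots, quick_lc.quadrature.knots)

    def test_baseline_evaluation_has_no_search(self, models, boxes):
        res = aq.evaluate_baseline("gl", models[1], boxes[1],
                                   aq.NoiseModel(0.05), 6)
        np.testing.assert_allclose(res.quadrature.knots, gauss_legendre(6).knots)
        assert res.sqrt_objective == pytest.approx(3.33e-2, rel=0.02)
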