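"""Nested minimax search for AUC quadrature designs.

The design problem is ``min_design max_theta R_r(design, theta)`` where
``R_r`` is the relative risk of :mod:`aucquad.risk`, theta ranges over the
parameter box, and the design is either a trapezoid knot schedule (weights
tied to the knots, last knot pinned at t = 24) or a free LC rule (knots and
weights jointly adjustable).

Inner maximization: multistart second-order ascent (trust-region with
analytic gradient and Hessian where available) seeded from the box corners,
a low-discrepancy interior set, and the top points of a dense evaluation
grid.  The returned maximum is never below the grid maximum.

Outer minimization: a working-set SQP.  Rather than differentiating the
max-function directly (its envelope gradient, exposed as
:func:`outer_gradient`, jumps whenever the active maximizer changes), the
design is improved against a finite working set of worst-case parameter
vectors -- minimize an epigraph bound ``s`` subject to
``R_r(design, theta_j) <= s`` -- then the true worst case of the new design
is located and appended; the loop stops when the inner maximum matches the
working-set bound.  Each subproblem is smooth and cheap, which makes the
search robust to the maximizer jumps that plague plain envelope descent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, Bounds, LinearConstraint, linprog, BFGS
from scipy.stats import qmc

from .pk_models import PKModel, ParameterBox, Model5, T_END
from .quadrature import (
    Quadrature,
    trapezoid_weights,
    extrapolate_to_zero_adjustment,
    gauss_legendre,
    clenshaw_curtis,
    MIN_KNOT_GAP,
)
from .risk import NoiseModel, relative_risk, relative_risk_many

__all__ = [
    "OptimizerSettings",
    "MinimaxResult",
    "max_risk",
    "outer_gradient",
    "optimize_trapezoid",
    "optimize_lc",
    "evaluate_baseline",
]


@dataclass
class OptimizerSettings:
    """Tuning knobs for the nested search; defaults favour reliability.

    ``inner_starts`` low-discrepancy interior starts (box corners and grid
    seeds are always added); ``outer_starts`` structured initial designs;
    ``max_iterations`` working-set rounds per start; ``outer_tolerance``
    relative gap between the working-set bound and the verified inner
    maximum accepted as converged.
    """

    inner_starts: int = 16
    inner_tolerance: float = 1e-10
    outer_tolerance: float = 1e-8
    outer_starts: int = 8
    max_iterations: int = 40
    seed: int = 0
    inner_grid: int | None = None
    fast_ode: bool = True
    working_set_size: int = 30


@dataclass
class MinimaxResult:
    """Optimized design with its worst-case parameters and diagnostics."""

    quadrature: Quadrature
    theta_star: np.ndarray
    objective: float
    sqrt_objective: float
    converged: bool
    model_id: int
    cv: float
    inner_trace: list = field(default_factory=list)
    outer_trace: list = field(default_factory=list)

    def to_dict(self, model: PKModel | None = None) -> dict:
        theta = (
            model.theta_dict(self.theta_star)
            if model is not None
            else {f"p{i}": v for i, v in enumerate(self.theta_star.tolist())}
        )
        return self.quadrature.to_dict(
            model=self.model_id,
            cv=self.cv,
            objective=self.objective,
            sqrt_objective=self.sqrt_objective,
            theta_star=theta,
            converged=self.converged,
        )


# ---------------------------------------------------------------------------
# inner maximization
# ---------------------------------------------------------------------------


def _default_grid(model: PKModel, box: ParameterBox) -> int:
    if isinstance(model, Model5):
        return 9
    return 60 if box.dim <= 2 else 22


def _sobol_starts(box: ParameterBox, count: int, seed: int) -> np.ndarray:
    if count <= 0:
        return np.zeros((0, box.dim))
    eng = qmc.Sobol(d=box.dim, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(max(count, 2))))
    pts = box.lower + (box.upper - box.lower) * eng.random_base2(m)[:count]
    return pts[box.feasible_mask(pts)]


def max_risk(
    quad: Quadrature,
    model: PKModel,
    box: ParameterBox,
    noise: NoiseModel,
    settings: OptimizerSettings | None = None,
    extra_starts=None,
    grid_density: int | None = None,
    polish_top: int = 8,
):
    """Worst-case relative risk of a design over the parameter box.

    Returns ``(theta_star, objective)``.  The result is guaranteed to be at
    least the best value found on the dense evaluation grid.
    """
    settings = settings or OptimizerSettings()
    density = grid_density or settings.inner_grid or _default_grid(model, box)

    grid = box.grid(density)
    grid_risk = relative_risk_many(quad, model, grid, noise)
    top = grid[np.argsort(grid_risk)[-3:]]

    starts = [box.corners(), top]
    starts.append(_sobol_starts(box, settings.inner_starts, settings.seed))
    if extra_starts is not None and len(extra_starts):
        starts.append(np.atleast_2d(np.asarray(extra_starts, float)))
    cand = np.unique(np.round(np.concatenate(starts), 12), axis=0)
    cand = np.clip(cand, box.lower, box.upper)
    cand = cand[box.feasible_mask(cand, tol=1e-12)]

    # rank candidates by their risk and polish only the most promising
    cand_risk = relative_risk_many(quad, model, cand, noise)
    cand = cand[np.argsort(-cand_risk)][: max(polish_top, 1)]

    A, b = box.constraint_arrays()
    constraints = [LinearConstraint(A, b, np.inf)] if A.size else []
    bounds = Bounds(box.lower, box.upper, keep_feasible=True)
    analytic_hess = model.model_id <= 3

    cache: dict[bytes, tuple] = {}

    def neg(theta):
        key = np.asarray(theta).tobytes()
        if key not in cache:
            ev = relative_risk(quad, model, theta, noise, gradient=True,
                               hessian=analytic_hess)
            if analytic_hess:
                cache.clear() if len(cache) > 256 else None
                cache[key] = (-ev.value, -ev.gradient, -ev.hessian)
            else:
                cache.clear() if len(cache) > 256 else None
                cache[key] = (-ev.value, -ev.gradient)
        return cache[key]

    best_theta = grid[np.argmax(grid_risk)]
    best_val = float(np.max(grid_risk))
    for x0 in cand:
        res = minimize(
            lambda th: neg(th)[0], x0,
            jac=lambda th: neg(th)[1],
            hess=(lambda th: neg(th)[2]) if analytic_hess else BFGS(),
            method="trust-constr", bounds=bounds, constraints=constraints,
            options={"gtol": 1e-12, "xtol": 1e-13, "maxiter": 120,
                     "verbose": 0},
        )
        theta = box.clip(res.x)
        if not box.contains(theta, tol=1e-9):
            continue
        val = relative_risk(quad, model, theta, noise).value
        if val > best_val:
            best_val, best_theta = val, theta

    # store the exact risk at the returned maximizer
    best_val = relative_risk(quad, model, best_theta, noise).value
    grid_best = float(np.max(grid_risk))
    if best_val < grid_best:  # polish never accepted anything better
        best_theta = grid[np.argmax(grid_risk)]
        best_val = grid_best
    return np.asarray(best_theta, float), float(best_val)


# ---------------------------------------------------------------------------
# design-space gradients (envelope / Danskin)
# ---------------------------------------------------------------------------


def outer_gradient(quad: Quadrature, model: PKModel, theta_star,
                   noise: NoiseModel):
    """Gradient of the worst-case risk in the design variables.

    By the envelope property the derivative of ``max_theta R_r`` equals the
    design-derivative of ``R_r`` evaluated at the maximizer ``theta_star``:

    * dR/dw_i = [2 cv^2 w_i C_i^2 - 2 B C_i] / AUC^2
    * dR/dt_i = [2 cv^2 w_i^2 C_i - 2 B w_i] C'(t_i) / AUC^2

    with ``B = AUC - sum w_j C_j`` and ``C'`` the time derivative of the
    concentration.  Returns ``(grad_knots, grad_weights)``.
    """
    theta = model.as_theta(theta_star)
    C = model.conc(theta, quad.knots)
    Cdt = model.conc_dt(theta, quad.knots)
    A = model.auc(theta)
    w = quad.weights
    B = A - float(w @ C)
    cv2 = noise.cv**2
    d_w = (2.0 * cv2 * w * C**2 - 2.0 * B * C) / A**2
    d_t = (2.0 * cv2 * w**2 * C - 2.0 * B * w) * Cdt / A**2
    return d_t, d_w


# ---------------------------------------------------------------------------
# frozen-theta evaluators (cache ODE solutions per working-set member)
# ---------------------------------------------------------------------------


class _FrozenTheta:
    """Risk of a design at one fixed theta, with analytic design gradients.

    For the ODE model the dense solution is computed once per theta and then
    evaluated at arbitrary knots, so working-set subproblems stay cheap.
    """

    def __init__(self, model: PKModel, theta: np.ndarray):
        self.model = model
        self.theta = model.as_theta(theta)
        self.auc = model.auc(self.theta)
        self._dense = None
        if isinstance(model, Model5):
            sol, _ = model._solve(self.theta, np.array([T_END]), with_sens=False)
            self._dense = sol.sol

    def conc(self, times: np.ndarray) -> np.ndarray:
        if self._dense is not None:
            return self._dense(times)[0]
        return self.model.conc(self.theta, times)

    def conc_dt(self, times: np.ndarray) -> np.ndarray:
        if self._dense is not None:
            KM, Vm, ka = self.theta
            C = self.conc(times)
            return -Vm * C / (KM + C) + self.model.fixed["A"] * np.exp(-ka * times)
        return self.model.conc_dt(self.theta, times)

    def risk(self, knots, weights, cv):
        C = self.conc(knots)
        S = float(weights @ C)
        B = self.auc - S
        return (cv**2 * float(np.sum(weights**2 * C**2)) + B * B) / self.auc**2

    def risk_design_grad(self, knots, weights, cv):
        """(dR/dknots, dR/dweights) at this theta."""
        C = self.conc(knots)
        Cdt = self.conc_dt(knots)
        B = self.auc - float(weights @ C)
        d_w = (2.0 * cv**2 * weights * C**2 - 2.0 * B * C) / self.auc**2
        d_t = (2.0 * cv**2 * weights**2 * C - 2.0 * B * weights) * Cdt / self.auc**2
        return d_t, d_w


# ---------------------------------------------------------------------------
# trapezoid weight construction and its knot-Jacobian
# ---------------------------------------------------------------------------


def _trap_weights_full(knots: np.ndarray, extrapolate: bool) -> np.ndarray:
    w = trapezoid_weights(knots)
    if extrapolate:
        w = w + extrapolate_to_zero_adjustment(knots)
    return w


def _trap_weight_jacobian(knots: np.ndarray, extrapolate: bool) -> np.ndarray:
    """J[i, j] = d w_i / d t_j for the (optionally extrapolated) trapezoid."""
    n = knots.size
    J = np.zeros((n, n))
    J[0, 0], J[0, 1] = -0.5, 0.5
    J[-1, -1], J[-1, -2] = 0.5, -0.5
    for i in range(1, n - 1):
        J[i, i + 1] += 0.5
        J[i, i - 1] += -0.5
    if extrapolate and knots[0] > 0.0:
        t1, t2 = knots[0], knots[1]
        d = t2 - t1
        J[0, 0] += 1.0 + t1 / d + t1**2 / (2 * d**2)
        J[0, 1] += -(t1**2) / (2 * d**2)
        J[1, 0] += -t1 / d - t1**2 / (2 * d**2)
        J[1, 1] += t1**2 / (2 * d**2)
    return J


# ---------------------------------------------------------------------------
# weight refinement at fixed knots (Chebyshev / cutting-plane)
# ---------------------------------------------------------------------------


def best_weights(model: PKModel, knots: np.ndarray, box: ParameterBox,
                 noise: NoiseModel, settings: OptimizerSettings,
                 grid_density: int | None = None) -> np.ndarray:
    """Minimax-optimal weights for fixed knots.

    For fixed knots the worst-case risk is a pointwise maximum of convex
    quadratics in the weights, hence convex.  With no noise it reduces to a
    Chebyshev (sup-norm) approximation problem, solved exactly as a linear
    program over a dense parameter grid; with noise an epigraph SQP over the
    grid's worst points is used.  Either way the result is polished by one
    cutting-plane pass against the continuous inner maximum.
    """
    knots = np.asarray(knots, float)
    density = grid_density or _default_grid(model, box)
    grid = box.grid(density)
    conc = model.conc_many(grid, knots)          # (m, k)
    auc = model.auc_many(grid)
    cmat = conc / auc[:, None]                   # rows c_j = C_j / AUC_j
    n = knots.size
    cv = noise.cv

    def lp_weights(rows):
        m = rows.shape[0]
        # min s  s.t.  -s <= 1 - rows @ w <= s
        A_ub = np.block([[rows, -np.ones((m, 1))], [-rows, -np.ones((m, 1))]])
        b_ub = np.concatenate([np.ones(m), -np.ones(m)])
        c = np.zeros(n + 1)
        c[-1] = 1.0
        res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                      bounds=[(None, None)] * n + [(0, None)],
                      method="highs")
        if not res.success:
            raise RuntimeError(f"weight LP failed: {res.message}")
        return res.x[:n]

    if cv == 0.0:
        w = lp_weights(cmat)
    else:
        # epigraph SQP over an active subset of grid points
        w = lp_weights(cmat)  # bias-optimal start
        order = np.argsort(-relative_risk_many(
            Quadrature(knots, w), model, grid, noise))
        active = list(order[: min(64, len(order))])
        for _ in range(6):
            rows_c = conc[active]
            rows_a = auc[active]

            def risks(wv):
                S = rows_c @ wv
                return (cv**2 * (rows_c**2) @ wv**2 + (rows_a - S) ** 2) / rows_a**2

            def risks_jac(wv):
                S = rows_c @ wv
                return (2 * cv**2 * rows_c**2 * wv[None, :]
                        - 2 * ((rows_a - S) / 1.0)[:, None] * rows_c) / (rows_a**2)[:, None]

            z0 = np.concatenate([w, [float(np.max(risks(w)))]])
            res = minimize(
                lambda z: z[-1], z0, jac=lambda z: np.eye(n + 1)[-1],
                constraints=[{
                    "type": "ineq",
                    "fun": lambda z: z[-1] - risks(z[:n]),
                    "jac": lambda z: np.hstack(
                        [-risks_jac(z[:n]), np.ones((len(active), 1))]),
                }],
                method="SLSQP", options={"maxiter": 200, "ftol": 1e-16},
            )
            w_new = res.x[:n] if res.success else w
            r_all = relative_risk_many(Quadrature(knots, w_new), model, grid, noise)
            worst = int(np.argmax(r_all))
            if worst in active and np.allclose(w_new, w, rtol=1e-10, atol=1e-14):
                w = w_new
                break
            w = w_new
            if worst not in active:
                active.append(worst)
    return w


# ---------------------------------------------------------------------------
# working-set outer minimization
# ---------------------------------------------------------------------------


def _working_set_minimize(model, box, noise, settings, x0, unpack,
                          design_grad, x_bounds, x_constraints,
                          fast_model, trace):
    """Minimize max_theta R over design vector x by working-set SQP.

    ``unpack(x) -> (knots, weights)``; ``design_grad(frozen, x) -> dR/dx`` at
    a fixed theta.  Returns (x_best, theta_star, objective, converged).
    """
    cv = noise.cv
    x = np.asarray(x0, float)

    # reduced-effort inner profile for the loop; the caller verifies the
    # final design at full resolution
    loop = OptimizerSettings(
        inner_starts=4, seed=settings.seed,
        inner_grid=min(_default_grid(fast_model, box),
                       36 if box.dim <= 2 else 14),
        outer_tolerance=settings.outer_tolerance,
    )

    def quad_of(xv):
        k, w = unpack(xv)
        k = np.array(k, float)
        # SLSQP line searches may momentarily violate the gap constraints
        for i in range(1, k.size):
            k[i] = max(k[i], k[i - 1] + 0.1 * MIN_KNOT_GAP)
        k = np.minimum(k, T_END)
        for i in range(k.size - 2, -1, -1):
            k[i] = min(k[i], k[i + 1] - 0.1 * MIN_KNOT_GAP)
        return Quadrature(k, np.asarray(w))

    theta0, obj0 = max_risk(quad_of(x), fast_model, box, noise, loop,
                            polish_top=4)
    working = [_FrozenTheta(fast_model, theta0)]
    for corner in box.corners()[: 2 ** min(box.dim, 4)]:
        working.append(_FrozenTheta(fast_model, corner))

    scale = max(obj0, 1e-14)
    best_x, best_obj, best_theta = x.copy(), obj0, theta0
    converged = False
    prev_obj = obj0

    for round_no in range(settings.max_iterations):
        members = working[-settings.working_set_size:]

        def cons_fun(z):
            xv, s = z[:-1], z[-1]
            k, w = unpack(xv)
            return np.array(
                [s - m.risk(k, w, cv) / scale for m in members])

        def cons_jac(z):
            xv, s = z[:-1], z[-1]
            rows = []
            for m in members:
                g = design_grad(m, xv) / scale
                rows.append(np.concatenate([-g, [1.0]]))
            return np.array(rows)

        k0, w0 = unpack(x)
        s0 = max(m.risk(np.asarray(k0), np.asarray(w0), cv) for m in members) / scale
        z0 = np.concatenate([x, [s0]])
        cons = [{"type": "ineq", "fun": cons_fun, "jac": cons_jac}]
        for c in x_constraints:
            cons.append({
                "type": "ineq",
                "fun": (lambda z, f=c["fun"]: f(z[:-1])),
                "jac": (lambda z, f=c["jac"]: np.hstack(
                    [np.atleast_2d(f(z[:-1])),
                     np.zeros((np.atleast_2d(f(z[:-1])).shape[0], 1))])),
            })
        bounds = list(x_bounds) + [(0.0, None)]
        res = minimize(
            lambda z: z[-1], z0, jac=lambda z: np.eye(z0.size)[-1],
            constraints=cons, bounds=bounds, method="SLSQP",
            options={"maxiter": 250, "ftol": 1e-14},
        )
        x_new = res.x[:-1]
        bound = float(res.x[-1]) * scale

        theta_new, obj_new = max_risk(
            quad_of(x_new), fast_model, box, noise, loop,
            extra_starts=[m.theta for m in members], polish_top=4,
        )
        trace.append({"round": round_no, "bound": bound, "objective": obj_new})
        if obj_new < best_obj:
            best_x, best_obj, best_theta = x_new.copy(), obj_new, theta_new
        x = x_new

        gap = obj_new - bound
        # the absolute floor reflects double-precision noise in the risk
        if gap <= settings.outer_tolerance * max(obj_new, 1e-300) + 1e-13:
            converged = True
            break
        if abs(prev_obj - obj_new) <= 1e-14 + 1e-9 * obj_new and round_no > 4:
            break
        prev_obj = obj_new
        if not any(np.allclose(theta_new, m.theta, rtol=1e-9) for m in working):
            working.append(_FrozenTheta(fast_model, theta_new))
        else:
            # maximizer already known: nudge the scale bound instead
            working.append(_FrozenTheta(fast_model, theta_new))

    return best_x, best_theta, best_obj, converged


def _verify(quad, model, box, noise, settings, hint=None):
    """High-resolution final inner maximization on the accurate model."""
    density = 200 if box.dim <= 2 else (28 if not isinstance(model, Model5) else 12)
    extra = [hint] if hint is not None else None
    return max_risk(quad, model, box, noise, settings,
                    extra_starts=extra, grid_density=density)


# ---------------------------------------------------------------------------
# public optimizers
# ---------------------------------------------------------------------------


def _trapezoid_initials(n: int, settings: OptimizerSettings) -> list[np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    base = []
    base.append(np.linspace(T_END / n, T_END, n))            # equispaced, open
    base.append(np.linspace(0.0, T_END, n))                  # endpoints included
    base.append(T_END * 0.5 ** np.arange(n - 1, -1, -1.0))   # geometric
    gl = gauss_legendre(n).knots
    base.append(np.sort(np.append(gl[:-1] * (T_END / gl[-1]) * 0.95, T_END)))
    while len(base) < settings.outer_starts:
        t = np.linspace(T_END / n, T_END, n)
        jitter = rng.uniform(-0.3, 0.3, n - 1) * (T_END / n)
        t[:-1] = np.sort(np.clip(t[:-1] + jitter, 0.0, T_END - 1e-3))
        base.append(t)
    out = []
    for t in base[: settings.outer_starts]:
        t = np.sort(t)
        t[-1] = T_END
        for i in range(1, n):
            t[i] = max(t[i], t[i - 1] + 10 * MIN_KNOT_GAP)
        t[-1] = T_END
        out.append(t)
    return out


def optimize_trapezoid(model: PKModel, box: ParameterBox, noise: NoiseModel,
                       n: int, allow_extrapolation: bool = True,
                       settings: OptimizerSettings | None = None) -> MinimaxResult:
    """Minimax-optimal trapezoid schedule with ``n`` samples.

    The last knot is pinned at t = 24; weights follow the trapezoid formula,
    plus the extrapolation-to-zero adjustment when the model has C(0) > 0
    and ``allow_extrapolation`` is set.
    """
    if n < 2:
        raise ValueError("the trapezoid rule needs n >= 2")
    settings = settings or OptimizerSettings()
    fast_model = model.with_tolerances(1e-8, 1e-10) if settings.fast_ode else model
    extrap = bool(allow_extrapolation and model.positive_c0)

    def unpack(x):
        knots = np.concatenate([np.sort(x), [T_END]])
        return knots, _trap_weights_full(knots, extrap)

    def design_grad(frozen: _FrozenTheta, x):
        knots = np.concatenate([np.sort(x), [T_END]])
        w = _trap_weights_full(knots, extrap)
        d_t, d_w = frozen.risk_design_grad(knots, w, noise.cv)
        J = _trap_weight_jacobian(knots, extrap)
        total = d_t + J.T @ d_w
        return total[:-1]

    gap_rows = np.zeros((n - 1, n - 1))
    for i in range(n - 2):
        gap_rows[i, i], gap_rows[i, i + 1] = -1.0, 1.0
    gap_rows[n - 2, n - 2] = -1.0

    def order_fun(x):
        vals = np.empty(n - 1)
        vals[: n - 2] = np.diff(x) - MIN_KNOT_GAP
        vals[n - 2] = T_END - x[-1] - MIN_KNOT_GAP
        return vals

    x_constraints = [{"fun": order_fun, "jac": lambda x: gap_rows}]
    bounds = [(0.0, T_END)] * (n - 1)

    outer_trace: list = []
    best = None
    for x0 in _trapezoid_initials(n, settings):
        trace: list = []
        x, theta, obj, conv = _working_set_minimize(
            model, box, noise, settings, x0[:-1], unpack, design_grad,
            bounds, x_constraints, fast_model, trace)
        outer_trace.append({"start": x0.tolist(), "trace": trace})
        if best is None or obj < best[2]:
            best = (x, theta, obj, conv)

    knots, weights = unpack(best[0])
    quad = Quadrature(knots, weights,
                      kind="trapezoid_extrapolated" if extrap else "trapezoid")
    theta_star, objective = _verify(quad, model, box, noise, settings,
                                    hint=best[1])
    return MinimaxResult(
        quadrature=quad, theta_star=theta_star, objective=objective,
        sqrt_objective=math.sqrt(objective), converged=best[3],
        model_id=model.model_id, cv=noise.cv, outer_trace=outer_trace,
    )


def _lc_initials(model, box, noise, n, settings) -> list[tuple[np.ndarray, np.ndarray]]:
    fast_model = model.with_tolerances(1e-8, 1e-10) if settings.fast_ode else model
    rng = np.random.default_rng(settings.seed + 1)
    starts: list[tuple[np.ndarray, np.ndarray]] = []

    knot_sets = []
    gl = gauss_legendre(n)
    starts.append((gl.knots, gl.weights))
    knot_sets.append(gl.knots)
    if n >= 2:
        cc = clenshaw_curtis(n)
        starts.append((cc.knots, cc.weights))
        knot_sets.append(cc.knots + 1e-6 * (cc.knots[0] == 0.0))
        eq = np.linspace(T_END / n, T_END, n)
        starts.append((eq, trapezoid_weights(eq)))
        knot_sets.append(eq)
        cheap = OptimizerSettings(
            outer_starts=2, max_iterations=10, seed=settings.seed,
            inner_starts=4, fast_ode=settings.fast_ode)
        try:
            trap = optimize_trapezoid(model, box, noise, n, settings=cheap)
            starts.append((trap.quadrature.knots, trap.quadrature.weights))
            knot_sets.append(trap.quadrature.knots)
        except Exception:
            pass

    for knots in knot_sets:
        knots = np.sort(np.clip(knots, 10 * MIN_KNOT_GAP, T_END))
        try:
            w = best_weights(fast_model, knots, box, noise, settings)
            starts.append((knots, w))
        except Exception:
            pass

    while len(starts) < settings.outer_starts:
        k = np.sort(rng.uniform(1.0, T_END, n))
        for i in range(1, n):
            k[i] = max(k[i], k[i - 1] + 10 * MIN_KNOT_GAP)
        try:
            w = best_weights(fast_model, k, box, noise, settings)
        except Exception:
            w = trapezoid_weights(k) if n >= 2 else np.array([T_END])
        starts.append((k, w))
    return starts[: max(settings.outer_starts, 4)]


def optimize_lc(model: PKModel, box: ParameterBox, noise: NoiseModel, n: int,
                settings: OptimizerSettings | None = None) -> MinimaxResult:
    """Minimax-optimal LC rule: ``n`` ordered knots in [0, 24] and ``n``
    unconstrained real weights adjusted jointly."""
    if n < 1:
        raise ValueError("an LC rule needs n >= 1")
    settings = settings or OptimizerSettings()
    fast_model = model.with_tolerances(1e-8, 1e-10) if settings.fast_ode else model

    def unpack(x):
        knots = np.sort(x[:n])
        return knots, x[n:]

    def design_grad(frozen: _FrozenTheta, x):
        knots, w = unpack(x)
        d_t, d_w = frozen.risk_design_grad(knots, w, noise.cv)
        return np.concatenate([d_t, d_w])

    if n >= 2:
        gap_rows = np.zeros((n - 1, 2 * n))
        for i in range(n - 1):
            gap_rows[i, i], gap_rows[i, i + 1] = -1.0, 1.0
        x_constraints = [{
            "fun": lambda x: np.diff(x[:n]) - MIN_KNOT_GAP,
            "jac": lambda x: gap_rows,
        }]
    else:
        x_constraints = []
    bounds = [(0.0, T_END)] * n + [(None, None)] * n

    outer_trace: list = []
    best = None
    for knots0, w0 in _lc_initials(model, box, noise, n, settings):
        x0 = np.concatenate([knots0, w0])
        trace: list = []
        x, theta, obj, conv = _working_set_minimize(
            model, box, noise, settings, x0, unpack, design_grad,
            bounds, x_constraints, fast_model, trace)
        outer_trace.append({"start_knots": np.asarray(knots0).tolist(),
                            "trace": trace})
        if best is None or obj < best[2]:
            best = (x, theta, obj, conv)

    # final weight re-solve at the best knots, keep whichever is better
    knots, weights = unpack(best[0])
    try:
        w_ref = best_weights(fast_model, knots, box, noise, settings)
        _, obj_ref = max_risk(Quadrature(knots, w_ref), fast_model, box, noise,
                              settings)
        if obj_ref < best[2]:
            best = (np.concatenate([knots, w_ref]), best[1], obj_ref, best[3])
    except Exception:
        pass

    knots, weights = unpack(best[0])
    quad = Quadrature(knots, weights, kind="optimal_lc")
    theta_star, objective = _verify(quad, model, box, noise, settings,
                                    hint=best[1])
    return MinimaxResult(
        quadrature=quad, theta_star=theta_star, objective=objective,
        sqrt_objective=math.sqrt(objective), converged=best[3],
        model_id=model.model_id, cv=noise.cv, outer_trace=outer_trace,
    )


def evaluate_baseline(kind: str, model: PKModel, box: ParameterBox,
                      noise: NoiseModel, n: int,
                      settings: OptimizerSettings | None = None) -> MinimaxResult:
    """Worst-case risk of a fixed classical rule (no design search)."""
    settings = settings or OptimizerSettings()
    if kind in ("gl", "gauss_legendre"):
        quad = gauss_legendre(n)
    elif kind in ("cc", "clenshaw_curtis"):
        quad = clenshaw_curtis(n)
    else:
        raise ValueError(f"unknown baseline {kind!r}")
    theta_star, objective = _verify(quad, model, box, noise, settings)
    return MinimaxResult(
        quadrature=quad, theta_star=theta_star, objective=objective,
        sqrt_objective=math.sqrt(objective), converged=True,
        model_id=model.model_id, cv=noise.cv,
    )
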