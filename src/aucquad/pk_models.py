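"""Concentration–time models, exact AUC, and parameter sensitivities.

Five standard pharmacokinetic models are provided, each on the fixed
observation interval [0, 24] h:

1. one-compartment, first-order absorption, single dose
2. one-compartment, first-order absorption, steady state (tau = 24 h)
3. two-compartment (biexponential), iv bolus
4. one-compartment, iv bolus, Michaelis–Menten elimination
5. one-compartment, first-order absorption, Michaelis–Menten elimination

Models 1–3 have closed-form concentration and AUC, with analytic gradients
and Hessians in the free parameters.  Model 4 has no explicit C(t) but is
defined by the implicit relation ``K_M ln(C/C0) + (C - C0) = -V_m t``; its
concentration is obtained by a safeguarded bisection solve, its AUC from the
closed-form identity ``AUC = [K_M (C0 - C_T) + (C0^2 - C_T^2)/2] / V_m``,
and first derivatives follow from the implicit-function theorem.  Model 5 is
integrated numerically with forward-sensitivity equations (the ODE state is
augmented with dC/dp and the running integral and its derivatives).
Second derivatives for models 4–5 are central finite differences of the
analytic/sensitivity gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize, LinearConstraint

__all__ = [
    "IntegrationError",
    "ParameterBox",
    "SensitivityBundle",
    "PKModel",
    "get_model",
    "default_box",
    "parse_constraint",
    "auc_range",
    "T_END",
]

T_END = 24.0
LN2 = math.log(2.0)

#: ODE tolerances: tight pair for reference evaluations, loose pair for
#: repeated calls inside optimizer loops.
ODE_RTOL_TIGHT, ODE_ATOL_TIGHT = 1e-10, 1e-12
ODE_RTOL_FAST, ODE_ATOL_FAST = 1e-8, 1e-10


class IntegrationError(RuntimeError):
    """Raised when an implicit solve or ODE integration fails to converge."""

    def __init__(self, message: str, model_id: int | None = None, theta=None):
        if model_id is not None:
            message = f"model {model_id}, theta={theta}: {message}"
        super().__init__(message)
        self.model_id = model_id
        self.theta = theta


# ---------------------------------------------------------------------------
# parameter boxes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBox:
    """Hyper-rectangle of admissible parameter values with optional linear
    inequality constraints ``a . theta >= b``."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    constraints: tuple[tuple[tuple[float, ...], float], ...] = ()

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower/upper must be 1-d arrays of equal length")
        if np.any(lower > upper):
            raise ValueError("lower bound exceeds upper bound")
        if len(self.names) != lower.size:
            raise ValueError("names/bounds length mismatch")
        if not np.any(self.feasible_mask(self.grid(5))):
            raise ValueError("constraints are unsatisfiable within the bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    def constraint_arrays(self):
        """Return (A, b) such that feasibility is ``A @ theta >= b``."""
        if not self.constraints:
            return np.zeros((0, self.dim)), np.zeros(0)
        A = np.array([a for a, _ in self.constraints], dtype=float)
        b = np.array([bb for _, bb in self.constraints], dtype=float)
        return A, b

    def feasible_mask(self, thetas: np.ndarray, tol: float = 0.0) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        mask = np.all((thetas >= self.lower - tol) & (thetas <= self.upper + tol), axis=1)
        A, b = self.constraint_arrays()
        if A.size:
            mask &= np.all(thetas @ A.T >= b - tol, axis=1)
        return mask

    def contains(self, theta: np.ndarray, tol: float = 1e-9) -> bool:
        return bool(self.feasible_mask(np.atleast_2d(theta), tol=tol)[0])

    def corners(self, feasible_only: bool = True) -> np.ndarray:
        p = self.dim
        idx = np.array(np.meshgrid(*[[0, 1]] * p, indexing="ij")).reshape(p, -1).T
        pts = np.where(idx == 0, self.lower, self.upper)
        if feasible_only:
            pts = pts[self.feasible_mask(pts, tol=1e-12)]
        return pts

    def grid(self, density: int, feasible_only: bool = True) -> np.ndarray:
        axes = [np.linspace(lo, hi, density) for lo, hi in zip(self.lower, self.upper)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        if feasible_only:
            pts = pts[self.feasible_mask(pts, tol=1e-12)]
        return pts

    def sample(self, rng: np.random.Generator, m: int) -> np.ndarray:
        """Uniform draws over the feasible region (rejection sampling)."""
        out = []
        got = 0
        while got < m:
            cand = rng.uniform(self.lower, self.upper, size=(max(m - got, 64), self.dim))
            cand = cand[self.feasible_mask(cand)]
            if cand.size == 0 and got == 0 and len(out) > 200:
                raise ValueError("feasible region appears to be empty")
            out.append(cand)
            got += len(cand)
        return np.concatenate(out, axis=0)[:m]

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)


def parse_constraint(text: str, names: tuple[str, ...]) -> tuple[tuple[float, ...], float]:
    """Parse a constraint string like ``"ka >= 2*ke"`` into ``(a, b)`` with
    the convention ``a . theta >= b``.

    Each side may be a number, a parameter name, or ``coef*name``; the
    operator is ``>=`` or ``<=``.
    """

    for op in (">=", "<="):
        if op in text:
            left, right = text.split(op)
            break
    else:
        raise ValueError(f"constraint {text!r} must contain '>=' or '<='")

    def side(expr: str) -> tuple[np.ndarray, float]:
        expr = expr.strip()
        vec = np.zeros(len(names))
        const = 0.0
        if "*" in expr:
            coef, name = expr.split("*")
            vec[names.index(name.strip())] = float(coef)
        elif expr in names:
            vec[names.index(expr)] = 1.0
        else:
            const = float(expr)
        return vec, const

    (lv, lc), (rv, rc) = side(left), side(right)
    a, b = lv - rv, rc - lc
    if op == "<=":
        a, b = -a, -b
    return tuple(a), b


# ---------------------------------------------------------------------------
# sensitivities container
# ---------------------------------------------------------------------------


@dataclass
class SensitivityBundle:
    """Concentration/AUC values with their parameter derivatives at a set of
    knots: ``conc`` has shape (k,), ``conc_grad`` (k, p), ``auc_grad`` (p,),
    Hessians (k, p, p) and (p, p) when requested."""

    conc: np.ndarray
    auc: float
    conc_grad: np.ndarray
    auc_grad: np.ndarray
    conc_hess: np.ndarray | None = None
    auc_hess: np.ndarray | None = None


# ---------------------------------------------------------------------------
# model base class
# ---------------------------------------------------------------------------


def _exp_auc_f(k: float | np.ndarray, T: float = T_END):
    """f(k) = (1 - e^{-Tk}) / k and its first two derivatives in k."""
    e = np.exp(-T * np.asarray(k, dtype=float))
    f = (1.0 - e) / k
    f1 = T * e / k - (1.0 - e) / k**2
    f2 = -(T**2) * e / k - 2.0 * T * e / k**2 + 2.0 * (1.0 - e) / k**3
    return f, f1, f2


class PKModel:
    """Base class: a concentration–time model on [0, 24] h with exact AUC and
    parameter sensitivities."""

    model_id: int
    param_names: tuple[str, ...]
    fixed: dict[str, float]
    #: True when C(0) > 0 for all admissible parameters (bolus-type input),
    #: which is when extrapolation of the first trapezoid panel to t=0 applies.
    positive_c0: bool = False

    interval = (0.0, T_END)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- conversions --------------------------------------------------------

    def as_theta(self, theta) -> np.ndarray:
        """Accept a mapping keyed by parameter name or an ordered sequence."""
        if isinstance(theta, dict):
            theta = [theta[name] for name in self.param_names]
        arr = np.asarray(theta, dtype=float)
        if arr.shape != (self.n_params,):
            raise ValueError(
                f"model {self.model_id} expects parameters {self.param_names}"
            )
        if np.any(arr <= 0):
            raise ValueError("all PK parameters must be strictly positive")
        return arr

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(theta, float).tolist()))

    # -- scalar-theta interface (subclasses implement) ----------------------

    def conc(self, theta, t) -> np.ndarray:
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self._conc(theta, t)

    def auc(self, theta) -> float:
        return float(self._auc(self.as_theta(theta)))

    def conc_grad(self, theta, t) -> np.ndarray:
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self._conc_grad(theta, t)

    def auc_grad(self, theta) -> np.ndarray:
        return self._auc_grad(self.as_theta(theta))

    def conc_dt(self, theta, t) -> np.ndarray:
        """Time derivative dC/dt at the given times (used for knot gradients)."""
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self._conc_dt(theta, t)

    # Hessians default to central finite differences of the analytic gradient.

    _FD_REL_STEP = 3e-6

    def conc_hess(self, theta, t) -> np.ndarray:
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self._fd_hess(lambda th: self._conc_grad(th, t), theta)

    def auc_hess(self, theta) -> np.ndarray:
        theta = self.as_theta(theta)
        H = self._fd_hess(lambda th: self._auc_grad(th), theta)
        return H

    def _fd_hess(self, grad_fn, theta: np.ndarray) -> np.ndarray:
        p = theta.size
        cols = []
        for j in range(p):
            h = self._FD_REL_STEP * max(abs(theta[j]), 1e-3)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            cols.append((np.asarray(grad_fn(tp)) - np.asarray(grad_fn(tm))) / (2 * h))
        H = np.stack(cols, axis=-1)
        return 0.5 * (H + np.swapaxes(H, -1, -2))  # symmetrize

    # -- vectorized-theta interface -----------------------------------------

    def conc_many(self, thetas: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Concentrations for a batch of parameter vectors: (m, p) x (k,) -> (m, k)."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return self._conc_many(thetas, times)

    def auc_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return self._auc_many(thetas)

    # Generic fallbacks loop over rows; closed-form models override.

    def _conc_many(self, thetas, times):
        return np.stack([self._conc(th, times) for th in thetas])

    def _auc_many(self, thetas):
        return np.array([self._auc(th) for th in thetas])

    # -- bundle -------------------------------------------------------------

    def sensitivities(self, theta, knots, hessians: bool = False) -> SensitivityBundle:
        theta = self.as_theta(theta)
        knots = np.atleast_1d(np.asarray(knots, dtype=float))
        if np.any(knots < self.interval[0] - 1e-12) or np.any(knots > self.interval[1] + 1e-12):
            raise ValueError("knots must lie inside the integration interval")
        bundle = SensitivityBundle(
            conc=self._conc(theta, knots),
            auc=float(self._auc(theta)),
            conc_grad=self._conc_grad(theta, knots),
            auc_grad=self._auc_grad(theta),
        )
        if hessians:
            bundle.conc_hess = self.conc_hess(theta, knots)
            bundle.auc_hess = self.auc_hess(theta)
        return bundle

    def with_tolerances(self, rtol: float, atol: float) -> "PKModel":
        """Return a copy using the given ODE tolerances (no-op for closed forms)."""
        return self


# ---------------------------------------------------------------------------
# models 1-3: closed forms
# ---------------------------------------------------------------------------


class Model1(PKModel):
    """One-compartment, first-order absorption, single oral dose:
    C = A (e^{-ke t} - e^{-ka t}), A = F D ka / (Vd (ka - ke)) fixed at 20."""

    model_id = 1
    param_names = ("ka", "ke")
    fixed = {"A": 20.0}
    positive_c0 = False

    def _conc(self, theta, t):
        ka, ke = theta
        return self.fixed["A"] * (np.exp(-ke * t) - np.exp(-ka * t))

    def _conc_many(self, thetas, times):
        ka = thetas[:, 0:1]
        ke = thetas[:, 1:2]
        t = times[None, :]
        return self.fixed["A"] * (np.exp(-ke * t) - np.exp(-ka * t))

    def _conc_grad(self, theta, t):
        ka, ke = theta
        A = self.fixed["A"]
        return np.stack([A * t * np.exp(-ka * t), -A * t * np.exp(-ke * t)], axis=1)

    def conc_hess(self, theta, t):
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ka, ke = theta
        A = self.fixed["A"]
        H = np.zeros((t.size, 2, 2))
        H[:, 0, 0] = -A * t**2 * np.exp(-ka * t)
        H[:, 1, 1] = A * t**2 * np.exp(-ke * t)
        return H

    def _conc_dt(self, theta, t):
        ka, ke = theta
        return self.fixed["A"] * (ka * np.exp(-ka * t) - ke * np.exp(-ke * t))

    def _auc(self, theta):
        ka, ke = theta
        fe, _, _ = _exp_auc_f(ke)
        fa, _, _ = _exp_auc_f(ka)
        return self.fixed["A"] * (fe - fa)

    def _auc_many(self, thetas):
        fe, _, _ = _exp_auc_f(thetas[:, 1])
        fa, _, _ = _exp_auc_f(thetas[:, 0])
        return self.fixed["A"] * (fe - fa)

    def _auc_grad(self, theta):
        ka, ke = theta
        _, fe1, _ = _exp_auc_f(ke)
        _, fa1, _ = _exp_auc_f(ka)
        return self.fixed["A"] * np.array([-fa1, fe1])

    def auc_hess(self, theta):
        ka, ke = self.as_theta(theta)
        _, _, fe2 = _exp_auc_f(ke)
        _, _, fa2 = _exp_auc_f(ka)
        return self.fixed["A"] * np.array([[-fa2, 0.0], [0.0, fe2]])


def _ss_g(k, t, tau=T_END):
    """g(k, t) = e^{-kt} / (1 - e^{-k tau}) with dg/dk and d2g/dk2."""
    u = np.exp(-k * t)
    v = np.exp(-k * tau)
    s = 1.0 - v
    g = u / s
    # s' = tau v ; u' = -t u ; v' = -tau v
    g1 = -u * (t * s + tau * v) / s**2
    # differentiate g1 = -u (t s + tau v) / s^2
    num = t * s + tau * v
    num1 = t * tau * v - tau**2 * v
    g2 = (t * u * num / s**2) - (u * num1 / s**2) + (2.0 * u * num * tau * v / s**3)
    return g, g1, g2


class Model2(PKModel):
    """Steady-state counterpart of model 1 with dosing interval tau = 24 h:
    C = A (e^{-ke t}/(1-e^{-ke tau}) - e^{-ka t}/(1-e^{-ka tau}))."""

    model_id = 2
    param_names = ("ka", "ke")
    fixed = {"A": 20.0, "tau": T_END}
    positive_c0 = True

    def _conc(self, theta, t):
        ka, ke = theta
        ge, _, _ = _ss_g(ke, t)
        ga, _, _ = _ss_g(ka, t)
        return self.fixed["A"] * (ge - ga)

    def _conc_many(self, thetas, times):
        ka = thetas[:, 0:1]
        ke = thetas[:, 1:2]
        t = times[None, :]
        ge, _, _ = _ss_g(ke, t)
        ga, _, _ = _ss_g(ka, t)
        return self.fixed["A"] * (ge - ga)

    def _conc_grad(self, theta, t):
        ka, ke = theta
        _, ge1, _ = _ss_g(ke, t)
        _, ga1, _ = _ss_g(ka, t)
        A = self.fixed["A"]
        return np.stack([-A * ga1, A * ge1], axis=1)

    def conc_hess(self, theta, t):
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ka, ke = theta
        _, _, ge2 = _ss_g(ke, t)
        _, _, ga2 = _ss_g(ka, t)
        A = self.fixed["A"]
        H = np.zeros((t.size, 2, 2))
        H[:, 0, 0] = -A * ga2
        H[:, 1, 1] = A * ge2
        return H

    def _conc_dt(self, theta, t):
        ka, ke = theta
        A = self.fixed["A"]
        tau = self.fixed["tau"]
        return A * (
            -ke * np.exp(-ke * t) / (1 - np.exp(-ke * tau))
            + ka * np.exp(-ka * t) / (1 - np.exp(-ka * tau))
        )

    def _auc(self, theta):
        ka, ke = theta
        # steady-state dosing-interval AUC telescopes to A (1/ke - 1/ka)
        return self.fixed["A"] * (1.0 / ke - 1.0 / ka)

    def _auc_many(self, thetas):
        return self.fixed["A"] * (1.0 / thetas[:, 1] - 1.0 / thetas[:, 0])

    def _auc_grad(self, theta):
        ka, ke = theta
        return self.fixed["A"] * np.array([1.0 / ka**2, -1.0 / ke**2])

    def auc_hess(self, theta):
        ka, ke = self.as_theta(theta)
        return self.fixed["A"] * np.array(
            [[-2.0 / ka**3, 0.0], [0.0, 2.0 / ke**3]]
        )


class Model3(PKModel):
    """Biexponential iv-bolus model: C = A1 e^{-k1 t} + alpha A1 e^{-k2 t},
    A1 = 10, free parameters (k1, k2, alpha = A2/A1)."""

    model_id = 3
    param_names = ("k1", "k2", "alpha")
    fixed = {"A1": 10.0}
    positive_c0 = True

    def _conc(self, theta, t):
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        return A1 * np.exp(-k1 * t) + alpha * A1 * np.exp(-k2 * t)

    def _conc_many(self, thetas, times):
        A1 = self.fixed["A1"]
        t = times[None, :]
        return A1 * np.exp(-thetas[:, 0:1] * t) + thetas[:, 2:3] * A1 * np.exp(
            -thetas[:, 1:2] * t
        )

    def _conc_grad(self, theta, t):
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        return np.stack(
            [
                -A1 * t * np.exp(-k1 * t),
                -alpha * A1 * t * np.exp(-k2 * t),
                A1 * np.exp(-k2 * t),
            ],
            axis=1,
        )

    def conc_hess(self, theta, t):
        theta = self.as_theta(theta)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        H = np.zeros((t.size, 3, 3))
        H[:, 0, 0] = A1 * t**2 * np.exp(-k1 * t)
        H[:, 1, 1] = alpha * A1 * t**2 * np.exp(-k2 * t)
        H[:, 1, 2] = H[:, 2, 1] = -A1 * t * np.exp(-k2 * t)
        return H

    def _conc_dt(self, theta, t):
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        return -k1 * A1 * np.exp(-k1 * t) - k2 * alpha * A1 * np.exp(-k2 * t)

    def _auc(self, theta):
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        f1, _, _ = _exp_auc_f(k1)
        f2, _, _ = _exp_auc_f(k2)
        return A1 * f1 + alpha * A1 * f2

    def _auc_many(self, thetas):
        A1 = self.fixed["A1"]
        f1, _, _ = _exp_auc_f(thetas[:, 0])
        f2, _, _ = _exp_auc_f(thetas[:, 1])
        return A1 * f1 + thetas[:, 2] * A1 * f2

    def _auc_grad(self, theta):
        k1, k2, alpha = theta
        A1 = self.fixed["A1"]
        _, f1d, _ = _exp_auc_f(k1)
        f2, f2d, _ = _exp_auc_f(k2)
        return np.array([A1 * f1d, alpha * A1 * f2d, A1 * f2])

    def auc_hess(self, theta):
        k1, k2, alpha = self.as_theta(theta)
        A1 = self.fixed["A1"]
        _, _, f1dd = _exp_auc_f(k1)
        _, f2d, f2dd = _exp_auc_f(k2)
        H = np.zeros((3, 3))
        H[0, 0] = A1 * f1dd
        H[1, 1] = alpha * A1 * f2dd
        H[1, 2] = H[2, 1] = A1 * f2d
        return H


# ---------------------------------------------------------------------------
# model 4: Michaelis-Menten elimination, iv bolus (implicit solution)
# ---------------------------------------------------------------------------


class Model4(PKModel):
    """iv bolus with Michaelis–Menten elimination, dC/dt = -Vm C/(KM + C),
    C(0) = C0 = 10.  C(t) satisfies KM ln(C/C0) + (C - C0) = -Vm t and AUC
    has the closed form [KM (C0 - C_T) + (C0^2 - C_T^2)/2] / Vm."""

    model_id = 4
    param_names = ("KM", "Vm")
    fixed = {"C0": 10.0}
    positive_c0 = True

    _BISECT_ITERS = 90

    def _c_implicit(self, KM, Vm, t):
        """Vectorized bisection for C(t) in (0, C0]; broadcasts KM, Vm, t."""
        C0 = self.fixed["C0"]
        KM, Vm, t = np.broadcast_arrays(
            np.asarray(KM, float), np.asarray(Vm, float), np.asarray(t, float)
        )
        lo = np.full(t.shape, 1e-300)
        hi = np.full(t.shape, float(C0))

        def h(C):
            return KM * np.log(C / C0) + (C - C0) + Vm * t

        for _ in range(self._BISECT_ITERS):
            mid = 0.5 * (lo + hi)
            pos = h(mid) > 0
            hi = np.where(pos, mid, hi)
            lo = np.where(pos, lo, mid)
        C = 0.5 * (lo + hi)
        if not np.all(np.isfinite(C)):
            raise IntegrationError("implicit solve failed", self.model_id, (KM, Vm))
        return C

    def _conc(self, theta, t):
        KM, Vm = theta
        return self._c_implicit(KM, Vm, t)

    def _conc_many(self, thetas, times):
        return self._c_implicit(
            thetas[:, 0:1], thetas[:, 1:2], times[None, :]
        )

    def _conc_grad(self, theta, t):
        KM, Vm = theta
        C0 = self.fixed["C0"]
        C = self._c_implicit(KM, Vm, t)
        hC = KM / C + 1.0
        dKM = -np.log(C / C0) / hC
        dVm = -t / hC
        return np.stack([dKM, dVm], axis=1)

    def _conc_dt(self, theta, t):
        KM, Vm = theta
        C = self._c_implicit(KM, Vm, t)
        return -Vm * C / (KM + C)

    def _auc(self, theta):
        KM, Vm = theta
        C0 = self.fixed["C0"]
        CT = float(self._c_implicit(KM, Vm, np.array([T_END]))[0])
        return (KM * (C0 - CT) + 0.5 * (C0**2 - CT**2)) / Vm

    def _auc_many(self, thetas):
        KM = thetas[:, 0]
        Vm = thetas[:, 1]
        C0 = self.fixed["C0"]
        CT = self._c_implicit(KM, Vm, np.full(KM.shape, T_END))
        return (KM * (C0 - CT) + 0.5 * (C0**2 - CT**2)) / Vm

    def _auc_grad(self, theta):
        KM, Vm = theta
        C0 = self.fixed["C0"]
        CT = float(self._c_implicit(KM, Vm, np.array([T_END]))[0])
        g = self._conc_grad(theta, np.array([T_END]))[0]
        auc = (KM * (C0 - CT) + 0.5 * (C0**2 - CT**2)) / Vm
        dKM = ((C0 - CT) - (KM + CT) * g[0]) / Vm
        dVm = -auc / Vm - (KM + CT) * g[1] / Vm
        return np.array([dKM, dVm])

    # reference ODE route (used in tests to cross-check the implicit solution)

    def conc_ode(self, theta, times, rtol=ODE_RTOL_TIGHT, atol=ODE_ATOL_TIGHT):
        KM, Vm = self.as_theta(theta)
        C0 = self.fixed["C0"]
        times = np.atleast_1d(np.asarray(times, float))

        def rhs(t, y):
            return [-Vm * y[0] / (KM + y[0]), y[0]]

        sol = solve_ivp(
            rhs, (0.0, T_END), [C0, 0.0], t_eval=np.union1d(times, [T_END]),
            rtol=rtol, atol=atol, method="LSODA", dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(sol.message, self.model_id, theta)
        return sol.sol(times)[0], float(sol.y[1, -1])


# ---------------------------------------------------------------------------
# model 5: Michaelis-Menten elimination with first-order input (ODE)
# ---------------------------------------------------------------------------


class Model5(PKModel):
    """First-order absorption with Michaelis–Menten elimination:
    dC/dt = -Vm C/(KM + C) + A e^{-ka t}, C(0) = 0, A = 5.

    The forward-sensitivity system augments the state with dC/dKM, dC/dVm,
    dC/dka, the running integral I = int C dt and its parameter derivatives
    (8 states in total)."""

    model_id = 5
    param_names = ("KM", "Vm", "ka")
    fixed = {"A": 5.0}
    positive_c0 = False

    def __init__(self, rtol: float = ODE_RTOL_TIGHT, atol: float = ODE_ATOL_TIGHT):
        self.rtol = rtol
        self.atol = atol

    def with_tolerances(self, rtol, atol):
        return Model5(rtol=rtol, atol=atol)

    def _solve(self, theta, times, with_sens: bool):
        KM, Vm, ka = theta
        A = self.fixed["A"]
        times = np.atleast_1d(np.asarray(times, float))
        t_span = (0.0, T_END)

        if with_sens:

            def rhs(t, y):
                C, sK, sV, sa, I, iK, iV, ia = y
                den = KM + C
                f = -Vm * C / den + A * np.exp(-ka * t)
                fC = -Vm * KM / den**2
                dy = [
                    f,
                    fC * sK + Vm * C / den**2,
                    fC * sV - C / den,
                    fC * sa - A * t * np.exp(-ka * t),
                    C,
                    sK,
                    sV,
                    sa,
                ]
                return dy

            y0 = np.zeros(8)
        else:

            def rhs(t, y):
                C, I = y
                return [-Vm * y[0] / (KM + y[0]) + A * np.exp(-ka * t), C]

            y0 = np.zeros(2)

        sol = solve_ivp(
            rhs, t_span, y0, t_eval=np.union1d(times, [T_END]),
            rtol=self.rtol, atol=self.atol, method="LSODA", dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(sol.message, self.model_id, theta)
        return sol, times

    def _conc(self, theta, t):
        sol, times = self._solve(theta, t, with_sens=False)
        return sol.sol(times)[0]

    def _auc(self, theta):
        sol, _ = self._solve(theta, np.array([T_END]), with_sens=False)
        return float(sol.y[1, -1])

    def _conc_grad(self, theta, t):
        sol, times = self._solve(theta, t, with_sens=True)
        return sol.sol(times)[1:4].T

    def _auc_grad(self, theta):
        sol, _ = self._solve(theta, np.array([T_END]), with_sens=True)
        return sol.y[5:8, -1]

    def _conc_dt(self, theta, t):
        KM, Vm, ka = theta
        C = self._conc(theta, t)
        return -Vm * C / (KM + C) + self.fixed["A"] * np.exp(-ka * t)

    def sensitivities(self, theta, knots, hessians: bool = False):
        # single integration supplies conc, auc and both gradients
        theta = self.as_theta(theta)
        knots = np.atleast_1d(np.asarray(knots, float))
        sol, times = self._solve(theta, knots, with_sens=True)
        at_knots = sol.sol(times)
        bundle = SensitivityBundle(
            conc=at_knots[0],
            auc=float(sol.y[4, -1]),
            conc_grad=at_knots[1:4].T,
            auc_grad=sol.y[5:8, -1],
        )
        if hessians:
            bundle.conc_hess = self.conc_hess(theta, knots)
            bundle.auc_hess = self.auc_hess(theta)
        return bundle

    # batch evaluation: all profiles stacked into one ODE system so that a
    # single adaptive integration serves the whole Monte-Carlo sample

    _BATCH = 4096

    def _profiles(self, thetas, times):
        A = self.fixed["A"]
        times = np.atleast_1d(np.asarray(times, float))
        conc_out = np.empty((len(thetas), times.size))
        auc_out = np.empty(len(thetas))
        for start in range(0, len(thetas), self._BATCH):
            chunk = thetas[start : start + self._BATCH]
            KM = chunk[:, 0]
            Vm = chunk[:, 1]
            ka = chunk[:, 2]
            m = len(chunk)

            def rhs(t, y):
                C = y[:m]
                dC = -Vm * C / (KM + C) + A * np.exp(-ka * t)
                return np.concatenate([dC, C])

            sol = solve_ivp(
                rhs, (0.0, T_END), np.zeros(2 * m),
                t_eval=np.union1d(times, [T_END]),
                rtol=max(self.rtol, 1e-8), atol=max(self.atol, 1e-10),
                method="RK45", dense_output=True,
            )
            if not sol.success:
                raise IntegrationError(sol.message, self.model_id, "batch")
            conc_out[start : start + m] = sol.sol(times)[:m]
            auc_out[start : start + m] = sol.y[m:, -1]
        return conc_out, auc_out

    def _conc_many(self, thetas, times):
        return self._profiles(thetas, times)[0]

    def _auc_many(self, thetas):
        return self._profiles(thetas, np.array([T_END]))[1]


# ---------------------------------------------------------------------------
# registry and default parameter boxes
# ---------------------------------------------------------------------------

_MODEL_CLASSES = {1: Model1, 2: Model2, 3: Model3, 4: Model4, 5: Model5}


def get_model(model_id: int, fast_ode: bool = False) -> PKModel:
    """Instantiate a model by its integer id (1-5).

    ``fast_ode=True`` relaxes ODE tolerances for use inside optimizer loops.
    """
    try:
        cls = _MODEL_CLASSES[int(model_id)]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}; expected 1-5") from None
    model = cls()
    if fast_ode:
        model = model.with_tolerances(ODE_RTOL_FAST, ODE_ATOL_FAST)
    return model


def default_box(model_id: int, constrain_absorption: bool = True) -> ParameterBox:
    """The published parameter box for each model.

    For models 1-2 the admissible region additionally imposes ka >= 2 ke
    (absorption at least twice as fast as elimination), which keeps the
    flip-flop degeneracy ka = ke out of the box and reproduces the published
    AUC minima; pass ``constrain_absorption=False`` for the raw rectangle.
    """
    model_id = int(model_id)
    if model_id in (1, 2):
        cons = ()
        if constrain_absorption:
            cons = ((parse_constraint("ka >= 2*ke", ("ka", "ke"))),)
        return ParameterBox(
            names=("ka", "ke"),
            lower=np.array([LN2 / 4, LN2 / 12]),
            upper=np.array([3 * LN2, LN2 / 4]),
            constraints=cons,
        )
    if model_id == 3:
        # the published k2 range is listed high-to-low; normalized ascending
        return ParameterBox(
            names=("k1", "k2", "alpha"),
            lower=np.array([0.5 * LN2, LN2 / 24, 0.8]),
            upper=np.array([6 * LN2, LN2 / 4, 1.25]),
        )
    if model_id == 4:
        return ParameterBox(
            names=("KM", "Vm"),
            lower=np.array([2.0, 0.2]),
            upper=np.array([20.0, 1.0]),
        )
    if model_id == 5:
        return ParameterBox(
            names=("KM", "Vm", "ka"),
            lower=np.array([2.0, 0.4, LN2 / 2]),
            upper=np.array([5.0, 0.7, LN2]),
        )
    raise ValueError(f"unknown model id {model_id!r}; expected 1-5")


# ---------------------------------------------------------------------------
# AUC range over a box
# ---------------------------------------------------------------------------


def auc_range(model: PKModel, box: ParameterBox, grid_density: int | None = None):
    """Extremes of AUC(theta) over the box: dense grid scan followed by a
    local constrained polish from the best grid points.  Deterministic.

    Returns ``(auc_min, auc_max)``.
    """
    if grid_density is None:
        grid_density = 100 if box.dim <= 2 else 40
    pts = box.grid(grid_density)
    aucs = model.auc_many(pts)

    A, b = box.constraint_arrays()
    cons = [LinearConstraint(A, b, np.inf)] if A.size else []
    bounds = list(zip(box.lower, box.upper))

    def polish(x0, sign):
        res = minimize(
            lambda th: sign * model.auc(th),
            x0,
            jac=lambda th: sign * model.auc_grad(th),
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 200},
        )
        x = box.clip(res.x) if res.success else x0
        if not box.contains(x, tol=1e-9):
            x = x0
        return model.auc(x)

    lo = polish(pts[np.argmin(aucs)], +1.0)
    hi = polish(pts[np.argmax(aucs)], -1.0)
    return min(lo, float(aucs.min())), max(hi, float(aucs.max()))
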