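"""Risk of an LC estimator under constant-CV measurement noise.

Measurements are ``C_hat_i = C(t_i, theta) (1 + eps)`` with zero-mean noise
of standard deviation ``sigma_i = c_v C(t_i, theta)``.  Only the first two
moments enter the risk, so no distributional assumption is needed:

* expectation      E(Q) = sum w_i C(t_i, theta)
* variance         V(Q) = c_v^2 sum w_i^2 C(t_i, theta)^2
* absolute risk    R    = V(Q) + [AUC - E(Q)]^2
* relative risk    R_r  = R / AUC^2

The relative risk is the quantity minimized (over designs) and maximized
(over the parameter box) by the minimax search.  Gradients and Hessians in
theta are assembled from the model sensitivities by the chain rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk_models import PKModel, SensitivityBundle
from .quadrature import Quadrature

__all__ = [
    "NoiseModel",
    "RiskEvaluation",
    "expected_estimate",
    "estimator_variance",
    "relative_risk",
    "absolute_risk",
    "relative_risk_many",
]


@dataclass(frozen=True)
class NoiseModel:
    """Constant coefficient-of-variation measurement noise, sigma = cv * C."""

    cv: float = 0.0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")


@dataclass
class RiskEvaluation:
    """Risk value with its bias-variance split and theta-derivatives."""

    value: float
    variance_term: float
    bias_term: float
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None


def expected_estimate(quad: Quadrature, model: PKModel, theta) -> float:
    """E(Q) = sum w_i C(t_i, theta): the noise-free value of the rule."""
    conc = model.conc(theta, quad.knots)
    return float(conc @ quad.weights)


def estimator_variance(quad: Quadrature, model: PKModel, theta,
                       noise: NoiseModel) -> float:
    """V(Q) = cv^2 sum w_i^2 C_i^2 for independent constant-CV errors."""
    conc = model.conc(theta, quad.knots)
    return float(noise.cv**2 * np.sum(quad.weights**2 * conc**2))


def _assemble(quad: Quadrature, bundle: SensitivityBundle, cv: float,
              relative: bool, gradient: bool, hessian: bool) -> RiskEvaluation:
    w = quad.weights
    C = bundle.conc
    A = bundle.auc
    if relative and A <= 0:
        raise ValueError("relative risk requires AUC > 0")
    S = float(w @ C)
    B = A - S
    var = cv**2 * float(np.sum(w**2 * C**2))
    num = var + B * B
    denom = A * A if relative else 1.0

    ev = RiskEvaluation(value=num / denom, variance_term=var / denom,
                        bias_term=B * B / denom)
    if not gradient:
        return ev

    gC = bundle.conc_grad        # (k, p)
    gA = bundle.auc_grad         # (p,)
    gS = w @ gC
    gB = gA - gS
    gvar = 2.0 * cv**2 * (w**2 * C) @ gC
    gnum = gvar + 2.0 * B * gB
    if relative:
        ev.gradient = gnum / denom - 2.0 * num * gA / (A * denom)
    else:
        ev.gradient = gnum

    if hessian:
        HC = bundle.conc_hess    # (k, p, p)
        HA = bundle.auc_hess     # (p, p)
        HS = np.einsum("i,ijk->jk", w, HC)
        HB = HA - HS
        Hvar = 2.0 * cv**2 * (
            np.einsum("i,ij,ik->jk", w**2, gC, gC)
            + np.einsum("i,ijk->jk", w**2 * C, HC)
        )
        Hnum = Hvar + 2.0 * (np.outer(gB, gB) + B * HB)
        if relative:
            ev.hessian = (
                Hnum / denom
                - 2.0 * (np.outer(gnum, gA) + np.outer(gA, gnum)) / (A * denom)
                - 2.0 * num * HA / (A * denom)
                + 6.0 * num * np.outer(gA, gA) / (A * A * denom)
            )
        else:
            ev.hessian = Hnum
    return ev


def relative_risk(quad: Quadrature, model: PKModel, theta, noise: NoiseModel,
                  gradient: bool = False, hessian: bool = False) -> RiskEvaluation:
    """Relative risk R_r = {cv^2 sum w_i^2 C_i^2 + [AUC - sum w_i C_i]^2} / AUC^2."""
    bundle = model.sensitivities(theta, quad.knots, hessians=hessian) \
        if (gradient or hessian) else SensitivityBundle(
            conc=model.conc(theta, quad.knots), auc=model.auc(theta),
            conc_grad=None, auc_grad=None)
    return _assemble(quad, bundle, noise.cv, relative=True,
                     gradient=gradient, hessian=hessian)


def absolute_risk(quad: Quadrature, model: PKModel, theta, noise: NoiseModel,
                  gradient: bool = False, hessian: bool = False) -> RiskEvaluation:
    """Absolute risk V(Q) + [AUC - E(Q)]^2 (area^2 units)."""
    bundle = model.sensitivities(theta, quad.knots, hessians=hessian) \
        if (gradient or hessian) else SensitivityBundle(
            conc=model.conc(theta, quad.knots), auc=model.auc(theta),
            conc_grad=None, auc_grad=None)
    return _assemble(quad, bundle, noise.cv, relative=False,
                     gradient=gradient, hessian=hessian)


def relative_risk_many(quad: Quadrature, model: PKModel, thetas: np.ndarray,
                       noise: NoiseModel) -> np.ndarray:
    """Vectorized relative risk over a batch of parameter vectors."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    conc = model.conc_many(thetas, quad.knots)      # (m, k)
    auc = model.auc_many(thetas)                    # (m,)
    S = conc @ quad.weights
    var = noise.cv**2 * (conc**2) @ (quad.weights**2)
    return (var + (auc - S) ** 2) / auc**2
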