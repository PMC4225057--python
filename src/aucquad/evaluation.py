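"""Monte-Carlo evaluation of AUC quadratures over a parameter box.

Random profiles are drawn uniformly over the (constrained) parameter box,
noise-free concentrations computed from the model, and Gaussian constant-CV
noise applied independently at each sampling time.  The summary statistics
mirror the performance columns reported for each design: bias (absolute
scale), RMSRE, and the extreme signed absolute/relative deviances.

Two consistency inequalities relate simulation output to the minimax
objective ``Obj`` (the worst-case relative risk of the design):

* ``RMSRE < sqrt(Obj)`` for any noise level, since the mean of the squared
  relative error over the box cannot exceed its maximum;
* with no noise, ``|max relative deviance| <= sqrt(Obj)``, since every
  profile's relative quadrature error is bounded by the worst case --
  a violated bound indicates a failed inner maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk_models import PKModel, ParameterBox, get_model, default_box
from .quadrature import Quadrature
from .minimax import MinimaxResult

__all__ = [
    "SimulationConfig",
    "SimulationStats",
    "simulate_profiles",
    "evaluate_method",
    "consistency_checks",
]

DEFAULT_PROFILES = 20_000


@dataclass
class SimulationConfig:
    """Monte-Carlo settings: which model/box, noise level, sample size, seed."""

    model_id: int
    cv: float
    n_profiles: int = DEFAULT_PROFILES
    seed: int = 0
    box: ParameterBox | None = None
    model: PKModel | None = None

    def __post_init__(self):
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.model is None:
            self.model = get_model(self.model_id)
        if self.box is None:
            self.box = default_box(self.model_id)


@dataclass
class SimulationStats:
    """Summary of a Monte-Carlo evaluation of one design."""

    bias: float
    rmsre: float
    max_deviance: float          # signed error of largest magnitude (conc*h)
    max_rel_deviance: float      # signed relative error of largest magnitude
    min_deviance: float          # most negative error
    min_rel_deviance: float      # most negative relative error
    n_profiles: int
    seed: int

    def as_row(self) -> dict:
        return {
            "bias": self.bias, "rmsre": self.rmsre,
            "max_deviance": self.max_deviance,
            "max_rel_deviance": self.max_rel_deviance,
            "min_deviance": self.min_deviance,
            "min_rel_deviance": self.min_rel_deviance,
            "n_profiles": self.n_profiles, "seed": self.seed,
        }


def simulate_profiles(config: SimulationConfig, times):
    """Draw random profiles and noisy measurements at the requested times.

    Returns ``(thetas, true_aucs, noisy_concentrations)`` with shapes
    (m, p), (m,), (m, k).  Parameters are uniform over the feasible box
    (rejection sampling for linear constraints); measurements are
    ``C (1 + cv z)`` with independent standard-normal ``z``.  Negative
    simulated measurements are kept: truncation would bias the zero-mean
    noise the risk formulas assume.
    """
    times = np.atleast_1d(np.asarray(times, float))
    lo, hi = config.model.interval
    if np.any(times < lo - 1e-12) or np.any(times > hi + 1e-12):
        raise ValueError("requested times fall outside the model interval")
    # separate child streams for parameters and noise keep a seed-extended
    # run a strict superset of a shorter run with the same seed
    rng_theta = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    thetas = config.box.sample(rng_theta, config.n_profiles)
    conc = config.model.conc_many(thetas, times)
    aucs = config.model.auc_many(thetas)
    noisy = conc * (1.0 + config.cv * rng_noise.standard_normal(conc.shape))
    return thetas, aucs, noisy


def evaluate_method(quad: Quadrature, config: SimulationConfig,
                    return_profiles: bool = False):
    """Apply an LC rule to simulated noisy profiles and summarize the errors.

    With ``return_profiles=True`` also returns the per-profile
    ``(true_auc, estimate)`` pairs.
    """
    _, aucs, noisy = simulate_profiles(config, quad.knots)
    estimates = noisy @ quad.weights
    err = estimates - aucs
    rel = err / aucs
    i_abs = int(np.argmax(np.abs(err)))
    i_rel = int(np.argmax(np.abs(rel)))
    stats = SimulationStats(
        bias=float(np.mean(err)),
        rmsre=float(np.sqrt(np.mean(rel**2))),
        max_deviance=float(err[i_abs]),
        max_rel_deviance=float(rel[i_rel]),
        min_deviance=float(np.min(err)),
        min_rel_deviance=float(np.min(rel)),
        n_profiles=config.n_profiles,
        seed=config.seed,
    )
    if return_profiles:
        return stats, np.column_stack([aucs, estimates])
    return stats


def consistency_checks(stats: SimulationStats, result: MinimaxResult) -> dict:
    """Verdicts for the objective-vs-simulation inequalities.

    ``rmsre_lt_sqrt_obj`` must hold for any noise level.  The relative
    deviance bound applies only to noise-free simulations; with cv > 0 it is
    reported as not applicable (random error can exceed the worst-case
    quadrature error).
    """
    sqrt_obj = result.sqrt_objective
    report = {
        "sqrt_objective": sqrt_obj,
        "rmsre": stats.rmsre,
        "rmsre_lt_sqrt_obj": bool(stats.rmsre < sqrt_obj),
    }
    if result.cv == 0:
        report["max_rel_deviance_le_sqrt_obj"] = bool(
            abs(stats.max_rel_deviance) <= sqrt_obj)
    else:
        report["max_rel_deviance_le_sqrt_obj"] = "not applicable"
    return report
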