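"""Stochastic simulation of the regime-shift process.

The analytic stream value ``E * L`` is an expectation over the random year
in which adverse evolution occurs. This module realizes that expectation by
Monte Carlo — both to validate the closed form and to support a reversible
two-state extension that has no single-jump interpretation.

Time convention: excess profit accrues at the start of each year and the
evolution draw happens at year end, so the stream always contains the
leading undiscounted term ``E`` and the shift year is at least 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ManagementScenario, effective_lifespan
from .errors import ValidationError

__all__ = [
    "SimulationResult",
    "sample_evolution_time",
    "simulate_pristine_stream",
    "simulate_reversible",
    "reversible_value",
    "default_horizon",
]

#: Relative truncation-bias threshold used to pick the default horizon.
_BIAS_TOL = 1e-10
_MAX_HORIZON = 1_000_000


def default_horizon(delta: float, kappa: float) -> int:
    """Smallest horizon T with relative truncation bias (delta*kappa)^T below 1e-10."""
    dk = delta * kappa
    if dk <= 0.0:
        return 1
    if dk >= 1.0:
        return _MAX_HORIZON
    return min(_MAX_HORIZON, max(1, math.ceil(math.log(_BIAS_TOL) / math.log(dk))))


@dataclass
class SimulationResult:
    """Monte Carlo estimate of a discounted excess-profit stream.

    ``shift_times`` holds the year each replicate left the pristine state
    for the first time (``inf`` when censored at the horizon); ``mean_pv``
    and ``std_error`` summarize the per-replicate present values.
    """

    pv_samples: np.ndarray
    shift_times: np.ndarray
    horizon: int
    seed: int
    reps: int
    analytic_pv: Optional[float] = None
    mean_pv: float = field(init=False)
    std_error: float = field(init=False)

    def __post_init__(self):
        self.pv_samples = np.asarray(self.pv_samples, dtype=float)
        self.mean_pv = float(self.pv_samples.mean())
        if self.reps > 1:
            self.std_error = float(self.pv_samples.std(ddof=1) / math.sqrt(self.reps))
        else:
            self.std_error = math.inf

    @property
    def n_shifted(self) -> int:
        return int(np.isfinite(self.shift_times).sum())

    def to_dict(self) -> dict:
        return {
            "mean_pv": self.mean_pv,
            "std_error": self.std_error,
            "analytic_pv": self.analytic_pv,
            "n_shifted": self.n_shifted,
            "reps": self.reps,
            "horizon": self.horizon,
            "seed": self.seed,
        }


def sample_evolution_time(kappa: float, reps: int, seed: int) -> np.ndarray:
    """Draw i.i.d. years of first adverse evolution.

    The shift year is geometric: ``P(T = t) = kappa**(t-1) * (1 - kappa)``
    for ``t = 1, 2, ...`` with mean ``1/(1-kappa)``. ``kappa = 1`` returns
    the no-shift-ever sentinel ``inf`` for every replicate.
    """
    if not (0.0 <= kappa <= 1.0):
        raise ValidationError(f"kappa={kappa} outside [0, 1]")
    if reps < 1:
        raise ValidationError(f"reps={reps} must be >= 1")
    if kappa == 1.0:
        return np.full(reps, np.inf)
    rng = np.random.default_rng(seed)
    return rng.geometric(1.0 - kappa, size=reps).astype(float)


def _resolve_inputs(scenario, gamma, E, delta, kappa):
    if scenario is not None:
        if gamma is None:
            raise ValidationError("gamma is required when a scenario is given")
        return scenario.excess_profit(gamma), scenario.delta, scenario.persistence(gamma)
    if E is None or delta is None or kappa is None:
        raise ValidationError("supply either (scenario, gamma) or (E, delta, kappa)")
    return float(E), float(delta), float(kappa)


def simulate_pristine_stream(
    scenario: Optional[ManagementScenario] = None,
    gamma: Optional[float] = None,
    reps: int = 100_000,
    horizon: Optional[int] = None,
    seed: int = 0,
    *,
    E: Optional[float] = None,
    delta: Optional[float] = None,
    kappa: Optional[float] = None,
) -> SimulationResult:
    """Monte Carlo estimate of the stream value ``E(gamma) * L(gamma)``.

    Each replicate draws a shift year ``T`` and accrues ``delta**(t-1) * E``
    for ``t = 1..T``, truncated at ``horizon``. Inputs come either from a
    scenario and action or from the raw ``(E, delta, kappa)`` triple.
    """
    E, delta, kappa = _resolve_inputs(scenario, gamma, E, delta, kappa)
    if not (0.0 <= delta < 1.0):
        raise ValidationError(f"delta={delta} outside [0, 1) for simulation")
    if horizon is None:
        horizon = default_horizon(delta, kappa)
    if horizon < 1:
        raise ValidationError(f"horizon={horizon} must be >= 1")

    dk = delta * kappa
    analytic = E * effective_lifespan(delta, kappa)
    bias = abs(E) * dk**horizon / (1.0 - dk) if dk > 0 else 0.0
    if analytic != 0 and bias > 1e-6 * abs(analytic):
        warnings.warn(
            f"horizon={horizon} leaves truncation bias <= {bias:.3g} "
            f"(analytic value {analytic:.6g})",
            stacklevel=2,
        )

    shift = sample_evolution_time(kappa, reps, seed) if kappa < 1.0 else np.full(reps, np.inf)
    years = np.minimum(shift, horizon)  # profit earned in years 1..years
    if delta > 0.0:
        pv = E * (1.0 - delta**years) / (1.0 - delta)
    else:
        pv = np.full(reps, float(E))  # only the first year counts
    shift_times = np.where(shift > horizon, np.inf, shift)
    return SimulationResult(pv, shift_times, int(horizon), int(seed), int(reps), analytic)


def reversible_value(E: float, delta: float, kappa: float, rho: float) -> float:
    """Exact expected discounted excess profit of the reversible chain.

    The pristine state pays ``E`` and persists with probability ``kappa``;
    the evolved state pays 0 excess and reverts with probability ``rho``.
    Values solve the linear system::

        V_p = E + delta * (kappa * V_p + (1 - kappa) * V_e)
        V_e =     delta * (rho * V_p + (1 - rho) * V_e)

    and the chain starts pristine, so the value is ``V_p``.
    """
    if not (0.0 <= delta < 1.0):
        raise ValidationError(f"delta={delta} outside [0, 1)")
    A = np.array(
        [
            [1.0 - delta * kappa, -delta * (1.0 - kappa)],
            [-delta * rho, 1.0 - delta * (1.0 - rho)],
        ]
    )
    b = np.array([E, 0.0])
    vp, _ve = np.linalg.solve(A, b)
    return float(vp)


def simulate_reversible(
    scenario: Optional[ManagementScenario] = None,
    gamma: Optional[float] = None,
    rho: float = 0.0,
    reps: int = 100_000,
    horizon: Optional[int] = None,
    seed: int = 0,
    *,
    E: Optional[float] = None,
    delta: Optional[float] = None,
    kappa: Optional[float] = None,
) -> SimulationResult:
    """Monte Carlo value of a two-state chain where evolution can revert.

    A generic relaxation of irreversibility: each year the pristine state
    becomes evolved with probability ``1 - kappa(gamma)`` and the evolved
    state reverts to pristine with probability ``rho``. Only the excess
    profit ``E`` (paid while pristine) is accumulated; the evolved-state
    annual profit is the baseline, excess 0. ``rho = 0`` recovers the
    irreversible model.
    """
    E, delta, kappa = _resolve_inputs(scenario, gamma, E, delta, kappa)
    if not (0.0 <= rho <= 1.0):
        raise ValidationError(f"reversal probability rho={rho} outside [0, 1]")
    if not (0.0 <= delta < 1.0):
        raise ValidationError(f"delta={delta} outside [0, 1) for simulation")
    if horizon is None:
        # tail value decays like delta**T regardless of the chain state
        horizon = default_horizon(delta, 1.0) if delta > 0 else 1
    analytic = reversible_value(E, delta, kappa, rho)

    rng = np.random.default_rng(seed)
    pristine = np.ones(reps, dtype=bool)
    pv = np.zeros(reps)
    shift_times = np.full(reps, np.inf)
    disc = 1.0
    for t in range(1, int(horizon) + 1):
        pv += np.where(pristine, disc * E, 0.0)
        disc *= delta
        u = rng.random(reps)
        stays = np.where(pristine, u < kappa, u < rho)
        newly_evolved = pristine & ~stays
        shift_times = np.where(newly_evolved & np.isinf(shift_times), t, shift_times)
        pristine = stays
    return SimulationResult(pv, shift_times, int(horizon), int(seed), int(reps), analytic)
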