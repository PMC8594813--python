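"""Optimal stewardship for an isolated manager.

The manager simply maximizes the stream value ``V(gamma) = E(gamma) *
L(gamma)`` over the action set. Three comparative-statics facts sharpen the
intuition: the incentive to steward rises with patience (larger ``delta``),
with management effectiveness (larger ``kappa(gamma) - kappa(gamma0)``),
and with a bleaker evolved state (smaller ``Pi_bar``). For a binary choice
with a fixed percentage cost ``c`` there is a critical discount factor
``delta*`` above which stewardship wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    REL_TOL,
    ManagementScenario,
    effective_lifespan,
    evaluate_action_expanded,
)
from .errors import InternalConsistencyError, ValidationError

__all__ = [
    "OptimizationResult",
    "CriticalDiscountResult",
    "ComparativeStaticsReport",
    "optimal_action",
    "critical_discount_factor",
    "comparative_statics",
]


@dataclass
class OptimizationResult:
    optimal_action: float
    optimal_value: float
    value_profile: pd.DataFrame  # columns gamma, E, L, V
    method: str  # "grid" | "refined"

    def to_dict(self) -> dict:
        return {
            "optimal_action": self.optimal_action,
            "optimal_value": self.optimal_value,
            "method": self.method,
            "value_profile": self.value_profile.to_dict(orient="records"),
        }


def optimal_action(
    scenario: ManagementScenario, grid_size: int = 1001, refine: bool = False
) -> OptimizationResult:
    """Maximize the stream value ``E(gamma) * L(gamma)`` over the action set.

    Finite action sets are enumerated. Continuous sets are grid-searched
    (``grid_size`` points, default 1001) and optionally refined by bounded
    scalar minimization (golden-section style) around the best grid point
    to ``1e-8`` in ``gamma``; grid search first keeps the method robust to
    non-smooth tabulated inputs. Argmax ties break toward the smaller
    action (less stewardship), mirroring the strict-inequality convention.
    """
    gammas = scenario.actions.probe(grid_size)
    Es = np.array([scenario.excess_profit(g) for g in gammas])
    Ls = np.array([effective_lifespan(scenario.delta, scenario.persistence(g)) for g in gammas])
    Vs = Es * Ls
    if not np.any(np.isfinite(Vs)):
        raise ValidationError("stream value is non-finite over the whole action set")
    profile = pd.DataFrame({"gamma": gammas, "E": Es, "L": Ls, "V": Vs})

    vmax = np.nanmax(Vs)
    tol = REL_TOL * max(1.0, abs(vmax))
    best_idx = int(np.argmax(Vs >= vmax - tol))  # first index within tolerance of max
    gstar, vstar = float(gammas[best_idx]), float(Vs[best_idx])
    method = "grid"

    if refine and scenario.actions.kind == "interval":
        lo, hi = scenario.actions.bounds
        h = (hi - lo) / (grid_size - 1) if grid_size > 1 else (hi - lo)
        a, b = max(lo, gstar - h), min(hi, gstar + h)
        res = optimize.minimize_scalar(
            lambda g: -scenario.value(float(g)),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > vstar:
            gstar, vstar = float(res.x), float(-res.fun)
        method = "refined"

    return OptimizationResult(gstar, vstar, profile, method)


@dataclass
class CriticalDiscountResult:
    """The discount factor at which a binary stewardship choice breaks even.

    ``feasible`` is False when even perfect patience (``delta -> 1``) does
    not justify the action; then ``delta_star`` and ``r_star`` are None.
    ``r_star = 1/delta_star - 1`` is the companion interest rate.
    """

    feasible: bool
    delta_star: Optional[float] = None
    r_star: Optional[float] = None

    def to_dict(self) -> dict:
        return {"feasible": self.feasible, "delta_star": self.delta_star, "r_star": self.r_star}


def critical_discount_factor(
    kappa_gamma: float, kappa_gamma0: float, cost_ratio: float
) -> CriticalDiscountResult:
    """Solve for the ``delta`` at which the expanded inequality binds.

    With percentage cost ``c`` (the right-hand side of the expanded
    inequality) the break-even discount factor is::

        delta* = c / (kappa(g) - kappa(g0) + c * kappa(g))

    Stewardship wins for ``delta > delta*``. The problem is infeasible when
    ``(kappa(g) - kappa(g0)) / (1 - kappa(g)) <= c`` — even ``delta -> 1``
    cannot pay for the action — and in particular whenever the action does
    not actually help (``kappa(g) <= kappa(g0)``) at positive cost.
    """
    for name, k in (("kappa_gamma", kappa_gamma), ("kappa_gamma0", kappa_gamma0)):
        if not (0.0 <= k <= 1.0):
            raise ValidationError(f"{name}={k} outside [0, 1]")
    if cost_ratio < 0:
        raise ValidationError(f"cost_ratio={cost_ratio} must be >= 0")
    c = float(cost_ratio)
    if c == 0.0:
        return CriticalDiscountResult(True, 0.0, math.inf)
    if kappa_gamma <= kappa_gamma0:
        return CriticalDiscountResult(False)
    if kappa_gamma < 1.0 and (kappa_gamma - kappa_gamma0) / (1.0 - kappa_gamma) <= c:
        return CriticalDiscountResult(False)
    delta_star = c / (kappa_gamma - kappa_gamma0 + c * kappa_gamma)
    return CriticalDiscountResult(True, delta_star, 1.0 / delta_star - 1.0)


_SWEEPABLE = ("delta", "kappa_effect", "evolved_profit")
# incentive = lhs - rhs of the expanded inequality; expected direction along
# an *increasing* grid of the swept parameter
_EXPECTED_DIRECTION = {"delta": 1, "kappa_effect": 1, "evolved_profit": -1}


@dataclass
class ComparativeStaticsReport:
    parameter: str
    grid: np.ndarray
    incentive: np.ndarray  # lhs - rhs along the grid
    direction: str  # "increasing" | "decreasing"

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": list(map(float, self.grid)),
            "incentive": list(map(float, self.incentive)),
            "direction": self.direction,
        }


def comparative_statics(
    scenario: ManagementScenario,
    gamma: float,
    parameter: str,
    grid: Sequence[float],
    gamma0: Optional[float] = None,
) -> ComparativeStaticsReport:
    """Sweep one primitive and report how the stewardship incentive moves.

    ``parameter`` is one of ``"delta"`` (the discount factor),
    ``"kappa_effect"`` (the value of ``kappa(gamma)``, holding
    ``kappa(gamma0)`` fixed) or ``"evolved_profit"`` (``Pi_bar``). The
    incentive is the gap ``lhs - rhs`` of the expanded inequality. The
    model guarantees monotonicity in each case — patience and management
    effectiveness raise the incentive, a richer evolved state lowers it —
    so a non-monotone sweep raises :class:`InternalConsistencyError`.
    """
    if parameter not in _SWEEPABLE:
        raise ValidationError(f"parameter must be one of {_SWEEPABLE}, got {parameter!r}")
    if gamma0 is None:
        gamma0 = scenario.gamma0
    pi_g = scenario.pristine_profit(gamma)
    pi_g0 = scenario.pristine_profit(gamma0)
    kap_g = scenario.persistence(gamma)
    kap_g0 = scenario.persistence(gamma0)

    grid = np.asarray(sorted(float(v) for v in grid))
    vals = []
    for v in grid:
        delta, kg, pibar = scenario.delta, kap_g, scenario.evolved_profit
        if parameter == "delta":
            delta = v
        elif parameter == "kappa_effect":
            kg = v
        else:
            pibar = v
        ev = evaluate_action_expanded(delta, kg, kap_g0, pi_g, pi_g0, pibar)
        vals.append(ev.lhs - ev.rhs)
    incentive = np.asarray(vals)

    diffs = np.diff(incentive)
    tol = 1e-12 * max(1.0, float(np.abs(incentive).max()))
    expected = _EXPECTED_DIRECTION[parameter]
    if expected > 0:
        ok = np.all(diffs >= -tol)
        direction = "increasing"
    else:
        ok = np.all(diffs <= tol)
        direction = "decreasing"
    if not ok:
        raise InternalConsistencyError(
            f"incentive sweep over {parameter} is not monotone {direction}; "
            "this violates a structural guarantee of the model"
        )
    return ComparativeStaticsReport(parameter, grid, incentive, direction)
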