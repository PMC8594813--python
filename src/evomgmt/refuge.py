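"""The Bt-corn refuge example in closed form.

Planting a fraction ``gamma`` of a farm with non-Bt corn (a refuge) slows
the evolution of Bt resistance but forgoes the Bt yield premium on that
land. When the farmer would keep planting non-Bt corn after resistance has
spread, every per-acre cost and revenue cancels from the percentage cost of
the refuge, leaving the remarkably simple expression ``gamma / (1 -
gamma)``: a 20% refuge costs 25% of annual excess profit, so it must raise
the effective life span of the resistance-free profit stream by at least
25% — e.g. from 8 effective years by at least 2 — to pay for itself.

A finite-horizon variant converts the criterion into calendar years of
crop efficacy: with efficacy lasting a deterministic ``T`` years and annual
discounting ``delta = 1/(1+r)``, the life span of the stream is ``(1 -
delta**T) / (1 - delta)``, and a refuge extending efficacy from ``N`` to
``M`` years pays off once the life-span ratio reaches ``1/(1-gamma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError

__all__ = [
    "RefugeScenario",
    "CalendarLifespanResult",
    "refuge_cost_percentage",
    "required_lifespan_gain",
    "finite_horizon_lifespan",
    "min_calendar_lifespan",
    "alternative_landuse_cost",
]


def refuge_cost_percentage(gamma: float) -> float:
    """Percentage cost ``gamma / (1 - gamma)`` of a refuge of fraction ``gamma``.

    This is the percentage increase in annual excess profit the farmer
    could get by planting Bt corn in the refuge instead. It is independent
    of per-acre costs and revenues (they cancel), which is why optimal
    refuge sizes are insensitive to prices.
    """
    gamma = float(gamma)
    if not (0.0 <= gamma < 1.0):
        if gamma == 1.0:
            raise ValidationError(
                "gamma=1 leaves no Bt planting and no excess stream: infinite cost"
            )
        raise ValidationError(f"refuge fraction gamma={gamma} outside [0, 1)")
    return gamma / (1.0 - gamma)


def required_lifespan_gain(L0: float, gamma: float) -> float:
    """Minimum effective-life-span increase (years) making refuge ``gamma`` pay.

    With baseline effective life span ``L0`` the refuge must add at least
    ``L0 * gamma / (1 - gamma)`` effective years.
    """
    L0 = float(L0)
    if L0 < 1.0:
        raise ValidationError(f"baseline effective lifespan L0={L0} must be >= 1")
    return L0 * refuge_cost_percentage(gamma)


def finite_horizon_lifespan(T: float, delta: float) -> float:
    """Life span ``(1 - delta**T) / (1 - delta)`` of a T-year certain stream."""
    if delta <= 0.0 or delta >= 1.0:
        raise ValidationError(f"delta={delta} outside (0, 1)")
    if T < 0:
        raise ValidationError(f"T={T} must be >= 0")
    return (1.0 - delta**T) / (1.0 - delta)


@dataclass
class CalendarLifespanResult:
    """Smallest calendar efficacy duration that justifies a refuge.

    ``m_real`` is the real-valued break-even duration; ``m_years`` its
    integer ceiling (whole growing seasons). ``feasible`` is False when no
    finite duration suffices (then both are None): the life-span ratio is
    bounded by ``1/(1 - delta**N)``, so feasibility requires
    ``delta**N > gamma``.
    """

    feasible: bool
    m_real: Optional[float] = None
    m_years: Optional[int] = None
    baseline_years: float = 0.0
    gamma: float = 0.0
    rate: float = 0.0

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "m_real": self.m_real,
            "m_years": self.m_years,
            "N": self.baseline_years,
            "gamma": self.gamma,
            "rate": self.rate,
        }


def min_calendar_lifespan(N: float, gamma: float, r: float) -> CalendarLifespanResult:
    """Smallest calendar life span ``M`` making a refuge of fraction ``gamma`` pay.

    Efficacy is modeled as a deterministic window: the excess stream lasts
    exactly ``T`` calendar years (persistence 1 until the crop fails, then
    0). The refuge pays once ``L_fin(M) / L_fin(N) >= 1/(1-gamma)`` with
    ``L_fin(T) = (1 - delta**T)/(1 - delta)`` and ``delta = 1/(1+r)``.

    Solving for the break-even ``M`` gives ``delta**M = 1 - (1 -
    delta**N)/(1-gamma)``; when the right side is not positive no finite
    ``M`` works and the result is flagged infeasible rather than raising.
    """
    gamma = float(gamma)
    if not (0.0 <= gamma < 1.0):
        raise ValidationError(f"refuge fraction gamma={gamma} outside [0, 1)")
    if r <= 0:
        raise ValidationError(f"interest rate r={r} must be > 0")
    if N < 1:
        raise ValidationError(f"baseline calendar lifespan N={N} must be >= 1")
    delta = 1.0 / (1.0 + r)
    if gamma == 0.0:
        return CalendarLifespanResult(True, float(N), math.ceil(N), N, gamma, r)
    target = 1.0 - (1.0 - delta**N) / (1.0 - gamma)  # required delta**M
    if target <= 0.0:
        return CalendarLifespanResult(False, None, None, N, gamma, r)
    m_real = math.log(target) / math.log(delta)
    return CalendarLifespanResult(True, m_real, math.ceil(m_real - 1e-12), N, gamma, r)


def alternative_landuse_cost(
    gamma: float, pi_bt: float, pi_non: float, pi_alt: float
) -> float:
    """Percentage refuge cost when the post-resistance land use differs.

    ``pi_bt`` and ``pi_non`` are per-acre pristine profits of Bt and non-Bt
    planting; ``pi_alt`` is the per-acre profit of the best land use after
    resistance has spread. The cost is::

        C = (pi_bt - Pi(gamma)) / (Pi(gamma) - pi_alt),
        Pi(gamma) = (1-gamma) * pi_bt + gamma * pi_non

    which reduces to ``gamma/(1-gamma)`` when ``pi_alt = pi_non`` and grows
    with the outside option — a more profitable fallback erodes the
    incentive to steward. Returns ``inf`` when the denominator is
    non-positive (the excess stream vanishes; stewardship can never pay).
    """
    gamma = float(gamma)
    if not (0.0 <= gamma < 1.0):
        raise ValidationError(f"refuge fraction gamma={gamma} outside [0, 1)")
    if pi_bt <= pi_alt:
        raise ValidationError(
            f"pristine Bt profit ({pi_bt}) must exceed the outside option ({pi_alt})"
        )
    pi_mixed = (1.0 - gamma) * pi_bt + gamma * pi_non
    denom = pi_mixed - pi_alt
    if denom <= 0.0:
        return math.inf
    return (pi_bt - pi_mixed) / denom


@dataclass
class RefugeScenario:
    """Bundle of the Bt-refuge example's primitives with convenience methods.

    Defaults reproduce the canonical comparison: a 26% refuge, a 15-year
    baseline efficacy window, 4%/year interest and an 8-effective-year
    baseline stream.
    """

    refuge_fraction: float = 0.26
    baseline_effective_lifespan: float = 8.0
    baseline_calendar_lifespan: float = 15.0
    interest_rate: float = 0.04
    post_resistance_profit: float = 0.0
    pi_bt: Optional[float] = None
    pi_non: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.refuge_fraction < 1.0):
            raise ValidationError(
                f"refuge fraction {self.refuge_fraction} outside [0, 1)"
            )
        if self.baseline_calendar_lifespan < 1:
            raise ValidationError("baseline calendar lifespan must be >= 1")

    def cost_percentage(self) -> float:
        return refuge_cost_percentage(self.refuge_fraction)

    def required_gain(self) -> float:
        return required_lifespan_gain(self.baseline_effective_lifespan, self.refuge_fraction)

    def min_calendar(self) -> CalendarLifespanResult:
        return min_calendar_lifespan(
            self.baseline_calendar_lifespan, self.refuge_fraction, self.interest_rate
        )
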