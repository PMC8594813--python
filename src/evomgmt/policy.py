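"""Regulatory interventions in the stewardship game.

A regulator can pay stewards a subsidy ``S`` per stewarding year, which
raises the steward's annual excess profit to ``E_p(gamma) + S`` and so
lowers the percentage cost curve; the benefit curve is untouched. The
qualitative impact hinges on the feedback structure: under negative
strategic feedback a small permanent subsidy nudges the unique equilibrium
up slightly, while under positive feedback a subsidy below the
belief-switching threshold changes nothing and one above it — even if paid
for a single year — can flip the population permanently from the
no-stewardship to the all-stewardship equilibrium. Because stewardship can
also benefit *other* managers (a positive externality,
``d(E_p L_p)/dp > 0``), a cartel coordinating everyone's choice may steward
more than any Nash equilibrium would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import optimize

from .errors import ValidationError
from .families import ParametricFunction
from .game import (
    DynamicsResult,
    EquilibriumSet,
    PopulationGame,
    best_response_dynamics,
    find_nash_equilibria,
)

__all__ = [
    "PolicyIntervention",
    "PolicyOutcome",
    "CartelResult",
    "apply_permanent_subsidy",
    "minimum_switching_subsidy",
    "temporary_subsidy_outcome",
    "permanent_subsidy_outcome",
    "collective_optimum",
    "externality_sign",
]


@dataclass
class PolicyIntervention:
    """A stewardship subsidy: ``S`` per year, permanent or one-year only.

    The subsidy is paid while stewarding in the pristine state (it enters
    the steward's excess profit).
    """

    subsidy: float
    duration: str = "permanent"  # "permanent" | "temporary_one_period"
    payment_condition: str = "pristine_stewarding"

    def __post_init__(self):
        if self.subsidy < 0:
            raise ValidationError(f"subsidy S={self.subsidy} must be >= 0")
        if self.duration not in ("permanent", "temporary_one_period"):
            raise ValidationError(f"unknown duration {self.duration!r}")


@dataclass
class PolicyOutcome:
    pre_equilibria: EquilibriumSet
    post_equilibria: EquilibriumSet
    long_run_p: float
    delta_p: float
    narrative_class: str  # "no_effect" | "marginal_shift" | "regime_switch"
    dynamics: Optional[DynamicsResult] = None

    def to_dict(self) -> dict:
        return {
            "pre_equilibria": self.pre_equilibria.to_dict(),
            "post_equilibria": self.post_equilibria.to_dict(),
            "long_run_p": self.long_run_p,
            "delta_p": self.delta_p,
            "narrative_class": self.narrative_class,
        }


def _shifted_E(fn: ParametricFunction, S: float) -> ParametricFunction:
    """E_p(gamma) + S, staying serializable for the shipped families."""
    if S == 0.0:
        return fn
    if fn.family == "constant":
        return ParametricFunction("constant", {"value": fn.params["value"] + S})
    if fn.family == "linear":
        return ParametricFunction(
            "linear", {"intercept": fn.params["intercept"] + S, "slope": fn.params["slope"]}
        )
    if fn.family == "table":
        return ParametricFunction(
            "table", {"x": fn.params["x"], "y": [y + S for y in fn.params["y"]]}
        )
    return ParametricFunction("callable", lambda p, fn=fn, S=S: fn(p) + S)


def apply_permanent_subsidy(game: PopulationGame, S: float) -> PopulationGame:
    """The game induced by paying stewards ``S`` per stewarding year.

    Stewards' excess profit becomes ``E_p(gamma) + S``, so the cost curve
    drops to ``C_S(p) = (E_p(gamma0) - E_p(gamma) - S)/(E_p(gamma) + S)``,
    strictly below ``C(p)`` for ``S > 0``; ``B`` is unchanged.
    """
    if S < 0:
        raise ValidationError(f"subsidy S={S} must be >= 0")
    if S == 0.0:
        return game
    return PopulationGame(
        E_steward=_shifted_E(game.E_steward, S),
        E_baseline=game.E_baseline,
        L_steward=game.L_steward,
        L_baseline=game.L_baseline,
        label=(game.label + f"+S={S}") if game.label else f"S={S}",
    )


def minimum_switching_subsidy(game: PopulationGame, p_grid=None) -> float:
    """Smallest subsidy making stewardship dominant for every ``p``.

    Solving ``B(p) = C_S(p)`` for ``S`` pointwise gives ``S(p) =
    (E_p(gamma0) - E_p(gamma) - B(p) E_p(gamma)) / (1 + B(p))``; the
    dominance threshold is the worst case ``S* = max_p S(p)`` (clipped at
    zero when stewardship already dominates).
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 1001)
    p_grid = np.asarray(p_grid, dtype=float)
    worst = 0.0
    for p in p_grid:
        B = game.benefit(p)
        if B <= -1.0:
            raise ValidationError(f"B(p)={B} <= -1 at p={p}: degenerate game")
        s = (game.E_baseline(p) - game.E_steward(p) - B * game.E_steward(p)) / (1.0 + B)
        worst = max(worst, s)
    return worst


def _narrative(pre: EquilibriumSet, long_run: float, baseline: float) -> str:
    if math.isclose(long_run, baseline, abs_tol=1e-6):
        return "no_effect"
    # regime switch: the long-run point coincides with a *different* stable
    # equilibrium of the original game
    for eq in pre.stable:
        if math.isclose(long_run, eq.p, abs_tol=1e-4) and not math.isclose(
            baseline, eq.p, abs_tol=1e-4
        ):
            return "regime_switch"
    return "marginal_shift"


def permanent_subsidy_outcome(
    game: PopulationGame, S: float, p_init: float = 0.0
) -> PolicyOutcome:
    """Long-run effect of a permanent stewardship subsidy ``S``.

    Managers adjust under the subsidized game from ``p_init``; the limit is
    compared with the no-subsidy limit from the same start.
    """
    pre = find_nash_equilibria(game)
    sub = apply_permanent_subsidy(game, S)
    post = find_nash_equilibria(sub)
    baseline = best_response_dynamics(game, p_init).limit
    dyn = best_response_dynamics(sub, p_init)
    narrative = _narrative(pre, dyn.limit, baseline)
    return PolicyOutcome(pre, post, dyn.limit, dyn.limit - baseline, narrative, dyn)


def temporary_subsidy_outcome(
    game: PopulationGame, S: float, p_init: float = 0.0
) -> PolicyOutcome:
    """Long-run effect of paying ``S`` for a single year only.

    During the subsidized year managers best-respond to ``p_init`` under
    the subsidized cost curve; if the subsidy makes stewardship dominant
    (``B > C_S`` for every ``p``) everyone stewards, moving the population
    to ``p = 1``. Afterwards the unsubsidized dynamics take over from that
    point; the limit is the permanent legacy of the temporary payment.
    """
    if p_init < 0 or p_init > 1:
        raise ValidationError(f"p_init={p_init} outside [0, 1]")
    pre = find_nash_equilibria(game)
    sub = apply_permanent_subsidy(game, S)
    post = find_nash_equilibria(sub)

    grid = np.linspace(0.0, 1.0, 1001)
    dominant = S > 0 and all(sub.gap(p) > 0 for p in grid)
    if dominant:
        p_after = 1.0
    elif S > 0:
        # one synchronous best response to the current population state
        g = sub.gap(p_init)
        p_after = 1.0 if g > 0 else (0.0 if g < 0 else p_init)
    else:
        p_after = p_init
    dyn = best_response_dynamics(game, p_after)
    baseline = best_response_dynamics(game, p_init).limit
    narrative = _narrative(pre, dyn.limit, baseline)
    return PolicyOutcome(pre, post, dyn.limit, dyn.limit - baseline, narrative, dyn)


@dataclass
class CartelResult:
    """Collectively optimal stewarding fraction versus Nash play.

    ``W(p) = p E_p(g) L_p(g) + (1-p) E_p(g0) L_p(g0)`` is the per-manager
    expected stream value when a fraction ``p`` stewards; a cartel picks
    its maximizer. ``gaps`` lists ``W(p_cartel) - W(p*)`` for each stable
    Nash point (nonnegative by construction).
    """

    p_cartel: float
    W_cartel: float
    nash: EquilibriumSet
    gaps: List[dict]

    def to_dict(self) -> dict:
        return {
            "p_cartel": self.p_cartel,
            "W_cartel": self.W_cartel,
            "nash": self.nash.to_dict(),
            "gaps": self.gaps,
        }


def collective_welfare(game: PopulationGame, p: float) -> float:
    """Per-manager expected stream value when a fraction ``p`` stewards."""
    return p * game.steward_value(p) + (1.0 - p) * game.baseline_value(p)


def collective_optimum(game: PopulationGame, p_grid=None) -> CartelResult:
    """Maximize the managers' collective welfare over the stewarding fraction.

    Grid argmax refined by bounded scalar maximization around the best grid
    point, compared against the stable Nash equilibria of individual play.
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 1001)
    p_grid = np.asarray(p_grid, dtype=float)
    W = np.array([collective_welfare(game, p) for p in p_grid])
    i = int(np.argmax(W))
    a = p_grid[max(0, i - 1)]
    b = p_grid[min(len(p_grid) - 1, i + 1)]
    p_cartel, W_cartel = float(p_grid[i]), float(W[i])
    if b > a:
        res = optimize.minimize_scalar(
            lambda p: -collective_welfare(game, float(p)),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > W_cartel:
            p_cartel, W_cartel = float(res.x), float(-res.fun)
    nash = find_nash_equilibria(game)
    gaps = [
        {"p_nash": eq.p, "gap": W_cartel - collective_welfare(game, eq.p)}
        for eq in nash.stable
    ]
    return CartelResult(p_cartel, W_cartel, nash, gaps)


def externality_sign(
    game: PopulationGame, action: str = "steward", p: float = 0.5, h: float = 1e-5
):
    """Sign of ``d(E_p L_p)/dp`` at ``p`` by finite differences.

    A positive derivative for the stewarded action is the positive
    externality making coordination valuable. Central differences are used
    away from the boundary; one-sided at ``p = 0`` or ``p = 1`` (flagged).
    Returns ``(sign, derivative, one_sided)`` with a +/-1e-9 zero band.
    """
    if action not in ("steward", "baseline"):
        raise ValidationError(f"action must be 'steward' or 'baseline', got {action!r}")
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p={p} outside [0, 1]")
    value = game.steward_value if action == "steward" else game.baseline_value
    one_sided = False
    if p - h < 0.0:
        deriv = (value(p + h) - value(p)) / h
        one_sided = True
    elif p + h > 1.0:
        deriv = (value(p) - value(p - h)) / h
        one_sided = True
    else:
        deriv = (value(p + h) - value(p - h)) / (2.0 * h)
    if abs(deriv) < 1e-9:
        sign = 0
    else:
        sign = 1 if deriv > 0 else -1
    return sign, deriv, one_sided
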