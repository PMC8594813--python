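"""Core regime-shift model of evolution management.

A biological resource (a Bt cornfield, a novel antibiotic, a fish farm) sits
in one of two states: *pristine* (adverse evolution such as resistance has
not yet occurred) and *evolved*. Each year the manager picks a stewardship
action ``gamma``; annual profit is ``Pi(gamma)`` while pristine and a
constant ``Pi_bar`` once evolved, with the shift treated as an irreversible
jump that the action can delay. Two discounts compound:

* economic discounting ``delta = 1/(1+r)`` for annual interest rate ``r``;
* evolutionary discounting ``kappa(gamma)``, the annual probability that
  adverse evolution does *not* occur under the chosen action.

The excess profit ``E(gamma) = Pi(gamma) - Pi_bar`` is then earned for an
*effective life span* of ``L(gamma) = 1 / (1 - delta * kappa(gamma))``
effective years, so the stream is worth ``V = E * L`` in present value.

Stewardship action ``gamma`` beats the no-stewardship choice ``gamma0``
(the maximizer of ``E``) exactly when the evolution management inequality

    (L(gamma) - L(gamma0)) / L(gamma0)  >  (E(gamma0) - E(gamma)) / E(gamma)

holds: the percentage gain in effective life span must exceed the
percentage gain in annual excess profit forgone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import NonFiniteLifespanError, ValidationError
from .families import ParametricFunction

__all__ = [
    "REL_TOL",
    "ActionSet",
    "ManagementScenario",
    "StewardshipEvaluation",
    "ExpandedEvaluation",
    "effective_lifespan",
    "excess_profit",
    "stream_value",
    "evaluate_action",
    "evaluate_action_expanded",
]

#: Relative tolerance for tie and argmax detection. All model quantities are
#: O(1)-O(1e3), so a relative band is appropriate.
REL_TOL = 1e-9

#: Grid used to probe continuous action sets for validation and argmax.
_PROBE_POINTS = 1001


# ---------------------------------------------------------------------------
# fundamental quantities
# ---------------------------------------------------------------------------

def effective_lifespan(delta: float, kappa: float) -> float:
    """Effective life span ``L = 1 / (1 - delta * kappa)`` in effective years.

    ``L`` is the multiplier converting one year's excess profit into the
    total present value of the stream: it combines economic discounting
    (``delta``) with the chance the stream survives evolution each year
    (``kappa``).

    Parameters
    ----------
    delta : float
        Annual discount factor, ``0 <= delta <= 1``; ``delta = 1`` is only
        admissible with ``kappa < 1``.
    kappa : float
        Annual persistence probability, in ``[0, 1]``.

    Raises
    ------
    NonFiniteLifespanError
        If ``delta * kappa == 1`` (an undiscounted immortal stream).
    ValidationError
        If either argument is out of range.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValidationError(f"discount factor delta={delta} outside [0, 1]")
    if not (0.0 <= kappa <= 1.0):
        raise ValidationError(f"persistence kappa={kappa} outside [0, 1]")
    dk = delta * kappa
    if dk >= 1.0:
        raise NonFiniteLifespanError(
            f"delta*kappa = {dk} >= 1: non-finite lifespan (undiscounted immortal stream)"
        )
    return 1.0 / (1.0 - dk)


def stream_value(E: float, L: float) -> float:
    """Present value ``V = E * L`` of the excess-profit stream.

    Equals the geometric series ``sum_t (delta*kappa)^t * E``.
    """
    if L < 1.0:
        raise ValidationError(f"effective lifespan L={L} < 1")
    return E * L


# ---------------------------------------------------------------------------
# scenario container
# ---------------------------------------------------------------------------

@dataclass
class ActionSet:
    """Either a finite grid of actions or a continuous interval.

    ``kind`` is ``"grid"`` (with ``values``) or ``"interval"`` (with
    ``bounds``). Membership on a grid is checked to relative tolerance.
    """

    kind: str
    values: Optional[Sequence[float]] = None
    bounds: Optional[tuple] = None

    def __post_init__(self):
        if self.kind == "grid":
            if not self.values:
                raise ValidationError("action grid must be nonempty")
            vals = sorted(float(v) for v in self.values)
            self.values = vals
            self.bounds = None
        elif self.kind == "interval":
            if self.bounds is None or len(self.bounds) != 2:
                raise ValidationError("interval action set needs bounds (lo, hi)")
            lo, hi = float(self.bounds[0]), float(self.bounds[1])
            if not lo < hi:
                raise ValidationError(f"interval bounds ({lo}, {hi}) must satisfy lo < hi")
            self.bounds = (lo, hi)
            self.values = None
        else:
            raise ValidationError(f"unknown action set kind {self.kind!r}")

    def __contains__(self, gamma: float) -> bool:
        gamma = float(gamma)
        if self.kind == "grid":
            return any(math.isclose(gamma, v, rel_tol=REL_TOL, abs_tol=REL_TOL) for v in self.values)
        lo, hi = self.bounds
        return lo - REL_TOL <= gamma <= hi + REL_TOL

    def probe(self, n: int = _PROBE_POINTS) -> np.ndarray:
        """Actions used for validation sweeps and grid argmax."""
        if self.kind == "grid":
            return np.asarray(self.values, dtype=float)
        lo, hi = self.bounds
        return np.linspace(lo, hi, n)

    def to_dict(self) -> dict:
        if self.kind == "grid":
            return {"type": "grid", "values": list(self.values)}
        return {"type": "interval", "bounds": list(self.bounds)}


def _resolve_discount(rate: Optional[float], factor: Optional[float]) -> float:
    if rate is None and factor is None:
        raise ValidationError("supply a discount rate r or a discount factor delta")
    if rate is not None:
        rate = float(rate)
        if rate < 0:
            raise ValidationError(f"interest rate r={rate} must be >= 0")
        implied = 1.0 / (1.0 + rate)
        if factor is not None and not math.isclose(float(factor), implied, rel_tol=REL_TOL):
            raise ValidationError(
                f"discount mismatch: factor {factor} != 1/(1+r) = {implied} for r={rate}"
            )
        return implied
    factor = float(factor)
    if not (0.0 <= factor < 1.0):
        raise ValidationError(f"discount factor delta={factor} outside [0, 1)")
    return factor


@dataclass
class ManagementScenario:
    """One decision-maker's economic environment.

    Parameters
    ----------
    pristine_profit : function of gamma
        Annual profit ``Pi(gamma)`` while the resource is pristine.
    evolved_profit : float
        Annual profit ``Pi_bar`` after adverse evolution (constant; the
        manager stops stewarding once evolution has occurred).
    persistence : function of gamma
        ``kappa(gamma)``, annual probability evolution does not occur.
    actions : ActionSet
    rate, factor : float, optional
        Give one of the interest rate ``r`` or the factor ``delta``;
        giving both requires ``delta = 1/(1+r)``.
    gamma0 : float, optional
        The no-stewardship action. By definition it maximizes the excess
        profit ``E``; if omitted it is computed, and if pinned to a
        non-maximizer a warning is emitted.
    """

    pristine_profit: ParametricFunction
    evolved_profit: float
    persistence: ParametricFunction
    actions: ActionSet
    rate: Optional[float] = None
    factor: Optional[float] = None
    gamma0: Optional[float] = None
    delta: float = field(init=False)

    def __post_init__(self):
        self.pristine_profit = ParametricFunction.coerce(self.pristine_profit)
        self.persistence = ParametricFunction.coerce(self.persistence)
        self.evolved_profit = float(self.evolved_profit)
        if not isinstance(self.actions, ActionSet):
            raise ValidationError("actions must be an ActionSet")
        self.delta = _resolve_discount(self.rate, self.factor)
        if self.rate is None:
            self.rate = 1.0 / self.delta - 1.0
        self.factor = self.delta

        probe = self.actions.probe()
        pis = np.array([self.pristine_profit(g) for g in probe])
        kappas = np.array([self.persistence(g) for g in probe])
        if np.any((kappas < -REL_TOL) | (kappas > 1 + REL_TOL)):
            bad = probe[np.argmax((kappas < -REL_TOL) | (kappas > 1 + REL_TOL))]
            raise ValidationError(
                f"persistence kappa(gamma) outside [0, 1] at gamma={bad}"
            )
        if pis.max() <= self.evolved_profit:
            raise ValidationError(
                "max over actions of pristine profit Pi(gamma) must exceed evolved "
                f"profit Pi_bar ({pis.max()} <= {self.evolved_profit}): adverse "
                "evolution would not be adverse"
            )
        # gamma0 is the E-maximizer (equivalently the Pi-maximizer); ties break
        # toward the smallest action.
        computed = float(probe[int(np.argmax(pis > pis.max() - REL_TOL * max(1.0, abs(pis.max()))))])
        if self.gamma0 is None:
            self.gamma0 = computed
        else:
            self.gamma0 = float(self.gamma0)
            if self.gamma0 not in self.actions:
                raise ValidationError(f"pinned gamma0={self.gamma0} not in the action set")
            pinned_pi = self.pristine_profit(self.gamma0)
            if pinned_pi < pis.max() - REL_TOL * max(1.0, abs(pis.max())):
                warnings.warn(
                    f"pinned gamma0={self.gamma0} is not the excess-profit maximizer "
                    f"(Pi={pinned_pi} < max Pi={pis.max()} at gamma={computed})",
                    stacklevel=2,
                )

    # -- convenience accessors ---------------------------------------------
    def excess_profit(self, gamma: float) -> float:
        return excess_profit(self, gamma)

    def lifespan(self, gamma: float) -> float:
        if gamma not in self.actions:
            raise ValidationError(f"gamma={gamma} not in the action set")
        return effective_lifespan(self.delta, self.persistence(gamma))

    def value(self, gamma: float) -> float:
        """Present value ``V(gamma) = E(gamma) * L(gamma)``."""
        return self.excess_profit(gamma) * self.lifespan(gamma)

    def to_dict(self) -> dict:
        return {
            "discount": {"factor": self.delta},
            "pristine_profit": self.pristine_profit.to_dict(),
            "evolved_profit": self.evolved_profit,
            "persistence": self.persistence.to_dict(),
            "actions": self.actions.to_dict(),
        }


def excess_profit(scenario: ManagementScenario, gamma: float) -> float:
    """Excess profit ``E(gamma) = Pi(gamma) - Pi_bar`` in currency/year.

    May be negative for poor actions; such actions are never beneficial.
    """
    if gamma not in scenario.actions:
        raise ValidationError(f"gamma={gamma} not in the action set")
    return scenario.pristine_profit(gamma) - scenario.evolved_profit


# ---------------------------------------------------------------------------
# the evolution management inequality
# ---------------------------------------------------------------------------

@dataclass
class StewardshipEvaluation:
    """Outcome of comparing action ``gamma`` against ``gamma0``.

    ``benefit_pct`` and ``cost_pct`` are the two sides of the dimensionless
    inequality; they are ``nan`` when ``E(gamma) <= 0`` forces the direct
    value comparison (``percentage_form_valid = False``). ``tie`` marks an
    exact knife edge, which is reported as not beneficial (the inequality
    is strict).
    """

    gamma: float
    excess_profit: float
    effective_lifespan: float
    stream_value: float
    benefit_pct: float
    cost_pct: float
    beneficial: bool
    tie: bool = False
    percentage_form_valid: bool = True
    gamma0: float = 0.0
    stream_value0: float = 0.0

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "E": self.excess_profit,
            "L": self.effective_lifespan,
            "V": self.stream_value,
            "B": self.benefit_pct,
            "C": self.cost_pct,
            "beneficial": self.beneficial,
            "tie": self.tie,
            "percentage_form_valid": self.percentage_form_valid,
        }


def _is_tie(v: float, v0: float) -> bool:
    return math.isclose(v, v0, rel_tol=REL_TOL, abs_tol=REL_TOL)


def evaluate_action(
    scenario: ManagementScenario, gamma: float, gamma0: Optional[float] = None
) -> StewardshipEvaluation:
    """Apply the evolution management inequality to ``gamma`` vs ``gamma0``.

    Returns the percentage benefit ``B = (L(g) - L(g0)) / L(g0)``, the
    percentage cost ``C = (E(g0) - E(g)) / E(g)``, and ``beneficial = B > C``
    — identical to comparing stream values ``V(g) > V(g0)`` directly. When
    ``E(gamma) <= 0`` the percentage form is undefined and the decision
    falls back to the direct value comparison, flagged via
    ``percentage_form_valid``.
    """
    if gamma0 is None:
        gamma0 = scenario.gamma0
    if gamma not in scenario.actions:
        raise ValidationError(f"gamma={gamma} not in the action set")
    if gamma0 not in scenario.actions:
        raise ValidationError(f"gamma0={gamma0} not in the action set")

    E = scenario.excess_profit(gamma)
    E0 = scenario.excess_profit(gamma0)
    L = scenario.lifespan(gamma)
    L0 = scenario.lifespan(gamma0)
    V, V0 = E * L, E0 * L0

    tie = _is_tie(V, V0)
    if E > 0:
        B = (L - L0) / L0
        C = (E0 - E) / E
        beneficial = (not tie) and B > C
        return StewardshipEvaluation(
            gamma, E, L, V, B, C, beneficial, tie, True, gamma0, V0
        )
    # percentage-cost form divides by E(gamma); fall back to direct comparison
    beneficial = (not tie) and V > V0
    return StewardshipEvaluation(
        gamma, E, L, V, math.nan, math.nan, beneficial, tie, False, gamma0, V0
    )


@dataclass
class ExpandedEvaluation:
    """Both sides of the expanded inequality in primitive quantities.

    ``lhs = delta * (kappa(g) - kappa(g0)) / (1 - delta * kappa(g))`` and
    ``rhs = (Pi(g0) - Pi(g)) / (Pi(g) - Pi_bar)``; stewardship wins when
    ``lhs > rhs``.
    """

    lhs: float
    rhs: float
    beneficial: bool
    tie: bool = False


def evaluate_action_expanded(
    delta: float,
    kappa_gamma: float,
    kappa_gamma0: float,
    pi_gamma: float,
    pi_gamma0: float,
    pi_bar: float,
) -> ExpandedEvaluation:
    """Evaluate the inequality written directly in ``delta, kappa, Pi``.

    Algebraically identical to :func:`evaluate_action`; useful when the
    primitive quantities are known but no scenario object exists.
    Requires ``Pi(gamma) > Pi_bar`` (the expanded form divides by the
    excess profit).
    """
    if pi_gamma <= pi_bar:
        raise ValidationError(
            f"expanded form needs Pi(gamma) > Pi_bar (got {pi_gamma} <= {pi_bar})"
        )
    for name, k in (("kappa(gamma)", kappa_gamma), ("kappa(gamma0)", kappa_gamma0)):
        if not (0.0 <= k <= 1.0):
            raise ValidationError(f"{name}={k} outside [0, 1]")
    dk = delta * kappa_gamma
    if dk >= 1.0:
        raise NonFiniteLifespanError(f"delta*kappa(gamma) = {dk} >= 1")
    lhs = delta * (kappa_gamma - kappa_gamma0) / (1.0 - dk)
    rhs = (pi_gamma0 - pi_gamma) / (pi_gamma - pi_bar)
    tie = math.isclose(lhs, rhs, rel_tol=REL_TOL, abs_tol=REL_TOL)
    return ExpandedEvaluation(lhs, rhs, (not tie) and lhs > rhs, tie)
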