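"""The interacting-managers stewardship game.

Each of a continuum of identical managers chooses between a fixed
stewardship level ``gamma`` and no stewardship ``gamma0``. Both the excess
profit ``E`` and the effective life span ``L`` may depend on the fraction
``p`` of managers who steward — e.g. widespread refuges change pest
pressure on everyone. Writing

    B(p) = (L_p(gamma) - L_p(gamma0)) / L_p(gamma0)   (percentage benefit)
    C(p) = (E_p(gamma0) - E_p(gamma)) / E_p(gamma)    (percentage cost)

an individual stewards exactly when ``B(p) > C(p)``. Nash equilibria are
the roots of ``g(p) = B(p) - C(p)`` (interior, where managers are
indifferent) together with the boundaries when no one wants to deviate.
The sign pattern of ``g`` across a root decides convergence stability
under best-response adjustment; the monotonicity of ``g`` classifies the
game as exhibiting negative strategic feedback (strategic substitutes) or
positive strategic feedback (strategic complements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .families import ParametricFunction

__all__ = [
    "PopulationGame",
    "Equilibrium",
    "EquilibriumSet",
    "FeedbackClassification",
    "DynamicsResult",
    "benefit_cost_curves",
    "find_nash_equilibria",
    "classify_feedback",
    "best_response_dynamics",
]

_FLAT_TOL = 1e-9  # |g| below this counts as indifference for continuum detection


@dataclass
class PopulationGame:
    """p-indexed primitives of the binary stewardship game.

    ``E_steward(p)``/``L_steward(p)`` are the excess profit and effective
    life span of a manager choosing ``gamma`` when a fraction ``p`` of the
    others steward; ``E_baseline``/``L_baseline`` are the same for
    ``gamma0``. ``E_steward`` must be positive on ``[0, 1]`` for the
    percentage forms to exist.
    """

    E_steward: ParametricFunction
    E_baseline: ParametricFunction
    L_steward: ParametricFunction
    L_baseline: ParametricFunction
    label: str = ""

    def __post_init__(self):
        for name in ("E_steward", "E_baseline", "L_steward", "L_baseline"):
            setattr(self, name, ParametricFunction.coerce(getattr(self, name)))
        for p in np.linspace(0.0, 1.0, 101):
            if self.E_steward(p) <= 0.0:
                raise ValidationError(
                    f"E_steward(p) must be > 0 on [0, 1]; found {self.E_steward(p)} at p={p}"
                )

    def benefit(self, p: float) -> float:
        """B(p): percentage life-span gain from stewarding."""
        L0 = self.L_baseline(p)
        return (self.L_steward(p) - L0) / L0

    def cost(self, p: float) -> float:
        """C(p): percentage excess-profit gain from not stewarding."""
        Es = self.E_steward(p)
        if Es <= 0.0:
            raise ValidationError(f"E_steward(p)={Es} <= 0 at p={p}")
        return (self.E_baseline(p) - Es) / Es

    def gap(self, p: float) -> float:
        """g(p) = B(p) - C(p); positive means stewarding is individually better."""
        return self.benefit(p) - self.cost(p)

    def steward_value(self, p: float) -> float:
        return self.E_steward(p) * self.L_steward(p)

    def baseline_value(self, p: float) -> float:
        return self.E_baseline(p) * self.L_baseline(p)

    def to_dict(self) -> dict:
        d = {
            "E_steward": self.E_steward.to_dict(),
            "E_baseline": self.E_baseline.to_dict(),
            "L_steward": self.L_steward.to_dict(),
            "L_baseline": self.L_baseline.to_dict(),
        }
        if self.label:
            d["label"] = self.label
        return d


def benefit_cost_curves(game: PopulationGame, p_grid=None) -> pd.DataFrame:
    """Tabulate (p, B(p), C(p), B-C) over a grid of stewarding fractions."""
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 101)
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any((p_grid < 0) | (p_grid > 1)):
        raise ValidationError("p grid must lie in [0, 1]")
    B = np.array([game.benefit(p) for p in p_grid])
    C = np.array([game.cost(p) for p in p_grid])
    return pd.DataFrame({"p": p_grid, "B": B, "C": C, "gap": B - C})


@dataclass
class Equilibrium:
    p: float
    kind: str  # "interior" | "boundary"
    convergence_stable: bool
    marginal: bool = False  # tangency: g = 0 with no sign change

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "kind": self.kind,
            "convergence_stable": self.convergence_stable,
            "marginal": self.marginal,
        }


@dataclass
class FeedbackClassification:
    label: str  # "negative" | "positive" | "mixed"
    flat: bool = False  # g constant over the grid (degenerate)


@dataclass
class EquilibriumSet:
    equilibria: List[Equilibrium]
    feedback_class: str
    gap_samples: pd.DataFrame
    continuum: Optional[tuple] = None  # (lo, hi) when g ~ 0 over an interval

    @property
    def stable(self) -> List[Equilibrium]:
        return [e for e in self.equilibria if e.convergence_stable]

    def to_dict(self) -> dict:
        return {
            "equilibria": [e.to_dict() for e in self.equilibria],
            "feedback_class": self.feedback_class,
            "continuum": list(self.continuum) if self.continuum else None,
        }


def classify_feedback(game: PopulationGame, p_grid=None) -> FeedbackClassification:
    """Classify the strategic feedback from the monotonicity of g = B - C.

    Monotone decreasing g means others' stewardship discourages one's own
    ("negative", strategic substitutes); monotone increasing means it
    encourages it ("positive", strategic complements); anything else is
    "mixed". A constant g is degenerate and is reported as weakly negative
    with ``flat=True``.
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 101)
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size < 3:
        raise ValidationError("feedback classification needs at least 3 grid points")
    g = np.array([game.gap(p) for p in p_grid])
    d = np.diff(g)
    tol = 1e-12 * max(1.0, float(np.abs(g).max()))
    if np.all(np.abs(d) <= tol):
        return FeedbackClassification("negative", flat=True)
    if np.all(d <= tol):
        return FeedbackClassification("negative")
    if np.all(d >= -tol):
        return FeedbackClassification("positive")
    return FeedbackClassification("mixed")


def find_nash_equilibria(
    game: PopulationGame, scan_resolution: float = 1e-3, tol: float = 1e-10
) -> EquilibriumSet:
    """Locate all Nash equilibria of the stewardship game with stability labels.

    Interior equilibria are sign changes of ``g(p) = B(p) - C(p)`` found by
    scanning at ``scan_resolution`` and polishing each bracket with Brent's
    method to ``tol``. A root where ``g`` passes from positive to negative
    is convergence stable (best-response flow pushes p back); a tangency
    (g touches zero without changing sign) is labeled marginal and not
    stable. The boundary p=0 is an equilibrium iff ``g(0) <= 0`` (stable
    when strict); p=1 iff ``g(1) >= 0`` (stable when strict). If ``g`` is
    indistinguishable from zero over a stretch of the scan, that stretch is
    reported as a continuum of equilibria rather than a point.
    """
    if not (0 < scan_resolution <= 0.5):
        raise ValidationError(f"scan_resolution={scan_resolution} outside (0, 0.5]")
    n = int(round(1.0 / scan_resolution)) + 1
    ps = np.linspace(0.0, 1.0, n)
    g = np.array([game.gap(p) for p in ps])
    samples = pd.DataFrame({"p": ps, "B": [game.benefit(p) for p in ps],
                            "C": [game.cost(p) for p in ps], "gap": g})

    # continuum detection: a run of >= 3 consecutive scan points with g ~ 0
    flat = np.abs(g) < _FLAT_TOL
    continuum = None
    if flat.any():
        idx = np.flatnonzero(flat)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        longest = max(runs, key=len)
        if len(longest) >= 3:
            continuum = (float(ps[longest[0]]), float(ps[longest[-1]]))

    equilibria: List[Equilibrium] = []
    for i in range(n - 1):
        a, b = ps[i], ps[i + 1]
        ga, gb = g[i], g[i + 1]
        if continuum and continuum[0] <= a and b <= continuum[1]:
            continue
        if ga == 0.0 and 0 < i:  # exact zero at a scan point
            prev_sign = np.sign(g[i - 1])
            next_sign = np.sign(gb)
            if a not in (0.0, 1.0):
                stable = bool(prev_sign > 0 and next_sign < 0)
                marginal = bool(prev_sign == next_sign and prev_sign != 0)
                equilibria.append(Equilibrium(float(a), "interior", stable, marginal))
            continue
        if ga * gb < 0.0:
            root = optimize.brentq(game.gap, a, b, xtol=tol)
            equilibria.append(Equilibrium(float(root), "interior", bool(ga > 0 and gb < 0)))

    g0, g1 = float(g[0]), float(g[-1])
    if g0 <= _FLAT_TOL and not (continuum and continuum[0] == 0.0):
        equilibria.insert(0, Equilibrium(0.0, "boundary", g0 < -_FLAT_TOL))
    if g1 >= -_FLAT_TOL and not (continuum and continuum[1] == 1.0):
        equilibria.append(Equilibrium(1.0, "boundary", g1 > _FLAT_TOL))

    fb = classify_feedback(game, ps)
    return EquilibriumSet(equilibria, fb.label, samples, continuum)


@dataclass
class DynamicsResult:
    trajectory: np.ndarray
    limit: float
    converged: bool
    steps: int

    def to_dict(self) -> dict:
        return {
            "limit": self.limit,
            "converged": self.converged,
            "steps": self.steps,
            "trajectory": list(map(float, self.trajectory)),
        }


def best_response_dynamics(
    game: PopulationGame,
    p_init: float,
    step_rate: float = 0.05,
    max_steps: int = 10_000,
    tol: float = 1e-8,
    smooth_eps: float = 1e-3,
) -> DynamicsResult:
    """Follow sign-smoothed best-response adjustment to a stable equilibrium.

    The stewarding fraction moves in the direction managers individually
    prefer: ``p <- clip(p + step * tanh(g(p)/eps), 0, 1)``. The smoothing
    avoids chattering exactly at a root; the step is halved each time
    ``g`` changes sign so the iteration contracts onto interior roots
    (a fixed step would orbit them). Limit points are convergence-stable
    equilibria of :func:`find_nash_equilibria`.
    """
    if not (0.0 <= p_init <= 1.0):
        raise ValidationError(f"p_init={p_init} outside [0, 1]")
    if not (0.0 < step_rate <= 1.0):
        raise ValidationError(f"step_rate={step_rate} outside (0, 1]")
    p = float(p_init)
    traj = [p]
    step = step_rate
    prev_sign = 0.0
    converged = False
    for _ in range(max_steps):
        gp = game.gap(p)
        sign = math.copysign(1.0, gp) if gp != 0.0 else 0.0
        if prev_sign != 0.0 and sign != 0.0 and sign != prev_sign:
            step *= 0.5
        prev_sign = sign if sign != 0.0 else prev_sign
        p_next = min(1.0, max(0.0, p + step * math.tanh(gp / smooth_eps)))
        traj.append(p_next)
        if abs(p_next - p) < tol:
            p = p_next
            converged = True
            break
        p = p_next
    return DynamicsResult(np.asarray(traj), p, converged, len(traj) - 1)
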