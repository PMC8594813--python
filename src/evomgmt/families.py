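"""Serializable parametric families for profit and persistence curves.

Scenario and game configs describe one-dimensional functions (of the
stewardship action ``gamma`` or of the stewarding fraction ``p``) as a named
family plus parameters, so that every fixture round-trips through YAML/JSON.
Arbitrary Python callables are accepted programmatically but refuse to
serialize.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["ParametricFunction", "constant", "linear", "logistic", "table"]

_FAMILIES = ("constant", "linear", "logistic", "table", "callable")


class ParametricFunction:
    """A scalar function from a small catalog of named families.

    Families
    --------
    constant : ``value``
    linear   : ``intercept + slope * x``
    logistic : ``lower + (upper - lower) / (1 + exp(-rate * (x - midpoint)))``
    table    : linear interpolation through ``(x, y)`` knots; evaluation
               outside the knot range is a validation error.
    callable : an arbitrary Python function (not serializable).
    """

    def __init__(self, family: str, params: Mapping | Callable[[float], float]):
        if family not in _FAMILIES:
            raise ValidationError(
                f"unknown function family {family!r}; choose one of {_FAMILIES}"
            )
        self.family = family
        if family == "callable":
            if not callable(params):
                raise ValidationError("family 'callable' requires a callable")
            self._fn = params
            self.params: dict = {}
            return
        params = dict(params)
        self.params = params
        try:
            if family == "constant":
                value = float(params.pop("value"))
                self._fn = lambda x: value
            elif family == "linear":
                a = float(params.pop("intercept"))
                b = float(params.pop("slope"))
                self._fn = lambda x: a + b * x
            elif family == "logistic":
                lo = float(params.pop("lower"))
                hi = float(params.pop("upper"))
                mid = float(params.pop("midpoint"))
                rate = float(params.pop("rate"))
                self._fn = lambda x: lo + (hi - lo) / (1.0 + math.exp(-rate * (x - mid)))
            elif family == "table":
                xs = np.asarray(params.pop("x"), dtype=float)
                ys = np.asarray(params.pop("y"), dtype=float)
                if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
                    raise ValidationError(
                        "family 'table' requires 1-d x and y of equal length >= 2"
                    )
                if np.any(np.diff(xs) <= 0):
                    raise ValidationError("table knots x must be strictly increasing")
                lo, hi = float(xs[0]), float(xs[-1])

                def _interp(x, xs=xs, ys=ys, lo=lo, hi=hi):
                    if x < lo - 1e-12 or x > hi + 1e-12:
                        raise ValidationError(
                            f"table evaluation at x={x} outside knot range [{lo}, {hi}]"
                        )
                    return float(np.interp(x, xs, ys))

                self._fn = _interp
                self.params = {"x": [float(v) for v in xs], "y": [float(v) for v in ys]}
                params = {}
        except KeyError as exc:
            raise ValidationError(
                f"family {family!r} missing required parameter {exc.args[0]!r}"
            ) from None
        if params:
            raise ValidationError(
                f"family {family!r} got unknown parameters {sorted(params)}"
            )
        # re-record canonical params for serialization
        if family == "constant":
            self.params = {"value": self._fn(0.0)}
        elif family == "linear":
            self.params = {"intercept": self._fn(0.0), "slope": self._fn(1.0) - self._fn(0.0)}
        elif family == "logistic":
            self.params = {"lower": lo, "upper": hi, "midpoint": mid, "rate": rate}

    def __call__(self, x: float) -> float:
        return float(self._fn(float(x)))

    def to_dict(self) -> dict:
        if self.family == "callable":
            raise ValidationError("a 'callable' function cannot be serialized")
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ParametricFunction":
        spec = dict(spec)
        try:
            family = spec.pop("family")
            params = spec.pop("params")
        except KeyError as exc:
            raise ValidationError(
                f"function spec missing key {exc.args[0]!r} (need 'family' and 'params')"
            ) from None
        if spec:
            raise ValidationError(f"function spec has unknown keys {sorted(spec)}")
        return cls(family, params)

    @classmethod
    def coerce(cls, obj) -> "ParametricFunction":
        """Accept a ParametricFunction, a {family, params} mapping, a bare
        number (constant), or a Python callable."""
        if isinstance(obj, cls):
            return obj
        if callable(obj):
            return cls("callable", obj)
        if isinstance(obj, (int, float)):
            return cls("constant", {"value": float(obj)})
        if isinstance(obj, Mapping):
            return cls.from_dict(obj)
        raise ValidationError(f"cannot interpret {obj!r} as a function")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParametricFunction({self.family!r}, {self.params!r})"


def constant(value: float) -> ParametricFunction:
    return ParametricFunction("constant", {"value": value})


def linear(intercept: float, slope: float) -> ParametricFunction:
    return ParametricFunction("linear", {"intercept": intercept, "slope": slope})


def logistic(lower: float, upper: float, midpoint: float, rate: float) -> ParametricFunction:
    return ParametricFunction(
        "logistic", {"lower": lower, "upper": upper, "midpoint": midpoint, "rate": rate}
    )


def table(x: Sequence[float], y: Sequence[float]) -> ParametricFunction:
    return ParametricFunction("table", {"x": list(x), "y": list(y)})
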