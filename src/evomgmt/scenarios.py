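"""Config parsing and the canonical fixture catalog.

Scenarios and games round-trip through YAML (or JSON) configs built from
the serializable function families. The fixture catalog ships the worked
examples the rest of the package is exercised on: the binary and
continuous Bt-refuge scenarios, the two stylized manager games (strategic
substitutes with one interior equilibrium; strategic complements with
stable corners), the hospital contact-tracing game in which an individual
hospital's action barely moves the life span (so the percentage benefit is
~0), and a small reversible-evolution demo.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .core import ActionSet, ManagementScenario
from .errors import ValidationError
from .families import ParametricFunction, constant, linear, table
from .game import PopulationGame

__all__ = [
    "FIXTURES",
    "load_scenario",
    "loads_scenario",
    "dump_scenario",
    "generate_fixture",
    "fixture_names",
]

_SCENARIO_KEYS = {"discount", "pristine_profit", "evolved_profit", "persistence", "actions", "gamma0"}
_GAME_KEYS = {"E_steward", "E_baseline", "L_steward", "L_baseline", "label"}


def _parse_actions(spec: Mapping) -> ActionSet:
    spec = dict(spec)
    kind = spec.pop("type", None)
    if kind == "grid":
        values = spec.pop("values", None)
        if values is None:
            raise ValidationError("actions of type 'grid' need 'values'")
    elif kind == "interval":
        bounds = spec.pop("bounds", None)
        if bounds is None:
            raise ValidationError("actions of type 'interval' need 'bounds'")
    else:
        raise ValidationError(f"actions 'type' must be 'grid' or 'interval', got {kind!r}")
    if spec:
        raise ValidationError(f"actions spec has unknown keys {sorted(spec)}")
    if kind == "grid":
        return ActionSet("grid", values=values)
    return ActionSet("interval", bounds=tuple(bounds))


def _parse_scenario(cfg: Mapping) -> ManagementScenario:
    unknown = set(cfg) - _SCENARIO_KEYS
    if unknown:
        raise ValidationError(f"scenario config has unknown keys {sorted(unknown)}")
    missing = {"discount", "pristine_profit", "evolved_profit", "persistence", "actions"} - set(cfg)
    if missing:
        raise ValidationError(f"scenario config missing keys {sorted(missing)}")
    discount = dict(cfg["discount"])
    rate = discount.pop("rate", None)
    factor = discount.pop("factor", None)
    if discount:
        raise ValidationError(f"discount spec has unknown keys {sorted(discount)}")
    return ManagementScenario(
        pristine_profit=ParametricFunction.coerce(cfg["pristine_profit"]),
        evolved_profit=float(cfg["evolved_profit"]),
        persistence=ParametricFunction.coerce(cfg["persistence"]),
        actions=_parse_actions(cfg["actions"]),
        rate=rate,
        factor=factor,
        gamma0=cfg.get("gamma0"),
    )


def _parse_game(cfg: Mapping) -> PopulationGame:
    unknown = set(cfg) - _GAME_KEYS
    if unknown:
        raise ValidationError(f"game config has unknown keys {sorted(unknown)}")
    missing = (_GAME_KEYS - {"label"}) - set(cfg)
    if missing:
        raise ValidationError(f"game config missing keys {sorted(missing)}")
    return PopulationGame(
        E_steward=ParametricFunction.coerce(cfg["E_steward"]),
        E_baseline=ParametricFunction.coerce(cfg["E_baseline"]),
        L_steward=ParametricFunction.coerce(cfg["L_steward"]),
        L_baseline=ParametricFunction.coerce(cfg["L_baseline"]),
        label=cfg.get("label", ""),
    )


def loads_scenario(text: str) -> Union[ManagementScenario, PopulationGame]:
    """Parse a YAML/JSON config string into a scenario or game."""
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ValidationError("config must be a mapping")
    if "pristine_profit" in cfg:
        return _parse_scenario(cfg)
    if "E_steward" in cfg:
        return _parse_game(cfg)
    raise ValidationError(
        "config is neither a scenario (needs 'pristine_profit') nor a game "
        "(needs 'E_steward'/'E_baseline'/'L_steward'/'L_baseline')"
    )


def load_scenario(path) -> Union[ManagementScenario, PopulationGame]:
    """Load and validate a scenario or game config from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file {path} does not exist")
    return loads_scenario(path.read_text())


def dump_scenario(obj, path=None, fmt: Optional[str] = None) -> str:
    """Serialize a scenario or game back to YAML (default) or JSON."""
    d = obj.to_dict()
    if fmt is None:
        fmt = "json" if path is not None and str(path).endswith(".json") else "yaml"
    text = json.dumps(d, indent=2) if fmt == "json" else yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# fixture catalog
# ---------------------------------------------------------------------------

def _bt_binary(**kw) -> ManagementScenario:
    """Binary Bt-refuge choice: no refuge vs a 20% refuge.

    Per-acre pristine profits 100 (Bt) and 60 (non-Bt) with the evolved
    state worth the non-Bt profit, so the 20% refuge costs exactly 25% of
    excess profit. Persistence is chosen so the baseline effective life
    span is 8 years and the refuge raises it to 10.4 (a 30% gain > 25%):
    the refuge is beneficial.
    """
    delta = kw.pop("delta", 0.95)
    pi_bt = kw.pop("pi_bt", 100.0)
    pi_non = kw.pop("pi_non", 60.0)
    gamma = kw.pop("gamma", 0.2)
    L0 = kw.pop("L0", 8.0)
    L1 = kw.pop("L1", 10.4)
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    kappa0 = (1.0 - 1.0 / L0) / delta
    kappa1 = (1.0 - 1.0 / L1) / delta
    return ManagementScenario(
        pristine_profit=table([0.0, gamma], [pi_bt, (1 - gamma) * pi_bt + gamma * pi_non]),
        evolved_profit=pi_non,
        persistence=table([0.0, gamma], [kappa0, kappa1]),
        actions=ActionSet("grid", values=[0.0, gamma]),
        factor=delta,
    )


def _bt_continuous(**kw) -> ManagementScenario:
    """Continuous refuge fraction on [0, 1] with linear profit and persistence."""
    delta = kw.pop("delta", 0.95)
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    return ManagementScenario(
        pristine_profit=linear(100.0, -40.0),  # (1-g)*100 + g*60
        evolved_profit=60.0,
        persistence=linear(0.8, 0.15),
        actions=ActionSet("interval", bounds=(0.0, 1.0)),
        factor=delta,
    )


def _fig3a_substitutes(**kw) -> PopulationGame:
    """Negative strategic feedback: B(p) = 0.5 - 0.3 p, C(p) = 0.2 + 0.2 p.

    The curves cross at p* = 0.6, the unique convergence-stable Nash
    equilibrium (some managers steward, others do not).
    """
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    return PopulationGame(
        E_steward=constant(1.0),
        E_baseline=linear(1.2, 0.2),  # C(p) = 0.2 + 0.2 p
        L_steward=linear(7.5, -1.5),  # B(p) = 0.5 - 0.3 p
        L_baseline=constant(5.0),
        label="fig3a_substitutes",
    )


def _fig3b_complements(**kw) -> PopulationGame:
    """Positive strategic feedback: B(p) = 0.1 + 0.6 p, C(p) = 0.3 + 0.2 p.

    Stable equilibria at p = 0 and p = 1 with an unstable interior point
    at p = 0.5.
    """
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    return PopulationGame(
        E_steward=constant(1.0),
        E_baseline=linear(1.3, 0.2),  # C(p) = 0.3 + 0.2 p
        L_steward=linear(5.5, 3.0),  # B(p) = 0.1 + 0.6 p
        L_baseline=constant(5.0),
        label="fig3b_complements",
    )


def _hospital_tracing(**kw) -> PopulationGame:
    """Contact tracing where one hospital's action barely moves the life span.

    ``L_p`` is the same whether or not the individual hospital traces (it
    rises with aggregate investment p), so the percentage benefit is
    identically 0 while tracing still costs money: no hospital finds it
    individually worthwhile, although collective investment would raise
    everyone's life span.
    """
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    L = linear(4.0, 4.0)
    return PopulationGame(
        E_steward=constant(0.9),
        E_baseline=constant(1.0),
        L_steward=L,
        L_baseline=L,
        label="hospital_tracing",
    )


def _reversible_demo(**kw) -> ManagementScenario:
    """Single-action scenario used to exercise the reversible-evolution chain."""
    if kw:
        raise ValidationError(f"unknown overrides {sorted(kw)}")
    return ManagementScenario(
        pristine_profit=constant(100.0),
        evolved_profit=99.0,  # unit excess profit
        persistence=constant(0.8),
        actions=ActionSet("grid", values=[0.0]),
        factor=0.9,
    )


FIXTURES = {
    "bt_binary": _bt_binary,
    "bt_continuous": _bt_continuous,
    "fig3a_substitutes": _fig3a_substitutes,
    "fig3b_complements": _fig3b_complements,
    "hospital_tracing": _hospital_tracing,
    "reversible_demo": _reversible_demo,
}


def fixture_names() -> list:
    return sorted(FIXTURES)


def generate_fixture(
    name: str,
    seed: int = 0,
    overrides: Optional[Mapping] = None,
    outdir=None,
) -> Union[ManagementScenario, PopulationGame]:
    """Build a named fixture, optionally writing its config to ``outdir``.

    All fixtures are deterministic; ``seed`` is recorded in the companion
    metadata file for provenance. Unknown names list the catalog.
    """
    if name not in FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    obj = FIXTURES[name](**dict(overrides or {}))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dump_scenario(obj, outdir / f"{name}.yaml")
        meta = {"name": name, "seed": seed, "kind": type(obj).__name__}
        (outdir / f"{name}.meta.json").write_text(json.dumps(meta, indent=2))
    return obj
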