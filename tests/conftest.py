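import numpy as np
import pytest
from hypothesis import settings

import evomgmt as em

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def bt_binary():
    return em.generate_fixture("bt_binary")


@pytest.fixture
def bt_continuous():
    return em.generate_fixture("bt_continuous")


@pytest.fixture
def fig3a():
    return em.generate_fixture("fig3a_substitutes")


@pytest.fixture
def fig3b():
    return em.generate_fixture("fig3b_complements")


@pytest.fixture
def hospital():
    return em.generate_fixture("hospital_tracing")


def random_binary_scenario(rng: np.random.Generator) -> em.ManagementScenario:
    """A random two-action scenario with positive excess profits and a
    stewardship action that genuinely slows evolution (kappa increases)."""
    delta = rng.uniform(0.3, 0.99)
    pibar = rng.uniform(0.0, 50.0)
    e0 = rng.uniform(1.0, 100.0)  # excess profit of the no-stewardship action
    e1 = e0 * rng.uniform(0.3, 1.0)  # stewarding forgoes some excess profit
    k0 = rng.uniform(0.2, 0.9)
    k1 = rng.uniform(k0, 0.999)
    return em.ManagementScenario(
        pristine_profit=em.table([0.0, 0.5], [pibar + e0, pibar + e1]),
        evolved_profit=pibar,
        persistence=em.table([0.0, 0.5], [k0, k1]),
        actions=em.ActionSet("grid", values=[0.0, 0.5]),
        factor=delta,
    )


def random_continuous_scenario(rng: np.random.Generator) -> em.ManagementScenario:
    """A random continuous-action scenario (logistic persistence, linear profit)."""
    delta = rng.uniform(0.5, 0.98)
    pibar = rng.uniform(0.0, 40.0)
    pi0 = pibar + rng.uniform(10.0, 100.0)
    slope = -rng.uniform(0.1, 0.8) * (pi0 - pibar)
    k_lo = rng.uniform(0.3, 0.8)
    k_hi = rng.uniform(k_lo, 0.999)
    mid = rng.uniform(0.2, 0.8)
    rate = rng.uniform(2.0, 15.0)
    return em.ManagementScenario(
        pristine_profit=em.linear(pi0, slope),
        evolved_profit=pibar,
        persistence=em.logistic(k_lo, k_hi, mid, rate),
        actions=em.ActionSet("interval", bounds=(0.0, 1.0)),
        factor=delta,
    )


def random_monotone_game(rng: np.random.Generator) -> em.PopulationGame:
    """A random game whose gap g(p) = B(p) - C(p) is linear (monotone)."""
    Es = rng.uniform(0.5, 2.0)
    c0 = rng.uniform(0.0, 0.5)
    c1 = rng.uniform(-0.3, 0.3)
    b0 = rng.uniform(0.0, 0.7)
    b1 = rng.uniform(-0.5, 0.5)
    L0 = rng.uniform(3.0, 8.0)
    return em.PopulationGame(
        E_steward=em.constant(Es),
        E_baseline=em.linear(Es * (1 + c0), Es * c1),  # C(p) = c0 + c1 p
        L_steward=em.linear(L0 * (1 + b0), L0 * b1),  # B(p) = b0 + b1 p
        L_baseline=em.constant(L0),
    )
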