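"""Core model: effective life span, excess profit, stream value, and the
evolution management inequality in its percentage and expanded forms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import evomgmt as em
from evomgmt.errors import NonFiniteLifespanError, ValidationError

from conftest import random_binary_scenario


class TestEffectiveLifespan:
    @pytest.mark.parametrize(
        "delta, kappa, expected",
        [
            (0.9, 1.0, 10.0),  # geometric series 1/(1-0.9)
            (0.0, 0.99, 1.0),  # complete discounting: only the current year
            (0.95, 0.875 / 0.95, 8.0),  # delta*kappa = 0.875
            (1.0, 0.5, 2.0),  # undiscounted but mortal stream
        ],
    )
    def test_values(self, delta, kappa, expected):
        assert em.effective_lifespan(delta, kappa) == pytest.approx(expected)

    def test_non_finite_lifespan(self):
        with pytest.raises(NonFiniteLifespanError):
            em.effective_lifespan(1.0, 1.0)

    @pytest.mark.parametrize("delta, kappa", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_out_of_range(self, delta, kappa):
        with pytest.raises(ValidationError):
            em.effective_lifespan(delta, kappa)

    @given(
        delta=st.floats(0.0, 0.999),
        kappa=st.floats(0.0, 1.0),
        bump=st.floats(0.0, 0.2),
    )
    def test_bounds_and_monotonicity(self, delta, kappa, bump):
        """1 <= L <= 1/(1-delta), nondecreasing in each argument."""
        L = em.effective_lifespan(delta, kappa)
        assert 1.0 <= L <= 1.0 / (1.0 - delta) + 1e-12
        assert em.effective_lifespan(min(delta + bump, 0.999), kappa) >= L - 1e-12
        assert em.effective_lifespan(delta, min(kappa + bump, 1.0)) >= L - 1e-12


class TestExcessProfit:
    def test_bt_arithmetic(self, bt_binary):
        # Pi(0.2) = 0.8*100 + 0.2*60 = 92; Pi_bar = 60
        assert bt_binary.excess_profit(0.2) == pytest.approx(32.0)
        assert bt_binary.excess_profit(0.0) == pytest.approx(40.0)

    def test_zero_when_profits_equal(self):
        s = em.ManagementScenario(
            pristine_profit=em.table([0.0, 1.0], [100.0, 40.0]),
            evolved_profit=40.0,
            persistence=em.constant(0.9),
            actions=em.ActionSet("grid", values=[0.0, 1.0]),
            factor=0.9,
        )
        assert s.excess_profit(1.0) == pytest.approx(0.0)

    def test_action_outside_set(self, bt_binary):
        with pytest.raises(ValidationError):
            bt_binary.excess_profit(0.37)


class TestStreamValue:
    def test_basics(self):
        assert em.stream_value(0.0, 7.3) == 0.0
        assert em.stream_value(60.0, 10.0) == pytest.approx(600.0)

    def test_matches_truncated_series(self):
        """Partial sums of the geometric excess stream converge to E*L within
        the analytic tail bound (delta*kappa)^(T+1)/(1-delta*kappa)."""
        dk, E = 0.9, 1.0
        target = em.stream_value(E, 1.0 / (1.0 - dk))
        assert target == pytest.approx(10.0)
        for T in (10, 50, 200, 500):
            partial = sum(E * dk**t for t in range(T + 1))
            tail = dk ** (T + 1) / (1.0 - dk)
            assert abs(target - partial) <= tail + 1e-12
        assert partial == pytest.approx(target, abs=1e-12)


class TestEvaluateAction:
    def test_identity_action_not_beneficial(self, bt_binary):
        ev = em.evaluate_action(bt_binary, bt_binary.gamma0)
        assert ev.benefit_pct == 0.0 and ev.cost_pct == 0.0
        assert not ev.beneficial and ev.tie

    def test_bt_refuge_clears_the_bar(self, bt_binary):
        """30% life-span gain beats the 25% cost of a 20% refuge."""
        ev = em.evaluate_action(bt_binary, 0.2)
        assert ev.cost_pct == pytest.approx(0.25)
        assert ev.benefit_pct == pytest.approx(0.30)
        assert ev.beneficial

    def test_knife_edge_is_not_beneficial(self):
        """Exactly a 25% life-span gain against a 25% cost: strict inequality
        reports the tie as not beneficial."""
        delta = 0.9375
        s = em.ManagementScenario(
            pristine_profit=em.table([0.0, 0.2], [100.0, 92.0]),
            evolved_profit=60.0,
            persistence=em.table([0.0, 0.2], [0.875 / delta, 0.9 / delta]),
            actions=em.ActionSet("grid", values=[0.0, 0.2]),
            factor=delta,
        )
        ev = em.evaluate_action(s, 0.2)
        assert ev.benefit_pct == pytest.approx(0.25)
        assert ev.cost_pct == pytest.approx(0.25)
        assert ev.tie and not ev.beneficial

    def test_decision_matches_direct_value_comparison(self):
        """On 200 random scenarios the inequality decision equals the sign of
        E(g)L(g) - E(g0)L(g0) computed directly."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            s = random_binary_scenario(rng)
            ev = em.evaluate_action(s, 0.5)
            v, v0 = s.value(0.5), s.value(0.0)
            assert ev.beneficial == (v > v0 and not math.isclose(v, v0, rel_tol=1e-9))

    def test_nonpositive_excess_falls_back_to_value_comparison(self):
        s = em.ManagementScenario(
            pristine_profit=em.table([0.0, 1.0], [100.0, 30.0]),  # E(1) = -10 < 0
            evolved_profit=40.0,
            persistence=em.table([0.0, 1.0], [0.5, 0.99]),
            actions=em.ActionSet("grid", values=[0.0, 1.0]),
            factor=0.9,
        )
        ev = em.evaluate_action(s, 1.0)
        assert not ev.percentage_form_valid
        assert math.isnan(ev.benefit_pct) and math.isnan(ev.cost_pct)
        assert not ev.beneficial  # negative excess can never beat a positive stream


class TestExpandedForm:
    def test_complete_discounting_kills_stewardship(self):
        ev = em.evaluate_action_expanded(0.0, 0.95, 0.8, 90.0, 100.0, 60.0)
        assert ev.lhs == 0.0 and not ev.beneficial

    def test_ineffective_management_never_beneficial(self):
        ev = em.evaluate_action_expanded(0.9, 0.8, 0.8, 90.0, 100.0, 60.0)
        assert ev.lhs == 0.0 and not ev.beneficial

    def test_agrees_with_percentage_form(self):
        """Algebraic equivalence: the expanded decision equals the
        percentage-form decision on random scenarios, bit for bit."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = random_binary_scenario(rng)
            ev2 = em.evaluate_action(s, 0.5)
            ev3 = em.evaluate_action_expanded(
                s.delta,
                s.persistence(0.5),
                s.persistence(0.0),
                s.pristine_profit(0.5),
                s.pristine_profit(0.0),
                s.evolved_profit,
            )
            assert ev3.beneficial == ev2.beneficial

    def test_requires_positive_excess(self):
        with pytest.raises(ValidationError):
            em.evaluate_action_expanded(0.9, 0.9, 0.8, 50.0, 100.0, 60.0)


class TestEvolvedProfitMonotonicity:
    def test_lowering_pibar_never_flips_beneficial_off(self):
        """A bleaker evolved state only strengthens the case for stewardship."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = random_binary_scenario(rng)
            ev = em.evaluate_action(s, 0.5)
            lower = em.ManagementScenario(
                pristine_profit=s.pristine_profit,
                evolved_profit=s.evolved_profit - rng.uniform(0.0, 30.0),
                persistence=s.persistence,
                actions=s.actions,
                factor=s.delta,
            )
            ev_lower = em.evaluate_action(lower, 0.5)
            if ev.beneficial:
                assert ev_lower.beneficial


class TestScenarioValidation:
    def test_discount_mismatch_rejected(self, bt_binary):
        with pytest.raises(ValidationError, match="mismatch"):
            em.ManagementScenario(
                pristine_profit=bt_binary.pristine_profit,
                evolved_profit=bt_binary.evolved_profit,
                persistence=bt_binary.persistence,
                actions=bt_binary.actions,
                rate=0.04,
                factor=0.9,
            )

    def test_rate_and_matching_factor_accepted(self, bt_binary):
        s = em.ManagementScenario(
            pristine_profit=bt_binary.pristine_profit,
            evolved_profit=bt_binary.evolved_profit,
            persistence=bt_binary.persistence,
            actions=bt_binary.actions,
            rate=0.04,
            factor=1 / 1.04,
        )
        assert s.delta == pytest.approx(1 / 1.04)

    def test_evolved_profit_must_be_adverse(self, bt_binary):
        with pytest.raises(ValidationError, match="must exceed"):
            em.ManagementScenario(
                pristine_profit=bt_binary.pristine_profit,
                evolved_profit=200.0,
                persistence=bt_binary.persistence,
                actions=bt_binary.actions,
                factor=0.95,
            )

    def test_gamma0_is_the_excess_profit_maximizer(self, bt_binary, bt_continuous):
        assert bt_binary.gamma0 == 0.0
        assert bt_continuous.gamma0 == 0.0

    def test_pinned_non_maximizer_warns(self, bt_binary):
        with pytest.warns(UserWarning, match="not the excess-profit maximizer"):
            em.ManagementScenario(
                pristine_profit=bt_binary.pristine_profit,
                evolved_profit=bt_binary.evolved_profit,
                persistence=bt_binary.persistence,
                actions=bt_binary.actions,
                factor=0.95,
                gamma0=0.2,
            )
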