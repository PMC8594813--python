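"""Subsidies, the dominance threshold, temporary-vs-permanent effects,
cartels, and externality diagnostics."""

import numpy as np
import pytest

import evomgmt as em
from evomgmt.errors import ValidationError


class TestPermanentSubsidy:
    def test_zero_subsidy_is_identity(self, fig3a):
        assert em.apply_permanent_subsidy(fig3a, 0.0) is fig3a

    def test_cost_curve_drops(self, fig3a):
        sub = em.apply_permanent_subsidy(fig3a, 0.05)
        for p in np.linspace(0, 1, 11):
            assert sub.cost(p) < fig3a.cost(p)
            assert sub.benefit(p) == pytest.approx(fig3a.benefit(p))

    def test_cost_strictly_decreasing_in_subsidy(self, fig3b):
        Ss = [0.0, 0.02, 0.05, 0.1, 0.2]
        for p in (0.0, 0.5, 1.0):
            costs = [em.apply_permanent_subsidy(fig3b, S).cost(p) for S in Ss]
            assert np.all(np.diff(costs) < 0)

    def test_small_subsidy_nudges_negative_feedback_equilibrium_up(self, fig3a):
        """Under strategic substitutes a small permanent subsidy moves the
        unique stable equilibrium up slightly — not to full stewardship."""
        out = em.permanent_subsidy_outcome(fig3a, 0.02, p_init=0.6)
        p_star = 0.6
        assert p_star < out.long_run_p < p_star + 0.1
        assert out.narrative_class == "marginal_shift"

    def test_stable_p_nondecreasing_in_subsidy(self, fig3a):
        limits = []
        for S in [0.0, 0.01, 0.03, 0.06, 0.1]:
            sub = em.apply_permanent_subsidy(fig3a, S)
            interior = [e for e in em.find_nash_equilibria(sub).stable]
            limits.append(interior[0].p)
        assert np.all(np.diff(limits) >= -1e-9)

    def test_small_subsidy_cannot_escape_no_stewardship_trap(self, fig3b):
        """Under strategic complements a subsidy below the gap-closing
        threshold leaves the p = 0 equilibrium (and behavior) intact."""
        s_star = em.minimum_switching_subsidy(fig3b)
        out = em.permanent_subsidy_outcome(fig3b, 0.5 * s_star, p_init=0.0)
        stable_ps = [e.p for e in out.post_equilibria.stable]
        assert 0.0 in stable_ps
        assert out.long_run_p == pytest.approx(0.0)
        assert out.narrative_class == "no_effect"


class TestMinimumSwitchingSubsidy:
    def test_zero_when_stewardship_already_dominant(self):
        game = em.PopulationGame(
            E_steward=em.constant(1.0),
            E_baseline=em.constant(1.1),
            L_steward=em.constant(7.5),
            L_baseline=em.constant(5.0),
        )
        assert em.minimum_switching_subsidy(game) == 0.0

    def test_fig3b_worst_case_at_p_zero(self, fig3b):
        """S(p) = (E0 - E - B E)/(1 + B) peaks at p = 0, giving 0.2/1.1."""
        s_star = em.minimum_switching_subsidy(fig3b)
        assert s_star == pytest.approx(0.2 / 1.1, rel=1e-6)

    def test_threshold_sharpness(self, fig3b):
        s_star = em.minimum_switching_subsidy(fig3b)
        grid = np.linspace(0, 1, 1001)
        above = em.apply_permanent_subsidy(fig3b, s_star + 1e-6)
        assert all(above.gap(p) > 0 for p in grid)
        below = em.apply_permanent_subsidy(fig3b, s_star - 1e-4)
        assert any(below.gap(p) <= 0 for p in grid)


class TestTemporarySubsidy:
    def test_negative_feedback_reverts(self, fig3a):
        """A large one-year subsidy pushes everyone to steward, but the
        unique equilibrium pulls the population straight back."""
        out = em.temporary_subsidy_outcome(fig3a, 5.0, p_init=0.6)
        assert out.long_run_p == pytest.approx(0.6, abs=1e-4)
        assert out.narrative_class == "no_effect"

    def test_positive_feedback_switches_permanently(self, fig3b):
        s_star = em.minimum_switching_subsidy(fig3b)
        out = em.temporary_subsidy_outcome(fig3b, 2 * s_star, p_init=0.0)
        assert out.long_run_p == pytest.approx(1.0)
        assert out.narrative_class == "regime_switch"
        assert out.delta_p == pytest.approx(1.0)

    def test_no_subsidy_is_plain_dynamics(self, fig3b):
        out = em.temporary_subsidy_outcome(fig3b, 0.0, p_init=0.4)
        assert out.long_run_p == pytest.approx(
            em.best_response_dynamics(fig3b, 0.4).limit
        )
        assert out.narrative_class == "no_effect"

    def test_negative_subsidy_rejected(self, fig3a):
        with pytest.raises(ValidationError):
            em.temporary_subsidy_outcome(fig3a, -1.0)


class TestCollectiveOptimum:
    def test_p_independent_game_has_no_externality_gap(self):
        game = em.PopulationGame(
            E_steward=em.constant(1.0),
            E_baseline=em.constant(1.1),
            L_steward=em.constant(7.5),
            L_baseline=em.constant(5.0),
        )
        res = em.collective_optimum(game)
        # stewarding dominates individually (B=0.5 > C=0.1) and collectively
        assert res.p_cartel == pytest.approx(1.0)
        for g in res.gaps:
            assert g["gap"] == pytest.approx(0.0, abs=1e-9)

    def test_positive_externality_cartel_stewards_more_than_nash(self, fig3a):
        """fig3a has d(E L)/dp > 0 for stewards (everyone gains as more
        steward... here the externality runs through the baseline), so the
        cartel picks at least the Nash stewarding level."""
        game = em.PopulationGame(
            E_steward=em.linear(1.0, 0.4),
            E_baseline=em.linear(1.25, 0.2),
            L_steward=em.linear(6.0, 2.0),
            L_baseline=em.linear(5.0, 2.0),
        )
        res = em.collective_optimum(game)
        stable = [e.p for e in res.nash.stable]
        assert res.p_cartel >= max(stable) - 1e-6
        for g in res.gaps:
            assert g["gap"] >= -1e-9

    def test_refined_optimum_matches_dense_grid(self, fig3a):
        from evomgmt.policy import collective_welfare

        res = em.collective_optimum(fig3a)
        dense = np.linspace(0, 1, 100_001)
        W = np.array([collective_welfare(fig3a, p) for p in dense])
        assert res.p_cartel == pytest.approx(dense[np.argmax(W)], abs=1e-4)
        assert res.W_cartel >= W.max() - 1e-9


class TestExternalitySign:
    def test_p_independent_game_is_zero(self):
        game = em.PopulationGame(
            E_steward=em.constant(1.0),
            E_baseline=em.constant(1.3),
            L_steward=em.constant(7.0),
            L_baseline=em.constant(5.0),
        )
        sign, deriv, one_sided = em.externality_sign(game, "steward", 0.5)
        assert sign == 0 and abs(deriv) < 1e-9 and not one_sided

    def test_linear_lifespan_derivative(self):
        game = em.PopulationGame(
            E_steward=em.constant(1.0),
            E_baseline=em.constant(1.3),
            L_steward=em.linear(5.0, 2.0),
            L_baseline=em.constant(5.0),
        )
        for p in (0.2, 0.5, 0.8):
            sign, deriv, _ = em.externality_sign(game, "steward", p)
            assert sign == 1
            assert deriv == pytest.approx(2.0, abs=1e-6)

    def test_quadratic_taylor_order(self):
        game = em.PopulationGame(
            E_steward=em.ParametricFunction("callable", lambda p: 1.0 + p**2),
            E_baseline=em.constant(1.3),
            L_steward=em.constant(5.0),
            L_baseline=em.constant(5.0),
        )
        # d(E L)/dp = 10 p; central difference is exact to O(h^2)
        for h in (1e-3, 1e-4):
            _, deriv, _ = em.externality_sign(game, "steward", 0.3, h=h)
            assert deriv == pytest.approx(3.0, abs=10 * h**2 + 1e-9)

    def test_boundary_is_one_sided(self, fig3a):
        _, _, one_sided = em.externality_sign(fig3a, "steward", 0.0)
        assert one_sided
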