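"""Welfare components, the lambda feasibility condition and the optimal bonus."""

import numpy as np
import pytest
from scipy import integrate, optimize

from adherence import (
    adherence_probability,
    adherence_threshold,
    bonus_feasibility,
    copayment_report,
    example_scenario,
    expected_cost_given_adherent,
    individual_welfare,
    individual_welfare_quadrature,
    optimal_bonus,
    random_incentive_scenario,
    random_scenario,
    societal_welfare,
    total_welfare,
    total_welfare_closed_quadratic,
    welfare_report,
)


def societal_welfare_quadrature(scenario):
    """Independent W_S: adherence mass from quadrature of the density."""
    cm = scenario.cost_model
    theta = adherence_threshold(scenario, 1)
    if theta <= 0:
        prob = 0.0
    else:
        prob, _ = integrate.quad(cm.pdf, 0.0, min(theta, cm.support_upper), epsabs=1e-12)
        prob = min(prob, 1.0)
    costs, inc, prefs = scenario.societal_costs, scenario.incentive, scenario.preferences
    net = (
        costs.cost_adherent
        - costs.cost_nonadherent
        - scenario.delta_p * prefs.delta * costs.followup_cost
    )
    payout_share = prob + (1.0 - prob) * (1.0 - inc.detection_prob)
    return (
        -costs.cost_nonadherent - prob * net
        - payout_share * (1.0 + inc.admin_share) * inc.bonus
    )


def with_bonus(scenario, b, p_d=None, lam=None):
    update = {"bonus": b}
    if p_d is not None:
        update["detection_prob"] = p_d
    if lam is not None:
        update["admin_share"] = lam
    return scenario.model_copy(
        update={"incentive": scenario.incentive.model_copy(update=update)}
    )


class TestExpectedCostGivenAdherent:
    def test_reference_value(self, s0):
        assert expected_cost_given_adherent(s0) == pytest.approx(0.108)

    def test_full_adherence_gives_full_support_mean(self):
        s = example_scenario(bonus=5.0)
        assert expected_cost_given_adherent(s) == pytest.approx(0.25)

    def test_empty_adherent_set_convention(self):
        s = example_scenario(bonus=-10.0)
        assert expected_cost_given_adherent(s) == 0.0


class TestIndividualWelfare:
    def test_reference_value(self, s0):
        assert individual_welfare(s0) == pytest.approx(0.046656, abs=1e-12)

    def test_zero_at_beta_zero_interior(self):
        s = example_scenario(beta=0.0)
        assert individual_welfare(s) == 0.0

    def test_bonus_value(self):
        s = example_scenario(bonus=0.1, detection_prob=0.5)
        assert individual_welfare(s) == pytest.approx(0.120756, abs=1e-12)
        assert individual_welfare_quadrature(s) == pytest.approx(0.120756, abs=1e-9)

    def test_upper_branch_formula(self):
        # threshold 0.216 + 0.4 >= c_max = 0.5: full adherence branch
        s = example_scenario(bonus=0.4)
        assert individual_welfare(s) == pytest.approx(-0.25 + 0.216 + 0.4, abs=1e-12)

    def test_pure_transfer_when_undetectable(self):
        # p_D = 0: nobody changes behavior, everyone pockets b
        base = example_scenario()
        s = example_scenario(bonus=0.2, detection_prob=0.0)
        assert individual_welfare(s) == pytest.approx(
            individual_welfare(base) + 0.2, abs=1e-12
        )

    def test_continuous_in_beta_across_branch_boundary(self):
        # delta*dp*du = 0.27 > c_max = 0.2, so the kink sits at beta* = 0.2/0.27
        beta_star = 0.2 / 0.27
        eps = 1e-8
        lo = individual_welfare(example_scenario(beta=beta_star - eps, c_max=0.2))
        hi = individual_welfare(example_scenario(beta=beta_star + eps, c_max=0.2))
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_monotone_increasing_in_beta(self):
        betas = np.linspace(0.05, 1.0, 20)
        values = [individual_welfare(example_scenario(beta=b)) for b in betas]
        assert np.all(np.diff(values) > 0)


class TestSocietalWelfare:
    def test_reference_value(self, s0):
        assert societal_welfare(s0) == pytest.approx(0.08936, abs=1e-12)

    def test_transfer_exactly_offsets_prevention_gain(self):
        s = example_scenario(bonus=0.23)
        assert societal_welfare(s) == pytest.approx(-0.01, abs=1e-12)

    def test_no_prevention_benefit_reduces_to_cost_mix(self, s0):
        s = s0.model_copy(
            update={
                "societal_costs": s0.societal_costs.model_copy(
                    update={"followup_cost": 0.0}
                )
            }
        )
        f = adherence_probability(s, 1)
        expected = -(f * 0.05 + (1 - f) * 0.01)
        assert societal_welfare(s) == pytest.approx(expected, abs=1e-12)


class TestTotalWelfare:
    def test_reference_values(self, s0):
        assert total_welfare(s0) == pytest.approx(0.136016, abs=1e-12)
        s = example_scenario(bonus=0.23)
        assert total_welfare(s) == pytest.approx(0.188916, abs=1e-12)
        assert total_welfare_closed_quadratic(s) == pytest.approx(0.188916, abs=1e-12)

    def test_report_components_sum(self, s0):
        rep = welfare_report(s0)
        assert rep.total == pytest.approx(rep.individual + rep.societal, abs=1e-10)

    def test_closed_forms_match_quadrature_on_random_scenarios(self, rng):
        for _ in range(200):
            s = random_scenario(
                rng,
                interior=rng.random() < 0.7,
                bonus=rng.uniform(-0.1, 0.3),
                detection_prob=rng.uniform(0.0, 1.0),
                admin_share=rng.uniform(0.0, 0.5),
            )
            w_i = individual_welfare(s)
            w_s = societal_welfare(s)
            assert w_i == pytest.approx(individual_welfare_quadrature(s), abs=1e-9)
            assert w_s == pytest.approx(societal_welfare_quadrature(s), abs=1e-9)

    def test_sum_matches_closed_quadratic_on_random_scenarios(self, rng):
        count = 0
        while count < 50:
            s = random_scenario(rng, bonus=rng.uniform(0.0, 0.1))
            theta = adherence_threshold(s, 1)
            if theta >= s.cost_model.c_max:
                continue
            count += 1
            assert total_welfare(s) == pytest.approx(
                total_welfare_closed_quadratic(s), abs=1e-9
            )

    def test_transfer_neutrality_at_zero_overhead(self, rng):
        """With lambda = 0, W depends on b only through the adherence channel."""
        for _ in range(20):
            s = random_scenario(rng, bonus=rng.uniform(0.0, 0.1))
            m = s.future_benefit
            theta = adherence_threshold(s, 1)
            cm = s.cost_model
            f = adherence_probability(s, 1)
            costs = s.societal_costs
            net = (
                costs.cost_adherent
                - costs.cost_nonadherent
                - s.delta_p * s.preferences.delta * costs.followup_cost
            )
            # redistribution-free form of W (no payout terms at all)
            expected = (
                -cm.partial_mean(0.0, theta) + f * m - costs.cost_nonadherent - f * net
            )
            assert total_welfare(s) == pytest.approx(expected, abs=1e-10)

    def test_high_overhead_makes_bonus_harmful(self):
        base = total_welfare(example_scenario())
        costly = total_welfare(example_scenario(bonus=0.1, admin_share=10.0))
        assert costly < base


class TestBonusFeasibility:
    def test_reference_feasible(self, s0):
        assert bonus_feasibility(s0) is True

    def test_strict_at_bound(self, s0):
        bound = (0.9 * 0.3 * 1.0 - 0.04) / 0.216
        assert bonus_feasibility(example_scenario(admin_share=bound)) is False
        assert bonus_feasibility(example_scenario(admin_share=bound - 1e-9)) is True

    def test_no_followup_costs_never_feasible(self, s0):
        s = s0.model_copy(
            update={
                "societal_costs": s0.societal_costs.model_copy(
                    update={"followup_cost": 0.0}
                )
            }
        )
        assert bonus_feasibility(s) is False

    def test_beta_zero_guard(self):
        s = example_scenario(beta=0.0)
        assert bonus_feasibility(s) is True  # numerator 0.23 > 0


class TestOptimalBonus:
    def test_reference_closed_form(self, s0):
        sol = optimal_bonus(s0)
        assert sol.method == "closed_form"
        assert sol.bonus == pytest.approx(0.23, abs=1e-12)
        assert sol.welfare == pytest.approx(0.188916, abs=1e-12)
        assert sol.interior and sol.feasible

    def test_vanishing_numerator_gives_zero_bonus(self, s0):
        # C_F chosen so delta*dp*C_F = C_A - C_NA
        s = s0.model_copy(
            update={
                "societal_costs": s0.societal_costs.model_copy(
                    update={"followup_cost": 0.04 / 0.27}
                )
            }
        )
        assert optimal_bonus(s).bonus == pytest.approx(0.0, abs=1e-12)

    def test_overhead_shrinks_bonus(self):
        sol = optimal_bonus(example_scenario(admin_share=0.1))
        assert sol.bonus == pytest.approx((0.27 - 0.04 - 0.0216) / 1.2, abs=1e-12)

    def test_closed_form_agrees_with_numeric_grid(self, s0):
        sol = optimal_bonus(s0)
        grid = np.linspace(0.0, 0.5, 20001)
        values = [total_welfare(with_bonus(s0, b)) for b in grid]
        b0 = grid[int(np.argmax(values))]
        res = optimize.minimize_scalar(
            lambda b: -total_welfare(with_bonus(s0, b)),
            bounds=(b0 - 5e-5, b0 + 5e-5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert sol.bonus == pytest.approx(res.x, abs=1e-6)

    def test_maximizes_over_grid(self, rng):
        s = random_incentive_scenario(rng)
        sol = optimal_bonus(s)
        grid = np.linspace(0.0, s.cost_model.c_max, 1000)
        assert all(sol.welfare >= total_welfare(with_bonus(s, b)) - 1e-12 for b in grid)

    def test_partial_observability_uses_numeric_route(self, s0):
        sol = optimal_bonus(with_bonus(s0, 0.0, p_d=0.7))
        assert sol.method == "numeric"
        # numeric optimum must beat nearby bonuses
        for b in (sol.bonus * 0.9, sol.bonus * 1.1):
            assert sol.welfare >= total_welfare(with_bonus(s0, b, p_d=0.7)) - 1e-9

    def test_infeasible_scheme_warns_and_returns_zero(self, s0):
        s = s0.model_copy(
            update={
                "societal_costs": s0.societal_costs.model_copy(
                    update={"followup_cost": 0.0}
                )
            }
        )
        with pytest.warns(UserWarning, match="overhead"):
            sol = optimal_bonus(s)
        assert not sol.feasible
        assert sol.bonus == pytest.approx(0.0, abs=1e-6)


class TestCopayment:
    def test_zero_copay_no_deltas(self, s0):
        rep = copayment_report(s0, 0.0)
        assert rep.adherence_delta == rep.individual_delta == rep.total_delta == 0.0

    def test_reference_adherence_drop(self, s0):
        rep = copayment_report(s0, 0.05)
        assert rep.adherence_delta == pytest.approx(-0.1, abs=1e-12)

    def test_copay_always_reduces_adherence_and_individual_welfare(self, rng):
        for _ in range(50):
            s = random_scenario(rng, detection_prob=rng.uniform(0.0, 1.0))
            rep = copayment_report(s, rng.uniform(0.0, 1.0))
            assert rep.adherence_delta <= 1e-15
            assert rep.individual_delta <= 1e-12

    def test_huge_copay_drives_adherence_to_zero(self, s0):
        rep = copayment_report(s0, 10.0)
        assert rep.adherence_delta == pytest.approx(-0.432)

    def test_negative_copay_rejected(self, s0):
        with pytest.raises(ValueError, match="copay"):
            copayment_report(s0, -0.1)
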