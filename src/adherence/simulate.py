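"""Agent-based Monte Carlo validation of the closed-form model.

A synthetic population of contract acceptors lives through the three periods:
each agent draws a cost type, decides at t = 1 via the perspective-1
threshold rule, draws its t = 2 health state (Bernoulli with p_adherent or
p_nonadherent), and — if non-adherent — whether its improper bonus claim is
detected.  Per-agent net utilities and societal cost contributions are
accumulated relative to the contract-rejection baseline, so their population
means estimate the individual and societal welfare components.

By default the period-2 health payoff enters each agent's bookkeeping in
expectation (the health draw is still recorded), which removes the Bernoulli
noise of the final period from the welfare estimates without biasing them;
``realized_outcomes=True`` switches to fully realized period-2 payoffs.

Randomness uses one root seed spawned into independent child streams for
costs, health transitions and detection, so enabling detection draws never
perturbs the cost draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Scenario, adherence_probability, adherence_threshold
from .welfare import individual_welfare, societal_welfare

__all__ = ["SimulationResult", "McComparison", "simulate_population", "mc_vs_analytic"]


@dataclass
class SimulationResult:
    """Synthetic-population outcome: per-agent records and welfare estimates."""

    n: int
    seed: int
    agents: pd.DataFrame
    empirical_adherence: float
    empirical_individual_welfare: float
    empirical_societal_welfare: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def empirical_total_welfare(self) -> float:
        return self.empirical_individual_welfare + self.empirical_societal_welfare

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "adherence": self.empirical_adherence,
            "individual_welfare": self.empirical_individual_welfare,
            "societal_welfare": self.empirical_societal_welfare,
            "total_welfare": self.empirical_total_welfare,
            "standard_errors": dict(self.standard_errors),
        }


def _sem(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(n))


def simulate_population(
    scenario: Scenario,
    n: int,
    seed: int,
    realized_outcomes: bool = False,
) -> SimulationResult:
    """Simulate ``n`` contract acceptors and estimate adherence and welfare.

    Bit-exactly reproducible for a given seed.  ``realized_outcomes`` makes
    the per-agent utilities and societal costs use the realized t = 2 health
    draw instead of its expectation (higher variance, same means).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = np.random.SeedSequence(seed)
    rng_costs, rng_health, rng_detect = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    prefs, therapy, inc = scenario.preferences, scenario.therapy, scenario.incentive
    util, costs_soc = scenario.utilities, scenario.societal_costs
    bd = prefs.beta * prefs.delta

    cost = scenario.cost_model.sample(n, rng_costs)
    adherent = cost <= adherence_threshold(scenario, 1)
    p_healthy = np.where(adherent, therapy.p_adherent, therapy.p_nonadherent)
    healthy_t2 = rng_health.random(n) < p_healthy
    # improper bonus claims by non-adherents; adherents are never "detected"
    detected = (rng_detect.random(n) < inc.detection_prob) & ~adherent

    # bonus receipt at t = 1 (negative bonus = co-payment, same semantics)
    payout = np.where(adherent, inc.bonus, np.where(detected, 0.0, inc.bonus))

    if realized_outcomes:
        u2 = np.where(healthy_t2, util.u_healthy, util.u_sick)
        # rejection baseline keeps the analytic expectation (counterfactual)
        u2_baseline = (
            therapy.p_nonadherent * util.u_healthy
            + (1.0 - therapy.p_nonadherent) * util.u_sick
        )
        health_gain = bd * (u2 - u2_baseline)
        followup = np.where(healthy_t2, 0.0, prefs.delta * costs_soc.followup_cost)
        followup_baseline = (1.0 - therapy.p_nonadherent) * prefs.delta * costs_soc.followup_cost
    else:
        health_gain = np.where(adherent, scenario.future_benefit, 0.0)
        followup = (1.0 - p_healthy) * prefs.delta * costs_soc.followup_cost
        followup_baseline = (1.0 - therapy.p_nonadherent) * prefs.delta * costs_soc.followup_cost

    utility = payout - np.where(adherent, cost, 0.0) + health_gain
    # a contract rejector incurs no period-1 treatment cost, only the
    # non-adherent follow-up risk — the baseline cancels in the follow-up term
    treatment_cost = np.where(adherent, costs_soc.cost_adherent, costs_soc.cost_nonadherent)
    societal = (
        -treatment_cost
        - (followup - followup_baseline)
        - (1.0 + inc.admin_share) * payout
    )

    agents = pd.DataFrame(
        {
            "cost": cost,
            "adherent": adherent,
            "healthy_t2": healthy_t2,
            "detected": detected,
            "utility": utility,
            "societal_cost": societal,
        }
    )
    return SimulationResult(
        n=n,
        seed=seed,
        agents=agents,
        empirical_adherence=float(adherent.mean()),
        empirical_individual_welfare=float(utility.mean()),
        empirical_societal_welfare=float(societal.mean()),
        standard_errors={
            "adherence": _sem(adherent.astype(float)),
            "individual_welfare": _sem(utility),
            "societal_welfare": _sem(societal),
        },
    )


@dataclass
class McComparison:
    """Monte Carlo estimates against closed-form values, with z-scores."""

    n: int
    seed: int
    rows: pd.DataFrame  # index: quantity; columns: analytic, estimate, se, z, passed

    @property
    def all_passed(self) -> bool:
        return bool(self.rows["passed"].all())


def mc_vs_analytic(
    scenario: Scenario,
    n: int,
    seed: int,
    z_limit: float = 3.0,
    realized_outcomes: bool = False,
) -> McComparison:
    """Compare simulated adherence and welfare with their closed forms.

    Each quantity passes when its simulation estimate lies within ``z_limit``
    standard errors of the analytic value.
    """
    if n < 1000:
        raise ValueError(f"n must be >= 1000 for a meaningful comparison, got {n}")
    sim = simulate_population(scenario, n, seed, realized_outcomes=realized_outcomes)
    analytic = {
        "adherence": adherence_probability(scenario, 1),
        "individual_welfare": individual_welfare(scenario),
        "societal_welfare": societal_welfare(scenario),
    }
    estimates = {
        "adherence": sim.empirical_adherence,
        "individual_welfare": sim.empirical_individual_welfare,
        "societal_welfare": sim.empirical_societal_welfare,
    }
    records = []
    for key, target in analytic.items():
        est = estimates[key]
        se = sim.standard_errors[key]
        if se > 0:
            z = (est - target) / se
        else:
            z = 0.0 if est == target else float("inf")
        records.append(
            {
                "quantity": key,
                "analytic": target,
                "estimate": est,
                "se": se,
                "z": z,
                "passed": abs(z) <= z_limit,
            }
        )
    rows = pd.DataFrame.from_records(records).set_index("quantity")
    return McComparison(n=n, seed=seed, rows=rows)
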