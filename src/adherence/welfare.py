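"""Individual, societal and total welfare, and financial-incentive design.

Welfare is measured from the perspective of period t = 1 as the expected net
benefit of the treatment contract over rejecting it (a rejector's payoff is
the non-adherent path with no bonus claim).  The individual component is

    W_I = -int_0^theta c f(c) dc + F(theta) * theta + (1 - p_D) * b,

with theta = beta*delta*delta_p*delta_u + p_D*b the perspective-1 adherence
threshold.  The societal component nets the period-1 therapy expenses, the
discounted period-2 follow-up costs averted by adherence, and the bonus
payout with its administrative overhead lambda:

    W_S = -C_NA - F * (C_A - C_NA - delta_p*delta*C_F)
          - [F + (1 - F)(1 - p_D)] * (1 + lambda) * b.

Total welfare W = W_I + W_S.  The bonus itself is a pure transfer; only the
adherence response and the overhead lambda move W, which under uniform costs
and full observability (p_D = 1) is a concave quadratic in b whose maximizer
is the closed-form optimal bonus

    b* = [delta*delta_p*C_F - (C_A - C_NA) - beta*delta*delta_p*delta_u*lambda]
         / (1 + 2*lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .core import (
    Scenario,
    SocietalCostParams,
    adherence_probability,
    adherence_threshold,
    _uniform_or_none,
)

__all__ = [
    "SocietalCostParams",
    "WelfareReport",
    "BonusSolution",
    "CopaymentReport",
    "expected_cost_given_adherent",
    "individual_welfare",
    "individual_welfare_quadrature",
    "societal_welfare",
    "total_welfare",
    "total_welfare_closed_quadratic",
    "welfare_report",
    "bonus_feasibility",
    "optimal_bonus",
    "copayment_report",
]


@dataclass(frozen=True)
class WelfareReport:
    """All welfare components of a scenario (total = individual + societal)."""

    individual: float
    societal: float
    total: float
    adherence_prob: float
    expected_cost_adherent: float


@dataclass(frozen=True)
class BonusSolution:
    """Result of the optimal-bonus problem.

    ``feasible`` is the overhead condition under which a bonus can raise total
    welfare at all; ``interior`` reports whether adherence at ``bonus`` stays
    strictly below 1 (the closed form presumes it); ``method`` is
    ``"closed_form"`` or ``"numeric"``.
    """

    bonus: float
    welfare: float
    feasible: bool
    interior: bool
    method: str


@dataclass(frozen=True)
class CopaymentReport:
    """Changes caused by a co-payment (bonus = -copay) relative to no incentive."""

    copay: float
    adherence_delta: float
    individual_delta: float
    societal_delta: float
    total_delta: float


def expected_cost_given_adherent(scenario: Scenario) -> float:
    """Mean cost type among adherents, E[c | c <= threshold]; 0 if nobody adheres."""
    theta = adherence_threshold(scenario, 1)
    prob = adherence_probability(scenario, 1)
    if prob <= 0.0:
        return 0.0
    return scenario.cost_model.partial_mean(0.0, theta) / prob


def individual_welfare(scenario: Scenario) -> float:
    """Expected net utility of the contract for a representative individual.

    Uniform cost models use the piecewise closed form; any other cost model
    evaluates the integral definition through its ``partial_mean`` contract.
    """
    theta = adherence_threshold(scenario, 1)
    inc = scenario.incentive
    receipt = (1.0 - inc.detection_prob) * inc.bonus
    uniform = _uniform_or_none(scenario)
    if uniform is not None:
        if theta < uniform.c_max:
            return max(theta, 0.0) ** 2 / (2.0 * uniform.c_max) + receipt
        return -uniform.c_max / 2.0 + scenario.future_benefit + inc.bonus
    cm = scenario.cost_model
    prob = adherence_probability(scenario, 1)
    return -cm.partial_mean(0.0, theta) + prob * theta + receipt


def individual_welfare_quadrature(scenario: Scenario) -> float:
    """Independent evaluation of W_I by adaptive quadrature of c * pdf(c).

    Bypasses any closed-form ``partial_mean``; used to cross-check the
    analytic branch of :func:`individual_welfare`.
    """
    theta = adherence_threshold(scenario, 1)
    inc = scenario.incentive
    receipt = (1.0 - inc.detection_prob) * inc.bonus
    cm = scenario.cost_model
    if theta <= 0.0:
        return receipt
    upper = min(theta, cm._quad_upper())
    integral, _ = integrate.quad(
        lambda c: c * cm.pdf(c), 0.0, upper, epsabs=1e-12, limit=200
    )
    prob = min(max(cm.cdf(theta), 0.0), 1.0)
    return -integral + prob * theta + receipt


def societal_welfare(scenario: Scenario) -> float:
    """Monetary welfare of society: therapy costs, averted follow-up costs, payouts.

    Society discounts with delta only (no present bias enters its accounting);
    at bonus = 0 the payout term vanishes and the plain no-incentive form is
    recovered exactly.
    """
    prefs, inc, costs = scenario.preferences, scenario.incentive, scenario.societal_costs
    prob = adherence_probability(scenario, 1)
    net_treatment = (
        costs.cost_adherent
        - costs.cost_nonadherent
        - scenario.delta_p * prefs.delta * costs.followup_cost
    )
    payout_share = prob + (1.0 - prob) * (1.0 - inc.detection_prob)
    return (
        -costs.cost_nonadherent
        - prob * net_treatment
        - payout_share * (1.0 + inc.admin_share) * inc.bonus
    )


def total_welfare(scenario: Scenario) -> float:
    """Joint welfare W = W_I + W_S."""
    return individual_welfare(scenario) + societal_welfare(scenario)


def total_welfare_closed_quadratic(scenario: Scenario) -> float:
    """Closed quadratic-in-b form of total welfare.

    Valid for uniform costs, full observability (detection_prob = 1) and an
    interior threshold (theta < c_max); raises ``ValueError`` outside that
    domain.  Serves as a second, independent route to W for validation.
    """
    uniform = _uniform_or_none(scenario)
    inc = scenario.incentive
    if uniform is None:
        raise ValueError("closed quadratic requires a uniform cost model")
    if inc.detection_prob != 1.0:
        raise ValueError("closed quadratic requires detection_prob = 1")
    m = scenario.future_benefit
    b = inc.bonus
    if not m + b < uniform.c_max:
        raise ValueError("closed quadratic requires an interior threshold")
    costs = scenario.societal_costs
    k = (
        costs.cost_adherent
        - costs.cost_nonadherent
        - scenario.delta_p * scenario.preferences.delta * costs.followup_cost
    )
    lam = inc.admin_share
    return (
        (m * m - 2.0 * m * k - 2.0 * (k + m * lam) * b - (1.0 + 2.0 * lam) * b * b)
        / (2.0 * uniform.c_max)
        - costs.cost_nonadherent
    )


def welfare_report(scenario: Scenario) -> WelfareReport:
    """Evaluate all welfare components of a scenario."""
    w_i = individual_welfare(scenario)
    w_s = societal_welfare(scenario)
    return WelfareReport(
        individual=w_i,
        societal=w_s,
        total=w_i + w_s,
        adherence_prob=adherence_probability(scenario, 1),
        expected_cost_adherent=expected_cost_given_adherent(scenario),
    )


def bonus_feasibility(scenario: Scenario) -> bool:
    """Whether the administrative overhead is low enough for a bonus to pay off.

    True iff ``admin_share < [delta*delta_p*C_F - (C_A - C_NA)] /
    (beta*delta*delta_p*delta_u)`` (strict).  When the denominator vanishes
    (beta = 0) the condition reduces to the numerator being positive.
    """
    prefs, costs = scenario.preferences, scenario.societal_costs
    numerator = prefs.delta * scenario.delta_p * costs.followup_cost - (
        costs.cost_adherent - costs.cost_nonadherent
    )
    denominator = scenario.future_benefit
    if denominator == 0.0:
        return numerator > 0.0
    return scenario.incentive.admin_share < numerator / denominator


def _with_bonus(scenario: Scenario, bonus: float) -> Scenario:
    inc = scenario.incentive.model_copy(update={"bonus": float(bonus)})
    return scenario.model_copy(update={"incentive": inc})


def _closed_form_bonus(scenario: Scenario) -> float:
    prefs, costs = scenario.preferences, scenario.societal_costs
    lam = scenario.incentive.admin_share
    numerator = (
        prefs.delta * scenario.delta_p * costs.followup_cost
        - (costs.cost_adherent - costs.cost_nonadherent)
        - scenario.future_benefit * lam
    )
    return numerator / (1.0 + 2.0 * lam)


_GRID_POINTS = 10_000


def optimal_bonus(scenario: Scenario) -> BonusSolution:
    """Bonus maximizing total welfare W(b) over b >= 0.

    Under full observability (detection_prob = 1), uniform costs and an
    interior solution the first-order condition gives the closed form
    ``b* = [delta*delta_p*C_F - (C_A - C_NA) - beta*delta*delta_p*delta_u*lambda]
    / (1 + 2*lambda)``; otherwise W is maximized numerically on a coarse grid
    followed by bounded scalar refinement (tolerance 1e-8).  The search upper
    bound is the bonus driving full adherence plus one support width, beyond
    which W is non-increasing.  Boundary solutions are reported with
    ``interior=False``.  If the overhead condition fails a warning is issued
    and the (typically zero) maximizer is still returned.
    """
    feasible = bonus_feasibility(scenario)
    if not feasible:
        warnings.warn(
            "administrative overhead too high for a bonus to raise total welfare "
            "(feasibility condition fails); the maximizer is typically b = 0",
            stacklevel=2,
        )
    uniform = _uniform_or_none(scenario)
    inc = scenario.incentive

    if uniform is not None and inc.detection_prob == 1.0:
        b_star = _closed_form_bonus(scenario)
        if b_star >= 0.0 and scenario.future_benefit + b_star < uniform.c_max:
            sol = _with_bonus(scenario, b_star)
            return BonusSolution(
                bonus=b_star,
                welfare=total_welfare(sol),
                feasible=feasible,
                interior=True,
                method="closed_form",
            )

    # numeric fallback: coarse grid then bounded refinement
    support = scenario.cost_model._quad_upper()
    if inc.detection_prob > 0.0:
        b_full = max((support - scenario.future_benefit) / inc.detection_prob, 0.0)
    else:
        b_full = 0.0
    b_upper = b_full + support
    grid = np.linspace(0.0, b_upper, _GRID_POINTS)
    values = np.array([total_welfare(_with_bonus(scenario, b)) for b in grid])
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda b: -total_welfare(_with_bonus(scenario, b)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [(float(res.x), -float(res.fun)), (float(grid[i]), float(values[i]))]
        b_best, w_best = max(candidates, key=lambda t: t[1])
    else:  # pragma: no cover - degenerate one-point bracket
        b_best, w_best = float(grid[i]), float(values[i])
    theta = scenario.future_benefit + inc.detection_prob * b_best
    interior = scenario.cost_model.cdf(theta) < 1.0
    return BonusSolution(
        bonus=b_best,
        welfare=w_best,
        feasible=feasible,
        interior=interior,
        method="numeric",
    )


def copayment_report(scenario: Scenario, copay: float) -> CopaymentReport:
    """Effect of an out-of-pocket co-payment, modeled as a negative bonus.

    Evaluates the scenario at bonus = -copay against bonus = 0.  Adherence and
    individual welfare can only fall (their deltas are <= 0).
    """
    if copay < 0:
        raise ValueError(f"copay must be >= 0, got {copay}")
    base = _with_bonus(scenario, 0.0)
    charged = _with_bonus(scenario, -copay)
    base_rep, charged_rep = welfare_report(base), welfare_report(charged)
    return CopaymentReport(
        copay=copay,
        adherence_delta=charged_rep.adherence_prob - base_rep.adherence_prob,
        individual_delta=charged_rep.individual - base_rep.individual,
        societal_delta=charged_rep.societal - base_rep.societal,
        total_delta=charged_rep.total - base_rep.total,
    )
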