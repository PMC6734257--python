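"""Domain types and the individual's adherence decision.

Three periods t = 0, 1, 2.  At t = 0 an asymptomatic individual accepts a
treatment contract and learns their cost type c.  At t = 1, still healthy,
they choose adherence (bearing c, possibly earning a bonus b) or
non-adherence.  At t = 2 they stay healthy with probability p_A (adherent)
or p_NA < p_A (non-adherent).  Future periods are discounted
quasi-hyperbolically with weights 1, beta*delta, beta*delta**2: beta < 1 puts
an extra premium on the present and makes preferences time-inconsistent.

The decision at t = 1 can be evaluated from two perspectives:

* perspective 0 — the plan made at contract time (t = 0), where both the
  cost and the health payoff lie in the future and are discounted by
  beta*delta and beta*delta**2;
* perspective 1 — the actual choice at t = 1, where the cost is immediate
  and only the health payoff is discounted (by beta*delta).

Comparing adherent and non-adherent intertemporal utilities reduces each
perspective to a cost threshold; the population adherence probability is the
cost CDF at that threshold, and the gap between the two perspectives'
probabilities quantifies the self-control problem.
"""

from __future__ import annotations

import enum
from typing import Literal

from pydantic import BaseModel, ConfigDict, model_validator

from .costs import CostModel, UniformCostModel

__all__ = [
    "HealthState",
    "HealthUtilities",
    "Preferences",
    "Therapy",
    "IncentiveScheme",
    "SocietalCostParams",
    "Scenario",
    "Perspective",
    "expected_stage2_utility",
    "intertemporal_utility",
    "adherence_threshold",
    "adherence_probability",
    "self_control_gap",
    "decide",
]

Perspective = Literal[0, 1]


class HealthState(enum.Enum):
    """The two clinical states: asymptomatic ('healthy') and symptomatic ('sick')."""

    HEALTHY = "healthy"
    SICK = "sick"


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid", arbitrary_types_allowed=True)


class HealthUtilities(_Frozen):
    """Instantaneous utilities of the two health states; u_healthy > u_sick."""

    u_healthy: float
    u_sick: float

    @model_validator(mode="after")
    def _check(self) -> "HealthUtilities":
        if not self.u_healthy > self.u_sick:
            raise ValueError(
                f"u_healthy must exceed u_sick (delta_u > 0); "
                f"got u_healthy={self.u_healthy}, u_sick={self.u_sick}"
            )
        return self

    @property
    def delta_u(self) -> float:
        return self.u_healthy - self.u_sick

    def of(self, state: HealthState) -> float:
        return self.u_healthy if state is HealthState.HEALTHY else self.u_sick


class Preferences(_Frozen):
    """Quasi-hyperbolic discounting parameters.

    ``delta`` is the per-period exponential discount factor; ``beta`` down-
    weights every non-current period uniformly (present bias).  beta = 1
    recovers exponential discounting.  beta = 0 is admitted as a limiting
    value used in welfare analysis.
    """

    beta: float
    delta: float

    @model_validator(mode="after")
    def _check(self) -> "Preferences":
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must lie in (0, 1], got {self.delta}")
        return self


class Therapy(_Frozen):
    """Transition probabilities to 'healthy' at t = 2; p_nonadherent < p_adherent."""

    p_adherent: float
    p_nonadherent: float

    @model_validator(mode="after")
    def _check(self) -> "Therapy":
        if not 0.0 <= self.p_nonadherent < self.p_adherent <= 1.0:
            raise ValueError(
                "transition probabilities must satisfy "
                f"0 <= p_nonadherent < p_adherent <= 1 (delta_p > 0); got "
                f"p_adherent={self.p_adherent}, p_nonadherent={self.p_nonadherent}"
            )
        return self

    @property
    def delta_p(self) -> float:
        return self.p_adherent - self.p_nonadherent


class IncentiveScheme(_Frozen):
    """Financial incentive for adherence.

    ``bonus`` is paid to adherent individuals; non-adherent individuals claim
    it improperly and keep it unless the abuse is detected, which happens
    with probability ``detection_prob``.  A negative bonus represents a
    co-payment with the same detection semantics.  ``admin_share`` is the
    administrative overhead of the scheme as a fraction of each bonus paid.
    """

    bonus: float = 0.0
    detection_prob: float = 1.0
    admin_share: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "IncentiveScheme":
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError(
                f"detection_prob must lie in [0, 1], got {self.detection_prob}"
            )
        if self.admin_share < 0.0:
            raise ValueError(f"admin_share must be >= 0, got {self.admin_share}")
        return self


class SocietalCostParams(_Frozen):
    """Monetary costs borne by society.

    ``cost_adherent`` / ``cost_nonadherent`` are the period-1 therapy expenses
    under adherence and non-adherence (the former is larger); ``followup_cost``
    is the period-2 cost of a case of illness (medical plus productivity loss).
    """

    cost_adherent: float
    cost_nonadherent: float
    followup_cost: float

    @model_validator(mode="after")
    def _check(self) -> "SocietalCostParams":
        if self.cost_adherent < 0 or self.cost_nonadherent < 0 or self.followup_cost < 0:
            raise ValueError("societal costs must be non-negative")
        if not self.cost_nonadherent < self.cost_adherent:
            raise ValueError(
                "cost_nonadherent must be strictly below cost_adherent; got "
                f"cost_adherent={self.cost_adherent}, "
                f"cost_nonadherent={self.cost_nonadherent}"
            )
        return self


class Scenario(_Frozen):
    """Bundle of all model parameters; the single input to every operation.

    With the default ``IncentiveScheme`` (bonus = 0) the plain no-incentive
    model is recovered exactly.
    """

    preferences: Preferences
    therapy: Therapy
    utilities: HealthUtilities
    cost_model: CostModel
    societal_costs: SocietalCostParams
    incentive: IncentiveScheme = IncentiveScheme()

    # -- frequently used compounds -------------------------------------
    @property
    def delta_p(self) -> float:
        return self.therapy.delta_p

    @property
    def delta_u(self) -> float:
        return self.utilities.delta_u

    @property
    def future_benefit(self) -> float:
        """beta * delta * delta_p * delta_u — the discounted health gain from adherence at t=1."""
        p = self.preferences
        return p.beta * p.delta * self.delta_p * self.delta_u


def expected_stage2_utility(
    therapy: Therapy, utilities: HealthUtilities, adherent: bool
) -> float:
    """Expected instantaneous utility at t = 2 given the t = 1 choice.

    ``p * u_healthy + (1 - p) * u_sick`` with ``p = p_adherent`` if adherent
    else ``p_nonadherent``.
    """
    p = therapy.p_adherent if adherent else therapy.p_nonadherent
    return p * utilities.u_healthy + (1.0 - p) * utilities.u_sick


def _check_perspective(perspective: int) -> None:
    if perspective not in (0, 1):
        raise ValueError(f"perspective must be 0 or 1, got {perspective!r}")


def intertemporal_utility(
    scenario: Scenario,
    perspective: Perspective,
    adherent: bool,
    cost: float = 0.0,
) -> float:
    """Discounted utility of the t = 1 choice, from the chosen vantage point.

    Adherents bear ``cost - bonus`` at t = 1; non-adherents collect the bonus
    undetected with probability ``1 - detection_prob``, for an expected
    period-1 payoff of ``(1 - detection_prob) * bonus``.  From perspective 0
    the period-1 and period-2 terms carry weights beta*delta and
    beta*delta**2; from perspective 1 the period-1 term is undiscounted and
    period 2 carries beta*delta.
    """
    _check_perspective(perspective)
    if adherent and cost < 0:
        raise ValueError(f"cost must be >= 0, got {cost}")
    prefs, inc = scenario.preferences, scenario.incentive
    u1_health = scenario.utilities.u_healthy
    u2 = expected_stage2_utility(scenario.therapy, scenario.utilities, adherent)
    if adherent:
        money = -(cost - inc.bonus)
    else:
        money = (1.0 - inc.detection_prob) * inc.bonus
    if perspective == 1:
        return money + u1_health + prefs.beta * prefs.delta * u2
    bd = prefs.beta * prefs.delta
    return bd * money + bd * u1_health + bd * prefs.delta * u2


def adherence_threshold(scenario: Scenario, perspective: Perspective) -> float:
    """Largest cost type still choosing adherence.

    Perspective 0: ``delta * delta_p * delta_u + detection_prob * bonus``;
    perspective 1 multiplies the health term by beta.  Equals the cost at
    which the adherent and non-adherent intertemporal utilities coincide.
    May be negative (large co-payment) or exceed the cost support; the CDF
    clamps downstream.
    """
    _check_perspective(perspective)
    prefs, inc = scenario.preferences, scenario.incentive
    if perspective == 1:
        health_term = scenario.future_benefit
    else:
        health_term = prefs.delta * scenario.delta_p * scenario.delta_u
    return health_term + inc.detection_prob * inc.bonus


def adherence_probability(scenario: Scenario, perspective: Perspective) -> float:
    """Population share adhering, i.e. the cost CDF at the threshold, in [0, 1]."""
    threshold = adherence_threshold(scenario, perspective)
    return float(min(max(scenario.cost_model.cdf(threshold), 0.0), 1.0))


def self_control_gap(scenario: Scenario) -> float:
    """Planned minus actual adherence probability (perspective 0 minus 1).

    Non-negative; zero under time-consistent preferences (beta = 1) and
    strictly positive when beta < 1 and the cost density is positive between
    the two thresholds.
    """
    return adherence_probability(scenario, 0) - adherence_probability(scenario, 1)


def decide(cost: float, scenario: Scenario, perspective: Perspective) -> bool:
    """Adherence choice of a cost type: adhere iff cost <= threshold (ties adhere)."""
    if cost < 0:
        raise ValueError(f"cost must be >= 0, got {cost}")
    return cost <= adherence_threshold(scenario, perspective)


def _uniform_or_none(scenario: Scenario) -> UniformCostModel | None:
    cm = scenario.cost_model
    return cm if isinstance(cm, UniformCostModel) else None
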