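"""Ready-made and randomly drawn scenarios.

``example_scenario`` is the package's reference parameterisation, used
throughout the documentation and tests: a moderately present-biased patient
(beta = 0.8, delta = 0.9) offered a therapy that raises the probability of
staying healthy from 0.6 to 0.9, with cost types uniform on [0, 0.5] and
follow-up costs large relative to therapy expenses.  ``random_scenario``
draws valid scenarios for property-based and cross-validation suites.
"""

from __future__ import annotations

import numpy as np

from .core import (
    HealthUtilities,
    IncentiveScheme,
    Preferences,
    Scenario,
    SocietalCostParams,
    Therapy,
)
from .costs import UniformCostModel

__all__ = ["example_scenario", "random_scenario", "random_incentive_scenario"]


def example_scenario(
    beta: float = 0.8,
    delta: float = 0.9,
    bonus: float = 0.0,
    detection_prob: float = 1.0,
    admin_share: float = 0.0,
    c_max: float = 0.5,
) -> Scenario:
    """The reference scenario (overridable in its most-swept parameters)."""
    return Scenario(
        preferences=Preferences(beta=beta, delta=delta),
        therapy=Therapy(p_adherent=0.9, p_nonadherent=0.6),
        utilities=HealthUtilities(u_healthy=1.0, u_sick=0.0),
        cost_model=UniformCostModel(c_max),
        societal_costs=SocietalCostParams(
            cost_adherent=0.05, cost_nonadherent=0.01, followup_cost=1.0
        ),
        incentive=IncentiveScheme(
            bonus=bonus, detection_prob=detection_prob, admin_share=admin_share
        ),
    )


def random_scenario(
    rng: np.random.Generator,
    interior: bool = True,
    bonus: float = 0.0,
    detection_prob: float = 1.0,
    admin_share: float = 0.0,
) -> Scenario:
    """Draw a valid uniform-cost scenario.

    With ``interior=True`` the cost ceiling is placed above the perspective-0
    threshold, so adherence is incomplete from both perspectives and all
    closed forms sit on their quadratic branch.
    """
    beta = rng.uniform(0.2, 1.0)
    delta = rng.uniform(0.5, 1.0)
    u_sick = rng.uniform(0.0, 0.5)
    u_healthy = u_sick + rng.uniform(0.5, 1.5)
    p_na = rng.uniform(0.1, 0.6)
    p_a = p_na + rng.uniform(0.1, 0.95 - p_na)
    ddu = delta * (p_a - p_na) * (u_healthy - u_sick)
    theta0 = ddu + detection_prob * max(bonus, 0.0)
    if interior:
        c_max = theta0 * rng.uniform(1.1, 2.5)
    else:
        c_max = theta0 * rng.uniform(0.3, 2.5)
    c_na = rng.uniform(0.0, 0.05)
    c_a = c_na + rng.uniform(0.01, 0.1)
    c_f = rng.uniform(0.0, 3.0)
    return Scenario(
        preferences=Preferences(beta=beta, delta=delta),
        therapy=Therapy(p_adherent=p_a, p_nonadherent=p_na),
        utilities=HealthUtilities(u_healthy=u_healthy, u_sick=u_sick),
        cost_model=UniformCostModel(c_max),
        societal_costs=SocietalCostParams(
            cost_adherent=c_a, cost_nonadherent=c_na, followup_cost=c_f
        ),
        incentive=IncentiveScheme(
            bonus=bonus, detection_prob=detection_prob, admin_share=admin_share
        ),
    )


def random_incentive_scenario(rng: np.random.Generator) -> Scenario:
    """Draw a scenario whose optimal bonus is feasible, positive and interior.

    Follow-up costs are drawn high enough that a bonus raises welfare even
    with the drawn administrative overhead, and the cost ceiling is placed
    above the threshold reached at the closed-form optimum, keeping the
    first-order condition on its interior branch.
    """
    base = random_scenario(rng, interior=True)
    prefs, therapy, util = base.preferences, base.therapy, base.utilities
    m = base.future_benefit
    c_a = base.societal_costs.cost_adherent
    c_na = base.societal_costs.cost_nonadherent
    ddp = prefs.delta * therapy.delta_p
    # feasibility bound on admin_share: lambda < (ddp*C_F - (C_A-C_NA)) / m
    c_f = (c_a - c_na) / ddp * rng.uniform(1.5, 4.0)
    lam_max = (ddp * c_f - (c_a - c_na)) / m
    lam = rng.uniform(0.0, 0.8 * lam_max)
    b_star = (ddp * c_f - (c_a - c_na) - m * lam) / (1.0 + 2.0 * lam)
    c_max = max(
        prefs.delta * therapy.delta_p * util.delta_u, m + b_star
    ) * rng.uniform(1.1, 2.0)
    return base.model_copy(
        update={
            "cost_model": UniformCostModel(c_max),
            "societal_costs": SocietalCostParams(
                cost_adherent=c_a, cost_nonadherent=c_na, followup_cost=c_f
            ),
            "incentive": IncentiveScheme(bonus=0.0, detection_prob=1.0, admin_share=lam),
        }
    )
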