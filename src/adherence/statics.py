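"""Comparative statics: analytic derivatives and parameter sweeps.

The two derivatives the model delivers in closed form are the marginal
effect of the bonus on adherence, ``dF/db = f(theta) * p_D`` with theta the
perspective-1 threshold, and the sensitivity of societal welfare to present
bias in the no-incentive model,

    dW_S/dbeta = -f(beta*delta*delta_p*delta_u) * delta*delta_p*delta_u
                 * (C_A - C_NA - delta_p*delta*C_F),

which is positive exactly when the averted follow-up costs outweigh the
extra treatment expense.  Both are verifiable against central finite
differences; ``sweep`` tabulates adherence, the self-control gap and all
welfare components along a parameter grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Scenario,
    adherence_probability,
    adherence_threshold,
    self_control_gap,
)
from .costs import UniformCostModel
from .welfare import individual_welfare, societal_welfare, total_welfare

__all__ = [
    "SweepTable",
    "marginal_adherence_wrt_bonus",
    "societal_welfare_beta_derivative",
    "fd_adherence_wrt_bonus",
    "fd_societal_welfare_wrt_beta",
    "sweep",
    "SWEEPABLE_PARAMETERS",
]

_FD_STEP = 1e-6


def marginal_adherence_wrt_bonus(scenario: Scenario) -> float:
    """dF/db = f(theta) * detection_prob: the bonus raises adherence through the CDF.

    Zero when detection_prob = 0 (the bonus is then collected by everyone and
    moves no decision).  Raises ``ValueError`` when the threshold sits at a
    support boundary, where F is not differentiable.
    """
    inc = scenario.incentive
    if inc.detection_prob == 0.0:
        return 0.0
    theta = adherence_threshold(scenario, 1)
    cm = scenario.cost_model
    prob = cm.cdf(theta)
    if prob <= 0.0 or prob >= 1.0:
        raise ValueError(
            "adherence threshold lies at or beyond a support boundary; "
            "F is not differentiable there"
        )
    return cm.pdf(theta) * inc.detection_prob


def societal_welfare_beta_derivative(scenario: Scenario) -> float:
    """dW_S/dbeta in the no-incentive model (bonus must be 0).

    Positive iff ``C_A - C_NA - delta_p*delta*C_F < 0`` and the density at the
    threshold is positive; returns 0 when the threshold lies beyond the
    support (full adherence, no margin to move).
    """
    if scenario.incentive.bonus != 0.0:
        raise ValueError("closed-form dW_S/dbeta applies to the no-incentive model only")
    prefs, costs = scenario.preferences, scenario.societal_costs
    ddu = prefs.delta * scenario.delta_p * scenario.delta_u
    theta = prefs.beta * ddu
    cm = scenario.cost_model
    if cm.cdf(theta) >= 1.0:
        return 0.0
    net = (
        costs.cost_adherent
        - costs.cost_nonadherent
        - scenario.delta_p * prefs.delta * costs.followup_cost
    )
    return -cm.pdf(theta) * ddu * net


def _central_or_one_sided(fun, x: float, lo: float, hi: float, step: float) -> float:
    """Central difference, falling back to one-sided at domain boundaries."""
    if x - step >= lo and x + step <= hi:
        return (fun(x + step) - fun(x - step)) / (2.0 * step)
    if x + step <= hi:
        return (fun(x + step) - fun(x)) / step
    return (fun(x) - fun(x - step)) / step


def fd_adherence_wrt_bonus(scenario: Scenario, step: float = _FD_STEP) -> float:
    """Finite-difference check of the bonus-adherence derivative."""

    def prob_at(b: float) -> float:
        inc = scenario.incentive.model_copy(update={"bonus": b})
        return adherence_probability(scenario.model_copy(update={"incentive": inc}), 1)

    b = scenario.incentive.bonus
    return _central_or_one_sided(prob_at, b, -np.inf, np.inf, step)


def fd_societal_welfare_wrt_beta(scenario: Scenario, step: float = _FD_STEP) -> float:
    """Finite-difference check of dW_S/dbeta (one-sided at beta = 0 or 1)."""

    def ws_at(beta: float) -> float:
        prefs = scenario.preferences.model_copy(update={"beta": beta})
        return societal_welfare(scenario.model_copy(update={"preferences": prefs}))

    return _central_or_one_sided(ws_at, scenario.preferences.beta, 0.0, 1.0, step)


# parameter name -> (component attribute on Scenario, field name)
_PARAM_PATHS: dict[str, tuple[str, str]] = {
    "beta": ("preferences", "beta"),
    "delta": ("preferences", "delta"),
    "bonus": ("incentive", "bonus"),
    "detection_prob": ("incentive", "detection_prob"),
    "admin_share": ("incentive", "admin_share"),
    "followup_cost": ("societal_costs", "followup_cost"),
}

SWEEPABLE_PARAMETERS = tuple(_PARAM_PATHS) + ("c_max",)


@dataclass
class SweepTable:
    """Model outputs along a one-parameter grid, with monotonicity flags."""

    parameter: str
    table: pd.DataFrame
    monotonicity: dict[str, str]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _set_parameter(scenario: Scenario, parameter: str, value: float) -> Scenario:
    if parameter == "c_max":
        if not isinstance(scenario.cost_model, UniformCostModel):
            raise ValueError("sweeping c_max requires a uniform cost model")
        return scenario.model_copy(update={"cost_model": UniformCostModel(value)})
    component, attr = _PARAM_PATHS[parameter]
    old = getattr(scenario, component)
    # model_copy skips validation; rebuild so invalid grid points are caught
    block = type(old)(**{**old.model_dump(), attr: float(value)})
    return scenario.model_copy(update={component: block})


def _monotonicity(values: np.ndarray) -> str:
    diffs = np.diff(values)
    if np.all(diffs >= -1e-12):
        return "non-decreasing"
    if np.all(diffs <= 1e-12):
        return "non-increasing"
    return "none"


def sweep(scenario: Scenario, parameter: str, grid) -> SweepTable:
    """Evaluate adherence, self-control gap and welfare along a parameter grid.

    The grid must be strictly increasing and within the parameter's valid
    range; grid points violating a scenario invariant are skipped with a
    warning rather than aborting the sweep.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of {SWEEPABLE_PARAMETERS}"
        )
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    rows = []
    for value in grid:
        try:
            s = _set_parameter(scenario, parameter, float(value))
        except ValueError as exc:  # includes pydantic ValidationError
            warnings.warn(
                f"skipping {parameter}={value}: {exc}", stacklevel=2
            )
            continue
        rows.append(
            {
                parameter: float(value),
                "adherence_t0": adherence_probability(s, 0),
                "adherence_t1": adherence_probability(s, 1),
                "self_control_gap": self_control_gap(s),
                "individual_welfare": individual_welfare(s),
                "societal_welfare": societal_welfare(s),
                "total_welfare": total_welfare(s),
            }
        )
    if not rows:
        raise ValueError("no valid grid points for the sweep")
    table = pd.DataFrame.from_records(rows)
    mono = {
        col: _monotonicity(table[col].to_numpy())
        for col in table.columns
        if col != parameter
    }
    return SweepTable(parameter=parameter, table=table, monotonicity=mono)
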