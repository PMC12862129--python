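"""Optimal sickness-insurance replacement rates from utility parameters.

The sufficient-statistics condition equates the moral-hazard elasticity sum
(entry odds + spell duration responses to the benefit) with the
proportional gap in marginal utility between the sick and healthy states::

    eps = u'(c_s, 1)/u'(c_e, 0) - 1

Under the state-dependent HARA model the gap has the closed form
``((c_s - omega - theta)/(c_e - omega))**(-gamma) - 1`` and the condition
inverts exactly to an optimal replacement rate at each income level::

    RR = omega/y_e + theta/y_e + (1 - omega/y_e) * (1 + eps)**(-1/gamma)

Net income stands in for consumption throughout (the identity mapping;
see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DomainError, UtilityParams
from .utility import marginal_utility, relative_prudence, \
    relative_risk_aversion

__all__ = [
    "PolicyConfig",
    "mu_gap_exact",
    "mu_gap_approx",
    "optimal_replacement_rate",
    "policy_curve",
]


@dataclass
class PolicyConfig:
    """Behavioral inputs of the policy calculation: the elasticity sum
    (default 1.5), an ascending income grid (thousand EUR/yr) and the
    utility parameters."""

    params: UtilityParams
    elasticity_sum: float = 1.5
    income_grid: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 121.0, 1.0))

    def __post_init__(self) -> None:
        if self.elasticity_sum < 0:
            raise ValueError("elasticity_sum must be >= 0")
        self.income_grid = np.asarray(self.income_grid, dtype=float)
        if self.income_grid.size and np.any(np.diff(self.income_grid) <= 0):
            raise ValueError("income_grid must be strictly ascending")


def mu_gap_exact(ce, cs, params: UtilityParams):
    """Exact marginal-utility gap u'(c_s,1)/u'(c_e,0) - 1.

    Equals ((c_s - omega - theta)/(c_e - omega))**(-gamma) - 1; strictly
    increasing as sick-state consumption falls.
    """
    return (np.asarray(marginal_utility(cs, 1, params))
            / np.asarray(marginal_utility(ce, 0, params)) - 1.0)


def mu_gap_approx(ce, cs, params: UtilityParams):
    """Second-order (risk aversion + prudence) approximation of the gap:
    RRA(ce,0) * x * (1 + RP(ce,0) * x / 2) with x = (dc + theta)/ce."""
    ce = np.asarray(ce, dtype=float)
    x = (ce - np.asarray(cs, dtype=float) + params.theta) / ce
    rra = relative_risk_aversion(ce, 0, params)
    rp = relative_prudence(ce, 0, params)
    return rra * x * (1.0 + 0.5 * rp * x)


def optimal_replacement_rate(ye, elasticity_sum, params: UtilityParams):
    """Optimal replacement rate RR = ys/ye at healthy income ``ye``.

    Closed form omega/ye + theta/ye + (1 - omega/ye)*(1+eps)**(-1/gamma);
    by construction mu_gap_exact(ye, RR*ye) == eps exactly.  Raises if the
    implied sick income leaves the utility domain (ys <= omega + theta).
    """
    if elasticity_sum < 0:
        raise ValueError("elasticity_sum must be >= 0")
    ye = np.asarray(ye, dtype=float)
    if not params.in_domain(ye, 0):
        raise DomainError("healthy income outside the utility domain")
    shrink = (1.0 + elasticity_sum) ** (-1.0 / params.gamma)
    rr = (params.omega / ye + params.theta / ye
          + (1.0 - params.omega / ye) * shrink)
    ys = rr * ye
    if np.any(ys - params.omega - params.theta <= 0.0):
        raise DomainError(
            "implied sick income <= omega + theta; replacement rate "
            "infeasible at this income")
    return rr if rr.ndim else float(rr)


def policy_curve(config: PolicyConfig) -> pd.DataFrame:
    """Replacement-rate schedule over the income grid.

    One row per grid income with the optimal RR, the implied sick income,
    healthy/sick relative risk aversion, the exact and approximate
    marginal-utility gaps at the optimum, a theta = 0 counterfactual RR
    (the schedule absent the fixed cost of sickness) and a feasibility
    flag.  Infeasible points are recorded, not dropped.
    ``.attrs['rr_increasing']`` reports the monotonicity diagnostic.
    """
    p = config.params
    p0 = p.replace(theta=0.0)
    rows = []
    for ye in config.income_grid:
        row = {"income": float(ye)}
        try:
            rr = optimal_replacement_rate(ye, config.elasticity_sum, p)
            ys = rr * ye
            row.update(
                optimal_rr=rr, sick_income=ys,
                rra_healthy=float(relative_risk_aversion(ye, 0, p)),
                rra_sick=float(relative_risk_aversion(ye, 1, p)),
                mu_gap_exact=float(mu_gap_exact(ye, ys, p)),
                mu_gap_approx=float(mu_gap_approx(ye, ys, p)),
                feasible=True)
        except (DomainError, ValueError) as exc:
            row.update(optimal_rr=float("nan"), sick_income=float("nan"),
                       rra_healthy=float("nan"), rra_sick=float("nan"),
                       mu_gap_exact=float("nan"),
                       mu_gap_approx=float("nan"), feasible=False,
                       note=str(exc))
        try:
            row["optimal_rr_theta0"] = optimal_replacement_rate(
                ye, config.elasticity_sum, p0)
        except (DomainError, ValueError):
            row["optimal_rr_theta0"] = float("nan")
        rows.append(row)
    curve = pd.DataFrame(rows)
    rr = curve.loc[curve["feasible"] == True, "optimal_rr"]  # noqa: E712
    curve.attrs["rr_increasing"] = bool((np.diff(rr) > 0).all()) \
        if len(rr) > 1 else None
    return curve
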