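"""Parameter container for the state-dependent HARA utility model.

The model predicts life satisfaction (LS, a 0-10 cardinal score) from net
income ``y`` (thousand EUR/yr) and a sickness indicator ``S``::

    LS = alpha + beta/(1-gamma) * ((y - omega - theta*S)/gamma)**(1-gamma)
         + delta*S + tau'X

``omega`` shifts the utility curve horizontally in both states (the
"institutions" parameter: baseline protection available at low income),
``theta`` shifts it additionally in the sick state (the fixed cost of
sickness, in thousand EUR/yr), ``gamma`` is the curvature parameter the
relative risk aversion converges to at high income, and ``alpha``,
``delta`` locate the LS scale.  ``gamma == 1`` selects the logarithmic
branch ``alpha + beta*ln(y - omega - theta*S) + delta*S + tau'X``.

Scale convention: income is measured in thousand EUR/yr and ``beta`` is
stored on the *internal* scale.  Published tables print ``beta`` in
thousands; :meth:`UtilityParams.from_printed` / :meth:`to_printed`
convert (internal = printed x 1000).  Only this convention puts predicted
LS near 7 at the sample mean income.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

#: printed-scale beta ("thousands" in published tables) x this = internal beta
PRINTED_BETA_SCALE = 1000.0


class DomainError(ValueError):
    """Shifted income y - omega - theta*S fell outside the utility domain."""


@dataclass
class UtilityParams:
    """Parameters of the state-dependent HARA life-satisfaction model."""

    alpha: float
    beta: float
    gamma: float
    omega: float
    theta: float
    delta: float
    tau: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    # -- scale conversions -------------------------------------------------
    @classmethod
    def from_printed(cls, alpha, beta_printed, gamma, omega, theta, delta,
                     tau=()) -> "UtilityParams":
        """Build from table-style values (beta printed in thousands)."""
        return cls(alpha, beta_printed * PRINTED_BETA_SCALE, gamma, omega,
                   theta, delta, np.asarray(tau, dtype=float))

    def to_printed(self) -> dict:
        """Dict of printed-scale values (beta divided by 1000)."""
        d = self.to_dict()
        d["beta"] = self.beta / PRINTED_BETA_SCALE
        return d

    # -- domain ------------------------------------------------------------
    def shifted_income(self, y, sick):
        """y - omega - theta*S, the argument of the HARA kernel."""
        y = np.asarray(y, dtype=float)
        sick = np.asarray(sick, dtype=float)
        return y - self.omega - self.theta * sick

    def in_domain(self, y, sick) -> bool:
        return bool(np.all(self.shifted_income(y, sick) > 0.0))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "gamma": float(self.gamma),
            "omega": float(self.omega),
            "theta": float(self.theta),
            "delta": float(self.delta),
            "tau": [float(t) for t in self.tau],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityParams":
        return cls(d["alpha"], d["beta"], d["gamma"], d["omega"], d["theta"],
                   d["delta"], np.asarray(d.get("tau", ()), dtype=float))

    def save(self, path, printed_scale: bool = False) -> None:
        """Write parameters as YAML; flags the beta scale explicitly."""
        d = self.to_printed() if printed_scale else self.to_dict()
        d["beta_scale"] = "printed" if printed_scale else "internal"
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "UtilityParams":
        d = yaml.safe_load(Path(path).read_text())
        scale = d.pop("beta_scale", "internal")
        if scale == "printed":
            d["beta"] = d["beta"] * PRINTED_BETA_SCALE
        return cls.from_dict(d)

    def replace(self, **kw) -> "UtilityParams":
        return replace(self, **kw)


#: Main published estimate (internal scale): the generating vector used by
#: the synthetic-data defaults and the recovery experiments.
MAIN_SPEC_PARAMS = UtilityParams.from_printed(
    alpha=9.93, beta_printed=2.79, gamma=3.19, omega=-56.49, theta=4.86,
    delta=-0.21)

#: No-controls published estimate (internal scale).
NO_CONTROLS_PARAMS = UtilityParams.from_printed(
    alpha=7.75, beta_printed=2.10, gamma=3.09, omega=-57.95, theta=6.28,
    delta=-0.17)

#: Printed standard errors of the main specification, for recovery bands.
MAIN_SPEC_SE = {"alpha": 0.20, "beta": 14.21, "gamma": 1.39, "omega": 39.35,
                "theta": 1.31, "delta": 0.04}
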