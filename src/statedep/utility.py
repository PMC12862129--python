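"""State-dependent HARA utility: evaluation, derivatives, risk measures.

All functions are vectorized over income ``y`` and the sickness indicator
``sick`` and raise :class:`~statedep.params.DomainError` (never a silent
NaN) when the shifted income ``y - omega - theta*S`` is not strictly
positive.
"""

from __future__ import annotations

import numpy as np

from .params import DomainError, UtilityParams

__all__ = [
    "evaluate_utility",
    "log_branch_utility",
    "marginal_utility",
    "relative_risk_aversion",
    "relative_prudence",
]


def _shifted(y, sick, params: UtilityParams):
    w = params.shifted_income(y, sick)
    if not np.all(w > 0.0):
        bad = np.atleast_1d(np.asarray(w <= 0.0)).nonzero()[0]
        raise DomainError(
            f"y - omega - theta*S must be > 0; violated at index {bad[:5]}"
            f" (omega={params.omega}, theta={params.theta})")
    return w


def evaluate_utility(y, sick, params: UtilityParams, controls_effect=0.0):
    """Predicted life satisfaction at income ``y`` (thousand EUR/yr).

    Returns ``alpha + beta/(1-gamma) * ((y-omega-theta*S)/gamma)**(1-gamma)
    + delta*S + controls_effect``; ``gamma == 1`` exactly is routed to the
    logarithmic branch (the objective is non-smooth across that boundary,
    so the two branches are kept separate rather than taking limits).

    For ``gamma > 1`` the non-linear term is negative and vanishes as
    income grows, so utility is bounded above by
    ``alpha + delta*S + controls_effect``.
    """
    if params.gamma == 1.0:
        return log_branch_utility(y, sick, params, controls_effect)
    w = _shifted(y, sick, params)
    g = params.gamma
    sick = np.asarray(sick, dtype=float)
    kern = params.beta / (1.0 - g) * (w / g) ** (1.0 - g)
    return params.alpha + kern + params.delta * sick + controls_effect


def log_branch_utility(y, sick, params: UtilityParams, controls_effect=0.0):
    """Logarithmic branch (gamma = 1): alpha + beta*ln(y-omega-theta*S) + ...

    Its implied relative risk aversion is ``y / (y - omega - theta*S)``,
    the gamma = 1 case of the closed form used by
    :func:`relative_risk_aversion`.
    """
    w = _shifted(y, sick, params)
    sick = np.asarray(sick, dtype=float)
    return (params.alpha + params.beta * np.log(w)
            + params.delta * sick + controls_effect)


def marginal_utility(y, sick, params: UtilityParams):
    """du/dy in LS points per thousand EUR: (beta/gamma)*((y-w-thS)/gamma)**-gamma.

    The expression is continuous at gamma = 1, where it reduces to the
    log-branch derivative beta/(y - omega - theta*S).
    """
    w = _shifted(y, sick, params)
    g = params.gamma
    return (params.beta / g) * (w / g) ** (-g)


def relative_risk_aversion(y, sick, params: UtilityParams):
    """RRA(y, S) = -y u''/u' = gamma * y / (y - omega - theta*S).

    Independent of alpha, beta, delta.  With omega + theta*S < 0 the RRA
    rises with income and converges to gamma from below; theta > 0 makes
    the sick-state RRA exceed the healthy-state RRA at every income.
    """
    w = _shifted(y, sick, params)
    return params.gamma * np.asarray(y, dtype=float) / w


def relative_prudence(y, sick, params: UtilityParams):
    """RP(y, S) = -y u'''/u'' = (gamma + 1) * y / (y - omega - theta*S)."""
    w = _shifted(y, sick, params)
    return (params.gamma + 1.0) * np.asarray(y, dtype=float) / w
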