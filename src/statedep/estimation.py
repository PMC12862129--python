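"""Weighted nonlinear least squares for the state-dependent HARA model.

The objective is sum_i w_i * (LS_i - model(y_i, S_i; params))^2, minimized
by a damped (Levenberg-Marquardt-type) least-squares loop with an analytic
Jacobian.  Trial steps whose parameters violate the utility domain for any
observation receive a finite penalty (10x the current objective) so the
damping can retreat and the search continue.  Multi-start fitting probes
the three curvature regimes (gamma below 1, 1-3.5, above 3.5) and the
logarithmic branch, and keeps the converged fit with the smallest SSE.

The model is linear in alpha, beta, delta, the control coefficients and
the year effects; only gamma, omega, theta enter nonlinearly.  No
individual fixed effects enter here - that comparison lives in
:mod:`statedep.comparison`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import UtilityParams
from .synthetic import CONTROL_COLUMNS, control_matrix

__all__ = [
    "FitResult",
    "IdentificationError",
    "DEFAULT_START",
    "default_regime_starts",
    "fit_utility_nls",
    "multi_start_fit",
    "standard_errors",
    "starting_value_sweep",
    "binarize_outcome",
]

#: published starting values {alpha=10, beta=0, gamma=2.7, omega=-15,
#: theta=15, delta=0}; controls and year effects start at zero.
DEFAULT_START = UtilityParams(alpha=10.0, beta=0.0, gamma=2.7, omega=-15.0,
                              theta=15.0, delta=0.0)

_PENALTY_FACTOR = 10.0
_BASE_NAMES = ["alpha", "beta", "gamma", "omega", "theta", "delta"]


class IdentificationError(ValueError):
    """The requested free parameters are not identified by the panel."""


#: curvature regions probed by the multi-start procedure; each regime's
#: search is confined to its region so the three fits can be compared
#: side by side even when the unconstrained objective drifts to a
#: boundary (gamma -> infinity degenerates toward exponential utility).
REGIME_BOUNDS = {
    "low": (1e-6, 1.0 - 1e-6),
    "mid": (1.0 + 1e-6, 3.5),
    "high": (3.5 + 1e-6, np.inf),
}


def _regime_of(gamma: float) -> str:
    if gamma == 1.0:
        return "log"
    if gamma < 1.0:
        return "low"
    return "mid" if gamma <= 3.5 else "high"


def default_regime_starts() -> list[UtilityParams]:
    """One start per curvature regime plus the log branch; the published
    default start (gamma = 2.7) represents the middle regime."""
    return [
        DEFAULT_START.replace(),                 # mid, 1 < gamma <= 3.5
        DEFAULT_START.replace(gamma=0.5),        # low, gamma < 1
        DEFAULT_START.replace(gamma=5.0),        # high, gamma > 3.5
        DEFAULT_START.replace(gamma=1.0),        # logarithmic branch
    ]


@dataclass
class FitResult:
    """Converged estimates plus diagnostics of one NLS fit."""

    params: UtilityParams                  # internal beta scale
    standard_errors: dict
    sse: float
    residual_se: float
    n: int
    converged: bool
    iterations: int
    start_values: UtilityParams
    regime: str
    year_effects: Optional[dict] = None
    n_penalized_steps: int = 0
    sse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    spec: dict = field(default_factory=dict)
    free_names: list = field(default_factory=list)
    free_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    covariance: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# model + Jacobian on a flat free-parameter vector
# ---------------------------------------------------------------------------

class _Design:
    """Flattened view of the problem: data arrays, free-parameter layout,
    model prediction and analytic Jacobian."""

    def __init__(self, panel: pd.DataFrame, use_controls: bool,
                 use_year_effects: bool, use_weights: bool,
                 fixed: dict, log_branch: bool, gamma_bounds=None):
        self.gamma_bounds = gamma_bounds
        self.y = panel["net_income"].to_numpy(dtype=float)
        self.S = panel["sick"].to_numpy(dtype=float)
        self.ls = panel["life_satisfaction"].to_numpy(dtype=float)
        w = panel["weight"].to_numpy(dtype=float) if use_weights else \
            np.ones(len(panel))
        self.w = w / w.mean()          # invariant to positive rescaling
        self.sqw = np.sqrt(self.w)
        self.log_branch = log_branch
        self.fixed = dict(fixed)
        if log_branch:
            self.fixed["gamma"] = 1.0

        self.X = control_matrix(panel) if use_controls else None
        self.control_names = ([f"tau_{c}" for c in CONTROL_COLUMNS]
                              if use_controls else [])
        if use_year_effects:
            years = np.sort(panel["year"].unique())
            self.year_levels = years[1:]        # first year is the base
            self.Z = (panel["year"].to_numpy()[:, None]
                      == self.year_levels[None, :]).astype(float)
            self.year_names = [f"year_{int(v)}" for v in self.year_levels]
        else:
            self.year_levels = np.empty(0, dtype=int)
            self.Z = None
            self.year_names = []

        self.free_names = [nm for nm in _BASE_NAMES if nm not in self.fixed]
        self.free_names += self.control_names + self.year_names
        self.n_base_free = len([nm for nm in _BASE_NAMES
                                if nm not in self.fixed])

    # -- vector <-> params -------------------------------------------------
    def pack(self, start: UtilityParams) -> np.ndarray:
        base = {nm: getattr(start, nm) for nm in _BASE_NAMES}
        x = [base[nm] for nm in _BASE_NAMES if nm not in self.fixed]
        if self.X is not None:
            tau = np.zeros(self.X.shape[1])
            tau[:min(start.tau.size, tau.size)] = \
                start.tau[:min(start.tau.size, tau.size)]
            x += list(tau)
        x += [0.0] * len(self.year_names)
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> dict:
        vals = dict(self.fixed)
        i = 0
        for nm in _BASE_NAMES:
            if nm not in vals:
                vals[nm] = x[i]
                i += 1
        vals["tau"] = (x[i:i + self.X.shape[1]] if self.X is not None
                       else np.empty(0))
        i += self.X.shape[1] if self.X is not None else 0
        vals["year"] = x[i:]
        return vals

    def to_params(self, x: np.ndarray) -> UtilityParams:
        v = self.unpack(x)
        return UtilityParams(v["alpha"], v["beta"], v["gamma"], v["omega"],
                             v["theta"], v["delta"], v["tau"])

    def project(self, x: np.ndarray) -> np.ndarray:
        """Clamp the free gamma component into the regime bounds."""
        if self.gamma_bounds is None or "gamma" in self.fixed:
            return x
        i = self.free_names.index("gamma")
        lo, hi = self.gamma_bounds
        if not lo <= x[i] <= hi:
            x = x.copy()
            x[i] = min(max(x[i], lo), hi)
        return x

    # -- model -------------------------------------------------------------
    def valid(self, x: np.ndarray) -> bool:
        v = self.unpack(x)
        g = v["gamma"]
        if g <= 0.0 or (not self.log_branch and abs(g - 1.0) < 1e-8):
            return False
        shifted = self.y - v["omega"] - v["theta"] * self.S
        return bool(np.all(shifted > 0.0))

    def predict(self, x: np.ndarray) -> np.ndarray:
        v = self.unpack(x)
        g = v["gamma"]
        shifted = self.y - v["omega"] - v["theta"] * self.S
        if self.log_branch:
            kern = v["beta"] * np.log(shifted)
        else:
            kern = v["beta"] / (1.0 - g) * (shifted / g) ** (1.0 - g)
        out = v["alpha"] + kern + v["delta"] * self.S
        if self.X is not None:
            out = out + self.X @ v["tau"]
        if self.Z is not None:
            out = out + self.Z @ v["year"]
        return out

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.sqw * (self.ls - self.predict(x))

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """d residual / d x (analytic); residual = sqrt(w)*(ls - model)."""
        v = self.unpack(x)
        g, b = v["gamma"], v["beta"]
        shifted = self.y - v["omega"] - v["theta"] * self.S
        cols = {}
        if self.log_branch:
            logw = np.log(shifted)
            cols["alpha"] = np.ones_like(shifted)
            cols["beta"] = logw
            cols["omega"] = -b / shifted
            cols["theta"] = -b * self.S / shifted
            cols["delta"] = self.S
        else:
            z = shifted / g
            t = z ** (1.0 - g)
            mu = (b / g) * z ** (-g)            # du/dy
            cols["alpha"] = np.ones_like(shifted)
            cols["beta"] = t / (1.0 - g)
            cols["gamma"] = (b / (1.0 - g) ** 2) * t \
                + (b / (1.0 - g)) * t * (-np.log(z) - (1.0 - g) / g)
            cols["omega"] = -mu
            cols["theta"] = -mu * self.S
            cols["delta"] = self.S
        J = [cols[nm] for nm in _BASE_NAMES if nm not in self.fixed]
        J = np.column_stack(J) if J else np.empty((shifted.size, 0))
        if self.X is not None:
            J = np.hstack([J, self.X])
        if self.Z is not None:
            J = np.hstack([J, self.Z])
        return -self.sqw[:, None] * J


# ---------------------------------------------------------------------------
# damped least squares
# ---------------------------------------------------------------------------

def _levenberg_marquardt(design: _Design, x0: np.ndarray,
                         max_iter: int = 1000, tol: float = 1e-10):
    """Marquardt-scaled damped least squares with finite penalties for
    domain-violating trial steps.  Returns (x, diagnostics)."""
    if not design.valid(x0):
        raise ValueError("starting values violate the utility domain")
    x = x0.copy()
    r = design.residuals(x)
    sse = float(r @ r)
    lam, nu = 1e-3, 2.0
    trace = [sse]
    n_pen = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = design.jacobian(x)
        A = J.T @ J
        gvec = J.T @ r
        d2 = np.maximum(np.diag(A), 1e-30)
        accepted = False
        for _ in range(50):                     # inner damping search
            M = A + lam * np.diag(d2)
            try:
                step = np.linalg.solve(M, -gvec)
            except np.linalg.LinAlgError:
                lam *= nu
                nu *= 2.0
                continue
            x_try = design.project(x + step)
            if design.valid(x_try):
                r_try = design.residuals(x_try)
                sse_try = float(r_try @ r_try)
            else:                                # finite penalty; retreat
                sse_try = _PENALTY_FACTOR * sse
                n_pen += 1
            if sse_try < sse:
                # Nielsen gain-ratio damping update
                step_taken = x_try - x
                pred = float(step_taken @ (lam * d2 * step_taken - gvec))
                rho = (sse - sse_try) / pred if pred > 0 else 1.0
                rel = (sse - sse_try) / max(sse, 1e-300)
                x, r, sse = x_try, r_try, sse_try
                trace.append(sse)
                lam = max(lam * max(1.0 / 3.0,
                                    1.0 - (2.0 * rho - 1.0) ** 3), 1e-14)
                nu = 2.0
                accepted = True
                if rel < tol or np.linalg.norm(step_taken) < tol:
                    converged = True
                break
            lam *= nu
            nu *= 2.0
            if lam > 1e15:
                break
        if converged:
            break
        if not accepted:                         # damping exhausted
            g_norm = float(np.linalg.norm(gvec, np.inf))
            converged = g_norm < 1e-6 * max(1.0, sse)
            break
    return x, {"sse": sse, "iterations": it, "converged": converged,
               "trace": np.asarray(trace), "n_penalized": n_pen}


def _covariance(design: _Design, x: np.ndarray, sse: float):
    """sigma^2 (J'WJ)^-1 with sigma^2 = SSE/(n-p); None if singular."""
    J = design.jacobian(x)
    n, p = J.shape
    if n <= p:
        return None, float("nan")
    sigma2 = sse / (n - p)
    A = J.T @ J
    d = np.sqrt(np.diag(A))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None, np.sqrt(sigma2)
    C = A / np.outer(d, d)                       # scale-free conditioning
    try:
        if np.linalg.cond(C) > 1e12:
            return None, np.sqrt(sigma2)
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        return None, np.sqrt(sigma2)
    Ainv = Cinv / np.outer(d, d)
    return sigma2 * Ainv, np.sqrt(sigma2)


def fit_utility_nls(panel: pd.DataFrame,
                    start: Optional[UtilityParams] = None,
                    use_controls: bool = True,
                    use_year_effects: bool = False,
                    weights: bool = True,
                    fixed: Optional[dict] = None,
                    log_branch: bool = False,
                    gamma_bounds: Optional[tuple] = None,
                    max_iter: int = 1000,
                    tol: float = 1e-10) -> FitResult:
    """Weighted NLS fit of the state-dependent HARA model to one panel.

    ``fixed`` maps parameter names (alpha..delta) to frozen values;
    ``log_branch=True`` estimates the gamma = 1 logarithmic branch;
    ``gamma_bounds`` confines the curvature search to one regime (trial
    gammas are clamped, so a fit may converge on the regime boundary).
    Non-convergence is reported via ``converged=False``, not an exception.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    start = DEFAULT_START if start is None else start
    fixed = dict(fixed or {})
    states = set(panel["sick"].unique())
    if len(states) < 2 and not {"theta", "delta"} <= set(fixed):
        raise IdentificationError(
            "panel contains a single sickness state; theta and delta are "
            "not identified (fix them to proceed)")

    design = _Design(panel, use_controls, use_year_effects, weights, fixed,
                     log_branch, gamma_bounds)
    x0 = design.pack(start)
    x, diag = _levenberg_marquardt(design, x0, max_iter=max_iter, tol=tol)

    cov, rse = _covariance(design, x, diag["sse"])
    if cov is not None:
        d = np.diag(cov)
        se = {nm: (float(np.sqrt(v)) if v > 0 else float("nan"))
              for nm, v in zip(design.free_names, d)}
    else:
        se = {nm: float("nan") for nm in design.free_names}

    params = design.to_params(x)
    v = design.unpack(x)
    year_effects = (dict(zip(design.year_names, v["year"]))
                    if design.year_names else None)
    return FitResult(
        params=params, standard_errors=se, sse=diag["sse"],
        residual_se=rse, n=len(panel), converged=diag["converged"],
        iterations=diag["iterations"], start_values=start,
        regime="log" if log_branch else _regime_of(start.gamma),
        year_effects=year_effects, n_penalized_steps=diag["n_penalized"],
        sse_trace=diag["trace"],
        spec={"use_controls": use_controls,
              "use_year_effects": use_year_effects, "weights": weights,
              "fixed": fixed, "log_branch": log_branch,
              "gamma_bounds": gamma_bounds},
        free_names=design.free_names, free_values=x, covariance=cov)


def multi_start_fit(panel: pd.DataFrame,
                    regime_starts: Optional[list] = None,
                    **fit_kwargs) -> FitResult:
    """Fit from one start per curvature regime and keep the lowest SSE.

    Defaults to the published start (gamma = 2.7) plus starts in the
    gamma < 1 and gamma > 3.5 regimes and the gamma = 1 log branch.  Each
    power-branch start searches within its own regime's gamma region
    (:data:`REGIME_BOUNDS`), so the regimes remain comparable side by
    side even when the unconstrained objective has no interior optimum in
    gamma.  Ties (relative SSE difference < 1e-8) break toward the regime
    of the published default, then toward smaller starting gamma.
    """
    starts = regime_starts if regime_starts is not None \
        else default_regime_starts()
    if not starts:
        raise ValueError("at least one start is required")
    fits, failures = [], []
    for s in starts:
        regime = _regime_of(s.gamma)
        try:
            f = fit_utility_nls(panel, start=s,
                                log_branch=(regime == "log"),
                                gamma_bounds=REGIME_BOUNDS.get(regime),
                                **fit_kwargs)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"start gamma={s.gamma}: {exc}")
            continue
        (fits if f.converged else failures).append(
            f if f.converged else
            f"start gamma={s.gamma}: no convergence after "
            f"{f.iterations} iterations (sse={f.sse:.6g})")
    if not fits:
        raise RuntimeError("no start converged:\n" + "\n".join(failures))

    best_sse = min(f.sse for f in fits)
    tied = [f for f in fits if (f.sse - best_sse) <= 1e-8 * max(best_sse, 1.0)]
    tied.sort(key=lambda f: (f.regime != _regime_of(DEFAULT_START.gamma),
                             f.start_values.gamma))
    return tied[0]


def standard_errors(fit: FitResult, panel: pd.DataFrame) -> dict:
    """Recompute Gauss-Newton SEs sqrt(diag(sigma^2 (J'WJ)^-1)) at the
    optimum of a converged fit; singular information yields NaN entries."""
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    sp = fit.spec
    design = _Design(panel, sp["use_controls"], sp["use_year_effects"],
                     sp["weights"], sp["fixed"], sp["log_branch"],
                     sp.get("gamma_bounds"))
    cov, _ = _covariance(design, fit.free_values, fit.sse)
    if cov is None:
        return {nm: float("nan") for nm in fit.free_names}
    return {nm: (float(np.sqrt(v)) if v > 0 else float("nan"))
            for nm, v in zip(fit.free_names, np.diag(cov))}


def starting_value_sweep(panel: pd.DataFrame, param_name: str, grid,
                         base_start: Optional[UtilityParams] = None,
                         instability_tol: float = 1e-3,
                         **fit_kwargs) -> pd.DataFrame:
    """Refit while varying one starting value over a grid.

    Returns one row per grid point with the converged estimates and SSE
    (failures recorded with NaN).  ``.attrs['unstable']`` maps each
    parameter to whether its estimate range across converged fits exceeds
    ``instability_tol * (1 + |median|)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    base = base_start if base_start is not None else DEFAULT_START
    rows = []
    for val in grid:
        s = base.replace(**{param_name: float(val)})
        row = {"start_value": float(val)}
        try:
            f = fit_utility_nls(panel, start=s,
                                log_branch=(param_name == "gamma"
                                            and val == 1.0), **fit_kwargs)
            row.update({nm: getattr(f.params, nm) for nm in _BASE_NAMES})
            row.update(sse=f.sse, converged=f.converged)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            row.update({nm: float("nan") for nm in _BASE_NAMES})
            row.update(sse=float("nan"), converged=False,
                       error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["converged"] == True]  # noqa: E712
    unstable = {}
    for nm in _BASE_NAMES:
        if len(ok) >= 2:
            rng_ = float(ok[nm].max() - ok[nm].min())
            med = float(ok[nm].median())
            unstable[nm] = rng_ > instability_tol * (1.0 + abs(med))
        else:
            unstable[nm] = False
    table.attrs["unstable"] = unstable
    return table


def binarize_outcome(panel: pd.DataFrame, cutoff: int) -> pd.DataFrame:
    """Replace life satisfaction by the indicator LS >= cutoff."""
    if not 0 <= cutoff <= 10:
        raise ValueError(f"cutoff must lie in [0, 10], got {cutoff}")
    out = panel.copy()
    out["life_satisfaction"] = (
        out["life_satisfaction"] >= cutoff).astype(float)
    return out
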