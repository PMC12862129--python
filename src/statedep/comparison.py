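"""Benchmark specifications for the state-dependence estimate.

Two benchmarks sit beside the nonlinear utility fit:

* a loglinear fixed-effects panel regression
  ``LS_it = lam_i + g_t + b1*log(y_it) + b2*S_it + b3*log(y_it)*S_it
  + X'd + e`` whose interaction coefficient ``b3`` carries the sign of
  state dependence (comparable to theta's sign), and
* a nonparametric penalized cubic regression spline of life satisfaction
  on income within each sickness state (the visual income-well-being
  gradient).

Individual fixed effects are absorbed by within-demeaning (year dummies
demeaned too, which is exactly the dummy-variable regression by
Frisch-Waugh-Lovell); standard errors are clustered by individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .estimation import FitResult
from .synthetic import control_matrix

__all__ = [
    "LoglinearResult",
    "fit_loglinear_fe",
    "spline_gradient",
    "compare_estimates",
]


@dataclass
class LoglinearResult:
    """Coefficients of the loglinear (interaction) benchmark."""

    beta_income: float
    beta_sick: float
    beta_interaction: float
    se_income: float
    se_sick: float
    se_interaction: float
    includes_individual_fe: bool
    includes_year_fe: bool
    n: int
    n_individuals: int


def _demean_within(M: np.ndarray, person: np.ndarray) -> np.ndarray:
    """Subtract person-level means from each column (within transform)."""
    df = pd.DataFrame(M)
    return (df - df.groupby(person).transform("mean")).to_numpy()


def fit_loglinear_fe(panel: pd.DataFrame,
                     include_individual_fe: bool = True,
                     include_year_fe: bool = True,
                     controls: bool = True,
                     weighted: bool = False) -> LoglinearResult:
    """OLS of life satisfaction on log income, sickness and their
    interaction, with optional individual/year fixed effects and controls.

    With individual FE only individuals with >= 2 observations contribute;
    a rank-deficient design (e.g. no within-person sickness variation)
    raises :class:`IdentificationError` via a singular-matrix check.
    """
    if (panel["net_income"] <= 0).any():
        raise ValueError("net incomes must be > 0 for the log specification")
    data = panel.copy()
    if include_individual_fe:
        counts = data.groupby("person_id")["person_id"].transform("size")
        data = data[counts >= 2]
        if data.empty:
            raise ValueError("no individuals with >= 2 observations")

    person = data["person_id"].to_numpy()
    logy = np.log(data["net_income"].to_numpy(dtype=float))
    sick = data["sick"].to_numpy(dtype=float)
    y = data["life_satisfaction"].to_numpy(dtype=float)

    one_state = data["sick"].nunique() < 2
    if one_state:
        # sickness structurally absent: income slope only, sick terms NaN
        names = ["log_income"]
        X = [logy]
    else:
        names = ["log_income", "sick", "log_income:sick"]
        X = [logy, sick, logy * sick]
    if controls:
        X.append(control_matrix(data))
        names += ["age", "age_sq", "household_size", "female", "married"]
    if include_year_fe:
        years = np.sort(data["year"].unique())[1:]
        X.append((data["year"].to_numpy()[:, None]
                  == years[None, :]).astype(float))
        names += [f"year_{int(v)}" for v in years]
    X = np.column_stack([np.column_stack([c]) if np.ndim(c) == 1 else c
                         for c in X])

    n_core = len(["log_income"] if one_state
                 else ["log_income", "sick", "log_income:sick"])
    if include_individual_fe:
        y = _demean_within(y[:, None], person).ravel()
        X = _demean_within(X, person)
    else:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["const"] + names
        n_core += 1

    # the interest coefficients must be identified; auxiliary controls
    # and year dummies that lose all (within) variation are dropped
    core_scale = np.linalg.norm(X[:, :n_core], axis=0)
    if np.any(core_scale < 1e-8 * np.sqrt(len(y))):
        raise np.linalg.LinAlgError(
            "singular design: an interest regressor has no (within) "
            "variation")
    keep = list(range(n_core)) + [
        j for j in range(n_core, X.shape[1])
        if np.linalg.norm(X[:, j]) > 1e-8 * np.sqrt(len(y))]
    X, names = X[:, keep], [names[j] for j in keep]
    # rank-revealing QR: prune still-collinear auxiliary columns
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum())
    if rank < X.shape[1]:
        kept_piv = sorted(piv[:rank])
        if any(j not in kept_piv for j in range(n_core)):
            raise np.linalg.LinAlgError(
                "singular design: an interest regressor is collinear "
                "with the fixed effects")
        X, names = X[:, kept_piv], [names[j] for j in kept_piv]

    w = data["weight"].to_numpy(dtype=float) if weighted else None
    model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": person})
    coef = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    nan = float("nan")
    return LoglinearResult(
        beta_income=float(coef["log_income"]),
        beta_sick=float(coef.get("sick", nan)),
        beta_interaction=float(coef.get("log_income:sick", nan)),
        se_income=float(se["log_income"]),
        se_sick=float(se.get("sick", nan)),
        se_interaction=float(se.get("log_income:sick", nan)),
        includes_individual_fe=include_individual_fe,
        includes_year_fe=include_year_fe,
        n=len(data),
        n_individuals=int(data["person_id"].nunique()))


def spline_gradient(panel: pd.DataFrame, state: int, knot_count: int = 6,
                    grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Penalized cubic regression spline of LS on income in one state.

    Cubic B-spline basis with ``knot_count`` interior knots at income
    quantiles; a second-difference penalty on the coefficients with the
    smoothing weight chosen by generalized cross-validation (no manual
    tuning).  Unweighted, matching a plain cross-section fit.  Returns a
    grid table with fitted values and pointwise 95% bands under Gaussian
    errors; ``.attrs`` records the chosen penalty and effective df.
    """
    sub = panel[panel["sick"] == state]
    x = sub["net_income"].to_numpy(dtype=float)
    y = sub["life_satisfaction"].to_numpy(dtype=float)
    n = x.size
    if n < knot_count + 4:
        raise ValueError(
            f"need >= {knot_count + 4} observations in state {state}, "
            f"got {n}")

    qs = np.linspace(0, 1, knot_count + 2)[1:-1]
    knots = np.unique(np.quantile(x, qs))
    lo, hi = float(x.min()), float(x.max())
    B = patsy.dmatrix(
        "bs(x, knots=knots, degree=3, include_intercept=True) - 1",
        {"x": x, "knots": knots}, return_type="matrix")
    design_info = B.design_info
    B = np.asarray(B)
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)          # second-difference penalty
    BtB = B.T @ B
    DtD = D.T @ D
    Bty = B.T @ y

    best = None
    for lam in np.r_[0.0, np.logspace(-4, 8, 25)]:
        M = BtB + lam * DtD + 1e-10 * np.eye(k)
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        beta = Minv @ Bty
        fitted = B @ beta
        rss = float(((y - fitted) ** 2).sum())
        edf = float(np.trace(Minv @ BtB))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, Minv, rss, edf)
    gcv, lam, beta, Minv, rss, edf = best
    sigma2 = rss / max(n - edf, 1.0)

    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 200)
    grid = np.clip(np.asarray(grid, dtype=float), lo, hi)  # basis support
    Bg = np.asarray(patsy.build_design_matrices(
        [design_info], {"x": grid, "knots": knots})[0])
    fit = Bg @ beta
    cov = sigma2 * (Minv @ BtB @ Minv)            # sandwich for the ridge
    se = np.sqrt(np.maximum(
        np.einsum("ij,jk,ik->i", Bg, cov, Bg), 0.0))
    out = pd.DataFrame({"income": grid, "fit": fit,
                        "lo95": fit - 1.96 * se, "hi95": fit + 1.96 * se})
    out.attrs.update(penalty=float(lam), edf=edf, gcv=float(gcv),
                     sigma=float(np.sqrt(sigma2)), n=n)
    return out


def compare_estimates(nls_fits: list[FitResult],
                      loglinear_fits: list[LoglinearResult],
                      labels: Optional[list[str]] = None) -> pd.DataFrame:
    """Pair the utility-model theta with the loglinear interaction b3.

    One row per paired specification: the fixed-cost estimate (sign and
    magnitude), the interaction coefficient, 10%-level significance of
    each, and the cross-model Pearson correlation of the two estimate
    vectors in ``.attrs['correlation']`` (NaN with fewer than two pairs).
    """
    if not nls_fits or not loglinear_fits:
        raise ValueError("both fit lists must be nonempty")
    if len(nls_fits) != len(loglinear_fits):
        raise ValueError(
            f"unpaired entries: {len(nls_fits)} utility fits vs "
            f"{len(loglinear_fits)} loglinear fits")
    labels = labels or [f"spec_{i + 1}" for i in range(len(nls_fits))]
    if len(labels) != len(nls_fits):
        raise ValueError("labels length must match the fit lists")

    z10 = 1.6448536269514722                     # 10% two-sided normal
    rows = []
    for lab, f, g in zip(labels, nls_fits, loglinear_fits):
        th_se = f.standard_errors.get("theta", float("nan"))
        rows.append({
            "spec": lab,
            "theta": f.params.theta,
            "theta_se": th_se,
            "theta_sig10": bool(abs(f.params.theta) > z10 * th_se)
            if np.isfinite(th_se) else False,
            "beta_interaction": g.beta_interaction,
            "beta_interaction_se": g.se_interaction,
            "beta_interaction_sig10":
                bool(abs(g.beta_interaction) > z10 * g.se_interaction)
                if np.isfinite(g.se_interaction) else False,
            "same_sign": bool(np.sign(f.params.theta)
                              == np.sign(g.beta_interaction)),
        })
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["theta"].std() > 0 \
            and table["beta_interaction"].std() > 0:
        corr = float(np.corrcoef(table["theta"],
                                 table["beta_interaction"])[0, 1])
    else:
        corr = float("nan")
    table.attrs["correlation"] = corr
    return table
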