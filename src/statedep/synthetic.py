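"""Synthetic person-year panels with the structure the analysis assumes.

The generator emulates a household-panel "switcher" subsample: working-age
individuals observed for ~9 years each, of which ~1.5 are sickness-absence
years, with net incomes (thousand EUR/yr) lognormal around 47.4 with SD
near 29, and a 0-10 life-satisfaction score generated from the
state-dependent HARA model plus Gaussian noise.

Sickness propensity is individual-level Beta with yearly Bernoulli draws,
which creates a realistic mix of never-sick, always-sick and switching
individuals; sick-year incomes are the healthy counterfactual reduced by a
proportional drop (default 4%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import MAIN_SPEC_PARAMS, UtilityParams
from .utility import evaluate_utility

__all__ = [
    "SyntheticConfig",
    "CALIBRATION_TARGETS",
    "PANEL_COLUMNS",
    "simulate_panel",
    "filter_switchers",
    "summarize_panel",
    "read_panel",
    "write_panel",
    "control_matrix",
    "CONTROL_COLUMNS",
]

#: fixed column set of a panel CSV
PANEL_COLUMNS = ["person_id", "year", "net_income", "sick",
                 "life_satisfaction", "age", "household_size", "female",
                 "married", "weight"]

#: design columns used whenever demographic controls enter a model
CONTROL_COLUMNS = ["age", "age_sq", "household_size", "female", "married"]

_FIRST_YEAR, _LAST_YEAR = 1993, 2018

#: Reference switcher-sample moments the generator defaults are calibrated
#: against (incomes in thousand EUR/yr): per-state means/SDs of life
#: satisfaction and net income, state counts, and panel-shape targets.
CALIBRATION_TARGETS = {
    "healthy_ls_mean": 6.97, "healthy_ls_sd": 1.65,
    "sick_ls_mean": 6.65, "sick_ls_sd": 1.85,
    "healthy_income_mean": 47.42665, "healthy_income_sd": 28.59994,
    "sick_income_mean": 45.65640, "sick_income_sd": 36.88043,
    "n_healthy": 56268, "n_sick": 10961, "n_individuals": 6994,
}


@dataclass
class SyntheticConfig:
    """Distributional knobs of the generator; defaults match the switcher
    subsample the analysis targets (counts, income moments, sick share)."""

    n_individuals: int = 13600
    years_per_individual: float = 9.2   # mean panel length, min 2
    income_log_mean: float = 3.703      # persistent log income (thousand EUR)
    income_log_sd: float = 0.537
    income_year_sd: float = 0.15        # within-person lognormal year shock
    sick_prob_mean: float = 0.09        # Beta mean of individual propensity
    sick_prob_concentration: float = 24.0
    sick_income_drop: float = 0.04      # proportional income drop, sick years
    true_params: UtilityParams = field(
        default_factory=lambda: MAIN_SPEC_PARAMS.replace())
    noise_sd: float = 1.6               # additive LS noise, LS points
    round_outcome: bool = False         # round+clip LS to integer 0-10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.income_log_sd, self.income_year_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.sick_prob_mean <= 1.0:
            raise ValueError("sick_prob_mean must lie in [0, 1]")
        if not 0.0 <= self.sick_income_drop < 1.0:
            raise ValueError("sick_income_drop must lie in [0, 1)")
        if self.years_per_individual < 2:
            raise ValueError("years_per_individual must be >= 2")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    def save(self, path) -> None:
        d = self.__dict__.copy()
        d["true_params"] = self.true_params.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "true_params" in d:
            d["true_params"] = UtilityParams.from_dict(d["true_params"])
        return cls(**d)


def control_matrix(panel: pd.DataFrame) -> np.ndarray:
    """Design columns [age, age^2/100, household_size, female, married].

    age^2 is scaled by 100 only to keep the columns on comparable scales.
    """
    age = panel["age"].to_numpy(dtype=float)
    return np.column_stack([
        age,
        age ** 2 / 100.0,
        panel["household_size"].to_numpy(dtype=float),
        panel["female"].to_numpy(dtype=float),
        panel["married"].to_numpy(dtype=float),
    ])


def simulate_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a person-year panel; byte-identical for a fixed seed.

    Life satisfaction equals the state-dependent HARA prediction under
    ``config.true_params`` plus N(0, noise_sd) noise; sick-year incomes are
    the healthy counterfactual times (1 - sick_income_drop).  Raises if any
    record's shifted income leaves the utility domain or if a noise-free
    prediction leaves the 0-10 scale (incompatible config), naming the
    offending record.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    # panel lengths: 2 + Poisson, so every individual can in principle switch
    T = 2 + rng.poisson(config.years_per_individual - 2.0, n)

    # individual-level draws
    if config.sick_prob_mean in (0.0, 1.0):
        p_sick = np.full(n, config.sick_prob_mean)
    else:
        c = config.sick_prob_concentration
        p_sick = rng.beta(config.sick_prob_mean * c,
                          (1.0 - config.sick_prob_mean) * c, n)
    log_inc = rng.normal(config.income_log_mean, config.income_log_sd, n)
    female = rng.integers(0, 2, n)
    married = (rng.random(n) < 0.6).astype(int)
    hh_size = 1 + np.minimum(rng.poisson(1.3, n), 5)
    weight = np.exp(rng.normal(0.0, 0.3, n))
    base_age = rng.integers(19, 65 - np.minimum(T - 1, 45))
    start_year = _FIRST_YEAR + (
        rng.random(n) * (_LAST_YEAR - _FIRST_YEAR + 2 - np.minimum(
            T, _LAST_YEAR - _FIRST_YEAR + 1))).astype(int)

    person = np.repeat(np.arange(n), T)
    t_idx = np.concatenate([np.arange(k) for k in T])
    n_rows = person.size

    sick = (rng.random(n_rows) < p_sick[person]).astype(int)
    year_shock = np.exp(rng.normal(-config.income_year_sd ** 2 / 2.0,
                                   config.income_year_sd, n_rows))
    healthy_income = np.exp(log_inc[person]) * year_shock
    income = healthy_income * (1.0 - config.sick_income_drop * sick)

    panel = pd.DataFrame({
        "person_id": person,
        "year": np.minimum(start_year[person] + t_idx, _LAST_YEAR),
        "net_income": income,
        "sick": sick,
        "life_satisfaction": 0.0,
        "age": np.minimum(base_age[person] + t_idx, 64),
        "household_size": hh_size[person],
        "female": female[person],
        "married": married[person],
        "weight": weight[person],
    })

    p = config.true_params
    w = p.shifted_income(income, sick)
    if np.any(w <= 0.0):
        i = int(np.argmax(w <= 0.0))
        raise ValueError(
            "incompatible config: shifted income <= 0 for person "
            f"{person[i]}, year {panel['year'].iloc[i]} "
            f"(income={income[i]:.3f}, sick={sick[i]})")
    controls = control_matrix(panel) @ p.tau if p.tau.size else 0.0
    mean_ls = evaluate_utility(income, sick, p, controls)
    out = np.asarray(mean_ls) * np.ones(n_rows)
    if np.any((out < 0.0) | (out > 10.0)):
        i = int(np.argmax((out < 0.0) | (out > 10.0)))
        raise ValueError(
            "incompatible config: noise-free prediction outside [0, 10] "
            f"for person {person[i]}, year {panel['year'].iloc[i]} "
            f"(prediction={out[i]:.3f})")
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, n_rows)
    if config.round_outcome:
        out = np.clip(np.round(out), 0.0, 10.0)
    panel["life_satisfaction"] = out
    return panel


def filter_switchers(panel: pd.DataFrame) -> pd.DataFrame:
    """Keep all person-years of individuals with >= 1 sick and >= 1 healthy
    year; warns and returns an empty panel if no one switches."""
    by = panel.groupby("person_id")["sick"]
    mixed = (by.max() == 1) & (by.min() == 0)
    keep = panel["person_id"].map(mixed)
    out = panel.loc[keep.to_numpy(dtype=bool)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no switchers in panel; returning empty panel",
                      stacklevel=2)
    return out


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table by sickness state (the Table-1-style summary).

    Rows: life satisfaction and net income, unweighted and weighted
    mean/SD plus observation counts per state.  Panel-level scalars
    (individuals, mean periods, mean sick periods) are in ``.attrs``.
    """
    if panel.empty:
        raise ValueError("summarize_panel requires a nonempty panel")

    def _stats(sub: pd.DataFrame) -> dict:
        w = sub["weight"].to_numpy(dtype=float)
        out = {}
        for var in ("life_satisfaction", "net_income"):
            x = sub[var].to_numpy(dtype=float)
            wm = np.average(x, weights=w)
            out[var] = {
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
                "weighted_mean": float(wm),
                "weighted_sd": float(np.sqrt(np.average((x - wm) ** 2,
                                                        weights=w))),
            }
        out["n"] = len(sub)
        return out

    rows = []
    for state, name in ((0, "healthy"), (1, "sick")):
        sub = panel[panel["sick"] == state]
        if sub.empty:
            continue
        st = _stats(sub)
        for var in ("life_satisfaction", "net_income"):
            rows.append({"state": name, "variable": var, **st[var],
                         "n": st["n"]})
    table = pd.DataFrame(rows)

    by = panel.groupby("person_id")["sick"]
    table.attrs["n_individuals"] = int(panel["person_id"].nunique())
    table.attrs["mean_periods"] = float(by.size().mean())
    table.attrs["mean_sick_periods"] = float(by.sum().mean())
    return table


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel as CSV with the fixed, documented column set."""
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV; validates columns and basic invariants."""
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel file missing columns: {missing}")
    if (panel["net_income"] <= 0).any():
        raise ValueError("net_income must be > 0")
    if (panel["weight"] <= 0).any():
        raise ValueError("weight must be > 0")
    return panel[PANEL_COLUMNS]
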