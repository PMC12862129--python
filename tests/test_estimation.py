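"""Tests for the weighted NLS estimator and its multi-start machinery."""

import numpy as np
import pandas as pd
import pytest

import statedep as sd
from statedep import (DEFAULT_START, IdentificationError, SyntheticConfig,
                      binarize_outcome, filter_switchers, fit_utility_nls,
                      multi_start_fit, simulate_panel, standard_errors,
                      starting_value_sweep)

PARAM_NAMES = ("alpha", "beta", "gamma", "omega", "theta", "delta")


def _params_close(fit, true, rel):
    for nm in PARAM_NAMES:
        est, tr = getattr(fit.params, nm), getattr(true, nm)
        assert est == pytest.approx(tr, rel=rel, abs=rel), nm


def test_noise_free_round_trip(noise_free_panel):
    """A fit started at the published defaults recovers the generating
    parameters of a noise-free panel to < 1e-4 relative, with SSE ~ 0."""
    fit = fit_utility_nls(noise_free_panel, use_controls=False)
    assert fit.converged
    _params_close(fit, sd.MAIN_SPEC_PARAMS, 1e-4)
    assert fit.sse < 1e-12


def test_noise_free_round_trip_with_controls(noise_free_panel):
    """Adding control regressors the data does not contain still recovers
    the generating parameters; the control coefficients go to ~ 0."""
    fit = fit_utility_nls(noise_free_panel, use_controls=True)
    assert fit.converged
    _params_close(fit, sd.MAIN_SPEC_PARAMS, 1e-4)
    assert np.allclose(fit.params.tau, 0.0, atol=1e-6)


def test_null_sick_effect_estimated_as_zero():
    """Data generated without any sickness effect: with theta fixed at 0
    the level effect delta is estimated as ~0 (within 2 SE)."""
    true = sd.MAIN_SPEC_PARAMS.replace(theta=0.0, delta=0.0)
    cfg = SyntheticConfig(n_individuals=2000, true_params=true,
                          sick_income_drop=0.0, seed=13)
    panel = filter_switchers(simulate_panel(cfg))
    fit = fit_utility_nls(panel, use_controls=False, fixed={"theta": 0.0})
    assert fit.converged
    assert abs(fit.params.delta) < 2 * fit.standard_errors["delta"]


def test_single_state_panel_raises_identification_error():
    cfg = SyntheticConfig(n_individuals=200, sick_prob_mean=0.0,
                          noise_sd=0.0, seed=3)
    panel = simulate_panel(cfg)
    with pytest.raises(IdentificationError):
        fit_utility_nls(panel, use_controls=False)
    # fixing the state-dependence parameters makes the fit possible
    fit = fit_utility_nls(panel, use_controls=False,
                          fixed={"theta": 0.0, "delta": 0.0})
    assert fit.converged
    assert fit.sse < 1e-10


def test_weight_rescaling_invariance(small_noisy_panel):
    """Multiplying all sampling weights by a positive constant leaves the
    estimates unchanged."""
    scaled = small_noisy_panel.copy()
    scaled["weight"] = scaled["weight"] * 7.3
    a = fit_utility_nls(small_noisy_panel, use_controls=False)
    b = fit_utility_nls(scaled, use_controls=False)
    _params_close(b, a.params, 1e-8)
    assert a.sse == pytest.approx(b.sse, rel=1e-10)


def test_sse_trace_monotone(small_noisy_panel):
    """Accepted damped-least-squares steps never increase the objective."""
    fit = fit_utility_nls(small_noisy_panel, use_controls=False)
    assert np.all(np.diff(fit.sse_trace) <= 0)


def test_refit_at_optimum_is_fixed_point(small_noisy_panel):
    """Restarting at the optimum leaves every parameter essentially
    unchanged (tiny drift along the flat gamma-omega-beta ridge aside)."""
    fit = fit_utility_nls(small_noisy_panel, use_controls=False)
    refit = fit_utility_nls(small_noisy_panel, start=fit.params,
                            use_controls=False)
    _params_close(refit, fit.params, 1e-4)


def test_empty_panel_raises():
    with pytest.raises(ValueError, match="empty"):
        fit_utility_nls(pd.DataFrame(columns=sd.PANEL_COLUMNS))


def test_duplication_scales_standard_errors():
    """Duplicating every observation halves the variance estimates: SEs
    shrink by ~1/sqrt(2)."""
    cfg = SyntheticConfig(n_individuals=1200, seed=17, noise_sd=0.8)
    panel = filter_switchers(simulate_panel(cfg))
    doubled = pd.concat([panel, panel], ignore_index=True)
    a = fit_utility_nls(panel, use_controls=False)
    b = fit_utility_nls(doubled, start=a.params, use_controls=False)
    for nm in ("alpha", "theta", "delta"):
        ratio = b.standard_errors[nm] / a.standard_errors[nm]
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)


def test_standard_errors_match_bootstrap():
    """Gauss-Newton SEs agree with a 200-draw nonparametric bootstrap
    within 20% on a small, well-identified panel.

    Checked for the parameters whose objective is locally quadratic
    (alpha, theta, delta); the gamma-omega-beta ridge produces
    heavy-tailed bootstrap draws for which a linearized SE is not the
    right yardstick on a small panel.
    """
    true = sd.UtilityParams(alpha=9.0, beta=20.0, gamma=2.0, omega=-10.0,
                            theta=4.0, delta=-0.3)
    cfg = SyntheticConfig(n_individuals=1500, true_params=true,
                          noise_sd=0.5, seed=19)
    panel = filter_switchers(simulate_panel(cfg))
    fit = fit_utility_nls(panel, use_controls=False)
    rng = np.random.default_rng(0)
    draws = {"theta": [], "delta": [], "alpha": []}
    for _ in range(200):
        resampled = panel.sample(n=len(panel), replace=True,
                                 random_state=rng.integers(2**31))
        bfit = fit_utility_nls(resampled, start=fit.params,
                               use_controls=False, tol=1e-8, max_iter=500)
        if bfit.converged:
            for nm in draws:
                draws[nm].append(getattr(bfit.params, nm))
    assert len(draws["theta"]) >= 150
    for nm in draws:
        boot_se = np.std(draws[nm], ddof=1)
        assert fit.standard_errors[nm] == pytest.approx(boot_se, rel=0.20)


def test_linear_submodel_matches_weighted_ols(small_noisy_panel):
    """With gamma, omega, theta fixed the model is linear in (alpha, beta,
    delta); the NLS solution must equal closed-form weighted OLS."""
    g, om, th = 3.19, -56.49, 4.86
    fixed = {"gamma": g, "omega": om, "theta": th}
    fit = fit_utility_nls(small_noisy_panel, use_controls=False,
                          fixed=fixed)
    y = small_noisy_panel["net_income"].to_numpy()
    S = small_noisy_panel["sick"].to_numpy(dtype=float)
    w = small_noisy_panel["weight"].to_numpy()
    w = w / w.mean()
    kern = ((y - om - th * S) / g) ** (1 - g) / (1 - g)
    X = np.column_stack([np.ones_like(y), kern, S])
    ls = small_noisy_panel["life_satisfaction"].to_numpy()
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * ls, rcond=None)
    assert fit.params.alpha == pytest.approx(coef[0], rel=1e-6)
    assert fit.params.beta == pytest.approx(coef[1], rel=1e-6)
    assert fit.params.delta == pytest.approx(coef[2], rel=1e-6, abs=1e-8)
    # closed-form WLS standard errors
    XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    resid = ls - X @ coef
    sigma2 = (w * resid**2).sum() / (len(y) - 3)
    se = np.sqrt(np.diag(sigma2 * XtWX_inv))
    assert fit.standard_errors["alpha"] == pytest.approx(se[0], rel=1e-5)
    assert fit.standard_errors["beta"] == pytest.approx(se[1], rel=1e-5)
    assert fit.standard_errors["delta"] == pytest.approx(se[2], rel=1e-5)


def test_standard_errors_recompute(small_noisy_panel):
    fit = fit_utility_nls(small_noisy_panel, use_controls=False)
    se = standard_errors(fit, small_noisy_panel)
    for nm in PARAM_NAMES:
        assert se[nm] == pytest.approx(fit.standard_errors[nm], rel=1e-10)


def test_multi_start_winner_has_lowest_sse(small_noisy_panel):
    """The selected fit's SSE is minimal among all converged regime fits,
    and the misspecified log branch fits worse than the power branch."""
    from statedep.estimation import (REGIME_BOUNDS, _regime_of,
                                     default_regime_starts)
    winner = multi_start_fit(small_noisy_panel, use_controls=False)
    log_rse = None
    for s in default_regime_starts():
        reg = _regime_of(s.gamma)
        f = fit_utility_nls(small_noisy_panel, start=s,
                            log_branch=(reg == "log"),
                            gamma_bounds=REGIME_BOUNDS.get(reg),
                            use_controls=False)
        if f.converged:
            assert winner.sse <= f.sse + 1e-6
        if reg == "log":
            log_rse = f.residual_se
    assert winner.regime != "log"
    assert log_rse > winner.residual_se


def test_multi_start_consistent_on_noise_free_panel(noise_free_panel):
    winner = multi_start_fit(noise_free_panel, use_controls=False)
    _params_close(winner, sd.MAIN_SPEC_PARAMS, 1e-4)


def test_multi_start_requires_starts(small_noisy_panel):
    with pytest.raises(ValueError):
        multi_start_fit(small_noisy_panel, regime_starts=[])


def test_sweep_stable_in_alpha(small_noisy_panel):
    """Sweeping the alpha starting value leaves the well-identified
    estimates unchanged (beta and omega may drift minutely along their
    flat ridge); a one-point grid reduces to a single fit."""
    table = starting_value_sweep(small_noisy_panel, "alpha",
                                 [6.0, 10.0, 14.0], use_controls=False)
    assert len(table) == 3
    assert table["converged"].all()
    for nm in ("alpha", "gamma", "theta", "delta"):
        spread = table[nm].max() - table[nm].min()
        assert spread < 1e-3 * (1 + abs(table[nm].median())), nm
        assert not table.attrs["unstable"][nm], nm
    single = starting_value_sweep(small_noisy_panel, "alpha", [10.0],
                                  use_controls=False)
    assert len(single) == 1


def test_sweep_gamma_across_regimes(small_noisy_panel):
    """Gamma starts spanning the three regimes are all recorded with
    their SSE; endpoints may differ by regime."""
    table = starting_value_sweep(small_noisy_panel, "gamma",
                                 [0.5, 2.7, 5.0], use_controls=False)
    assert len(table) == 3
    assert table.loc[table["converged"], "sse"].notna().all()


def test_sweep_empty_grid_raises(small_noisy_panel):
    with pytest.raises(ValueError):
        starting_value_sweep(small_noisy_panel, "gamma", [])


@pytest.mark.parametrize("ls,cutoff,expected", [
    (6.0, 6, 1.0), (5.9, 6, 0.0), (9.0, 9, 1.0), (3.0, 0, 1.0),
])
def test_binarize_boundary(ls, cutoff, expected):
    panel = pd.DataFrame({"life_satisfaction": [ls], "sick": [0]})
    out = binarize_outcome(panel, cutoff)
    assert out["life_satisfaction"].iloc[0] == expected


def test_binarize_invalid_cutoff():
    panel = pd.DataFrame({"life_satisfaction": [5.0]})
    with pytest.raises(ValueError):
        binarize_outcome(panel, 11)


def test_binarize_preserves_other_fields(small_noisy_panel):
    out = binarize_outcome(small_noisy_panel, 7)
    assert set(out["life_satisfaction"].unique()) <= {0.0, 1.0}
    pd.testing.assert_series_equal(out["net_income"],
                                   small_noisy_panel["net_income"])


def test_year_effects_estimated_when_requested(small_noisy_panel):
    fit = fit_utility_nls(small_noisy_panel, use_controls=False,
                          use_year_effects=True)
    assert fit.converged
    assert fit.year_effects is not None
    # data has no year effects: estimated dummies are small
    vals = np.array(list(fit.year_effects.values()))
    assert np.abs(vals).max() < 0.5
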