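# Methods

## Model

The package treats a 0–10 life-satisfaction score as a cardinal proxy for
utility and fits a state-dependent HARA function of net income
*y* (thousand EUR/yr) with sickness indicator *S*:

u(y, S) = α + β/(1−γ) · ((y − ω − θS)/γ)^(1−γ) + δS + τ′X,

valid on y − ω − θS > 0. The derived quantities are closed forms:

* marginal utility u′ = (β/γ)·((y − ω − θS)/γ)^(−γ);
* relative risk aversion RRA = γy/(y − ω − θS);
* relative prudence RP = (γ+1)y/(y − ω − θS).

γ = 1 is a separate logarithmic branch, α + β·ln(y − ω − θS) + δS + τ′X,
estimated on its own: the least-squares objective is non-smooth across
the γ = 1 boundary, so the limit is never taken numerically (marginal
utility, by contrast, is continuous there).

α, β, δ and the controls absorb the LS measurement scale and do not
enter marginal utility; ω, θ, γ carry all the policy content. Income is
measured in thousands so that the regressor magnitudes are comparable to
the outcome scale; published tables print β "in thousands", and the
internal β equals the printed value × 1000 (`UtilityParams.from_printed`
converts). Only this convention puts predicted LS near 7 at the sample
mean income.

## Policy mapping

Treating net income as consumption (the identity mapping — the
consumption-from-income equation the framework leaves open is not
modeled), the optimal-benefit condition equates the moral-hazard
elasticity sum ε (sickness-entry odds + spell duration, supplied by the
user as a single number, default 1.5) with the marginal-utility gap
u′(c_s,1)/u′(c_e,0) − 1 = ((c_s−ω−θ)/(c_e−ω))^(−γ) − 1. Its exact
inversion gives the replacement-rate schedule

RR(y_e) = ω/y_e + θ/y_e + (1 − ω/y_e)(1+ε)^(−1/γ),

and `mu_gap_exact(ye, RR·ye) = ε` holds to machine precision by
construction (tested to <1e-10). A second-order expansion
RRA·x·(1 + RP·x/2), x = (Δc+θ)/c_e, is also provided; its error is
O(x³) (tested via a log-log slope ≈ 3). Algebraically RR can exceed 1 at
very low incomes (θ/y_e dominates) and the implied sick income always
stays inside the utility domain whenever y_e > ω; grid points with
y_e ≤ ω are reported as infeasible rather than clipped.

## Estimation

Weighted NLS minimizes Σ wᵢ(LSᵢ − u(yᵢ, Sᵢ))² by a damped least-squares
(Levenberg–Marquardt-type) loop with an analytic Jacobian. Specifics:

* **Damping.** Marquardt diagonal scaling with the Nielsen gain-ratio
  update (on acceptance λ ← λ·max(1/3, 1−(2ρ−1)³); on rejection λ ← λν,
  ν ← 2ν). Accepted steps never increase the objective (a tested
  invariant).
* **Domain violations.** A trial vector that pushes any observation's
  y − ω − θS below zero (or γ out of range) is assigned a finite penalty
  of 10× the current SSE, so the step is rejected and the damping
  retreats; the count of penalized trials is reported. The model layer
  itself raises on domain violations — penalization is purely the
  optimizer's concern.
* **Convergence.** Relative SSE change < 1e-10 or step norm < 1e-10,
  at most 1,000 iterations; an exhausted damping search with a tiny
  gradient also counts as converged. Non-convergence is flagged on the
  result, not raised.
* **Weights** are normalized to mean 1, making the fit invariant to
  positive rescaling and keeping σ̂² = SSE/(n−p) interpretable.
* **Standard errors** are Gauss–Newton: σ̂²(JᵀWJ)⁻¹ at the optimum.
  Conditioning is assessed on the correlation-scaled information matrix
  (the raw matrix is ill-scaled because β is ~10³ times δ); a genuinely
  singular fit reports NaN rather than fabricated numbers. On small
  panels the SEs of the well-conditioned parameters (α, θ, δ) agree with
  a nonparametric bootstrap within 20%; the γ–ω–β ridge (below) makes
  bootstrap draws of the other three heavy-tailed, which is a property
  of the problem, not of the SE formula.
* **Fixed effects.** Individual fixed effects are deliberately absent
  from the NLS (the nonlinear estimation does not support them); the
  loglinear benchmark supplies them instead.

### Multi-start regimes and the curvature ridge

The objective is nearly flat along a ridge in (γ, ω, β): larger γ with
more negative ω and larger β produce almost identical fitted curves.
The multi-start procedure therefore probes one start per curvature
regime — the default start {α=10, β=0, γ=2.7, ω=−15, θ=15, δ=0} for the
middle regime (γ ∈ (1, 3.5]), plus starts in the low (γ < 1) and high
(γ > 3.5) regimes and the γ = 1 log branch — and keeps the converged fit
with the smallest SSE, breaking ties toward the middle regime and then
the smaller starting γ.

Each regime's search is confined to its own γ interval (trial values are
clamped in the update step). This is a deliberate design choice: on a
nontrivial fraction of noisy realizations the unconstrained SSE has no
interior minimum in γ — it decreases monotonically as γ → ∞ while
ω → −∞, the kernel degenerating toward exponential utility — so an
unconstrained mid/high search never converges there. Bounding the
regimes keeps the three power-branch fits comparable side by side,
yields a converged (possibly boundary) estimate in each region, and
prevents the misspecified log branch from winning by walkover. A
boundary estimate (γ̂ = 3.5 exactly) signals a flat-curvature
realization; its reported SEs are conventional Gauss–Newton values and
should be read with that in mind.

## Synthetic panels

The generator emulates a "switcher" subsample of a household panel —
working-age employed individuals observed in both sick and healthy
years. Defaults (all overridable via `SyntheticConfig`):

* **Panel shape**: 13,600 individuals, lengths T = 2 + Poisson(7.2)
  (mean 9.2, so every individual can in principle switch). After
  filtering to switchers this yields ≈6,990 individuals and ≈67,500
  person-years — calibrated to the reference counts (6,994 individuals,
  67,229 person-years, i.e. ≈9.6 periods each; the reference also quotes
  8.97 mean periods, which is inconsistent with its own counts — the
  generator targets the counts).
* **Sickness**: individual propensity p ~ Beta(mean 0.09,
  concentration 24), year draws Bernoulli(p). Among switchers this gives
  ≈16.6% sick person-years and ≈1.6 sick periods per individual,
  matching the reference shares (16.3%, 1.48–1.6).
* **Income**: persistent individual income lognormal(3.703, 0.537) ×
  a mean-one lognormal year shock (σ = 0.15) → mean ≈47.4, SD ≈28.6
  thousand EUR. Sick years earn (1 − 0.04)× the healthy counterfactual,
  the reference's ≈4% gap.
* **Outcome**: LS = u(y, S; true params) + N(0, 1.6). The default true
  vector is the published main estimate (α=9.93, β=2790, γ=3.19,
  ω=−56.49, θ=4.86, δ=−0.21) with no control effects and no year
  effects. Controls (age, household size, female, married) and weights
  are generated but, by default, do not influence the outcome.
* **Scale handling**: the generator refuses configurations whose
  noise-free predictions leave [0, 10], naming the offending record.
  With rounding on, noisy outcomes are rounded and clipped to integer
  0–10; with rounding off (the default, used for recovery tests because
  rounding biases NLS recovery) the noisy outcome is left untouched and
  can spill slightly above 10.

What the generator does *not* emulate: real attrition and sampling
design, interview timing relative to sickness spells (the measurement
error discussed in the source analysis), correlation between sickness
propensity and income, scale-use heterogeneity, and genuine control or
year effects. Passing recovery tests therefore demonstrate that the
estimator recovers the truth when the model is correctly specified at
realistic sample sizes and noise — not that the model is correct for
real survey data. Note one visible consequence: because the published α
absorbs control and year effects that the generator omits, simulated LS
levels sit near 9.2 rather than 7; gaps and gradients, which drive all
estimates of interest, are unaffected.

At the calibrated conditions, recovery is tight for θ relative to its
information content: across 20 seeds the multi-start estimate averages
≈4.5 (truth 4.86) with SD ≈1.3, matching the published SE of 1.31, and
the ±2-estimated-SE interval covers the truth in 90% of runs. Individual
seeds can still land ~2σ out — that is the sampling distribution, not an
estimator defect.

## Benchmarks

* **Loglinear fixed-effects model**: LS on log income, sickness, and
  their interaction, with individual and year fixed effects and
  controls. Individual effects are absorbed by within-demeaning (year
  dummies demeaned too, which equals the dummy-variable regression by
  Frisch–Waugh–Lovell; tested to 1e-8). Standard errors are clustered by
  individual. Interest regressors that lose all within variation raise
  a singularity error; auxiliary controls that do (e.g. time-invariant
  dummies under individual FE, or age against year dummies) are dropped
  by rank-revealing QR. Weighting is off by default with a flag, as the
  reference analysis does not state it.
* **Spline gradient**: a penalized cubic regression spline of LS on
  income within one sickness state — B-spline basis with six interior
  knots at income quantiles, second-difference coefficient penalty, and
  the penalty weight chosen by generalized cross-validation (no manual
  tuning), with pointwise Gaussian 95% bands. Unweighted, as a plain
  cross-section fit.
* **Cross-model table**: pairs each utility-model θ with the loglinear
  interaction coefficient, flags 10%-level significance of each, and
  reports the correlation of the two estimate vectors across
  specifications.

## Numerical and design choices

* Binarization of the outcome uses LS ≥ cutoff (the direction is a
  recorded flag; the source analysis does not state it).
* The marital-status control is a single indicator labeled `married`
  (source texts disagree between "single" and "married"; one indicator
  carries the same information up to sign).
* Starting-value sweeps refit the model varying one starting value at a
  time and flag instability when an estimate's range across the grid
  exceeds 1e-3·(1 + |median|). β and ω are expected to drift minutely
  along the ridge even on well-behaved problems.
* Ties in multi-start selection are resolved at relative SSE 1e-8.
* The acceptance script's recovery experiment fits without controls,
  matching the generator's defaults; adding control regressors the data
  does not contain only adds variance.

## Known limitations

* The estimator provides no ordered-response treatment of the 0–10
  scale; cardinality is assumed throughout.
* Policy calculations take net income as consumption and ignore
  redistribution preferences, liquidity constraints, and general
  equilibrium effects.
* Elasticities enter only as a user-supplied sum; the behavioral model
  generating them is out of scope.
* γ̂ exactly on a regime boundary indicates the data cannot pin down
  curvature in that region; treat ω̂ and β̂ from such fits with caution
  (their SEs are large, which is the honest signal).
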