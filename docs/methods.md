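# Methods

## Model and assumptions

`cyclomort` treats each tropical-cyclone (TC) strike as an impulse — a
short-lived physical event of intensity `z` (state-area-averaged maximum
sustained wind, m/s) — and the monthly state mortality rate as the additive
superposition of (i) a rich deterministic control surface and (ii) scaled
copies of one characteristic impulse-response function (IRF) `β_ℓ`, the
change in deaths per 100,000 per month ℓ months after 1 m/s of incidence.
Additivity across overlapping storms is the identifying assumption; it is
plausible because any single storm moves the monthly mortality rate by a
small fraction of its level. Exposure timing and intensity are taken as good
as randomly assigned conditional on the controls, which is why the model must
pass the lead-falsification and placebo-randomization checks below before its
estimates are interpretable.

The control surface is deliberately nonparametric: state-by-calendar-month
fixed effects and their linear trends, state-specific polynomial time trends
(order up to 8), national month-of-sample fixed effects, and a state-specific
quadratic in temperature. Each block removes a family of confounders
(geography and seasonality, slow demographic/policy change, evolving
seasonality, national shocks such as epidemics, and the known nonlinear
temperature–mortality relation, respectively). Omitting any of them makes the
placebo tests fail on realistic synthetic data, which is the practical
argument for keeping all five.

## Estimation

The model is solved by (optionally population-weighted) OLS. The two
fixed-effect families are never materialized: the outcome and the exposure
lag block are residualized by the method of alternating projections over
(a) state×calendar-month cells with within-cell basis `[1, t]` and (b)
(region×)month-of-sample cells with basis `[1]`; remaining continuous
controls (state polynomial trends, state temperature terms) are then
partialled out through a pivoted QR. By Frisch–Waugh–Lovell, OLS of the
residualized outcome on the residualized exposure block reproduces the
exposure coefficients, their classical covariance block and the residuals of
the full dense regression; the test suite verifies this to machine precision
against dense dummy-variable least squares, including the covariance and the
residual degrees of freedom.

Degrees of freedom are counted exactly. The rank of the fixed-effect union
has a closed form (`absorb.fe_union_rank`): the two families overlap
precisely in the functions of (region, calendar month) — linear in `t` when
the seasonal-trend basis is on — because calendar month is a deterministic
function of month-of-sample. The continuous block's rank comes from the
pivoted QR of its FE-residualized columns. Real collinearities are expected
and handled, not exceptional: per-state linear trends lie exactly in the span
of the state×calendar-month trend basis, and for every higher power one
column per power is absorbed by the month-of-sample effects; the QR drops
them and records their names in the fit echo.

Numerical choices:

- the time index is rescaled to [0, 1] before powers are taken — raw month
  indices raised to the 8th power would destroy conditioning;
- alternating projections iterate to a 1e-11 relative tolerance (capped at
  2000 sweeps); group-level Gram matrices use closed-form 1×1/2×2 inverses
  with an intercept-only fallback for degenerate cells;
- exposure columns that vanish identically are flagged non-identified at
  design time, and a rank-deficient exposure block aborts the fit naming the
  offending lag columns;
- a zero outcome yields zero coefficients and R² defined as 0.

Edge policy: the estimation sample keeps outcome months with a complete
`n_lags` history (supplied by the generator's burn-in) and a complete
`n_leads` future; `edge="zero_pad"` instead keeps all outcome months and
treats out-of-window exposure as zero, for sensitivity checks only.

Uncertainty is classical OLS (`σ̂²(X̃'X̃)⁻¹`): on correctly specified
synthetic panels the residuals are near-Gaussian and serially unstructured
(the `diagnostics()` report checks skewness, excess kurtosis, per-period SD
and lag-1..12 autocorrelations), and the permutation tests corroborate the
asymptotic intervals. A state-clustered sandwich covariance is available but
not the default. Cumulative responses `Ω_ℓ` propagate the full covariance
(`Var(Ω_ℓ) = 1'V1`); leads are reverse-cumulated so `Ω_{-1} = 0` and
`Ω_ℓ − Ω_{ℓ-1} = β_ℓ` everywhere. Reported "±" values follow the field's
convention of estimate/t rounded to two significant figures.

## Randomization and permutation inference

Four shuffle schemes destroy the wind–mortality pairing while each preserving
a different marginal structure: `total` (global multiset), `within_state`
(per-state multiset, timing destroyed), `within_month` (per-month multiset,
geography destroyed), `across_state` (intact series, state labels permuted
uniformly; a derangement option exists). Shuffles act on the raw wind series
— burn-in included — before lag expansion, so every draw is an internally
consistent time series; each scheme's conservation law is asserted on every
draw. Each draw re-fits the full model; the cached control projection makes
this cheap. A draw that fails to fit is excluded and counted; more than 1%
failures aborts the study.

Pointwise p-values `p_ℓ = #{|Ω_ℓ^rand| > |Ω_ℓ^obs|}/n` are exchangeable-valid
and verified uniform under the null. Two joint quantities are reported:

- `joint_p`, the fraction of draws exceeding the observed curve at *every*
  lag in the range. This is the intuitive "an entire curve this extreme by
  chance" probability, but it is **not a calibrated p-value**: under the null
  most curves are maximal in the dominance partial order, so the statistic
  piles up near zero (measured ≈30% rejection at a 5% threshold on null
  panels). It is reported as a descriptive extremity measure only.
- `joint_p_max`, the permutation p-value of the studentized max statistic
  `max_ℓ |Ω_ℓ|/sd_ℓ` with the per-lag SD pooled over draws and the observed
  curve and the `(count+1)/(n+1)` rule. This is exactly valid under
  exchangeability and is the quantity to threshold; its null rejection rate
  is verified ≤ nominal.

## Heterogeneity and nonlinearity

Group-specific responses interact only the exposure lag block with group
indicators; all control blocks stay common. Groups may partition states
(risk quartiles from long-run mean incidence: the lowest non-zero quartile is
"low", quartiles 2–4 pooled are "high"; zero-incidence states are outside the
grouping) or time (era splits, with exposure attributed to the storm's
landfall month). A single group reproduces the pooled fit exactly. Equality
across groups is tested by a classical F-test on the coefficient differences
over a chosen lag range.

The nonlinear variant makes the response cubic in incidence (`wind^r`,
r = 1..3, computed on the raw monthly series before lag expansion),
separately by risk group. Its cumulative dose–response
`Ω_g(w) = Σ_r (Σ_ℓ θ_{r,ℓ}) wʳ` is zero at `w = 0` by construction and nests
the linear model when the higher-order terms vanish; delta-method standard
errors accompany it.

## Burden accounting

Each storm-by-state event contributes
`pop_{i,t+ℓ}/10⁵ · (response at lag ℓ)` excess deaths; linear responses scale
by incidence, nonlinear ones evaluate the group's dose curve at the event's
incidence. Streams superpose exactly into the national monthly envelope
(verified against a brute-force double loop). The default horizon is 172
months — the window of elevated response — with 240 available. Streams
reaching past the panel's end are truncated; the unrealized mass is reported
using the final month's population as the stand-in path. Per-storm averages
divide by distinct storms, not storm-by-state events. Per-state proportions
divide attributed deaths by observed deaths (undefined and flagged where a
cell records none).

Counterfactual populations: `fixed_year(y)` freezes each state at its year-y
mean; `deflated(base, target)` keeps the target year's spatial shares but
rescales by `1/(1+Δ)`, `Δ = (Σpop_target − Σpop_base)/Σpop_base`, so the
national total returns to the base year. Trends are OLS slopes of the
monthly national series; differences between scenarios attribute the trend to
the storm sequence, spatial redistribution, or demographic growth. No
uncertainty is propagated from `β̂` into burdens by default (point-estimate
attribution); migration across states is not modelled.

## The synthetic generator

The generator is the package's statement of study conditions, with every
component returned as ground truth. Defaults: quadratic IRF
`0.0237 + 0.000535·ℓ − 0.0000039·ℓ²` per 100,000 per m/s truncated at 172
months (a realistic long, hump-shaped response peaking near six years);
compound Poisson arrivals at 1 storm per state-year with 70% of arrivals in a
4-month season (August–November); lognormal incidence with `μ=1.5, σ=0.9`
(mean ≈ 6.7 m/s, 95th percentile ≈ 19 m/s, rare events in the tens of m/s —
a long right tail comparable to observed state-level incidence); baseline
mortality 85 per 100,000 per month with SD 10 across states; sinusoidal
state seasonality; degree-3 polynomial trends spanning ~±12 per 100,000 over
the window; seasonal-trend slopes SD 3; national shocks SD 1.5; a
state-specific quadratic temperature response centered on each state's
climate; Gaussian noise SD 2 per 100,000; exponential population growth
0.2–2% per year from bases of 0.3–8 million. Storms, ground-truth surfaces
and noise use independent child streams of one seed, so the storm history is
invariant to noise settings, and deaths are kept continuous (not rounded) so
noise-free runs are exactly invertible. Negative simulated death counts are
clipped at zero and counted; under the defaults clipping never occurs.

What the generator does *not* emulate: spatial correlation of storms across
neighboring states, geophysical track structure, measurement error in
exposure, ICD-coding breaks, within-state population redistribution, or
migration. Passing recovery tests therefore demonstrates the estimator's
correctness under the stated data-generating assumptions — not robustness to
exposure mismeasurement or cross-state spillovers in real data.

## Problem sizes used in the shipped studies

The package's own validation studies run at deliberately compact sizes: the
recovery study uses 200 replicates of 20 states × 360 months with a 24-month
truncated quadratic IRF (the full 172-month horizon behaves identically but
needs proportionally longer panels); placebo nulls use 12 states × 240 months
with 100 draws per scheme; permutation calibration uses 100 replicates × 100
draws at 8 states × 180 months with a 6-lag window. These sizes keep each
study's Monte-Carlo error well below the effects being checked.

## Known limitations

- Classical (homoskedastic) covariance is the default by design; panels with
  genuinely clustered errors should use `vcov_clustered` and expect the
  permutation tests, not the asymptotic intervals, to carry the inference.
- The closed-form fixed-effect rank assumes a generic panel (each
  state×calendar-month cell observed in at least two distinct months, full
  temperature variation); exotic sparsity patterns would require the dense
  rank computation the tests use for verification.
- The dominance-style joint probability is reported for comparability but
  must not be thresholded as a p-value; use `joint_p_max`.
- Burden truncation at the panel boundary understates the last cohort of
  storms' totals; the truncated mass is reported so users can bound it.
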