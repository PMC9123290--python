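# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite can show.

## Outcome model: left-censored Gaussian (tobit)

The CES-D total (0–60) is treated as a censored observation of a latent
normal symptom score: y = max(0, y*), y* = x′β + ε, ε ~ N(0, σ²). The
log-likelihood mixes the normal density for uncensored rows with the lower
tail mass Φ(−x′β/σ) for rows at the floor. Coefficients are therefore on
the latent symptom scale; `tobit_expected` maps a fit back to the observed
scale via E[y|x] = Φ(z)·x′β + σ·φ(z), z = x′β/σ.

Estimation maximises the likelihood in (β, log σ) — the log
parameterisation removes the positivity boundary — by BFGS with the
analytic gradient, started from OLS on the uncensored subset (σ₀ = that
fit's residual SD). Convergence requires gradient ∞-norm < 1e-6 (max 200
iterations); when BFGS exits within rounding distance of the optimum but
above tolerance, up to five damped Newton steps (numeric Hessian of the
analytic gradient) polish the solution. Non-convergence is surfaced as
`converged=False` plus a `RuntimeWarning`, never silently accepted.
Standard errors come from the inverse observed information; se(σ) by the
delta method from se(log σ). The ceiling at 60 is ignored by the model; at
the calibrated parameters P(y* > 60) is ~1e-15. CES-D is modelled as
continuous although the generator rounds it to integers; rounding perturbs
moments by < 0.03 on this scale.

The engine was cross-checked against an independent left-censored Gaussian
ML implementation (R `survival::survreg`, gaussian family) on a frozen
fixture: coefficients, SEs, scale and log-likelihood agree to ~1e-9.

Logistic regressions (binary mediators, gender-item odds ratios) use the
statsmodels Newton MLE. Complete separation raises an error advising a
penalised fit, which this package deliberately does not provide.

## Gender index

Item codings (femininity-oriented): working hours — sample quartiles,
reversed; equivalized income — ×0.7 (≈1/√2) when a partner shares the
household, then sample quartiles, reversed, with quartiles computed *after*
equivalization (the order follows the description of the measure);
occupation segregation — fixed bands ≤25 / 26–50 / 51–75 / ≥76% female
workers → 0..3; education — high 0, intermediate 1, low 2; informal
caregiving — none 0, <8 h/week 1, ≥8 h/week 2; chores — sample quartiles,
unreversed. The literal codings cap the sum at 16 (3+3+3+2+2+3); the
source description of the index mentions a 0–22 range that the stated item
codings cannot produce, so the package implements the verifiable codings
and exposes the code tables in config for users who wish to reproduce a
0–22 variant.

Quantiles are linear-interpolation ("type 7") sample quantiles; quartile
bands are half-open [qₖ, qₖ₊₁) with the top band closed. Dichotomisation is
"feminine ⇔ total > cutoff" with ties to masculine; the default cutoff is
the within-sample median of totals, and the fixed historical cutoff 7
(masculine 0–7, feminine 8+) is available for replication. The same
median-split rule (high ⇔ score > median, ties low) dichotomises the six
working-condition sum scores.

## Moderation and mediation

Differential vulnerability: tobit of CES-D on {condition, group,
condition×group, centered age}, reference groups male/masculine and low
exposure; the interaction is judged by a Wald z. The twelve interaction
tests of the full report are presented unadjusted for multiplicity, and the
report flags this.

Differential exposure: paths fitted per mediator — a (logistic), b and c′
(one tobit), c (a separate tobit). The ACME for a binary mediator is
β_M · meanᵢ[p̂ᵢ(M=1|T=1) − p̂ᵢ(M=1|T=0)], each person kept at their own
age. On the latent (linear-predictor) scale this product form is exact,
which makes the invariances testable: a-slope 0 ⇒ ACME ≡ 0, and recoding
the mediator flips a and b but leaves the ACME unchanged. An alternative
"expected" scale routes the same probability contrast through the censored
outcome expectation (averaged over the two exposure arms); it is offered
because indirect effects on the observed scale are attenuated by the floor,
but the latent scale is the default and is what the decomposition
c ≈ c′ + ACME refers to (approximate, since c comes from a separately
fitted model). CIs for the ACME are percentile intervals over seeded
nonparametric person resamples (500 by default); path coefficients keep
Wald intervals. Resamples whose fits fail are dropped and counted; >10%
failures abort. Exposure–mediator interaction in the outcome model and
multiple-mediator models are out of scope.

## Multiple imputation

Chained equations with predictive-mean matching for every incomplete
column (continuous, ordinal and categorical alike — donors are observed
values, so imputations stay in the observed support): 10 cycles, 5 donors,
an approximate Bayesian parameter draw (scaled-inverse-χ² σ², normal β)
behind each prediction, all driven by spawned per-imputation seeds.
Pooling follows Rubin's rules exactly as stated in the module docstring;
B = 0 falls back to normal rather than t quantiles. When mediation is run
under MI, each completed dataset gets its own bootstrap and the ACME is
pooled with its bootstrap variance as the within-imputation variance — a
documented approximation, since no exact finite-m combination rule exists
for bootstrap percentile intervals.

## Synthetic cohort generator

The generator emulates the study conditions: n = 313, 43.5% female, age
N(58.9, 2.4²); the six gender items drawn per sex from the published
category frequencies, then given a raw value uniform inside the category's
band so the quartile-coding path is genuinely exercised; partner prevalence
0.80 (not reported in the source; Dutch late-50s norm); income sampled on
the equivalized scale and un-equivalized for storage. One cell of the
working-hours table is garbled in print; the male top-quartile share 0.181
is back-solved from row-sum and marginal constraints and is flagged as
uncertain in the config.

Working-condition sum scores must survive a *median* split with the
configured per-sex "high" prevalences (which average below 50%). A
continuous score cannot do that — a median split forces ~half "high" — so
scores are built as two integer bands around the range midpoint with a
probability clump exactly at the midpoint, sized (with margin
`tie_margin=0.10`) so the whole-sample median lands on the midpoint; the
ties-to-low rule then recovers every person's latent high/low draw exactly.
This is the package's own device for making dichotomisation lossless in
simulation; real questionnaire scores would not behave this way.

CES-D: latent = 6.1 + 1.7·female + Σ effects of high conditions (−0.5,
−0.5, +0.4, −1.6, −2.1, −1.3 for physical, psychosocial, cognitive
demands, autonomy, variation, support) + 0.1·(age − 58.9) + N(0, 6.9²),
rounded, clipped to [0, 60]. Intercept and σ were calibrated once with the
closed-form censored-normal moments so the observed outcome has mean ≈ 5.7,
SD ≈ 5.6 and ≈ 26% at the floor, matching the study's descriptives (total
5.7 (5.6); men ≈ 5.1, women ≈ 6.5). The age slope and the MAR parameters
(log-odds +0.5 for women, +0.1 per year of age, intercept solved by
bisection to hit the marginal `missing_rate`) are not reported in the
source and were chosen once as plausible values. An optional
`outcome_interactions` entry adds a true female-by-condition latent effect
for moderation power/recovery studies.

What the generator does *not* emulate: item-level questionnaires (both
CES-D and the working-condition scales are generated at sum-score level),
correlations among gender items beyond those induced by sex, attrition and
the study's eligibility filtering, survey weights, and any real-world
confounding of conditions with unmeasured traits. Passing tests therefore
demonstrate that the estimators are correct for data satisfying their
assumptions, not that the substantive findings generalise.

## Design choices and problem sizes

- Sex-level structure is the generator's primitive; gender-level contrasts
  emerge through the sex-item correlations. This reproduces the study's
  qualitative gender findings without asserting an independent causal role
  for the index.
- Directional (sign) claims in the end-to-end checks are evaluated on a
  2000-person simulated cohort: signs are population-level claims, and a
  single 313-person draw does not identify the sign of effects this small.
  Determinism checks run at the default n = 313.
- Gender-item odds-ratio reports are unadjusted (matching that table's
  presentation); all outcome models adjust for age, centered at the sample
  mean, which affects only intercepts.
- Simulation studies in the test suite use 100–500 replicates for
  coverage claims, a dozen replicates for the heavier imputation-recovery
  smoke check, and n = 313–5000 per replicate — sizes at which
  Monte-Carlo error is small relative to the asserted tolerances
  (coverage bands of a few percentage points, recovery within 3 SEs).

## Known limitations

Path-by-path estimation (not a joint SEM); no survey weights; no
sensitivity analysis for sequential ignorability; single-mediator models
only; the bootstrap is percentile (not BCa); MI×bootstrap combination is
approximate as noted; the gender index is the fixed unweighted sum — no
weighted or continuous-index variants.
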