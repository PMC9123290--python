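# genderpaths

Sex and gender differences in depressive symptoms among older workers, and
the role working conditions play in them, as a reusable, tested Python
pipeline.

## The scientific problem

Women in their late working years report more depressive symptoms than men
and leave the labour force earlier. Two mechanisms could route such
inequalities through the workplace:

- **differential exposure** — sexes/genders hold jobs with different
  conditions (less autonomy, less task variation, …), and those conditions
  affect mental health: the conditions *mediate* the inequality;
- **differential vulnerability** — the same condition affects the sexes/
  genders differently: sex/gender *moderates* the condition–health link.

Crucially, *sex* (biological, male/female) and *gender* (a social role
profile) are distinct exposures. Gender is operationalised here as a
six-item labour-market **gender index** — working hours, equivalized
household income, occupation segregation (% female workers in the sector),
education, informal caregiving, household-chore time — each item coded
toward femininity, summed (0–16 under the literal codings) and dichotomised
at the median into masculine/feminine.

The outcome is a CES-D depressive-symptom total (0–60) measured one wave
(~3 years) after the exposures. Because CES-D scores pile up at 0, ordinary
least squares is biased; the package instead fits **tobit (left-censored
Gaussian) regressions** by maximum likelihood:

y*ᵢ = xᵢ′β + εᵢ, εᵢ ~ N(0, σ²), yᵢ = max(0, y*ᵢ)

ℓ(β, σ) = Σ_{yᵢ>0} [log φ((yᵢ−xᵢ′β)/σ) − log σ] + Σ_{yᵢ=0} log Φ(−xᵢ′β/σ)

Mediation uses the classic path notation — a (logistic: mediator ~
exposure + age), b and c′ (tobit: CES-D ~ mediator + exposure + age), c
(tobit: CES-D ~ exposure + age) — and the **average causal mediation
effect** for a binary mediator,

ACME = β_M · meanᵢ[ p̂ᵢ(M=1 | T=1) − p̂ᵢ(M=1 | T=0) ],

with a seeded 500-resample percentile bootstrap for its confidence
interval. Missing data are handled by chained-equations predictive-mean-
matching imputation with Rubin's-rules pooling (T = W + (1 + 1/m)·B).

The cohort data this design comes from are available only on request, so
the package ships a calibrated **synthetic cohort generator** (313 persons,
43.5% female, age ≈ N(58.9, 2.4), sex-specific item frequencies and
working-condition prevalences, CES-D as a rounded zero-censored latent
normal) that reproduces the study's descriptive structure and gives every
downstream stage known ground truth to be tested against.

## Worked example

```python
import genderpaths as gp

an = gp.add_analysis_columns(gp.generate_cohort(gp.GeneratorConfig(seed=1, n=2000)))
r = gp.mediate(an, "gender", "autonomy", n_boot=500, seed=42)
```

prints (see `examples/05_mediation.py`):

```
gender -> autonomy -> CES-D
  a  =  -0.24 (-0.42; -0.05)
  b  =  -2.05 (-2.73; -1.37)
  c' =   1.17 (0.50; 1.84)
  indirect =  0.12 bootstrap 95% CI (0.03; 0.22)
```

Reading: feminine workers have lower log-odds of high autonomy (a < 0);
high autonomy predicts fewer latent depressive symptoms (b < 0); their
product — the indirect effect, 0.12 latent CES-D points with a CI excluding
0 — is the share of the gender gap carried by autonomy, while c′ ≈ 1.2 is
the direct gender gap that remains. The `examples/` directory walks through
every capability (simulation, index construction, tobit fits, moderation,
mediation, imputation/pooling, the full pipeline); a thin CLI
(`genderpaths simulate|index|fit-tobit|moderate|mediate|impute|pipeline`)
exposes the same stages for shell use.

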