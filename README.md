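# fpecea — cost-effectiveness of group-based fall-prevention exercise

`fpecea` is a health-economic decision model for group-based fall-prevention
exercise (FPE) offered to independently living people aged 75 and over,
evaluated against no intervention from the perspective of the German
statutory health insurance (SHI). It is written for health economists and
HTA analysts who want a fully scriptable, testable Markov cohort analysis
of this intervention: the primary outcome is the
incremental cost-effectiveness ratio (ICER) in € per avoided hip fracture.

## The model

A closed cohort enters at age 75 in the *well* state and is tracked over
50 six-month cycles (25 years) through six health states:

```
well → hip fracture (acute, tunnel) → post-fracture ⇄ (re-fracture)
                  ↘ nursing home ⇄ re-fracture in nursing home
every state → death (absorbing)
```

Per-cycle transition probabilities are age-band- and sex-specific; nursing
home admission is possible only in the first cycle after a hip fracture and
is irreversible. The intervention multiplies the first-fracture probability
by an effective risk ratio

```
RR_eff(t) = 1 − participation · m(t) · (1 − RR),   RR = 0.73 (95% CI 0.56–0.95)
```

where the adherence multiplier m(t) decays proportionally by 28% per
program year and is zero from year 4 on. Costs comprise the program fees
(€139/93/49/5 per year, decaying with adherence), hip-fracture treatment
(€7,280 hospital + €961 revision + €2,209 rehabilitation + €1,114
outpatient per fracture) and long-term care by state of residence. Costs
and outcome counts are discounted at 3% per year (configurable).

On top of the deterministic base case the package provides one-way
sensitivity analysis with tornado ranking, best-/worst-case scenarios, a
vectorised 10,000-iteration probabilistic sensitivity analysis (beta /
gamma / lognormal parameter distributions) with cost-effectiveness
acceptability curves, two structural model variants (non-fracture
nursing-home admissions; vertebral-fracture states with a combined
outcome), a budget-impact extrapolation, and an individual-level
microsimulation that serves as an independent verification oracle for the
cohort engine.

## Worked example

The bundled base case reproduces the deterministic analysis for women:

```
$ fpecea base-case --sex women --out out/
       row  total_cost  cost_intervention  cost_treatment  cost_ltc  hip_fractures  refractures  nh_admissions  icer
       fpe       30400                265            2284     27850         0.1975       0.0489         0.0244
    no-fpe       30219                  0            2323     27896         0.2009       0.0499         0.0246
difference         180                265             -39       -46        -0.0033      -0.0010        -0.0002 53831
ICER: €53,831 per avoided hip fracture
```

Reading the table: a woman entering at 75 accumulates an expected €30,219
in present-value costs without the program, and 0.2009 expected hip
fractures (0.0499 of them re-fractures). Offering FPE costs €265 per
person in fees, averts 0.0033 fractures and recoups €85 in treatment and
care costs, so each avoided hip fracture costs the payer €53,831 — far
above any conventional willingness to pay, which is the analysis' central
finding. The same run for men gives €107,760 per avoided fracture.

The probabilistic analysis and the acceptability curve:

```
$ fpecea ceac --n-iter 2000 --seed 3 --out out/
women: P(CE | WTP=0) = 0.484
men:   P(CE | WTP=0) = 0.477
```

Library use mirrors the CLI:

```python
import fpecea

params = fpecea.base_case()
result = fpecea.run_cea(params, sex="women")
print(result.icer)                      # 53831.4...
psa = fpecea.run_psa(params, 10_000, seed=1, sex="women")
curve = fpecea.ceac(psa)                # WTP grid -> P(cost-effective)
```

Parameter files are plain CSV/YAML (see `src/fpecea/data/base_case/`); the
structural variants and the budget-impact population table use the same
schema. Files named `*_synthetic.csv` are constructed demonstration
stand-ins, not published inputs.

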