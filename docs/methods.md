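# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with a 6-month cycle
over a 25-year horizon (50 cycles), entry at age 75, run separately for
women and men. States: WELL, HIP_FRACTURE (acute tunnel, occupied for
exactly one cycle), POST_FRACTURE, NURSING_HOME, NH_REFRACTURE (acute
tunnel) and DEAD (absorbing). A re-fracture during the acute window is a
self-loop on the tunnel state and counts as a new fracture event;
re-fractures at home re-enter the tunnel from POST_FRACTURE; nursing-home
residents re-fracture into NH_REFRACTURE and, surviving, return to
NURSING_HOME. Nursing-home admission is possible only on leaving the acute
state and is irreversible.

Transition probabilities are taken per 6-month cycle as given in the input
tables, by age band (75–79, 80–84, 85–89, 90–94, 95+; long-term-care costs
use 90+ as the top band) and sex. The 95+ pre-fracture and acute-fracture
mortalities equal the 90–94 values because the underlying sources stop at
90+. Age advances by half a year per cycle; band lookup uses the integer
part of the age at the start of the cycle.

### Row composition

The sources do not state how competing transitions combine, so the package
fixes conventions:

- WELL row: fracture, death (and, in variant I, other-cause nursing-home
  admission) compete **additively**; the residual stays WELL. This keeps
  the well-state fracture probability exactly equal to its input value.
- All post-fracture rows: **mortality first**, then conditional splits
  among survivors (nursing-home admission and re-fracture from the acute
  state; re-fracture from POST_FRACTURE and NURSING_HOME), residual to the
  default destination. Rows therefore sum to one by construction; a
  parameter combination whose conditional splits exceed probability one
  raises a structured error naming the state and cycle.

### Intervention effect

The program multiplies the first-fracture probability by
`1 − participation · m(y) · (1 − RR)` with RR = 0.73 (95% CI 0.56–0.95).
`m(y)` is the residual-adherence multiplier in program year `y` (0-based):
proportional decay of 28% per year, `m(y) = 0.72^y`, truncated to exactly
zero from year 4. The *proportional* (geometric) reading of the annual
decrease was preferred over a linear `1 − 0.28·y` ramp; both are available
through the configuration (`annual_decay_fraction`,
`effect_zero_after_years`). The RR applies to first fractures only — it
stems from trials in community-dwelling people at average risk — and, in
variant II, to vertebral fracture incidence.

The participation rate dilutes the effect for offered individuals who
never take part. It is not identifiable from the cost tables; the default
of 0.7 reflects typical uptake of structured group-exercise offers among
community-dwelling German elderly and is a plain configuration scalar.

### Costs and discounting

Costs accrue on entry into each cycle's destination state (no half-cycle
correction; a configuration switch exists): long-term care per 6 months by
state occupied (well / post-fracture (also the acute cycle) / nursing
home), treatment per incident hip fracture (hospital + revision +
rehabilitation + outpatient, €11,564 total at base case), and program fees
as half the annual fee per cycle, charged to WELL occupants of the
intervention arm during program years 1–4.

Costs **and outcome counts** are discounted at 3% per year by default
(`discount_rate`, `discount_outcomes`), the German guideline convention
for health-economic evaluation. The reported per-person totals, fracture
counts and admissions are therefore present values; undiscounted
accounting is one switch away. The ICER divides the unrounded discounted
cost increment by the unrounded discounted fractures averted.

## Sensitivity analyses

One-way analysis moves one parameter *group* (all age-band cells of a
clinical parameter, a cost category, the fee schedule, or the RR over its
95% CI) to its stored bounds: ±20% for probabilities without published
intervals, ±40% for treatment and care costs, ±50% for fees. The tornado
ranks groups by the absolute ICER spread. Best case combines low fees,
high treatment/post-fracture-care costs and RR = 0.56; worst case is the
mirror image.

The probabilistic analysis draws probabilities from beta distributions
(method of moments: mean = point estimate, SD = range width / 3.92; a
non-fittable cell falls back to a ±20% uniform with a warning), costs from
gamma (mean = point estimate, SD 40%, fees 50%) and the RR from a
lognormal fitted to its 95% CI. Draw granularity follows the input tables:
flat cells (treatment components, nursing-home care) get one draw per
iteration; age-banded care costs and per-year fees get independent draws
per band/year. Probabilities and the RR are shared by both strategy arms;
**cost parameters are drawn per arm** (`cost_draws="per-arm"`), so cost
uncertainty does not cancel in the increments. This branch-wise assignment
— familiar from decision-tree software where distributions attach to
branch nodes — is what produces the characteristic acceptability curve
that starts near 50% at zero willingness to pay and rises shallowly;
with fully shared draws (`cost_draws="shared"`) the curve instead starts
near zero and saturates quickly. Net monetary benefit ties at exactly zero
count as not cost-effective. All draws come from one seeded generator in
fixed table order, so a seed reproduces the sample bit for bit.

## Structural variants

Variant I adds other-cause nursing-home admission from WELL and
POST_FRACTURE (composed before the residual self-loop). Variant II adds an
acute vertebral-fracture tunnel and a post-vertebral state; vertebral
incidence is RR-modified, vertebral events carry their own treatment cost
and care level, and the outcome becomes combined hip + vertebral fractures
avoided. The variants' parameter values are supplied by the user in the
standard schema; the bundled `variant_*_synthetic.csv` files are
constructed stand-ins with plausible magnitudes for demonstrations and
qualitative tests (null-parameter variants reproduce the base case to
machine precision; directional effects on the ICER are asserted, exact
magnitudes are not).

## Budget impact

Per (age, sex) stratum of a user-supplied population table the cohort
model is re-run with that entry age, the horizon truncated at the
stratum's remaining life expectancy (capped at age 100), and the
incremental cost annualised as total over the truncated horizon divided by
the horizon in years, then multiplied by the head count. The result is
linear in counts by construction. National population and life-expectancy
inputs are deliberately not bundled.

## Verification: the microsimulation oracle

`fpecea.microsimulate` pushes individual sample paths through exactly the
same per-cycle transition matrices by categorical sampling and accrues the
same costs and events. Individual *i* consumes row *i* of a pre-drawn
uniform matrix derived from the master seed, so results are independent of
iteration order. The central correctness property — asserted in the test
suite for the base case (150,000–200,000 individuals) and for randomly
perturbed parameter sets (25,000 each) — is that the cohort trace's
expectations fall within 3 Monte Carlo standard errors of the
microsimulation means for costs, fractures and admissions. With
deterministic (0/1) transition rows the two engines agree exactly.

The synthetic-data generator draws complete parameter sets around the base
case with the PSA distributions scaled by a perturbation factor (scale 0
returns the base case exactly). It emulates parameter uncertainty only; it
does not emulate structural misspecification, patient-level heterogeneity
within an age band, or secular trends in fracture incidence — so passing
oracle and property tests validates the arithmetic of the engine, not the
external validity of the inputs.

## Numerical choices, conventions, limitations

- Occupancy vectors are checked to sum to 1 within 1e-9 per cycle; matrix
  rows within 1e-12.
- The deterministic engine and the PSA share one vectorised code path
  (parameter draws enter as an extra array axis), so a 10,000-iteration
  PSA runs in seconds and cannot diverge from the base-case semantics.
- Tie-breaks: ICERs are reported only in the north-east quadrant
  (extra cost, fractures averted); dominance and undefined cases carry
  flags rather than infinities. NMB ties count against the intervention.
- Table inputs are consumed as printed; one garbled cell in the source
  table of well-state care costs (85–89 band) was restored from the age
  progression of the surrounding cells.
- Known reproduction limits: with the conventions above the women's ICER,
  all per-arm totals and the acceptability-curve anchors match the
  published analysis within a few percent, but the published men's
  incremental fracture count (0.0013) implies a sex-specific offset that
  no printed parameter generates; the model computes ≈0.0020 averted
  fractures for men and hence a lower men's ICER (≈€108k vs €170k).
  Likewise the published nursing-home admission proportions exceed what
  the printed single-opportunity admission probabilities can produce;
  admissions are nearly cost-neutral here, so costs and ICERs are
  unaffected. Both gaps are documented rather than patched with
  unpublishable fudge factors.
- QALYs, fracture sites other than hip/vertebral, short-term nursing-home
  stays, delayed fracture-related admissions and mental-health or
  cardiovascular co-benefits are out of scope.
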