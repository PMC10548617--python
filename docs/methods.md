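# Methods

## Scope and model

`norscba` evaluates a virtual overdose monitoring service from a payer's
perspective.  The benefit side is the economic value of overdose deaths the
service averts; the cost side is the program's operating budget plus the
medical-systems cost of the overdose responses it triggers.  The analysis
is deterministic given its inputs; all randomness lives in the synthetic
log generator and the Monte Carlo over mortality, both seeded.

### Medical-systems cost (TMSc)

Each EMS-attended overdose is priced as ambulance fee + emergency-department
visit + physician assessment + one nasal naloxone kit + the *expected*
hospitalization cost (admission probability × admission cost).
Hospitalization enters as an expectation, not a sampled count, so TMSc is an
exact linear function of the tally.  False-positive EMS dispatches cost one
ambulance fee; a community-based response costs one naloxone kit — the only
supply it consumes, which is also why the community response cost parameter
defaults to the naloxone price.  Non-overdose EMS call-outs (psychosis,
domestic violence, break-ins during a monitored session) are tallied but not
priced: they are not part of the overdose pathway the model costs.

The hospital-pathway count `T_OD` defaults to the EMS call-out count
`T_EMS`: every EMS-attended overdose enters the ambulance/ED/admission
pathway, and no separate hospital-transport count is observed.

### Value of a prevented death

The human-capital approach: average annual income in the age band containing
the median age of death from drug toxicity ($73,530 2022 CAD), times an
assumed employment rate (0.67), times the productive years remaining between
the median age at death (38) and the average retirement age (64.8), i.e.
26.8 years — $1,320,304.68 per death.  No discounting of future earnings and
no QALY/DALY weighting is applied; the output is undiscounted lost
productivity.  This valuation is conventional in supervised-consumption-site
evaluations and is ethically contested; it is a comparability choice, not an
endorsement.

### Deaths averted

`Np = N (Pn − Pi)` with `N` the unique overdosing clients, `Pn` the death
probability after an unwitnessed overdose and `Pi` the on-service death
probability.  Base case: `Pi = 0` (no deaths have occurred on the line) and
`N` counts unique callers per funding period (13 + 10 = 23), the
conservative choice; unknown-caller events (4) can be included via
`include_unknown_callers`, giving N = 27.  Caller uniqueness is evaluated
within each period independently, so the combined N is the sum of
per-period unique counts.  `Pi > Pn` is permitted but warned about: it
models a harmful service and produces negative deaths averted.

### Net benefit and ratio

`TCB = value of deaths averted − operating cost − TMSc`; the benefit-to-cost
ratio shares the denominator `operating + TMSc`, which makes
`ratio > 1 ⇔ TCB > 0` an identity the tests assert.  The reported ratio
range evaluates the ratio at the endpoints of the `Pn` literature range
(8–80%) — the arithmetic of the published interval matches that construction
exactly, so no percentile interval is used for it.

## Uncertainty

- **Monte Carlo over `Pn`** — the sampling distribution is configurable
  (uniform, triangular, or fixed); the default is uniform over the 8–80%
  literature range with 100,000 draws and an explicit seed, since no
  distribution is established in the literature.  Summaries are the mean and
  central 95% percentile interval of `Pn` and of `N·Pn`.  Main tables use
  the fixed 0.45 point estimate.
- **`Pi` interval** — with zero observed on-service deaths, the 95% upper
  bound uses the exact Garwood construction (chi-square quantile inversion
  of the Poisson tails) rather than a normal approximation, which collapses
  at zero counts.  Tests cross-check it against a direct tail-sum inversion.
- **Scaling grid** — deaths averted `round(N(Pn − Pi))` for service sizes
  1,000–10,000 and `Pi` from 0 to 0.7% (half-up to the nearest integer).
- **Two-way grid** — net benefit and ratio across operating-budget
  multipliers (40–200%) and `Pn` (8–80%).  Only the operating budget is
  scaled; medical costs are held fixed, since they vary with utilization,
  not with the program budget.
- **Break-even mortality** — `total cost / (N · VOL)`, the `Pn` at which the
  ratio crosses 1 (≈ 0.052 under the bundled profile).

## Numerical choices

Currency is exact `Decimal`; floats convert through their shortest decimal
repr.  Rounding is half-up to cents, applied once per reported component
(component sums, value of deaths averted, per-response savings) — this
reproduces the published tables to the cent.  Ratios are kept unrounded
internally and displayed at 2 decimals; grid death counts round half-up to
integers.  Division by a zero total cost or zero life-years raises rather
than returning infinities; an empty log yields zero tallies and a ratio
flagged as NaN.

The bundled `nors2022` profile's total operating cost is the sum of the two
per-period budgets ($787,500.00 + $580,875.00 = $1,368,375.00), from which
all published ratios derive; the separately reported program-funding figure
($1,366,749) is stored as metadata and can replace the combined-total row
via `use_reported_operating_total`.  The $1,626 difference between the two
figures is not explained in the source material.  Similarly, the published
per-community-response saving ($4,350.81) differs from the formula value
(expected EMS-pathway cost $4,475.82 − $125 = $4,350.82) by one cent, and an
abstract-level figure of $4,470.82 is inconsistent with both; the package
computes from the formula and tests agreement within $0.10.  The published
per-period prevented-death counts (21/7/28) are not derivable from
N = 23 × 0.45; the life-years table therefore accepts prevented-death
counts as direct inputs rather than endorsing a derivation.

## Synthetic data

The generator emulates the service's call structure: multinomial call
categories, Bernoulli overdoses within substance-use calls, EMS vs
community response assignment, rare false-positive and non-overdose
dispatches, and Dirichlet-multinomial caller weights so overdoses
concentrate in few callers (tunable concentration; the field reports the
top 1% of supervised-consumption clients accounting for ~25% of overdose
events).  Default rates are calibrated to the observed totals (e.g.
overdose probability 60/3113 per substance-use call).  Timestamps are
uniform within each period; no day/night or seasonal structure, call
durations, staffing or geography are modelled, and callers do not recur
across periods.  Passing tests on generated logs therefore demonstrate
correct accounting and rate recovery, not realism of temporal or
caller-linkage structure in real call logs.

A separate hand-built deterministic fixture (`nors_fixture`) reproduces the
published outcome table cell-for-cell and drives the end-to-end tests; it
is synthetic, constructed to match published aggregates, not real client
data.

## Problem sizes

The test suite runs the full pipeline on the 5,159-record fixture, 200
generator replicates at 200 calls each for rate recovery, and Monte Carlo
summaries at 10,000–100,000 draws; the whole suite completes in a few
seconds on one CPU.

## Limitations

Morbidity, quality-of-life, referral and mental-health de-escalation
benefits are not valued; no ICU or rehabilitation costing (none was
observed); no record linkage of callers to health records; no
province-specific fee schedules beyond the stored ranges; no joint
probabilistic sensitivity over cost parameters (only `Pn` and the operating
budget vary).
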