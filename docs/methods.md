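# Methods

## Problem setting

Insurance claims in several European countries record drug deliveries but
no diagnoses. Treated diabetes can nevertheless be phenotyped from
deliveries of ATC group A10 (drugs used in diabetes: `A10A` insulins,
`A10B` oral hypoglycemic agents, OHAs), because these drugs have no other
indication in routine use. The package implements the full chain from raw
delivery records to validity-bounded prevalence estimates, plus a
synthetic-data generator that stands in for the (non-distributable) real
claims.

## Case definition

A *delivery* is a distinct (patient, date) pair among prefix-matched
claims: several reimbursement lines from one pharmacy visit count once.
Raw-line counting is available (`distinct_dates=False`) but inflates the
criteria counts. ATC matching is case-insensitive string-prefix matching;
no ontology lookup is attempted. The claim year is the calendar year of
the delivery date (ISO-8601).

A single delivery threshold of ≥3/year is the canonical cross-sectional
definition of treated diabetes in claims (it screens out prescription and
coding errors). For a longitudinal window the definition is relaxed into
four criteria (see README); the qualifying years need **not** be
consecutive, since treatment gaps are common — a `consecutive_years`
switch restores the stricter reading. For criterion 2 the year with ≥3
deliveries does not double-count toward the two ≥2-delivery years
(otherwise criterion 2 collapses into a weaker criterion 1);
`overlapping_criterion2=True` selects the other reading. Criterion 4's
fixed years are generalized to the last two years of the phase-1 window so
the algorithm ports to any study window; the death year is the calendar
year of the death date.

Detection runs phase 1 on the reporting window and re-evaluates all four
criteria on the full history for patients phase 1 missed (both phases use
the same predicates; the phase label is recorded). For the per-criterion
breakdown a *primary criterion* is attributed lowest-number-first, except
that criterion 4 — a truncation rescue, not a clinical pattern — is
attributed only when nothing else matches. All satisfied criteria are
recorded regardless.

## Type classification

Step 2 classifies every OHA-exposed case as type 2: OHAs are not a type-1
treatment. Step 3 handles insulin-only cases, whose OHA history may simply
predate the window: those strictly older than threshold *y* at their first
insulin delivery are re-claimed as type 2 ("older than *y*" is read as
age > y; an inclusive switch exists). Age is event year minus birth year —
claims registries carry birth year, not birth date.

*y* is estimated from the switch cohort: OHA-exposed cases whose last
`A10B` year precedes at least one later `A10A` delivery and who never
return to OHAs within the horizon. The switch year is the first insulin
year after the last OHA year; *y* = ⌊mean(switch year − birth year)⌋
(floor, matching the convention that an estimated 66.3 is applied as 66;
nearest-integer rounding is available). Patients alternating OHA/insulin
with a trailing OHA segment are not switchers. Switchers without a birth
year are dropped with a logged count; with no switchers at all a
configured default (66) applies. The operational definition of "switched
to insulin alone" (persistence to the end of the observed horizon, one
trailing insulin delivery sufficing) is a design choice of this package
and is recorded in the cohort output.

Known limitation, inherent to the rule: every type-1 patient whose first
insulin delivery falls after age *y* is misclassified type 2. In elderly
age classes type 1 is rare and care pathways converge, so the impact is
bounded — and it is exactly what the validity bounds quantify.

## Validity bounds without a gold standard

Let POPtot = Pos + Neg be the classified population and T2P the unknown
true type-2 proportion, D2 = T2P·POPtot, D1 = POPtot − D2. For fixed T2P
the confusion matrix is a one-parameter family in FN:

    TP = D2 − FN,  FP = Pos − TP,  TN = Neg − FN,

with FN ranging over all values satisfying 0 ≤ FN ≤ min(Neg, D2, fn_cap)
and FP ≤ min(D1, fp_cap). The default caps encode the extreme scenarios at
the endpoints of the T2P range — fp_cap = Pos − T2P_min·POPtot (at the
lower extreme every classifier negative is truly negative, FN = 0) and
fn_cap = T2P_max·POPtot − Pos (at the upper extreme every positive is
truly positive, FP = 0). D2 is kept real-valued in all ratios; counts are
rounded only for display. Metrics are reported in percent at one decimal,
rounded half-up. The implementation is verified against exhaustive
enumeration of every consistent integer assignment on small populations.

The T2P range itself is not estimable from deliveries; it is configuration
(default [0.928, 0.967]), optionally pooled from per-age-class bounds by
`t2p_range_from_classes` (share-weighted sums). The per-age-class capping
that a finer decomposition would induce on interior grid rows is exposed
through explicit `fp_cap`/`fn_cap` arguments but not defaulted, because
the class-level inputs behind it are generally not published; with default
caps the extreme rows are exact and interior intervals are conservative
(slightly wider TP/SE/PPV lower bounds than a class-capped computation
would give).

`discharge_crosscheck` counts rejected patients carrying an ICD-10 E10–E14
hospital discharge (3-character root match). It reports the raw count and
leaves the denominator to the caller, since several denominators
(rejected, preselected, covered population) are defensible.

## Prevalence, trends, projection

A case is prevalent each year from their first A10 delivery (searched over
the full claims horizon, not just the reporting period) until the period
end or death; the death year counts — a patient treated in their death
year was a treated case that year. Rates are published only for the
reporting period (default 2000–2006), where claims coverage is complete.

Stratified rates use 10-year age classes [0,10) … [90,100] by default;
persons with missing sex or birth year are excluded from the affected
strata with a logged count. Direct age-standardization is
Σ weight(class)·rate(class) against a reference age structure whose
weights must sum to 1; classes missing a rate raise an error unless
explicitly imputed zero.

The trend summary is the arithmetic mean of year-over-year relative
changes (a geometric-mean variant exists); the linearity check is the R²
of OLS rate-on-year. Projection uses **Brown's** double exponential
smoothing — single constant α, both smoothed statistics initialized at the
first observation, forecast(h) = level + h·trend from the final state — with
α selected from the grid 0.05…0.95 (step 0.05) by minimum in-sample
one-step RMSE (first observation excluded from the error). Brown's method
is exact on a linear trend once transients decay, which matches the
near-linear series this method targets; Holt's two-parameter variant was
deliberately not used since a single smoothing constant is the stated
selection criterion's natural companion and keeps the grid search
one-dimensional. Binomial (Wald) confidence intervals for prevalence are
available but no claim is made that they match any particular published
interval, whose method is typically unstated.

## Synthetic populations

`simulate_population` draws a covered population of `n_population` persons
and assigns roles: treated type 2 (default 4%), treated type 1 (0.2%,
i.e. ~5% of diabetics), sporadic "noise" users (2%), background. All
randomness flows from one seeded generator; identical configs give
byte-identical tables.

* **Type 2** onset years are uniform over the horizon with onset ages
  ~N(60, 12) clipped to [30, 95]; treated years receive `3 + Poisson(μ−3)`
  OHA deliveries (μ = 5 by default), so *adherent* patients refill at
  least quarterly and any adherent patient treated ≥2 full years satisfies
  criterion 1 by construction — this is what makes perfect recall on the
  adherent stratum a provable property rather than a tuning outcome.
* **Switchers** (15% of type 2) move to insulin-only in a year drawn
  within the horizon, at ages ~N(66.3, 5) — the fraction is deliberately
  larger than in a national population so that a 5,000-person test
  population still yields a cohort (~30) from which the mean switch age is
  recoverable to within ±2 years; a realistic per-population switch rate
  of ~1% would leave the estimator no data at this scale.
* **Travellers** (3% of type 2) fill exactly twice a year for ≥3 years:
  the population criterion 3 exists for.
* **Type 1** patients receive insulin only, from onset ages ~N(18, 8).
* **Noise users** get 1–2 deliveries in one year — rejected by all
  criteria by construction, emulating prescription/coding errors.
* **Deaths** follow an annual Gompertz hazard 2·10⁻⁵·e^(0.09·age)
  (capped at 0.7), truncating claims at the death date.
* Delivery dates within a year are jittered around a ~28-day refill grid.

What the generator does **not** emulate: dosage/DDD structure, insurance
churn, combination therapy (simulated type-2 patients take OHAs *or*
insulin, never both in one year), seasonal refill patterns, or
age-specific onset incidence beyond the Gaussian onset-age draw. Passing
tests therefore demonstrate the algorithm's logic and its behaviour under
the stated trajectories, not its operating characteristics on any real
population.

Presets: `tiny` (n=400, unit tests), `luxembourg_like` (n=5,000, ~4%
treated type-2 prevalence, switch ages centred on 66.3), `high_noise`
(8% sporadic users). Problem sizes were chosen so the full suite runs in
seconds while leaving every stochastic check statistically meaningful.

## Numerical and degenerate-input conventions

* Percent displays: one decimal, ties rounded half-up (`round_half_up`);
  internal arithmetic is full double precision throughout.
* Empty claims → empty delivery matrix, not an error; empty criterion set
  → patient not a case; empty switch cohort → configured default
  threshold with a warning.
* Denominator tables must be positive; a missing year/stratum denominator
  is an error naming the stratum rather than a silent zero.
* DES requires ≥3 observations; α strictly inside (0,1); RMSE ties on the
  α grid resolve to the smallest α (first in the grid).
* Completeness proportions on empty tables are NaN (undefined), not 0.

## Testing strategy

Criterion logic, confusion-matrix intervals and DES α-selection are each
checked against independent brute-force oracles (explicit subset
enumeration, exhaustive integer assignment, re-stated recursions).
Invariants — monotonicity of detection in deliveries, partition of the
case set, convexity of standardization, no claims after death — run as
seeded/derandomized property tests. Published-figure checks use only
numbers that are mutually derivable from printed totals.
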