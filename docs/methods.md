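# Methods

## Model structure

The natural history of cervical disease is a discrete-time Markov chain
over eleven states: Normal, low-grade squamous intraepithelial lesion
(LSIL), high-grade lesion (HSIL), local/regional/distant invasive cancer,
treated counterparts of the three cancer stages, and two absorbing death
states (cancer death, other-cause death). Cycles are monthly. LSIL sits
below the CIN2+ treatment threshold, so screening "true positives" are
HSIL and invasive cancer.

Within a cycle, competing risks are resolved in a fixed order: background
(all-cause) death applies first; conditional on surviving it, the monthly
disease event probabilities (progression, regression, cancer death, cure)
apply directly as probabilities, with residual mass remaining in state.
Rows are validated to be stochastic at every age; a parameter combination
whose event probabilities exceed one raises a construction error naming
the row rather than silently renormalizing.

Background mortality comes from an age-indexed life table of annual death
probabilities *q*(age), converted to monthly probabilities under a
constant hazard within the year, with the HIV standardized mortality
ratio applied on the hazard scale:

    q_m(age) = 1 − (1 − q(age))^(SMR/12)

The hazard-scale choice keeps *q*ₘ a probability for any SMR and matches
demographic practice; for small *q* it is within a few percent of simple
multiplication.

Women whose lesion treatment succeeds, and treated-cancer patients who
cure, return to Normal with no memory of prior disease: the transition
parameters are population aggregates over women with and without disease
history, so a distinct post-treatment compartment would double-count that
history and cancer recurrence is deliberately not modeled.

## Screening and treatment cascade

Seven strategies: preventative cryotherapy for all women without
screening (one visit), VIA screen-and-treat (one visit), Pap or HPV
testing (two visits: screen, then results and treatment), and the three
test pairs (three visits, joint sensitivity/specificity). All loss to
follow-up (32% for 2-visit, 48% for 3-visit cascades) occurs before the
final treatment visit: lost women incur every screening visit's cost but
receive no treatment, benefit, or side-effect exposure — the only
cost-consistent reading of a single aggregate LTFU probability per visit
count.

Screen-positive completers with HSIL (or false-positive Normal/LSIL)
receive ablative treatment, 80% cryotherapy / 20% LEEP, plus one month of
side-effect risk (1%/month; 16% of events major). HSIL treatment succeeds
with probability 0.9; treated LSIL/Normal incur cost without state
change. Screen-positive completers in a cancer state undergo colposcopy
(the staging gateway) plus the stage-specific cancer-care cost and enter
the corresponding treated state. Pair strategies charge both tests' unit
costs to every screened woman; only joint test performance is published,
so the restriction of the confirmatory test to first-test positives
cannot be priced separately, and the one-way ranges on screening costs
absorb the approximation.

The single "treatment effectiveness" parameter (0.9) plays two roles,
interpreted as: efficacy of ablative lesion treatment (HSIL reverts to
Normal with probability 0.9 at treatment), and a hazard reduction for
treated cancer (monthly cancer mortality and stage progression multiplied
by 1 − 0.9 = 0.1). Treated cancer cures at 0.15/month, exiting all
treated-state cost accrual.

Symptomatic presentation: untreated regional or distant cancer — in the
cryotherapy-for-all arm, among LTFU women, or after a false-negative
screen — is detected and treated with probability one in the month the
state is occupied (stage cost, treated state, palliative care in
subsequent months). Untreated local cancer remains undetected until it
progresses. No detection probabilities are published for this setting;
late-stage symptomatic presentation is the standard assumption, and the
policy is exposed as a `DetectionPolicy` configuration block so its
influence can be probed.

## Accounting

Costs (2014 USD) are tracked under a societal perspective (direct
medical, direct non-medical, and indirect/time costs) and a clinic
perspective (direct costs to the facility only); every societal unit cost
dominates its clinic counterpart, and this ordering is validated at load
and propagates to lifetime costs. State-occupancy costs follow the
treated states: monthly palliative care for treated regional/distant
cancer and monthly side-effect risk for any treated-cancer state, both
starting the month after entry; the stage treatment cost is booked in the
detection/workup month.

Both costs and life-years discount at exactly 0.25% per month (the
published annual 3% figure's stated monthly counterpart, not
(1.03)^(1/12)−1). Life-years accrue 1/12 per live person at the start of
each month with no half-cycle correction; over a ~60-year horizon of
monthly cycles the correction would shift life expectancy by under 0.05
years, far below the differences of interest. Month 0 contains the
cascade and the first natural-history transition, so in the disease-free
constant-mortality limit discounted life expectancy is exactly the
geometric annuity Σₜ sᵗvᵗ/12 (s monthly survival, v monthly discount
factor) — this closed form is enforced in the tests to relative error
1e−6. The iteration stops when live mass falls below 1e−9 or the cohort
reaches the life table's closing age (100); headline life expectancy is
the discounted series, with the undiscounted series emitted alongside.

## Parameters

All inputs live in one flat YAML document (`data/base_case.yaml`),
validated by pydantic models: every probability bounded to [0, 1],
simplex vectors summing to one (to a 2e−3 tolerance that accommodates a
printed pair summing to 1.001, renormalized where consumed), one-way
ranges bracketing their base values, and societal ≥ clinic for every unit
cost. The CD4 ≤ 200 and CD4 > 500 scenario overrides (prevalence, initial
splits, SMR, progression, test performance) ride along in the document;
`apply_scenario` applies them, dropping the one-way ranges of overridden
cells (ranges describe the base case). Resolved scenario files
(`cd4_low.yaml`, `cd4_high.yaml`) are bundled for direct loading.

`enumerate_oneway` yields a low/high parameter set per ranged parameter
in table row order. Perturbing one component of an initial-split vector
rescales its complement proportionally so the vector stays a simplex;
cost ranges apply to the societal value with the clinic value scaled by
the same ratio (one printed range per cost row). The tornado analysis
reruns both strategies of a comparison at each endpoint and reports the
incremental-cost interval, sorted by bar width.

## Threshold analysis

The LTFU threshold solves for the 2-visit loss-to-follow-up at which
HPV's lifetime societal cost equals single-visit VIA's, varying only
`ltfu_2visit` (VIA, being single-visit, does not depend on it). Brent
root finding on [0, base LTFU] to within $0.01, with an explicit
"no threshold in range" error when the cost difference does not change
sign; tests cross-check the root against a 101-point grid search.

## Synthetic life table

The mortality schedule the study setting calls for is the WHO Kenya 2011
female life table, which is not redistributable here;
`read_life_table` ingests any CSV export of it
(`data/life_table_format.md` documents the layout and the 5-year → 1-year
conversion). For tests and offline runs the package bundles
`kenya_female_2011_synthetic()`: a deterministic Gompertz–Makeham
schedule, hazard a + b·cᵃᵍᵉ with a = 0.004/yr, b = 3e−5, c = 1.10 over
ages 15–100, closed with q(100) = 1. The Makeham constant represents the
flat HIV-era excess in young-adult female mortality; the parameters were
calibrated once to the era's summary indicators (probability of dying
between 15 and 60 ≈ 0.24) and are not tuned to any model output. The
stand-in reproduces the *shape* of adult mortality but not the WHO
table's exact levels, so qualitative strategy orderings and all
structural properties transfer to real data, while absolute costs and
life expectancies shift with the mortality level (the bundled table is
somewhat lighter at older ages than the WHO schedule, lengthening life
expectancy and with it discounted downstream costs).

## Microsimulation cross-check

`microsimulate` samples individual women through the identical cascade
and transition machinery — categorical transitions from the same monthly
matrices, sampled treatment modality, side-effect events and detection —
and reports mean cost and life expectancy with Monte-Carlo standard
errors. At 50 000 women per strategy the cohort engine agrees within
three standard errors on both outcomes; with degenerate (0/1)
probabilities a single trajectory reproduces the cohort result exactly.
The simulator shares no accumulation code with the cohort engine's
expectation arithmetic, so agreement exercises the cascade costing, state
reassignment, detection and discounting logic end to end.

## Problem sizes and runtime

A cohort run is one 11-state vector times ≤ 744 monthly matrices
(milliseconds). The scenario table is 21 runs; each tornado is 50 ranged
parameters × 2 endpoints × 2 strategies; the threshold bisection is ~40
runs; the microsimulation cross-check uses 50 000 women per strategy.
The full analysis suite completes in well under a minute on one CPU.

## Known limitations

- One lifetime screen at a fixed age; no periodic screening, no optimal
  screening-age search.
- No cancer recurrence and no CD4 drift over time (states carry no
  history).
- Age-binary test performance (<40/≥40) is not modeled; no stratified
  values are published.
- HPV-DNA carriage is not a separate compartment; the lesion-grade chain
  carries the dynamics the published parameters support.
- Cryotherapy's possible prevention of HPV acquisition is not modeled.
- Only one-way and scenario sensitivity analyses; no probabilistic
  sensitivity analysis.
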