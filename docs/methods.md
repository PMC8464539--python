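# Methods

## Model structure

The model couples a one-shot acute-phase decision tree (first 90 days) to a
yearly-cycle Markov cohort model over seven health states: modified Rankin
Scale (mRS) 0–5 and death. Two strategies are compared on the same cohort of
suspected-stroke patients receiving CTA: usual-care reading, and AI-aided
reading that recovers a fraction of the LVOs usual care misses. The
strategies differ *only* in the LVO detection rate and in a per-analysis
software fee; everything downstream (eligibility, outcome distributions,
costs, utilities, mortality) is shared.

### Acute phase

Detected, IAT-eligible LVO patients take the treated 90-day mRS
distribution; all other LVO patients take the untreated one. Missed-but-
ineligible and detected-but-ineligible patients receive no IAT either way
and are therefore outcome-identical: the tree collapses so that only
*eligible misses* drive the increment between strategies. Eligibility
(43.8%) is treated as independent of detection — nothing in the source data
suggests missed LVOs are differentially eligible. Acute costs are the
blended treatment averages (IAT-eligible $11,728, non-eligible $1,004), the
per-mRS 90-day management costs (death state included), the AI fee ($40 per
analysis, charged for every CTA patient in the AI arm since the software
screens all comers), and an optional linear false-positive reading-time
surcharge (`fp_rate_points × fp_cost_per_point`, default 0 — reported
elsewhere as negligible at $0.07 per percentage point). The acute phase is
undiscounted. Acute utility accrues over `acute_year_fraction` of a year
(default 90/365.25) at the 90-day state's utility; the convention is
configurable (set it to 0 to exclude acute QALYs) because published totals
round it away.

### Lifetime phase

Cycle t (t = 1..70) applies, in order: (1) background mortality at the
life-table probability `q_x` for age `age0 + t − 1`, with plateau
extrapolation beyond the table end; (2) recurrent stroke with annual
probability 2.84% among survivors. Recurrent-stroke outcomes follow the
untreated 90-day distribution under a no-improvement constraint, with two
implemented redistribution rules:

- `clamp_max` (default): new state = max(current state, drawn state); a
  death draw is always fatal. This honors "recurrence outcomes follow the
  untreated distribution" while never letting a recurrence improve the mRS.
- `truncate_renormalize`: draw from the untreated distribution restricted
  to states ≥ current (death included), renormalized.

The hazard ordering (mortality, then recurrence) changes results by well
under 0.1% at these magnitudes but is fixed for determinism. Accrual is
end-of-cycle on the post-transition occupancy with discount exponent t
(costs 4%/yr, utilities 1.5%/yr); there is no half-cycle correction, and
cycle 1 is a full year starting at day 90. Recurrence does not re-trigger
acute-phase costs by default; the `recurrence_acute_costs` switch adds the
new state's acute cost in the recurrence cycle. There is no stroke-excess
mortality beyond the recurrence mechanism.

Patients without an LVO default to the `healthy` profile: mRS 0 utility,
zero stroke costs, background mortality only, no recurrence. All
*incremental* results are provably invariant to this choice (the non-LVO
branch is identical in both arms; the test suite asserts it); only the
percent-of-usual-care denominators depend on it, which is why those
percentages are approximate. Alternatives: `non_iat` (non-LVO patients
behave like untreated stroke patients) and `custom` (user-supplied
distribution).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_lvo` | 0.306 | LVO prevalence among CTA-receiving suspected strokes |
| `p_eligible` | 0.438 | IAT-eligible fraction of LVO patients |
| `p_missed` | 0.06 | LVO miss rate of usual care (varied 1–20% in scenarios) |
| `reduction` | 0.50 | fraction of misses recovered by AI (varied 1–100%) |
| `p_recurrent` | 0.0284 | annual recurrent-stroke probability |
| `age0`, `cohort_n` | 66, 71,840 | cohort starting age; yearly UK cohort size |
| `tx_iat`, `tx_no_iat` | $11,728, $1,004 | blended treatment cost per (non-)eligible patient |
| `ai_per_analysis` | $40 | software fee per CTA analysis |
| `discount_costs`, `discount_utilities` | 4%, 1.5% | annual discount rates |
| `cycles` | 70 | yearly Markov cycles |
| `wtp_per_qaly` | $25,662 | willingness-to-pay (£20,000 at the 2019 average rate) |

All costs are final 2019 USD; the package performs no inflation or currency
pipeline (the sources did that upstream), and `convert_currency` exists only
for willingness-to-pay derivation. Note £20,000 × 1.283 = $25,660; the
stored default keeps the published $25,662 rather than the recomputed
product. The mRS distributions and per-state cost/utility vectors are listed
in `config/base_case.yaml`.

## Life tables and synthetic inputs

Background mortality requires a national life table, which is not
redistributable here. `gompertz_life_table(a, b, c, max_age)` generates
synthetic tables with `q_x = min(1, c + a·e^{b·age})`; the defaults
(a = 3.5e-5, b = 0.094, c = 4e-4) give realistic adult mortality doubling
(~7.4 years). The bundled fixture `data/life_table_uk_synthetic.csv`
(= `uk_like_life_table()`, a = 1.93e-5, b = 0.0975, c = 2e-4, ages 0–100)
is instead calibrated to widely published UK 2017–2019 unisex magnitudes —
q(66) ≈ 1.2%, q(80) ≈ 4.7%, remaining life expectancy at 66 ≈ 18.5 years.
It is a synthetic stand-in, unisex and without the infant-mortality hump;
lifetime results computed with it reproduce published reference values to
within roughly 15%, not exactly, and passing tests therefore certify model
mechanics and magnitudes, not agreement with any particular national table
vintage. `random_params(seed, jitter)` perturbs every scalar by independent
uniform factors (probabilities clamped, distributions renormalized,
utilities kept monotone) for property testing; it emulates parameter
uncertainty, not sampling noise in real registry data.

## Numerical choices

- Distribution constructor renormalizes inputs whose sum is within 0.5% of
  1 (so printed rounded percentages load) and rejects anything further off.
- Occupancy rows conserve mass to 1e-9 and the death column is
  non-decreasing; both are asserted over 1,000 jittered parameter sets.
- In the zero-mortality, zero-recurrence limit the engine matches the
  closed-form discounted annuities to 1e-9 relative.
- The per-analysis fee enters the increment affinely with slope exactly 1;
  the price grid exploits this (one model evaluation per performance
  column), and a test verifies the shortcut against full re-evaluation.
- Threshold price is the fee nulling the increment, `p* = −IC(price 0)`,
  reported to the nearest dollar and floored at 0.
- Reports round dollars to integers and QALYs to 4 decimals; internal math
  is full precision. CSV round trips use `%.17g` on write and round-trip
  float parsing on read.

## Validation oracle

`microsim_oracle` simulates individual patients under the identical rules
(seeded, vectorized) and reports Monte-Carlo means and standard errors. The
deterministic cohort engine is required to agree within 3 standard errors at
n = 200,000 — a structural cross-check that the matrix propagation and the
per-patient rules implement the same process.

## Sensitivity analysis

`one_way_sensitivity` re-runs the comparison with one parameter at a time at
a low/high bound. Default bounds are ±20% on the clinical probabilities,
treatment costs, per-state cost vectors and discount rates (the parameters
not already swept in the scenario grid) and ±10 years on the starting age;
bounds are configurable per parameter. Rows are ordered by induced cost
spread (tornado order). At the default bounds the incremental cost stays
negative and the incremental QALYs positive, so dominance is robust; the
long-term cost scale and starting age induce the largest swings.

## Known limitations

- The `healthy` non-LVO profile makes absolute (not incremental) totals and
  percent-of-usual-care figures depend on an assumption about stroke-free
  patients' costs.
- No tunnel states, time-varying recurrence risk, post-recurrence treatment
  pathways, stroke-excess mortality, probabilistic sensitivity analysis, or
  modelling of time-to-treatment gains and AI false-positive overtreatment.
- The recurrence redistribution mechanics, within-cycle ordering and
  half-cycle convention are modelling choices exposed as configuration; the
  sources do not pin them down.
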