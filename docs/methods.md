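# Methods

## Model structure

The cost-effectiveness engine is a cohort Markov model with an annual cycle.
The live state space is EDSS 0–9 on the integer grid (half-point trial
levels are floored, so 6.5 maps to 6), duplicated into on-treatment and
off-treatment branches, plus one absorbing death state — 21 states. The
published description of the model is ambiguous between 9 and 10 EDSS
levels; the input tables parameterise ten columns (EDSS 0–9), so the
ten-level reading is used.

Within each cycle events occur in a fixed order:

1. **Death.** The age- and sex-specific background probability `q` (life
   table, sex-mixed with the cohort's 39.9% male share rather than
   simulating sexes separately) is scaled by the EDSS mortality multiplier
   `m` on the rate scale, `q' = 1 − (1 − q)^m`, capped at 1. Treatment has
   no direct mortality effect; it acts indirectly by slowing EDSS
   accumulation.
2. **Discontinuation.** On-treatment survivors below the stopping level
   stop with annual probability `1 − (1 − p₀)^HRd`, where `p₀` is the
   reference arm's baseline probability and `HRd` the arm's discontinuation
   hazard ratio. Discontinued patients revert to natural-history
   progression, keep management and relapse costs, accrue no further drug
   or administration cost, and never restart.
3. **EDSS movement.** On-treatment patients move by the efficacy-adjusted
   matrix, off-treatment patients by the natural-history matrix.
4. **Stopping rule.** Anyone arriving at EDSS ≥ 7 while on treatment moves
   to the off-treatment branch. On-treatment rows at or above the stop
   level discontinue with probability one, which keeps the operator well
   defined for the small (0.18%) EDSS-7 mass present at baseline, which is
   seeded on the on-treatment branch like the rest of the cohort.

Efficacy adjustment applies the CDP-6 hazard ratio to the aggregate
probability of moving to any higher EDSS level, row by row, on the rate
scale (`p' = 1 − (1 − p)^HR`), redistributing over the higher destinations
in their original proportions and absorbing the difference into the stay
probability. Improvement probabilities are untouched and the result stays
row-stochastic; the adjustment refuses hazard ratios large enough that a
row's stay probability cannot absorb the added progression mass. `HR = 1`
is an exact (bitwise) identity. Alternative event orderings differ at
O(q·p) and are not identifiable from published information; the ordering
above is fixed and documented.

The cohort starts at age 48.0 with the published baseline EDSS
distribution. The lifetime horizon is operationalised as age 100 (52
cycles) or live mass below 10⁻⁶, whichever comes first.

## Valuation

Costs and utilities are valued on start-of-cycle occupancy with no
half-cycle correction (the source model does not state one; the choice is
switchable by valuing a trace under a different rule). Cycle `t` is
discounted by `(1.03)^(−t)` for both costs and effects. Per cycle the model
accrues: live occupancy (life-years); occupancy × EDSS utility (QALYs,
negative at EDSS 8–9); management cost by EDSS band (€2,102 / €4,822 /
€8,052 for EDSS 0–3 / 4–6 / 7–9); expected relapses × €405, with the arm's
ARR relative risk applied on the on-treatment branch; and, for on-treatment
occupancy, annual drug cost plus administration/monitoring. Drug cost uses
a 365.25-day year with fractional packs: siponimod 365.25/28 packs ×
€1,890.9 = €24,666.12/year; interferon beta-1b 182.625/5 vials × €285.3 =
€10,420.58/year (Extavia pricing; Betaferon differs by under €0.01 per
vial). The year-1 versus later administration tariff is keyed to model time
(first cycle), not per-patient treatment duration; the distinction is
below the model's resolution and the alternative is a one-line change.
Relapses affect costs only; no relapse disutility is applied because the
utility inputs are defined by EDSS alone.

## Sensitivity analysis

Distribution families are assigned by standard practice (the source states
none): lognormal for hazard ratios and relative risks with
`σ = (ln hi − ln lo)/3.92` and median at the point estimate; beta for
probabilities and utilities; gamma for costs. Published ranges and 95% CIs
are read as 95% interval endpoints and moments are matched with mean = base
and SD = width/3.92; utilities with negative ranges use a location-shifted
beta on the range widened by half its width on each side. Relapse
probabilities have no published range and default to ±20%. Draws are
independent across parameters (no correlation structure is published);
mortality multipliers and the transition matrix are not varied by default,
with Dirichlet row-resampling of the matrix available behind a flag
(`sample_psa(..., vary_matrix=True)`). The PSA default is 5,000 replicates
(the published count is unstated). The tornado sets each parameter to its
bounds with all others at base; ties and the base case reproduce the
deterministic NMB exactly.

The CDP-3 scenario substitutes the 3-month-confirmed progression hazard
ratios (interferon beta-1b 0.74, siponimod 0.61) for the CDP-6 values and
reruns the identical pipeline.

## Budget impact

The eligible population comes from the multiplicative funnel
(59,641,488 × 0.2% × 13.7% × 91.8% × 60% × 65% × 99.6%). The running
product is carried unrounded between stages and integerised per stage only
for reporting; this reproduces the published stage counts (119,283; 16,342;
5,851; 5,827), which chained rounding of already-rounded stages cannot.
The population and its baseline EDSS occupancy are held fixed over the
3-year horizon: at this horizon the scenario difference is dominated by
drug-acquisition costs, and management/relapse costs cancel between
scenarios. Per-patient DMT costs are drug acquisition plus
administration/monitoring (first-year tariff for a DMT's newly gained share
relative to the prior year, with the pre-entry market as year-0) plus an
annual adverse-event cost. Ocrelizumab is costed at 600 mg twice a year
priced per 330 mg vial, read as 2 vials per administration: 4 × €6,250 =
€25,000/year (the printed 330 mg is preserved although marketed vials are
300 mg), with €1,150 / €363 first/later-year monitoring.

## Synthetic inputs

Several inputs of the original analyses exist only in unpublished appendix
material. The `synthetic_data` module generates structurally faithful
stand-ins; none claims to equal the unpublished data, and every headline
monetary output depends on them.

- **Transition matrix.** Band-dominant rows: one-level progression
  intensity 0.30 at EDSS 0 with gradient 0.97 per level, improvement 0.04,
  two-level jumps at 15% of the one-level mass, seeded log-normal jitter
  (SD 0.05). The defaults were calibrated to disease realism before any
  downstream result was inspected: the exact absorbing-chain expected time
  from EDSS 3 to EDSS ≥ 7 under natural history is 14.0 years, inside the
  8–18-year window pre-registered from published SPMS progression ranges.
- **Life table.** Gompertz hazard `h = a·e^(b·age)` with a = 1.65×10⁻⁵,
  b = 0.10, male hazards 1.6× female; q(48) ≈ 2 per 1,000, a plausible
  general-population level. Ages 18–100.
- **Discontinuation.** Baseline 0.10/year for interferon beta-1b (no
  published value exists); siponimod applies its hazard ratio 0.87 to it.
- **Adverse-event costs.** Flat annual: siponimod €150, interferon €300,
  ocrelizumab €200 — order-of-magnitude stand-ins, applied annually (the
  once-per-initiation alternative is configurable by editing the DMT spec).
- **Market shares.** Without-siponimod market: interferon 60%, ocrelizumab
  40%, flat. Siponimod uptake is logistic with ceiling 0.42, its rate and
  midpoint solved exactly so treated counts hit the published anchors of
  405 (year 1) and 2,236 (year 3) at 5,827 eligible. Displacement comes
  from interferon for 1.2% and 1.6% of the market in years 1–2 and zero in
  year 3, the remainder from ocrelizumab — reproducing the published
  qualitative pattern (interferon falls early, ocrelizumab late) and the
  positive/positive/negative annual budget signs.

Because the synthetic natural history is not the trial placebo matrix, the
packaged base case yields an ICER of roughly €93,000/QALY rather than any
published figure; tests assert structure (mass conservation, oracle
agreement, orderings, identities, calibration anchors, sign patterns), not
headline money values. What passing tests show is that the machinery is
correct and the calibration anchors hold — not that the packaged inputs
reproduce the original model's outputs.

## Numerical choices

- Row-stochasticity tolerance 10⁻¹²; cohort mass conservation tolerance
  10⁻⁹; live-mass cutoff 10⁻⁶.
- The cohort expectation is validated against a 200,000-walker seeded
  microsimulation using the same cycle operators (3-SE agreement at cycles
  1, 5 and 20); the microsimulation exists only as a test oracle.
- The progression hazard ratio is identifiable from a (natural, adjusted)
  matrix pair: a least-squares fit of aggregate upward probabilities
  recovers it to 10⁻⁶, used as an inverse-problem sanity check.
- CEAC ties (net benefit exactly equal) favour the reference arm, so
  per-WTP probabilities sum to one; the default WTP grid is €0–100,000 in
  €1,000 steps.
- ICER is flagged undefined (NaN) at ΔQALY = 0; dominance is flagged,
  never raised.
- Monetary strings may use dot or Italian decimal conventions; the locale
  is always explicit in the configuration, never guessed.

## Problem sizes

The deterministic lifetime run is 52 cycles and completes in tens of
milliseconds; the 5,000-replicate PSA completes in well under a minute on
one CPU. Property tests sweep 1,000 random model configurations at a
15-cycle horizon, chosen to exercise the dynamics densely while keeping the
suite fast.

## Known limitations

- No treatment-effect waning: full CDP-6 efficacy persists while on
  treatment, which likely flatters long-horizon effectiveness.
- No re-treatment after discontinuation, no treatment sequencing.
- Cohort-level sex mixing slightly misstates mortality relative to
  simulating sexes separately (the cohort's sex composition would otherwise
  drift as male mortality exceeds female).
- The budget model has no patient-level churn; "new to DMT" is approximated
  by share increments.
- NHS perspective only: no informal care or productivity costs, and no
  EVPI computation.
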