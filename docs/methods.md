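# Methods

## The decision problem

Community telemedicine screening for diabetic retinopathy (DR) photographs
the fundus at a local health centre and grades the image remotely. Two
grading arrangements are compared for an urban Chinese programme: grading
by retinal experts (*manual* arm) and grading by a convolutional-network
classifier (*AI* arm). The AI arm is slightly cheaper per attendee (US
$9.60 vs $10.10 on site) but imperfect at flagging sight-threatening DR
(STDR), so it misses cases a human grader would refer. The question is
whether the labour-cost saving justifies the effectiveness loss — a
cost-effectiveness (years without blindness) and cost-utility (QALY)
comparison from the societal perspective.

## Markov cohort model

A closed cohort of community residents with diabetes enters at age 65 and
is followed for 30 one-year cycles through eight states:

```
no DR -> non-STDR -> { STDR, DME } -> blindness -> death
                      (each: undetected | treated)
```

* STDR (severe non-proliferative / proliferative DR) and diabetic macular
  edema (DME) are parallel severe branches reachable from non-STDR; both
  carry the same utility (0.70) but different treatment costs (laser or
  vitrectomy vs anti-VEGF injections).
* Disease never regresses. Treatment only multiplies the annual
  progression-to-blindness probability by `rx_progression_multiplier`
  (default 0.35, range ±10%).
* Death is reachable from every state. An age-specific background
  probability is adjusted per state on the odds scale:
  `q = OR·o/(1+OR·o)`, `o = p/(1−p)`. Mortality applies as a direct
  competing probability within the row; the residual mass stays put, and a
  row whose composed outflow exceeds one is a configuration error.
* Blindness and treatment states distinguish a first year from subsequent
  years through inflow ("tunnel") bookkeeping rather than extra states:
  first-year costs are charged on the inflow mass, follow-up costs on the
  continuing mass. The expected values are identical to an explicit tunnel
  state and the state space stays at eight (verified against the
  individual-level oracle, which tracks the flags explicitly).

**Cycle order.** Screen → accrue cycle costs and utilities → transition.
Screening results return within weeks in the programme modelled, so
detection and treatment start fall in the same annual cycle. Utilities and
state-membership costs accrue from the state occupied at cycle start; a
`half_cycle` flag switches the membership accruals to the mean of
cycle-start and cycle-end occupancy (off by default — the comparison is
between two screening arms in the same model, so the correction nearly
cancels in the incrementals).

**Screening.** Each cycle, all alive states attend (the programme
re-screens diagnosed patients annually). Undetected STDR/DME mass moves to
the treated sub-state with probability `sensitivity × effective
compliance`; detected-but-noncompliant patients stay undetected and are
re-screened next year. Disease-free and mild mass generates false-positive
referral examinations at `(1−specificity) × effective compliance` — a cost
with no state change. Effective compliance is `clamp(compliance ×
multiplier, 0, 1)`; the multiplier (base 1.0, range ±25%) models the
behavioural effect of immediate AI feedback and applies to the AI arm only.

**Outcomes.** Costs and QALYs are discounted at 3.5%/year by cycle index.
Years without blindness accrue over all alive non-blind states and are
*undiscounted* by default (`discount_effects` flag to change): the
published summary figures are mutually consistent only if the
effectiveness measure is undiscounted while QALYs are discounted, and
NICE-style practice reports life-year-type measures both ways. ICER and
ICUR are the incremental cost divided by incremental years without
blindness and QALYs respectively, AI minus manual, reported per person and
per 100,000 screened.

**WHO threshold classification.** For a QALY-gaining intervention, cost
per QALY below 1× GDP per capita (US $22,600, Shanghai 2020) is *highly
cost-effective*, 1–3× *cost-effective*, above 3× (US $67,800) *not
cost-effective*. For a QALY-losing, cost-saving intervention the rule
reverses: savings per QALY lost above 3× GDP are *highly cost-effective*,
1–3× *cost-effective*, below 1× *not cost-effective*. Ratios exactly on a
boundary take the more favourable class (the source rules are open
intervals; the convention is configurable and tested both ways).

## Parameters

Every scalar input is a `ParameterSpec` with base value, low/high range,
distribution family and provenance tag. Ranges default to ±10% for
probability-type quantities, ±50% for costs and ±25% for the AI compliance
multiplier. Two provenance classes matter:

* **paper-text** — printed values, fixed: utilities 0.87 / 0.79 / 0.70 /
  0.55 (no DR / non-STDR / STDR incl. DME / blind; death 0), AI
  sensitivity 80.47% (range = its 95% CI, 75.07–85.14%) and specificity
  97.96% (96.75–98.81%), referral compliance 50.4%, screening costs
  $10.10/$9.60, first-year blindness burden $8,920 split 53.2%/6.4%/40.4%
  into direct-medical/direct-nonmedical/indirect, discount rate 3.5%, GDP
  thresholds, exchange rate 6.90 CNY/USD (any CNY-entered cost converts at
  load).
* **supplement-placeholder** — values the source study keeps in
  unpublished appendices: annual transition probabilities, the baseline
  state mix, the mortality table and odds ratios, referral-examination and
  treatment cost components, and the manual-grading accuracy range used in
  sensitivity analysis. These ship as plausible magnitudes chosen once so
  that base-case outputs land in the neighbourhood of the published scale
  (per-person lifetime cost ≈ $3,200–3,500, ≈ 6.75 QALYs, ≈ 9.8 years
  without blindness, ICUR ≈ $15,000 saved per QALY lost). That calibration
  keeps report formats and acceptance arithmetic on realistic scales; it
  is a convenience, **not** a reproduction claim, and every quantity that
  depends on a placeholder is labelled as such by its provenance tag.

The background mortality table is a Gompertz-like placeholder,
`q(a) = 0.0253·e^{0.082(a−65)}` for ages 65–94 (held constant beyond the
table), standing in for the published Chinese life table; state odds
ratios (1.8 / 2.2 / 2.7 / 3.4 for diabetic no-DR / non-STDR / STDR / blind)
encode the excess mortality of the diabetic cohort. Utility ordering
(no DR ≥ non-STDR ≥ STDR ≥ blind) is enforced on the base configuration;
one-at-a-time sensitivity excursions of a single utility may cross a
neighbour within its ±10% range, as is standard for independent one-way
sweeps and independent PSA draws.

Manual grading accuracy is 100% in the base case (double expert grading)
with `dist = fixed`, so it contributes to the tornado through its
trained-grader range but is not drawn in the PSA.

## Sensitivity analyses

**One-way DSA.** Each parameter in turn is set to its low and high
endpoint with everything else at base and the paired model re-run.
Entries are tornado-ordered by ICUR spread. Endpoints where the ratio
changes meaning — dominance, or a sign flip of the QALY difference — are
flagged and listed apart instead of plotted; the AI compliance multiplier
is the canonical flagged entry, and gets its own sweep
(`compliance_threshold_scan`) reporting the classification over a
multiplier grid on [0.75, 1.25] and the smallest multiplier reaching each
class.

**PSA.** 10,000 Monte Carlo draws. Families follow convention: beta for
probabilities and utilities, gamma for costs, log-normal for odds ratios
and the compliance multiplier. Fits are moment-matched with mean = base
and `sd = (high − low)/(2·1.96)`, treating the deterministic range as a
95% interval (the source gives ranges, not SDs; this is the standard
convention and is configurable by editing the ranges). The log-normal is
parameterised to match the mean and sd of the quantity itself, not of its
logarithm, since only a point value and range are available. One shared
draw feeds both arms, so incremental scatter reflects strategy structure
rather than sampling noise. Draws failing validation are rejected and
redrawn (counted; >1% triggers a warning naming the worst offender — the
shipped set rejects none). Acceptability curves use net monetary benefit
`NMB = λ·QALY − cost` over a grid from 0 to 3× GDP with both thresholds
forced onto the grid; ties split equally.

## Synthetic scenarios and the oracle

`generate_scenario(seed)` emulates the structure of the unpublished
appendices: printed values stay fixed, placeholders are drawn uniformly
from their deterministic ranges (the range moves with the drawn base,
preserving relative width), and the result must pass full validation.
This powers the property suites — conservation of probability mass,
row-stochastic matrices, monotone death occupancy — across a thousand
random parameterizations.

`microsim_oracle` is the independent check on the cohort engine: 200,000
individuals simulated with Bernoulli screening events and multinomial
transitions drawn from the *same* matrices, tracking first-year flags
explicitly. Agreement within Monte-Carlo error therefore validates the
expectation bookkeeping (including the tunnel accounting), not the disease
model itself. The validation suite runs 20 seeded scenarios and requires
the cohort value to sit within 3 standard errors in at least 19 of 20 per
outcome; the analysis driver prints the z-scores for inspection.

What passing these tests does **not** show: that the placeholder
magnitudes equal the study's unpublished values, or that the base-case
totals reproduce the published table. They show the machinery —
conversion, conservation, discounting, costing, ratio and threshold logic,
distribution fitting, CEAC accounting — is correct on any valid input.

## Numerical choices

* Rate↔probability conversion uses `log1p`/`expm1`; the round trip is
  exact to 1e-12 over p ∈ [0, 0.999].
* Occupancy conservation tolerance 1e-10 per cycle; transition-matrix row
  sums 1e-12.
* Ratios with a zero denominator are NaN and flagged; classification then
  falls back to the cost comparison.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical seed + config reproduces byte-identical CSV exports.
* Problem sizes in the shipped suites: 1,000 scenarios for conservation,
  20 scenarios × 200,000 individuals for the oracle, 10⁶ draws per
  distribution-recovery check, 10,000 PSA draws in the analysis scripts.

## Known limitations

* Placeholder parameters make absolute cost/QALY levels illustrative; only
  structure and printed values are faithful to the source programme.
* No correlation between PSA parameters (no copula), no EVPI.
* Whether follow-up anti-VEGF injections apply to all treated STDR or only
  DME is ambiguous in the source; here DME follow-up includes an injection
  plus review and STDR follow-up is a review plus retreatment allowance,
  with both costs independently sweepable.
* The cohort is homogeneous at entry (no individual-level heterogeneity in
  the engine; the microsimulation exists only as an oracle).
* No multi-way DSA, no more-than-two-strategy frontier.
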