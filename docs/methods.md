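# Methods note

This note documents the model implemented by `obesim`: structure,
assumptions, default parameters and their rationale, the scope of the
synthetic input generator, numerical conventions, open design decisions,
and limitations. Nothing here asserts an empirical result that is not
computed by the test suite or `scripts/acceptance.py`.

## 1. Model structure

A closed cohort is simulated deterministically at the level of cohort
means and occupancy fractions (no microsimulation). Cycles are annual;
the default horizon is 40 years. State is carried in a `CohortState`:
alive fraction, cohort-mean risk factors (BMI, SBP, TC, HDL, HbA1c),
glycaemic mix (normal glucose tolerance / prediabetes / type 2 diabetes),
chronic-state occupancies (T2D, sleep apnoea, post-ACS, post-stroke,
three cancers, post-knee-surgery), on-treatment fraction, and a parallel
*reference* risk-factor path evolved without treatment effects (used by
the scenario switches, §6).

Within each cycle the order of operations is fixed:

1. **Treatment status** — update the on-drug fraction and the cycle's
   cohort-mean risk-factor deltas from the arm trajectory (§2).
2. **Risk factors** — baseline + treatment delta + bariatric offset +
   natural drift; HbA1c additionally rises 0.05 %-points per year.
3. **Incidences** — annualized event and state risks from the risk
   equations (§3), applied to the at-risk occupancies; glycaemic
   transitions (T2D absorbing; prediabetes reversal at end of cycle 1;
   a 12.7 % return of the reversed pool at cycle *duration* + 1).
4. **Mortality** — combined background, BMI-gradient, chronic-state and
   case-fatality mortality (§4).
5. **Accrual** — life-years, QALYs and the component × payer cost grid
   on end-of-cycle occupancy (§5), discounted at 1.5 %/year.

An optional half-cycle correction averages adjacent cycle-boundary alive
fractions for accrual; it is off by default so that accrual conventions
match the printed tables being emulated.

## 2. Treatment effects

Trial efficacy enters as year-1 cohort-mean deltas per surrogate
endpoint, specified per glycaemic subgroup. The cohort is split into
weighted *effect streams*:

- **Responders** (fraction `responder_fraction`) keep the arm's deltas.
  While on treatment in year *y*, the delta is
  `delta_year1 · maintenance_ratio^(y−1)` with `maintenance_ratio = 0.88`
  (a week-104/week-68 persistence ratio, shared across arms).
- **Non-responders** stop under the ≥5 % weight-loss stopping rule at
  week ~20, revert to diet-and-exercise deltas, and are charged half a
  year of drug cost in cycle 1 (`nonresponder_cost_years = 0.5`).
- With the stopping rule switched off, a single blended stream carries
  the responder-weighted mean deltas and the whole cohort pays drug cost.

Treatment lasts 2 years. After cessation a stream's residual delta is
`delta_at_cessation · (1 − return_rate(years_post))` with the catch-up
schedule [0.54, 1.0]: 54 % of the effect is regained after one year and
100 % after two, so cohort BMI returns exactly to baseline at cycle 4.
From full catch-up onward a natural drift of +0.1 kg/m²/year applies.
Under the *trial-product* estimand with discontinuation enabled, a
per-cycle discontinuation rate (0.15) erodes both efficacy and drug
exposure, mixed exactly over cessation cohorts; under the default
*treatment-policy* estimand population-level effects are used as-is.

Next-line bariatric surgery: after the drug course, a one-time uptake
(5 %) among those with BMI ≥ 35 kg/m² (inclusive) receives a −8 kg/m²
offset and the surgery cost/disutility.

## 3. Risk equations

Hard-endpoint risks come from declared-form equations on centred
covariates (age − 50, BMI − 25, SBP − 120, TC/HDL − 4, female, smoker,
glycaemic indicators):

- `logistic`: risk = expit(intercept + linear predictor);
- `hazard`: risk = 1 − exp(−h₀ · exp(linear predictor)).

Equations with a stated horizon H > 1 year are annualized assuming a
constant hazard: q₁ = 1 − (1 − q_H)^(1/H). First cardiovascular events
apply to event-free occupancy and recurrent events to post-ACS/post-stroke
occupancy; incident CVD is split 0.35/0.20/0.30/0.15 into MI / unstable
angina / stroke / TIA. Breast and endometrial cancer risks are scaled by
the female fraction and gated at the menopause age (51). Cancers are
absorbing states; knee replacement moves occupancy to a post-surgery
state. Sleep apnoea risk always uses the treated BMI (it responds to
weight change in every scenario).

## 4. Mortality

Per cycle the survival probability is

`(1 − q_bg · HR_bmi · HR_states) · Π_e (1 − rate_e · CF_e · HR_bmi)`

where `q_bg` is the sex-weighted life-table probability reduced by a
cause-deduction factor (0.25) to avoid double counting modelled causes;
`HR_bmi = 1.03^(BMI − 25)`; `HR_states = Π_s (1 + occ_s·(HR_s − 1))`
combines chronic-state hazard ratios linearly in occupancy (post-ACS 1.6,
post-stroke 1.8, T2D 1.4); and `CF_e` are case fatalities (MI 0.05,
stroke 0.10, UA 0.02, knee 0.002, bariatric 0.003).

## 5. Economics

**Utilities.** Complication-free utility is a linear regression
`1.132 − 0.0045·BMI − 0.002·age − 0.02·female`, capped at 1 (≈0.85 at the
baseline cohort), minus additive chronic-state, acute-event and
adverse-event decrements; hence QALYs ≤ life-years by construction.

**Costs.** Costs accrue on a (component × payer) grid: components
intervention / chronic / events / monitoring / lifestyle / adverse-event;
payers public, private, and work-productivity loss (WPL). Drug cost is
borne by the private payer; WPL accrues only while age < 65; the societal
perspective sums all payers. Discounting is 1.5 %/year for both costs and
benefits; costs are in Canadian dollars.

## 6. Scenario toggles

`ScenarioToggles` switches: stopping rule on/off; estimand
(treatment-policy vs trial-product) with per-cycle discontinuation;
next-line bariatric surgery; and effect-on-{T2D, CVD, cancer, mortality,
knee} switches. Switching an effect off routes the corresponding risk
equation through the reference (untreated) risk-factor path so that the
stream is equalized across arms; the mortality switch evaluates the BMI
hazard ratio at the reference BMI.

## 7. Cost-effectiveness analytics

- **Frontier**: strictly dominated points removed, survivors sorted by
  (QALY, cost), then adjacent-triple extended-dominance removal iterated
  to a fixpoint; ICURs reported along the frontier and vs the reference,
  with `dominant`/`dominated` sentinels where ratios are undefined.
  The tests validate the construction against an independent greedy
  minimum-ICER oracle on thousands of random instances.
- **NMB**: `wtp · QALY − cost` at CAD 50 000/QALY.
- **DSA**: one-way perturbation of dot-path parameters; tornado ranked by
  ICUR spread.
- **PSA**: per-iteration redraw of all listed parameters with
  moment-matched normal/gamma/beta distributions (a zero standard error
  reproduces the mean exactly); 1000 iterations by default; CEAC (per-WTP
  winner frequencies, ties broken toward the cheaper arm), CEAF (arm with
  highest mean NMB), and a running-ICUR convergence diagnostic.

## 8. What the synthetic generator emulates — and what it does not

`obesim.synthetic.default_deck()` pins the study conditions of the
emulated evaluation: age 50, BMI 37.5, 67 % female, glycaemic mix
0.260/0.464/0.276, HbA1c 8.1 % in the T2D pool, 8-year diabetes duration,
catch-up [0.54, 1.0], prediabetes return 0.127, 1.5 % discounting, 40-year
horizon, WTP 50 000, bariatric threshold 35, 2-year treatment, PSA n=1000,
retirement at 65. These constants are fixed (`PINNED`) and are asserted
literally by the test suite.

Everything else — the Gompertz-form life table, risk-equation
coefficients, cost and disutility tables, and arm effect sizes — is a
**synthetic fill** with literature-plausible signs and magnitudes. The
fills preserve qualitative orderings (weight loss and drug cost:
semaglutide > liraglutide > NB-32 > orlistat > diet-and-exercise) but make
no claim of fidelity to any unpublished supplementary inputs, and the
engine's outputs under the synthetic deck are not expected to match
published totals numerically. The published Table values themselves are
carried verbatim as a separate fixture (`TABLE1_BLOCKS` /
`table1_fixture`) used only by the frontier analytics, which is how the
printed incremental-cost arithmetic is reproduced exactly.
`random_deck(seed, scale)` jitters the synthetic fills (never the pinned
constants) for property testing; `scale=0` returns the default deck.

## 9. Numerical choices

- Pure-Python floats in the engine (cohort-mean model: ~40 cycles × a few
  dozen quantities; a full run takes milliseconds); NumPy only for PSA
  draws and analytics.
- Risks clamped to [0, 1] after evaluation; glycaemic transitions conserve
  mass to 1e-9 (property-tested).
- Frontier tie-breaks: exact-duplicate (cost, QALY) points keep the
  lexicographically first name; equal-QALY points resolve by strict
  dominance.
- Deck serialization writes floats via `repr` so a save/load round trip is
  byte-identical.
- PSA uses `numpy.random.default_rng(seed)`; a given seed reproduces the
  cloud exactly.

## 10. Open design decisions

- **State-HR combination**: chronic-state mortality HRs combine as
  `Π_s (1 + occ_s·(HR_s − 1))` — linear in occupancy per state — a
  mean-cohort aggregation choice.
- **Stopping-rule-off scenario** is implemented holding drug-exposure and
  efficacy inputs fixed (blended-efficacy stream, full-cohort drug cost),
  which makes the QALY gain weakly smaller and cost larger than with the
  rule on; emulations that swap in separate intention-to-treat efficacy
  inputs would need a different deck, not a different toggle.
- **Semaglutide annual drug cost** (5000) was chosen so the synthetic
  intervention-cost ordering follows the published ordering; it is an
  input-realism choice, not a calibrated value.
- **Mortality switch** retains the chronic-state HRs; only the direct
  BMI gradient and the switched-off incidence pathways are equalized.

## 11. Limitations

- Mean-cohort dynamics ignore covariance between risk factors and
  occupancy (e.g. the BMI of the T2D pool equals the cohort mean).
- The synthetic risk equations are not validated against any cohort; all
  absolute outputs under the synthetic deck are illustrative.
- Annual cycles coarsen early post-event mortality and costs.
- The PSA perturbs a curated parameter list, not every input, and draws
  parameters independently (no correlation structure).
- Half-cycle correction is available but off by default, consistent with
  the emulated accrual convention.
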