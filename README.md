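# obesim

A cohort Markov cost-utility model for weight-management pharmacotherapy,
with cost-effectiveness frontier construction, deterministic and
probabilistic sensitivity analysis, and a command-line interface.

## The problem

Anti-obesity drugs (orlistat, naltrexone–bupropion, liraglutide,
semaglutide) reduce body weight and improve cardiometabolic risk factors,
but they are expensive and their benefits accrue over decades through
avoided disease. Deciding whether a payer should fund them requires a
decision-analytic model that (1) projects short-horizon trial effects on
surrogate endpoints — BMI, blood pressure, lipids, glycaemia — into
lifetime incidence of hard endpoints such as type 2 diabetes,
cardiovascular events, cancers, sleep apnoea and knee replacement;
(2) attaches costs and health-related quality of life to those outcomes
under several payer perspectives; and (3) compares the competing drugs
simultaneously on a cost-effectiveness frontier rather than pairwise.

`obesim` implements such a model as a transparent, fully testable Python
package. Its default inputs are a synthetic but realistic input deck
(pinned, labelled synthetic) that emulates a published Canadian evaluation
closely enough to reproduce its headline incremental-cost arithmetic and
frontier structure.

## The model

A closed cohort (mean age 50, mean BMI 37.5, 67 % female, mixed glycaemic
status) is simulated in annual cycles over 40 years. Each cycle applies,
in order:

1. **Treatment status** — responders to a 2-year course keep the arm's
   year-1 risk-factor deltas with a geometric maintenance decay;
   non-responders stop under a ≥5 % weight-loss stopping rule and revert
   to diet-and-exercise effects. After cessation, deltas regain along a
   catch-up schedule (54 % after one year, 100 % after two), followed by a
   natural BMI drift of 0.1 kg/m² per year.
2. **Risk factors** — cohort-mean BMI, SBP, TC/HDL and HbA1c paths per
   arm, plus the glycaemic mix (normal / prediabetes / type 2 diabetes,
   with diabetes absorbing and a prediabetes-reversal pathway).
3. **Incidences** — annualized risks of type 2 diabetes, first and
   recurrent cardiovascular events (split into MI / unstable angina /
   stroke / TIA), three obesity-related cancers, sleep apnoea and knee
   replacement, from declared-form logistic or exponential-hazard
   equations on centred covariates.
4. **Mortality** — background life-table mortality (net of modelled
   causes), a per-BMI-unit hazard ratio, chronic-state hazard ratios, and
   event case fatality.
5. **Accrual** — life-years, utilities (regression baseline capped at 1,
   additive state/event/adverse-event decrements) and costs on a
   component × payer grid (public, private, work-productivity-loss;
   societal = all three, with productivity loss only before age 65).
   Costs and QALYs are discounted at 1.5 % per year.

Analytics on top of the engine: incremental tables per perspective,
cost-effectiveness frontiers with strict and extended dominance, ICURs and
net monetary benefit at a CAD 50 000/QALY threshold, one-way tornado DSA,
and probabilistic sensitivity analysis (moment-matched normal / gamma /
beta draws) with CEAC/CEAF curves and a convergence diagnostic.

## Worked example

```python
from obesim import default_deck, run_simulation
from obesim.analysis import incremental_table, render_table

deck = default_deck()
results = {arm: run_simulation(deck, arm) for arm in deck.arms}
print(render_table(incremental_table(results, "diet_exercise", "societal")))
```

```
          arm  intervention_cost  disease_cost  total_cost  total_qaly  incr_cost  incr_qaly  icur_next  icur_vs_reference       classification
diet_exercise                  0        105653      105653       16.13        NaN        NaN        NaN                NaN            reference
     orlistat               2312        105305      107617       16.15        NaN        NaN        NaN           118464.0 extendedly_dominated
         nb32               3814        104804      108618       16.17        NaN        NaN        NaN            74499.0 extendedly_dominated
  liraglutide               7111        103109      110220       16.24        NaN        NaN        NaN            40691.0            dominated
  semaglutide               8704        100658      109362       16.37     3709.0       0.24    15365.0            15365.0          on_frontier
```

The BMI path shows the treat–catch-up–drift shape: for semaglutide the
first seven cycles are `37.5, 32.56, 33.15, 35.5, 37.5, 37.6, 37.7` —
a dip while on drug, exact return to baseline at the full-catch-up cycle,
then slow natural drift. The semaglutide arm accrues 21.20 discounted
life-years and 16.37 discounted QALYs.

The same analyses are available from the shell:

```bash
obesim make-deck deck/            # write the default deck bundle
obesim run deck/ --out out/       # traces + incremental table
obesim frontier points.csv --reference diet_exercise
obesim dsa deck/ --params params.csv --out out/
obesim psa deck/ --n 1000 --seed 7 --out out/
```

## Layout

| Module | Contents |
| --- | --- |
| `obesim.deck` | Input-deck dataclasses, validation, (de)serialization |
| `obesim.treatment` | Effect streams, maintenance, stopping rule, catch-up |
| `obesim.risk` | Risk equations, annualization, mortality hazards |
| `obesim.econ` | Discounting, utilities, component × payer cost grid |
| `obesim.core` | The annual-cycle cohort engine |
| `obesim.cea` | Frontier, dominance, ICUR/NMB, DSA, PSA, CEAC/CEAF |
| `obesim.synthetic` | Pinned synthetic default deck, jittered random decks, published-table fixtures |
| `obesim.analysis` / `obesim.cli` | Batch analysis runner and `obesim` CLI |

See `docs/methods.md` for the full methods note, parameter tables and
limitations.
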