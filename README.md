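# drscreen

Cost accounting and cost-effectiveness modelling for diabetic-retinopathy
(DR) screening programmes and diabetic macular oedema (DMO) treatment.

Telemedicine screening with non-mydriatic fundus photography finds new
retinopathy in roughly 8% of screened diabetes patients per year; treating
the sight-threatening minority — above all CSMO (clinically significant
macular oedema) with intravitreal anti-VEGF injections — now dominates the
cost of such programmes. `drscreen` packages the analysis pipeline a
programme needs to reason about those costs:

- **registry** — validated screening-registry and cost-ledger tables, annual
  incidence rates, per-patient costs, mean ± sd summaries and the yearly
  roll-up of DMO cost components;
- **econ** — discounting at an annual rate *r* (present value
  `(1+r)^(-t)`), QALY accrual, the incremental cost-effectiveness ratio
  `ICER = ΔC/ΔE` with dominance/quadrant handling, horizon proration of
  QALY gains, and Welch's two-sample *t*-test for treatment comparison;
- **markov** — a deterministic Markov cohort model: occupancy vector ×
  row-stochastic transition matrix per annual cycle, undetected/detected
  state pairs, screening episodes on the interval grid with test
  sensitivity/specificity (defaults 90.2% / 98.6%), discounted cost and
  QALY accrual;
- **synthetic** — seeded generators of patient-level registries, treatment
  records and cost schedules whose aggregates emulate the programme the
  package models (≈35% screened/year; annual incidences ≈8.37% any-DR,
  2.64% sight-threatening DR, 2.19% DMO; 5.7/4.7/2.9 anti-VEGF injections
  in years 1–3);
- **reference** — the programme's published aggregate tables (2007–2014),
  bundled as data so every derived figure can be recomputed;
- **cli** — a thin `drscreen` command (`generate`, `summarize`, `markov`,
  `cea`, `treatcompare`).

The intended audience is health-economics and ophthalmic-epidemiology
analysts who want the arithmetic behind screening-interval and
treatment-policy decisions to be explicit, tested and reproducible.

## Worked example

```bash
python examples/cost_utility.py
```

prints

```
remaining horizon from age 60.67: 17.33 years
anti-VEGF vs laser: ICER EUR 30,364.43 per QALY (+6,376.53 EUR / +0.2100 QALY)
cost-effective at EUR 38,460/QALY? True
QALY gain prorated to a 15-year horizon: 0.18
```

Reading: a DMO cohort with mean age 60.67 and a 78-year life expectancy is
modelled over 17.33 remaining years. Anti-VEGF treatment costs
€7,153.62 − €777.09 = €6,376.53 more per patient-year than laser and gains
0.21 QALY, i.e. ≈€30,364 per QALY — under the €38,460 (£30,000)
willingness-to-pay bound, so cost-effective. Prorated linearly to a 15-year
horizon the gain is 0.18 QALY.

The other scripts in `examples/` each exercise one capability: yearly
screening-cost accounting (`screening_costs.py`), the annual-vs-2.5-year
screening ICERs (`screening_cea.py`), the DMO cost roll-up and the laser →
anti-VEGF cost jump (`dmo_costs.py`), a cohort run of the bundled demo
Markov model (`markov_cohort.py`), and the seeded synthetic pipeline with
parameter recovery (`synthetic_pipeline.py`).

A note on the demo Markov model: transition probabilities and utilities are
illustrative placeholders (`src/drscreen/data/demo_model.yaml`); substantive
use requires literature-derived values supplied through the same config
format.

## Command line

```bash
drscreen generate --seed 7 --out data/            # synthetic registry + ledger + treatments
drscreen summarize --registry data/registry.csv --ledger data/ledger.csv --out tables/
drscreen markov --config src/drscreen/data/demo_model.yaml --out traj.csv
drscreen cea --config model.yaml --out cea.json
drscreen treatcompare --treatments data/treatments.csv --out tc.json
```

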