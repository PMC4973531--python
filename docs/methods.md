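# Methods

## Scope and data

`drscreen` models the direct costs of a population-based diabetic-
retinopathy (DR) screening programme and of diabetic macular oedema (DMO)
treatment, after the pattern of an eight-year (2007–2014) Spanish programme
of 15,396 diabetes patients screened by telemedicine at 2.5-year intervals.
No patient-level data are distributed: `drscreen.reference` bundles only the
programme's published aggregate tables (yearly screened counts, incident
cases, cost totals and components, and the inputs of its cost-effectiveness
comparisons), and `drscreen.synthetic` generates patient-level data that
reproduce that aggregate structure from a seed.

## Registry accounting

A registry row is one patient-year: screening attendance, worst-eye DR
grade (`none < mild < moderate < severe < proliferative`) and DMO status
(`none`, `extrafoveal`, `csmo`). Sight-threatening DR (STDR) is defined as
grade ≥ severe **or** CSMO (sight-threatening maculopathy). A cost-ledger
row is one euro line item in a closed category set (screening, diagnosis,
laser, anti_vegf, vitrectomy, follow_up).

- Annual incidence = 100·cases/screened, reported at 2 decimals.
- Per-patient cost = total/n, reported at 2 decimals.
- Cost summaries report mean, **sample** standard deviation (n−1; the
  convention is not documented by the source tables, n−1 is the
  conventional choice for small yearly samples), min, max.
- The DMO roll-up sums all non-diagnosis lines into the treatment total and
  adds the single diagnosis line for the grand total.

Rounding is half-away-from-zero and applied only at presentation; all
internal arithmetic is unrounded.

### Inconsistencies in the published tables

The bundled reference tables carry a few internal inconsistencies of the
source material, preserved as printed:

- *Incidence rounding.* The published incidence cells do not follow a
  single rounding convention: 407/5027 = 8.0963% is printed 8.09 (truncation)
  while 402/4989 = 8.0577% is printed 8.06 (rounding). This package uses
  half-up rounding everywhere, so it reports 8.10 for 2007; tests compare
  the 2007 cell to within one unit of the last printed digit.
- *DMO components vs totals.* The component lines reconcile exactly with
  the printed treatment totals only for 2008–2010. For 2007 the component
  sum (72,566) equals the printed *grand* total, not the printed treatment
  total (56,880); for 2011–2014 the component sums fall short of the
  printed treatment totals (e.g. 434,364 vs 459,384 in 2011). The printed
  treatment and grand totals are therefore kept as data in their own right;
  exact roll-up checks cover 2008–2010.
- *Screening CEA, any-DR row.* (1347.89 − 482.32)/0.77 = 1124.1, not the
  published 1096.88; the unrounded QALY increment behind the published
  figure is not recoverable. Exact ICER reproduction is asserted only for
  the STDR row (4571.2); the DMO row is checked against direct arithmetic
  (7443.39, within 0.002 relative of the published 7443.28).
- *Per-patient DMO means.* €777.09 (laser) and €7,153.62 (anti-VEGF) per
  patient-year are not exactly derivable from the yearly patient counts;
  they are treated as inputs, not derived quantities.
- The STDR count rows are larger than the severe+proliferative grade rows
  because STDR includes sight-threatening maculopathy; the two sets of rows
  cannot be reconciled exactly and are not forced to be.

## Economic primitives

Discounting uses the standard present-value factor `(1+r)^(−t)` with a
default annual rate of 3%, applied to both costs and utilities. The ICER of
a candidate ("hi") arm over a comparator ("lo") is ΔC/ΔE; strict dominance
(cheaper **and** more effective) suppresses the ratio, a zero QALY
increment leaves it undefined, and a defined ratio is annotated with its
cost-effectiveness-plane quadrant — in the southwest quadrant (cheaper and
less effective) the same number must be read as a saving per QALY forgone,
so it is never reported silently as a plain ICER. The default
willingness-to-pay bound is €38,460/QALY (£30,000).

The remaining modelling horizon is life expectancy (default 78 years, the
figure for Spanish diabetes patients) minus baseline age. QALY-gain
rescaling between horizons is **linear proration** without discounting:
0.21 × 15/17.33 = 0.18, which is the convention the published comparison
follows (an annuity-factor rescale at 3% would give 0.19 instead).

Treatment arms are compared with Welch's unequal-variance two-sample
*t*-test, two-sided (delegated to `scipy.stats.ttest_ind(equal_var=False)`;
an independently coded Welch formula serves as the test oracle). The source
analysis states only "two-sample t-test"; Welch is the safer default for
cost and visual-acuity data with unequal variances. The laser arm's VA gain
is quoted in the source once as 0.68 ± 1.78 and once as 0.86 ± 0.78
letters; this package uses 0.68 ± 1.78 throughout.

## Markov cohort engine

States carry a per-cycle euro cost and a utility weight in [0, 1]; disease
states come in undetected/detected (treated) pairs. The transition matrix
is validated row-stochastic to 1e-9; a state named `dead` must be absorbing
with zero cost and utility. Cycles are annual. Screening episodes fall on
the nearest whole cycle (half-up) to each multiple of the interval, so a
2.5-year interval screens at cycles 0, 3, 5, 8, … — the least-distorting
discretization of a non-integer interval onto annual cycles. At a screening
cycle:

- undetected-disease mass moves to the detected counterpart with
  probability = sensitivity (default 0.902);
- all living mass pays the episode cost (default €40.43);
- healthy mass pays a false-positive work-up (one diagnosis visit, rate
  1 − specificity, default specificity 0.986) and returns to its state the
  next cycle.

State costs and utilities accrue at the **end** of each cycle with no
half-cycle correction, discounted at the cycle's time; screening costs are
discounted at the episode time. Because it is not documented whether
published QALY figures discount from baseline or from the first screening
episode, the accrual anchor is configurable (`anchor="end"` discounts cycle
*c* at time *c*, `"start"` at *c* − 1); the default is `"end"`.

Mortality is handled by the fixed horizon (78 − baseline age) rather than
an annual death hazard; a dead state with nonzero hazard can be expressed
in any transition matrix if wanted, but the bundled demo keeps it at zero.
The computation is a deterministic expected-value cohort — no Monte-Carlo
microsimulation.

The engine is verified against an independently coded naive accrual loop
(≤ 4 states, ≤ 6 cycles, 1e-9 agreement), and obeys: mass conservation at
every cycle; cumulative QALYs non-increasing in the discount rate; QALYs
non-decreasing as the screening interval shortens whenever detection slows
progression to blindness; and zero sensitivity reduces screening to a pure
cost with the never-screened QALY trajectory.

Transition probabilities and utilities are **not** bundled as defaults of
any scientific standing: `data/demo_model.yaml` ships clearly-labelled
illustrative values and substantive analyses must supply their own (e.g.
meta-analytic progression rates and published time-trade-off utilities by
visual-acuity band; `econ.DEFAULT_UTILITIES` is likewise an illustrative
placeholder set).

## Synthetic generator

The generator emulates the programme's *aggregate* structure, not its
longitudinal dynamics:

- Screening attendance is Bernoulli(0.35) per patient-year, independent
  across years; disease events are drawn only for screened patient-years
  (the programme observes disease at screening).
- Any-DR, STDR and DMO are drawn with the configured marginal incidences
  (defaults 8.37%, 2.64%, 2.19%) by decomposition: CSMO is carved out of
  the STDR mass (share 0.62 of DMO) and extrafoveal DMO out of the
  non-sight-threatening DR mass, so all three marginals are recovered
  exactly by construction under the STDR definition above. A consequence is
  that the generated severe/proliferative grade counts exceed the
  published per-grade rows, which are themselves irreconcilable with the
  published STDR counts.
- Events are independent Bernoulli draws per screened patient-year; there
  is no within-patient progression correlation (progression realism lives
  in the Markov engine, not the generator), and no covariates beyond age.
- Ages: per-patient baseline ~ N(65.66, 12.23²) clipped to [20, 95],
  advancing one year per calendar year; DMO patient-years are drawn around
  the DMO cohort mean N(60.67, 10.37²), emulating the cross-sectional age
  structure rather than individual ageing of DMO cases.
- Anti-VEGF injection counts are Poisson with the configured yearly means
  (5.7, 4.7, 2.9) — the source reports means only, and Poisson is the
  minimal count law with that mean; the choice is config-swappable.
- VA gains are truncated normals on each arm's observed range (laser
  [−11, 6], anti-VEGF [0, 10]) with the **location moment-matched** so the
  truncated mean equals the configured mean (solved by Brent's method).
  Naive truncation of N(6.84, 3.22²) to [0, 10] would bias the mean to
  ≈6.03; moment-matching respects the range and recovers the mean, at the
  price of a sample sd somewhat below the nominal 3.22.
- Cost attribution is deterministic given events (screening episode €40.43
  per screened patient-year; per-category diagnosis/treatment/follow-up
  unit costs from the default schedule), so generated screening cost over
  screened count equals the episode cost exactly.
- All randomness derives from one integer seed via deterministic
  sub-streams; identical configurations give identical output.

Passing recovery tests therefore show that the pipeline arithmetic is
correct on data with the right aggregate shape — they do not validate the
generator as an epidemiological simulator of any real population.

## Numerical and testing choices

- Monetary/rate rounding: half-away-from-zero via `decimal`, presentation
  only.
- Row-stochasticity tolerance 1e-9; mass-conservation check 1e-12 per step.
- Generated ages/VA gains/costs are rounded to 2–3 decimals so CSV
  round-trips are bit-exact.
- Fixed-seed stochastic recovery tests use a 3-standard-error band
  (binomial or t-based): a 2-SE band would false-alarm on ~5% of seeds for
  a correct generator. Deterministic identities are tested exactly or at
  1e-9.
- Test problem sizes: registries of 3,000–10,000 patients over 1–3 years
  and cohort runs of ≤ 17 annual cycles, which keep the full suite around a
  few seconds while leaving sampling error far below the tested tolerances.

## Known limitations

- The cohort model is annual-cycle, expected-value, with no half-cycle
  correction and no competing mortality beyond the fixed horizon.
- The generator has no within-patient correlation, no screening-interval
  structure (attendance is i.i.d.), and no risk factors (HbA1c, insulin
  use, diabetes duration) — the high-risk criteria named by the source are
  never quantified there and are deliberately omitted rather than guessed.
- Single currency (EUR), direct costs only, no probabilistic sensitivity
  analysis.
- Published-table inconsistencies listed above mean a handful of printed
  cells cannot be reproduced exactly by any convention; the package
  documents them instead of forcing agreement.
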