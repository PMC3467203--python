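# Methods

This note documents the model implemented in `afcea`: its structure and
assumptions, the parameters that matter, the numerical choices, what the
synthetic components emulate, and the limitations a user should keep in
mind when interpreting results.

## Decision problem and structure

Two lifelong anticoagulation strategies for a 65-year-old cohort with
nonvalvular atrial fibrillation (AF) are compared from a payer
perspective: apixaban 5 mg twice daily and dose-adjusted warfarin
(INR 2–3).  The model is a discrete-time Markov cohort model with a
2-week cycle and a 35-year (lifetime) horizon — 913 cycles, ages 65 to
just under 100.

A health state is the tuple *(treatment, ischemic-stroke sequela,
ICH sequela, MI history, alive)*:

* **treatment** — the strategy drug, or aspirin.  Any non-fatal
  intracranial hemorrhage (ICH) or extracranial hemorrhage (ECH) causes
  permanent discontinuation of the anticoagulant and a switch to aspirin;
  aspirin is absorbing with respect to treatment.
* **stroke/ICH sequela** — none, minor (residual deficit), or major.
  Severity is monotone: no event moves a patient to a less severe state.
  A second minor ischemic stroke escalates to the major-stroke state; a
  second major ischemic stroke is fatal.  A non-fatal ICH in a stroke
  survivor produces a combined stroke-and-ICH state with its own
  bi-weekly cost.
* Transient ischemic attacks, strokes with no residual deficit (RIND),
  minor bleeds, and non-fatal ECH are *temporary* events: they carry an
  event cost (and, for bleeds, a transient disutility) but leave the
  state unchanged.

The reachable state space is enumerated once per strategy (25 states) by
exhaustively applying the event rules, so the cohort recursion is a pure
matrix–vector iteration, and at most one event can strike per cycle: all
competing events plus an explicit "no event" remainder form one
categorical distribution per state and cycle.  The run aborts if the
per-cycle event probabilities ever sum to ≥ 1 (an implausible parameter
combination); over the published ranges they stay far below that.

## Event probabilities

Baseline annual rates on warfarin (%/yr), treatment effects, severity
splits, utilities, and costs are taken from the bundled scenario file;
each carries a base value and a plausible range.  Key transformations:

* **Rate → probability.**  Constant hazard within a cycle:
  `p = 1 − exp(−(rate/100)·14/365.25)`.
* **Age dependence.**  Stroke, ICH and MI rates grow with attained age by
  published per-decade risk ratios (1.4, 1.97, 1.3).  By default the
  ratio is applied in whole-decade steps (`rr^floor(Δage/10)`), matching
  the age-banded form in which such risk estimates are reported and
  tabulated; a continuous per-cycle exponent (`rr^(Δage/10)`) is
  available via the `age_adjustment: continuous` scenario switch.  The
  choice is consequential: the continuous form front-loads event risk
  within each decade and produces a markedly heavier hemorrhage burden
  (and hence a larger apparent advantage for apixaban), so it is exposed
  as an explicit switch rather than buried in the engine.
* **TIA accounting.**  28 % of ischemic neurologic events are TIAs.  The
  1.05 %/yr figure is treated as the *stroke* rate, and TIAs are added at
  `stroke_rate × 28/72` so TIAs make up 28 % of all ischemic neurologic
  events.  TIAs are costed like RIND events and leave no sequela.
* **Severity splits.**  Strokes split fatal/major/minor/RIND
  (8.2/40.2/42.5/9.1 on an anticoagulant, 17.9/30.0/41.0/11.0 on
  aspirin); ICH splits fatal/major/minor 36.4/14.1/49.5.  Printed
  fractions are accepted within rounding distance of 100 % (the aspirin
  row sums to 99.9) and renormalised exactly.
* **Aspirin.**  Relative to warfarin: stroke ×2.08, all hemorrhage
  ×0.87, MI ×1.42, with aspirin-specific stroke severity.
* **Background mortality.**  The life-table annual probability is
  treated as a hazard and multiplied by 1.3 (AF) and further by 2.3 for
  ischemic-stroke survivors (multiplicative composition; a switch lets
  2.3 *replace* 1.3 instead).  ICH-only survivors keep the 1.3
  multiplier; their excess risk enters through event fatality instead.
* **Fatal fractions.**  ECH and MI fatality fractions are structural
  scenario fields defaulting to 0 (no published value): those events kill
  only through background mortality.

## Economics

Costs are 2012 US$.  Bi-weekly state costs (drug: warfarin + INR
monitoring $18, apixaban $95, aspirin $0.30; sequela care: minor stroke
$1,232, major stroke $2,683, ICH $2,835, stroke-and-ICH $3,595, MI $152)
accrue every cycle spent in a state; one-time event costs (e.g. ICH
$41,645, major stroke $14,783, non-event death $5,000) are charged as
transition rewards in the event cycle.  A death caused by a modelled
event charges that event's cost (the cost table has no separate
fatal-event entries).  The apixaban price has a documented $95-vs-$103
ambiguity; $95 is the default and the `apixaban_wac_cost` scenario
variant uses $103.

Utilities multiply: treatment weight (0.987 warfarin, 0.994 apixaban,
0.998 aspirin) × sequela weights (major neurologic 0.39, minor 0.75, MI
0.84); coexisting sequelae combine multiplicatively by default (a
`minimum` rule is available).  A non-fatal ECH carries the −0.16 major-
bleed decrement for one full cycle; a minor bleed carries −0.16 for 2 of
the 14 days.  Cycle utilities are clamped to [0, 1].

Rewards accrue to everyone alive at the start of a cycle (patients dying
in a cycle accrue that cycle's time, utility and costs), and both costs
and health outcomes are discounted at 3 %/yr with factor
`(1.03)^(−t_years)` at the cycle's start time.  No half-cycle correction
is applied by default — with 2-week cycles it is immaterial — but a
trapezoid (average of start- and end-of-cycle occupancy for state
rewards) is available as a switch.  Money is kept to full precision
internally and rounded only in reports.

## Life table

The bundled fixture (`us_life_table_2010_synthetic.csv`) is a
**synthetic** Gompertz
approximation to 2010-era US unisex period mortality: `q(x) = 0.013 ·
exp(0.092·(x − 65))`, ages 65–100, giving q(65) = 1.3 %, q(85) ≈ 8.2 %,
q(95) ≈ 20.6 %.  It reproduces a remaining life expectancy at 65 of
about 19 years before the AF multiplier.  Any two-column CSV
(`age,annual_mortality_probability`) can replace it via the scenario
file to study sensitivity to this choice; lookups use the attained
integer age and clamp beyond the last row.

## Sensitivity analyses

* **One-way.**  Each ranged parameter is swept across its range; where
  the incremental cost (dominance boundary) or net monetary benefit at
  $50,000/QALY (WTP boundary) changes sign, the crossing is located by
  bracketed grid bisection to 10⁻⁶ of the range.  Re-evaluated at a
  reported dominance threshold, |ΔCost| < $1.  When a severity-split
  fraction is swept, the *other* members of its group are renormalised so
  the swept value keeps its face meaning.
* **Two-way.**  A full grid over two parameters (canonically the
  baseline stroke and ICH rates, the former over the 0.61–5.82 %/yr
  registry range), each cell classified dominant / cost-effective at WTP
  / not cost-effective.
* **Horizon.**  The comparison re-run with the horizon truncated
  (1–35 years); the ICER improves monotonically with horizon and crosses
  $50,000/QALY around year 9 under base-case values.
* **PSA.**  10,000 iterations; every parameter with a printed range —
  including the discount rate — is drawn independently from
  triangular(low, base, high) by inverse CDF; split groups are
  renormalised to 100 after sampling; N/A-range structural parameters
  (the per-decade ratios, the minor-ICH fraction) stay fixed.  Both
  strategies run on the *same* draw.  "Cost-effective at WTP" means
  NMB > 0, which is coherent on all four quadrants of the CE plane.
  Degenerate ranges reproduce the deterministic result exactly, and the
  engine is vectorised over draws, so the PSA is a single batched cohort
  run per strategy.

## Microsimulation oracle and synthetic event histories

The patient-level microsimulation draws individual trajectories from the
*same* per-cycle outcome tables the cohort engine integrates (they are
built by the same code), so its sample means are unbiased estimates of
the cohort totals and any systematic divergence is a bug by
construction; the test suite checks agreement within 3 standard errors
at 200,000 patients.  Each patient has an RNG stream keyed by (master
seed, patient id), so trajectory *i* is reproducible regardless of the
number of patients or internal batching.  In record mode the simulator
emits long-format event histories (patient, cycle, age, state, event,
cost increment, utility) as synthetic patient-level data for downstream
demonstrations.  The microsimulation shares the cohort model's
homogeneity assumptions — no individual heterogeneity beyond age
progression — so agreement between the two engines validates the
arithmetic, not the model's realism.

## Problem sizes and determinism

Default analysis sizes: 913 cycles deterministic; 10,000 PSA draws;
200,000 microsimulation patients for oracle validation (a few minutes in
total on one CPU).  All Monte Carlo components take explicit integer
seeds; repeated runs with the same seed are bit-identical.

## Known limitations

* Treatment effects from a single trial (median 1.8 years) are
  extrapolated over a lifetime and held constant.
* Every major hemorrhage is assumed to end anticoagulation permanently
  in favour of aspirin.
* Costs are 2012 US$ as printed; no inflation machinery, no societal
  (productivity) costs, no INR time-in-therapeutic-range modelling, and
  no comparison with other direct oral anticoagulants.
* The bundled life table is a smooth synthetic approximation; results
  that hinge on very old ages inherit its tail behaviour.
* Bi-weekly sequela costs apply for the remainder of life, so lifetime
  totals are sensitive to survivor longevity assumptions (the mortality
  multipliers and the life table) — more so than the incremental
  comparison, which benefits from cancellation.
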