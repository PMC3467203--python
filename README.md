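# afcea — cost-effectiveness of apixaban vs warfarin in atrial fibrillation

`afcea` is a Markov cohort cost-effectiveness model comparing apixaban
5 mg twice daily against adjusted-dose warfarin (target INR 2–3) for
stroke prevention in patients with nonvalvular atrial fibrillation (AF)
and at least one additional stroke risk factor.  It is written for health
economists and outcomes researchers who want a fully scriptable,
re-runnable implementation of this class of anticoagulation decision
model: deterministic base case, one-way/two-way sensitivity analyses with
threshold search, a triangular-distribution probabilistic sensitivity
analysis (PSA), and a patient-level microsimulation that validates the
cohort engine.

## The model

A hypothetical cohort of 65-year-old AF patients (CHADS₂ ≈ 2) starts
"well with AF" on one strategy drug and moves through 2-week cycles until
death or a 35-year horizon.  Health states combine current antithrombotic
treatment (strategy drug, or aspirin after a major hemorrhage forces
permanent discontinuation), ischemic-stroke sequela (none/minor/major),
intracranial-hemorrhage (ICH) sequela, and MI history; death is absorbing
and severity is monotone (a second minor stroke escalates to a major
stroke; a second major stroke is fatal).  At most one event occurs per
cycle.

Annual event rates on warfarin (ischemic stroke 1.05 %/yr, ICH 0.80,
extracranial hemorrhage 3.09, clinically relevant minor bleeding 2.55,
MI 0.61) are scaled by treatment hazard ratios (e.g. HR 0.42 for ICH on
apixaban) and by per-decade risk ratios for attained age (1.4 stroke,
1.97 ICH, 1.3 MI), then converted to per-cycle probabilities under a
constant hazard: `p = 1 − exp(−r·Δt)`.  Background mortality comes from
an age-specific life table multiplied by 1.3 for AF (×2.3 further for
stroke survivors).  Costs (2012 US$) and utilities attach to states
(bi-weekly drug and sequela costs, multiplicative utility weights) and to
events (one-time transition costs, transient bleed disutilities); both
are discounted at 3 %/yr.  Strategies are compared by incremental cost,
QALYs, life-years, ICER = ΔC/ΔE, and net monetary benefit
NMB = λ·ΔQALY − ΔCost at λ = $50,000/QALY.

Every model quantity, with its sensitivity range, lives in a bundled YAML
scenario (`afcea/data/default_scenario.yaml`) and is overridable from
Python or the command line.  See `docs/methods.md` for modelling choices
and limitations.

## Worked example

```python
import afcea

apix, warf, cmp_ = afcea.run_base_case()
print(f"apixaban: ${apix.outcome.cost:,.0f}, {apix.outcome.qaly:.2f} QALY")
print(f"warfarin: ${warf.outcome.cost:,.0f}, {warf.outcome.qaly:.2f} QALY")
print(f"{cmp_.quadrant}: saves ${-cmp_.delta_cost:,.0f}, "
      f"gains {cmp_.delta_qaly:.2f} QALY, {cmp_.delta_ly:.2f} LY")

psa = afcea.run_psa(afcea.load_scenario(), 10_000, seed=1)
print(f"dominant in {100*psa.frac_dominant:.1f}% of draws, "
      f"cost-effective in {100*psa.frac_ce_at_wtp:.1f}%")
```

prints

```
apixaban: $97,626, 11.40 QALY
warfarin: $100,060, 11.03 QALY
dominant: saves $2,434, gains 0.36 QALY, 0.22 LY
dominant in 57.6% of draws, cost-effective in 98.7%
```

Apixaban is *dominant*: it costs less over a lifetime (the higher drug
price is more than offset by avoided intracranial and extracranial
hemorrhages and their downstream care) and yields more quality-adjusted
life.  The PSA draws every ranged parameter from a triangular
(low, likeliest, high) distribution and re-runs both strategies on each
joint draw; the two percentages summarise where the 10,000 incremental
points fall on the cost-effectiveness plane.

The same analyses are available from the shell:

```sh
afcea base-case --out results/base
afcea owsa --parameter apixaban_cost_2wk --out results/owsa
afcea twsa --param-a stroke_rate_warfarin --range-a 0.61:5.82:10 --out results/twsa
afcea psa --n 10000 --seed 1 --out results/psa
afcea microsim --n 100000 --seed 1 --out results/microsim
```

Each command writes JSON/CSV reports plus a `manifest.json` recording the
exact invocation.

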