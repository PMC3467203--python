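# Base-case scenario: 65-year-old cohort with nonvalvular atrial fibrillation
# (mean CHADS2 ~2.1), apixaban 5 mg BID versus adjusted-dose warfarin (INR 2-3),
# 2-week cycles, lifetime (35-year) horizon, 3%/yr discounting, 2012 US$.
# Each parameter gives its base-case value and, where available, the low/high
# ends of the plausible range used in sensitivity analyses (null = no range;
# such parameters are held fixed in probabilistic sensitivity analysis).
model:
  start_age: 65
  cycle_length_days: 14
  horizon_years: 35
  willingness_to_pay: 50000
  # Fractions of extracranial hemorrhages and myocardial infarctions that are
  # immediately fatal. These are structural defaults of this implementation
  # (events are non-fatal beyond background mortality), not published values.
  fatal_ech_fraction: 0.0
  fatal_mi_fraction: 0.0
life_table: null  # null -> bundled synthetic 2010-era US table

parameters:
  # --- Costs (2012 US$) ---
  warfarin_tablets_cost_2wk:   {base: 15, low: 1, high: 24}
  inr_test_cost:               {base: 6, low: 4, high: 10}
  warfarin_inr_cost_2wk:       {base: 18, low: 3, high: 28}
  apixaban_cost_2wk:           {base: 95, low: 51, high: 154}
  aspirin_cost_2wk:            {base: 0.3, low: 0.07, high: 2.8}
  event_cost_rind:             {base: 6562, low: 3500, high: 13000}
  event_cost_minor_stroke:     {base: 9956, low: 4500, high: 18000}
  event_cost_major_stroke:     {base: 14783, low: 11000, high: 27500}
  biweekly_cost_minor_stroke:  {base: 1232, low: 500, high: 2000}
  biweekly_cost_major_stroke:  {base: 2683, low: 1000, high: 4500}
  event_cost_ich:              {base: 41645, low: 16500, high: 71000}
  biweekly_cost_ich:           {base: 2835, low: 1000, high: 4500}
  biweekly_cost_stroke_and_ich: {base: 3595, low: 1600, high: 7000}
  event_cost_ech:              {base: 5830, low: 2000, high: 9000}
  event_cost_minor_bleed:      {base: 42, low: 0, high: 200}
  event_cost_mi:               {base: 20357, low: 16500, high: 24000}
  biweekly_cost_mi:            {base: 152, low: 69, high: 300}
  event_cost_nonevent_death:   {base: 5000, low: 0, high: 10000}
  discount_rate_pct:           {base: 3, low: 0, high: 5}

  # --- Quality-of-life (utilities) ---
  utility_warfarin:            {base: 0.987, low: 0.940, high: 1}
  utility_apixaban:            {base: 0.994, low: 0.975, high: 1}
  utility_aspirin:             {base: 0.998, low: 0.994, high: 1}
  utility_major_neuro:         {base: 0.39, low: 0, high: 1}
  utility_minor_neuro:         {base: 0.75, low: 0, high: 1}
  disutility_major_bleed:      {base: -0.16, low: -0.3, high: 0}
  disutility_minor_bleed:      {base: -0.16, low: -0.3, high: 0}
  utility_mi:                  {base: 0.84, low: 0.5, high: 1}

  # --- Event rates (% per year on warfarin) and treatment effects ---
  stroke_rate_warfarin:        {base: 1.05, low: 0.92, high: 1.24}
  hr_stroke_apixaban:          {base: 1.0, low: 0.74, high: 1.13}
  rr_stroke_aspirin:           {base: 2.08, low: 1.59, high: 2.70}
  rr_stroke_per_decade:        {base: 1.4, low: null, high: null}
  tia_pct_of_ischemic_events:  {base: 28, low: null, high: null}

  # Severity split of ischemic strokes on an anticoagulant (% of strokes)
  stroke_pct_fatal:            {base: 8.2, low: 8.2, high: 10.1}
  stroke_pct_major:            {base: 40.2, low: 40.2, high: 41.7}
  stroke_pct_minor:            {base: 42.5, low: 34.8, high: 42.5}
  stroke_pct_rind:             {base: 9.1, low: 9.1, high: 13.3}
  # Severity split of ischemic strokes on aspirin
  aspirin_stroke_pct_fatal:    {base: 17.9, low: 10.1, high: 17.9}
  aspirin_stroke_pct_major:    {base: 30.0, low: 30.0, high: 41.1}
  aspirin_stroke_pct_minor:    {base: 41.0, low: 34.8, high: 41.0}
  aspirin_stroke_pct_rind:     {base: 11.0, low: 11.0, high: 13.3}

  ich_rate_warfarin:           {base: 0.80, low: 0.63, high: 0.89}
  hr_ich_apixaban:             {base: 0.42, low: 0.30, high: 0.58}
  rr_ich_per_decade:           {base: 1.97, low: null, high: null}
  ich_pct_fatal:               {base: 36.4, low: 28.3, high: 45.2}
  ich_pct_major:               {base: 14.1, low: 9.0, high: 21.4}
  ich_pct_minor:               {base: 49.5, low: null, high: null}

  ech_rate_warfarin:           {base: 3.09, low: 2.59, high: 3.16}
  hr_ech_apixaban:             {base: 0.69, low: 0.60, high: 0.80}
  minor_bleed_rate_warfarin:   {base: 2.55, low: 2.32, high: 2.80}
  rr_minor_bleed_apixaban:     {base: 0.69, low: 0.59, high: 0.80}
  rr_hemorrhage_aspirin:       {base: 0.87, low: 0.59, high: 0.90}

  mi_rate_warfarin:            {base: 0.61, low: 0.51, high: 0.76}
  hr_mi_apixaban:              {base: 1.0, low: 0.66, high: 1.17}
  rr_mi_aspirin:               {base: 1.42, low: 0.84, high: 2.39}
  rr_mi_per_decade:            {base: 1.3, low: null, high: null}

  rr_death_af:                 {base: 1.3, low: 1.12, high: 1.62}
  rr_death_af_stroke:          {base: 2.3, low: 1.3, high: 3.0}
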