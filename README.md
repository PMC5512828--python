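# penrisk

Total cardiovascular-risk scoring and prevention-concordance analysis for
low-resource primary-care EMR cohorts.

## The problem

Primary-care programmes in low-resource and humanitarian settings increasingly
manage cardiovascular disease (CVD) prevention with a *total risk* approach:
instead of treating single risk factors, patients are stratified by their
estimated 10-year risk of a cardiovascular event using the WHO/ISH risk charts,
and treatment decisions (notably statin/lipid-lowering therapy) follow WHO PEN
protocol thresholds.  Evaluating such a programme from its routine electronic
records raises a set of recurring, fiddly analysis tasks:

* screening the database with WHO PEN-derived inclusion rules (everyone ≥ 40;
  adults 18–39 only with a qualifying risk factor);
* scoring each patient on the WHO/ISH chart — a complete 640-cell lookup over
  sex × age band × smoking × diabetes × SBP band × total-cholesterol band;
* choosing *which* SBP/cholesterol measurement to score with, relative to an
  index date (first on/after enrolment; most recent before a prescription or
  documented score);
* imputing missing values (a constant 130 mmHg fill for the rare missing SBP;
  an OLS regression on age, sex and SBP for the ~20% missing cholesterol);
* classifying treatment eligibility into mutually exclusive categories
  (existing CVD → diabetic ≥ 40 → TC ≥ 8 mmol/L → chart risk ≥ 20% → not
  eligible) and tabulating prescribing concordance;
* comparing clinician-*documented* risk scores with re-*calculated* ones:
  cross-tabulation, aggregation at the 20% threshold, Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e), and Wilson continuity-corrected /
  Clopper–Pearson binomial intervals for every proportion.

`penrisk` packages this whole pipeline as a tested library plus a small CLI,
together with a synthetic EMR cohort generator that reproduces the published
population structure of a large refugee NCD-clinic cohort (stratum mix, risk
factor marginals, missingness, documentation-error process, prescribing
rates), so every stage is testable without access to clinic data.

The packaged default chart is a clearly labelled **synthetic** WHO/ISH-style
chart (monotone in all six axes, log-linear risk); the published chart cell
values are not redistributed.  Any chart transcribed into the documented CSV
format can be used instead.

## Worked example

```python
from penrisk import simulate, report
from penrisk.charts import RiskFactorInput, calculate_risk, default_chart

chart = default_chart()

# score one person
inp = RiskFactorInput(sex="male", age=62, smoker=True, diabetic=True, sbp=165, tc=6.5)
print(calculate_risk(inp, chart).label)        # -> 20-<30

# simulate a study-sized cohort and run the full analysis
cohort = simulate.generate(simulate.default_spec(n_patients=2907), seed=42)
rep = report.run_pipeline(cohort.records, chart)
for key in ("cvd_history", "eligible", "eligible_prescribed"):
    h = rep.headline[key]
    print(key, f"{h['percent']:.1f}% (95% CI {h['ci_low']:.1f}, {h['ci_high']:.1f})")
```

prints

```
20-<30
cvd_history 19.7% (95% CI 18.3, 21.2)
eligible 56.9% (95% CI 55.1, 58.7)
eligible_prescribed 48.2% (95% CI 45.8, 50.6)
```

i.e. in this synthetic replicate 19.7% of the cohort has an existing CVD
history, 56.9% is eligible for lipid-lowering treatment under the PEN-derived
rules, and 48.2% of the eligible patients actually hold a prescription —
the prescribing-concordance gap the analysis is designed to surface.
`rep.table3`/`rep.table4` hold the documented-vs-calculated cross-tabs and
`rep.kappa` the agreement statistics.

The same pipeline is scriptable from a shell:

```bash
penrisk simulate --n 2907 --seed 42 --out cohort/
penrisk score   --cohort cohort/ --out scores.csv
penrisk report  --cohort cohort/ --out results/
```

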