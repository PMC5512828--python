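# Methods

This note records the scientific conventions, parameter choices and known
limitations of the package.  It is written for a maintainer or analyst who
wants to know exactly what is computed and why each open design point was
resolved the way it was.

## Risk model

Risk is the WHO/ISH 10-year total cardiovascular risk *category*, obtained by
table lookup, never by a continuous equation.  A chart is a complete function
from (sex, age band, smoking, diabetes, SBP band, TC band) to one of five
ordered categories `<10`, `10-<20`, `20-<30`, `30-<40`, `>=40` (percent
10-year event risk); 2·4·2·2·4·5 = 640 cells.  "High risk" everywhere means
category ≥ 20%.

Banding conventions (all half-open, lower-inclusive):

* age bands 40/50/60/70 with cut points 50, 60, 70; ages 18–39 are scored
  with the 40 band.  The published charts start at 40, but the screening
  protocol enrols qualifying adults from 18, so the youngest band is extended
  downward.  This is a package convention, not a WHO statement, and is the
  main interpretive choice a user should be aware of when scoring under-40s.
* SBP bands `<140, 140-159, 160-179, >=180` mmHg — an SBP of exactly 140.0
  falls in `140-159`.  Extreme readings (e.g. 210 mmHg) are scoreable; they
  land in the top band.
* TC bands with edges 5, 6, 7, 8 mmol/L; 8.0 falls in `>=8`.

Smoking is "positive" for current smokers and anyone who quit within the
previous 12 months.  Type 1 and type 2 diabetes are equivalent everywhere a
rule says "diabetic".

### The packaged chart is synthetic

The published WHO/ISH chart cell values are under copyright and are not
printed in the evaluation literature this package operationalises, so the
packaged default (`data/chart_emrb_synthetic.csv`, built by
`charts.synthetic_chart`) is a synthetic stand-in: log-risk is linear in the
axis ranks (increments 0.50 per age band, 0.30 per SBP band, 0.12 per TC
band, 0.30 for smoking, 0.45 for diabetes, 0.20 for male sex, anchored at
1.8% for the lowest-risk cell) and cut at 10/20/30/40%.  This reproduces the
real charts' qualitative behaviour — monotone in every axis, smoking and
diabetes acting multiplicatively — and is validated for completeness and
monotonicity in the test suite, but *its cell values are not the published
ones*.  Every quantity in the acceptance path is independent of specific
cell values; analyses of real cohorts should load a transcribed chart CSV
(`charts.load_chart`), which the loader validates for completeness,
duplicates and category validity before any lookup is allowed.

## Cohort screening

Inclusion follows the WHO PEN Protocol 1 adaptation: everyone aged ≥ 40;
adults 18–39 with at least one of: positive smoking status, diabetes, family
history of CVD or of diabetes in a first/second-degree relative, or high
waist circumference (≥ 90 cm women / ≥ 100 cm men, inclusive).  Missing
waist or family-history fields count as negative — screening an existing
database can only use what is recorded; no fidelity claim is made for how
the original programme handled absent fields.  `filter_cohort` partitions
its input exactly into included patients plus an exclusion tally
(under-18 / under-40-without-risk-factor), a property the tests enforce on
arbitrary inputs.

## Index dates and measurement selection

Three analyses, three anchors:

| analysis | index date | direction |
|---|---|---|
| enrolment risk profile | enrolment date | prospective (first on/after) |
| eligibility of prescribed patients | first lipid-lowering prescription | retrospective (latest strictly before) |
| documented-score accuracy | first documented risk score | retrospective |

Retrospective selection is *strictly* before the index date by default
(`retrospective_strict`): a lab drawn on the prescription day may postdate
the prescribing decision.  Same-date ties break to the first record in file
order and are logged; the underlying data carry no intra-day ordering, so any
rule here is arbitrary and the chosen one is at least reproducible.

## Imputation

Two stages, in a fixed order because SBP is a predictor of TC:

1. **SBP**: missing values (rare, ~0.5%) are filled with a constant cohort
   admission mean, default 130 mmHg (`sbp_fill_mmHg`, configurable for other
   cohorts).
2. **TC**: an OLS model `TC ~ age + female + SBP` is fitted on the complete
   cases of the *enrolment-profile* selection and reused for all three
   analysis contexts (one model, as in the original analysis).  Sex enters
   as a female indicator; any full-rank coding gives identical predictions.
   The fit requires ≥ 4 complete cases and a full-rank design and fails
   loudly otherwise.

Imputation never alters an observed value, and `sbp_imputed`/`tc_imputed`
flags mark exactly the filled entries.

## Eligibility and concordance

Mutually exclusive categories in precedence order: `history_of_cvd` →
`dm_ge40` → `tc_ge8` → `risk_ge20` → `risk_lt20`; the first four are
eligible.  The precedence mirrors the secondary-prevention-first column
order of the published prescribing table.  The TC used by the `tc_ge8` rule
is the same selected/imputed value used for scoring in the same context, and
age is age at enrolment (the database stores age, not birth date).
Concordance is reported per category as n, prescribed count, percent and a
95% CI, plus the overall eligible-prescribed proportion.

## Agreement analysis

One (documented, calculated) pair per patient with ≥ 1 documented score,
using the first score by date.  The calculated side is `history_of_cvd` for
patients with a CVD history (their management is secondary prevention
regardless of chart score), else the chart category from retrospective
selection at the documentation date.

Derived views:

* **binary 2×2** at the 20% threshold, CVD history counting as
  calculated-high;
* **CVD match rule** for kappa: a CVD-history patient documented ≥ 20% was
  clinically called correctly, so the calculated side is rewritten to the
  documented category.  After the rule, the square cross-tab keeps a sixth
  `history_of_cvd` level with an empty documented margin for CVD patients
  documented < 20%; both the 6-level kappa on this table and the 2×2 kappa
  are reported, since the exact construction used in the source analysis is
  not recoverable.  The headline "documented correct" proportion is the
  plain diagonal share of pairs (a CVD calculated side never counts as
  correct there).

Cohen's kappa is computed from the standard closed form with p_o the
diagonal share and p_e the margin product; it returns NaN when p_e = 1.  No
significance test is attached (the source analysis does not specify one).

Binomial intervals: Wilson score with continuity correction (default — it
reproduces every headline interval printed in the source study) and
Clopper–Pearson (`exact`, which matches the style of the smaller printed
proportions).  Both are clipped to [0, 1] and always bracket x/n.

## Synthetic cohort generator

`simulate.default_spec()` encodes the published study population: stratum
shares (e.g. 608/2907 with CVD history, 1650/2907 below 10% risk),
per-stratum age median/IQR, percent male, diabetes (type 1/2), smoking,
family-history and high-waist prevalences, SBP and TC means/SDs; TC
missingness 576/2907, SBP missingness 15/2907; documentation probability
680/2907; prescribing probabilities 0.706 / 0.374 / 0.636 / 0.167 / 0.163
per eligibility category.

Modelling choices where the source gives only summaries:

* **Ages** are log-normal per stratum with μ = ln(median) and
  σ = ln(q75/q25)/(2·z₀.₇₅), clipped to [18, 100] — the published tables
  give median (IQR) only, and a log-normal reproduces both with mild right
  skew.
* **SBP/TC** are Gaussian with the published stratum means/SDs, truncated to
  physiologic bounds (SBP 70–260 mmHg, TC 2–15 mmol/L; engineering bounds,
  essentially never active).
* **Within-stratum conditional independence** of all risk factors: no
  correlation structure is published, so none is claimed.
* **Documentation error kernel**: per-stratum distribution of the documented
  category, defaulting to the normalised column profile of the published
  documented-vs-calculated cross-tab — i.e. calibrated under-calling.  For
  CVD-stratum patients a documented category below 20% is counted as a
  documentation error (matching the match-rule semantics).  Fully
  configurable, including a delta (identity) kernel for error-free cohorts.
* **Prescribing** is Bernoulli per patient given the *latent truth*
  eligibility category, which is derived from the drawn condition flags,
  diabetes, age, true TC and latent stratum.
* Every generated record passes the inclusion screen (the generator emulates
  the post-screening analysis database): an under-40 draw with no qualifying
  factor gets its family history of diabetes set, the most prevalent factor.

Latent stratum labels drive the measurement distributions; the chart
category the pipeline computes from the drawn measurements will generally
differ from the latent stratum (the marginals overlap heavily across
strata), so calibration tests compare against the latent truth
(`truth_table`), not chart output.  What passing generator-based tests show
is that the pipeline *recovers the parameters the generator used* —
missingness, stratum mix, documentation rate, per-category prescribing
probabilities — not that it would reproduce any particular clinic's data;
real EMR features like visit-level dynamics, informative missingness,
within-patient measurement drift and coded-condition noise are deliberately
out of scope.

## Problem sizes and numerical conventions

Calibration and recovery tests run at n = 10⁴ patients (binomial SE ≈ 0.4
percentage points for the missingness checks) with 50 seeded replicates for
the prescribing-coverage property; a ≥ 90% per-category coverage threshold
leaves headroom under the conservative (over-covering) Wilson-CC interval.
Quantiles use linear-interpolation order statistics; percentages are
reported at one decimal with raw numerator/denominator always alongside;
the report generator re-derives every percentage from its counts and fails
hard on any inconsistency.  All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical seeds give byte-identical
cohort CSVs.

## Known limitations

* The default chart is synthetic (above); absolute category frequencies from
  it do not estimate real-population risk distributions.
* Single imputation only; no uncertainty propagation for imputed values.
* Prescribing is not adherence; the concordance table measures prescriptions
  written, nothing downstream.
* The kappa printed in the source study (0.178) is not exactly recoverable
  from its printed tables under any construction enumerated here (2×2 gives
  ≈ 0.166; 6-level variants ≈ 0.164–0.195); the package reports its own
  variants and does not attempt to match that figure.
* Gender-stratified analyses, blood-pressure/aspirin concordance and any
  qualitative material are out of scope.
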