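"""Pipeline orchestration and publication-style report tables.

``run_pipeline`` executes the whole quantitative analysis on a cohort:
inclusion screening, enrolment-profile measurement selection and imputation,
chart scoring, treatment-eligibility categorisation with prescribing
concordance, and the documented-vs-calculated agreement analysis.  The
result bundles the flow tally, a per-stratum population summary, the
concordance table, the agreement cross-tabs with kappa variants, headline
proportions with confidence intervals, and a provenance block.  Every
percentage in the report is re-derived from its numerator/denominator pair
as a self-consistency audit before the report is returned.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import agreement as agr
from . import charts, eligibility, selection
from .charts import RiskCategory, RiskFactorInput
from .eligibility import ConcordanceTable
from .emr import PatientRecord, filter_cohort, has_cvd_history, read_cohort, smoking_positive

__all__ = ["AnalysisReport", "run_pipeline", "run_pipeline_from_files", "population_summary"]

STRATA_ORDER = ("<10", "10-<20", "20-<30", "30-<40", ">=40", "history_of_cvd")


@dataclass
class AnalysisReport:
    flow: dict
    population: pd.DataFrame
    concordance: ConcordanceTable
    table3: pd.DataFrame | None
    table4: pd.DataFrame | None
    kappa: dict
    headline: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "flow": self.flow,
            "population": self.population.reset_index().to_dict(orient="records"),
            "concordance": {
                "per_category": self.concordance.per_category.reset_index().to_dict(orient="records"),
                "overall": {
                    "n_eligible": self.concordance.overall_n_eligible,
                    "n_prescribed": self.concordance.overall_n_prescribed,
                    "percent": self.concordance.overall_percent,
                    "ci": self.concordance.overall_ci,
                },
            },
            "table3": None if self.table3 is None else self.table3.reset_index().to_dict(orient="records"),
            "table4": None if self.table4 is None else self.table4.reset_index().to_dict(orient="records"),
            "kappa": self.kappa,
            "headline": self.headline,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, default=_jsonify, **kwargs)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.population.to_csv(outdir / "table1_population.csv")
        self.concordance.per_category.to_csv(outdir / "table2_concordance.csv")
        if self.table3 is not None:
            self.table3.to_csv(outdir / "table3_agreement.csv")
        if self.table4 is not None:
            self.table4.to_csv(outdir / "table4_agreement_binary.csv")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, RiskCategory):
        return o.label
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON serialisable: {o!r}")


def _pct(x: int, n: int, ci_method: str) -> dict:
    lo, hi = agr.proportion_ci(x, n, method=ci_method)
    return {"x": x, "n": n, "percent": 100.0 * x / n, "ci_low": 100 * lo, "ci_high": 100 * hi}


def population_summary(
    patients: Sequence[PatientRecord],
    strata: dict[str, str],
    rows: dict[str, selection.SelectedInputs],
    ci_method: str = "wilson_cc",
) -> pd.DataFrame:
    """Per-stratum population summary (CVD history plus five risk strata).

    ``strata`` maps patient_id to stratum label, ``rows`` to the selected
    (post-imputation) enrolment measurements.  Quantiles use the standard
    linear-interpolation order statistics.  Empty strata appear with n=0.
    """
    total = len(patients)
    by_stratum: dict[str, list[PatientRecord]] = {s: [] for s in STRATA_ORDER}
    for p in patients:
        by_stratum[strata[p.patient_id]].append(p)

    out = []
    for s in STRATA_ORDER:
        members = by_stratum[s]
        n = len(members)
        if n == 0:
            out.append({"stratum": s, "n": 0})
            continue
        ages = np.array([p.age for p in members], dtype=float)
        sbps = np.array([rows[p.patient_id].sbp for p in members], dtype=float)
        tcs = np.array([rows[p.patient_id].tc for p in members], dtype=float)
        share = _pct(n, total, ci_method)
        waists = [(p.waist_cm, p.sex) for p in members if p.waist_cm is not None]
        from .emr import high_waist

        out.append(
            {
                "stratum": s,
                "n": n,
                "percent_of_total": share["percent"],
                "percent_ci_low": share["ci_low"],
                "percent_ci_high": share["ci_high"],
                "median_age": float(np.median(ages)),
                "age_q25": float(np.percentile(ages, 25)),
                "age_q75": float(np.percentile(ages, 75)),
                "percent_male": 100.0 * sum(p.sex == "male" for p in members) / n,
                "percent_dm_type1": 100.0 * sum(p.diabetes_type == "type1" for p in members) / n,
                "percent_dm_type2": 100.0 * sum(p.diabetes_type == "type2" for p in members) / n,
                "percent_smoking": 100.0 * sum(smoking_positive(p.smoking) for p in members) / n,
                "mean_sbp": float(sbps.mean()),
                "sd_sbp": float(sbps.std(ddof=1)) if n > 1 else float("nan"),
                "mean_tc": float(tcs.mean()),
                "sd_tc": float(tcs.std(ddof=1)) if n > 1 else float("nan"),
                "percent_fh_dm": 100.0 * sum(p.family_history_dm for p in members) / n,
                "percent_fh_cvd": 100.0 * sum(p.family_history_cvd for p in members) / n,
                "percent_high_waist": (
                    100.0 * sum(high_waist(w, sx) for w, sx in waists) / len(waists)
                    if waists
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(out).set_index("stratum")


def _score_enrolment(
    p: PatientRecord, row: selection.SelectedInputs, chart: charts.RiskChart
) -> RiskCategory:
    return charts.calculate_risk(
        RiskFactorInput(
            sex=p.sex,
            age=p.age,
            smoker=smoking_positive(p.smoking),
            diabetic=p.is_diabetic,
            sbp=row.sbp,
            tc=row.tc,
        ),
        chart,
    )


def run_pipeline(
    records: Sequence[PatientRecord],
    chart: charts.RiskChart | None = None,
    config: dict | None = None,
) -> AnalysisReport:
    """Execute the full analysis: screen, select/impute, score, categorise,
    tabulate agreement, and audit the report for self-consistency.

    Deterministic given the records, chart and config.
    """
    cfg = {
        "sbp_fill_mmHg": selection.DEFAULT_SBP_FILL,
        "retrospective_strict": True,
        "ci_method": "wilson_cc",
        "chart_subregion": None,
    }
    cfg.update(config or {})
    if chart is None:
        chart = charts.default_chart()
    chart_report = charts.validate_chart(chart)
    if not chart_report.ok:
        raise charts.ChartError(chart_report.summary())
    ci_method = cfg["ci_method"]
    strict = bool(cfg["retrospective_strict"])

    included, tally = filter_cohort(records)
    flow = {
        "screened": len(records),
        "included": len(included),
        **tally,
    }
    if not included:
        raise ValueError("no patients meet the inclusion criteria; nothing to analyse")

    # enrolment-profile selection + imputation (fits the TC model reused below)
    row_list, model = selection.resolve_cohort_inputs(included, sbp_fill=float(cfg["sbp_fill_mmHg"]))
    rows = {r.patient_id: r for r in row_list}

    strata: dict[str, str] = {}
    for p in included:
        if has_cvd_history(p.conditions):
            strata[p.patient_id] = "history_of_cvd"
        else:
            strata[p.patient_id] = _score_enrolment(p, rows[p.patient_id], chart).label

    population = population_summary(included, strata, rows, ci_method=ci_method)

    assignments = eligibility.assign_cohort(included, chart, model, strict=strict)
    conc = eligibility.concordance(assignments, ci_method=ci_method)

    pairs = agr.documented_accuracy_pairs(included, chart, model, strict=strict)
    if pairs:
        table3 = agr.agreement_table(pairs)
        table4 = agr.aggregate_binary(table3)
        matched = agr.apply_cvd_match_rule(pairs)
        kappa = {
            "n_pairs": len(pairs),
            "kappa_binary": agr.cohen_kappa(table4),
            "kappa_6level_matched": agr.cohen_kappa(agr.square_table(matched)),
            "documented_correct_percent": 100.0 * sum(
                not isinstance(c, str) and d == c for d, c in pairs
            ) / len(pairs),
        }
    else:
        table3 = table4 = None
        kappa = {"n_pairs": 0, "empty": True}

    n_inc = len(included)
    n_cvd = sum(1 for s in strata.values() if s == "history_of_cvd")
    n_doc = len(pairs)
    n_eligible = conc.overall_n_eligible
    n_cvd_or_dm = sum(1 for a in assignments if a.category in ("history_of_cvd", "dm_ge40"))
    headline = {
        "cvd_history": _pct(n_cvd, n_inc, ci_method),
        "low_risk_lt10": _pct(sum(1 for s in strata.values() if s == "<10"), n_inc, ci_method),
        "documented": _pct(n_doc, n_inc, ci_method),
        "eligible": _pct(n_eligible, n_inc, ci_method),
        "eligible_prescribed": (
            _pct(conc.overall_n_prescribed, n_eligible, ci_method) if n_eligible else None
        ),
        "eligible_via_cvd_or_dm": (
            _pct(n_cvd_or_dm, n_eligible, ci_method) if n_eligible else None
        ),
    }

    provenance = {
        "package": "penrisk",
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "chart_subregion": chart.subregion,
        "n_records": len(records),
        "tc_model": {
            "intercept": model.intercept,
            "coef_age": model.coef_age,
            "coef_female": model.coef_female,
            "coef_sbp": model.coef_sbp,
            "fit_n": model.fit_n,
        },
    }

    report = AnalysisReport(
        flow=flow,
        population=population,
        concordance=conc,
        table3=table3,
        table4=table4,
        kappa=kappa,
        headline=headline,
        provenance=provenance,
    )
    _audit(report)
    return report


def _audit(report: AnalysisReport) -> None:
    """Recompute every reported percentage from its counts; raise on mismatch."""
    flow = report.flow
    if flow["included"] + flow["excluded_under18"] + flow["excluded_under40_no_risk"] != flow["screened"]:
        raise AssertionError("flow tally does not partition the screened population")
    n_inc = flow["included"]
    if int(report.population["n"].sum()) != n_inc:
        raise AssertionError("population strata do not sum to the included count")
    if int(report.concordance.per_category["n"].sum()) != n_inc:
        raise AssertionError("eligibility categories do not partition the cohort")
    for key, h in report.headline.items():
        if h is None:
            continue
        if not math.isclose(h["percent"], 100.0 * h["x"] / h["n"], abs_tol=1e-9):
            raise AssertionError(f"headline {key} percentage inconsistent with its counts")
    for cat, r in report.concordance.per_category.iterrows():
        if r["n"] and not math.isclose(
            r["percent_prescribed"], 100.0 * r["n_prescribed"] / r["n"], abs_tol=1e-9
        ):
            raise AssertionError(f"concordance percentage inconsistent for {cat}")
    if report.table3 is not None and report.table4 is not None:
        if int(report.table3.to_numpy().sum()) != int(report.table4.to_numpy().sum()):
            raise AssertionError("binary aggregation does not conserve the pair count")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline_from_files(
    cohort_dir, chart_path=None, config: dict | None = None, condition_map=None
) -> AnalysisReport:
    """File-based entry point: reads the three cohort CSVs and a chart CSV,
    runs the pipeline, and adds input hashes to the provenance block."""
    cohort_dir = Path(cohort_dir)
    from .emr import load_condition_map

    cmap = load_condition_map(condition_map) if condition_map else None
    records = read_cohort(cohort_dir, condition_map=cmap)
    chart_path = Path(chart_path) if chart_path else charts.default_chart_path()
    chart = charts.load_chart(chart_path)
    report = run_pipeline(records, chart, config)
    report.provenance["inputs"] = {
        name: _sha256(cohort_dir / name)
        for name in ("patients.csv", "measurements.csv", "prescriptions.csv")
        if (cohort_dir / name).exists()
    }
    report.provenance["inputs"]["chart"] = _sha256(Path(str(chart_path)))
    return report
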