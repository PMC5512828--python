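"""Lipid-lowering treatment eligibility and prescribing-concordance tabulation.

Eligibility follows the WHO PEN-derived programme rule: patients with
existing CVD (secondary prevention), diabetics aged >= 40, patients with
total cholesterol >= 8 mmol/L, or patients with WHO/ISH chart risk >= 20%
are eligible for lipid-lowering treatment.  Patients are reported in
mutually exclusive categories with that same precedence (secondary
prevention first), so each patient appears exactly once.

The risk category feeding the rule depends on prescribing status: for
patients ever prescribed lipid-lowering treatment, risk is recalculated at
the date of first prescription using the most recent prior measurements
(what the prescriber could have seen); for never-prescribed patients the
enrolment-profile score is used.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Sequence

import pandas as pd

from . import charts
from .agreement import proportion_ci
from .charts import RiskCategory
from .emr import PatientRecord, has_cvd_history, smoking_positive
from .selection import ImputationModel, SelectedInputs, complete_inputs

__all__ = [
    "CATEGORIES",
    "EligibilityAssignment",
    "risk_for_eligibility",
    "assign_category",
    "assign_cohort",
    "concordance",
    "ConcordanceTable",
]

#: Mutually exclusive categories in precedence order.
CATEGORIES = ("history_of_cvd", "dm_ge40", "tc_ge8", "risk_ge20", "risk_lt20")
ELIGIBLE_CATEGORIES = frozenset(CATEGORIES[:4])


@dataclass(frozen=True)
class EligibilityAssignment:
    patient_id: str
    category: str
    eligible: bool
    prescribed_llt: bool
    risk_used: RiskCategory
    risk_context: str  # 'enrolment_profile' | 'treatment_eligibility'

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.eligible != (self.category in ELIGIBLE_CATEGORIES):
            raise ValueError("eligible flag inconsistent with category")


def risk_for_eligibility(
    patient: PatientRecord,
    chart: charts.RiskChart,
    model: ImputationModel,
    strict: bool = True,
) -> tuple[RiskCategory, str, SelectedInputs]:
    """Risk category and context used for the eligibility decision.

    Prescribed patients: retrospective selection at the first lipid-lowering
    prescription date; others: prospective selection at enrolment.  Returns
    (category, context, selected inputs after imputation).
    """
    llt_date = patient.first_llt_date()
    if llt_date is not None:
        context = "treatment_eligibility"
        row = complete_inputs(patient, llt_date, "retrospective", model, strict=strict)
    else:
        context = "enrolment_profile"
        row = complete_inputs(patient, patient.enrolment_date, "prospective", model, strict=strict)
    cat = charts.calculate_risk(
        charts.RiskFactorInput(
            sex=patient.sex,
            age=patient.age,
            smoker=smoking_positive(patient.smoking),
            diabetic=patient.is_diabetic,
            sbp=row.sbp,
            tc=row.tc,
        ),
        chart,
    )
    return cat, context, row


def assign_category(
    patient: PatientRecord,
    risk: RiskCategory,
    tc: float,
    risk_context: str = "enrolment_profile",
) -> EligibilityAssignment:
    """First matching rule wins: CVD history, diabetic & >= 40, TC >= 8,
    chart risk >= 20%, else not eligible."""
    if has_cvd_history(patient.conditions):
        category = "history_of_cvd"
    elif patient.is_diabetic and patient.age >= 40:
        category = "dm_ge40"
    elif tc >= 8.0:
        category = "tc_ge8"
    elif risk.is_high:
        category = "risk_ge20"
    else:
        category = "risk_lt20"
    return EligibilityAssignment(
        patient_id=patient.patient_id,
        category=category,
        eligible=category in ELIGIBLE_CATEGORIES,
        prescribed_llt=patient.first_llt_date() is not None,
        risk_used=risk,
        risk_context=risk_context,
    )


def assign_cohort(
    patients: Sequence[PatientRecord],
    chart: charts.RiskChart,
    model: ImputationModel,
    strict: bool = True,
) -> list[EligibilityAssignment]:
    """Assign every patient to its mutually exclusive eligibility category."""
    out = []
    for p in patients:
        risk, context, row = risk_for_eligibility(p, chart, model, strict=strict)
        out.append(assign_category(p, risk, row.tc, risk_context=context))
    return out


@dataclass
class ConcordanceTable:
    """Per-category prescribing counts with CIs, plus the overall
    eligible-prescribed proportion."""

    per_category: pd.DataFrame
    overall_n_eligible: int
    overall_n_prescribed: int
    overall_percent: float | None
    overall_ci: tuple[float, float] | None


def concordance(
    assignments: Sequence[EligibilityAssignment],
    ci_method: str = "wilson_cc",
) -> ConcordanceTable:
    """Prescribing concordance by mutually exclusive category.

    Category counts always sum to the cohort size.  Empty categories are
    emitted with n=0 and an undefined (NaN) percentage.
    """
    rows = []
    for cat in CATEGORIES:
        members = [a for a in assignments if a.category == cat]
        n = len(members)
        n_rx = sum(a.prescribed_llt for a in members)
        if n:
            pct = 100.0 * n_rx / n
            lo, hi = proportion_ci(n_rx, n, method=ci_method)
            rows.append((cat, n, n_rx, pct, 100 * lo, 100 * hi, False))
        else:
            rows.append((cat, 0, 0, float("nan"), float("nan"), float("nan"), True))
    df = pd.DataFrame(
        rows,
        columns=["category", "n", "n_prescribed", "percent_prescribed", "ci_low", "ci_high", "undefined"],
    ).set_index("category")

    eligible = [a for a in assignments if a.eligible]
    n_el = len(eligible)
    n_el_rx = sum(a.prescribed_llt for a in eligible)
    if n_el:
        pct = 100.0 * n_el_rx / n_el
        lo, hi = proportion_ci(n_el_rx, n_el, method=ci_method)
        return ConcordanceTable(df, n_el, n_el_rx, pct, (100 * lo, 100 * hi))
    return ConcordanceTable(df, 0, 0, None, None)
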