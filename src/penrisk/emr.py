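"""Clinic EMR data model, condition coding and cohort inclusion screening.

Models a longitudinal outpatient NCD-clinic extract: per-patient demographics
and risk factors, visit-stamped SBP/total-cholesterol measurements,
prescriptions, and clinician-documented risk categories.  Inclusion screening
follows the WHO PEN Protocol 1 adaptation used by the programme: everyone
aged >= 40 is screened, and adults 18-39 only if they smoke, are diabetic,
have a family history of CVD or diabetes in a first/second-degree relative,
or a high waist circumference.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .charts import RiskCategory

__all__ = [
    "CVD_CONDITION_CODES",
    "KNOWN_CONDITION_CODES",
    "SmokingStatus",
    "Measurement",
    "Prescription",
    "PatientRecord",
    "has_cvd_history",
    "smoking_positive",
    "high_waist",
    "meets_inclusion",
    "filter_cohort",
    "read_cohort",
    "write_cohort",
    "load_condition_map",
]

#: Controlled vocabulary of condition codes counting as previous CVD.
CVD_CONDITION_CODES = frozenset(
    {
        "stable_angina",
        "unstable_angina",
        "myocardial_infarction",
        "angioplasty",
        "congestive_heart_failure",
        "peripheral_vascular_disease",
        "other_cvd",
        "cv_or_cerebrovascular_complication",
    }
)

#: Full vocabulary: CVD codes plus the clinic's other enrolment conditions.
KNOWN_CONDITION_CODES = CVD_CONDITION_CODES | {
    "hypertension",
    "diabetes",
    "copd",
    "asthma",
}

MEASUREMENT_KINDS = ("sbp", "total_cholesterol")


@dataclass(frozen=True)
class SmokingStatus:
    """Smoking field: 'current', 'never', or 'quit' with months since quitting."""

    status: str
    quit_months: int | None = None

    def __post_init__(self) -> None:
        if self.status not in ("current", "never", "quit"):
            raise ValueError(f"smoking status must be current/never/quit, got {self.status!r}")
        if self.status == "quit" and (self.quit_months is None or self.quit_months < 0):
            raise ValueError("quit status requires a non-negative quit_months")


NEVER_SMOKED = SmokingStatus("never")


@dataclass(frozen=True)
class Measurement:
    """One dated measurement; SBP in mmHg, total cholesterol in mmol/L.

    ``missing=True`` models an ordered-but-unrecorded value (empty field in
    the source extract); the value is then None.
    """

    date: dt.date
    kind: str
    value: float | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise ValueError(f"measurement kind must be one of {MEASUREMENT_KINDS}, got {self.kind!r}")
        if not self.missing and (self.value is None or self.value <= 0):
            raise ValueError(f"non-missing measurement needs a positive value, got {self.value!r}")


@dataclass(frozen=True)
class Prescription:
    date: dt.date
    drug_class: str  # 'lipid_lowering' | 'other'

    def __post_init__(self) -> None:
        if self.drug_class not in ("lipid_lowering", "other"):
            raise ValueError(f"drug_class must be lipid_lowering/other, got {self.drug_class!r}")


@dataclass
class PatientRecord:
    """One enrolled patient.

    Measurement and prescription dates may legitimately predate enrolment
    (values carried over from referral paperwork), so no ordering constraint
    is imposed beyond valid dates.
    """

    patient_id: str
    sex: str
    age: int
    enrolment_date: dt.date
    conditions: frozenset[str] = frozenset()
    family_history_cvd: bool = False
    family_history_dm: bool = False
    diabetes_type: str = "none"  # 'none' | 'type1' | 'type2'
    smoking: SmokingStatus = NEVER_SMOKED
    waist_cm: float | None = None
    measurements: list[Measurement] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    documented_scores: list[tuple[dt.date, RiskCategory]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.diabetes_type not in ("none", "type1", "type2"):
            raise ValueError(f"diabetes_type must be none/type1/type2, got {self.diabetes_type!r}")
        self.conditions = frozenset(self.conditions)

    @property
    def is_diabetic(self) -> bool:
        """Type 1 and type 2 both count as diabetic for every rule."""
        return self.diabetes_type in ("type1", "type2")

    def first_llt_date(self) -> dt.date | None:
        dates = [p.date for p in self.prescriptions if p.drug_class == "lipid_lowering"]
        return min(dates) if dates else None

    def first_documented_score(self) -> tuple[dt.date, RiskCategory] | None:
        return min(self.documented_scores, key=lambda s: s[0]) if self.documented_scores else None


def has_cvd_history(conditions: Iterable[str]) -> bool:
    """True iff any condition code in the CVD vocabulary is present.

    A pure set-membership test: order and duplication never matter.  Codes
    outside the known vocabulary are ignored with a warning so that newer
    extracts with extra codes still screen.
    """
    codes = set(conditions)
    unknown = codes - KNOWN_CONDITION_CODES
    if unknown:
        warnings.warn(
            f"ignoring unknown condition codes: {sorted(unknown)}",
            stacklevel=2,
        )
    return bool(codes & CVD_CONDITION_CODES)


def smoking_positive(smoking: SmokingStatus) -> bool:
    """Current smoker, or quit within the previous 12 months."""
    if smoking.status == "current":
        return True
    if smoking.status == "quit":
        return smoking.quit_months < 12
    return False


def high_waist(waist_cm: float | None, sex: str) -> bool:
    """Waist >= 90 cm (women) / >= 100 cm (men), inclusive.

    A missing waist measurement returns False: the criterion is simply
    unassessable and inclusion can only come from the other criteria.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if waist_cm is None:
        return False
    if waist_cm <= 0:
        raise ValueError("waist_cm must be positive when present")
    threshold = 100.0 if sex == "male" else 90.0
    return waist_cm >= threshold


def meets_inclusion(patient: PatientRecord) -> bool:
    """Cohort inclusion screen (WHO PEN Protocol 1 adaptation).

    Under-18s are never included; everyone >= 40 is; 18-39-year-olds need at
    least one qualifying risk factor.  Missing family-history or waist fields
    are treated as negative.
    """
    if patient.age < 18:
        return False
    if patient.age >= 40:
        return True
    return (
        smoking_positive(patient.smoking)
        or patient.is_diabetic
        or patient.family_history_cvd
        or patient.family_history_dm
        or high_waist(patient.waist_cm, patient.sex)
    )


def filter_cohort(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Partition a screened population into included patients and an exclusion tally.

    Returns ``(included, tally)`` with tally keys ``excluded_under18`` and
    ``excluded_under40_no_risk``; the tally and the included list always
    partition the input exactly.
    """
    included: list[PatientRecord] = []
    tally = {"excluded_under18": 0, "excluded_under40_no_risk": 0}
    for rec in records:
        if rec.age < 18:
            tally["excluded_under18"] += 1
        elif not meets_inclusion(rec):
            tally["excluded_under40_no_risk"] += 1
        else:
            included.append(rec)
    return included, tally


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Three UTF-8 CSVs with header rows, ISO-8601 dates, empty fields for missing:
#   patients.csv      patient_id,sex,age,enrolment_date,conditions,
#                     family_history_cvd,family_history_dm,diabetes_type,
#                     smoking_status,quit_months,waist_cm
#   measurements.csv  patient_id,date,kind,value   (kind also admits
#                     'documented_risk', whose value is a category label)
#   prescriptions.csv patient_id,date,drug_class
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _read_bool(x: str, column: str) -> bool:
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {x!r} in column {column}")


def _read_date(x: str) -> dt.date:
    return dt.date.fromisoformat(str(x).strip())


def load_condition_map(path) -> dict[str, str]:
    """YAML mapping of source condition strings to vocabulary codes."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ValueError(f"condition map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_cohort(directory, condition_map: dict[str, str] | None = None) -> list[PatientRecord]:
    """Read patients/measurements/prescriptions CSVs from ``directory``."""
    directory = Path(directory)
    pat = pd.read_csv(directory / "patients.csv", dtype=str, keep_default_na=False)
    meas_path = directory / "measurements.csv"
    rx_path = directory / "prescriptions.csv"
    meas = (
        pd.read_csv(meas_path, dtype=str, keep_default_na=False)
        if meas_path.exists()
        else pd.DataFrame(columns=["patient_id", "date", "kind", "value"])
    )
    rx = (
        pd.read_csv(rx_path, dtype=str, keep_default_na=False)
        if rx_path.exists()
        else pd.DataFrame(columns=["patient_id", "date", "drug_class"])
    )

    measurements: dict[str, list[Measurement]] = {}
    documented: dict[str, list[tuple[dt.date, RiskCategory]]] = {}
    for row in meas.itertuples(index=False):
        pid = str(row.patient_id)
        date = _read_date(row.date)
        kind = str(row.kind).strip()
        raw = str(row.value).strip()
        if kind == "documented_risk":
            documented.setdefault(pid, []).append((date, RiskCategory.from_label(raw)))
        else:
            missing = raw == ""
            value = None if missing else float(raw)
            measurements.setdefault(pid, []).append(
                Measurement(date=date, kind=kind, value=value, missing=missing)
            )

    prescriptions: dict[str, list[Prescription]] = {}
    for row in rx.itertuples(index=False):
        prescriptions.setdefault(str(row.patient_id), []).append(
            Prescription(date=_read_date(row.date), drug_class=str(row.drug_class).strip())
        )

    records: list[PatientRecord] = []
    for row in pat.itertuples(index=False):
        pid = str(row.patient_id)
        raw_conditions = [c for c in str(row.conditions).split(";") if c.strip()]
        if condition_map:
            raw_conditions = [condition_map.get(c.strip(), c.strip()) for c in raw_conditions]
        status = str(row.smoking_status).strip() or "never"
        quit_months = str(getattr(row, "quit_months", "")).strip()
        smoking = SmokingStatus(status, int(quit_months) if quit_months else None)
        waist_raw = str(getattr(row, "waist_cm", "")).strip()
        records.append(
            PatientRecord(
                patient_id=pid,
                sex=str(row.sex).strip().lower(),
                age=int(row.age),
                enrolment_date=_read_date(row.enrolment_date),
                conditions=frozenset(c.strip() for c in raw_conditions),
                family_history_cvd=_read_bool(row.family_history_cvd, "family_history_cvd"),
                family_history_dm=_read_bool(row.family_history_dm, "family_history_dm"),
                diabetes_type=str(row.diabetes_type).strip() or "none",
                smoking=smoking,
                waist_cm=float(waist_raw) if waist_raw else None,
                measurements=measurements.get(pid, []),
                prescriptions=prescriptions.get(pid, []),
                documented_scores=documented.get(pid, []),
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], directory) -> None:
    """Write the three cohort CSVs (inverse of :func:`read_cohort`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pat_rows, meas_rows, rx_rows = [], [], []
    for r in records:
        pat_rows.append(
            {
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age": r.age,
                "enrolment_date": r.enrolment_date.isoformat(),
                "conditions": ";".join(sorted(r.conditions)),
                "family_history_cvd": str(r.family_history_cvd).lower(),
                "family_history_dm": str(r.family_history_dm).lower(),
                "diabetes_type": r.diabetes_type,
                "smoking_status": r.smoking.status,
                "quit_months": "" if r.smoking.quit_months is None else r.smoking.quit_months,
                "waist_cm": "" if r.waist_cm is None else f"{r.waist_cm:.1f}",
            }
        )
        for m in r.measurements:
            meas_rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": m.date.isoformat(),
                    "kind": m.kind,
                    "value": "" if m.missing else f"{m.value:.2f}",
                }
            )
        for date, cat in r.documented_scores:
            meas_rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": date.isoformat(),
                    "kind": "documented_risk",
                    "value": cat.label,
                }
            )
        for p in r.prescriptions:
            rx_rows.append(
                {"patient_id": r.patient_id, "date": p.date.isoformat(), "drug_class": p.drug_class}
            )

    pd.DataFrame(pat_rows).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(meas_rows, columns=["patient_id", "date", "kind", "value"]).to_csv(
        directory / "measurements.csv", index=False
    )
    pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_class"]).to_csv(
        directory / "prescriptions.csv", index=False
    )
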