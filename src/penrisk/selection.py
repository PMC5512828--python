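"""Index-date measurement selection and the two imputation procedures.

Each analysis anchors on an *index date* and picks one SBP and one total
cholesterol value per patient:

* enrolment profile — index = enrolment date, *prospective* selection (the
  first measurement on or after the index date);
* treatment eligibility of prescribed patients — index = first lipid-lowering
  prescription, *retrospective* selection (the most recent measurement
  strictly before the index date);
* documented-score accuracy — index = first documented risk score,
  retrospective selection.

"Strictly before" is a deliberate convention for retrospective mode: a lab
drawn on the prescription day may postdate the prescribing decision.  It can
be relaxed with ``strict=False``.

Missing values are then filled in two stages, mirroring routine practice for
this kind of extract: SBP, missing only rarely, is filled with a constant
admission mean (130 mmHg by default); cholesterol, missing far more often, is
predicted from an ordinary-least-squares model on the complete cases with
age, sex and (already-filled) SBP as predictors.  SBP filling must precede
the cholesterol model because SBP is one of its predictors.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .emr import Measurement, PatientRecord

__all__ = [
    "DEFAULT_SBP_FILL",
    "SelectedInputs",
    "ImputationModel",
    "first_prospective",
    "first_retrospective",
    "select_inputs",
    "impute_sbp",
    "fit_tc_model",
    "impute_tc",
    "resolve_cohort_inputs",
    "complete_inputs",
]

log = logging.getLogger(__name__)

DEFAULT_SBP_FILL = 130.0  # mmHg, cohort admission mean


def _candidates(
    measurements: Iterable[Measurement], kind: str
) -> list[tuple[int, Measurement]]:
    return [
        (i, m)
        for i, m in enumerate(measurements)
        if m.kind == kind and not m.missing and m.value is not None
    ]


def first_prospective(
    measurements: Sequence[Measurement], index_date: dt.date, kind: str
) -> Measurement | None:
    """Earliest non-missing measurement of ``kind`` dated on/after the index date.

    Same-date ties break to the first record in file order (logged); returns
    None when no eligible measurement exists.
    """
    cands = [(i, m) for i, m in _candidates(measurements, kind) if m.date >= index_date]
    if not cands:
        return None
    best = min(cands, key=lambda im: (im[1].date, im[0]))
    if sum(1 for _, m in cands if m.date == best[1].date) > 1:
        log.info("same-date tie on %s at %s; using first record in file order", kind, best[1].date)
    return best[1]


def first_retrospective(
    measurements: Sequence[Measurement],
    index_date: dt.date,
    kind: str,
    strict: bool = True,
) -> Measurement | None:
    """Most recent non-missing measurement of ``kind`` before the index date.

    ``strict=True`` (default) requires the date to be strictly earlier than
    the index date; with ``strict=False`` an index-day measurement also
    qualifies.  Same-date ties break to the first record in file order.
    """
    if strict:
        cands = [(i, m) for i, m in _candidates(measurements, kind) if m.date < index_date]
    else:
        cands = [(i, m) for i, m in _candidates(measurements, kind) if m.date <= index_date]
    if not cands:
        return None
    latest = max(m.date for _, m in cands)
    best = min((im for im in cands if im[1].date == latest), key=lambda im: im[0])
    if sum(1 for _, m in cands if m.date == latest) > 1:
        log.info("same-date tie on %s at %s; using first record in file order", kind, latest)
    return best[1]


@dataclass(frozen=True)
class SelectedInputs:
    """Per-patient values selected for one analysis context."""

    patient_id: str
    sex: str
    age: int
    sbp: float | None
    tc: float | None
    sbp_imputed: bool = False
    tc_imputed: bool = False


def select_inputs(
    patient: PatientRecord,
    index_date: dt.date,
    direction: str,
    strict: bool = True,
) -> SelectedInputs:
    """Select SBP and TC for one patient relative to an index date."""
    if direction == "prospective":
        sbp = first_prospective(patient.measurements, index_date, "sbp")
        tc = first_prospective(patient.measurements, index_date, "total_cholesterol")
    elif direction == "retrospective":
        sbp = first_retrospective(patient.measurements, index_date, "sbp", strict=strict)
        tc = first_retrospective(patient.measurements, index_date, "total_cholesterol", strict=strict)
    else:
        raise ValueError(f"direction must be prospective/retrospective, got {direction!r}")
    return SelectedInputs(
        patient_id=patient.patient_id,
        sex=patient.sex,
        age=patient.age,
        sbp=None if sbp is None else sbp.value,
        tc=None if tc is None else tc.value,
    )


@dataclass(frozen=True)
class ImputationModel:
    """Constant SBP fill plus an affine cholesterol predictor.

    Predicted TC (mmol/L) = intercept + coef_age*age + coef_female*[female]
    + coef_sbp*SBP, fitted by OLS on complete cases.
    """

    sbp_fill: float
    intercept: float
    coef_age: float
    coef_female: float
    coef_sbp: float
    fit_n: int

    def predict_tc(self, age: float, sex: str, sbp: float) -> float:
        female = 1.0 if sex == "female" else 0.0
        return self.intercept + self.coef_age * age + self.coef_female * female + self.coef_sbp * sbp


def impute_sbp(rows: Sequence[SelectedInputs], fill: float = DEFAULT_SBP_FILL) -> list[SelectedInputs]:
    """Fill absent SBP with the constant ``fill`` (default 130 mmHg), flagging
    exactly the filled entries; observed values are never touched."""
    out = []
    n_filled = 0
    for r in rows:
        if r.sbp is None:
            out.append(replace(r, sbp=fill, sbp_imputed=True))
            n_filled += 1
        else:
            out.append(r)
    if n_filled:
        log.info("imputed SBP=%g for %d of %d patients", fill, n_filled, len(rows))
    return out


def fit_tc_model(
    rows: Sequence[SelectedInputs], sbp_fill: float = DEFAULT_SBP_FILL
) -> ImputationModel:
    """Fit the cholesterol OLS model on complete cases (TC and SBP observed
    or SBP already filled).

    Requires at least 4 complete cases and a full-rank design; rank
    deficiency (e.g. a single-sex cohort with constant age) raises.
    """
    cases = [r for r in rows if r.tc is not None and r.sbp is not None]
    if len(cases) < 4:
        raise ValueError(f"need >= 4 complete cases to fit the 4-parameter TC model, got {len(cases)}")
    df = pd.DataFrame(
        {
            "age": [r.age for r in cases],
            "female": [1.0 if r.sex == "female" else 0.0 for r in cases],
            "sbp": [r.sbp for r in cases],
            "tc": [r.tc for r in cases],
        }
    )
    X = sm.add_constant(df[["age", "female", "sbp"]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design: age/sex/SBP are collinear in the complete cases")
    fit = sm.OLS(df["tc"], X).fit()
    params = fit.params
    return ImputationModel(
        sbp_fill=sbp_fill,
        intercept=float(params["const"]),
        coef_age=float(params["age"]),
        coef_female=float(params["female"]),
        coef_sbp=float(params["sbp"]),
        fit_n=len(cases),
    )


def impute_tc(rows: Sequence[SelectedInputs], model: ImputationModel) -> list[SelectedInputs]:
    """Predict absent TC from (age, sex, SBP); SBP must already be filled."""
    out = []
    n_filled = 0
    for r in rows:
        if r.tc is None:
            if r.sbp is None:
                raise ValueError(
                    f"patient {r.patient_id}: SBP must be imputed before TC prediction"
                )
            out.append(replace(r, tc=model.predict_tc(r.age, r.sex, r.sbp), tc_imputed=True))
            n_filled += 1
        else:
            out.append(r)
    if n_filled:
        log.info("imputed TC by regression for %d of %d patients", n_filled, len(rows))
    return out


def resolve_cohort_inputs(
    patients: Sequence[PatientRecord],
    sbp_fill: float = DEFAULT_SBP_FILL,
) -> tuple[list[SelectedInputs], ImputationModel]:
    """Enrolment-profile selection for a cohort, with both imputations applied.

    Selects prospectively from each patient's enrolment date, fills SBP with
    the constant, fits the TC model on the complete cases of this selection,
    predicts the missing TCs, and returns the completed rows together with
    the fitted model (reused by the other analysis contexts).
    """
    rows = [select_inputs(p, p.enrolment_date, "prospective") for p in patients]
    rows = impute_sbp(rows, fill=sbp_fill)
    model = fit_tc_model(rows, sbp_fill=sbp_fill)
    rows = impute_tc(rows, model)
    return rows, model


def complete_inputs(
    patient: PatientRecord,
    index_date: dt.date,
    direction: str,
    model: ImputationModel,
    strict: bool = True,
) -> SelectedInputs:
    """Select-and-impute for a single patient in any context using a fitted model."""
    row = select_inputs(patient, index_date, direction, strict=strict)
    (row,) = impute_sbp([row], fill=model.sbp_fill)
    (row,) = impute_tc([row], model)
    return row
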