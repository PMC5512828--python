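"""Synthetic EMR cohort generator.

The study database behind this kind of analysis is routine clinical data and
is never deposited, so the pipeline is exercised against synthetic cohorts
that reproduce the published population structure: a latent risk stratum per
patient (history of CVD plus the five chart categories) with the published
stratum mix, per-stratum demographic and risk-factor marginals, realistic
missingness of cholesterol (~19.8%) and SBP (~0.5%), a ~23.3% risk-score
documentation rate with a configurable documentation-error kernel, and
per-eligibility-category lipid-lowering prescribing probabilities.

Within a stratum, risk factors are drawn conditionally independently — the
source tables publish marginals only, so no within-stratum correlation
structure is claimed.  Ages are log-normal calibrated to the published
median/IQR; SBP and TC are Gaussian with the published stratum means/SDs,
truncated to physiologic bounds.  The documentation-error kernel defaults to
the observed documented-vs-calculated confusion pattern, which concentrates
its mass on under-calling (documenting a lower category than the truth).

Everything is driven by one integer seed; the same spec and seed give
byte-identical cohorts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .charts import RiskCategory
from .emr import (
    CVD_CONDITION_CODES,
    Measurement,
    PatientRecord,
    Prescription,
    SmokingStatus,
    meets_inclusion,
)

__all__ = [
    "StratumParams",
    "CohortSpec",
    "SyntheticCohort",
    "default_spec",
    "generate",
    "truth_table",
    "load_spec",
    "save_spec",
]

STRATA = ("<10", "10-<20", "20-<30", "30-<40", ">=40", "history_of_cvd")
HIGH_STRATA = frozenset({"20-<30", "30-<40", ">=40"})

# quartile z-score of the standard normal, for median/IQR -> lognormal sigma
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class StratumParams:
    """Marginal distributions for one latent risk stratum."""

    share: float
    age_median: float
    age_q25: float
    age_q75: float
    pct_male: float
    p_dm_type1: float
    p_dm_type2: float
    p_smoking: float
    sbp_mean: float
    sbp_sd: float
    tc_mean: float
    tc_sd: float
    p_fh_dm: float
    p_fh_cvd: float
    p_high_waist: float


@dataclass
class CohortSpec:
    """Full generator configuration; :func:`default_spec` fills it with the
    published study-population values."""

    n_patients: int
    strata: dict[str, StratumParams]
    p_missing_tc: float
    p_missing_sbp: float
    p_documented: float
    #: per-stratum documented-category distribution over the five categories
    doc_kernel: dict[str, list[float]]
    #: Bernoulli prescribing probability per eligibility category
    prescribing: dict[str, float]
    sbp_bounds: tuple[float, float] = (70.0, 260.0)
    tc_bounds: tuple[float, float] = (2.0, 15.0)
    start_date: dt.date = dt.date(2014, 12, 15)
    enrolment_window_days: int = 320
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError with field-level messages for an invalid spec."""
        errors: list[str] = []
        if self.n_patients < 0:
            errors.append(f"n_patients must be >= 0, got {self.n_patients}")
        for name, p in (
            ("p_missing_tc", self.p_missing_tc),
            ("p_missing_sbp", self.p_missing_sbp),
            ("p_documented", self.p_documented),
        ):
            if not 0 <= p <= 1:
                errors.append(f"{name} must be in [0, 1], got {p}")
        mix = sum(s.share for s in self.strata.values())
        if self.strata and abs(mix - 1.0) > 0.02:
            errors.append(f"stratum shares must sum to 1 (got {mix:.4f})")
        for key, s in self.strata.items():
            if key not in STRATA:
                errors.append(f"unknown stratum {key!r}")
                continue
            if not 0 <= s.share <= 1:
                errors.append(f"strata[{key}].share must be in [0, 1]")
            if s.sbp_sd <= 0 or s.tc_sd <= 0:
                errors.append(f"strata[{key}]: sds must be > 0")
            if not (s.age_q25 <= s.age_median <= s.age_q75):
                errors.append(f"strata[{key}]: age quartiles must be ordered")
            for pname in ("pct_male", "p_dm_type1", "p_dm_type2", "p_smoking",
                          "p_fh_dm", "p_fh_cvd", "p_high_waist"):
                v = getattr(s, pname)
                if not 0 <= v <= 1:
                    errors.append(f"strata[{key}].{pname} must be in [0, 1], got {v}")
        for key, probs in self.doc_kernel.items():
            if key not in STRATA:
                errors.append(f"doc_kernel has unknown stratum {key!r}")
            elif len(probs) != 5 or any(p < 0 for p in probs) or sum(probs) <= 0:
                errors.append(f"doc_kernel[{key}] must be 5 non-negative weights with positive sum")
        for key, p in self.prescribing.items():
            if not 0 <= p <= 1:
                errors.append(f"prescribing[{key}] must be in [0, 1], got {p}")
        if errors:
            raise ValueError("invalid cohort spec:\n  " + "\n  ".join(errors))


def default_spec(n_patients: int = 2907, seed: int = 0) -> CohortSpec:
    """The study-population defaults.

    Stratum shares, age medians/IQRs, and risk-factor marginals follow the
    published population summary; missingness is 576/2907 (TC) and 15/2907
    (SBP); documentation probability is 680/2907; the documentation kernel is
    the observed documented-vs-calculated confusion pattern; prescribing
    probabilities are the published per-category rates.
    """
    strata = {
        "<10": StratumParams(1650 / 2907, 50, 42, 57, 0.338, 0.024, 0.425, 0.237,
                             124.39, 17.60, 5.16, 0.96, 0.690, 0.392, 0.795),
        "10-<20": StratumParams(325 / 2907, 64, 60, 71, 0.412, 0.003, 0.631, 0.197,
                                139.74, 18.62, 5.18, 1.13, 0.652, 0.258, 0.797),
        "20-<30": StratumParams(139 / 2907, 66, 61.0, 72.5, 0.417, 0.007, 0.647, 0.324,
                                146.58, 20.95, 5.41, 1.61, 0.489, 0.295, 0.734),
        "30-<40": StratumParams(70 / 2907, 64, 61.25, 71, 0.343, 0.000, 0.800, 0.286,
                                156.07, 15.39, 5.64, 1.25, 0.657, 0.214, 0.857),
        ">=40": StratumParams(115 / 2907, 66, 62, 71, 0.409, 0.009, 0.800, 0.287,
                              171.64, 20.47, 6.28, 1.59, 0.635, 0.296, 0.835),
        "history_of_cvd": StratumParams(608 / 2907, 61, 53, 68, 0.535, 0.002, 0.523, 0.312,
                                        129.03, 22.96, 4.74, 1.11, 0.625, 0.423, 0.727),
    }
    doc_kernel = {
        "<10": [413, 38, 2, 1, 0],
        "10-<20": [52, 22, 2, 1, 0],
        "20-<30": [25, 10, 4, 0, 0],
        "30-<40": [15, 3, 2, 4, 0],
        ">=40": [14, 2, 3, 4, 1],
        "history_of_cvd": [56, 5, 1, 0, 0],
    }
    prescribing = {
        "history_of_cvd": 0.706,
        "dm_ge40": 0.374,
        "tc_ge8": 0.636,
        "risk_ge20": 0.167,
        "risk_lt20": 0.163,
    }
    return CohortSpec(
        n_patients=n_patients,
        strata=strata,
        p_missing_tc=576 / 2907,
        p_missing_sbp=15 / 2907,
        p_documented=680 / 2907,
        doc_kernel=doc_kernel,
        prescribing=prescribing,
        seed=seed,
    )


@dataclass
class SyntheticCohort(Sequence):
    """Generated records plus the latent ground truth used to create them."""

    records: list[PatientRecord]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _draw_age(rng: np.random.Generator, s: StratumParams) -> int:
    mu = np.log(s.age_median)
    sigma = np.log(s.age_q75 / s.age_q25) / (2 * _Z75)
    age = float(np.exp(rng.normal(mu, max(sigma, 1e-6))))
    return int(np.clip(round(age), 18, 100))


def _draw_trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                       bounds: tuple[float, float]) -> float:
    # resample a few times, then clip: bounds are several SDs out so clipping
    # is essentially never reached
    for _ in range(10):
        v = rng.normal(mean, sd)
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    return float(np.clip(v, *bounds))


def _truth_category(stratum: str, diabetic: bool, age: int, tc_true: float) -> str:
    if stratum == "history_of_cvd":
        return "history_of_cvd"
    if diabetic and age >= 40:
        return "dm_ge40"
    if tc_true >= 8.0:
        return "tc_ge8"
    if stratum in HIGH_STRATA:
        return "risk_ge20"
    return "risk_lt20"


def generate(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort; the same spec and seed give identical output.

    Every generated record satisfies the cohort inclusion screen (the
    generator emulates the post-screening analysis database): an under-40
    draw that would fail screening has its family history of diabetes set,
    the most prevalent qualifying factor.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    names = list(spec.strata)
    shares = np.array([spec.strata[k].share for k in names], dtype=float)
    shares = shares / shares.sum()
    kernel = {
        k: np.asarray(w, dtype=float) / np.sum(w) for k, w in spec.doc_kernel.items()
    }
    cvd_codes = sorted(CVD_CONDITION_CODES)

    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_patients):
        stratum = names[rng.choice(len(names), p=shares)]
        s = spec.strata[stratum]
        sex = "male" if rng.random() < s.pct_male else "female"
        age = _draw_age(rng, s)
        u = rng.random()
        if u < s.p_dm_type1:
            dm = "type1"
        elif u < s.p_dm_type1 + s.p_dm_type2:
            dm = "type2"
        else:
            dm = "none"
        if rng.random() < s.p_smoking:
            smoking = SmokingStatus("current")
        elif rng.random() < 0.1:
            smoking = SmokingStatus("quit", quit_months=int(rng.integers(12, 120)))
        else:
            smoking = SmokingStatus("never")
        fh_dm = rng.random() < s.p_fh_dm
        fh_cvd = rng.random() < s.p_fh_cvd
        waist_threshold = 100.0 if sex == "male" else 90.0
        if rng.random() < s.p_high_waist:
            waist = waist_threshold + float(rng.uniform(0, 30))
        else:
            waist = waist_threshold - float(rng.uniform(1, 35))
        if rng.random() < 0.05:
            waist = None  # occasionally unmeasured

        conditions: set[str] = set()
        if stratum == "history_of_cvd":
            n_codes = 1 + int(rng.random() < 0.3)
            conditions = set(rng.choice(cvd_codes, size=n_codes, replace=False))

        enrol = spec.start_date + dt.timedelta(days=int(rng.integers(0, spec.enrolment_window_days)))

        sbp_true = _draw_trunc_normal(rng, s.sbp_mean, s.sbp_sd, spec.sbp_bounds)
        tc_true = _draw_trunc_normal(rng, s.tc_mean, s.tc_sd, spec.tc_bounds)
        sbp_missing = rng.random() < spec.p_missing_sbp
        tc_missing = rng.random() < spec.p_missing_tc

        measurements: list[Measurement] = []
        if not sbp_missing:
            measurements.append(Measurement(enrol, "sbp", round(sbp_true, 1)))
            if rng.random() < 0.7:  # follow-up visit reading
                fu = enrol + dt.timedelta(days=int(rng.integers(30, 90)))
                v = float(np.clip(sbp_true + rng.normal(0, 5), *spec.sbp_bounds))
                measurements.append(Measurement(fu, "sbp", round(v, 1)))
        if not tc_missing:
            lab = enrol + dt.timedelta(days=int(rng.integers(0, 14)))
            measurements.append(Measurement(lab, "total_cholesterol", round(tc_true, 2)))

        truth_cat = _truth_category(stratum, dm != "none", age, tc_true)
        prescribed = rng.random() < spec.prescribing.get(truth_cat, 0.0)
        prescriptions: list[Prescription] = []
        if prescribed:
            rx_date = enrol + dt.timedelta(days=int(rng.integers(21, 90)))
            prescriptions.append(Prescription(rx_date, "lipid_lowering"))
        if rng.random() < 0.5:
            prescriptions.append(
                Prescription(enrol + dt.timedelta(days=int(rng.integers(0, 30))), "other")
            )

        documented_scores: list[tuple[dt.date, RiskCategory]] = []
        documented = rng.random() < spec.p_documented
        doc_error: bool | None = None
        if documented:
            doc_date = enrol + dt.timedelta(days=int(rng.integers(14, 60)))
            doc_cat = RiskCategory(int(rng.choice(5, p=kernel[stratum])))
            documented_scores.append((doc_date, doc_cat))
            if stratum == "history_of_cvd":
                # a CVD history is clinically high risk; documenting <20% is an error
                doc_error = not doc_cat.is_high
            else:
                doc_error = doc_cat.label != stratum

        rec = PatientRecord(
            patient_id=f"S{i:06d}",
            sex=sex,
            age=age,
            enrolment_date=enrol,
            conditions=frozenset(conditions),
            family_history_cvd=fh_cvd,
            family_history_dm=fh_dm,
            diabetes_type=dm,
            smoking=smoking,
            waist_cm=None if waist is None else round(waist, 1),
            measurements=measurements,
            prescriptions=prescriptions,
            documented_scores=documented_scores,
        )
        if not meets_inclusion(rec):
            rec.family_history_dm = True

        records.append(rec)
        truth_rows.append(
            {
                "patient_id": rec.patient_id,
                "stratum": stratum,
                "truth_category": truth_cat,
                "sbp_true": sbp_true,
                "tc_true": tc_true,
                "sbp_missing": sbp_missing,
                "tc_missing": tc_missing,
                "documented": documented,
                "documentation_error": doc_error,
                "prescribed_llt": prescribed,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "stratum", "truth_category", "sbp_true", "tc_true",
            "sbp_missing", "tc_missing", "documented", "documentation_error",
            "prescribed_llt",
        ],
    )
    return SyntheticCohort(records=records, truth=truth)


def truth_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Latent ground truth per patient, for parameter-recovery tests."""
    return cohort.truth.copy()


# ---------------------------------------------------------------------------
# YAML spec round-trip
# ---------------------------------------------------------------------------


def save_spec(spec: CohortSpec, path) -> None:
    d = asdict(spec)
    d["start_date"] = spec.start_date.isoformat()
    d["sbp_bounds"] = list(spec.sbp_bounds)
    d["tc_bounds"] = list(spec.tc_bounds)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["strata"] = {k: StratumParams(**v) for k, v in d["strata"].items()}
    d["start_date"] = dt.date.fromisoformat(d["start_date"])
    d["sbp_bounds"] = tuple(d["sbp_bounds"])
    d["tc_bounds"] = tuple(d["tc_bounds"])
    spec = CohortSpec(**d)
    spec.validate()
    return spec
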