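"""WHO/ISH cardiovascular risk chart engine (cholesterol-based variant).

The WHO/ISH charts estimate 10-year combined fatal/non-fatal cardiovascular
event risk as a banded category from six axes: sex, age band, current smoking,
diabetes, systolic blood pressure band and total cholesterol band.  Charts are
published per epidemiological subregion; the default here targets EMR B
(Eastern Mediterranean region B, which covers Jordan and Syria).

The engine is a complete table lookup: a :class:`RiskChart` holds one category
for every one of the 2 x 4 x 2 x 2 x 4 x 5 = 640 cells, and scoring an
individual means discretising their risk factor values onto the chart axes and
reading the cell.  The published chart cell values are under WHO copyright and
are not redistributed here; the packaged default chart
(``data/chart_emrb_synthetic.csv``) is a synthetic stand-in built by
:func:`synthetic_chart` that reproduces the qualitative structure of the real
charts (monotone in every axis, roughly log-linear risk) without copying any
published cell.  Users with access to the published EMR B chart can transcribe
it into the same CSV format and pass it anywhere a chart is accepted.

Band conventions
----------------
All bands are half-open and lower-inclusive: SBP 140.0 falls in 140-159,
TC 5.0 in 5-<6, age 50 in the 50 band.  Adults aged 18-39 are scored with the
lowest (40-year) age band; the published charts start at 40 but the screening
protocol enrols qualifying adults from 18, so the youngest band is extended
downward as an explicit convention of this package.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RiskCategory",
    "RiskFactorInput",
    "RiskChart",
    "ChartError",
    "ChartReport",
    "age_band",
    "sbp_band",
    "tc_band",
    "calculate_risk",
    "validate_chart",
    "load_chart",
    "write_chart",
    "synthetic_chart",
    "default_chart",
    "AGE_BANDS",
    "SBP_BANDS",
    "TC_BANDS",
]


class RiskCategory(enum.IntEnum):
    """Ordered 10-year CVD risk stratum.

    The integer value is the rank (0 = lowest).  ``HIGH`` in clinical usage
    means risk >= 20%, i.e. rank >= 2.
    """

    UNDER_10 = 0
    FROM_10 = 1
    FROM_20 = 2
    FROM_30 = 3
    OVER_40 = 4

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    @property
    def is_high(self) -> bool:
        """True iff the stratum is at or above the 20% treatment threshold."""
        return self >= RiskCategory.FROM_20

    @classmethod
    def from_label(cls, label: str) -> "RiskCategory":
        try:
            return _LABEL_TO_CATEGORY[label.strip()]
        except KeyError:
            raise ValueError(
                f"invalid risk category label {label!r}; "
                f"expected one of {sorted(_LABEL_TO_CATEGORY)}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_CATEGORY_LABELS = {
    RiskCategory.UNDER_10: "<10",
    RiskCategory.FROM_10: "10-<20",
    RiskCategory.FROM_20: "20-<30",
    RiskCategory.FROM_30: "30-<40",
    RiskCategory.OVER_40: ">=40",
}
_LABEL_TO_CATEGORY = {v: k for k, v in _CATEGORY_LABELS.items()}
# tolerated spellings seen in hand-edited files
_LABEL_TO_CATEGORY.update(
    {
        "<10%": RiskCategory.UNDER_10,
        "10 to <20": RiskCategory.FROM_10,
        "20 to <30": RiskCategory.FROM_20,
        "30 to <40": RiskCategory.FROM_30,
        ">=40%": RiskCategory.OVER_40,
        "≥40": RiskCategory.OVER_40,
    }
)

AGE_BANDS: tuple[int, ...] = (40, 50, 60, 70)
SBP_BANDS: tuple[str, ...] = ("<140", "140-159", "160-179", ">=180")
TC_BANDS: tuple[str, ...] = ("<5", "5-<6", "6-<7", "7-<8", ">=8")
SEXES: tuple[str, ...] = ("male", "female")

#: (sex, age_band, smoker, diabetic, sbp_band, tc_band)
ChartKey = tuple[str, int, bool, bool, str, str]


def age_band(age: float) -> int:
    """Map an age in years to the chart age band (40, 50, 60 or 70).

    Adults under 40 are scored with the 40 band (see module docstring).
    Ages below 18 are outside the screening protocol and rejected.
    """
    if age < 18:
        raise ValueError(f"age {age} is below the adult screening threshold of 18")
    if age < 50:
        return 40
    if age < 60:
        return 50
    if age < 70:
        return 60
    return 70


def sbp_band(sbp: float) -> str:
    """Systolic blood pressure (mmHg) to chart row, half-open lower-inclusive."""
    if sbp <= 0:
        raise ValueError(f"SBP must be positive, got {sbp}")
    if sbp < 140:
        return "<140"
    if sbp < 160:
        return "140-159"
    if sbp < 180:
        return "160-179"
    return ">=180"


def tc_band(tc: float) -> str:
    """Total cholesterol (mmol/L) to chart column, half-open lower-inclusive."""
    if tc <= 0:
        raise ValueError(f"total cholesterol must be positive, got {tc}")
    if tc < 5:
        return "<5"
    if tc < 6:
        return "5-<6"
    if tc < 7:
        return "6-<7"
    if tc < 8:
        return "7-<8"
    return ">=8"


@dataclass(frozen=True)
class RiskFactorInput:
    """The six risk-factor values needed to score one person."""

    sex: str
    age: float
    smoker: bool
    diabetic: bool
    sbp: float
    tc: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.sbp <= 0 or self.tc <= 0:
            raise ValueError("SBP and total cholesterol must be positive")

    def chart_key(self) -> ChartKey:
        return (
            self.sex,
            age_band(self.age),
            bool(self.smoker),
            bool(self.diabetic),
            sbp_band(self.sbp),
            tc_band(self.tc),
        )


class ChartError(ValueError):
    """A chart failed validation or a lookup hit a missing cell."""


@dataclass
class ChartReport:
    """Validation report: empty lists mean the chart is usable."""

    missing: list[ChartKey] = field(default_factory=list)
    duplicates: list[ChartKey] = field(default_factory=list)
    invalid: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.duplicates or self.invalid)

    def summary(self) -> str:
        if self.ok:
            return "chart OK: 640/640 cells present and valid"
        parts = []
        if self.missing:
            parts.append(f"{len(self.missing)} missing cells (first: {self.missing[0]})")
        if self.duplicates:
            parts.append(f"{len(self.duplicates)} duplicated cells (first: {self.duplicates[0]})")
        if self.invalid:
            parts.append(f"{len(self.invalid)} invalid entries (first: {self.invalid[0]})")
        return "chart problems: " + "; ".join(parts)


def all_chart_keys() -> Iterable[ChartKey]:
    for sex in SEXES:
        for ab in AGE_BANDS:
            for smoker in (False, True):
                for diabetic in (False, True):
                    for sb in SBP_BANDS:
                        for tb in TC_BANDS:
                            yield (sex, ab, smoker, diabetic, sb, tb)


@dataclass
class RiskChart:
    """A complete banded risk lookup table for one subregion."""

    subregion: str
    cells: dict[ChartKey, RiskCategory]

    def lookup(self, inp: RiskFactorInput) -> RiskCategory:
        key = inp.chart_key()
        try:
            return self.cells[key]
        except KeyError:
            raise ChartError(
                f"chart {self.subregion!r} has no cell for {key}; run validate_chart"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subregion": self.subregion,
                "sex": k[0],
                "age_band": k[1],
                "smoker": k[2],
                "diabetic": k[3],
                "sbp_band": k[4],
                "tc_band": k[5],
                "category": v.label,
            }
            for k, v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def calculate_risk(inp: RiskFactorInput, chart: RiskChart) -> RiskCategory:
    """Score one person: discretise onto the chart axes and read the cell.

    Deterministic; any two inputs falling in the same cell get the same
    category, and nothing outside the six axes influences the result.
    """
    return chart.lookup(inp)


def validate_chart(chart: RiskChart) -> ChartReport:
    """Check completeness (all 640 cells) and cell-value validity."""
    report = ChartReport()
    for key in all_chart_keys():
        if key not in chart.cells:
            report.missing.append(key)
    for key, value in chart.cells.items():
        if not isinstance(value, RiskCategory):
            report.invalid.append((key, value))
    return report


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(x: str) -> bool:
    try:
        return _BOOL[str(x).strip().lower()]
    except KeyError:
        raise ValueError(f"cannot interpret {x!r} as a boolean") from None


def load_chart(path, subregion: str | None = None, strict: bool = True) -> RiskChart:
    """Load a chart CSV (one row per cell) and, if ``strict``, enforce the
    640-cell completeness invariant.

    Expected columns: subregion, sex, age_band, smoker, diabetic, sbp_band,
    tc_band, category.  Duplicate or invalid rows are collected and raised as
    a single :class:`ChartError` naming the offenders.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"subregion", "sex", "age_band", "smoker", "diabetic", "sbp_band", "tc_band", "category"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ChartError(f"chart file {path} lacks columns {sorted(missing_cols)}")
    if subregion is not None:
        df = df[df["subregion"] == subregion]
        if df.empty:
            raise ChartError(f"chart file {path} has no rows for subregion {subregion!r}")
    regions = df["subregion"].unique()
    if len(regions) > 1:
        raise ChartError(
            f"chart file holds multiple subregions {list(regions)}; pass subregion= to pick one"
        )
    report = ChartReport()
    cells: dict[ChartKey, RiskCategory] = {}
    for row in df.itertuples(index=False):
        try:
            key: ChartKey = (
                str(row.sex).strip().lower(),
                int(row.age_band),
                _parse_bool(row.smoker),
                _parse_bool(row.diabetic),
                str(row.sbp_band).strip(),
                str(row.tc_band).strip(),
            )
            cat = RiskCategory.from_label(str(row.category))
        except ValueError:
            report.invalid.append(tuple(row))
            continue
        if key in cells:
            report.duplicates.append(key)
            continue
        cells[key] = cat
    chart = RiskChart(subregion=str(regions[0]), cells=cells)
    completeness = validate_chart(chart)
    report.missing = completeness.missing
    if strict and not report.ok:
        raise ChartError(report.summary())
    return chart


def write_chart(chart: RiskChart, path) -> None:
    chart.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic default chart
# ---------------------------------------------------------------------------

# log-risk increments per axis step; tuned for plausibility, not transcribed
# from any published chart
_BASE_LOG_RISK = math.log(1.8)
_AGE_STEP = 0.50
_SBP_STEP = 0.30
_TC_STEP = 0.12
_SMOKER = 0.30
_DIABETIC = 0.45
_MALE = 0.20


def synthetic_chart(subregion: str = "EMR-B-synthetic") -> RiskChart:
    """Build the synthetic WHO/ISH-style chart shipped as the package default.

    Risk is modelled as log-linear in the axis ranks, anchored so a low-risk
    profile (young non-smoking non-diabetic woman with SBP <140 and TC <5)
    sits under 2% and the worst cell exceeds 40%, then cut at the chart
    thresholds 10/20/30/40%.  This reproduces the real charts' qualitative
    behaviour — risk is monotone in every axis, diabetes and smoking roughly
    multiply risk — but no cell value is copied from the published charts.
    """
    cells: dict[ChartKey, RiskCategory] = {}
    for sex, ab, smoker, diabetic, sb, tb in all_chart_keys():
        log_risk = (
            _BASE_LOG_RISK
            + _AGE_STEP * AGE_BANDS.index(ab)
            + _SBP_STEP * SBP_BANDS.index(sb)
            + _TC_STEP * TC_BANDS.index(tb)
            + (_SMOKER if smoker else 0.0)
            + (_DIABETIC if diabetic else 0.0)
            + (_MALE if sex == "male" else 0.0)
        )
        risk_pct = math.exp(log_risk)
        if risk_pct < 10:
            cat = RiskCategory.UNDER_10
        elif risk_pct < 20:
            cat = RiskCategory.FROM_10
        elif risk_pct < 30:
            cat = RiskCategory.FROM_20
        elif risk_pct < 40:
            cat = RiskCategory.FROM_30
        else:
            cat = RiskCategory.OVER_40
        cells[(sex, ab, smoker, diabetic, sb, tb)] = cat
    return RiskChart(subregion=subregion, cells=cells)


def default_chart_path():
    """Path of the packaged synthetic EMR-B-style chart CSV."""
    from importlib.resources import files

    return files("penrisk") / "data" / "chart_emrb_synthetic.csv"


def default_chart() -> RiskChart:
    return load_chart(default_chart_path())
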