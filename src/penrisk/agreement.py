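"""Documented-vs-calculated risk agreement: cross-tabulation, Cohen's kappa,
and binomial confidence intervals.

The accuracy analysis compares the risk category a clinician wrote in the
record (*documented*) with the category recalculated from the recorded risk
factors (*calculated*).  Patients with a CVD history are carried on the
calculated side as their own ``history_of_cvd`` level, since their management
is secondary prevention regardless of chart score.  Two derived views are
provided:

* a binary 2x2 aggregation at the clinically significant 20% threshold,
  where a CVD history counts as calculated-high;
* a kappa-ready square table after the *CVD match rule*: a CVD-history
  patient whose documented score was >= 20% is coded as a match (the
  documented category is copied onto the calculated side), because the
  clinician's high-risk call was clinically correct.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .charts import RiskCategory
from .emr import PatientRecord, has_cvd_history, smoking_positive
from .selection import ImputationModel, complete_inputs
from . import charts

__all__ = [
    "HISTORY_OF_CVD",
    "CATEGORY_LABELS",
    "documented_accuracy_pairs",
    "agreement_table",
    "aggregate_binary",
    "apply_cvd_match_rule",
    "square_table",
    "cohen_kappa",
    "observed_agreement",
    "proportion_ci",
]

#: Sentinel for the calculated-side secondary-prevention level.
HISTORY_OF_CVD = "history_of_cvd"

CATEGORY_LABELS = tuple(c.label for c in RiskCategory)
CALCULATED_LABELS = CATEGORY_LABELS + (HISTORY_OF_CVD,)

Calculated = RiskCategory | str  # a RiskCategory or HISTORY_OF_CVD
Pair = tuple[RiskCategory, Calculated]


def _calc_label(c: Calculated) -> str:
    return c if isinstance(c, str) else c.label


def documented_accuracy_pairs(
    patients: Sequence[PatientRecord],
    chart: charts.RiskChart,
    model: ImputationModel,
    strict: bool = True,
) -> list[Pair]:
    """One (documented, calculated) pair per patient with a documented score.

    The index date is the date of the patient's first documented score; SBP
    and TC are selected retrospectively from it and imputed where absent.
    The calculated side is ``history_of_cvd`` for patients with a CVD
    history, else the chart category.
    """
    pairs: list[Pair] = []
    for p in patients:
        doc = p.first_documented_score()
        if doc is None:
            continue
        doc_date, doc_cat = doc
        if has_cvd_history(p.conditions):
            pairs.append((doc_cat, HISTORY_OF_CVD))
            continue
        row = complete_inputs(p, doc_date, "retrospective", model, strict=strict)
        calc = charts.calculate_risk(
            charts.RiskFactorInput(
                sex=p.sex,
                age=p.age,
                smoker=smoking_positive(p.smoking),
                diabetic=p.is_diabetic,
                sbp=row.sbp,
                tc=row.tc,
            ),
            chart,
        )
        pairs.append((doc_cat, calc))
    return pairs


def agreement_table(pairs: Sequence[Pair]) -> pd.DataFrame:
    """5x6 cross-tab: documented category rows x calculated status columns."""
    tab = pd.DataFrame(
        0, index=list(CATEGORY_LABELS), columns=list(CALCULATED_LABELS), dtype=int
    )
    for doc, calc in pairs:
        tab.loc[doc.label, _calc_label(calc)] += 1
    tab.index.name = "documented"
    tab.columns.name = "calculated"
    return tab


def aggregate_binary(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse to 2x2 at the 20% threshold; CVD history counts as
    calculated-high.  Total count is conserved."""
    high_rows = [c.label for c in RiskCategory if c.is_high]
    low_rows = [c.label for c in RiskCategory if not c.is_high]
    high_cols = high_rows + [HISTORY_OF_CVD]
    low_cols = low_rows
    out = pd.DataFrame(
        {
            "high": [
                int(table.loc[high_rows, high_cols].to_numpy().sum()),
                int(table.loc[low_rows, high_cols].to_numpy().sum()),
            ],
            "low": [
                int(table.loc[high_rows, low_cols].to_numpy().sum()),
                int(table.loc[low_rows, low_cols].to_numpy().sum()),
            ],
        },
        index=["high", "low"],
    )
    out.index.name = "documented"
    out.columns.name = "calculated"
    return out


def apply_cvd_match_rule(pairs: Sequence[Pair]) -> list[Pair]:
    """Code CVD-history patients with a documented score >= 20% as matches.

    For those pairs the calculated side is rewritten to equal the documented
    category; every other pair is returned unchanged.  The resulting square
    cross-tab can only gain diagonal mass.
    """
    out: list[Pair] = []
    for doc, calc in pairs:
        if calc == HISTORY_OF_CVD and doc.is_high:
            out.append((doc, doc))
        else:
            out.append((doc, calc))
    return out


def square_table(pairs: Sequence[Pair]) -> pd.DataFrame:
    """6x6 square cross-tab over the five categories plus ``history_of_cvd``.

    The documented margin of the CVD level is structurally empty (clinicians
    document a chart category, never "history of CVD"); the level is kept so
    that CVD patients documented <20% remain representable after the match
    rule.
    """
    labels = list(CALCULATED_LABELS)
    tab = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for doc, calc in pairs:
        tab.loc[doc.label, _calc_label(calc)] += 1
    tab.index.name = "documented"
    tab.columns.name = "calculated"
    return tab


def cohen_kappa(table) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``table`` is any square count matrix (array or DataFrame) with the same
    category order on rows and columns.  Returns NaN ("undefined") when the
    expected agreement p_e equals 1 (all mass in a single row and column).
    """
    a = np.asarray(table, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"kappa needs a square table, got shape {a.shape}")
    n = a.sum()
    if n < 1:
        raise ValueError("kappa needs at least one observation")
    p_o = np.trace(a) / n
    p_e = float(np.dot(a.sum(axis=1), a.sum(axis=0))) / n**2
    if math.isclose(p_e, 1.0):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def observed_agreement(table) -> float:
    """Raw diagonal proportion p_o of a square cross-tab."""
    a = np.asarray(table, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"observed agreement needs a square table, got shape {a.shape}")
    return float(np.trace(a) / a.sum())


_Z95 = stats.norm.ppf(0.975)


def proportion_ci(
    x: int, n: int, method: str = "wilson_cc", level: float = 0.95
) -> tuple[float, float]:
    """Two-sided confidence interval for a binomial proportion x/n.

    ``wilson_cc`` is the Wilson score interval with continuity correction;
    ``exact`` is Clopper-Pearson (beta quantiles).  Both are clipped to
    [0, 1] and always bracket x/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    alpha = 1.0 - level
    p = x / n
    if method == "wilson_cc":
        z = stats.norm.ppf(1 - alpha / 2)
        z2 = z * z
        denom = 2 * (n + z2)
        if x == 0:
            lower = 0.0
        else:
            lower = (2 * n * p + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
        if x == n:
            upper = 1.0
        else:
            upper = (2 * n * p + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    elif method == "exact":
        lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    else:
        raise ValueError(f"method must be 'wilson_cc' or 'exact', got {method!r}")
    return (max(0.0, min(lower, p)), min(1.0, max(upper, p)))
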