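"""Agreement statistics: cross-tabs, the CVD match rule, Cohen's kappa, CIs."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from penrisk.agreement import (
    CALCULATED_LABELS,
    HISTORY_OF_CVD,
    aggregate_binary,
    agreement_table,
    apply_cvd_match_rule,
    cohen_kappa,
    documented_accuracy_pairs,
    observed_agreement,
    proportion_ci,
    square_table,
)
from penrisk.charts import RiskCategory
from penrisk.selection import ImputationModel

from conftest import ENROL, make_patient, sbp, tc

MODEL = ImputationModel(130.0, 2.0, 0.03, 0.4, 0.01, fit_n=10)

# Published documented-vs-calculated cross-tabulation used as a worked input:
# rows = documented category, columns = calculated <10, 10-<20, 20-<30,
# 30-<40, >=40, history-of-CVD.
STUDY_TABLE = {
    "<10": [413, 52, 25, 15, 14, 56],
    "10-<20": [38, 22, 10, 3, 2, 5],
    "20-<30": [2, 2, 4, 2, 3, 1],
    "30-<40": [1, 1, 0, 4, 4, 0],
    ">=40": [0, 0, 0, 0, 1, 0],
}


def study_pairs():
    pairs = []
    for doc_label, counts in STUDY_TABLE.items():
        doc = RiskCategory.from_label(doc_label)
        for calc, count in zip(list(RiskCategory) + [HISTORY_OF_CVD], counts):
            pairs.extend([(doc, calc)] * count)
    return pairs


class TestPairs:
    def test_first_documented_score_used(self, constant_low_chart):
        p = make_patient(
            measurements=[sbp(-5, 120.0), tc(-3, 4.0)],
            documented_scores=[
                (ENROL + dt.timedelta(days=40), RiskCategory.FROM_20),
                (ENROL + dt.timedelta(days=10), RiskCategory.UNDER_10),
            ],
        )
        pairs = documented_accuracy_pairs([p], constant_low_chart, MODEL)
        assert pairs == [(RiskCategory.UNDER_10, RiskCategory.UNDER_10)]

    def test_undocumented_patients_excluded(self, constant_low_chart):
        p = make_patient(measurements=[sbp(-5, 120.0)])
        assert documented_accuracy_pairs([p], constant_low_chart, MODEL) == []

    def test_cvd_history_on_calculated_side(self, constant_low_chart):
        p = make_patient(
            conditions={"congestive_heart_failure"},
            documented_scores=[(ENROL, RiskCategory.FROM_30)],
        )
        pairs = documented_accuracy_pairs([p], constant_low_chart, MODEL)
        assert pairs == [(RiskCategory.FROM_30, HISTORY_OF_CVD)]

    def test_retrospective_selection_from_documentation_date(self, tc_rank_chart):
        # TC 8.5 recorded before the documented score drives the category (>=8 band -> rank 4)
        p = make_patient(
            age=50,
            measurements=[sbp(-10, 120.0), tc(-5, 8.5), tc(10, 4.0)],
            documented_scores=[(ENROL, RiskCategory.UNDER_10)],
        )
        pairs = documented_accuracy_pairs([p], tc_rank_chart, MODEL)
        assert pairs == [(RiskCategory.UNDER_10, RiskCategory.OVER_40)]


class TestAggregateBinary:
    def test_study_table_collapses_to_published_2x2(self):
        table = agreement_table(study_pairs())
        assert int(table.to_numpy().sum()) == 680
        binary = aggregate_binary(table)
        assert binary.loc["high", "high"] == 19
        assert binary.loc["high", "low"] == 6
        assert binary.loc["low", "high"] == 130
        assert binary.loc["low", "low"] == 525

    def test_all_zero(self):
        empty = agreement_table([])
        assert aggregate_binary(empty).to_numpy().sum() == 0

    def test_cvd_column_counts_as_calculated_high(self):
        table = agreement_table([(RiskCategory.UNDER_10, HISTORY_OF_CVD)])
        binary = aggregate_binary(table)
        assert binary.loc["low", "high"] == 1 and binary.to_numpy().sum() == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(RiskCategory)),
                st.sampled_from(list(RiskCategory) + [HISTORY_OF_CVD]),
            ),
            max_size=50,
        )
    )
    def test_count_conservation(self, pairs):
        table = agreement_table(pairs)
        assert int(aggregate_binary(table).to_numpy().sum()) == len(pairs)


class TestCvdMatchRule:
    def test_high_documented_cvd_becomes_match(self):
        out = apply_cvd_match_rule([(RiskCategory.FROM_30, HISTORY_OF_CVD)])
        assert out == [(RiskCategory.FROM_30, RiskCategory.FROM_30)]

    def test_low_documented_cvd_unchanged(self):
        pairs = [(RiskCategory.UNDER_10, HISTORY_OF_CVD)]
        assert apply_cvd_match_rule(pairs) == pairs

    def test_non_cvd_unchanged(self):
        pairs = [(RiskCategory.FROM_20, RiskCategory.UNDER_10)]
        assert apply_cvd_match_rule(pairs) == pairs

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(RiskCategory)),
                st.sampled_from(list(RiskCategory) + [HISTORY_OF_CVD]),
            ),
            max_size=50,
        )
    )
    def test_diagonal_never_decreases(self, pairs):
        before = np.trace(square_table(pairs).to_numpy())
        after = np.trace(square_table(apply_cvd_match_rule(pairs)).to_numpy())
        assert after >= before


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 3, 9])) == pytest.approx(1.0)

    def test_independent_margins_give_zero(self):
        rows = np.array([10, 20, 5], dtype=float)
        cols = np.array([8, 4, 12], dtype=float)
        table = np.outer(rows, cols)  # p_o == p_e by construction
        assert cohen_kappa(table) == pytest.approx(0.0, abs=1e-12)

    def test_published_2x2(self):
        """Hand arithmetic: p_o = 544/680, p_e = 351530/462400."""
        table = np.array([[19, 6], [130, 525]])
        expected = (544 / 680 - 351530 / 462400) / (1 - 351530 / 462400)
        assert cohen_kappa(table) == pytest.approx(expected)
        assert cohen_kappa(table) == pytest.approx(0.166, abs=5e-4)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cohen_kappa(np.ones((2, 3)))

    def test_degenerate_table_undefined(self):
        assert math.isnan(cohen_kappa(np.array([[7, 0], [0, 0]])))

    @given(
        table=st.lists(
            st.lists(st.integers(0, 20), min_size=3, max_size=3), min_size=3, max_size=3
        ),
        perm=st.permutations([0, 1, 2]),
    )
    def test_label_permutation_invariance(self, table, perm):
        a = np.array(table, dtype=float)
        if a.sum() == 0:
            return
        p = list(perm)
        k1 = cohen_kappa(a)
        k2 = cohen_kappa(a[np.ix_(p, p)])
        if math.isnan(k1):
            assert math.isnan(k2)
        else:
            assert k1 == pytest.approx(k2)

    @given(
        table=st.lists(
            st.lists(st.integers(0, 15), min_size=3, max_size=3), min_size=3, max_size=3
        )
    )
    def test_matches_statsmodels(self, table):
        """Independent cross-check against the statsmodels implementation."""
        from statsmodels.stats.inter_rater import cohens_kappa

        a = np.array(table, dtype=float)
        margins_ok = a.sum() > 0 and not math.isclose(
            float(np.dot(a.sum(1), a.sum(0))) / a.sum() ** 2, 1.0
        )
        if not margins_ok:
            return
        ours = cohen_kappa(a)
        theirs = float(cohens_kappa(a, return_results=False))
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_matches_resampling_estimate_of_chance_agreement(self):
        """Monte-Carlo oracle: estimate expected chance agreement by pairing
        independent draws from the row and column margins."""
        rng = np.random.default_rng(42)
        table = np.array([[30, 5, 2], [4, 25, 6], [1, 7, 20]], dtype=float)
        n = table.sum()
        rows = rng.choice(3, size=200_000, p=table.sum(1) / n)
        cols = rng.choice(3, size=200_000, p=table.sum(0) / n)
        p_e_hat = float(np.mean(rows == cols))
        p_o = np.trace(table) / n
        kappa_hat = (p_o - p_e_hat) / (1 - p_e_hat)
        assert cohen_kappa(table) == pytest.approx(kappa_hat, abs=0.01)


class TestSquareTable:
    def test_residual_cvd_level_retained(self):
        pairs = apply_cvd_match_rule(
            [
                (RiskCategory.FROM_30, HISTORY_OF_CVD),  # becomes a match
                (RiskCategory.UNDER_10, HISTORY_OF_CVD),  # stays in the CVD column
            ]
        )
        table = square_table(pairs)
        assert list(table.columns) == list(CALCULATED_LABELS)
        assert table.loc["30-<40", "30-<40"] == 1
        assert table.loc["<10", HISTORY_OF_CVD] == 1
        assert table.loc[HISTORY_OF_CVD].sum() == 0  # documented margin empty

    def test_observed_agreement_on_study_table(self):
        table = square_table(study_pairs())
        assert observed_agreement(table) == pytest.approx(444 / 680)


class TestProportionCi:
    def test_wilson_cc_published_example(self):
        lo, hi = proportion_ci(4, 11, "wilson_cc")
        assert round(100 * lo, 1) == 12.4
        assert round(100 * hi, 1) == 68.4

    def test_exact_published_example(self):
        lo, hi = proportion_ci(6, 25, "exact")
        assert round(lo, 2) == 0.09
        assert round(hi, 2) == 0.45

    def test_boundaries(self):
        assert proportion_ci(0, 10, "wilson_cc")[0] == 0.0
        assert proportion_ci(10, 10, "wilson_cc")[1] == 1.0
        assert proportion_ci(0, 10, "exact")[0] == 0.0
        assert proportion_ci(10, 10, "exact")[1] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_ci(1, 10, method="wald")

    @given(n=st.integers(1, 200), frac=st.floats(0, 1))
    def test_interval_brackets_the_estimate(self, n, frac):
        x = min(n, int(frac * (n + 1)))
        for method in ("wilson_cc", "exact"):
            lo, hi = proportion_ci(x, n, method)
            assert 0.0 <= lo <= x / n <= hi <= 1.0

    @given(n=st.integers(1, 80), frac=st.floats(0, 1))
    def test_exact_matches_statsmodels_beta(self, n, frac):
        from statsmodels.stats.proportion import proportion_confint

        x = min(n, int(frac * (n + 1)))
        lo, hi = proportion_ci(x, n, "exact")
        slo, shi = proportion_confint(x, n, method="beta")
        assert lo == pytest.approx(float(slo), abs=1e-10)
        assert hi == pytest.approx(float(shi), abs=1e-10)
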