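"""Index-date measurement selection and the two imputation procedures."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

from penrisk.selection import (
    ImputationModel,
    SelectedInputs,
    complete_inputs,
    first_prospective,
    first_retrospective,
    fit_tc_model,
    impute_sbp,
    impute_tc,
    resolve_cohort_inputs,
)

from conftest import ENROL, make_patient, sbp, tc


class TestProspective:
    def test_earliest_after_index(self):
        ms = [sbp(10, 150.0), sbp(3, 140.0)]
        assert first_prospective(ms, ENROL, "sbp").value == 140.0

    def test_absent_when_nothing_follows(self):
        assert first_prospective([sbp(-5, 120.0)], ENROL, "sbp") is None
        assert first_prospective([], ENROL, "sbp") is None

    def test_same_date_tie_uses_file_order(self):
        ms = [sbp(3, 111.0), sbp(3, 222.0)]
        assert first_prospective(ms, ENROL, "sbp").value == 111.0
        assert first_prospective(list(reversed(ms)), ENROL, "sbp").value == 222.0

    def test_missing_flagged_rows_skipped(self):
        from penrisk.emr import Measurement

        ms = [Measurement(ENROL, "sbp", None, missing=True), sbp(5, 130.0)]
        assert first_prospective(ms, ENROL, "sbp").value == 130.0


class TestRetrospective:
    def test_most_recent_prior(self):
        ms = [sbp(-20, 120.0), sbp(-2, 150.0)]
        assert first_retrospective(ms, ENROL, "sbp").value == 150.0

    def test_index_day_excluded_when_strict(self):
        ms = [sbp(0, 150.0)]
        assert first_retrospective(ms, ENROL, "sbp", strict=True) is None
        assert first_retrospective(ms, ENROL, "sbp", strict=False).value == 150.0

    def test_empty_history(self):
        assert first_retrospective([], ENROL, "sbp") is None

    @given(st.permutations(list(range(5))))
    def test_permutation_invariant_without_ties(self, order):
        """Selection depends only on dates/values, not on record order,
        whenever all dates are distinct."""
        ms = [sbp(-d - 1, 100.0 + d) for d in range(5)]
        shuffled = [ms[i] for i in order]
        assert first_retrospective(shuffled, ENROL, "sbp").value == 100.0


def _row(pid="P", sex="female", age=50, sbp_v=None, tc_v=None):
    return SelectedInputs(pid, sex, age, sbp_v, tc_v)


class TestImputeSbp:
    def test_fills_and_flags(self):
        rows = impute_sbp([_row(sbp_v=None), _row("Q", sbp_v=142.0)])
        assert rows[0].sbp == 130.0 and rows[0].sbp_imputed
        assert rows[1].sbp == 142.0 and not rows[1].sbp_imputed

    def test_noop_is_identity(self):
        rows = [_row(sbp_v=120.0), _row("Q", sbp_v=135.0)]
        assert impute_sbp(rows) == rows

    def test_custom_fill(self):
        assert impute_sbp([_row()], fill=125.0)[0].sbp == 125.0


class TestFitTcModel:
    TRUTH = (2.0, 0.03, 0.4, 0.01)  # intercept, age, female, sbp

    def _exact_rows(self, n=50, rng=None, noise=0.0):
        rng = rng or np.random.default_rng(7)
        rows = []
        b0, ba, bf, bs = self.TRUTH
        for i in range(n):
            age = int(rng.integers(20, 80))
            female = i % 2
            sbp_v = float(rng.uniform(100, 180))
            tc_v = b0 + ba * age + bf * female + bs * sbp_v + (rng.normal(0, noise) if noise else 0)
            rows.append(_row(f"P{i}", "female" if female else "male", age, sbp_v, tc_v))
        return rows

    def test_zero_noise_exact_recovery(self):
        model = fit_tc_model(self._exact_rows())
        np.testing.assert_allclose(
            [model.intercept, model.coef_age, model.coef_female, model.coef_sbp],
            self.TRUTH,
            atol=1e-8,
        )

    def test_noisy_fit_matches_independent_normal_equations(self):
        """The fitted coefficients equal an independent normal-equations
        solve and land within 3 SEs of the generating truth."""
        rng = np.random.default_rng(11)
        rows = self._exact_rows(n=5000, rng=rng, noise=0.5)
        model = fit_tc_model(rows)

        # independent oracle: solve (X'X) b = X'y directly
        X = np.column_stack(
            [
                np.ones(len(rows)),
                [r.age for r in rows],
                [1.0 if r.sex == "female" else 0.0 for r in rows],
                [r.sbp for r in rows],
            ]
        )
        y = np.array([r.tc for r in rows])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            [model.intercept, model.coef_age, model.coef_female, model.coef_sbp],
            beta,
            rtol=1e-8,
        )
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(rows) - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(beta - self.TRUTH) < 3 * se)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_tc_model(self._exact_rows(n=3))

    def test_rank_deficient_rejected(self):
        rows = [_row(f"P{i}", "female", 50, 130.0, 5.0) for i in range(10)]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_tc_model(rows)


class TestImputeTc:
    MODEL = ImputationModel(130.0, 2.0, 0.03, 0.4, 0.01, fit_n=50)

    def test_affine_prediction(self):
        # 2 + 0.03*50 + 0.4 + 0.01*130 = 5.2
        rows = impute_tc([_row(age=50, sex="female", sbp_v=130.0)], self.MODEL)
        assert rows[0].tc == pytest.approx(5.2)
        assert rows[0].tc_imputed

    def test_observed_untouched(self):
        rows = impute_tc([_row(sbp_v=130.0, tc_v=6.6)], self.MODEL)
        assert rows[0].tc == 6.6 and not rows[0].tc_imputed

    def test_requires_sbp_first(self):
        with pytest.raises(ValueError, match="SBP must be imputed"):
            impute_tc([_row(sbp_v=None)], self.MODEL)

    def test_all_missing_cohort_becomes_scoreable(self):
        rows = impute_tc(impute_sbp([_row(pid=f"P{i}", age=40 + i) for i in range(10)]), self.MODEL)
        assert all(r.sbp is not None and r.tc is not None for r in rows)
        assert all(r.sbp_imputed and r.tc_imputed for r in rows)


class TestCohortResolution:
    def test_sbp_fill_precedes_tc_model(self):
        """A patient missing both values gets TC predicted from SBP=130,
        proving the fill happened before the model was applied."""
        complete = [
            make_patient(pid=f"C{i}", age=40 + i, sex="female" if i % 2 else "male",
                         measurements=[sbp(0, 110.0 + (13 * i) % 50), tc(1, 4.0 + (7 * i) % 9 * 0.3)])
            for i in range(8)
        ]
        target = make_patient(pid="T", age=50, sex="female")
        rows, model = resolve_cohort_inputs(complete + [target])
        t = next(r for r in rows if r.patient_id == "T")
        assert t.sbp == 130.0 and t.sbp_imputed and t.tc_imputed
        assert t.tc == pytest.approx(model.predict_tc(50, "female", 130.0))

    def test_imputed_flags_mark_exactly_the_filled_entries(self):
        complete = [
            make_patient(pid=f"C{i}", age=40 + i, sex="female" if i % 2 else "male",
                         measurements=[sbp(0, 110.0 + (13 * i) % 50), tc(1, 4.0 + (7 * i) % 9 * 0.3)])
            for i in range(8)
        ]
        rows, _ = resolve_cohort_inputs(complete)
        assert not any(r.sbp_imputed or r.tc_imputed for r in rows)
        assert [r.sbp for r in rows] == [110.0 + (13 * i) % 50 for i in range(8)]

    def test_complete_inputs_retrospective(self):
        p = make_patient(measurements=[sbp(-10, 150.0), sbp(5, 170.0), tc(-3, 6.0)])
        model = ImputationModel(130.0, 2.0, 0.03, 0.4, 0.01, fit_n=10)
        row = complete_inputs(p, ENROL, "retrospective", model)
        assert row.sbp == 150.0 and row.tc == 6.0
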