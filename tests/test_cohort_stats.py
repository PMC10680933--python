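"""Survival machinery, association dispatch, TIL categorization, risk groups."""

import numpy as np
import pandas as pd
import pytest

from stromaratio.cohort_stats import (
    PatientRecord,
    association_test,
    categorize_til,
    cox_fit,
    frame_to_records,
    joint_risk_group,
    km_estimate,
    logrank_test,
    records_to_frame,
    screen_and_select,
)
from stromaratio.errors import DataError, FitError, ParameterError
from stromaratio.synthetic_data import CohortSpec, generate_cohort
from stromaratio.tsr import STROMA_POOR, STROMA_RICH


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([3.0, 7.0, 9.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0
        assert km.n_events == 0

    def test_product_limit_by_hand_all_events(self):
        km = km_estimate([5.0, 10.0, 15.0], [1, 1, 1])
        assert km.survival_at(5.0) == pytest.approx(2 / 3)
        assert km.survival_at(10.0) == pytest.approx(1 / 3)
        assert km.survival_at(15.0) == 0.0
        assert km.survival_at(4.9) == 1.0

    def test_product_limit_with_censoring_by_hand(self):
        # censored at 10: risk set at t=15 is {15}, so S drops 2/3 -> 0
        km = km_estimate([5.0, 10.0, 15.0], [1, 0, 1])
        assert km.survival_at(5.0) == pytest.approx(2 / 3)
        assert km.survival_at(14.9) == pytest.approx(2 / 3)
        assert km.survival_at(15.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 50)
        km = km_estimate(t, np.ones(50, int))
        for q in (5.0, 10.0, 20.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(DataError):
            km_estimate([-1.0], [1])


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        g = (np.array([2.0, 4.0, 6.0]), np.array([1, 1, 0]))
        for k in (2, 3, 4):
            chi2, df, p = logrank_test([g] * k)
            assert chi2 == pytest.approx(0.0, abs=1e-10)
            assert df == k - 1
            assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_statistic(self, toy_survival):
        # summing hypergeometric O-E terms over the six event times gives
        # (O-E) = 1.85 and Var = 0.6775
        chi2, df, p = logrank_test([toy_survival["a"], toy_survival["b"]])
        assert chi2 == pytest.approx(1.85**2 / 0.6775, rel=1e-9)
        assert df == 1

    def test_single_group_rejected(self, toy_survival):
        with pytest.raises(ParameterError):
            logrank_test([toy_survival["a"]])

    def test_no_events_rejected(self):
        with pytest.raises(ParameterError):
            logrank_test([([1.0, 2.0], [0, 0]), ([3.0], [0])])


class TestCox:
    @staticmethod
    def _frame(n, rng, hr=1.0):
        x = (rng.random(n) < 0.4).astype(float)
        lam = np.log(2) / 40.0 * np.where(x == 1, hr, 1.0)
        t = rng.exponential(1 / lam)
        e = np.ones(n, dtype=int)
        cens = rng.choice(n, size=n // 5, replace=False)
        e[cens] = 0
        t[cens] *= rng.random(len(cens))
        return pd.DataFrame({"time": t, "event": e, "x": x})

    def test_null_covariate_log_hr_near_zero(self):
        df = self._frame(2000, np.random.default_rng(1), hr=1.0)
        res = cox_fit(df, covariates=["x"])
        assert abs(np.log(res.hr("x"))) < 0.1

    def test_recovers_true_hazard_ratio(self):
        df = self._frame(2000, np.random.default_rng(2), hr=1.6)
        res = cox_fit(df, covariates=["x"])
        assert 1.45 <= res.hr("x") <= 1.77
        assert res.table.loc["x", "ci_lower"] <= res.hr("x") <= res.table.loc["x", "ci_upper"]
        assert res.ties == "efron"

    def test_no_events_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(FitError):
            cox_fit(df, covariates=["x"])

    def test_constant_covariate_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(FitError):
            cox_fit(df, covariates=["x"])


class TestScreenAndSelect:
    @staticmethod
    def _frame(n, rng, conf_hr=1.0):
        exposure = (rng.random(n) < 0.4).astype(float)
        confounder = (rng.random(n) < 0.5).astype(float)
        noise = (rng.random(n) < 0.5).astype(float)
        lam = np.log(2) / 40.0 * np.where(confounder == 1, conf_hr, 1.0)
        t = rng.exponential(1 / lam)
        return pd.DataFrame(
            {"time": t, "event": 1, "exposure": exposure, "conf": confounder, "noise": noise}
        )

    def test_exposure_forced_even_when_null(self):
        df = self._frame(300, np.random.default_rng(3))
        res = screen_and_select(df, "OS", ["conf", "noise"], exposure="exposure")
        assert "exposure" in res.table.index

    def test_strong_confounder_retained(self):
        kept = 0
        for seed in range(10):
            df = self._frame(400, np.random.default_rng(seed), conf_hr=2.5)
            res = screen_and_select(df, "OS", ["conf", "noise"], exposure="exposure")
            if "conf" in res.table.index:
                kept += 1
        assert kept >= 9

    def test_null_candidates_mostly_dropped(self):
        only_exposure = 0
        for seed in range(10):
            df = self._frame(300, np.random.default_rng(100 + seed))
            res = screen_and_select(df, "OS", ["conf", "noise"], exposure="exposure")
            if list(res.table.index) == ["exposure"]:
                only_exposure += 1
        assert only_exposure >= 7
        assert res.selection_trace  # trace is recorded


class TestAssociationDispatch:
    def test_printed_cd68_table_chi_square(self):
        # 2x2 with all expected counts >= 5 dispatches to chi-square without
        # continuity correction; p rounds to 0.002
        name, stat, p = association_test([[70, 46], [23, 2]])
        assert name == "chi-square"
        assert round(p, 3) == 0.002

    def test_balanced_table_p_one(self):
        name, stat, p = association_test([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_sparse_table_dispatches_fisher(self):
        # expected counts (1.5, 8.5, 1.5, 8.5): 50% below 5
        name, stat, p = association_test([[1, 9], [2, 8]])
        assert name == "fisher"
        assert stat is None

    def test_dispatch_is_function_of_expected_counts(self):
        # scaling the same proportions up pushes expected counts over 5
        name, _, _ = association_test([[10, 90], [20, 80]])
        assert name == "chi-square"

    def test_sparse_rxc_refused_with_message(self):
        with pytest.raises(ParameterError, match="Fisher"):
            association_test([[1, 0, 1], [0, 1, 0], [1, 1, 0]])

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            association_test([[0, 0], [3, 4]])


class TestTilCategorization:
    def test_quartile_threshold_with_interpolated_boundary(self):
        res = categorize_til([0, 0, 1, 1, 2, 2, 3, 3], "quartile_binary")
        assert res.thresholds == (3,)
        assert list(res.labels) == ["LOW"] * 6 + ["HIGH"] * 2

    def test_tied_mass_goes_up(self):
        res = categorize_til([5, 5, 5, 0, 0, 0, 0, 0], "quartile_binary")
        assert (res.labels == "HIGH").sum() == 3

    def test_all_equal_degenerates_to_low(self):
        res = categorize_til([2, 2, 2, 2], "quartile_binary")
        assert res.degenerate
        assert set(res.labels) == {"LOW"}

    def test_tertile_scheme_orders_levels(self):
        res = categorize_til([0, 0, 1, 2, 2, 3, 4, 5], "tertile_3way")
        codes = {"LOW": 0, "MEDIUM": 1, "HIGH": 2}
        mapped = [codes[l] for l in res.labels]
        assert sorted(mapped) == mapped  # input sorted -> labels monotone

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            categorize_til([])


class TestJointRiskGroup:
    @pytest.mark.parametrize(
        "stroma,til,expected",
        [
            (STROMA_POOR, "HIGH", "LOW"),
            (STROMA_RICH, "HIGH", "MEDIUM"),
            (STROMA_POOR, "LOW", "MEDIUM"),
            (STROMA_RICH, "LOW", "HIGH"),
        ],
    )
    def test_mapping(self, stroma, til, expected):
        assert joint_risk_group(stroma, til) == expected

    def test_missing_input_rejected(self):
        with pytest.raises(DataError):
            joint_risk_group("UNKNOWN", "HIGH")


class TestRecordsRoundTrip:
    def test_frame_round_trip(self):
        records, _ = generate_cohort(CohortSpec(n_patients=25, seed=5))
        frame = records_to_frame(records)
        back = frame_to_records(frame)
        assert len(back) == 25
        assert back[0].patient_id == records[0].patient_id
        assert back[3].til_scores == records[3].til_scores
        assert back[7].os_months == pytest.approx(records[7].os_months)

    def test_pfs_exceeding_os_rejected(self):
        with pytest.raises(DataError):
            PatientRecord("p", "PDS", os_months=10.0, os_event=1, pfs_months=12.0, pfs_event=1)

    def test_missing_required_columns(self):
        with pytest.raises(DataError):
            frame_to_records(pd.DataFrame({"patient_id": ["a"]}))
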