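import numpy as np
import pandas as pd
import pytest

import neoscr as ns
from neoscr.errors import CollinearityError, ValidationError
from neoscr.models import (
    DaywiseExposureModel,
    DaywiseExposureResults,
    build_daywise_design,
)


def results_with_params(beta_exposed, beta_interaction, cov_scale=1e-4, interaction_var=None):
    """Hand-built Results object to exercise the contrast formulas in closed form."""
    index = ["const", "time", "exposed", "exposed:time"]
    params = pd.Series([1.0, 0.0, beta_exposed, beta_interaction], index=index)
    variances = [cov_scale] * 3 + [cov_scale if interaction_var is None else interaction_var]
    cov = pd.DataFrame(np.diag(variances), index=index, columns=index)
    data = pd.DataFrame(
        {"patient_id": ["a"] * 28, "pna_day": range(1, 29),
         "log_day": np.log(np.arange(1, 29.0)), "pottel_score": 1.0, "exposed": 1}
    )
    fit_info = {"alpha": 0.05, "time_scale": "log", "reml": True,
                "re_structure": "intercept_slope", "n_obs": 28, "n_patients": 1,
                "llf": 0.0, "aic": 0.0}
    return DaywiseExposureResults(params, cov, {"residual_var": 1.0}, fit_info, data, "drug", None)


class TestDayContrastFormulas:
    def test_interaction_free_difference_is_constant(self):
        # interaction-free model: no interaction term contributes estimate or variance
        res = results_with_params(0.05, 0.0, interaction_var=0.0)
        tab = res.day_contrasts([1, 5, 14, 28])
        assert tab["diff"].tolist() == pytest.approx([0.05] * 4)
        widths = (tab["ci_hi"] - tab["ci_lo"]).tolist()
        assert widths == pytest.approx([widths[0]] * 4)

    def test_log_identity_at_day_e(self):
        res = results_with_params(0.0, 0.02)
        tab = res.day_contrasts([np.e])
        assert tab["diff"].iloc[0] == pytest.approx(0.02, abs=1e-12)

    def test_difference_is_beta_exposed_plus_beta_interaction_log_day(self):
        res = results_with_params(0.03, -0.01)
        for day in (1, 4, 9, 28):
            tab = res.day_contrasts([day])
            assert tab["diff"].iloc[0] == pytest.approx(0.03 - 0.01 * np.log(day), abs=1e-12)
            assert tab["mean_exposed"].iloc[0] - tab["mean_unexposed"].iloc[0] == pytest.approx(
                tab["diff"].iloc[0], abs=1e-12
            )

    def test_no_extrapolation_outside_fitted_days(self):
        res = results_with_params(0.05, 0.0)
        with pytest.raises(ValidationError, match="outside the fitted day range"):
            res.day_contrasts([40])

    def test_ci_contains_point_estimate_and_p_in_unit_interval(self):
        res = results_with_params(0.02, 0.01)
        tab = res.day_contrasts([2, 7, 21])
        assert ((tab["ci_lo"] <= tab["diff"]) & (tab["diff"] <= tab["ci_hi"])).all()
        assert ((tab["p_value"] > 0) & (tab["p_value"] <= 1)).all()


def simulate_linear_model(n_pat=40, beta=(1.0, 0.02, 0.05, 0.01), noise=1e-4, seed=0):
    """Data generated exactly from the fixed-effect structure, tiny noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pat):
        exposed_pat = i % 2
        for d in range(1, 15):
            ld = np.log(d)
            exposed = exposed_pat if d >= 3 else 0
            y = beta[0] + beta[1] * ld + beta[2] * exposed + beta[3] * exposed * ld
            rows.append((f"P{i}", d, ld, y + rng.normal(0, noise), exposed))
    return pd.DataFrame(rows, columns=["patient_id", "pna_day", "log_day", "pottel_score", "exposed"])


class TestDaywiseFitting:
    def test_noise_free_limit_recovers_contrasts(self):
        data = simulate_linear_model()
        res = DaywiseExposureModel(data, drug_label="drug").fit()
        beta_e, beta_i = 0.05, 0.01
        for day in (3, 7, 14):
            got = res.day_contrasts([day])["diff"].iloc[0]
            assert got == pytest.approx(beta_e + beta_i * np.log(day), abs=1e-3)

    def test_single_patient_rejected(self):
        data = simulate_linear_model(n_pat=1)
        with pytest.raises(ValidationError, match="at least 2 patients"):
            DaywiseExposureModel(data)

    def test_constant_exposure_rejected(self):
        data = simulate_linear_model()
        data["exposed"] = 0
        with pytest.raises(ValidationError, match="constant"):
            DaywiseExposureModel(data)

    def test_relabelling_and_row_order_invariance(self, small_cohort, small_scored):
        res1 = ns.fit_daywise_model(small_scored, small_cohort.calendar, ns.IBUPROFEN)
        shuffled = small_scored.sample(frac=1, random_state=1).reset_index(drop=True)
        mapping = {p: f"Z{j:03d}" for j, p in enumerate(sorted(small_scored["patient_id"].unique(), reverse=True))}
        relabeled = shuffled.assign(patient_id=shuffled["patient_id"].map(mapping))
        cal_df = small_cohort.calendar.to_frame()
        cal2 = ns.ExposureCalendar(cal_df.assign(patient_id=cal_df["patient_id"].map(mapping)))
        res2 = ns.fit_daywise_model(relabeled, cal2, ns.IBUPROFEN)
        t1 = res1.day_contrasts([4, 5, 6])
        t2 = res2.day_contrasts([4, 5, 6])
        for col in ("mean_exposed", "mean_unexposed", "diff"):
            assert t1[col].tolist() == pytest.approx(t2[col].tolist(), abs=1e-6)

    def test_exposed_patient_counts_and_reportable_days(self, small_cohort, small_scored):
        res = ns.fit_daywise_model(small_scored, small_cohort.calendar, ns.IBUPROFEN)
        counts = res.exposed_patient_counts()
        days = res.reportable_days(min_exposed_patients=2)
        assert all(counts[d] >= 2 for d in days)
        assert all(d in days for d in counts.index[counts >= 2])

    def test_summary_mentions_structure(self, small_cohort, small_scored):
        res = ns.fit_daywise_model(small_scored, small_cohort.calendar, ns.IBUPROFEN)
        text = res.summary()
        assert "ibuprofen" in text and "exposed" in text and "random" in text

    def test_log_time_preferred_on_log_linear_data(self):
        """AIC favours the log-time model on data with a log-linear trend."""
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            rng = np.random.default_rng(800 + seed)
            rows = []
            for i in range(50):
                b0 = rng.normal(0, 0.1)
                for d in range(1, 21):
                    ld = np.log(d)
                    exposed = int(i % 3 == 0 and 4 <= d <= 9)
                    y = 1.3 - 0.12 * ld + 0.05 * exposed + b0 + rng.normal(0, 0.08)
                    rows.append((f"P{i}", d, ld, y, exposed))
            data = pd.DataFrame(
                rows, columns=["patient_id", "pna_day", "log_day", "pottel_score", "exposed"]
            )
            aic_log = DaywiseExposureModel(data, time_scale="log").fit(reml=False).aic
            aic_lin = DaywiseExposureModel(data, time_scale="linear").fit(reml=False).aic
            wins += aic_log <= aic_lin
        assert wins >= int(0.9 * n_rep)


class TestAdjustedAnalysis:
    def test_empty_adjustment_group_equals_unadjusted(self, small_cohort, small_scored):
        cal_df = small_cohort.calendar.to_frame()
        cal_no_abx = ns.ExposureCalendar(cal_df[cal_df["drug"] == "ibuprofen"])
        res_u = ns.fit_daywise_model(small_scored, cal_no_abx, ns.IBUPROFEN)
        res_a = ns.fit_daywise_model(small_scored, cal_no_abx, ns.IBUPROFEN, adjust_for=ns.ANTIBIOTICS)
        assert res_a.fit_info.get("co_drug_dropped")
        assert res_a.params.tolist() == pytest.approx(res_u.params.tolist(), abs=1e-8)

    def test_identical_indicators_raise_collinearity_error(self, make_obs_frame):
        records = []
        rng = np.random.default_rng(4)
        for i in range(12):
            start = int(rng.integers(2, 5))
            for d in range(start, start + 3):
                records += [(f"P{i}", "ibuprofen", d), (f"P{i}", "amikacin", d)]
        cal = ns.ExposureCalendar.from_records(records)
        obs = make_obs_frame(
            [(f"P{i}", d, 0.6 + 0.01 * d) for i in range(12) for d in range(1, 12)]
        )
        scored = ns.score_cohort(obs, ns.ReferenceTable({d: 0.7 for d in range(1, 15)}), cal)
        with pytest.raises(CollinearityError, match="identical"):
            ns.fit_daywise_model(scored, cal, ns.IBUPROFEN, adjust_for=ns.AMIKACIN)

    def test_adjusted_analysis_returns_primary_contrasts(self, small_cohort, small_scored):
        tab = ns.adjusted_analysis(small_scored, small_cohort.calendar, ns.IBUPROFEN, ns.ANTIBIOTICS)
        assert (tab["drug_group"] == "ibuprofen").all()
        assert (tab["analysis"] == "daywise_adjusted").all()


class TestCumulativeModel:
    def test_category_zero_is_reference(self, small_cohort, small_scored):
        res, tab = ns.fit_cumulative_model(small_scored, small_cohort.calendar, ns.IBUPROFEN)
        row0 = tab[tab["day_or_category"] == "0"].iloc[0]
        assert row0["diff"] == 0.0
        assert np.isnan(row0["p_value"])
        assert ((tab["mean_exposed_lo"] <= tab["mean_exposed"])
                & (tab["mean_exposed"] <= tab["mean_exposed_hi"])).all()

    def test_no_drug_given_single_category(self, make_obs_frame, empty_calendar):
        obs = make_obs_frame([(f"P{i}", d, 0.7) for i in range(6) for d in range(1, 8)])
        scored = ns.score_cohort(obs, ns.ReferenceTable({d: 0.7 for d in range(1, 10)}), empty_calendar)
        res, tab = ns.fit_cumulative_model(scored, empty_calendar, ns.IBUPROFEN)
        assert tab["day_or_category"].tolist() == ["0"]

    def test_sparse_category_merged_and_logged(self, make_obs_frame):
        # one patient with a single 2-day course sampled only once at category 2
        records = [("Q", "ibuprofen", 2), ("Q", "ibuprofen", 3)]
        for i in range(10):
            records += [(f"P{i}", "ibuprofen", 5)]
        cal = ns.ExposureCalendar.from_records(records)
        rng = np.random.default_rng(0)
        rows = [("Q", 4, 0.7 + 0.01 * rng.standard_normal())]  # category 2, n=1
        rows += [(f"P{i}", d, 0.7 + 0.01 * rng.standard_normal())
                 for i in range(10) for d in (1, 3, 6)]        # categories 0 and 1
        obs = make_obs_frame(rows)
        scored = ns.score_cohort(obs, ns.ReferenceTable({d: 0.7 for d in range(1, 10)}), cal)
        res, tab = ns.fit_cumulative_model(scored, cal, ns.IBUPROFEN)
        assert any("category 2" in m for m in res.fit_info.get("merged_categories", []))
        assert "2" not in tab["day_or_category"].tolist()
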