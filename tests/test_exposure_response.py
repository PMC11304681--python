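"""Concentration-QTc mixed model: dataset assembly, REML fit, predictions."""

import numpy as np
import pandas as pd
import pytest

import tqtpipe as tq
from tqtpipe import exposure_response as er


class TestBuildDataset:
    def test_placebo_rows_have_zero_concentration(self, small_dataset):
        plc = small_dataset[small_dataset["treatment"] == tq.PLACEBO]
        assert (plc["conc_islatravir"] == 0).all()
        assert (plc["conc_moxifloxacin"] == 0).all()

    def test_join_attaches_measured_concentration(self, small_trial,
                                                  small_dataset):
        pk = small_trial.pk
        row = small_dataset[
            (small_dataset["treatment"] == tq.ISLATRAVIR_HIGH)
            & (small_dataset["time_h"] == 1.0)
        ].iloc[0]
        src = pk[(pk["subject"] == row["subject"])
                 & (pk["period"] == row["period"])
                 & (pk["analyte"] == "islatravir") & (pk["time_h"] == 1.0)]
        expected = 0.0 if src["blq"].iloc[0] else src["conc"].iloc[0]
        assert row["conc_islatravir"] == pytest.approx(expected)

    def test_blq_counts_as_zero_row_retained(self, small_trial):
        agg = tq.aggregate_triplicates(small_trial.ecg)
        series = tq.baseline_and_delta(agg, 0.3754)
        pk = small_trial.pk.copy()
        sel = (pk["analyte"] == "islatravir") & (pk["time_h"] == 24.0)
        pk.loc[sel, "blq"] = True
        pk.loc[sel, "conc"] = np.nan
        ds = tq.build_cqt_dataset(series, pk)
        rows = ds[(ds["treatment"].str.startswith("islatravir"))
                  & (ds["time_h"] == 24.0)]
        assert len(rows) > 0
        assert (rows["conc_islatravir"] == 0).all()

    def test_window_and_centering(self, small_dataset):
        assert small_dataset["time_h"].between(0, 24, inclusive="right").all()
        assert small_dataset["baseline_centered"].mean() == pytest.approx(
            0.0, abs=1e-9)


class TestRemlFit:
    def test_matches_statsmodels_mixedlm(self, small_dataset):
        """Independent REML oracle: random intercepts for subject and
        subject-by-period reproduce the double-CS structure."""
        smf = pytest.importorskip("statsmodels.formula.api")
        fit = tq.fit_cqt(small_dataset)
        df = small_dataset.copy()
        md = smf.mixedlm(
            "delta_qtcp_ms ~ C(treatment, Treatment('placebo')) + C(time_h)"
            " + conc_islatravir + conc_moxifloxacin + baseline_centered",
            df, groups=df["subject"], re_formula="1",
            vc_formula={"period": "0 + C(period)"},
        )
        mf = md.fit(reml=True)
        assert fit.vc["sigma2_residual"] == pytest.approx(mf.scale, rel=1e-3)
        assert fit.vc["sigma2_subject_period"] == pytest.approx(
            float(mf.vcomp[0]), rel=1e-3, abs=1e-3)
        assert fit.params["conc_islatravir"] == pytest.approx(
            mf.params["conc_islatravir"], abs=1e-5)
        assert fit.params["conc_moxifloxacin"] == pytest.approx(
            mf.params["conc_moxifloxacin"], abs=1e-6)
        assert fit.reml_loglik == pytest.approx(mf.llf, abs=1e-4)

    def test_gls_equals_dense_matrix_oracle(self):
        """At fixed components, beta equals the closed-form dense-V GLS."""
        rng = np.random.default_rng(3)
        n_subj, n_per, n_t = 6, 2, 3
        subject = np.repeat(np.arange(n_subj), n_per * n_t)
        period = np.tile(np.repeat([1, 2], n_t), n_subj)
        X = np.column_stack([np.ones(subject.size),
                             rng.normal(size=subject.size),
                             rng.normal(size=subject.size)])
        y = rng.normal(size=subject.size)
        vc = (2.0, 1.5, 1.0)
        beta, cov = er.gls_solution(X, y, subject, period, vc)
        # dense oracle
        V = np.zeros((subject.size, subject.size))
        for i in range(subject.size):
            for j in range(subject.size):
                if subject[i] == subject[j]:
                    V[i, j] += vc[0]
                    if period[i] == period[j]:
                        V[i, j] += vc[1]
                if i == j:
                    V[i, j] += vc[2]
        Vi = np.linalg.inv(V)
        beta_oracle = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(beta, beta_oracle, rtol=1e-10)
        np.testing.assert_allclose(cov, np.linalg.inv(X.T @ Vi @ X),
                                   rtol=1e-10)

    def test_independent_noise_reduces_to_ols(self):
        """Data without subject/period structure: estimates match OLS."""
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(50), 8),
            "sequence": 1,
            "period": np.tile(np.repeat([1, 2], 4), 50),
            "treatment": np.tile(["placebo", "placebo", "active", "active"],
                                 100),
            "time_h": np.tile([1.0, 2.0], 200),
            "delta_qtcp_ms": rng.normal(size=n),
            "baseline_qtcp_ms": 400.0,
            "baseline_centered": rng.normal(size=n),
            "conc_x": 0.0,
        })
        df.loc[df["treatment"] == "active", "conc_x"] = rng.uniform(
            0, 4, size=(df["treatment"] == "active").sum())
        df.attrs["analyte_for_treatment"] = {"active": "x"}
        df.attrs["placebo"] = "placebo"
        fit = tq.fit_cqt(df)
        X = np.column_stack([
            np.ones(n),
            (df["treatment"] == "active").astype(float),
            (df["time_h"] == 2.0).astype(float),
            df["conc_x"], df["baseline_centered"],
        ])
        ols = np.linalg.lstsq(X, df["delta_qtcp_ms"], rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=0.02)
        assert fit.vc["sigma2_subject"] < 0.1
        assert fit.vc["sigma2_subject_period"] < 0.1

    def test_covariance_symmetric_psd(self, small_dataset):
        fit = tq.fit_cqt(small_dataset)
        C = fit.cov_params.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)
        assert all(v >= 0 for v in fit.vc.values())
        assert fit.df_resid == fit.n_obs - len(fit.params)

    def test_too_few_subjects_rejected(self, small_dataset):
        one = small_dataset[small_dataset["subject"]
                            <= small_dataset["subject"].min()]
        with pytest.raises(ValueError):
            tq.fit_cqt(one)


@pytest.fixture(scope="module")
def fit(small_dataset):
    return tq.fit_cqt(small_dataset)


class TestPrediction:

    def test_zero_reference_is_treatment_effect_alone(self, fit):
        p = tq.predict_ddqtc(fit, tq.MOXIFLOXACIN, 0.0, "lower")
        assert p.estimate == pytest.approx(
            fit.params["trt[moxifloxacin_400mg]"])

    def test_affine_in_reference_concentration(self, fit):
        p0 = tq.predict_ddqtc(fit, tq.ISLATRAVIR_HIGH, 0.0)
        p1 = tq.predict_ddqtc(fit, tq.ISLATRAVIR_HIGH, 2.0)
        p2 = tq.predict_ddqtc(fit, tq.ISLATRAVIR_HIGH, 4.0)
        assert (p2.estimate - p0.estimate) == pytest.approx(
            2 * (p1.estimate - p0.estimate), rel=1e-9)

    def test_ci_contains_estimate_and_duality(self, fit):
        p = tq.predict_ddqtc(fit, tq.ISLATRAVIR_HIGH, 3.8, "upper")
        assert p.ci90[0] < p.estimate < p.ci90[1]
        assert p.bound == p.ci90[1]
        q = tq.predict_ddqtc(fit, tq.MOXIFLOXACIN, 1800.0, "lower")
        assert q.bound == q.ci90[0]

    def test_baseline_shift_invariance(self, small_trial, small_dataset):
        """Adding a constant to every baseline leaves ddQTc unchanged."""
        agg = tq.aggregate_triplicates(small_trial.ecg)
        series = tq.baseline_and_delta(agg, tq.fit_correction(agg).exponent)
        shifted = series.copy()
        shifted["baseline_qtcp_ms"] += 50.0
        ds2 = tq.build_cqt_dataset(shifted, small_trial.pk)
        f1 = tq.fit_cqt(small_dataset)
        f2 = tq.fit_cqt(ds2)
        p1 = tq.predict_ddqtc(f1, tq.ISLATRAVIR_HIGH, 3.8)
        p2 = tq.predict_ddqtc(f2, tq.ISLATRAVIR_HIGH, 3.8)
        assert p1.estimate == pytest.approx(p2.estimate, abs=1e-6)
        assert p1.ci90 == pytest.approx(p2.ci90, abs=1e-5)

    def test_unknown_treatment_rejected(self, fit):
        with pytest.raises(ValueError):
            tq.predict_ddqtc(fit, "verapamil", 1.0)


class TestDecisionRules:
    @staticmethod
    def _pred(bound, side):
        if side == "upper":
            ci = (bound - 4.0, bound)
        else:
            ci = (bound, bound + 4.0)
        return er.DeltaDeltaPrediction("t", 1.0, sum(ci) / 2, ci, side)

    def test_upper_bound_below_10_is_negative(self):
        d = tq.decision_rules([self._pred(9.99, "upper")])
        assert d["qt_negative"]

    def test_upper_bound_exactly_10_is_not_negative(self):
        d = tq.decision_rules([self._pred(10.0, "upper")])
        assert not d["qt_negative"]

    def test_lower_bound_above_5_confirms_sensitivity(self):
        d = tq.decision_rules([self._pred(12.10, "lower")])
        assert d["assay_sensitivity"]

    def test_lower_bound_exactly_5_does_not_confirm(self):
        d = tq.decision_rules([self._pred(5.0, "lower")])
        assert not d["assay_sensitivity"]

    def test_combined_study_decision(self):
        d = tq.decision_rules([self._pred(2.5, "upper"),
                               self._pred(9.0, "upper"),
                               self._pred(12.1, "lower")])
        assert d["qt_negative"] and d["assay_sensitivity"]
        assert d["per_treatment"] == {"t": True}


class TestTimepointAnalysis:
    def test_no_effect_no_noise_gives_zero_differences(self):
        trial = tq.simulate_trial(
            tq.TrialDesign(n_per_sequence=(2, 2, 1, 4)),
            tq.default_pk_params(),
            {t: tq.QtModelParams(between_subject_sd=0, between_period_sd=0,
                                 residual_sd=1e-3, circadian_amplitude=0,
                                 conc_slope=0.0)
             for t in (tq.PLACEBO, tq.ISLATRAVIR_LOW, tq.ISLATRAVIR_HIGH,
                       tq.MOXIFLOXACIN)},
            seed=2,
        )
        agg = tq.aggregate_triplicates(trial.ecg)
        series = tq.baseline_and_delta(agg, 0.3754)
        ds = tq.build_cqt_dataset(series, trial.pk)
        tp = tq.timepoint_analysis(ds)
        assert np.abs(tp["estimate_ms"]).max() < 0.05

    def test_positive_control_peaks_near_tmax(self, small_dataset):
        tp = tq.timepoint_analysis(small_dataset)
        moxi = tp[tp["treatment"] == tq.MOXIFLOXACIN]
        t_peak = moxi.loc[moxi["estimate_ms"].idxmax(), "time_h"]
        assert 1.0 <= t_peak <= 4.0  # simulated moxifloxacin Tmax ~2.4 h

    def test_null_arm_bounds_stay_below_threshold(self):
        """Pointwise upper bounds rarely exceed 10 ms under the null."""
        n_exceed = total = 0
        for seed in range(6):
            trial = tq.simulate_default_trial(400 + seed,
                                              design=tq.TrialDesign(
                                                  n_per_sequence=(4, 4, 2, 8)))
            agg = tq.aggregate_triplicates(trial.ecg)
            series = tq.baseline_and_delta(agg, tq.fit_correction(agg).exponent)
            ds = tq.build_cqt_dataset(series, trial.pk)
            tp = tq.timepoint_analysis(ds)
            isl = tp[tp["treatment"].str.startswith("islatravir")]
            n_exceed += int((isl["hi90_ms"] > 10.0).sum())
            total += len(isl)
        assert n_exceed <= 0.1 * total
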