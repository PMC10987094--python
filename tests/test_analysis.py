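"""Task-exposure binning, mixed-model battery, contrasts, titration trend."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ssveptag import analysis as an
from ssveptag.analysis import (EffectTable, bin_task_exposure, fit_mixed,
                               focal_pvalue, load_registry,
                               marginal_contrast_trend, prepare_table,
                               run_battery, run_model)
from ssveptag.synthetic_eeg import TableParams, null_table_params, \
    simulate_analysis_table


def _df(n_per_subject, n_subjects=3):
    rows = []
    for s in range(n_subjects):
        for k in range(n_per_subject):
            rows.append({"subject_id": s, "trial_order": k})
    return pd.DataFrame(rows)


class TestExposureBinning:
    def test_even_split(self):
        df = _df(100)
        bins = bin_task_exposure(df)
        counts = bins.groupby(df["subject_id"]).value_counts()
        assert set(counts.values) == {20}

    def test_remainder_goes_to_earliest_bins(self):
        df = _df(103, n_subjects=1)
        bins = bin_task_exposure(df)
        sizes = bins.value_counts().sort_index().tolist()
        assert sizes == [21, 21, 21, 20, 20]

    def test_ordering_preserved(self):
        df = _df(53, n_subjects=2)
        df["task_exposure_bin"] = bin_task_exposure(df)
        for _, sub in df.groupby("subject_id"):
            for k in range(1, 5):
                assert (sub.loc[sub.task_exposure_bin == k, "trial_order"].max()
                        < sub.loc[sub.task_exposure_bin == k + 1,
                                  "trial_order"].min())

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bin_task_exposure(_df(4, n_subjects=1))


class TestFitMixed:
    def test_constant_response_gives_zero_effects(self):
        tab = simulate_analysis_table(TableParams(n_subjects=3,
                                                  trials_per_subject=60), seed=0)
        tab["flat"] = 1.0
        et = fit_mixed(tab, "flat", "C(cue, Treatment('neutral'))",
                       pairwise_factor="cue")
        assert (et.effects["F"] == 0.0).all()
        assert (et.contrasts["delta"] == 0.0).all()

    def test_contrasts_reproduce_condition_means_on_balanced_data(self, rng):
        # perfectly balanced by subject: GLS fixed effects reduce to OLS,
        # so treatment contrasts equal raw condition-mean differences
        rows = []
        true = {"valid": 1.0, "invalid": 0.4, "neutral": 0.0}
        for s in range(4):
            for cue, mu in true.items():
                for _ in range(25):
                    rows.append({"subject_id": s, "cue": cue,
                                 "y": mu + 0.3 * s + rng.normal(0, 0.2)})
        tab = pd.DataFrame(rows)
        et = fit_mixed(tab, "y", "C(cue, Treatment('neutral'))",
                       pairwise_factor="cue")
        means = tab.groupby("cue")["y"].mean()
        for _, c in et.contrasts.iterrows():
            assert abs(c["delta"] - (means[c["level_a"]]
                                     - means[c["level_b"]])) < 1e-9

    def test_identity_reports_residual_df_label(self):
        tab = simulate_analysis_table(TableParams(n_subjects=4,
                                                  trials_per_subject=60), seed=1)
        et = fit_mixed(tab, "marginal_ssvep_evidence",
                       "C(cue, Treatment('neutral'))")
        assert set(et.effects["df_method"]) <= {"residual", "residual-ols"}
        assert (et.effects["df2"] > 0).all()

    def test_logit_model_uses_fixed_subject_intercepts(self):
        tab = simulate_analysis_table(TableParams(n_subjects=4,
                                                  trials_per_subject=120), seed=2)
        et = fit_mixed(tab, "correct", "C(cue, Treatment('neutral'))",
                       link="logit", pairwise_factor="cue")
        assert set(et.effects["df_method"]) == {"wald-fixed-intercept"}
        assert not any("subject" in t for t in et.effects["term"])

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError):
            fit_mixed(pd.DataFrame({"y": [1.0], "subject_id": [0]}), "y", "1",
                      link="probit")

    def test_empty_subset_raises(self):
        tab = simulate_analysis_table(TableParams(n_subjects=2,
                                                  trials_per_subject=30), seed=3)
        tab["marginal_ssvep_evidence"] = np.nan
        with pytest.raises(ValueError):
            fit_mixed(tab, "marginal_ssvep_evidence", "C(cue)")


class TestRecovery:
    def test_invalid_cue_reduction_recovered(self):
        # static 10% encoding-gain reduction on invalid trials
        tp = TableParams(n_subjects=12, trials_per_subject=600,
                         cue_encoding_gain={"valid": 1.0, "invalid": 0.9,
                                            "neutral": 1.0})
        tab = prepare_table(simulate_analysis_table(tp, seed=5))
        reg = load_registry()["models"]["ssvep_evidence"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            et = run_model(tab, "ssvep_evidence", reg)
        c = et.contrast("invalid", "valid")
        assert c["delta"] < 0 and c["p"] < 0.05

    def test_causal_ssvep_link_signs(self):
        tp = TableParams(n_subjects=8, trials_per_subject=800,
                         ssvep_to_accuracy_logit=0.5, ssvep_to_rt_s=-0.05)
        tab = prepare_table(simulate_analysis_table(tp, seed=6))
        reg = load_registry()["models"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc = run_model(tab, "ssvep_accuracy_link", reg["ssvep_accuracy_link"])
            rt = run_model(tab, "ssvep_rt_link", reg["ssvep_rt_link"])
        b_acc = acc.coefficients.set_index("name").loc[
            "marginal_ssvep_evidence", "estimate"]
        b_rt = rt.coefficients.set_index("name").loc[
            "marginal_ssvep_evidence", "estimate"]
        assert b_acc > 0 and acc.coefficients.set_index("name").loc[
            "marginal_ssvep_evidence", "p"] < 0.05
        assert b_rt < 0

    def test_shuffled_ssvep_breaks_link(self):
        tp = TableParams(n_subjects=8, trials_per_subject=400,
                         ssvep_to_accuracy_logit=0.5)
        tab = simulate_analysis_table(tp, seed=7)
        rng = np.random.default_rng(0)
        tab["marginal_ssvep_evidence"] = rng.permutation(
            tab["marginal_ssvep_evidence"].to_numpy())
        tab = prepare_table(tab)
        reg = load_registry()["models"]["ssvep_accuracy_link"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            et = run_model(tab, "ssvep_accuracy_link", reg)
        assert focal_pvalue(et, reg) > 0.05

    def test_mb_and_alpha_effects_recovered(self):
        tp = TableParams(n_subjects=10, trials_per_subject=400)
        tab = prepare_table(simulate_analysis_table(tp, seed=8))
        reg = load_registry()["models"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mb = run_model(tab, "mb_lateralization", reg["mb_lateralization"])
            al = run_model(tab, "alpha_engagement", reg["alpha_engagement"])
        assert mb.contrast("cued", "neutral")["delta"] > 0
        assert focal_pvalue(mb, reg["mb_lateralization"]) < 0.05
        assert al.contrast("cued", "neutral")["delta"] > 0  # neutral lower
        assert focal_pvalue(al, reg["alpha_engagement"]) < 0.05


class TestBatteryPlumbing:
    EXPECTED_MODELS = [
        "rt_by_validity_accuracy", "rt_correct", "rt_error", "accuracy",
        "ssvep_evidence", "ssvep_evidence_exposure", "ssvep_baseline",
        "ssvep_target_nontarget", "ssvep_prepost_response",
        "ssvep_accuracy_link", "ssvep_rt_link",
        "mb_lateralization", "alpha_engagement",
    ]

    def test_registry_is_complete(self):
        reg = load_registry()
        assert list(reg["models"]) == self.EXPECTED_MODELS
        for spec in reg["models"].values():
            assert {"response", "fixed", "focal"} <= set(spec)

    def test_grouped_entry_points_cover_registry(self):
        grouped = (an.BEHAVIOUR_MODELS + an.SSVEP_MODELS + an.LINK_MODELS
                   + an.MB_ALPHA_MODELS)
        assert sorted(grouped) == sorted(self.EXPECTED_MODELS)

    def test_full_battery_runs_and_reports_focal_terms(self):
        tab = simulate_analysis_table(
            TableParams(n_subjects=5, trials_per_subject=120), seed=9)
        reg = load_registry()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_battery(tab, reg)
        assert set(results) == set(self.EXPECTED_MODELS)
        for name, et in results.items():
            p = focal_pvalue(et, reg["models"][name])
            assert 0.0 <= p <= 1.0

    def test_effect_frame_schema(self):
        tab = simulate_analysis_table(
            TableParams(n_subjects=4, trials_per_subject=100), seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_battery(tab, models=["alpha_engagement"])
        frame = an.effect_tables_to_frame(results)
        assert list(frame.columns) == ["model", "term", "F", "df1", "df2", "p",
                                       "contrast", "delta", "p_contrast"]


class TestContrastTrend:
    def test_r_squared_matches_least_squares_oracle(self, rng):
        tab = prepare_table(simulate_analysis_table(
            TableParams(n_subjects=6, trials_per_subject=100), seed=11))
        res = marginal_contrast_trend(tab)
        means = (tab.groupby(["subject_id", "task_exposure_bin"])
                 ["marginal_contrast_pct"].mean().reset_index())
        x = means["task_exposure_bin"].to_numpy(float)
        y = means["marginal_contrast_pct"].to_numpy(float)
        X = np.c_[np.ones_like(x), x]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert abs(res.slope - beta[1]) < 1e-9
        assert abs(res.r_squared - r2) < 1e-9

    def test_declining_titration_detected(self):
        tab = prepare_table(simulate_analysis_table(
            TableParams(n_subjects=10, trials_per_subject=200), seed=12))
        res = marginal_contrast_trend(tab)
        assert res.slope < 0 and res.p < 0.05

    def test_constant_contrast_zero_slope(self):
        tp = TableParams(n_subjects=4, trials_per_subject=100,
                         contrast_by_bin=[12.0] * 5)
        tab = prepare_table(simulate_analysis_table(tp, seed=13))
        res = marginal_contrast_trend(tab)
        assert res.slope == 0.0 and res.r_squared == 0.0


def test_null_generator_type_one_spot_check():
    """Small-n spot check that focal p-values are roughly uniform under the
    null (the full 500-replicate calibration runs in the acceptance suite)."""
    reg = load_registry()
    ps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(10):
            tab = simulate_analysis_table(null_table_params(4, 120),
                                          seed=40_000 + rep)
            results = run_battery(tab, reg)
            ps.extend(focal_pvalue(et, reg["models"][n])
                      for n, et in results.items())
    ps = np.array(ps)
    assert 0.0 < ps.mean() < 1.0
    assert (ps < 0.05).mean() < 0.25
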