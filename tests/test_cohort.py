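"""Cohort generator: covariate marginals, exposure calibration, dates, outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import moodmine as mm
from moodmine import defaults as D
from moodmine.cohort import (
    ConfigurationError,
    calibrate_intercept,
    covariate_linear_predictor,
    sample_covariates,
    sample_presentation_dates,
    stage_rng,
    window_cutoff,
)
from moodmine.models import slice_followup


def _three_se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestCovariates:
    def test_marginals_match_configured_mix(self):
        n = 27_704
        profiles = sample_covariates(n, np.random.default_rng(0))
        for cov, table in D.COVARIATE_COUNTS.items():
            total = sum(table.values())
            for level, count in table.items():
                p = count / total
                observed = (profiles[cov] == level).mean()
                assert abs(observed - p) < _three_se(p, n) + 1e-9, (cov, level)

    def test_degenerate_distribution(self):
        tables = {k: dict(v) for k, v in D.COVARIATE_COUNTS.items()}
        tables["diagnosis"] = {"bipolar": 1.0}
        profiles = sample_covariates(100, np.random.default_rng(0), tables)
        assert (profiles["diagnosis"] == "bipolar").all()

    def test_invalid_probability_table(self):
        tables = {k: dict(v) for k, v in D.COVARIATE_COUNTS.items()}
        tables["gender"] = {"male": 0.5, "female": 0.4}  # sums to 0.9
        with pytest.raises(ConfigurationError):
            sample_covariates(10, np.random.default_rng(0), tables)

    def test_determinism_under_seed(self):
        a = sample_covariates(10_000, np.random.default_rng(42))
        b = sample_covariates(10_000, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)


class TestIntercept:
    def test_closed_form_when_no_covariate_effects(self):
        eta = np.zeros(1000)
        b0 = calibrate_intercept(eta, 0.121)
        assert b0 == pytest.approx(np.log(0.121 / 0.879), abs=1e-8)
        assert expit(b0 + eta).mean() == pytest.approx(0.121, abs=1e-8)

    def test_symmetry_at_half(self):
        assert calibrate_intercept(np.zeros(5), 0.5) == pytest.approx(0.0, abs=1e-10)

    def test_postcondition_with_heterogeneous_effects(self):
        rng = np.random.default_rng(1)
        eta = rng.normal(0, 1.5, size=2000)
        for target in (0.05, 0.121, 0.8):
            b0 = calibrate_intercept(eta, target)
            assert expit(b0 + eta).mean() == pytest.approx(target, abs=1e-8)

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            calibrate_intercept(np.zeros(5), 1.0)


class TestExposure:
    def test_stratified_prevalences(self):
        cfg = mm.CohortConfig(n=27_704, mode="stratified", seed=3)
        cohort = mm.generate_cohort(cfg, outcomes=False)
        bip = cohort[cohort["diagnosis"] == "bipolar"]
        assert abs(bip["mi_true"].mean() - 0.226) < _three_se(0.226, len(bip))
        # overall prevalence = diagnosis-mix-weighted average of strata rates
        total = sum(D.DIAGNOSIS_COUNTS.values())
        expected = (
            sum(D.DIAGNOSIS_COUNTS[d] * p for d, p in D.MI_PREVALENCE_BY_DIAGNOSIS.items())
            / total
        )
        assert abs(cohort["mi_true"].mean() - expected) < _three_se(expected, len(cohort))

    def test_model_mode_intercept_only(self):
        cfg = mm.CohortConfig(
            n=27_704,
            mode="model",
            seed=4,
            mi_log_odds={k: 0.0 for k in D.MI_LOG_ODDS},
        )
        cohort = mm.generate_cohort(cfg, outcomes=False)
        assert abs(cohort["mi_true"].mean() - 0.121) < _three_se(0.121, len(cohort))

    def test_missing_coefficient_is_configuration_error(self):
        profiles = sample_covariates(500, np.random.default_rng(0))
        effects = dict(D.MI_LOG_ODDS)
        effects.pop(("diagnosis", "bipolar"))
        with pytest.raises(ConfigurationError, match="bipolar"):
            covariate_linear_predictor(profiles, effects)


class TestPresentationDates:
    def test_eligible_counts_exact_at_reference_size(self):
        cfg = mm.CohortConfig(n=27_704, seed=5)
        dates = sample_presentation_dates(cfg, np.random.default_rng(0))
        for w, expected in D.PRESENTATION_COUNTS.items():
            assert int((dates <= window_cutoff(w)).sum()) == expected

    def test_scaled_counts_monotone(self):
        counts = D.scaled_presentation_counts(2770)
        values = [counts[w] for w in D.WINDOWS]
        assert values[0] == 2770
        assert all(a >= b for a, b in zip(values, values[1:]))
        # rounded tenths of the reference counts
        assert counts[60] == round(13_032 * 2770 / 27_704)

    def test_yearly_stratum_counts_are_successive_differences(self):
        cfg = mm.CohortConfig(n=27_704, seed=6)
        dates = sample_presentation_dates(cfg, np.random.default_rng(1))
        fy2012 = (dates >= np.datetime64("2012-04-01")).sum()
        assert int(fy2012) == 27_704 - 24_848

    def test_non_increasing_counts_enforced(self):
        with pytest.raises(ConfigurationError):
            mm.CohortConfig(
                n=100, presentation_counts={12: 100, 24: 110, 36: 90, 48: 80, 60: 70}
            ).window_counts()


class TestOutcomes:
    def test_cumulative_outcomes_monotone(self, mid_cohort):
        for a, b in zip(D.WINDOWS, D.WINDOWS[1:]):
            assert (
                mid_cohort[f"inpatient_days_{b}"] >= mid_cohort[f"inpatient_days_{a}"]
            ).all()
            assert (mid_cohort[f"admissions_{b}"] >= mid_cohort[f"admissions_{a}"]).all()
            for flag in ("compulsory", "antipsychotic", "mood_stabiliser"):
                assert (mid_cohort[f"{flag}_{b}"] >= mid_cohort[f"{flag}_{a}"]).all()

    def test_admissions_overdispersed(self, mid_cohort):
        sub = slice_followup(mid_cohort, 60)
        no_mi = sub[sub["mi_true"] == 0]["admissions_60"]
        assert no_mi.var(ddof=1) > no_mi.mean()

    def test_no_exposure_group_anchors(self, mid_cohort):
        sub = slice_followup(mid_cohort, 60)
        no_mi = sub[sub["mi_true"] == 0]
        assert no_mi[f"inpatient_days_60"].mean() == pytest.approx(25.5, abs=4.0)
        assert no_mi[f"admissions_60"].mean() == pytest.approx(0.43, abs=0.05)
        assert no_mi[f"compulsory_60"].mean() == pytest.approx(0.12, abs=0.02)

    def test_null_model_equalises_groups(self):
        cfg = mm.CohortConfig(n=6000, mode="stratified", seed=9)
        cohort = mm.generate_cohort(cfg, outcomes=False)
        mm.simulate_outcomes(
            cohort,
            cfg,
            stage_rng(cfg.seed, "outcomes"),
            compulsory_or={w: 1.0 for w in D.WINDOWS},
            covariate_log_effects={},
            days_covariate_effects={},
        )
        g = cohort.groupby("mi_true")["compulsory_60"].mean()
        assert abs(g[1] - g[0]) < 4 * np.sqrt(0.12 * 0.88 / (cohort["mi_true"] == 1).sum())

    def test_negative_identity_link_mean_rejected(self):
        cfg = mm.CohortConfig(n=500, mode="stratified", seed=10)
        cohort = mm.generate_cohort(cfg, outcomes=False)
        with pytest.raises(ConfigurationError, match="identity-link|increase"):
            mm.simulate_outcomes(
                cohort,
                cfg,
                stage_rng(cfg.seed, "outcomes"),
                days_covariate_effects={("diagnosis", "bipolar"): -1000.0},
            )

    def test_byte_identical_under_seed(self):
        cfg = mm.CohortConfig(n=800, seed=21)
        a = mm.generate_cohort(cfg)
        b = mm.generate_cohort(mm.CohortConfig(n=800, seed=21))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_derived_dispersion_value(self):
        # var = mu + alpha*mu^2 at the 0-60 no-exposure anchors
        assert D.NB_DISPERSION == pytest.approx((1.19 - 0.43) / 0.43**2)
        assert D.NB_DISPERSION == pytest.approx(4.11, abs=0.01)
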