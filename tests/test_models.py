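"""Outcome models against closed forms and independent likelihood checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from moodmine import defaults as D
from moodmine.cohort import sample_covariates
from moodmine.models import (
    FitError,
    descriptive_tables,
    fit_linear,
    fit_logistic,
    fit_negative_binomial,
    fit_zinb_with_vuong,
    slice_followup,
    vuong_statistic,
)


def _two_group(counts):
    """(mi, y) rows from counts {(mi, y): n}."""
    rows = [(mi, y) for (mi, y), k in counts.items() for _ in range(k)]
    return pd.DataFrame(rows, columns=["mi_true", "y"])


class TestSmallInstanceOracles:
    def test_logistic_two_by_two_closed_form(self):
        df = _two_group({(1, 1): 6, (1, 0): 2, (0, 1): 3, (0, 0): 9})
        res = fit_logistic(df, "y", covariates=())
        assert res.effect("mi") == pytest.approx((6 * 9) / (2 * 3), rel=1e-6)

    def test_logistic_six_rows(self):
        df = pd.DataFrame({"mi_true": [0, 0, 0, 1, 1, 1], "y": [0, 0, 1, 0, 1, 1]})
        res = fit_logistic(df, "y", covariates=())
        assert res.effect("mi") == pytest.approx(4.0, rel=1e-5)

    def test_linear_two_group_equals_mean_difference(self):
        df = pd.DataFrame({"mi_true": [0, 0, 0, 1, 1, 1], "y": [1.0, 2.0, 3.0, 7.0, 9.0, 14.0]})
        res = fit_linear(df, "y", covariates=())
        assert res.effect("mi") == pytest.approx(10.0 - 2.0, abs=1e-9)

    def test_logistic_maximises_independent_likelihood(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"mi_true": rng.integers(0, 2, 80)})
        df["y"] = (rng.random(80) < 0.3 + 0.3 * df["mi_true"]).astype(int)
        res = fit_logistic(df, "y", covariates=())
        X = np.column_stack([np.ones(len(df)), df["mi_true"]])
        y = df["y"].to_numpy()

        def nll(beta):
            eta = X @ beta
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        fitted = res.table["coef"].to_numpy()
        best = optimize.minimize(nll, fitted, method="Nelder-Mead", options={"xatol": 1e-10})
        assert nll(fitted) <= best.fun + 1e-6

    def test_negative_binomial_maximises_independent_likelihood(self):
        rng = np.random.default_rng(4)
        mi = rng.integers(0, 2, 400)
        mu = np.exp(0.2 + 0.7 * mi)
        y = rng.poisson(rng.gamma(2.0, mu / 2.0))
        df = pd.DataFrame({"mi_true": mi, "y": y})
        res = fit_negative_binomial(df, "y", covariates=())
        X = np.column_stack([np.ones(len(df)), mi])

        def nll(theta):
            beta, alpha = theta[:-1], theta[-1]
            if alpha <= 0:
                return np.inf
            m = np.exp(X @ beta)
            size = 1.0 / alpha
            return -stats.nbinom.logpmf(y, size, size / (size + m)).sum()

        fitted = np.append(res.table["coef"].to_numpy(), res.dispersion)
        best = optimize.minimize(nll, fitted, method="Nelder-Mead", options={"xatol": 1e-10})
        assert nll(fitted) <= best.fun + 1e-6

    def test_rank_deficiency_raises(self):
        df = pd.DataFrame({"mi_true": [1, 1, 1], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(FitError):
            fit_linear(df, "y", covariates=())


class TestSliceFollowup:
    def test_nested_window_sizes(self, mid_cohort):
        expected = D.scaled_presentation_counts(len(mid_cohort))
        sizes = [len(slice_followup(mid_cohort, w)) for w in D.WINDOWS]
        assert sizes == [expected[w] for w in D.WINDOWS]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_unknown_window(self, mid_cohort):
        with pytest.raises(ValueError):
            slice_followup(mid_cohort, 18)


class TestDescriptives:
    def test_hand_computed_toy_cohort(self):
        df = pd.DataFrame(
            {
                "patient_id": [1, 2, 3, 4],
                "presentation_date": np.array(["2007-05-01"] * 4, dtype="datetime64[D]"),
                "mi_true": [1, 1, 0, 0],
                "inpatient_days_60": [10.0, 20.0, 0.0, 4.0],
                "admissions_60": [1, 3, 0, 1],
                "compulsory_60": [1, 0, 0, 0],
                "antipsychotic_60": [1, 1, 0, 1],
                "mood_stabiliser_60": [0, 0, 0, 1],
            }
        )
        tabs = descriptive_tables(df, windows=(60,))
        hosp = tabs["hospitalisation"].set_index("group")
        assert hosp.loc["MI", "mean_days"] == pytest.approx(15.0)
        assert hosp.loc["MI", "sd_days"] == pytest.approx(np.std([10, 20], ddof=1))
        assert hosp.loc["MI", "pct_compulsory"] == pytest.approx(50.0)
        assert hosp.loc["no MI", "mean_admissions"] == pytest.approx(0.5)
        assert hosp.loc["no MI", "var_admissions"] == pytest.approx(0.5)
        rx = tabs["prescribing"].set_index("group")
        assert rx.loc["MI", "pct_antipsychotic"] == pytest.approx(100.0)
        assert rx.loc["no MI", "pct_mood_stabiliser"] == pytest.approx(50.0)

    def test_empty_group_is_flagged_not_fatal(self):
        df = pd.DataFrame(
            {
                "patient_id": [1],
                "presentation_date": np.array(["2007-05-01"], dtype="datetime64[D]"),
                "mi_true": [0],
                "inpatient_days_60": [1.0],
                "admissions_60": [0],
                "compulsory_60": [0],
                "antipsychotic_60": [0],
                "mood_stabiliser_60": [0],
            }
        )
        hosp = descriptive_tables(df, windows=(60,))["hospitalisation"].set_index("group")
        assert np.isnan(hosp.loc["MI", "mean_days"]) and hosp.loc["MI", "n"] == 0


class TestVuongAndZinb:
    @staticmethod
    def _sim(seed, n=8000, pi=0.2):
        rng = np.random.default_rng(seed)
        df = sample_covariates(n, rng)
        df["mi_true"] = (rng.random(n) < 0.3).astype(int)
        mu = np.exp(np.log(1.5) + np.log(2.0) * df["mi_true"])
        y = rng.poisson(rng.gamma(1.0, mu))
        y[rng.random(n) < pi] = 0
        df["adm"] = y
        return df

    def test_vuong_detects_structural_zeros(self):
        favoured = 0
        for seed in range(5):
            _, v = fit_zinb_with_vuong(self._sim(seed), "adm", covariates=())
            favoured += v.statistic > 0 and v.pvalue < 0.05
        assert favoured >= 4

    def test_zinb_close_to_nb_without_structural_zeros(self):
        df = self._sim(99, pi=0.0)
        zinb, _ = fit_zinb_with_vuong(df, "adm", covariates=())
        nb = fit_negative_binomial(df, "adm", covariates=())
        assert zinb.effect("mi") <= nb.effect("mi") + 0.15

    def test_degenerate_comparison_raises(self):
        ll = np.array([-1.0, -2.0, -0.5])
        with pytest.raises(FitError, match="degenerate"):
            vuong_statistic(ll, ll.copy())


class TestEffectRecoveryStructure:
    def test_effect_scale_cis_bracket_estimates(self, mid_cohort):
        sub = slice_followup(mid_cohort, 60)
        for res in (
            fit_logistic(sub, "compulsory_60"),
            fit_negative_binomial(sub, "admissions_60"),
            fit_linear(sub, "inpatient_days_60"),
        ):
            t = res.table
            assert (t["ci_low"] <= t["effect"]).all()
            assert (t["effect"] <= t["ci_high"]).all()

    def test_adjusted_equals_unadjusted_under_null_covariates(self):
        import moodmine as mm
        from moodmine.cohort import stage_rng

        cfg = mm.CohortConfig(n=8000, mode="stratified", seed=31)
        cohort = mm.generate_cohort(cfg, outcomes=False)
        mm.simulate_outcomes(
            cohort,
            cfg,
            stage_rng(cfg.seed, "outcomes"),
            covariate_log_effects={},
            days_covariate_effects={},
        )
        adj = fit_logistic(cohort, "compulsory_12")
        unadj = fit_logistic(cohort, "compulsory_12", covariates=())
        assert np.log(adj.effect("mi")) == pytest.approx(
            np.log(unadj.effect("mi")), abs=0.15
        )

    def test_exposure_misclassification_attenuates_effect(self, mid_cohort):
        rng = np.random.default_rng(8)
        df = mid_cohort.copy()
        mi = df["mi_true"].to_numpy().astype(bool)
        # recall 0.7: drop 30% of true positives; precision ~0.9: add false
        # positives at ~1/9th of the retained positive count
        kept = mi & (rng.random(len(df)) < 0.7)
        n_fp_target = int(round(kept.sum() / 9))
        neg_idx = np.flatnonzero(~mi)
        fp = np.zeros(len(df), dtype=bool)
        fp[rng.choice(neg_idx, size=n_fp_target, replace=False)] = True
        df["mi_noisy"] = (kept | fp).astype(int)
        true_fit = fit_logistic(df, "compulsory_12", mi_col="mi_true")
        noisy_fit = fit_logistic(df, "compulsory_12", mi_col="mi_noisy")
        assert abs(np.log(noisy_fit.effect("mi"))) < abs(np.log(true_fit.effect("mi")))
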