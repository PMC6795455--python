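"""Association model: LRT calibration, forward selection, contrast coding
and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kneeae.association import (association_table, build_design,
                                fit_final_model, forward_select,
                                successive_difference_columns)
from kneeae.lmm import LMMProblem, lrt_pvalue
from kneeae.synthetic import simulate_measurement_table
from kneeae.types import GenerativeParams, StudyDesign

from conftest import table3_params


def association_design(n):
    """One session of two sets per participant: two repeated measurements."""
    return StudyDesign(n_participants=n, n_days=1, n_weeks=1,
                       day1_multi_rp=False)


class TestContrastCoding:
    def test_zero_noise_recovers_level_differences_exactly(self):
        """With no noise the coefficients are exactly the adjacent-level
        mean differences and the intercept the across-level average
        (checked against the directly computed level means)."""
        means = {1: 200.0, 2: 281.77, 3: 259.23, 4: 220.84}
        kl = np.repeat([1, 2, 3, 4], 6)
        y = np.array([means[k] for k in kl])
        C, names = successive_difference_columns(kl)
        X = np.column_stack([np.ones(kl.size), C])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta[0] == pytest.approx(np.mean(list(means.values())))
        assert beta[1] == pytest.approx(means[1] - means[2])
        assert beta[2] == pytest.approx(means[2] - means[3])
        assert beta[3] == pytest.approx(means[3] - means[4])
        assert names[0] == "KL 1 vs KL 2"

    def test_invalid_grade_rejected(self):
        with pytest.raises(ValueError):
            successive_difference_columns(np.array([1, 2, 5]))


class TestLRTCalibration:
    def test_null_pvalues_approximately_uniform(self):
        """LRT p-values for a pure-noise covariate follow Uniform(0,1)."""
        rng = np.random.default_rng(0)
        G, m = 30, 2
        pat = np.repeat(np.arange(G), m)
        ones = np.ones((G * m, 1))
        ps = []
        for _ in range(300):
            y = rng.normal(0, 2.0, G)[pat] + rng.normal(0, 1.0, G * m)
            x = rng.normal(size=G * m)
            null = LMMProblem(y, ones, patient=pat,
                              fe_names=["i"]).fit(reml=False, n_restarts=1)
            alt = LMMProblem(y, np.column_stack([ones, x]), patient=pat,
                             fe_names=["i", "x"]).fit(reml=False, n_restarts=1)
            ps.append(lrt_pvalue(null, alt))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestForwardSelection:
    def test_noise_candidates_enter_at_roughly_nominal_rate(self):
        """With k independent noise candidates at cutoff 0.1, at least one
        enters with probability about 1 - 0.9^k (simulation at k = 3)."""
        rng = np.random.default_rng(1)
        n_any = 0
        reps = 120
        for r in range(reps):
            G = 40
            pat = np.repeat(np.arange(G), 2)
            df = pd.DataFrame({
                "participant_id": pat,
                "biomarker_value": rng.normal(0, 2.0, G)[pat]
                + rng.normal(0, 1.0, 2 * G),
                "age": rng.normal(size=2 * G),
                "bmi": rng.normal(size=2 * G),
                "vas_pain_worst_knee": rng.normal(size=2 * G)})
            sel, _ = forward_select(df, candidates=("age", "bmi",
                                                    "vas_pain_worst_knee"))
            n_any += bool(sel)
        expect = 1 - 0.9 ** 3
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(n_any / reps - expect) < 4 * se

    def test_true_covariates_selected_first_at_large_n(self):
        tab = simulate_measurement_table(association_design(600),
                                         table3_params(), seed=2)
        sel, trace = forward_select(tab)
        assert set(sel[:3]) == {"kl_grade", "weight_kg", "contralateral_pain"}
        assert all(s.p_value < 0.1 for s in trace if s.entered)
        assert all(s.p_value >= 0.1 for s in trace if not s.entered)

    def test_empty_pool_gives_intercept_only(self):
        tab = simulate_measurement_table(association_design(30),
                                         table3_params(), seed=3)
        sel, trace = forward_select(tab, candidates=())
        assert sel == [] and trace == []

    def test_collinear_candidate_skipped(self):
        tab = simulate_measurement_table(association_design(60),
                                         table3_params(), seed=4)
        tab["bmi"] = 2.0 * tab["weight_kg"] - 30.0   # exact collinearity
        sel, _ = forward_select(tab, candidates=("weight_kg", "bmi"))
        # the two are statistically equivalent: exactly one may enter
        assert len(set(sel) & {"weight_kg", "bmi"}) == 1


class TestFinalModel:
    def test_zero_noise_exact_recovery(self):
        params = GenerativeParams(
            intercept=160.13, kl_contrasts=(-81.77, 22.54, 38.39),
            weight_coef=2.06, contralateral_pain_coef=57.05,
            sd_patient=0.0, sd_session_in_patient=0.0, sd_day_in_patient=0.0,
            sd_rp=0.0, sd_residual=0.0, machine_offsets=(0, 0, 0),
            kl_probs=(0.25, 0.25, 0.25, 0.25))
        tab = simulate_measurement_table(association_design(200), params,
                                         seed=5)
        fit = fit_final_model(tab, ["kl_grade", "weight_kg",
                                    "contralateral_pain"])
        est = dict(zip(fit.coefficients["parameter"],
                       fit.coefficients["estimate"]))
        assert est["Intercept"] == pytest.approx(160.13, abs=1e-4)
        assert est["KL 1 vs KL 2"] == pytest.approx(-81.77, abs=1e-4)
        assert est["Weight"] == pytest.approx(2.06, abs=1e-5)
        assert est["Pain in contralateral knee"] == pytest.approx(57.05,
                                                                  abs=1e-4)
        assert fit.sd_residual < 0.1

    def test_moderate_n_recovery_of_table_parameters(self):
        tab = simulate_measurement_table(association_design(500),
                                         table3_params(), seed=6)
        fit = fit_final_model(tab, ["kl_grade", "weight_kg",
                                    "contralateral_pain"])
        est = dict(zip(fit.coefficients["parameter"],
                       fit.coefficients["estimate"]))
        assert est["Intercept"] == pytest.approx(160.13, abs=15.0)
        assert est["KL 1 vs KL 2"] == pytest.approx(-81.77, abs=30.0)
        assert est["Weight"] == pytest.approx(2.06, abs=0.6)
        assert fit.sd_participant == pytest.approx(93.17, rel=0.1)
        assert fit.sd_residual == pytest.approx(22.51, rel=0.1)

    def test_intercept_is_across_kl_average_at_reference(self):
        """Contrast-coding correctness: the fitted intercept equals the
        unweighted mean of model-implied KL-level means at centred weight
        and no pain."""
        tab = simulate_measurement_table(association_design(400),
                                         table3_params(), seed=7)
        fit = fit_final_model(tab, ["kl_grade", "weight_kg",
                                    "contralateral_pain"])
        df = tab.copy()
        df["weight_kg"] = df["weight_kg"].mean()
        df["contralateral_pain"] = 0
        level_means = []
        for k in (1, 2, 3, 4):
            dk = df.copy()
            dk["kl_grade"] = k
            Xk, _ = build_design(dk, fit.covariates)
            # weight centring inside build_design uses dk's own mean: 0
            level_means.append((Xk @ fit.fit.beta).mean())
        est = fit.coefficients["estimate"].iloc[0]
        assert est == pytest.approx(np.mean(level_means), abs=1e-6)

    def test_row_permutation_invariance(self):
        tab = simulate_measurement_table(association_design(80),
                                         table3_params(), seed=8)
        fit1 = fit_final_model(tab, ["kl_grade", "weight_kg"])
        fit2 = fit_final_model(tab.sample(frac=1.0, random_state=1),
                               ["kl_grade", "weight_kg"])
        assert fit1.coefficients["estimate"].to_numpy() == pytest.approx(
            fit2.coefficients["estimate"].to_numpy(), abs=1e-6)

    def test_incomplete_cases_dropped_and_counted(self):
        tab = simulate_measurement_table(association_design(50),
                                         table3_params(), seed=9)
        tab.loc[tab.index[:4], "weight_kg"] = np.nan
        fit = fit_final_model(tab, ["kl_grade", "weight_kg"])
        assert fit.n_dropped_incomplete == 4
        assert fit.n_obs == len(tab) - 4
        out = association_table(fit)
        assert out["parameter"].iloc[-1] == \
            "Standard deviation of residual error"
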