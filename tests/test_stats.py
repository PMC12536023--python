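"""Descriptive tests, mixed models, change-score and SRS regressions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.formula.api as smf

from pafreact import (
    bonferroni_gate,
    change_score_regression,
    change_scores,
    chi_square_2x2,
    fit_reactivity_lmm,
    fit_subgroup_lmm,
    pooled_two_sample_t,
    srs_association,
)


def build_table(dr, eo, diagnosis, age, sex, srs=None, region="temporal_right"):
    """Long-format PAF table from per-subject arrays."""
    n = len(dr)
    srs = np.full(n, 50.0) if srs is None else srs
    rows = []
    for i in range(n):
        for cond, val in (("DR", dr[i]), ("EO", eo[i])):
            rows.append(
                {
                    "subject": f"s{i:03d}",
                    "diagnosis": diagnosis[i],
                    "condition": cond,
                    "region": region,
                    "paf_hz": val,
                    "age_months": age[i],
                    "sex": sex[i],
                    "srs_total": srs[i],
                }
            )
    return pd.DataFrame(rows)


class TestPooledT:
    @pytest.mark.parametrize(
        "g1,g2,expected_t,expected_df",
        [
            # (mean, se, n) summaries; expected values are the printed
            # statistics these summaries reproduce
            ((47.9, 1.7, 29), (68.9, 3.0, 22), 6.44, 49),
            ((115.0, 3.5, 13), (103.1, 4.2, 19), -2.02, 30),
            ((119.8, 4.1, 16), (97.0, 9.9, 3), -2.19, 17),
            ((99.7, 2.7, 29), (90.2, 3.8, 22), -2.10, 49),
            ((112.7, 1.1, 29), (115.0, 0.9, 22), 1.56, 49),
        ],
    )
    def test_reproduces_printed_group_comparisons(self, g1, g2, expected_t, expected_df):
        t, df = pooled_two_sample_t(*g1, *g2)
        assert df == expected_df
        assert t == pytest.approx(expected_t, abs=0.02)

    def test_identical_groups_give_zero(self):
        t, _ = pooled_two_sample_t(10.0, 1.0, 10, 10.0, 2.0, 12)
        assert t == 0.0

    def test_matches_scipy_on_explicit_samples(self):
        a = np.array([4.1, 5.3, 6.2])
        b = np.array([7.7, 8.1, 6.9])
        t_mine, df = pooled_two_sample_t(
            a.mean(), a.std(ddof=1) / np.sqrt(3), 3,
            b.mean(), b.std(ddof=1) / np.sqrt(3), 3,
        )
        ref = scipy.stats.ttest_ind(b, a, equal_var=True)
        assert t_mine == pytest.approx(ref.statistic, abs=1e-10)
        assert df == 4

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_two_sample_t(1.0, 0.5, 1, 2.0, 0.5, 10)
        with pytest.raises(ValueError):
            pooled_two_sample_t(1.0, 0.0, 5, 2.0, 0.5, 10)


class TestChiSquare:
    def test_sex_distribution_example(self):
        # 16/13 male/female vs 14/8
        stat, _ = chi_square_2x2([[16, 13], [14, 8]])
        assert stat == pytest.approx(0.37, abs=0.005)

    def test_proportional_table_gives_zero(self):
        stat, p = chi_square_2x2([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            expected = (
                n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            stat, _ = chi_square_2x2([[a, b], [c, d]])
            assert stat == pytest.approx(expected, rel=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 10]])


def exact_effect_table(n_per_group=12, resid_sd=0.0, seed=0):
    """Table generated exactly from a known fixed-effect structure."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    diagnosis = ["TD"] * n_per_group + ["ASD"] * n_per_group
    asd = (np.arange(n) >= n_per_group).astype(float)
    age = np.linspace(60, 95, n)
    sex = np.tile([0, 1], n)[:n].astype(float)
    truth = dict(b0=5.0, b_asd=0.5, b_eo=0.3, b_int=-0.6, b_age=0.03, b_sex=0.2)
    dr = truth["b0"] + truth["b_asd"] * asd + truth["b_age"] * age + truth["b_sex"] * sex
    eo = dr + truth["b_eo"] + truth["b_int"] * asd
    if resid_sd:
        dr = dr + rng.normal(0, resid_sd, n)
        eo = eo + rng.normal(0, resid_sd, n)
    return build_table(dr, eo, diagnosis, age, sex), truth


class TestReactivityLMM:
    def test_noiseless_fixed_effects_recovered_exactly(self):
        table, truth = exact_effect_table(resid_sd=1e-8)
        res = fit_reactivity_lmm(table, "temporal_right")
        assert res.coef("diagnosis") == pytest.approx(truth["b_asd"], abs=1e-4)
        assert res.coef("condition") == pytest.approx(truth["b_eo"], abs=1e-4)
        assert res.coef("diagnosis_x_condition") == pytest.approx(truth["b_int"], abs=1e-4)
        assert res.coef("age") == pytest.approx(truth["b_age"], abs=1e-4)
        assert res.coef("sex") == pytest.approx(truth["b_sex"], abs=1e-4)

    def test_missing_rows_dropped_without_affecting_other_regions(self):
        table, _ = exact_effect_table(resid_sd=0.2)
        other, _ = exact_effect_table(resid_sd=0.3, seed=5)
        other = other.assign(region="frontal_left")
        combined = pd.concat([table, other], ignore_index=True)
        ref = fit_reactivity_lmm(combined, "temporal_right")
        # knock out some frontal rows; temporal fit must not move
        mask = (combined.region == "frontal_left") & (combined.subject < "s005")
        combined.loc[mask, "paf_hz"] = np.nan
        again = fit_reactivity_lmm(combined, "temporal_right")
        pd.testing.assert_frame_equal(ref.table, again.table)

    def test_too_few_subjects_per_group_rejected(self):
        table, _ = exact_effect_table()
        only_td = table[table.diagnosis == "TD"]
        with pytest.raises(ValueError, match="ASD"):
            fit_reactivity_lmm(only_td, "temporal_right")


class TestSubgroupLMM:
    def test_td_condition_effect_recovered(self):
        table, truth = exact_effect_table(resid_sd=1e-8)
        res = fit_subgroup_lmm(table, "temporal_right", "TD")
        assert res.coef("condition") == pytest.approx(truth["b_eo"], abs=1e-4)

    def test_asd_condition_effect_includes_interaction(self):
        table, truth = exact_effect_table(resid_sd=1e-8)
        res = fit_subgroup_lmm(table, "temporal_right", "ASD")
        assert res.coef("condition") == pytest.approx(
            truth["b_eo"] + truth["b_int"], abs=1e-4
        )


class TestBonferroniGate:
    def test_corrected_threshold_over_five_regions(self):
        flags = bonferroni_gate([0.005, 0.012], 5)
        assert flags.tolist() == [True, False]

    def test_boundary_is_strict(self):
        assert not bonferroni_gate([0.05], 1)[0]
        assert bonferroni_gate([0.0499999], 1)[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_gate([1.2], 5)


class TestChangeScoreRegression:
    def test_noise_free_linear_construction_recovered_exactly(self):
        n = 40
        rng = np.random.default_rng(1)
        age = rng.uniform(60, 95, n)
        sex = rng.integers(0, 2, n).astype(float)
        asd = (np.arange(n) >= n // 2).astype(float)
        dr = rng.normal(9.5, 0.7, n)
        delta = 0.4 - 0.6 * (dr - 9.5) - 0.3 * asd + 0.01 * age + 0.1 * sex
        table = build_table(dr, dr + delta, np.where(asd == 1, "ASD", "TD"), age, sex)
        res = change_score_regression(table, "temporal_right")
        assert res.coef("baseline_paf") == pytest.approx(-0.6, abs=1e-8)
        assert res.coef("diagnosis") == pytest.approx(-0.3, abs=1e-8)
        assert res.coef("age") == pytest.approx(0.01, abs=1e-8)
        assert res.coef("sex") == pytest.approx(0.1, abs=1e-8)

    def test_regression_to_the_mean_slope_is_corr_minus_one(self):
        # equicorrelated same-variance conditions: E[slope] = rho - 1
        n, rho = 4000, 0.6
        rng = np.random.default_rng(7)
        shared = rng.normal(0, np.sqrt(rho), n)
        dr = 10.0 + shared + rng.normal(0, np.sqrt(1 - rho), n)
        eo = 10.0 + shared + rng.normal(0, np.sqrt(1 - rho), n)
        age = rng.uniform(60, 95, n)
        sex = rng.integers(0, 2, n).astype(float)
        diagnosis = np.where(rng.random(n) < 0.5, "ASD", "TD")
        table = build_table(dr, eo, diagnosis, age, sex)
        res = change_score_regression(table, "temporal_right")
        assert res.coef("baseline_paf") == pytest.approx(rho - 1.0, abs=0.05)

    def test_interaction_term_optional(self):
        table, _ = exact_effect_table(resid_sd=0.1)
        res = change_score_regression(table, "temporal_right", include_interaction=True)
        assert "baseline_x_diagnosis" in res.table.term.tolist()

    def test_subjects_missing_a_condition_are_dropped(self):
        table, _ = exact_effect_table(resid_sd=0.1)
        table.loc[
            (table.subject == "s000") & (table.condition == "EO"), "paf_hz"
        ] = np.nan
        cs = change_scores(table, "temporal_right")
        assert "s000" not in cs.subject.tolist()

    def test_robust_and_classical_ses_agree_under_homoscedasticity(self):
        n = 2000
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y})
        classical = smf.ols("y ~ x", df).fit()
        robust = smf.ols("y ~ x", df).fit(cov_type="HC1")
        assert robust.bse["x"] == pytest.approx(classical.bse["x"], rel=0.05)
        # variance growing with |x| inflates the robust SE above classical
        y_het = 1.0 + 0.5 * x + rng.normal(0, 1, n) * (0.2 + np.abs(x))
        df_het = pd.DataFrame({"x": x, "y": y_het})
        classical_h = smf.ols("y ~ x", df_het).fit()
        robust_h = smf.ols("y ~ x", df_het).fit(cov_type="HC1")
        assert robust_h.bse["x"] > classical_h.bse["x"]


class TestSrsAssociation:
    def test_exact_log_linear_construction_recovered(self):
        n = 40
        rng = np.random.default_rng(4)
        age = rng.uniform(60, 95, n)
        sex = rng.integers(0, 2, n).astype(float)
        dr = rng.normal(9.5, 0.5, n)
        delta = rng.normal(0.1, 0.4, n)
        log_srs = 3.9 - 0.324 * delta + 0.017 * age + 0.2 * sex
        table = build_table(
            dr, dr + delta, ["TD"] * n, age, sex, srs=np.exp(log_srs)
        )
        res = srs_association(table, "temporal_right")
        assert res.coef("delta_paf") == pytest.approx(-0.324, abs=1e-6)
        assert res.coef("age") == pytest.approx(0.017, abs=1e-6)

    def test_nonpositive_srs_rejected_before_log(self):
        table, _ = exact_effect_table(resid_sd=0.1)
        table["srs_total"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            srs_association(table, "temporal_right")
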