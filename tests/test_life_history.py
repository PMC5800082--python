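"""Mortality summaries, ANOVA/t/binomial tests and age-temperature fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aedes_thermal import life_history as life
from aedes_thermal import synthetic_data as synth
from aedes_thermal.life_history import (
    fit_age_curve,
    mortality_anova,
    mortality_table,
    pairwise_t,
    sex_ratio_test,
    size_anova,
    size_summary,
)


def records_from_cup_mortalities(temp_mortalities, larvae=40):
    """Build an individual-record table with exact per-cup mortalities."""
    rows = []
    for temp, cups in temp_mortalities.items():
        for cup, mort in enumerate(cups, start=1):
            n_dead = round(mort * larvae)
            for i in range(larvae):
                survived = i >= n_dead
                rows.append({
                    "temperature_C": temp, "cup_id": cup,
                    "sex": "female" if survived and i % 2 else ("male" if survived else "unknown"),
                    "survived": survived,
                    "age_pupation_days": 10.0 if survived else np.nan,
                    "age_emergence_days": 12.0 if survived else np.nan,
                    "age_death_days": 20.0 if survived else 3.0,
                    "r1_mm": 3.5 if survived else np.nan,
                })
    return pd.DataFrame(rows)


class TestMortalityTable:
    def test_total_mortality_is_100_percent(self):
        df = records_from_cup_mortalities({0.0: [1.0] * 5})
        out = mortality_table(df)
        assert out["mean_mortality_pct"].iloc[0] == 100.0
        assert out["sd_pct"].iloc[0] == 0.0

    def test_uniform_10_percent_cups(self):
        df = records_from_cup_mortalities({20.0: [0.1] * 5})
        out = mortality_table(df)
        assert out["mean_mortality_pct"].iloc[0] == pytest.approx(10.0)
        assert out["sd_pct"].iloc[0] == pytest.approx(0.0)

    def test_scale_invariant_to_cup_size(self):
        small = records_from_cup_mortalities({20.0: [0.25, 0.5]}, larvae=8)
        big = records_from_cup_mortalities({20.0: [0.25, 0.5]}, larvae=80)
        pd.testing.assert_frame_equal(mortality_table(small), mortality_table(big))

    def test_synthetic_26C_fixture_mortality_near_truth(self, truth):
        """With the generator's survival factorisation the 26 degC mortality
        equals 1 - clip(briere/dev_rate) within binomial error."""
        design = synth.ExperimentDesign(temperatures_C=(26.0,), cups_per_treatment=20)
        df = synth.simulate_life_history(design, truth, seed=6)
        expected = 100 * (1 - float(truth.survival(26.0)))
        out = mortality_table(df)
        se = 100 * np.sqrt(0.25 / (20 * 40))
        assert abs(out["mean_mortality_pct"].iloc[0] - expected) < 4 * se


class TestMortalityTests:
    def test_identical_groups_give_null_anova(self):
        df = records_from_cup_mortalities({10.0: [0.2] * 5, 20.0: [0.2] * 5})
        res = mortality_anova(df)
        assert res.value == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_strongly_separated_groups_significant_after_correction(self):
        rng = np.random.default_rng(1)
        groups = {
            10.0: np.clip(0.1 + 0.02 * rng.standard_normal(5), 0, 1),
            25.0: np.clip(0.9 + 0.02 * rng.standard_normal(5), 0, 1),
        }
        df = records_from_cup_mortalities(
            {t: list(np.round(v, 3)) for t, v in groups.items()}, larvae=1000
        )
        anova = mortality_anova(df)
        assert anova.p < 0.001
        pair = pairwise_t(df)[0]
        assert pair.p < 0.001 and pair.adjustment == "bonferroni"

    def test_anova_agrees_with_reference_implementation(self, life_records):
        """Cross-check the module's F against scipy's one-way ANOVA."""
        res = mortality_anova(life_records)
        cups = life_records.groupby(["temperature_C", "cup_id"])["survived"].mean()
        groups = [
            np.arcsin(np.sqrt(1 - g.to_numpy()))
            for _, g in cups.groupby("temperature_C")
        ]
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.value == pytest.approx(float(f_ref))
        assert res.p == pytest.approx(float(p_ref))

    def test_bonferroni_multiplier_is_number_of_pairs(self, life_records):
        results = pairwise_t(life_records)
        n_temp = life_records["temperature_C"].nunique()
        assert len(results) == n_temp * (n_temp - 1) // 2
        # adjusted p never exceeds 1 and equals min(1, raw * m) by construction
        assert all(0 <= r.p <= 1 for r in results)


class TestSexRatio:
    def test_balanced_counts_give_p_one(self):
        df = records_from_cup_mortalities({20.0: [0.0]}, larvae=20)
        df.loc[df.index[:10], "sex"] = "female"
        df.loc[df.index[10:], "sex"] = "male"
        assert sex_ratio_test(df).p == pytest.approx(1.0)

    def test_all_male_closed_form(self):
        df = records_from_cup_mortalities({20.0: [0.0]}, larvae=20)
        df["sex"] = "male"
        assert sex_ratio_test(df).p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_35_of_50_females_matches_exact_binomial_sum(self):
        df = records_from_cup_mortalities({20.0: [0.0]}, larvae=50)
        df.loc[df.index[:35], "sex"] = "female"
        df.loc[df.index[35:], "sex"] = "male"
        res = sex_ratio_test(df)
        # oracle: two-sided exact binomial as sum of point probabilities
        pmf = stats.binom.pmf(np.arange(51), 50, 0.5)
        p_exact = pmf[pmf <= pmf[35] * (1 + 1e-9)].sum()
        assert res.p == pytest.approx(p_exact, rel=1e-9)
        assert res.p == pytest.approx(0.0066, abs=5e-4)

    def test_no_adults_rejected(self):
        df = records_from_cup_mortalities({0.0: [1.0]})
        with pytest.raises(ValueError):
            sex_ratio_test(df)


class TestAgeCurve:
    def test_noiseless_means_recover_generating_coefficients(self, truth):
        """Exact mean emergence ages reproduce (290.75, 0.17, 8.32) to 1e-3."""
        temps = [10, 14, 17, 20, 23, 25, 28, 31]
        rows = []
        for t in temps:
            rows.append({
                "temperature_C": t, "cup_id": 1, "sex": "female", "survived": True,
                "age_pupation_days": np.nan,
                "age_emergence_days": float(truth.age_curves["emergence"](t)),
                "age_death_days": np.nan, "r1_mm": np.nan,
            })
        fit = fit_age_curve(pd.DataFrame(rows), "emergence")
        assert (fit.A, fit.k, fit.c) == pytest.approx((290.75, 0.17, 8.32), abs=1e-3)
        # fastest emergence ~ 12.5 d at 25 degC
        assert fit(25.0) == pytest.approx(12.47, abs=0.05)

    def test_constant_ages_flagged_degenerate(self):
        rows = [{
            "temperature_C": t, "cup_id": 1, "sex": "female", "survived": True,
            "age_pupation_days": np.nan, "age_emergence_days": 20.0,
            "age_death_days": np.nan, "r1_mm": np.nan,
        } for t in (10, 15, 20, 25)]
        fit = fit_age_curve(pd.DataFrame(rows), "emergence")
        assert fit.degenerate and fit.k == 0.0
        assert fit.c == pytest.approx(20.0)

    def test_too_few_temperatures_rejected(self, life_records):
        few = life_records[life_records["temperature_C"].isin([25.0, 26.0])]
        with pytest.raises(ValueError):
            fit_age_curve(few, "emergence")

    def test_temperature_explains_over_80_percent_of_age_variance(self, life_records):
        """On generator fixtures (CV = 0.1) rearing temperature dominates ages."""
        adults = life_records[life_records["survived"]]
        y = adults["age_emergence_days"].to_numpy()
        groups = adults.groupby("temperature_C")["age_emergence_days"]
        ss_between = sum(len(g) * (g.mean() - y.mean()) ** 2 for _, g in groups)
        ss_total = ((y - y.mean()) ** 2).sum()
        assert ss_between / ss_total > 0.8


def size_fixture(truth, temps, n_per_cell, rng):
    """Adult records with R1 lengths drawn from the truth size distribution.

    Bypasses the survival filter (survival is exactly 0 at T_max = 31 degC,
    where the study still measured wings) to test the size statistics on
    their own.
    """
    rows = []
    for t in temps:
        for sex in ("female", "male"):
            mean = float(truth.mean_r1_mm(t, sex))
            sigma = np.sqrt(np.log(1 + truth.r1_cv**2))
            r1 = rng.lognormal(np.log(mean) - sigma**2 / 2, sigma, size=n_per_cell)
            for i, v in enumerate(r1):
                rows.append({
                    "temperature_C": t, "cup_id": 1 + i % 5, "sex": sex,
                    "survived": True, "age_pupation_days": 10.0,
                    "age_emergence_days": 12.0, "age_death_days": 30.0,
                    "r1_mm": float(v),
                })
    return pd.DataFrame(rows)


class TestBodySize:
    def test_truth_size_gradient_recovered(self, truth):
        """Female means 4.26 mm at 15 degC and 3.04 mm at 31 degC within 3 SE."""
        rng = np.random.default_rng(8)
        df = size_fixture(truth, (15.0, 31.0), 100, rng)
        summ = size_summary(df)
        for temp, expected in ((15.0, 4.26), (31.0, 3.04)):
            row = summ[(summ["temperature_C"] == temp) & (summ["sex"] == "female")].iloc[0]
            se = row["sd_mm"] / np.sqrt(row["n"])
            assert abs(row["mean_r1_mm"] - expected) < 3 * se

    def test_single_level_anova_rejected(self, truth):
        rng = np.random.default_rng(9)
        df = size_fixture(truth, (25.0,), 50, rng)
        df = df[df["sex"] == "female"]
        with pytest.raises(ValueError):
            size_anova(df)

    def test_percent_difference_scale_removes_the_sex_effect(self, truth):
        """Pure temperature-size-rule data (males a constant fraction of
        female size): normalising to each sex's maximal group mean collapses
        the sex term. Because the normaliser is itself estimated, the sex
        F keeps an inflated null distribution, so the check is on medians
        over replicates: median sex p clears 0.05 and the sex F drops by
        more than an order of magnitude relative to the raw scale, while
        temperature stays overwhelmingly significant."""
        rng = np.random.default_rng(10)
        p_sex, f_sex, f_sex_raw, p_temp = [], [], [], []
        for _ in range(50):
            df = size_fixture(truth, (15.0, 23.0, 31.0), 30, rng)
            res = {r.label: r for r in size_anova(df, response="pct_diff_to_max")}
            raw = {r.label: r for r in size_anova(df)}
            p_sex.append(res["pct_diff_to_max: sex"].p)
            f_sex.append(res["pct_diff_to_max: sex"].value)
            f_sex_raw.append(raw["r1_mm: sex"].value)
            p_temp.append(res["pct_diff_to_max: temperature"].p)
        assert np.median(p_sex) > 0.05
        assert np.median(f_sex) < np.median(f_sex_raw) / 20
        assert max(p_temp) < 0.001

    def test_raw_scale_shows_temperature_and_sex_effects(self, life_records):
        res = {r.label: r for r in size_anova(life_records)}
        assert res["r1_mm: temperature"].p < 0.001
        assert res["r1_mm: sex"].p < 0.001
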