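"""Potential impact fractions and the cohort life table."""

import numpy as np
import pytest

from ssbtax import adjust_mortality, health_outcomes, pif, run_life_table
from ssbtax.config import AGE_GROUPS, SEXES
from ssbtax.lifetable import cohort_trace
from ssbtax.population import STRATA_KEYS


class TestPif:
    def test_no_shift_gives_zero(self):
        p = [0.2, 0.3, 0.5]
        assert pif(p, p, [1.0, 1.2, 1.5]) == 0.0

    def test_two_class_hand_example(self):
        # RR (1, 2), P (0.5, 0.5) -> risk 1.5; P' (0.75, 0.25) -> 1.25.
        assert pif([0.5, 0.5], [0.75, 0.25], [1.0, 2.0]) == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_adverse_shift_gives_negative_pif(self):
        assert pif([0.75, 0.25], [0.5, 0.5], [1.0, 2.0]) < 0

    def test_non_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pif([0.5, 0.4], [0.5, 0.5], [1.0, 2.0])
        with pytest.raises(ValueError, match="shape"):
            pif([0.5, 0.5], [0.5, 0.5], [1.0, 2.0, 3.0])


class TestAdjustMortality:
    @pytest.mark.parametrize(
        "m,p,expected",
        [(0.01, 0.0, 0.01), (0.01, 0.1, 0.009), (0.01, -0.05, 0.0105)],
    )
    def test_scaling(self, m, p, expected):
        assert adjust_mortality(m, p) == pytest.approx(expected, rel=1e-12)

    def test_pif_at_or_above_one_rejected(self):
        with pytest.raises(ValueError, match="PIF"):
            adjust_mortality(0.01, 1.0)

    def test_result_clamped_below_one(self):
        assert adjust_mortality(0.9999, -10.0) < 1.0


class TestCohortTrace:
    def test_two_cycle_hand_calculation(self):
        # 1000 people, constant m = 0.1, r = 0, half-cycle correction:
        # deaths 100 + 90 = 190; person-years 950 + 855 = 1805.
        tr = cohort_trace(1000.0, 30, [0.1] * 6, horizon=2, discount_rate=0.0)
        assert tr["deaths"].sum() == pytest.approx(190.0, rel=1e-12)
        assert tr["person_years"].sum() == pytest.approx(1805.0, rel=1e-12)

    def test_zero_mortality_full_person_years(self):
        tr = cohort_trace(500.0, 20, [1e-300] * 6, horizon=5, discount_rate=0.0)
        assert tr["deaths"].sum() == pytest.approx(0.0, abs=1e-6)
        assert tr["person_years"].sum() == pytest.approx(500.0 * 5, rel=1e-9)

    def test_discounting_strictly_reduces_person_years(self):
        tr = cohort_trace(1000.0, 30, [0.01] * 6, horizon=10, discount_rate=0.06)
        assert (tr["discounted_py"] < tr["person_years"]).all()

    def test_cohort_ages_into_higher_mortality_group(self):
        rates = [0.001, 0.002, 0.004, 0.008, 0.016, 0.032]
        tr = cohort_trace(1000.0, 63, rates, horizon=4, discount_rate=0.0)
        # ages 63, 64 use the 55-64 rate; 65, 66 use the 65+ rate
        m = tr["deaths"] / tr["alive_start"]
        assert m.iloc[0] == pytest.approx(0.016)
        assert m.iloc[2] == pytest.approx(0.032)


class TestRunLifeTable:
    def test_population_conservation_every_cycle(self, population):
        lt = run_life_table(population, horizon=10, discount_rate=0.06)
        for (sex, age), grp in lt.by_cycle.groupby(["sex", "age_group"], sort=False):
            alive = grp["alive_start"].to_numpy()
            deaths = grp["deaths"].to_numpy()
            assert np.allclose(alive[1:], alive[:-1] - deaths[:-1], rtol=1e-12)
            assert (deaths >= 0).all()

    def test_initial_alive_matches_stratum_counts(self, population):
        lt = run_life_table(population, horizon=3, discount_rate=0.0)
        first = lt.by_cycle[lt.by_cycle["cycle"] == 1]
        for row in first.itertuples():
            assert row.alive_start == pytest.approx(
                population.stratum(row.sex, row.age_group).count, rel=1e-12
            )

    def test_matches_cohort_trace_oracle_on_single_age(self, population):
        """The vectorised table equals the per-cohort reference, summed."""
        lt = run_life_table(population, horizon=5, discount_rate=0.06)
        sex, age = "female", "25-34"
        s = population.stratum(sex, age)
        rates = population.mortality_rates(sex)
        expected = np.zeros(5)
        for a0 in range(25, 35):
            tr = cohort_trace(s.count / 10.0, a0, rates, horizon=5, discount_rate=0.06)
            expected += tr["person_years"].to_numpy()
        got = lt.by_cycle[
            (lt.by_cycle["sex"] == sex) & (lt.by_cycle["age_group"] == age)
        ]["person_years"].to_numpy()
        assert np.allclose(got, expected, rtol=1e-10)

    def test_totals_sum_over_sexes(self, population):
        lt = run_life_table(population, horizon=5, discount_rate=0.06)
        for col in ("deaths", "person_years", "discounted_py"):
            assert lt.total(col) == pytest.approx(
                lt.total(col, "female") + lt.total(col, "male"), rel=1e-9
            )

    def test_half_cycle_toggle_changes_person_years_only(self, population):
        on = run_life_table(population, horizon=5, discount_rate=0.0, half_cycle=True)
        off = run_life_table(population, horizon=5, discount_rate=0.0, half_cycle=False)
        assert on.total("deaths") == pytest.approx(off.total("deaths"), rel=1e-12)
        assert on.total("person_years") > off.total("person_years")


class TestHealthOutcomes:
    def test_identical_inputs_give_zero(self, population):
        a = run_life_table(population, horizon=5, discount_rate=0.06)
        b = run_life_table(population, horizon=5, discount_rate=0.06)
        out = health_outcomes(a, b)
        assert out.deaths_averted["total"] == 0.0
        assert out.life_years_gained["total"] == 0.0

    def test_uniform_risk_reduction_averts_deaths_and_gains_years(self, population):
        base = run_life_table(population, horizon=20, discount_rate=0.06)
        pifs = {key: 0.01 for key in STRATA_KEYS}
        interv = run_life_table(
            population, horizon=20, discount_rate=0.06, pif_by_stratum=pifs
        )
        out = health_outcomes(base, interv)
        for sex in (*SEXES, "total"):
            assert out.deaths_averted[sex] > 0
            assert out.life_years_gained[sex] > 0
        assert out.deaths_averted["total"] == pytest.approx(
            out.deaths_averted["female"] + out.deaths_averted["male"], rel=1e-9
        )

    def test_mismatched_horizons_rejected(self, population):
        a = run_life_table(population, horizon=5, discount_rate=0.06)
        b = run_life_table(population, horizon=6, discount_rate=0.06)
        with pytest.raises(ValueError, match="horizon"):
            health_outcomes(a, b)
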