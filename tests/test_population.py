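"""Synthetic population: counts, consumption allocation, BMI calibration, mortality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from ssbtax import RunConfig, allocate_consumption, build_population, fit_lognormal_bmi, sample_bmi_heights
from ssbtax.config import AGE_GROUPS, BEVERAGES, SEXES
from ssbtax.population import CalibrationError, achieved_bmi_moments, load_fixture


class TestBuildPopulation:
    def test_sex_totals_match_census_projection(self, population):
        assert population.sex_count("female") == pytest.approx(4_271_631, rel=1e-3)
        assert population.sex_count("male") == pytest.approx(4_072_855, rel=1e-3)
        assert population.total_count == pytest.approx(8_344_486, rel=1e-3)

    def test_uniform_age_shares_split_each_sex_evenly(self):
        cfg = RunConfig.model_validate(
            {"population": {"age_shares": [1 / 6] * 6}}
        )
        pop = build_population(cfg)
        for sex in SEXES:
            for age in AGE_GROUPS:
                assert pop.stratum(sex, age).count == pytest.approx(
                    cfg.population.sex_totals[sex] / 6
                )

    def test_weighted_mean_ssb_matches_spreadsheet_oracle(self, population, default_config):
        # Independent recomputation: explicit loop over the consumption table.
        num = den = 0.0
        shares = default_config.population.age_shares
        for sex in SEXES:
            for i, age in enumerate(AGE_GROUPS):
                w = default_config.population.sex_totals[sex] * shares[i]
                num += w * default_config.population.weekly_servings[sex][age]["ssb"]
                den += w
        assert population.weighted_mean_servings("ssb") == pytest.approx(num / den, rel=1e-12)

    def test_stratum_consumption_equals_configured_table(self, population, default_config):
        for sex in SEXES:
            for age in AGE_GROUPS:
                for bev in BEVERAGES:
                    assert population.stratum(sex, age).weekly_servings[bev] == (
                        default_config.population.weekly_servings[sex][age][bev]
                    )

    def test_invalid_age_shares_name_the_field(self):
        with pytest.raises(ValueError, match="age_shares"):
            RunConfig.model_validate({"population": {"age_shares": [0.5, 0.5, 0, 0, 0, 0.1]}})

    def test_missing_stratum_consumption_rejected(self):
        servings = RunConfig().population.weekly_servings
        del servings["male"]["65+"]["milk"]
        with pytest.raises(ValueError, match="weekly_servings"):
            RunConfig.model_validate({"population": {"weekly_servings": servings}})

    def test_mortality_schedule_increasing_and_calibrated(self, population, default_config):
        for sex in SEXES:
            rates = population.mortality_rates(sex)
            assert (np.diff(rates) > 0).all()
            assert ((rates > 0) & (rates < 1)).all()
        w = population.counts
        m = np.array([s.mortality_rate for s in population.strata])
        assert (w * m).sum() / w.sum() == pytest.approx(
            default_config.mortality.mean_annual_rate, rel=1e-9
        )


class TestBmiCalibration:
    @pytest.mark.parametrize(
        "mean,prev", [(24.3, 0.135), (22.5, 0.0399), (23.38, 0.08)]
    )
    def test_lognormal_fit_matches_root_finding_oracle(self, mean, prev):
        """The closed-form fit agrees with a bracketing root search on sigma."""

        def prevalence_given_sigma(sigma: float) -> float:
            mu = np.log(mean) - sigma**2 / 2.0  # pins the mean
            return 1.0 - stats.norm.cdf((np.log(30.0) - mu) / sigma)

        sigma_oracle = brentq(lambda s: prevalence_given_sigma(s) - prev, 1e-6, 1.0, xtol=1e-12)
        mu_oracle = np.log(mean) - sigma_oracle**2 / 2.0
        mu, sigma = fit_lognormal_bmi(mean, prev)
        assert sigma == pytest.approx(sigma_oracle, abs=1e-6)
        assert mu == pytest.approx(mu_oracle, abs=1e-6)

    def test_fit_reproduces_its_targets(self):
        mu, sigma = fit_lognormal_bmi(24.3, 0.135)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(24.3, rel=1e-12)
        assert 1 - stats.norm.cdf((np.log(30) - mu) / sigma) == pytest.approx(0.135, rel=1e-9)

    def test_zero_prevalence_degenerates_to_point_mass(self, population):
        mu, sigma = fit_lognormal_bmi(23.38, 0.0)
        assert sigma == 0.0
        assert np.exp(mu) == pytest.approx(23.38)

    def test_infeasible_calibration_raises_with_diagnostics(self):
        with pytest.raises(CalibrationError, match="cannot reach"):
            fit_lognormal_bmi(20.0, 0.40)
        with pytest.raises(CalibrationError):
            fit_lognormal_bmi(31.0, 0.10)  # mean above the cutoff


class TestBmiSampling:
    def test_per_sex_moments_hit_targets_at_large_n(self, population, full_sample, default_config):
        moments = achieved_bmi_moments(population, full_sample)
        for sex in SEXES:
            target = default_config.bmi.targets[sex]
            assert moments.loc[sex, "mean_bmi"] == pytest.approx(target.mean_bmi, rel=5e-3)
            assert abs(
                moments.loc[sex, "obesity_prevalence"] - target.obesity_prevalence
            ) < 0.005

    def test_same_seed_is_bit_identical(self, population):
        a = sample_bmi_heights(population, 500, seed=3)
        b = sample_bmi_heights(population, 500, seed=3)
        c = sample_bmi_heights(population, 500, seed=4)
        for key in a.bmi:
            assert np.array_equal(a.bmi[key], b.bmi[key])
            assert np.array_equal(a.height[key], b.height[key])
        assert not np.array_equal(a.bmi[("female", "15-24")], c.bmi[("female", "15-24")])

    def test_sample_bounds_and_size(self, small_sample):
        for key, arr in small_sample.bmi.items():
            assert arr.shape == (2_000,)
            assert (arr > 10).all() and (arr < 70).all()
            h = small_sample.height[key]
            assert (h > 1.2).all() and (h < 2.2).all()

    def test_too_small_sample_rejected(self, population):
        with pytest.raises(ValueError, match="n_per_stratum"):
            sample_bmi_heights(population, 50, seed=0)


class TestAllocation:
    def test_uniform_shares_give_every_stratum_the_mean(self):
        counts = np.array([10.0, 20.0, 30.0])
        out = allocate_consumption(1.55, [1, 1, 1], counts)
        assert np.allclose(out, 1.55)

    def test_all_zero_shares_error(self):
        with pytest.raises(ValueError, match="zero"):
            allocate_consumption(1.0, [0, 0, 0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        shares=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=12),
        per_capita=st.floats(0.01, 20.0),
        data=st.data(),
    )
    def test_allocation_conserves_per_capita_mean(self, shares, per_capita, data):
        if sum(shares) == 0:
            shares[0] = 1.0
        counts = data.draw(
            st.lists(
                st.floats(1.0, 1e6), min_size=len(shares), max_size=len(shares)
            )
        )
        out = allocate_consumption(per_capita, shares, counts)
        w = np.asarray(counts)
        assert float((w * out).sum() / w.sum()) == pytest.approx(per_capita, rel=1e-9)

    def test_table_profile_shares_scale_the_profile(self, population, default_config):
        # Shares proportional to the consumption table reproduce the table up
        # to the single factor that enforces the per-capita mean.
        profile = np.array(
            [s.weekly_servings["ssb"] for s in population.strata]
        )
        out = allocate_consumption(1.55, profile, population.counts)
        ratios = out / profile
        assert np.allclose(ratios, ratios[0])


class TestFixtures:
    def test_table2_fixture_matches_config_defaults(self, default_config):
        df = load_fixture("table2")
        assert len(df) == 36
        for row in df.itertuples():
            assert default_config.population.weekly_servings[row.sex][row.age_group][
                row.beverage
            ] == pytest.approx(row.weekly_servings)

    def test_table1_fixture_carries_core_parameters(self):
        df = load_fixture("table1").set_index("parameter")
        assert df.loc["ssb_price", "value"] == pytest.approx(3.77)
        assert df.loc["own_price_elasticity_ssb", "value"] == pytest.approx(-1.30)
        assert df.loc["adult_population", "value"] == pytest.approx(8_344_486)
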