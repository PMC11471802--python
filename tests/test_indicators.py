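"""Indicator estimators: ogive MLE vs grid oracle, CF/K identities, LDI, L95, ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import codtrends as ct
from conftest import grid_mle_ogive, simulate_maturity_sample


def two_point_design():
    """10 fish at 30 cm (2 mature) and 10 at 50 cm (8 mature)."""
    lengths = np.array([30.0] * 10 + [50.0] * 10)
    mature = np.array([1] * 2 + [0] * 8 + [1] * 8 + [0] * 2, dtype=bool)
    return lengths, mature


class TestFitOgive:
    def test_two_point_symmetry_gives_midpoint(self):
        lengths, mature = two_point_design()
        fit = ct.fit_ogive(lengths, mature)
        assert fit.converged
        assert fit.l50 == pytest.approx(40.0, abs=1e-8)

    def test_matches_grid_mle_on_toy_fixture(self):
        # 12-record fixed fixture
        lengths = np.array([25.0, 28.0, 31.0, 34.0, 36.0, 38.0,
                            41.0, 43.0, 46.0, 49.0, 52.0, 55.0])
        mature = np.array([0, 0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 1], dtype=bool)
        fit = ct.fit_ogive(lengths, mature, min_n=10)
        a, b, l50 = grid_mle_ogive(lengths, mature)
        assert fit.alpha == pytest.approx(a, abs=1e-4)
        assert fit.beta == pytest.approx(b, abs=1e-5)
        assert fit.l50 == pytest.approx(l50, abs=1e-4)

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        lengths, mature = simulate_maturity_sample(seed=5, n=500)
        fit = ct.fit_ogive(lengths, mature)
        X = sm.add_constant(lengths)
        res = sm.GLM(mature.astype(float), X, family=sm.families.Binomial()).fit()
        assert fit.alpha == pytest.approx(res.params[0], rel=1e-6)
        assert fit.beta == pytest.approx(res.params[1], rel=1e-6)
        assert fit.se_beta == pytest.approx(res.bse[1], rel=1e-4)

    def test_predicted_proportion_at_l50_is_half(self):
        lengths, mature = simulate_maturity_sample(seed=11, n=800)
        fit = ct.fit_ogive(lengths, mature)
        assert expit(fit.alpha + fit.beta * fit.l50) == pytest.approx(0.5, abs=1e-12)

    def test_single_class_is_no_fit(self):
        lengths = np.linspace(30, 60, 30)
        fit = ct.fit_ogive(lengths, np.ones(30, dtype=bool))
        assert not fit.converged and not fit.accepted
        assert "single" in fit.reason

    def test_too_few_records(self):
        fit = ct.fit_ogive([30.0, 50.0], [False, True])
        assert not fit.accepted and "fewer than" in fit.reason

    def test_decreasing_ogive_rejected_but_reported(self):
        rng = np.random.default_rng(3)
        lengths = np.linspace(20, 60, 200)
        mature = rng.random(200) < expit(-0.5 * (lengths - 40))  # falling ogive
        fit = ct.fit_ogive(lengths, mature)
        assert fit.converged and fit.beta < 0
        assert not fit.accepted and "non-increasing" in fit.reason

    def test_separation_detected(self):
        # perfectly separated data diverge under MLE
        lengths = np.concatenate([np.linspace(20, 39, 15), np.linspace(41, 60, 15)])
        mature = lengths > 40
        fit = ct.fit_ogive(lengths, mature)
        assert not fit.converged
        assert "separation" in fit.reason or "converge" in fit.reason

    def test_insignificant_fit_not_accepted(self):
        rng = np.random.default_rng(8)
        lengths = np.linspace(20, 60, 40)
        mature = rng.random(40) < 0.5  # maturity independent of length
        fit = ct.fit_ogive(lengths, mature)
        if fit.converged:
            assert not fit.accepted


def _sd_block(year, sd, l50, n_per_point=50):
    """Symmetric two-point design around a known L50 (exact by construction)."""
    lengths = np.array([l50 - 10.0] * n_per_point + [l50 + 10.0] * n_per_point)
    k = int(round(0.2 * n_per_point))
    mature = np.array([1] * k + [0] * (n_per_point - k)
                      + [1] * (n_per_point - k) + [0] * k, dtype=bool)
    return pd.DataFrame({
        "year": year, "sd": sd, "length_cm": lengths,
        "maturity_status": np.where(mature, "mature", "immature"),
    })


class TestAnnualL50:
    def test_mean_over_accepted_subdivisions(self):
        df = pd.concat([
            _sd_block(1950, 25, 38.0),
            _sd_block(1950, 26, 40.0),
            _sd_block(1950, 27, 42.0),
        ])
        series, audit = ct.annual_l50(df, sds=(25, 26, 27))
        assert series.loc[1950, "value"] == pytest.approx(40.0, abs=1e-7)
        assert series.loc[1950, "n"] == 3

    def test_rejected_fit_excluded_from_mean(self):
        rng = np.random.default_rng(1)
        flat = pd.DataFrame({
            "year": 1950, "sd": 27,
            "length_cm": np.linspace(20, 60, 40),
            "maturity_status": np.where(rng.random(40) < 0.5, "mature", "immature"),
        })
        df = pd.concat([_sd_block(1950, 25, 38.0), _sd_block(1950, 26, 42.0), flat])
        series, audit = ct.annual_l50(df, sds=(25, 26, 27))
        rejected = [f for (_, sd, f) in audit if sd == 27]
        assert rejected and not rejected[0].accepted
        assert series.loc[1950, "value"] == pytest.approx(40.0, abs=1e-7)
        assert series.loc[1950, "n"] == 2

    def test_year_without_accepted_fits_is_missing(self):
        df = _sd_block(1950, 25, 40.0, n_per_point=5)  # n=10 < min_n
        series, _ = ct.annual_l50(df, sds=(25,))
        assert np.isnan(series.loc[1950, "value"]) and series.loc[1950, "n"] == 0

    def test_recovers_simulated_truth(self):
        lengths, mature = simulate_maturity_sample(seed=21, n=2000)
        df = pd.DataFrame({
            "year": 1960, "sd": 25, "length_cm": lengths,
            "maturity_status": np.where(mature, "mature", "immature"),
        })
        series, _ = ct.annual_l50(df, sds=(25,))
        assert series.loc[1960, "value"] == pytest.approx(40.0, abs=1.0)


class TestConditionFactors:
    @pytest.mark.parametrize("L, W, expected", [(50, 1250, 1.0), (40, 640, 1.0), (50, 1000, 0.8)])
    def test_fulton_cf_values(self, L, W, expected):
        assert ct.fulton_cf(W, L) == pytest.approx(expected)

    def test_fulton_cf_rejects_non_positive(self):
        with pytest.raises(ValueError):
            ct.fulton_cf(0, 50)
        with pytest.raises(ValueError):
            ct.fulton_cf(1000, -1)

    def _cf_frame(self, n, length=50.0, cf=1.0, year=1950, sd=25):
        w = cf * length**3 / 100.0
        return pd.DataFrame({"year": year, "sd": sd,
                             "length_cm": [length] * n, "weight_g": [w] * n})

    def test_threshold_is_strictly_more_than_five(self):
        five = self._cf_frame(5)
        series = ct.annual_cf(five, sds=(25,))
        assert np.isnan(series.loc[1950, "value"])
        six = self._cf_frame(6)
        series = ct.annual_cf(six, sds=(25,))
        assert series.loc[1950, "value"] == pytest.approx(1.0)

    def test_interval_boundaries(self):
        inside = self._cf_frame(6, length=41.0)
        outside = self._cf_frame(6, length=40.5, cf=5.0)
        df = pd.concat([inside, outside])
        series = ct.annual_cf(df, sds=(25,))
        assert series.loc[1950, "value"] == pytest.approx(1.0)  # 40.5 cm fish excluded

    def test_annual_mean_over_subdivisions(self):
        df = pd.concat([self._cf_frame(6, cf=0.8, sd=25), self._cf_frame(6, cf=1.2, sd=26)])
        series = ct.annual_cf(df, sds=(25, 26))
        assert series.loc[1950, "value"] == pytest.approx(1.0)
        assert series.loc[1950, "n"] == 2


class TestLengthWeight:
    def test_noiseless_power_law_recovered(self):
        lengths = np.linspace(21, 99, 60)
        df = pd.DataFrame({"length_cm": lengths, "weight_g": 0.01 * lengths**3})
        fit = ct.fit_length_weight(df)
        assert fit.a == pytest.approx(0.01, rel=1e-6)
        assert fit.b == pytest.approx(3.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_bounds_restrict_fit(self):
        lengths = np.concatenate([np.linspace(21, 99, 40), [10.0, 110.0]])
        weights = 0.01 * lengths**3
        weights[-2:] *= 10  # gross outliers outside 20-100 cm must be ignored
        df = pd.DataFrame({"length_cm": lengths, "weight_g": weights})
        fit = ct.fit_length_weight(df)
        assert fit.n == 40
        assert fit.b == pytest.approx(3.0, rel=1e-6)

    def test_too_few_records_raises(self):
        df = pd.DataFrame({"length_cm": [30.0] * 5, "weight_g": [270.0] * 5})
        with pytest.raises(ValueError):
            ct.fit_length_weight(df)

    def test_simulator_round_trip_exact(self, noiseless_population):
        cfg = ct.SimConfig(seed=13, years=(1950, 1951), sample_size_per_year=500)
        df = ct.simulate_individual_records(noiseless_population, cfg)
        df = df.rename(columns={})
        fit = ct.fit_length_weight(df)
        assert fit.a == pytest.approx(noiseless_population.lw_a, rel=1e-6)
        assert fit.b == pytest.approx(noiseless_population.lw_b, rel=1e-6)

    def test_lecren_identities(self):
        lengths = np.linspace(21, 99, 30)
        df = pd.DataFrame({"length_cm": lengths, "weight_g": 0.01 * lengths**3})
        fit = ct.fit_length_weight(df)
        assert ct.lecren_k(0.01 * 50.0**3, 50.0, fit) == pytest.approx(1.0, rel=1e-9)
        assert ct.lecren_k(1.1 * fit.predict(37.0), 37.0, fit) == pytest.approx(1.1, rel=1e-9)

    def test_lecren_geometric_mean_is_one_on_fitting_sample(self):
        rng = np.random.default_rng(17)
        lengths = rng.uniform(21, 99, 400)
        weights = 0.011 * lengths**2.95 * np.exp(rng.normal(0, 0.08, 400))
        df = pd.DataFrame({"length_cm": lengths, "weight_g": weights})
        fit = ct.fit_length_weight(df)
        k = ct.lecren_k(weights, lengths, fit)
        # OLS log residuals sum to zero -> geometric mean of K is exactly 1
        assert np.exp(np.mean(np.log(k))) == pytest.approx(1.0, abs=1e-10)


class TestLdi:
    def test_single_class_zero(self):
        assert ct.ldi({30: 17}) == pytest.approx(0.0)

    def test_uniform_maximum(self):
        assert ct.ldi({20: 4, 25: 4, 30: 4, 35: 4, 40: 4}) == pytest.approx(np.log(5))

    def test_sub_lmin_classes_ignored(self):
        counts = {15: 99, 20: 5, 25: 3, 30: 2}
        p = np.array([0.5, 0.3, 0.2])
        assert ct.ldi(counts) == pytest.approx(float(-np.sum(p * np.log(p))), rel=1e-12)

    def test_scaling_invariance_and_bounds(self):
        counts = {20: 3, 25: 9, 33: 1, 47: 6}
        v = ct.ldi(counts)
        assert ct.ldi({k: 10 * c for k, c in counts.items()}) == pytest.approx(v, rel=1e-12)
        assert 0.0 <= v <= np.log(4)

    def test_no_fish_above_lmin_missing(self):
        assert np.isnan(ct.ldi({15: 10}))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ct.ldi({20: -1})


class TestL95:
    def test_degenerate_all_equal(self):
        assert ct.l95(lengths=[50.0] * 20) == pytest.approx(50.0)

    def test_interpolation_rule_oracle(self):
        lengths = np.arange(20.0, 120.0)  # 100 sorted values
        # h = (n-1)*0.95 + 1 on 1-based order statistics
        h = (100 - 1) * 0.95 + 1
        lo = int(np.floor(h))
        expected = lengths[lo - 1] + (h - lo) * (lengths[lo] - lengths[lo - 1])
        assert ct.l95(lengths=lengths) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_adding_small_fish(self):
        lengths = list(np.linspace(25, 90, 40))
        v = ct.l95(lengths=lengths)
        assert ct.l95(lengths=lengths + [5.0, 12.0, 19.9]) == pytest.approx(v, rel=1e-12)

    def test_counts_input_expands_at_lower_bounds(self):
        counts = {30: 10, 40: 10}
        expanded = [30.0] * 10 + [40.0] * 10
        assert ct.l95(counts=counts) == pytest.approx(ct.l95(lengths=expanded), rel=1e-12)

    @given(st.lists(st.floats(20.0, 150.0), min_size=5, max_size=40),
           st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_under_adding_longer_fish(self, lengths, extra):
        v = ct.l95(lengths=lengths)
        assert ct.l95(lengths=lengths + [v + extra]) >= v - 1e-12

    def test_empty_missing(self):
        assert np.isnan(ct.l95(lengths=[10.0, 15.0]))


class TestProductivityRatios:
    def _series(self):
        years = pd.Index(range(1996, 2002), name="year")
        return pd.DataFrame({
            "catch": [100.0] * 6,
            "recruits": [1e6, 2e6, 1e6, 1e6, 1e6, 1e6],
        }, index=years)

    def test_cpr_unit_arithmetic(self):
        cpr = ct.catch_per_recruit(self._series())
        assert cpr.loc[2000] == pytest.approx(100.0)  # 100 t / 1e6 recruits
        assert cpr.loc[2001] == pytest.approx(50.0)   # lagged on 1997's 2e6

    def test_cpr_first_lag_years_missing(self):
        cpr = ct.catch_per_recruit(self._series())
        assert cpr.loc[1996:1999].isna().all()

    def test_cpr_identity_lag(self):
        cpr = ct.catch_per_recruit(self._series(), lag=0)
        assert cpr.loc[1996] == pytest.approx(100.0)

    def test_cpr_zero_recruits_missing(self):
        df = self._series()
        df.loc[1996, "recruits"] = 0.0
        cpr = ct.catch_per_recruit(df)
        assert np.isnan(cpr.loc[2000])

    def test_total_mortality_scalar(self):
        assert ct.total_mortality(0.2, 0.2) == pytest.approx(0.4)
        assert ct.total_mortality(0.3, None, year=1950) == pytest.approx(0.5)
        assert ct.total_mortality(0.0, 0.2) == pytest.approx(0.2)
        assert np.isnan(ct.total_mortality(0.3, None, year=2000))

    def test_total_mortality_series_convention(self):
        f = pd.Series([0.3, 0.3, 0.3], index=[1950, 1990, 1991])
        m = pd.Series([np.nan, np.nan, 0.25], index=[1950, 1990, 1991])
        z = ct.total_mortality(f, m)
        assert z.loc[1950] == pytest.approx(0.5)  # conventional M = 0.2
        assert z.loc[1990] == pytest.approx(0.5)
        assert z.loc[1991] == pytest.approx(0.55)

    def test_total_mortality_rejects_negative(self):
        with pytest.raises(ValueError):
            ct.total_mortality(-0.1, 0.2)

    def test_exploitation_rate(self):
        assert ct.exploitation_rate(0.2, 0.4) == pytest.approx(0.5)
        assert ct.exploitation_rate(0.0, 0.2) == pytest.approx(0.0)
        assert np.isnan(ct.exploitation_rate(0.2, 0.0))
        # F = M implies ER = 0.5 at any positive level
        for f in (0.05, 0.4, 1.3):
            assert ct.exploitation_rate(f, 2 * f) == pytest.approx(0.5)
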