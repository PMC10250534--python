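import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropclim import metrics
from cropclim.calendar import (
    DAYS_PER_YEAR,
    MONTH_ENDS,
    MONTH_STARTS,
    SEASON_SLICES,
)
from cropclim.metrics import (
    DEFAULT_THRESHOLDS,
    MetricThresholds,
    annual_gdd,
    chill_hours,
    chill_hours_days,
    context_vector,
    context_vectors,
    daily_gdd,
    disaggregate_hourly,
    frost_free_season_length,
    generic_vector,
    heat_degree_hours,
    heat_degree_hours_days,
    precipitation_uniformity,
)


def constant_year(tmax, tmin, prcp=0.0):
    return (
        np.full(DAYS_PER_YEAR, float(tmax)),
        np.full(DAYS_PER_YEAR, float(tmin)),
        np.full(DAYS_PER_YEAR, float(prcp)),
    )


def brute_force_hourly(tmax, tmin):
    """Independent re-statement of the sine disaggregation, hour by hour."""
    out = []
    for h in range(24):
        mean = (tmax + tmin) / 2.0
        amp = (tmax - tmin) / 2.0
        out.append(mean + amp * np.sin(2 * np.pi * (h - 9) / 24.0))
    return out


class TestThresholds:
    def test_defaults(self):
        t = DEFAULT_THRESHOLDS
        assert t.gdd_base == 0.0
        assert t.gdd_upper == 29.44
        assert t.heat_threshold == 32.0
        assert (t.chill_low, t.chill_high) == (0.0, 7.22)

    def test_invalid(self):
        with pytest.raises(ValueError):
            MetricThresholds(gdd_base=30.0, gdd_upper=29.44)
        with pytest.raises(ValueError):
            MetricThresholds(chill_low=8.0)
        with pytest.raises(ValueError):
            MetricThresholds(heat_threshold=np.inf)


class TestDailyGdd:
    def test_plain_average(self):
        assert daily_gdd(20.0, 10.0) == pytest.approx(15.0)

    def test_both_below_base(self):
        assert daily_gdd(-5.0, -10.0) == 0.0

    def test_upper_clip(self):
        assert daily_gdd(35.0, 10.0) == pytest.approx((29.44 + 10) / 2)

    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            daily_gdd(5.0, 10.0)


class TestAnnualGdd:
    def test_constant_year(self):
        tx, tn, _ = constant_year(20, 10)
        assert annual_gdd(tx, tn) == pytest.approx(15.0 * 365)

    def test_all_subzero(self):
        tx, tn, _ = constant_year(-2, -8)
        assert annual_gdd(tx, tn) == 0.0

    def test_single_warm_day(self):
        tx, tn, _ = constant_year(-2, -8)
        tx[200], tn[200] = 20.0, 10.0
        assert annual_gdd(tx, tn) == pytest.approx(15.0)

    def test_requires_full_year(self):
        with pytest.raises(ValueError):
            annual_gdd(np.zeros(200), np.zeros(200))


class TestSeasonLength:
    def test_no_frost(self):
        tn = np.full(DAYS_PER_YEAR, 5.0)
        assert frost_free_season_length(tn) == 365

    def test_all_frost(self):
        tn = np.full(DAYS_PER_YEAR, 0.0)  # tmin == 0 is frost
        assert frost_free_season_length(tn) == 0

    def test_single_frost_day(self):
        tn = np.full(DAYS_PER_YEAR, 5.0)
        tn[99] = -1.0  # day 100
        assert frost_free_season_length(tn) == 265


class TestHourlyDisaggregation:
    def test_zero_amplitude(self):
        assert np.all(disaggregate_hourly(10.0, 10.0) == 10.0)

    def test_extrema_hours(self):
        hours = disaggregate_hourly(30.0, 10.0)
        assert hours[15] == pytest.approx(30.0)
        assert hours[3] == pytest.approx(10.0)

    def test_mean_conservation_exact(self):
        hours = disaggregate_hourly(30.0, 10.0)
        assert hours.mean() == pytest.approx(20.0, abs=1e-9)

    @given(
        tmin=st.floats(-40, 40),
        spread=st.floats(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_mean(self, tmin, spread):
        tmax = tmin + spread
        hours = disaggregate_hourly(tmax, tmin)
        assert hours.min() >= tmin - 1e-9
        assert hours.max() <= tmax + 1e-9
        assert hours.mean() == pytest.approx((tmax + tmin) / 2, abs=1e-9)


class TestHeatDegreeHours:
    def test_constant_exceedance(self):
        assert heat_degree_hours_days(np.array([33.0]), np.array([33.0])) == 24.0

    def test_below_threshold(self):
        assert heat_degree_hours_days(np.array([30.0]), np.array([30.0])) == 0.0

    def test_matches_brute_force_single_day(self):
        expected = sum(max(0.0, t - 32.0) for t in brute_force_hourly(34.0, 30.0))
        got = heat_degree_hours_days(np.array([34.0]), np.array([30.0]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_season_only(self):
        # hot days outside JAS contribute nothing
        tx = np.full(DAYS_PER_YEAR, 40.0)
        tn = np.full(DAYS_PER_YEAR, 35.0)
        jas = SEASON_SLICES["JAS"]
        expected = heat_degree_hours_days(tx[jas], tn[jas])
        assert heat_degree_hours(tx, tn) == pytest.approx(expected)

    def test_brute_force_oracle_100_random_days(self, rng):
        tn = rng.uniform(10, 34, 100)
        tx = tn + rng.uniform(0, 15, 100)
        expected = np.array(
            [sum(max(0.0, t - 32.0) for t in brute_force_hourly(a, b))
             for a, b in zip(tx, tn)]
        ).sum()
        assert heat_degree_hours_days(tx, tn) == pytest.approx(expected, abs=1e-9)


class TestChillHours:
    def test_full_season_in_band(self):
        tx = np.full(182, 5.0)
        assert chill_hours_days(tx, tx) == 24 * 182

    def test_above_band(self):
        tx = np.full(182, 10.0)
        assert chill_hours_days(tx, tx) == 0

    def test_inclusive_upper_bound(self):
        tx = np.full(182, 20.0)
        tx[10] = 7.22
        assert chill_hours_days(tx, tx) == 24

    def test_inclusive_lower_bound(self):
        tx = np.full(182, 20.0)
        tx[0] = 0.0
        assert chill_hours_days(tx, tx) == 24

    def test_brute_force_oracle_100_random_days(self, rng):
        tn = rng.uniform(-10, 10, 100)
        tx = tn + rng.uniform(0, 15, 100)
        expected = sum(
            sum(1 for t in brute_force_hourly(a, b) if 0.0 <= t <= 7.22)
            for a, b in zip(tx, tn)
        )
        assert chill_hours_days(tx, tn) == expected

    def test_season_assembly(self):
        n_years = 3
        tmax = np.full((n_years, DAYS_PER_YEAR), 20.0)
        tmin = tmax.copy()
        # chill only in prior-year December (year 0) and current-year Jan (year 1)
        tmax[0, MONTH_STARTS[11]:MONTH_ENDS[11]] = 5.0
        tmin[0, MONTH_STARTS[11]:MONTH_ENDS[11]] = 5.0
        tmax[1, :31] = 5.0
        tmin[1, :31] = 5.0
        assert chill_hours(tmax, tmin, 1) == 24 * (31 + 31)
        assert chill_hours(tmax, tmin, 2) == 0

    def test_first_year_rejected(self):
        tmax = np.full((2, DAYS_PER_YEAR), 5.0)
        with pytest.raises(ValueError):
            chill_hours(tmax, tmax, 0)


class TestPrecipUniformity:
    def test_uniform_months(self):
        prcp = np.zeros(DAYS_PER_YEAR)
        for m in range(12):
            prcp[MONTH_STARTS[m]] = 50.0
        assert precipitation_uniformity(prcp) == 0.0

    def test_single_wet_month(self):
        prcp = np.zeros(DAYS_PER_YEAR)
        prcp[MONTH_STARTS[5]] = 100.0
        assert precipitation_uniformity(prcp) == 100.0

    def test_ramp(self):
        prcp = np.zeros(DAYS_PER_YEAR)
        for m in range(12):
            prcp[MONTH_STARTS[m]] = 10.0 * (m + 1)
        assert precipitation_uniformity(prcp) == pytest.approx(110.0)

    def test_within_month_permutation_invariance(self, rng):
        prcp = rng.gamma(1.0, 2.0, DAYS_PER_YEAR)
        shuffled = prcp.copy()
        for m in range(12):
            seg = shuffled[MONTH_STARTS[m]:MONTH_ENDS[m]]
            rng.shuffle(seg)
        assert precipitation_uniformity(shuffled) == pytest.approx(
            precipitation_uniformity(prcp)
        )


class TestGenericVector:
    def test_constant_year(self):
        tx, tn, pr = constant_year(20, 10, prcp=2.0)
        v = generic_vector(tx, tn, pr)
        assert v.shape == (8,)
        assert np.allclose(v[:4], 15.0)
        assert np.allclose(v[4:], 2.0 * np.array([90, 91, 92, 92]))

    def test_jfm_only_rain(self):
        tx, tn, pr = constant_year(20, 10)
        pr[SEASON_SLICES["JFM"]] = 1.0
        v = generic_vector(tx, tn, pr)
        assert v[4] == pytest.approx(90.0)
        assert np.all(v[5:] == 0.0)

    def test_season_blocks_cover_year(self):
        lengths = [
            SEASON_SLICES[s].stop - SEASON_SLICES[s].start
            for s in ("JFM", "AMJ", "JAS", "OND")
        ]
        assert lengths == [90, 91, 92, 92]
        assert sum(lengths) == 365


class TestContextVector:
    def test_composition(self):
        n_years = 2
        tmax = np.full((n_years, DAYS_PER_YEAR), 20.0)
        tmin = np.full((n_years, DAYS_PER_YEAR), 10.0)
        prcp = np.full((n_years, DAYS_PER_YEAR), 2.0)
        v = context_vector(tmax, tmin, prcp, 1)
        assert v[0] == pytest.approx(15.0 * 365)  # gdd
        assert v[1] == 365  # season length
        assert v[2] == 0.0  # hdh
        assert v[3] == 0.0  # chill: 15 degC all season
        # months differ in day counts: 31*2 - 28*2 = 6 mm
        assert v[4] == pytest.approx(6.0)

    def test_deterministic(self, rng):
        tmin = rng.normal(8, 5, (3, DAYS_PER_YEAR))
        tmax = tmin + rng.uniform(1, 12, (3, DAYS_PER_YEAR))
        prcp = rng.gamma(1, 2, (3, DAYS_PER_YEAR))
        a = context_vector(tmax, tmin, prcp, 1)
        b = context_vector(tmax, tmin, prcp, 1)
        assert np.array_equal(a, b)

    def test_first_year_dropped(self, rng):
        tmin = rng.normal(8, 5, (4, DAYS_PER_YEAR))
        tmax = tmin + rng.uniform(1, 12, (4, DAYS_PER_YEAR))
        prcp = rng.gamma(1, 2, (4, DAYS_PER_YEAR))
        with pytest.raises(ValueError):
            context_vector(tmax, tmin, prcp, 0)
        vs = context_vectors(tmax, tmin, prcp)
        assert vs.shape == (3, 5)
        assert np.array_equal(vs[0], context_vector(tmax, tmin, prcp, 1))


class TestMonotonicity:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_warming_never_decreases_gdd_or_hdh(self, seed):
        r = np.random.default_rng(seed)
        tmin = r.normal(10, 8, DAYS_PER_YEAR)
        tmax = tmin + r.uniform(0, 15, DAYS_PER_YEAR)
        assert annual_gdd(tmax + 1, tmin + 1) >= annual_gdd(tmax, tmin)
        assert heat_degree_hours(tmax + 1, tmin + 1) >= heat_degree_hours(tmax, tmin)

    def test_gdd_invariant_to_day_permutation(self, rng):
        tmin = rng.normal(10, 8, DAYS_PER_YEAR)
        tmax = tmin + rng.uniform(0, 15, DAYS_PER_YEAR)
        perm = rng.permutation(DAYS_PER_YEAR)
        assert annual_gdd(tmax[perm], tmin[perm]) == pytest.approx(
            annual_gdd(tmax, tmin)
        )
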