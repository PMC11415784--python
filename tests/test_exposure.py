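"""Thresholds, extreme-day counting, heat index, and ensemble means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tempmort.exposure import (
    ExposureError,
    add_exposure_lags,
    compute_thresholds,
    count_extreme_days,
    gcm_ensemble_exposure,
    heat_index,
    aggregate_centroids,
)


def _daily(temps, county=0, start="1990-01-01"):
    dates = pd.date_range(start, periods=len(temps), freq="D")
    return pd.DataFrame({"county_id": county, "date": dates, "temp_C": np.asarray(temps, float)})


def sort_percentile(values, q):
    """Independent sort-and-interpolate percentile oracle (linear rule)."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestThresholds:
    def test_uniform_sample_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 40, 1000)
        df = _daily(vals)
        thr = compute_thresholds(df, (1990, 1993))
        assert thr["hot_threshold_C"].iloc[0] == pytest.approx(sort_percentile(vals, 97.5), abs=1e-9)
        assert thr["cold_threshold_C"].iloc[0] == pytest.approx(sort_percentile(vals, 2.5), abs=1e-9)
        # roughly 39 and 1 for uniform(0, 40)
        assert thr["hot_threshold_C"].iloc[0] == pytest.approx(39.0, abs=0.5)
        assert thr["cold_threshold_C"].iloc[0] == pytest.approx(1.0, abs=0.5)

    def test_constant_series_rejected(self):
        df = _daily(np.full(400, 20.0))
        with pytest.raises(ExposureError, match="degenerate"):
            compute_thresholds(df, (1990, 1991))

    def test_percentile_pair_monotonicity(self):
        rng = np.random.default_rng(3)
        df = _daily(rng.normal(15, 8, 1200))
        base = compute_thresholds(df, (1990, 1993))
        strict = compute_thresholds(df, (1990, 1993), (99.0, 1.0))
        assert strict["hot_threshold_C"].iloc[0] >= base["hot_threshold_C"].iloc[0]
        assert strict["cold_threshold_C"].iloc[0] <= base["cold_threshold_C"].iloc[0]

    def test_day_floor_enforced(self):
        df = _daily(np.arange(50, dtype=float))
        with pytest.raises(ExposureError, match="fewer than"):
            compute_thresholds(df, (1990, 1990))

    def test_nonfinite_rejected(self):
        vals = np.arange(400, dtype=float)
        vals[5] = np.nan
        with pytest.raises(ExposureError, match="non-finite"):
            compute_thresholds(_daily(vals), (1990, 1991))


class TestCounting:
    def _thr(self, hot, cold):
        t = pd.DataFrame({"county_id": [0], "hot_threshold_C": [hot], "cold_threshold_C": [cold]})
        return t

    def test_interior_temperatures_count_zero(self):
        df = _daily(np.full(365, 15.0))
        panel = count_extreme_days(df, self._thr(30.0, 0.0))
        assert (panel["n_hot_days"] == 0).all()
        assert (panel["n_cold_days"] == 0).all()

    def test_hand_built_month(self):
        temps = np.full(31, 20.0)
        temps[[3, 10, 11, 25]] = 35.0  # 4 hot days
        temps[0] = -5.0  # 1 cold day
        df = _daily(temps, start="1990-01-01")
        panel = count_extreme_days(df, self._thr(30.0, 0.0))
        assert panel.loc[0, "n_hot_days"] == 4
        assert panel.loc[0, "n_cold_days"] == 1

    def test_threshold_equality_not_counted(self):
        temps = np.full(31, 20.0)
        temps[5] = 30.0  # exactly at hot threshold
        temps[6] = 0.0   # exactly at cold threshold
        panel = count_extreme_days(_daily(temps), self._thr(30.0, 0.0))
        assert panel.loc[0, "n_hot_days"] == 0
        assert panel.loc[0, "n_cold_days"] == 0

    def test_period_outside_series_rejected(self):
        df = _daily(np.arange(365, dtype=float))
        with pytest.raises(ExposureError, match="outside"):
            count_extreme_days(df, self._thr(300.0, -1.0), period=(1989, 1990))

    def test_missing_threshold_county_rejected(self):
        df = _daily(np.arange(365, dtype=float), county=7)
        with pytest.raises(ExposureError, match="missing"):
            count_extreme_days(df, self._thr(300.0, -1.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_counting_conservation_over_year(self, seed):
        """Sum of monthly counts equals a whole-year flag count."""
        rng = np.random.default_rng(seed)
        temps = rng.normal(12, 9, 365)
        df = _daily(temps)
        thr = self._thr(25.0, -3.0)
        panel = count_extreme_days(df, thr)
        assert panel["n_hot_days"].sum() == int((temps > 25.0).sum())
        assert panel["n_cold_days"].sum() == int((temps < -3.0).sum())
        assert ((panel["n_hot_days"] >= 0) & (panel["n_cold_days"] >= 0)).all()

    def test_warming_shift_monotonicity(self):
        rng = np.random.default_rng(11)
        temps = rng.normal(12, 9, 730)
        thr = self._thr(25.0, -3.0)
        a = count_extreme_days(_daily(temps), thr)
        b = count_extreme_days(_daily(temps + 2.0), thr)
        assert (b["n_hot_days"] >= a["n_hot_days"]).all()
        assert (b["n_cold_days"] <= a["n_cold_days"]).all()

    def test_hot_and_cold_never_share_a_day(self):
        # strict inequalities against ordered thresholds make overlap impossible;
        # verify counts are bounded by days in month
        rng = np.random.default_rng(2)
        temps = rng.normal(10, 15, 365)
        panel = count_extreme_days(_daily(temps), self._thr(20.0, 0.0))
        dim = pd.Series(pd.date_range("1990-01-01", periods=365, freq="D")).dt.daysinmonth
        days_per_month = dim.groupby(pd.date_range("1990-01-01", periods=365, freq="D").month).first()
        total = panel["n_hot_days"] + panel["n_cold_days"]
        assert (total.to_numpy() <= days_per_month.loc[panel["month"]].to_numpy()).all()


class TestLags:
    def test_lag_alignment(self):
        panel = pd.DataFrame(
            {
                "county_id": [0, 0, 0, 1, 1, 1],
                "year": 2000,
                "month": [1, 2, 3, 1, 2, 3],
                "n_hot_days": [1, 2, 3, 4, 5, 6],
                "n_cold_days": [6, 5, 4, 3, 2, 1],
            }
        )
        out = add_exposure_lags(panel)
        assert np.isnan(out.loc[0, "n_hot_days_lag1"])
        assert out.loc[1, "n_hot_days_lag1"] == 1
        assert out.loc[2, "n_cold_days_lag1"] == 5
        assert np.isnan(out.loc[3, "n_hot_days_lag1"])  # new county restarts


class TestHeatIndex:
    @staticmethod
    def rothfusz_reference(T_f, rh):
        """Independent transliteration of the published NWS regression."""
        hi = (
            -42.379 + 2.04901523 * T_f + 10.14333127 * rh - 0.22475541 * T_f * rh
            - 0.00683783 * T_f**2 - 0.05481717 * rh**2 + 0.00122874 * T_f**2 * rh
            + 0.00085282 * T_f * rh**2 - 0.00000199 * T_f**2 * rh**2
        )
        if rh < 13 and 80 <= T_f <= 112:
            hi -= ((13 - rh) / 4) * ((17 - abs(T_f - 95.0)) / 17) ** 0.5
        elif rh > 85 and 80 <= T_f <= 87:
            hi += ((rh - 85) / 10) * ((87 - T_f) / 5)
        return hi

    def test_low_temperature_fallback_near_air_temperature(self):
        # 26 °C (≈79 °F) is below the regression regime
        assert abs(heat_index(26.0, 50.0) - 26.0) < 1.0

    def test_reference_regression_match(self):
        # 32.2 °C = 90 °F at 70% RH; published chart value is 105 °F
        ours_F = heat_index(32.2, 70.0) * 9 / 5 + 32
        ref = self.rothfusz_reference(32.2 * 9 / 5 + 32, 70.0)
        assert abs(ours_F - ref) < 1e-6
        assert abs(ours_F - 105.0) < 1.5

    def test_reference_match_on_grid(self):
        for T_c in [28.0, 31.0, 34.0, 38.0, 42.0]:
            for rh in [5.0, 40.0, 70.0, 95.0]:
                T_f = T_c * 9 / 5 + 32
                simple = 0.5 * (T_f + 61.0 + (T_f - 68.0) * 1.2 + rh * 0.094)
                if (simple + T_f) / 2 < 80:
                    continue
                ours_F = heat_index(T_c, rh) * 9 / 5 + 32
                assert abs(ours_F - self.rothfusz_reference(T_f, rh)) < 1e-6

    def test_zero_humidity_edge_finite(self):
        v = heat_index(35.0, 0.0)
        assert np.isfinite(v)

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ExposureError):
            heat_index(30.0, 120.0)

    def test_monotone_in_temperature_at_fixed_rh(self):
        T = np.linspace(28, 43, 40)
        hi = heat_index(T, np.full_like(T, 60.0))
        assert (np.diff(hi) > 0).all()


class TestEnsemble:
    def _panel(self, hot_july):
        return pd.DataFrame(
            {
                "county_id": [0, 0],
                "year": [2050, 2051],
                "month": [7, 7],
                "n_hot_days": hot_july,
                "n_cold_days": [0, 0],
            }
        )

    def test_identical_panels_mean_is_panel(self):
        p = self._panel([10, 10])
        clim, ens = gcm_ensemble_exposure({"a": p, "b": p, "c": p})
        assert ens.loc[0, "n_hot_days"] == 10

    def test_two_gcm_arithmetic_mean(self):
        clim, ens = gcm_ensemble_exposure({"a": self._panel([10, 10]), "b": self._panel([20, 20])})
        assert ens.loc[0, "n_hot_days"] == 15

    def test_vectorized_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        panels = {}
        for g in range(20):
            df = pd.MultiIndex.from_product(
                [range(6), [2050, 2051], range(1, 13)], names=["county_id", "year", "month"]
            ).to_frame(index=False)
            df["n_hot_days"] = rng.integers(0, 10, len(df))
            df["n_cold_days"] = rng.integers(0, 6, len(df))
            panels[f"g{g:02d}"] = df
        clim, ens = gcm_ensemble_exposure(panels)
        # brute-force loop over counties, months, GCMs
        for c in range(6):
            for m in range(1, 13):
                vals = []
                for g, df in panels.items():
                    sub = df[(df.county_id == c) & (df.month == m)]
                    vals.append(sub["n_hot_days"].mean())
                expected = sum(vals) / len(vals)
                got = ens[(ens.county_id == c) & (ens.month == m)]["n_hot_days"].iloc[0]
                assert got == pytest.approx(expected, rel=1e-12)

    def test_mismatched_counties_rejected(self):
        a = self._panel([10, 10])
        b = self._panel([10, 10]).assign(county_id=5)
        with pytest.raises(ExposureError, match="mismatched"):
            gcm_ensemble_exposure({"a": a, "b": b})


def test_centroid_aggregation_mean():
    df = pd.DataFrame(
        {
            "county_id": [0, 0, 0, 1],
            "date": pd.to_datetime(["2000-01-01"] * 3 + ["2000-01-01"]),
            "temp_C": [10.0, 12.0, 14.0, 5.0],
        }
    )
    out = aggregate_centroids(df)
    assert out.loc[out.county_id == 0, "temp_C"].iloc[0] == pytest.approx(12.0)
    assert out.loc[out.county_id == 1, "temp_C"].iloc[0] == pytest.approx(5.0)
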