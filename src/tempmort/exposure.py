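"""County extreme-temperature thresholds and monthly extreme-day panels.

An extreme heat (cold) day is a day whose county daily-mean temperature
lies strictly above (below) a high (low) percentile — default 97.5th /
2.5th — of that county's baseline-period daily means. Monthly counts of
such days are the exposure variables of the mortality model.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExposureError",
    "compute_thresholds",
    "count_extreme_days",
    "add_exposure_lags",
    "heat_index",
    "gcm_ensemble_exposure",
    "aggregate_centroids",
]

DEFAULT_PERCENTILES = (97.5, 2.5)


class ExposureError(ValueError):
    """Invalid input to an exposure operation."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ExposureError(f"{what}: missing columns {missing}")


def compute_thresholds(
    daily_temps: pd.DataFrame,
    baseline_range: tuple[int, int],
    percentile_pair: tuple[float, float] = DEFAULT_PERCENTILES,
    min_days: int = 100,
) -> pd.DataFrame:
    """Empirical per-county extreme-temperature thresholds.

    Parameters
    ----------
    daily_temps
        Columns ``county_id``, ``date`` (datetime-like), ``temp_C``.
    baseline_range
        Inclusive year range pooled to form the reference distribution.
    percentile_pair
        ``(hot, cold)`` percentiles; linear interpolation between order
        statistics.
    min_days
        Minimum baseline days per county.

    Returns
    -------
    DataFrame with ``county_id``, ``hot_threshold_C``, ``cold_threshold_C``
    and attrs ``percentile_pair``, ``baseline_range``.
    """
    _require_columns(daily_temps, ["county_id", "date", "temp_C"], "compute_thresholds")
    hot_p, cold_p = percentile_pair
    if not 0 < cold_p < hot_p < 100:
        raise ExposureError(f"percentile pair must satisfy 0 < cold < hot < 100: {percentile_pair}")
    years = pd.DatetimeIndex(daily_temps["date"]).year
    base = daily_temps.loc[(years >= baseline_range[0]) & (years <= baseline_range[1])]
    if base.empty:
        raise ExposureError(f"no baseline days in year range {baseline_range}")
    if not np.isfinite(base["temp_C"]).all():
        bad = base.loc[~np.isfinite(base["temp_C"]), "county_id"].unique()
        raise ExposureError(f"non-finite temperatures for counties {sorted(bad)[:10]}")
    n_days = base.groupby("county_id")["temp_C"].size()
    short = n_days[n_days < min_days]
    if len(short):
        raise ExposureError(
            f"counties with fewer than {min_days} baseline days: {sorted(short.index)[:20]}"
        )
    g = base.groupby("county_id")["temp_C"]
    hot = g.quantile(hot_p / 100.0)
    cold = g.quantile(cold_p / 100.0)
    out = pd.DataFrame(
        {"county_id": hot.index, "hot_threshold_C": hot.values, "cold_threshold_C": cold.values}
    ).reset_index(drop=True)
    degenerate = out.loc[out["cold_threshold_C"] >= out["hot_threshold_C"], "county_id"]
    if len(degenerate):
        raise ExposureError(
            "degenerate thresholds (cold >= hot; e.g. constant temperature series) "
            f"for counties {sorted(degenerate)[:20]}"
        )
    out.attrs["percentile_pair"] = tuple(percentile_pair)
    out.attrs["baseline_range"] = tuple(baseline_range)
    return out


def count_extreme_days(
    daily_temps: pd.DataFrame,
    thresholds: pd.DataFrame,
    period: tuple[int, int] | None = None,
    with_lags: bool = False,
    provenance: str = "observed",
) -> pd.DataFrame:
    """Monthly counts of extreme heat/cold days per county.

    A day counts as hot only if ``temp_C`` is strictly above the hot
    threshold, cold only if strictly below the cold threshold, so a
    single day can never be both and ties are uncounted.
    """
    _require_columns(daily_temps, ["county_id", "date", "temp_C"], "count_extreme_days")
    _require_columns(thresholds, ["county_id", "hot_threshold_C", "cold_threshold_C"], "thresholds")
    df = daily_temps.copy()
    dates = pd.DatetimeIndex(df["date"])
    df["year"] = dates.year
    df["month"] = dates.month
    if period is not None:
        lo, hi = period
        have_lo, have_hi = int(df["year"].min()), int(df["year"].max())
        if lo < have_lo or hi > have_hi:
            raise ExposureError(
                f"requested period {period} outside series years [{have_lo}, {have_hi}]"
            )
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    missing = set(df["county_id"].unique()) - set(thresholds["county_id"])
    if missing:
        raise ExposureError(f"thresholds missing for counties {sorted(missing)[:20]}")
    df = df.merge(thresholds[["county_id", "hot_threshold_C", "cold_threshold_C"]], on="county_id")
    df["hot"] = (df["temp_C"] > df["hot_threshold_C"]).astype(np.int64)
    df["cold"] = (df["temp_C"] < df["cold_threshold_C"]).astype(np.int64)
    panel = (
        df.groupby(["county_id", "year", "month"], sort=True)[["hot", "cold"]]
        .sum()
        .reset_index()
        .rename(columns={"hot": "n_hot_days", "cold": "n_cold_days"})
    )
    panel["provenance"] = provenance
    if with_lags:
        panel = add_exposure_lags(panel)
    panel.attrs["percentile_pair"] = thresholds.attrs.get("percentile_pair")
    return panel


def add_exposure_lags(panel: pd.DataFrame) -> pd.DataFrame:
    """Append 1-month lag columns within each county (chronological order).

    The first month of each county's series has no predecessor; its lag
    is NaN and such rows are dropped at model-fitting time.
    """
    panel = panel.sort_values(["county_id", "year", "month"]).reset_index(drop=True)
    g = panel.groupby("county_id")
    panel["n_hot_days_lag1"] = g["n_hot_days"].shift(1)
    panel["n_cold_days_lag1"] = g["n_cold_days"].shift(1)
    return panel


def heat_index(temp_C, relative_humidity_pct):
    """Apparent temperature (heat index) in °C.

    The US National Weather Service regression (Rothfusz 1990) with its
    published low/high-humidity adjustment terms and the simple-formula
    fallback below the 80 °F regime. The regression is Fahrenheit-native;
    conversion is handled internally. Accepts scalars or arrays.
    """
    T = np.asarray(temp_C, dtype=float) * 9.0 / 5.0 + 32.0
    RH = np.asarray(relative_humidity_pct, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ExposureError("relative humidity must lie in [0, 100]")
    T, RH = np.broadcast_arrays(T, RH)

    simple = 0.5 * (T + 61.0 + (T - 68.0) * 1.2 + RH * 0.094)
    hi = np.where(T < 40.0, T, simple)

    full = (
        -42.379
        + 2.04901523 * T
        + 10.14333127 * RH
        - 0.22475541 * T * RH
        - 6.83783e-3 * T * T
        - 5.481717e-2 * RH * RH
        + 1.22874e-3 * T * T * RH
        + 8.5282e-4 * T * RH * RH
        - 1.99e-6 * T * T * RH * RH
    )
    low_rh = (RH < 13.0) & (T >= 80.0) & (T <= 112.0)
    adj1 = ((13.0 - RH) / 4.0) * np.sqrt(np.clip(17.0 - np.abs(T - 95.0), 0.0, None) / 17.0)
    high_rh = (RH > 85.0) & (T >= 80.0) & (T <= 87.0)
    adj2 = ((RH - 85.0) / 10.0) * ((87.0 - T) / 5.0)
    full = full - np.where(low_rh, adj1, 0.0) + np.where(high_rh, adj2, 0.0)

    # NWS rule: full regression applies once the simple estimate reaches 80 °F.
    out_F = np.where((simple + T) / 2.0 >= 80.0, full, hi)
    out_C = (out_F - 32.0) * 5.0 / 9.0
    if np.isscalar(temp_C) or np.ndim(temp_C) == 0:
        return float(out_C)
    return out_C


def gcm_ensemble_exposure(
    per_gcm_panels: Mapping[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-GCM climatological monthly means and their ensemble mean.

    For each GCM the multi-year mean count per county × calendar month is
    taken; the ensemble panel is the unweighted mean across GCMs. Both
    are returned because death projections run per GCM and average the
    resulting deaths, while the ensemble exposure panel drives the
    delta-method confidence interval.
    """
    if not per_gcm_panels:
        raise ExposureError("no GCM panels supplied")
    county_sets = {k: frozenset(v["county_id"].unique()) for k, v in per_gcm_panels.items()}
    ref = next(iter(county_sets.values()))
    bad = [k for k, s in county_sets.items() if s != ref]
    if bad:
        raise ExposureError(f"GCM panels with mismatched county sets: {bad}")
    clim: dict[str, pd.DataFrame] = {}
    for gcm, panel in per_gcm_panels.items():
        _require_columns(panel, ["county_id", "month", "n_hot_days", "n_cold_days"], f"panel {gcm}")
        clim[gcm] = (
            panel.groupby(["county_id", "month"], sort=True)[["n_hot_days", "n_cold_days"]]
            .mean()
            .reset_index()
        )
    stacked = pd.concat(clim.values(), ignore_index=True)
    ensemble = (
        stacked.groupby(["county_id", "month"], sort=True)[["n_hot_days", "n_cold_days"]]
        .mean()
        .reset_index()
    )
    return clim, ensemble


def aggregate_centroids(centroid_temps: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-centroid daily series to county means.

    Hook for gridded products: the county daily mean is the unweighted
    mean over the grid centroids falling in the county. Expects columns
    ``county_id``, ``date``, ``temp_C`` (one row per centroid-day).
    """
    _require_columns(centroid_temps, ["county_id", "date", "temp_C"], "aggregate_centroids")
    return (
        centroid_temps.groupby(["county_id", "date"], sort=True)["temp_C"]
        .mean()
        .reset_index()
    )
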