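"""Mid-century excess-death projection under paired emissions/population
scenarios.

The current-period fit is frozen: coefficients, county and calendar-month
fixed effects, and covariate contributions stay at their estimated
values; only extreme-day counts and population are replaced by projected
values. Each GCM in the ensemble is projected separately and the
ensemble mean of the resulting deaths is reported; the confidence
interval reflects coefficient uncertainty only (evaluated at the
ensemble-mean exposure), with GCM spread reported as the per-model
min/max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import (
    AttributionError,
    COMPONENTS,
    DeltaEstimate,
    ExcessDeathEstimate,
    excess_from_arrays,
    per_capita,
    percent_change,
)
from .model import PPMLFit

__all__ = [
    "ProjectionError",
    "ScenarioProjection",
    "SCENARIOS",
    "project_excess",
    "sensitivity_suite",
]

# Valid emissions × demographic pairings (IPCC AR6 convention).
SCENARIOS = {
    "ssp2-4.5": {"rcp": "rcp45", "ssp": "ssp2"},
    "ssp5-8.5": {"rcp": "rcp85", "ssp": "ssp5"},
}


class ProjectionError(ValueError):
    pass


@dataclass
class ScenarioProjection:
    """Projection results for one scenario and one stratum fit."""

    scenario: str
    scope: str
    per_gcm: pd.DataFrame  # gcm × component excess deaths
    estimates: dict[str, ExcessDeathEstimate]
    population: float
    pct_change: dict[str, DeltaEstimate] = field(default_factory=dict)
    pct_change_per_1m: dict[str, DeltaEstimate] = field(default_factory=dict)

    def ensemble_mean(self, component: str) -> float:
        return self.estimates[component].value


def _eta_base(fit: PPMLFit) -> pd.DataFrame:
    """Exposure-free linear predictor averaged over current-period years.

    Removing the exposure contribution from η̂ leaves county FE +
    calendar-month FE + year FE + covariate terms; averaging that over
    the (balanced) current-period years per county × calendar month
    freezes fixed effects and covariates at their current-period values
    with the year effect at its period mean.
    """
    exp_terms = fit.spec.heat_terms() + fit.spec.cold_terms()
    contrib = np.zeros(fit.n_obs)
    for t in exp_terms:
        contrib += float(fit.params[t]) * fit.panel[t].to_numpy(dtype=float)
    df = fit.panel[["county_id", "year", "month"]].copy()
    # offset subtraction puts count-mode fits on the same per-100k rate scale
    df["eta0"] = fit.eta - fit.offset - contrib
    return df.groupby(["county_id", "month"], sort=True)["eta0"].mean().reset_index()


def _derive_lag_columns(panel: pd.DataFrame, per_year: bool) -> pd.DataFrame:
    """Lagged exposure for projection panels that lack it.

    Climatological (county × calendar month) panels treat the mean year
    as stationary: the lag for month m is the mean count of month m−1,
    with January wrapping to December. Per-year panels get an ordinary
    within-county chronological shift (first months drop out).
    """
    if per_year:
        from .exposure import add_exposure_lags

        return add_exposure_lags(panel.copy()).dropna(
            subset=[c for c in ("n_hot_days_lag1", "n_cold_days_lag1")]
        )
    prev = panel.copy()
    prev["month"] = prev["month"] % 12 + 1  # month m supplies the lag of month m+1
    prev = prev.rename(
        columns={"n_hot_days": "n_hot_days_lag1", "n_cold_days": "n_cold_days_lag1"}
    )
    return panel.merge(
        prev[["county_id", "month", "n_hot_days_lag1", "n_cold_days_lag1"]],
        on=["county_id", "month"],
        how="left",
    )


def _excess_for_panel(
    fit: PPMLFit,
    panel: pd.DataFrame,
    population: pd.DataFrame,
    per_year: bool,
) -> dict:
    """Excess-death components for one projected exposure panel."""
    heat_terms = fit.spec.heat_terms()
    cold_terms = fit.spec.cold_terms()
    exp_terms = heat_terms + cold_terms
    pop = population.set_index("county_id")["population"]
    missing = set(panel["county_id"].unique()) - set(pop.index)
    if missing:
        raise ProjectionError(f"projected population missing counties {sorted(missing)[:10]}")
    missing_lags = [t for t in exp_terms if t.endswith("_lag1") and t not in panel.columns]
    if missing_lags:
        panel = _derive_lag_columns(panel, per_year)
    for t in exp_terms:
        if t not in panel.columns:
            raise ProjectionError(f"projection panel missing exposure column {t!r}")
    if per_year:
        # evaluate against the fitted county-months, adding only the
        # exposure *difference* — the identity scenario (projected
        # exposure == observed) then reproduces the fit bit-for-bit
        fitted = fit.panel[["county_id", "year", "month"] + exp_terms].rename(
            columns={t: f"{t}__fitted" for t in exp_terms}
        )
        fitted["eta_rate"] = fit.eta - fit.offset
        df = panel.merge(fitted, on=["county_id", "year", "month"], how="inner")
        if len(df) != len(panel):
            raise ProjectionError("per-year projection panel must match fitted county-months")
        eta = df["eta_rate"].to_numpy().copy()
        for t in exp_terms:
            delta = df[t].to_numpy(dtype=float) - df[f"{t}__fitted"].to_numpy(dtype=float)
            eta = eta + float(fit.params[t]) * delta
        n_years = df["year"].nunique()
    else:
        base = _eta_base(fit)
        df = panel.merge(base, on=["county_id", "month"], how="inner")
        if df["eta0"].isna().any() or len(df) < len(panel):
            raise ProjectionError("projected counties/months not covered by the fit")
        eta = df["eta0"].to_numpy().copy()
        for t in exp_terms:
            eta = eta + float(fit.params[t]) * df[t].to_numpy(dtype=float)
        n_years = 1  # climatological panel: 12 calendar months = one mean year
    pop_row = pop.loc[df["county_id"]].to_numpy(dtype=float)
    if np.any(pop_row <= 0):
        raise ProjectionError("projected population must be strictly positive")
    mu = np.exp(eta) * pop_row / 1e5
    exposures = {t: df[t].to_numpy(dtype=float) for t in exp_terms}
    betas = fit.params[exp_terms]
    out = {"n_years": n_years, "mu": mu, "exposures": exposures, "betas": betas,
           "heat_terms": heat_terms, "cold_terms": cold_terms}
    return out


def project_excess(
    fit: PPMLFit,
    per_gcm_exposure: dict[str, pd.DataFrame],
    projected_population: pd.DataFrame,
    scenario: str,
    current: dict[str, ExcessDeathEstimate] | None = None,
    scope: str | None = None,
) -> ScenarioProjection:
    """Project excess deaths for one scenario across a GCM ensemble.

    Parameters
    ----------
    fit
        Current-period PPML fit (coefficients and FE frozen).
    per_gcm_exposure
        Mapping GCM name → exposure panel. Climatological panels are
        keyed by ``county_id``/``month`` (multi-year means); panels with
        a ``year`` column are evaluated per year against the fitted
        county-months (the identity-scenario path).
    projected_population
        ``county_id``, ``population`` for this scenario's demographic
        projection.
    current
        Component → current-period estimate; when given, percent changes
        (absolute and per-capita) are attached.

    Notes
    -----
    The ensemble mean is the arithmetic mean of per-GCM excess deaths;
    the CI is a delta-method interval evaluated at the ensemble-mean
    exposure and centered on the ensemble mean.
    """
    if scenario not in SCENARIOS:
        raise ProjectionError(
            f"scenario {scenario!r} not among declared pairings {sorted(SCENARIOS)}"
        )
    if not per_gcm_exposure:
        raise ProjectionError("no GCM exposure panels supplied")
    fitted_counties = set(fit.panel["county_id"].unique())
    scope = scope or fit.label or "all"

    per_gcm_rows = []
    for gcm, panel in per_gcm_exposure.items():
        extra = set(panel["county_id"].unique()) - fitted_counties
        if extra:
            raise ProjectionError(
                f"GCM {gcm}: projected counties outside the fitted set: {sorted(extra)[:10]}"
            )
        per_year = "year" in panel.columns
        parts = _excess_for_panel(fit, panel, projected_population, per_year)
        row = {"gcm": gcm}
        for comp in COMPONENTS:
            v, _ = excess_from_arrays(
                parts["mu"], parts["exposures"], parts["betas"],
                parts["heat_terms"], parts["cold_terms"], comp,
            )
            row[comp] = v / parts["n_years"]
        per_gcm_rows.append(row)
    per_gcm = pd.DataFrame(per_gcm_rows).set_index("gcm")

    # ensemble-mean exposure panel for the delta-method CI
    first = next(iter(per_gcm_exposure.values()))
    per_year = "year" in first.columns
    keys = ["county_id", "year", "month"] if per_year else ["county_id", "month"]
    exp_terms = fit.spec.heat_terms() + fit.spec.cold_terms()
    stacked = pd.concat(per_gcm_exposure.values(), ignore_index=True)
    avail = [t for t in exp_terms if t in stacked.columns]  # lags derived downstream
    ens_panel = stacked.groupby(keys, sort=True)[avail].mean().reset_index()
    parts = _excess_for_panel(fit, ens_panel, projected_population, per_year)
    key = fit.label or f"fit@{id(fit):x}"
    pop_total = float(projected_population["population"].sum())

    estimates: dict[str, ExcessDeathEstimate] = {}
    for comp in COMPONENTS:
        v_ens, grad = excess_from_arrays(
            parts["mu"], parts["exposures"], parts["betas"],
            parts["heat_terms"], parts["cold_terms"], comp,
        )
        terms = list(parts["betas"].index)
        est = DeltaEstimate(
            float(per_gcm[comp].mean()),
            {key: grad / parts["n_years"]},
            {key: fit.cov.loc[terms, terms]},
        )
        estimates[comp] = ExcessDeathEstimate(
            scope=scope, component=comp, period=scenario, estimate=est, population=pop_total
        )

    proj = ScenarioProjection(
        scenario=scenario,
        scope=scope,
        per_gcm=per_gcm,
        estimates=estimates,
        population=pop_total,
    )
    if current is not None:
        for comp in COMPONENTS:
            cur = current[comp]
            proj.pct_change[comp] = percent_change(cur.estimate, estimates[comp].estimate)
            proj.pct_change_per_1m[comp] = percent_change(
                per_capita(cur.estimate, cur.population),
                per_capita(estimates[comp].estimate, pop_total),
            )
    return proj


def sensitivity_suite(config) -> pd.DataFrame:
    """Rerun the full pipeline under the pre-registered sensitivity
    variants and tabulate them side by side.

    Variants: primary (97.5/2.5 thresholds), alternative thresholds
    (99th/1st percentiles), 1-month lagged exposure terms, and extreme
    heat defined on the maximum daily heat index. Each row reports the
    all-adults combined excess for the current period and both
    scenarios, plus percent changes.
    """
    from dataclasses import replace

    from .pipeline import run_study

    variants = {
        "primary": {},
        "thresholds_99_1": {"percentiles": (99.0, 1.0)},
        "lagged_exposure": {"lags": 1},
        "heat_index": {"heat_index": True},
    }
    rows = []
    for name, overrides in variants.items():
        cfg = replace(config, **overrides)
        res = run_study(cfg)
        scope = "all_adults" if "all_adults" in res.current else next(iter(res.current))
        row = {"variant": name}
        row["current_combined"] = res.current[scope]["combined"].value
        for scen in cfg.scenarios:
            proj = res.projections[scen][scope]
            row[f"{scen}_combined"] = proj.estimates["combined"].value
            row[f"{scen}_pct_change"] = proj.pct_change["combined"].value
        rows.append(row)
    return pd.DataFrame(rows)
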