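"""End-to-end synthetic pipeline: simulate → exposure → smooth → fit →
attribute → project.

This is the programmatic backbone behind the `run-all` CLI command and
the sensitivity suite; each stage is an ordinary function from the
corresponding module, so any stage can be rerun in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import COMPONENTS, ExcessDeathEstimate, excess_deaths, stratified_report
from .config import PipelineConfig
from .exposure import (
    add_exposure_lags,
    compute_thresholds,
    count_extreme_days,
    gcm_ensemble_exposure,
    heat_index,
)
from .model import ModelSpec, PPMLFit, ppml_fit
from .projection import SCENARIOS, ScenarioProjection, project_excess
from .smoothing import build_grid_neighbors, smooth_panel_rates
from .synthetic import RCPS, StudyData, simulate_study

__all__ = ["StudyResult", "run_study", "build_variant_exposure"]


@dataclass
class StudyResult:
    config: PipelineConfig
    sim: StudyData
    thresholds: pd.DataFrame
    exposure: pd.DataFrame
    mortality: pd.DataFrame  # smoothed, exposure-merged modelling panel
    fits: dict[str, PPMLFit]
    current: dict[str, dict[str, ExcessDeathEstimate]]  # scope -> component -> estimate
    report: pd.DataFrame
    projections: dict[str, dict[str, ScenarioProjection]]  # scenario -> scope -> projection
    stage_log: list[dict] = field(default_factory=list)

    def projection_table(self) -> pd.DataFrame:
        rows = []
        for scen, by_scope in self.projections.items():
            for scope, proj in by_scope.items():
                for comp in COMPONENTS:
                    est = proj.estimates[comp]
                    lo, hi = est.ci
                    pm = est.per_1m
                    pm_lo, pm_hi = pm.ci()
                    row = {
                        "scenario": scen,
                        "scope": scope,
                        "component": comp,
                        "estimate": est.value,
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "per_1m": pm.value,
                        "per_1m_lo": pm_lo,
                        "per_1m_hi": pm_hi,
                        "gcm_min": float(proj.per_gcm[comp].min()),
                        "gcm_max": float(proj.per_gcm[comp].max()),
                    }
                    if comp in proj.pct_change:
                        pc = proj.pct_change[comp]
                        pclo, pchi = pc.ci()
                        row.update(pct_change=pc.value, pct_change_lo=pclo, pct_change_hi=pchi)
                        pcm = proj.pct_change_per_1m[comp]
                        pcmlo, pcmhi = pcm.ci()
                        row.update(
                            pct_change_per_1m=pcm.value,
                            pct_change_per_1m_lo=pcmlo,
                            pct_change_per_1m_hi=pcmhi,
                        )
                    rows.append(row)
        return pd.DataFrame(rows)


def build_variant_exposure(
    sim: StudyData,
    percentiles: tuple[float, float],
    use_heat_index: bool,
    lags: int,
):
    """Exposure panels for the requested threshold/heat-index variant.

    The default variant reuses the panels computed at simulation time;
    others are recounted from the stored daily series. The heat-index
    variant defines hot days on the daily-maximum apparent temperature
    scale (thresholds recomputed from the same baseline years, same
    percentile), while cold days remain on the daily-mean scale.
    """
    cfg = sim.config
    default = tuple(percentiles) == (97.5, 2.5) and not use_heat_index
    if default:
        thresholds = sim.thresholds
        current = sim.exposure
        per_gcm = sim.projected_exposure
    else:
        obs = sim.temperatures.observed
        thresholds = compute_thresholds(obs, cfg.baseline_years, percentiles)
        current = count_extreme_days(obs, thresholds, period=cfg.current_years)
        per_gcm = {
            rcp: {
                gcm: count_extreme_days(
                    sim.temperatures.gcm_series(rcp, gcm), thresholds, provenance=f"{gcm}+{rcp}"
                )
                for gcm in sim.temperatures.gcm_shifts[rcp].index
            }
            for rcp in RCPS
        }
        if use_heat_index:
            hi_obs = obs[["county_id", "date"]].copy()
            hi_obs["temp_C"] = heat_index(obs["temp_max_C"].to_numpy(), obs["rh_pct"].to_numpy())
            hi_thr = compute_thresholds(hi_obs, cfg.baseline_years, percentiles)
            hot_cur = count_extreme_days(hi_obs, hi_thr, period=cfg.current_years)
            current = current.drop(columns="n_hot_days").merge(
                hot_cur[["county_id", "year", "month", "n_hot_days"]],
                on=["county_id", "year", "month"],
            )
            for rcp in RCPS:
                for gcm in list(per_gcm[rcp]):
                    series = sim.temperatures.gcm_series(rcp, gcm)
                    hi_ser = series[["county_id", "date"]].copy()
                    hi_ser["temp_C"] = heat_index(
                        series["temp_max_C"].to_numpy(), series["rh_pct"].to_numpy()
                    )
                    hot = count_extreme_days(hi_ser, hi_thr)
                    per_gcm[rcp][gcm] = per_gcm[rcp][gcm].drop(columns="n_hot_days").merge(
                        hot[["county_id", "year", "month", "n_hot_days"]],
                        on=["county_id", "year", "month"],
                    )
    if lags:
        current = add_exposure_lags(current.copy())
    return thresholds, current, per_gcm


def run_study(config: PipelineConfig, include_projection: bool = True) -> StudyResult:
    """Run the full pipeline on a synthetic study. Deterministic under
    ``config.synthetic.seed``."""
    config.validate()
    log: list[dict] = []
    sim = simulate_study(config.synthetic, include_projection=include_projection)
    log.append({"stage": "simulate", "rows": len(sim.mortality)})

    thresholds, exposure, per_gcm = build_variant_exposure(
        sim, config.percentiles, config.heat_index, config.lags
    )
    log.append({"stage": "exposure", "rows": len(exposure)})

    # merge (possibly variant/lagged) exposure into the mortality panel
    exp_cols = [c for c in exposure.columns if c.startswith("n_hot") or c.startswith("n_cold")]
    panel = sim.mortality.drop(columns=["n_hot_days", "n_cold_days"]).merge(
        exposure[["county_id", "year", "month"] + exp_cols],
        on=["county_id", "year", "month"],
        how="left",
    )

    neighbors = build_grid_neighbors(config.synthetic.grid_shape)
    smoothed_parts = []
    for stratum, grp in panel.groupby("stratum", sort=True):
        smoothed_parts.append(
            smooth_panel_rates(
                grp,
                neighbors,
                granularity=config.smoothing_granularity,
                enabled=config.smoothing,
            )
        )
    panel = pd.concat(smoothed_parts, ignore_index=True)
    panel = panel.sort_values(["stratum", "county_id", "year", "month"]).reset_index(drop=True)
    log.append({"stage": "smooth", "rows": len(panel)})

    covariates = tuple(
        (f"cov_{k}", 4) for k in range(config.synthetic.n_covariates)
    )
    spec_kwargs = dict(
        lags=config.lags,
        covariates=covariates,
        outcome_mode=config.outcome_mode,
        outcome_col="rate_smoothed" if config.outcome_mode == "rate" else "rate",
    )
    fits: dict[str, PPMLFit] = {}
    for stratum, grp in panel.groupby("stratum", sort=True):
        spec = ModelSpec(**spec_kwargs)
        fits[stratum] = ppml_fit(grp.reset_index(drop=True), spec, label=str(stratum))
    log.append({"stage": "fit", "rows": sum(f.n_obs for f in fits.values())})

    combine = {"all_adults": sorted(fits)} if len(fits) > 1 else {}
    report = stratified_report(fits, combine=combine)
    current: dict[str, dict[str, ExcessDeathEstimate]] = {}
    for scope, fit in fits.items():
        current[scope] = {c: excess_deaths(fit, component=c, scope=scope) for c in COMPONENTS}
    if combine:
        current["all_adults"] = {}
        for comp in COMPONENTS:
            members = [current[m][comp] for m in combine["all_adults"]]
            total = members[0].estimate
            pop = members[0].population
            for m in members[1:]:
                total = total + m.estimate
                pop += m.population
            current["all_adults"][comp] = ExcessDeathEstimate(
                "all_adults", comp, "current", total, pop
            )
    log.append({"stage": "attribute", "rows": len(report)})

    projections: dict[str, dict[str, ScenarioProjection]] = {}
    if include_projection:
        for scen in config.scenarios:
            rcp = SCENARIOS[scen]["rcp"]
            ssp = SCENARIOS[scen]["ssp"]
            gcm_clim, _ = gcm_ensemble_exposure(per_gcm[rcp])
            projections[scen] = {}
            for scope, fit in fits.items():
                pop_s = sim.projected_populations.query(
                    "ssp == @ssp and stratum == @scope"
                )[["county_id", "population"]]
                projections[scen][scope] = project_excess(
                    fit,
                    gcm_clim,
                    pop_s,
                    scen,
                    current=current[scope],
                    scope=scope,
                )
            if combine:
                projections[scen]["all_adults"] = _combine_projections(
                    scen,
                    [projections[scen][m] for m in combine["all_adults"]],
                    current["all_adults"],
                )
        log.append(
            {"stage": "project", "rows": sum(len(p) for p in projections.values())}
        )

    return StudyResult(
        config=config,
        sim=sim,
        thresholds=thresholds,
        exposure=exposure,
        mortality=panel,
        fits=fits,
        current=current,
        report=report,
        projections=projections,
        stage_log=log,
    )


def _combine_projections(
    scenario: str,
    parts: list[ScenarioProjection],
    current: dict[str, ExcessDeathEstimate],
) -> ScenarioProjection:
    """Sum independent stratum projections into an aggregate scope."""
    from .attribution import per_capita, percent_change

    per_gcm = sum(p.per_gcm for p in parts)
    pop = sum(p.population for p in parts)
    estimates = {}
    for comp in COMPONENTS:
        total = parts[0].estimates[comp].estimate
        for p in parts[1:]:
            total = total + p.estimates[comp].estimate
        estimates[comp] = ExcessDeathEstimate("all_adults", comp, scenario, total, pop)
    proj = ScenarioProjection(
        scenario=scenario,
        scope="all_adults",
        per_gcm=per_gcm,
        estimates=estimates,
        population=pop,
    )
    for comp in COMPONENTS:
        cur = current[comp]
        proj.pct_change[comp] = percent_change(cur.estimate, estimates[comp].estimate)
        proj.pct_change_per_1m[comp] = percent_change(
            per_capita(cur.estimate, cur.population),
            per_capita(estimates[comp].estimate, pop),
        )
    return proj
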