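"""Synthetic temperature–mortality study generator with known ground truth.

Emulates the statistical structure of a national county-level analysis:
seasonal county climatologies with AR(1) daily noise, county-specific
extreme-day thresholds derived from a baseline period, Poisson death
counts driven by county/month/year fixed effects plus planted log-linear
extreme-day effects, a pseudo-GCM projection ensemble (constant per-GCM
warming offsets), and stratified population growth under two SSP-like
scenarios. Every downstream stage has a parameter-recovery target
because the generating parameters are returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import ConfigError, StratumSpec, SyntheticConfig
from .exposure import compute_thresholds, count_extreme_days

__all__ = [
    "TemperatureSim",
    "SyntheticTruth",
    "StudyData",
    "simulate_temperatures",
    "simulate_study",
    "RCPS",
]

RCPS = ("rcp45", "rcp85")

# Count overflow guard: expected deaths per county-month above this abort
# the simulation rather than silently saturating the Poisson sampler.
MAX_EXPECTED_COUNT = 1e8


@dataclass
class TemperatureSim:
    """Daily temperature series for one synthetic study.

    ``observed`` covers the baseline + current periods. The projection
    period is stored once as ``projection_base`` (climatology + one
    weather realization); each pseudo-GCM's series is that base plus a
    constant warming offset, materialized on demand by
    :meth:`gcm_series` to keep 20-model ensembles cheap.
    """

    observed: pd.DataFrame
    projection_base: pd.DataFrame
    gcm_shifts: dict[str, pd.Series]  # rcp -> Series indexed by gcm name
    county_params: pd.DataFrame

    def gcm_series(self, rcp: str, gcm: str) -> pd.DataFrame:
        shift = float(self.gcm_shifts[rcp][gcm])
        out = self.projection_base.copy()
        out["temp_C"] = out["temp_C"] + shift
        if "temp_max_C" in out:
            out["temp_max_C"] = out["temp_max_C"] + shift
        return out


@dataclass
class SyntheticTruth:
    """Generating parameters and closed-form expected excess deaths."""

    strata: dict[str, StratumSpec]
    county_effects: pd.Series
    month_effects: pd.Series
    year_effects: pd.Series
    gcm_shifts: dict[str, pd.Series]
    true_eta: dict[str, np.ndarray]  # stratum -> log expected rate per panel row
    expected_excess: dict[tuple[str, str], float]  # (stratum|"all", component) -> mean annual
    exposure: pd.DataFrame


@dataclass
class StudyData:
    """Everything `simulate_study` produces."""

    config: SyntheticConfig
    temperatures: TemperatureSim
    thresholds: pd.DataFrame
    exposure: pd.DataFrame
    projected_exposure: dict[str, dict[str, pd.DataFrame]]  # rcp -> gcm -> panel
    mortality: pd.DataFrame
    populations: pd.DataFrame
    projected_populations: pd.DataFrame
    truth: SyntheticTruth


def _daily_segment(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    county_params: pd.DataFrame,
    years: list[int],
) -> pd.DataFrame:
    """One contiguous multi-year daily series for all counties."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    n_c, n_d = len(county_params), len(dates)
    a = county_params["mean_C"].to_numpy()[:, None]
    A = county_params["amplitude_C"].to_numpy()[:, None]
    phi = county_params["phase"].to_numpy()[:, None]
    clim = a + A * np.sin(2.0 * np.pi * doy[None, :] / 365.25 + phi)
    if cfg.noise_sd_C > 0:
        innov_sd = cfg.noise_sd_C * np.sqrt(1.0 - cfg.ar1_rho**2)
        eps = rng.standard_normal((n_c, n_d)) * innov_sd
        # AR(1) with a stationary draw as the initial state.
        eps[:, 0] = rng.standard_normal(n_c) * cfg.noise_sd_C
        noise = lfilter([1.0], [1.0, -cfg.ar1_rho], eps, axis=1)
    else:
        noise = np.zeros((n_c, n_d))
    temp = clim + noise
    diurnal = county_params["diurnal_half_range_C"].to_numpy()[:, None]
    rh = np.clip(
        75.0 - 1.0 * (temp - a) + rng.standard_normal((n_c, n_d)) * 8.0, 5.0, 100.0
    )
    out = pd.DataFrame(
        {
            "county_id": np.repeat(county_params["county_id"].to_numpy(), n_d),
            "date": np.tile(dates.to_numpy(), n_c),
            "temp_C": temp.ravel(),
            "temp_max_C": (temp + diurnal).ravel(),
            "rh_pct": rh.ravel(),
        }
    )
    return out


def simulate_temperatures(config: SyntheticConfig) -> TemperatureSim:
    """Simulate daily county temperatures for all three study periods.

    Per county: ``T(c,d) = a_c + A_c sin(2π·doy/365.25 + φ_c) + AR(1)``.
    The projection period gets one weather realization shared by all
    pseudo-GCMs; each GCM adds a constant offset drawn once per model
    (RCP8.5 offsets are a fixed multiple of the RCP4.5 draws).
    Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = np.arange(config.n_counties, dtype=np.int64)
    county_params = pd.DataFrame(
        {
            "county_id": ids,
            "mean_C": rng.uniform(*config.mean_temp_range_C, config.n_counties),
            "amplitude_C": rng.uniform(*config.seasonal_amplitude_range_C, config.n_counties),
            # peak near mid-July
            "phase": rng.normal(-1.9, 0.05, config.n_counties),
            "diurnal_half_range_C": rng.uniform(4.0, 7.0, config.n_counties),
        }
    )
    baseline = _daily_segment(config, rng, county_params, config.years("baseline"))
    current = _daily_segment(config, rng, county_params, config.years("current"))
    observed = pd.concat([baseline, current], ignore_index=True)
    projection_base = _daily_segment(config, rng, county_params, config.years("projection"))
    gcm_names = [f"gcm{i + 1:02d}" for i in range(config.n_gcms)]
    shifts45 = rng.normal(config.warming_shift_mean_C, config.warming_shift_sd_C, config.n_gcms)
    gcm_shifts = {
        "rcp45": pd.Series(shifts45, index=gcm_names, name="shift_C"),
        "rcp85": pd.Series(shifts45 * config.rcp85_shift_factor, index=gcm_names, name="shift_C"),
    }
    return TemperatureSim(observed, projection_base, gcm_shifts, county_params)


def _fixed_effects(cfg: SyntheticConfig, rng: np.random.Generator):
    alpha = rng.normal(0.0, cfg.county_effect_sd, cfg.n_counties)
    alpha -= alpha.mean()
    months = np.arange(1, 13)
    gamma = cfg.month_effect_amplitude * np.cos(2.0 * np.pi * (months - 1) / 12.0)
    gamma = gamma - gamma.mean() + rng.normal(0.0, 0.01, 12)
    years = np.array(cfg.years("current"))
    delta = rng.normal(0.0, cfg.year_effect_sd, len(years))
    delta -= delta.mean()
    return (
        pd.Series(alpha, index=np.arange(cfg.n_counties), name="alpha"),
        pd.Series(gamma, index=months, name="gamma"),
        pd.Series(delta, index=years, name="delta"),
    )


def _component_excess(mu: np.ndarray, H: np.ndarray, C: np.ndarray, bh: float, bc: float):
    heat = float(np.sum(mu * (1.0 - np.exp(-bh * H))))
    cold = float(np.sum(mu * (1.0 - np.exp(-bc * C))))
    return heat, cold


def simulate_study(config: SyntheticConfig, include_projection: bool = True) -> StudyData:
    """Generate a full synthetic study with ground truth.

    Deaths per stratum follow
    ``deaths ~ Poisson(pop/1e5 · exp(log base_rate + α_c + γ_m + δ_y
    + β_h·H + β_c·C))`` on the current period; covariates are smooth
    county-year series with no effect on mortality (so fitted covariate
    terms should be null). The truth object carries the closed-form
    expected excess deaths ``Σ μ(1−e^{−βH})`` per component evaluated at
    the true parameters.

    ``include_projection=False`` skips counting projection-period
    extreme days (useful in Monte-Carlo loops that only exercise the
    current-period fit); death draws are unaffected.
    """
    config.validate()
    temps = simulate_temperatures(config)
    # Independent stream for the mortality side so temperature and death
    # noise are separable but both seeded from config.seed.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    thresholds = compute_thresholds(temps.observed, config.baseline_years)
    exposure = count_extreme_days(
        temps.observed, thresholds, period=config.current_years, provenance="observed"
    )
    projected_exposure: dict[str, dict[str, pd.DataFrame]] = {}
    for rcp in RCPS if include_projection else ():
        projected_exposure[rcp] = {}
        for gcm in temps.gcm_shifts[rcp].index:
            series = temps.gcm_series(rcp, gcm)
            projected_exposure[rcp][gcm] = count_extreme_days(
                series, thresholds, provenance=f"{gcm}+{rcp}"
            )

    alpha, gamma, delta = _fixed_effects(config, rng)
    pop_total = rng.uniform(*config.pop_range, config.n_counties)
    strata = config.resolved_strata()

    # covariates: smooth county-year series, no mortality effect
    years = config.years("current")
    cov_frames = []
    for k in range(config.n_covariates):
        b0 = rng.normal(0.0, 1.0, config.n_counties)
        b1 = rng.normal(0.0, 0.1, config.n_counties)
        grid = pd.MultiIndex.from_product(
            [np.arange(config.n_counties), years], names=["county_id", "year"]
        ).to_frame(index=False)
        grid[f"cov_{k}"] = (
            b0[grid["county_id"]] + b1[grid["county_id"]] * (grid["year"] - years[0])
        )
        cov_frames.append(grid.set_index(["county_id", "year"]))
    covariates = pd.concat(cov_frames, axis=1).reset_index() if cov_frames else None

    base = exposure.sort_values(["county_id", "year", "month"]).reset_index(drop=True)
    n_years = len(years)
    panels = []
    pops = []
    true_eta: dict[str, np.ndarray] = {}
    expected_excess: dict[tuple[str, str], float] = {}
    H = base["n_hot_days"].to_numpy(dtype=float)
    C = base["n_cold_days"].to_numpy(dtype=float)
    fe = (
        alpha.loc[base["county_id"]].to_numpy()
        + gamma.loc[base["month"]].to_numpy()
        + delta.loc[base["year"]].to_numpy()
    )
    tot_heat = tot_cold = 0.0
    for s in strata:
        pop = pop_total * s.pop_share
        pop_row = pop[base["county_id"].to_numpy()]
        eta = np.log(s.base_rate) + fe + s.beta_heat * H + s.beta_cold * C
        mu = pop_row / 1e5 * np.exp(eta)
        if mu.max() > MAX_EXPECTED_COUNT:
            raise ConfigError(
                f"expected count overflow: max expected deaths {mu.max():.3g} in stratum {s.name!r}"
            )
        deaths = rng.poisson(mu).astype(np.int64)
        panel = base[["county_id", "year", "month", "n_hot_days", "n_cold_days"]].copy()
        panel.insert(0, "stratum", s.name)
        panel["population"] = pop_row
        panel["deaths"] = deaths
        panel["rate"] = deaths / pop_row * 1e5
        if covariates is not None:
            panel = panel.merge(covariates, on=["county_id", "year"], how="left")
        panels.append(panel)
        pops.append(
            pd.DataFrame(
                {"stratum": s.name, "county_id": np.arange(config.n_counties), "population": pop}
            )
        )
        true_eta[s.name] = eta
        heat, cold = _component_excess(mu, H, C, s.beta_heat, s.beta_cold)
        expected_excess[(s.name, "heat")] = heat / n_years
        expected_excess[(s.name, "cold")] = cold / n_years
        expected_excess[(s.name, "combined")] = (heat + cold) / n_years
        tot_heat += heat / n_years
        tot_cold += cold / n_years
    expected_excess[("all", "heat")] = tot_heat
    expected_excess[("all", "cold")] = tot_cold
    expected_excess[("all", "combined")] = tot_heat + tot_cold

    mortality = pd.concat(panels, ignore_index=True)
    populations = pd.concat(pops, ignore_index=True)

    proj_pops = []
    for ssp, growth in config.pop_growth.items():
        jitter = np.exp(rng.normal(0.0, config.pop_growth_jitter_sd, config.n_counties))
        for s in strata:
            factor = growth.get(s.name, 1.0)
            proj_pops.append(
                pd.DataFrame(
                    {
                        "ssp": ssp,
                        "stratum": s.name,
                        "county_id": np.arange(config.n_counties),
                        "population": pop_total * s.pop_share * factor * jitter,
                    }
                )
            )
    projected_populations = pd.concat(proj_pops, ignore_index=True)

    truth = SyntheticTruth(
        strata={s.name: s for s in strata},
        county_effects=alpha,
        month_effects=gamma,
        year_effects=delta,
        gcm_shifts=temps.gcm_shifts,
        true_eta=true_eta,
        expected_excess=expected_excess,
        exposure=base,
    )
    return StudyData(
        config=config,
        temperatures=temps,
        thresholds=thresholds,
        exposure=base,
        projected_exposure=projected_exposure,
        mortality=mortality,
        populations=populations,
        projected_populations=projected_populations,
        truth=truth,
    )
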