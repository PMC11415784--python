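"""Configuration objects for synthetic studies and the end-to-end pipeline.

The synthetic study is a deliberately small analogue of a national
county-level temperature–mortality analysis: a grid of counties, a
baseline climatology period used only for thresholds, a "current" period
on which the exposure–mortality model is fit, and a mid-century
projection period covered by an ensemble of pseudo-GCMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "StratumSpec",
    "SyntheticConfig",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


YearRange = tuple[int, int]


@dataclass(frozen=True)
class StratumSpec:
    """One population stratum fit with its own exposure–mortality model.

    ``beta_heat``/``beta_cold`` are log-linear effects per extreme day
    (e.g. ``log(1.0009)`` is a 0.09% higher monthly rate per extra hot
    day). ``base_rate`` is deaths per 100,000 person-months and
    ``pop_share`` the stratum's share of county adult population.
    """

    name: str
    beta_heat: float
    beta_cold: float
    base_rate: float
    pop_share: float

    def validate(self) -> None:
        if self.base_rate <= 0:
            raise ConfigError(f"stratum {self.name!r}: base_rate must be > 0")
        if not 0 < self.pop_share <= 1:
            raise ConfigError(f"stratum {self.name!r}: pop_share must be in (0, 1]")


# Default strata: two age groups with planted per-day effects on the scale
# reported for US adults (older: +0.09%/heat day, +0.26%/cold day;
# younger: +0.17%, +0.27%) and realistic all-cause base rates
# (older ≈4%/yr, younger ≈0.4%/yr).
DEFAULT_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("older", math.log(1.0009), math.log(1.0026), 330.0, 0.22),
    StratumSpec("younger", math.log(1.0017), math.log(1.0027), 35.0, 0.78),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study generator.

    Each synthetic county stands in for an aggregate of real counties
    (the default 100-county grid at 200k–3M adults per county carries
    roughly the person-time of the ~3100-county US study), so planted
    per-day effects of 0.1–0.3% are statistically identifiable at toy
    scale.
    """

    n_counties: int = 100
    grid_shape: tuple[int, int] = (10, 10)
    baseline_years: YearRange = (1996, 2000)
    current_years: YearRange = (2008, 2012)
    projection_years: YearRange = (2036, 2040)
    n_gcms: int = 20
    # Single-stratum override; when None the default two age strata are used.
    beta_heat: float | None = None
    beta_cold: float | None = None
    base_rate: float = 80.0
    strata: tuple[StratumSpec, ...] | None = None
    pop_range: tuple[float, float] = (200_000.0, 3_000_000.0)
    # Climatology: T(c,d) = a_c + A_c sin(2π doy/365.25 + φ_c) + AR(1) noise.
    mean_temp_range_C: tuple[float, float] = (4.0, 18.0)
    seasonal_amplitude_range_C: tuple[float, float] = (8.0, 14.0)
    noise_sd_C: float = 3.5        # stationary sd of the AR(1) residual
    ar1_rho: float = 0.7           # day-to-day persistence
    # Pseudo-GCM ensemble: constant per-GCM warming offsets.
    warming_shift_mean_C: float = 2.0
    warming_shift_sd_C: float = 0.4
    rcp85_shift_factor: float = 1.6
    # SSP population growth factors (projection vs current), per stratum.
    pop_growth: dict = field(
        default_factory=lambda: {
            "ssp2": {"older": 1.190, "younger": 0.868},
            "ssp5": {"older": 1.350, "younger": 0.985},
        }
    )
    pop_growth_jitter_sd: float = 0.10
    n_covariates: int = 2
    county_effect_sd: float = 0.15
    year_effect_sd: float = 0.03
    month_effect_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_counties <= 0:
            raise ConfigError("n_counties must be positive")
        r, c = self.grid_shape
        if r * c != self.n_counties:
            raise ConfigError(
                f"grid_shape {self.grid_shape} incompatible with n_counties={self.n_counties}"
            )
        for label, rng in [
            ("baseline_years", self.baseline_years),
            ("current_years", self.current_years),
            ("projection_years", self.projection_years),
        ]:
            if rng[1] < rng[0]:
                raise ConfigError(f"{label} is a degenerate (empty) year range: {rng}")
        if not (
            self.baseline_years[1] < self.current_years[0]
            and self.current_years[1] < self.projection_years[0]
        ):
            raise ConfigError(
                "year ranges must be ordered baseline < current < projection and non-overlapping"
            )
        if self.n_gcms < 1:
            raise ConfigError("n_gcms must be >= 1")
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be > 0")
        if self.pop_range[0] <= 0 or self.pop_range[1] < self.pop_range[0]:
            raise ConfigError("pop_range must be positive and ordered")
        if not 0 <= self.ar1_rho < 1:
            raise ConfigError("ar1_rho must lie in [0, 1)")
        if self.noise_sd_C < 0:
            raise ConfigError("noise_sd_C must be >= 0")
        for s in self.resolved_strata():
            s.validate()

    def resolved_strata(self) -> tuple[StratumSpec, ...]:
        """Strata actually simulated.

        Explicit ``strata`` wins; otherwise explicit ``beta_heat``/
        ``beta_cold`` define a single all-adults stratum; otherwise the
        default two age strata are used.
        """
        if self.strata is not None:
            return tuple(self.strata)
        if self.beta_heat is not None or self.beta_cold is not None:
            return (
                StratumSpec(
                    "adults",
                    self.beta_heat or 0.0,
                    self.beta_cold or 0.0,
                    self.base_rate,
                    1.0,
                ),
            )
        return DEFAULT_STRATA

    def years(self, which: str) -> list[int]:
        rng = getattr(self, f"{which}_years")
        return list(range(rng[0], rng[1] + 1))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (the `run-all` command)."""

    out_dir: str = "tempmort_out"
    seed: int = 0
    percentiles: tuple[float, float] = (97.5, 2.5)
    lags: int = 0
    heat_index: bool = False
    smoothing: bool = True
    smoothing_granularity: str = "pooled"  # "pooled" | "monthly"
    outcome_mode: str = "rate"  # "rate" | "count"
    scenarios: tuple[str, ...] = ("ssp2-4.5", "ssp5-8.5")
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        hot, cold = self.percentiles
        if not (0 < cold < hot < 100):
            raise ConfigError(f"percentile pair must satisfy 0 < cold < hot < 100: {self.percentiles}")
        if self.lags not in (0, 1):
            raise ConfigError("lags must be 0 or 1")
        if self.outcome_mode not in ("rate", "count"):
            raise ConfigError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.smoothing_granularity not in ("pooled", "monthly"):
            raise ConfigError(f"unknown smoothing_granularity {self.smoothing_granularity!r}")
        self.synthetic.validate()


def _to_plain(obj):
    if isinstance(obj, (SyntheticConfig, PipelineConfig, StratumSpec)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn_raw = raw.pop("synthetic", {}) or {}
    strata = syn_raw.pop("strata", None)
    if strata is not None:
        strata = tuple(StratumSpec(**s) for s in strata)
    syn_kwargs = dict(syn_raw)
    for key in ("grid_shape", "baseline_years", "current_years", "projection_years", "pop_range",
                "mean_temp_range_C", "seasonal_amplitude_range_C"):
        if key in syn_kwargs and syn_kwargs[key] is not None:
            syn_kwargs[key] = tuple(syn_kwargs[key])
    syn = SyntheticConfig(strata=strata, **syn_kwargs)
    for key in ("percentiles", "scenarios"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(synthetic=syn, **raw)
    cfg.validate()
    return cfg
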