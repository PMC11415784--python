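import numpy as np
import pandas as pd
import pytest

from tempmort.config import PipelineConfig, StratumSpec, SyntheticConfig


def tiny_synthetic_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A 3×3-county study small enough for per-test use."""
    kwargs = dict(
        n_counties=9,
        grid_shape=(3, 3),
        baseline_years=(1996, 1997),
        current_years=(2000, 2002),
        projection_years=(2005, 2006),
        n_gcms=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture
def tiny_config():
    return tiny_synthetic_config()


@pytest.fixture
def tiny_pipeline_config():
    return PipelineConfig(synthetic=tiny_synthetic_config())


@pytest.fixture(scope="session")
def default_study():
    """One full default-scale study, shared by read-only tests."""
    from tempmort.pipeline import run_study

    return run_study(PipelineConfig())


def random_small_panel(rng: np.random.Generator, n_counties=None, n_months=None):
    """A random small county×month panel with Poisson deaths, for
    comparing the absorbed-FE fit with an explicit-dummies fit."""
    n_counties = n_counties or int(rng.integers(3, 6))
    n_months = n_months or int(rng.integers(12, 25))
    years = np.repeat(np.arange(2000, 2000 + (n_months + 11) // 12), 12)[:n_months]
    months = (np.arange(n_months) % 12) + 1
    rows = []
    alpha = rng.normal(0, 0.3, n_counties)
    gamma = {m: g for m, g in zip(range(1, 13), rng.normal(0, 0.2, 12))}
    delta = {y: d for y, d in zip(np.unique(years), rng.normal(0, 0.1, len(np.unique(years))))}
    pops = rng.uniform(5e4, 5e5, n_counties)
    for c in range(n_counties):
        H = rng.poisson(1.5, n_months)
        C = rng.poisson(1.0, n_months)
        eta = np.log(60.0) + alpha[c] + np.array([gamma[m] for m in months]) + np.array(
            [delta[y] for y in years]
        ) + 0.02 * H - 0.015 * C
        mu = pops[c] / 1e5 * np.exp(eta)
        deaths = rng.poisson(mu)
        for k in range(n_months):
            rows.append(
                dict(
                    county_id=c,
                    year=int(years[k]),
                    month=int(months[k]),
                    n_hot_days=int(H[k]),
                    n_cold_days=int(C[k]),
                    population=pops[c],
                    deaths=int(deaths[k]),
                    rate=deaths[k] / pops[c] * 1e5,
                )
            )
    return pd.DataFrame(rows)


def explicit_dummy_design(panel: pd.DataFrame, exposure_cols):
    """Full dummy design (county/month/year) for the oracle fit."""
    X = panel[list(exposure_cols)].to_numpy(dtype=float)
    dummies = pd.get_dummies(
        panel[["county_id", "month", "year"]].astype(str), drop_first=False
    )
    # drop one level per extra FE set to avoid perfect collinearity
    keep = []
    seen_sets = set()
    for col in dummies.columns:
        prefix = col.split("_")[0]
        if prefix != "county" and prefix not in seen_sets:
            seen_sets.add(prefix)
            continue  # reference level
        keep.append(col)
    D = dummies[keep].to_numpy(dtype=float)
    names = list(exposure_cols) + keep
    return np.column_stack([X, D]), names


def make_true_fit(sim, stratum: str):
    """A PPMLFit carrying the *generating* parameters of a synthetic
    study (zero coefficient uncertainty), for truth-injection checks."""
    from tempmort.model import ModelSpec, PPMLFit

    panel = sim.mortality[sim.mortality["stratum"] == stratum].reset_index(drop=True)
    spec = ModelSpec()
    s = sim.truth.strata[stratum]
    terms = ["n_hot_days", "n_cold_days"]
    params = pd.Series([s.beta_heat, s.beta_cold], index=terms)
    cov = pd.DataFrame(np.zeros((2, 2)), index=terms, columns=terms)
    eta = sim.truth.true_eta[stratum]
    return PPMLFit(
        spec=spec,
        label=stratum,
        params=params,
        cov=cov,
        panel=panel,
        eta=eta,
        mu=np.exp(eta),
        y=panel["rate"].to_numpy(),
        weights=panel["population"].to_numpy(dtype=float),
        offset=np.zeros(len(panel)),
        deviance=float("nan"),
        loglik=float("nan"),
        bic=float("nan"),
        n_obs=len(panel),
        k_explicit=2,
        k_absorbed=0,
        score_norm=0.0,
        dropped=pd.DataFrame(columns=["fixed_effect", "level", "n_rows"]),
    )
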