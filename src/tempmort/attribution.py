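"""Counterfactual excess deaths attributable to extreme temperature days.

Excess deaths are the difference between expected deaths at the
observed extreme-day counts and expected deaths with those counts set
to zero, everything else (fixed effects, covariates) held at observed
values. With a log-linear model this is

    E_heat = Σ_ct μ̂_ct (1 − e^{−β̂_h H_ct})

and analogously for cold; "combined" is their sum, so heat + cold =
combined holds exactly (each component zeroes one exposure at a time
from the same joint fit).

Confidence intervals use the delta method on the exposure coefficients
with their robust covariance: estimates carry analytic gradients keyed
by fit, so sums across strata, per-capita rescalings and ratios
(percent change) propagate uncertainty exactly and additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelError, PPMLFit, Z95

__all__ = [
    "AttributionError",
    "DeltaEstimate",
    "ExcessDeathEstimate",
    "predict_expected_deaths",
    "excess_from_arrays",
    "excess_deaths",
    "excess_ci_simulation",
    "per_capita",
    "percent_change",
    "stratified_report",
    "COMPONENTS",
]

COMPONENTS = ("heat", "cold", "combined")


class AttributionError(ValueError):
    pass


@dataclass
class DeltaEstimate:
    """A scalar estimate with gradients w.r.t. one or more fits' exposure
    coefficients, enabling exact delta-method variance propagation."""

    value: float
    grads: dict[str, pd.Series] = field(default_factory=dict)
    covs: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def variance(self) -> float:
        v = 0.0
        for key, g in self.grads.items():
            V = self.covs[key].loc[g.index, g.index].to_numpy()
            v += float(g.to_numpy() @ V @ g.to_numpy())
        return v

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def ci(self, z: float = Z95) -> tuple[float, float]:
        return self.value - z * self.se, self.value + z * self.se

    def __add__(self, other: "DeltaEstimate") -> "DeltaEstimate":
        grads = {k: v.copy() for k, v in self.grads.items()}
        covs = dict(self.covs)
        for k, g in other.grads.items():
            grads[k] = grads[k].add(g, fill_value=0.0) if k in grads else g.copy()
        covs.update(other.covs)
        return DeltaEstimate(self.value + other.value, grads, covs)

    def scale(self, factor: float) -> "DeltaEstimate":
        return DeltaEstimate(
            self.value * factor,
            {k: g * factor for k, g in self.grads.items()},
            dict(self.covs),
        )


@dataclass
class ExcessDeathEstimate:
    """Mean annual excess deaths for one scope × component."""

    scope: str
    component: str
    period: str
    estimate: DeltaEstimate
    population: float  # mean annual population at risk

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def ci(self) -> tuple[float, float]:
        return self.estimate.ci()

    @property
    def per_1m(self) -> "DeltaEstimate":
        return per_capita(self.estimate, self.population)

    def row(self) -> dict:
        lo, hi = self.ci
        pm = self.per_1m
        pm_lo, pm_hi = pm.ci()
        return {
            "scope": self.scope,
            "component": self.component,
            "period": self.period,
            "estimate": self.value,
            "ci_lo": lo,
            "ci_hi": hi,
            "per_1m": pm.value,
            "per_1m_lo": pm_lo,
            "per_1m_hi": pm_hi,
        }


def _fit_key(fit: PPMLFit) -> str:
    return fit.label or f"fit@{id(fit):x}"


def expected_deaths_array(fit: PPMLFit) -> np.ndarray:
    """Expected deaths per retained county-month at the fitted values."""
    if fit.spec.outcome_mode == "rate":
        return np.exp(fit.eta) * fit.panel["population"].to_numpy() / 1e5
    return np.exp(fit.eta)


def predict_expected_deaths(fit: PPMLFit, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expected deaths μ̂ per county-month.

    With ``panel=None`` returns predictions on the fitting panel. A
    supplied panel must be a subset of the fitted county-months (no
    out-of-sample county prediction in the current period, since county
    fixed effects are only defined for fitted counties).
    """
    base = fit.panel[["county_id", "year", "month"]].copy()
    base["expected_deaths"] = expected_deaths_array(fit)
    if panel is None:
        return base
    merged = panel[["county_id", "year", "month"]].merge(
        base, on=["county_id", "year", "month"], how="left"
    )
    if merged["expected_deaths"].isna().any():
        missing = merged.loc[merged["expected_deaths"].isna(), "county_id"].unique()
        raise AttributionError(
            f"counties/months absent from fit (no out-of-sample prediction): {sorted(missing)[:10]}"
        )
    return merged


def excess_from_arrays(
    mu_deaths: np.ndarray,
    exposures: dict[str, np.ndarray],
    betas: pd.Series,
    heat_terms: list[str],
    cold_terms: list[str],
    component: str,
) -> tuple[float, pd.Series]:
    """Core counterfactual sum and its gradient w.r.t. exposure betas.

    ``s_heat = Σ_j β_j x_j`` over heat terms (lags included); the heat
    excess is ``Σ μ(1−e^{−s_heat})``. Gradients: ∂/∂β_j = Σ x_j μ for j a
    heat term, ``Σ x_j μ (1−e^{−s_heat})`` for j a cold term (μ itself
    depends on every exposure coefficient).
    """
    terms = list(betas.index)
    s = {}
    for comp, tlist in (("heat", heat_terms), ("cold", cold_terms)):
        acc = np.zeros(len(mu_deaths))
        for t in tlist:
            acc += float(betas[t]) * exposures[t]
        s[comp] = acc
    if component == "combined":
        vh, gh = excess_from_arrays(mu_deaths, exposures, betas, heat_terms, cold_terms, "heat")
        vc, gc = excess_from_arrays(mu_deaths, exposures, betas, heat_terms, cold_terms, "cold")
        return vh + vc, gh.add(gc, fill_value=0.0)
    if component not in ("heat", "cold"):
        raise AttributionError(f"component must be one of {COMPONENTS}: {component!r}")
    own = heat_terms if component == "heat" else cold_terms
    other = cold_terms if component == "heat" else heat_terms
    shrink = 1.0 - np.exp(-s[component])
    value = float(np.sum(mu_deaths * shrink))
    grad = pd.Series(0.0, index=terms)
    for t in own:
        grad[t] = float(np.sum(exposures[t] * mu_deaths))
    for t in other:
        grad[t] = float(np.sum(exposures[t] * mu_deaths * shrink))
    return value, grad


def excess_deaths(
    fit: PPMLFit,
    component: str = "combined",
    scope: str | None = None,
    period: str = "current",
    mask: np.ndarray | None = None,
) -> ExcessDeathEstimate:
    """Mean annual excess deaths for one component from a fitted model.

    The total over the fitted panel is divided by the number of distinct
    years to give a mean annual figure; the 95% CI is the delta-method
    normal interval on the exposure-coefficient block of the robust
    covariance.
    """
    mu = expected_deaths_array(fit)
    panel = fit.panel
    if mask is not None:
        mu = mu[mask]
        panel = panel.loc[mask]
    heat_terms = fit.spec.heat_terms()
    cold_terms = fit.spec.cold_terms()
    exp_terms = heat_terms + cold_terms
    exposures = {t: panel[t].to_numpy(dtype=float) for t in exp_terms}
    betas = fit.params[exp_terms]
    n_years = panel["year"].nunique()
    value, grad = excess_from_arrays(mu, exposures, betas, heat_terms, cold_terms, component)
    key = _fit_key(fit)
    # divide (not multiply by a reciprocal) so the identity-scenario
    # projection, which divides the same totals, matches bit-for-bit
    est = DeltaEstimate(
        value / n_years, {key: grad / n_years}, {key: fit.cov.loc[exp_terms, exp_terms]}
    )
    pop = float(panel.groupby(["year", "county_id"])["population"].first().sum() / n_years)
    return ExcessDeathEstimate(
        scope=scope or fit.label or "all",
        component=component,
        period=period,
        estimate=est,
        population=pop,
    )


def per_capita(estimate: DeltaEstimate, population: float) -> DeltaEstimate:
    """Rescale an excess-death estimate to deaths per 1 million persons."""
    if population <= 0:
        raise AttributionError("population must be > 0")
    return estimate.scale(1e6 / population)


def percent_change(current: DeltaEstimate, projected: DeltaEstimate) -> DeltaEstimate:
    """100·(projected − current)/current with a delta-method CI.

    Current and projected excess are functions of the same exposure
    coefficients, so the ratio's gradient uses the shared covariance:
    ∂R/∂θ = 100·(P'C − PC')/C².
    """
    C, P = current.value, projected.value
    if C <= 0:
        raise AttributionError(f"percent change undefined for non-positive current estimate {C}")
    value = 100.0 * (P - C) / C
    keys = set(current.grads) | set(projected.grads)
    grads = {}
    covs = {}
    for k in keys:
        gC = current.grads.get(k)
        gP = projected.grads.get(k)
        idx = (gC.index if gC is not None else gP.index)
        gC = gC if gC is not None else pd.Series(0.0, index=idx)
        gP = gP if gP is not None else pd.Series(0.0, index=idx)
        gP, gC = gP.align(gC, fill_value=0.0)
        grads[k] = 100.0 * (gP * C - P * gC) / (C * C)
        covs[k] = current.covs.get(k, projected.covs.get(k))
    return DeltaEstimate(value, grads, covs)


def stratified_report(
    fits: dict[str, PPMLFit],
    combine: dict[str, list[str]] | None = None,
    period: str = "current",
) -> pd.DataFrame:
    """Tidy excess-death table by scope × component.

    ``combine`` maps an aggregate scope to member scopes whose
    estimates (and gradients) are summed — e.g. all adults as the sum of
    the two age-group fits. Aggregates computed from region-restricted
    fits are intentionally not forced to sum to any national figure.
    """
    combine = combine if combine is not None else {}
    for agg, members in combine.items():
        missing = [m for m in members if m not in fits]
        if missing:
            raise AttributionError(f"aggregate {agg!r} missing member fits {missing}")
    rows = []
    per_scope: dict[str, dict[str, ExcessDeathEstimate]] = {}
    for scope, fit in fits.items():
        per_scope[scope] = {}
        for comp in COMPONENTS:
            est = excess_deaths(fit, component=comp, scope=scope, period=period)
            per_scope[scope][comp] = est
            rows.append(est.row())
    for agg, members in combine.items():
        for comp in COMPONENTS:
            parts = [per_scope[m][comp] for m in members]
            total = parts[0].estimate
            pop = parts[0].population
            for p_ in parts[1:]:
                total = total + p_.estimate
                pop += p_.population
            rows.append(
                ExcessDeathEstimate(agg, comp, period, total, pop).row()
            )
    return pd.DataFrame(rows)


def excess_ci_simulation(
    fit: PPMLFit,
    component: str = "combined",
    n_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-simulation alternative to the delta-method CI.

    Draws exposure coefficients from N(β̂, V̂) (robust covariance),
    re-evaluates the mean annual excess for each draw — expected deaths
    are re-derived from the exposure-free part of the linear predictor,
    so μ varies with each draw — and returns percentile bounds.
    """
    heat_terms = fit.spec.heat_terms()
    cold_terms = fit.spec.cold_terms()
    terms = heat_terms + cold_terms
    beta_hat = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(beta_hat, V, size=n_draws)

    panel = fit.panel
    X = panel[terms].to_numpy(dtype=float)
    pop = panel["population"].to_numpy(dtype=float)
    eta0 = (fit.eta - fit.offset) - X @ beta_hat  # exposure-free, rate scale
    n_years = panel["year"].nunique()
    own = {"heat": heat_terms, "cold": cold_terms, "combined": terms}[component]
    own_idx = [terms.index(t) for t in own]

    values = np.empty(n_draws)
    chunk = 200
    for start in range(0, n_draws, chunk):
        b = draws[start : start + chunk]  # (c, k)
        eta = eta0[None, :] + b @ X.T  # (c, n)
        mu = np.exp(eta) * (pop / 1e5)[None, :]
        if component == "combined":
            s_h = b[:, [terms.index(t) for t in heat_terms]] @ X[:, [terms.index(t) for t in heat_terms]].T
            s_c = b[:, [terms.index(t) for t in cold_terms]] @ X[:, [terms.index(t) for t in cold_terms]].T
            shrink = (1.0 - np.exp(-s_h)) + (1.0 - np.exp(-s_c))
        else:
            s = b[:, own_idx] @ X[:, own_idx].T
            shrink = 1.0 - np.exp(-s)
        values[start : start + chunk] = (mu * shrink).sum(axis=1) / n_years
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(values, alpha)), float(np.quantile(values, 1.0 - alpha))
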