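"""Poisson pseudo-maximum-likelihood estimation with absorbed fixed effects.

The exposure–mortality model is

    E[y_ct] = exp(α_c + γ_m + δ_y + β_h H_ct + β_c C_ct + f(covariates))

estimated by the Poisson score equations (pseudo-likelihood: the outcome
may be a non-integer rate, and no Poisson variance assumption is made —
inference uses a heteroskedasticity-robust sandwich). The three
high-dimensional fixed-effect sets are never materialized as dummies;
at each IRLS step the working response and regressors are residualized
against them by alternating weighted within-group demeaning, then the
coefficients are updated by weighted least squares on the demeaned
system (Frisch–Waugh–Lovell).

Two outcome modes: ``rate`` (default) models the age-adjusted monthly
rate per 100,000 with analytic weights equal to population; ``count``
models death counts with a log-population offset. Both give identical
exposure coefficients in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .splines import rcs_basis, SplineBasis

__all__ = [
    "ModelError",
    "ConvergenceError",
    "ModelSpec",
    "PPMLFit",
    "ppml_fit",
    "percent_change_per_day",
    "bic_compare",
    "Z95",
]

Z95 = 1.96  # normal quantile used for all reported 95% intervals


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelSpec:
    """What enters the fit besides the absorbed fixed effects."""

    exposure_cols: tuple[str, ...] = ("n_hot_days", "n_cold_days")
    lags: int = 0
    exposure_spec: str = "linear"  # "linear" | "spline" (BIC comparison)
    fixed_effects: tuple[str, ...] = ("county_id", "month", "year")
    covariates: tuple[tuple[str, int], ...] = ()  # (column, n_knots)
    outcome_mode: str = "rate"  # "rate" | "count"
    outcome_col: str = "rate"
    cluster: str | None = None

    def validate(self) -> None:
        if not self.exposure_cols:
            raise ModelError("exposure terms are required")
        if self.exposure_spec not in ("linear", "spline"):
            raise ModelError(f"unknown exposure_spec {self.exposure_spec!r}")
        if self.outcome_mode not in ("rate", "count"):
            raise ModelError(f"unknown outcome_mode {self.outcome_mode!r}")
        if not self.fixed_effects:
            raise ModelError("at least one fixed-effect set is required")
        if self.lags not in (0, 1):
            raise ModelError("lags must be 0 or 1")

    def term_columns(self) -> list[str]:
        cols = list(self.exposure_cols)
        if self.lags:
            cols += [f"{c}_lag1" for c in self.exposure_cols]
        return cols

    def heat_terms(self) -> list[str]:
        return [c for c in self.term_columns() if "hot" in c or "heat" in c]

    def cold_terms(self) -> list[str]:
        return [c for c in self.term_columns() if "cold" in c]


@dataclass
class PPMLFit:
    """Result of a PPML fixed-effects fit.

    ``params``/``cov`` cover the explicit (non-absorbed) terms only; the
    absorbed fixed effects survive inside ``eta`` (the full linear
    predictor per retained observation), which is what prediction and
    attribution need.
    """

    spec: ModelSpec
    label: str
    params: pd.Series
    cov: pd.DataFrame
    panel: pd.DataFrame  # retained rows: ids, exposure, population, outcome
    eta: np.ndarray
    mu: np.ndarray  # fitted outcome scale (rate or count)
    y: np.ndarray
    weights: np.ndarray
    offset: np.ndarray
    deviance: float
    loglik: float
    bic: float
    n_obs: int
    k_explicit: int
    k_absorbed: int
    score_norm: float
    dropped: pd.DataFrame
    trace: list[float] = field(default_factory=list)
    spline_bases: dict[str, SplineBasis] = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def cov_block(self, terms: Sequence[str]) -> np.ndarray:
        return self.cov.loc[list(terms), list(terms)].to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        se = self.se
        pct = 100.0 * (np.exp(self.params) - 1.0)
        lo = 100.0 * (np.exp(self.params - Z95 * se) - 1.0)
        hi = 100.0 * (np.exp(self.params + Z95 * se) - 1.0)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "robust_se": se,
                "pct_change": pct,
                "ci_lo": lo,
                "ci_hi": hi,
                "p": self.pvalues,
            }
        )


def _drop_separated(df: pd.DataFrame, y: np.ndarray, fe_cols: Sequence[str]):
    """Iteratively drop observations in FE groups whose outcome sums to zero.

    Such groups are perfectly predicted (their FE diverges to −inf) and
    carry no information about the exposure coefficients; this mirrors
    the separation handling of modern PPML software.
    """
    keep = np.ones(len(df), dtype=bool)
    log_entries = []
    changed = True
    while changed:
        changed = False
        for col in fe_cols:
            codes = df.loc[keep, col]
            sums = pd.Series(y[keep]).groupby(codes.to_numpy()).sum()
            dead = set(sums[sums <= 0].index)
            if dead:
                hit = keep & df[col].isin(dead).to_numpy()
                log_entries += [
                    {"fixed_effect": col, "level": lvl, "n_rows": int((df[col][hit] == lvl).sum())}
                    for lvl in sorted(dead)
                ]
                keep &= ~df[col].isin(dead).to_numpy()
                changed = True
    return keep, pd.DataFrame(log_entries, columns=["fixed_effect", "level", "n_rows"])


def _demean(M: np.ndarray, codes: list[np.ndarray], sizes: list[int], w: np.ndarray,
            tol: float = 1e-10, max_sweeps: int = 10_000) -> np.ndarray:
    """Residualize columns of M against all FE sets by alternating
    weighted within-group demeaning (Halperin alternating projections)."""
    M = M.copy()
    scale = np.maximum(1.0, np.abs(M).max(axis=0))
    sw = [np.bincount(c, weights=w, minlength=s) for c, s in zip(codes, sizes)]
    for _ in range(max_sweeps):
        worst = 0.0
        for c, s, denom in zip(codes, sizes, sw):
            for j in range(M.shape[1]):
                means = np.bincount(c, weights=w * M[:, j], minlength=s) / denom
                M[:, j] -= means[c]
                adj = np.abs(means).max() / scale[j]
                if adj > worst:
                    worst = adj
        if worst < tol:
            break
    else:
        raise ConvergenceError("fixed-effect demeaning did not converge", [])
    return M


def _build_design(panel: pd.DataFrame, spec: ModelSpec):
    spec.validate()
    df = panel.copy()
    cols = spec.term_columns()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelError(f"panel missing exposure columns {missing}")
    design_cols: dict[str, np.ndarray] = {}
    spline_bases: dict[str, SplineBasis] = {}
    for c in cols:
        design_cols[c] = df[c].to_numpy(dtype=float)
    if spec.exposure_spec == "spline":
        # extra restricted-cubic terms in each exposure, knots placed on
        # the positive support (monthly counts are mostly zero)
        for c in spec.exposure_cols:
            x = df[c].to_numpy(dtype=float)
            pos = np.unique(x[x > 0])
            if len(pos) < 3:
                raise ModelError(f"too few positive values in {c} for a spline exposure")
            knots = tuple(np.percentile(x[x > 0], [10, 50, 90]))
            if len(np.unique(knots)) < 3:
                raise ModelError(f"degenerate spline knots for {c}: {knots}")
            basis, dm = rcs_basis(x, knots=knots)
            spline_bases[c] = basis
            for j, name in enumerate(basis.column_names(c)[1:], start=1):
                design_cols[name] = dm[:, j]
    for name, n_knots in spec.covariates:
        if name not in df.columns:
            raise ModelError(f"panel missing covariate {name!r}")
        basis, dm = rcs_basis(df[name].to_numpy(dtype=float), n_knots=n_knots)
        spline_bases[name] = basis
        for j, cname in enumerate(basis.column_names(name)):
            design_cols[cname] = dm[:, j]
    X = pd.DataFrame(design_cols, index=df.index)
    return df, X, spline_bases


def ppml_fit(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    label: str = "",
    max_iter: int = 100,
    dev_tol: float = 1e-9,
    demean_tol: float = 1e-10,
) -> PPMLFit:
    """Fit the Poisson pseudo-ML fixed-effects model.

    Parameters
    ----------
    panel
        County×month panel with the outcome, ``population``, exposure
        columns, fixed-effect id columns, and any covariates.
    spec
        Model specification; defaults to linear exposure terms with
        county/month/year fixed effects in rate mode.

    Raises
    ------
    ConvergenceError
        If IRLS fails to converge (the deviance trace is attached).
    ModelError
        On collinear exposure columns (named) or invalid input.
    """
    spec = spec or ModelSpec()
    df, X, spline_bases = _build_design(panel, spec)

    # rows with undefined design values (e.g. first-month lags) drop out
    finite = np.isfinite(X.to_numpy()).all(axis=1)
    df, X = df.loc[finite], X.loc[finite]

    if "population" not in df.columns:
        raise ModelError("panel missing 'population' column")
    bad_pop = df["population"].to_numpy(dtype=float) <= 0
    if bad_pop.any():
        rows = df.loc[bad_pop, ["county_id", "year", "month"]].head(5).to_dict("records")
        raise ModelError(f"non-positive population in rows {rows}")

    if spec.outcome_mode == "rate":
        if spec.outcome_col not in df.columns:
            raise ModelError(f"panel missing outcome column {spec.outcome_col!r}")
        y = df[spec.outcome_col].to_numpy(dtype=float)
        w = df["population"].to_numpy(dtype=float)
        offset = np.zeros(len(df))
    else:
        y = df["deaths"].to_numpy(dtype=float)
        w = np.ones(len(df))
        offset = np.log(df["population"].to_numpy(dtype=float) / 1e5)
    if np.any(y < 0):
        raise ModelError("outcome must be non-negative")

    keep, dropped = _drop_separated(df, y, spec.fixed_effects)
    df, X, y, w, offset = df.loc[keep], X.loc[keep], y[keep], w[keep], offset[keep]
    n = len(df)
    if n == 0:
        raise ModelError("no observations left after separation drops")

    codes, sizes = [], []
    for col in spec.fixed_effects:
        c, _ = pd.factorize(df[col], sort=True)
        codes.append(c)
        sizes.append(int(c.max()) + 1)
    for col, s in zip(spec.fixed_effects, sizes):
        if s == 0:
            raise ModelError(f"fixed-effect set {col!r} is empty")

    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]

    mu = (y + y.mean()) / 2.0
    mu = np.maximum(mu, 1e-8)
    eta = np.log(mu)
    dev_old = np.inf
    trace: list[float] = []
    for it in range(max_iter):
        W = w * mu
        z = (eta - offset) + (y - mu) / mu
        M = _demean(np.column_stack([Xv, z]), codes, sizes, W, tol=demean_tol)
        Xt, zt = M[:, :p], M[:, p]
        XtW = Xt * W[:, None]
        A = Xt.T @ XtW
        if it == 0:
            rank = np.linalg.matrix_rank(A)
            if rank < p:
                # name the offending columns via pivoted QR on the demeaned design
                from scipy.linalg import qr

                _, R, piv = qr(np.sqrt(W)[:, None] * Xt, pivoting=True, mode="economic")
                d = np.abs(np.diag(R))
                bad = [X.columns[piv[j]] for j in range(p) if d[j] < d[0] * 1e-10]
                raise ModelError(f"collinear design columns after FE absorption: {bad}")
        beta = np.linalg.solve(A, XtW.T @ z)
        resid = zt - Xt @ beta
        eta = offset + (z - resid)
        mu = np.exp(eta)  # outcome-scale mean (offset included in count mode)
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * float(np.sum(w * (ylogy - (y - mu))))
        trace.append(dev)
        if abs(dev - dev_old) <= dev_tol * (0.1 + abs(dev)):
            break
        dev_old = dev
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (deviance trace attached)", trace
        )

    W = w * mu
    M = _demean(np.column_stack([Xv]), codes, sizes, W, tol=demean_tol)
    Xt = M[:, :p]
    A = Xt.T @ (Xt * W[:, None])
    score = w * (y - mu)
    score_norm = float(np.abs(Xt.T @ score).max())
    k_absorbed = sum(sizes) - (len(sizes) - 1)
    k_total = p + k_absorbed
    ss_factor = n / max(n - k_total, 1)
    Ainv = np.linalg.inv(A)
    if spec.cluster:
        groups, _ = pd.factorize(df[spec.cluster], sort=True)
        G = int(groups.max()) + 1
        S = np.zeros((G, p))
        np.add.at(S, groups, Xt * score[:, None])
        B = S.T @ S
        ss_factor = (G / max(G - 1, 1)) * ((n - 1) / max(n - k_total, 1))
    else:
        B = (Xt * (score**2)[:, None]).T @ Xt
    V = Ainv @ B @ Ainv * ss_factor
    V = (V + V.T) / 2.0

    loglik = float(np.sum(w * (np.where(y > 0, y * np.log(mu), 0.0) - mu)))
    bic = -2.0 * loglik + p * math.log(n)

    keep_cols = [c for c in df.columns if c not in ("provenance",)]
    fit_panel = df[keep_cols].reset_index(drop=True)
    return PPMLFit(
        spec=spec,
        label=label,
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(V, index=X.columns, columns=X.columns),
        panel=fit_panel,
        eta=eta,
        mu=mu,
        y=y,
        weights=w,
        offset=offset,
        deviance=dev,
        loglik=loglik,
        bic=bic,
        n_obs=n,
        k_explicit=p,
        k_absorbed=k_absorbed,
        score_norm=score_norm,
        dropped=dropped,
        trace=trace,
        spline_bases=spline_bases,
    )


def percent_change_per_day(fit: PPMLFit, term: str) -> dict[str, float]:
    """Percent change in the monthly mortality rate per extra extreme day.

    ``100·(e^β − 1)`` with 95% interval ``100·(e^{β±1.96·SE} − 1)``.
    """
    if term not in fit.params.index:
        raise ModelError(f"term {term!r} not in fit (have {list(fit.params.index)})")
    b = float(fit.params[term])
    se = float(fit.se[term])
    return {
        "term": term,
        "estimate": b,
        "se": se,
        "pct_change": 100.0 * (math.exp(b) - 1.0),
        "ci_lo": 100.0 * (math.exp(b - Z95 * se) - 1.0),
        "ci_hi": 100.0 * (math.exp(b + Z95 * se) - 1.0),
        "p": float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else float("nan"),
    }


def bic_compare(fits: Sequence[PPMLFit]) -> pd.DataFrame:
    """Rank specifications by BIC (−2·log-pseudolikelihood + k·ln n).

    ``k`` counts explicit (non-absorbed) parameters. All fits must be on
    the same observations; ties go to the fit with fewer parameters,
    then to input order.
    """
    if not fits:
        raise ModelError("no fits to compare")
    ns = {f.n_obs for f in fits}
    if len(ns) > 1:
        raise ModelError(f"fits on differing observation counts: {sorted(ns)}")
    rows = [
        {
            "label": f.label or f"fit{i}",
            "order": i,
            "k": f.k_explicit,
            "loglik": f.loglik,
            "bic": f.bic,
        }
        for i, f in enumerate(fits)
    ]
    out = pd.DataFrame(rows).sort_values(["bic", "k", "order"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def direct_standardized_rate(
    deaths, population, standard_population
) -> float:
    """Directly age-standardized rate per 100,000.

    Stratum-specific crude rates weighted by a fixed standard
    population: ``1e5 · Σ_a w_a (d_a/n_a) / Σ_a w_a``. In synthetic
    studies the standard is the simulated base-year population.
    """
    d = np.asarray(deaths, dtype=float)
    n = np.asarray(population, dtype=float)
    w = np.asarray(standard_population, dtype=float)
    if np.any(n <= 0) or np.any(w < 0) or w.sum() <= 0:
        raise ModelError("populations must be positive and standard weights non-negative")
    return float(1e5 * np.sum(w * d / n) / w.sum())
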