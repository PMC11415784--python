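"""Counterfactual excess deaths: identities, closed-form truth,
delta-method propagation, and report shaping."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from tempmort.attribution import (
    AttributionError,
    DeltaEstimate,
    excess_deaths,
    excess_from_arrays,
    per_capita,
    percent_change,
    predict_expected_deaths,
    stratified_report,
)
from tempmort.model import ModelSpec, ppml_fit
from tempmort.pipeline import run_study
from tempmort.synthetic import simulate_study

from conftest import (
    explicit_dummy_design,
    make_true_fit,
    random_small_panel,
    tiny_synthetic_config,
)


@pytest.fixture(scope="module")
def tiny_result():
    from tempmort.config import PipelineConfig

    return run_study(
        PipelineConfig(synthetic=tiny_synthetic_config()), include_projection=False
    )


class TestPrediction:
    def test_score_identity_total_deaths_preserved(self, tiny_result):
        """At convergence Σμ̂ = Σy on the fitted (smoothed) outcome
        scale (county FE span the intercept)."""
        for fit in tiny_result.fits.values():
            pred = predict_expected_deaths(fit)
            outcome_deaths = (
                fit.panel[fit.spec.outcome_col] * fit.panel["population"] / 1e5
            ).sum()
            assert pred["expected_deaths"].sum() == pytest.approx(outcome_deaths, rel=1e-6)

    def test_single_cell_arithmetic(self):
        """Rate 50 per 100k on a population of 200,000 -> 100 deaths."""
        cfg = tiny_synthetic_config()
        sim = simulate_study(cfg, include_projection=False)
        fit = make_true_fit(sim, "older")
        fit.eta = np.full(fit.n_obs, np.log(50.0))
        fit.panel = fit.panel.assign(population=200_000.0)
        pred = predict_expected_deaths(fit)
        np.testing.assert_allclose(pred["expected_deaths"], 100.0)

    def test_matches_explicit_dummies_oracle(self):
        rng = np.random.default_rng(21)
        panel = random_small_panel(rng, n_counties=4, n_months=12)
        fit = ppml_fit(panel, ModelSpec())
        X, _ = explicit_dummy_design(panel, ("n_hot_days", "n_cold_days"))
        oracle = sm.GLM(
            panel["rate"].to_numpy(), X, family=sm.families.Poisson(),
            var_weights=panel["population"].to_numpy(),
        ).fit()
        ours = predict_expected_deaths(fit)["expected_deaths"].to_numpy()
        theirs = oracle.fittedvalues * panel["population"].to_numpy() / 1e5
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)

    def test_unknown_county_rejected(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        alien = pd.DataFrame({"county_id": [999], "year": [2000], "month": [1]})
        with pytest.raises(AttributionError, match="absent"):
            predict_expected_deaths(fit, alien)


class TestExcess:
    def test_null_coefficients_zero_excess(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        betas = pd.Series(0.0, index=["n_hot_days", "n_cold_days"])
        mu = np.exp(fit.eta) * fit.panel["population"].to_numpy() / 1e5
        exposures = {t: fit.panel[t].to_numpy(dtype=float) for t in betas.index}
        v, g = excess_from_arrays(
            mu, exposures, betas, ["n_hot_days"], ["n_cold_days"], "combined"
        )
        assert v == 0.0
        assert g["n_hot_days"] > 0  # CI still has width centered at 0

    def test_zero_exposure_zero_heat_excess(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        mu = np.ones(fit.n_obs)
        exposures = {
            "n_hot_days": np.zeros(fit.n_obs),
            "n_cold_days": fit.panel["n_cold_days"].to_numpy(dtype=float),
        }
        v, _ = excess_from_arrays(
            mu, exposures, fit.params[["n_hot_days", "n_cold_days"]],
            ["n_hot_days"], ["n_cold_days"], "heat",
        )
        assert v == 0.0

    def test_truth_injection_matches_closed_form(self):
        """Attribution at the true parameters reproduces the generator's
        closed-form expected excess to 1e-10 relative."""
        cfg = tiny_synthetic_config()
        sim = simulate_study(cfg, include_projection=False)
        for stratum in sim.truth.strata:
            fit = make_true_fit(sim, stratum)
            for comp in ("heat", "cold", "combined"):
                est = excess_deaths(fit, component=comp)
                assert est.value == pytest.approx(
                    sim.truth.expected_excess[(stratum, comp)], rel=1e-10
                )

    def test_heat_cold_combined_additivity(self, tiny_result):
        for scope in tiny_result.current:
            c = tiny_result.current[scope]
            assert c["heat"].value + c["cold"].value == pytest.approx(
                c["combined"].value, rel=1e-12
            )

    def test_monotone_in_exposure(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        assert fit.params["n_hot_days"] > 0
        base = excess_deaths(fit, component="heat").value
        bumped_panel = fit.panel.copy()
        bumped_panel["n_hot_days"] += 1
        mu = np.exp(fit.eta) * fit.panel["population"].to_numpy() / 1e5
        exposures = {t: bumped_panel[t].to_numpy(dtype=float) for t in ("n_hot_days", "n_cold_days")}
        v, _ = excess_from_arrays(
            mu, exposures, fit.params[["n_hot_days", "n_cold_days"]],
            ["n_hot_days"], ["n_cold_days"], "heat",
        )
        assert v / fit.panel["year"].nunique() > base

    def test_gradient_matches_numerical_differentiation(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        mu0 = np.exp(fit.eta) * fit.panel["population"].to_numpy() / 1e5
        terms = ["n_hot_days", "n_cold_days"]
        exposures = {t: fit.panel[t].to_numpy(dtype=float) for t in terms}
        betas = fit.params[terms]
        H, C = exposures["n_hot_days"], exposures["n_cold_days"]

        def excess(bh, bc, comp):
            # independent re-evaluation: mu re-derived from the exposure-free
            # part of the linear predictor so that mu varies with beta
            eta0 = fit.eta - betas["n_hot_days"] * H - betas["n_cold_days"] * C
            mu = np.exp(eta0 + bh * H + bc * C) * fit.panel["population"].to_numpy() / 1e5
            if comp == "heat":
                return np.sum(mu * (1 - np.exp(-bh * H)))
            return np.sum(mu * (1 - np.exp(-bc * C)))

        eps = 1e-7
        for comp in ("heat", "cold"):
            _, grad = excess_from_arrays(
                mu0, exposures, betas, ["n_hot_days"], ["n_cold_days"], comp
            )
            bh, bc = betas["n_hot_days"], betas["n_cold_days"]
            num_h = (excess(bh + eps, bc, comp) - excess(bh - eps, bc, comp)) / (2 * eps)
            num_c = (excess(bh, bc + eps, comp) - excess(bh, bc - eps, comp)) / (2 * eps)
            assert grad["n_hot_days"] == pytest.approx(num_h, rel=1e-4)
            assert grad["n_cold_days"] == pytest.approx(num_c, rel=1e-4)

    def test_ci_width_scales_with_se(self, tiny_result):
        fit = next(iter(tiny_result.fits.values()))
        est = excess_deaths(fit, component="heat")
        lo, hi = est.ci
        width = hi - lo
        est4 = excess_deaths(fit, component="heat")
        for k in est4.estimate.covs:
            est4.estimate.covs[k] = est4.estimate.covs[k] * 4.0
        lo4, hi4 = est4.ci
        assert (hi4 - lo4) == pytest.approx(2.0 * width, rel=1e-9)


class TestPerCapita:
    def test_published_scale_back_solve(self):
        """8248.6 annual excess deaths among ~233.0M adults is 35.4 per
        1M per year."""
        est = DeltaEstimate(8248.6)
        assert per_capita(est, 233_011_300).value == pytest.approx(35.4, abs=0.05)

    def test_zero_and_scaling(self):
        assert per_capita(DeltaEstimate(0.0), 1e6).value == 0.0
        a = per_capita(DeltaEstimate(100.0), 1e6).value
        b = per_capita(DeltaEstimate(100.0), 2e6).value
        assert a == pytest.approx(2 * b)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(AttributionError):
            per_capita(DeltaEstimate(1.0), 0.0)


class TestStratifiedReport:
    def test_age_groups_sum_to_all_adults(self, tiny_result):
        rep = tiny_result.report.set_index(["scope", "component"])
        for comp in ("heat", "cold", "combined"):
            assert rep.loc[("all_adults", comp), "estimate"] == pytest.approx(
                rep.loc[("older", comp), "estimate"] + rep.loc[("younger", comp), "estimate"],
                rel=1e-12,
            )

    def test_identical_strata_double(self, tiny_result):
        fit = tiny_result.fits["older"]
        rep = stratified_report({"a": fit, "b": fit}, combine={"both": ["a", "b"]})
        rep = rep.set_index(["scope", "component"])
        assert rep.loc[("both", "combined"), "estimate"] == pytest.approx(
            2 * rep.loc[("a", "combined"), "estimate"], rel=1e-12
        )

    def test_missing_stratum_fit_rejected(self, tiny_result):
        fit = tiny_result.fits["older"]
        with pytest.raises(AttributionError, match="missing"):
            stratified_report({"a": fit}, combine={"both": ["a", "b"]})

    def test_report_columns(self, tiny_result):
        expected = {
            "scope", "component", "period", "estimate", "ci_lo", "ci_hi",
            "per_1m", "per_1m_lo", "per_1m_hi",
        }
        assert expected <= set(tiny_result.report.columns)


class TestAlternativeCI:
    def test_simulation_ci_agrees_with_delta_method(self, tiny_result):
        """The parametric-simulation interval should roughly match the
        delta-method interval when the excess is near-linear in beta."""
        from tempmort.attribution import excess_ci_simulation

        fit = tiny_result.fits["older"]
        est = excess_deaths(fit, component="combined")
        lo_d, hi_d = est.ci
        lo_s, hi_s = excess_ci_simulation(fit, "combined", n_draws=4000, seed=0)
        width_d, width_s = hi_d - lo_d, hi_s - lo_s
        assert width_s == pytest.approx(width_d, rel=0.15)
        assert lo_s < est.value < hi_s

    def test_simulation_ci_deterministic_under_seed(self, tiny_result):
        from tempmort.attribution import excess_ci_simulation

        fit = tiny_result.fits["older"]
        a = excess_ci_simulation(fit, "heat", n_draws=500, seed=3)
        b = excess_ci_simulation(fit, "heat", n_draws=500, seed=3)
        assert a == b


def test_direct_standardization_hand_example():
    """Two age bands, standard population fixing the weights."""
    from tempmort.model import direct_standardized_rate

    # crude rates 100 and 1000 per 100k; standard weights 0.8/0.2
    rate = direct_standardized_rate(
        deaths=[10.0, 100.0],
        population=[10_000.0, 10_000.0],
        standard_population=[80_000.0, 20_000.0],
    )
    assert rate == pytest.approx(0.8 * 100.0 + 0.2 * 1000.0)
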