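import math

import numpy as np
import pandas as pd
import pytest

import gwgcharts as g
from gwgcharts.model import (
    Design,
    DesignError,
    DiagnosticsError,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    SamplerConfig,
    load_draws,
    log_posterior,
    save_draws,
)
from gwgcharts.reference import load_reference_effects
from gwgcharts.splines import SplineSpec

from . import oracles
from .conftest import single_stratum_config

SPLINE = SplineSpec(df=5, interior_knots=(15.0, 22.0, 28.0, 34.0),
                    boundary_knots=(8.0, 41.0))


def test_log_transform_round_trip_and_domain():
    assert g.log_transform(0.0) == pytest.approx(math.log(20.0))
    x = np.array([-9.9, 0.0, 11.5, 29.9])
    np.testing.assert_allclose(g.back_transform(g.log_transform(x)), x, atol=1e-12)
    # prior mean of 3 on the log scale is (almost exactly) zero gain
    assert g.back_transform(3.0) == pytest.approx(0.0855, abs=1e-4)
    with pytest.raises(ValueError):
        g.log_transform(-20.0)


def test_exp_coefficient_reproduces_reporting_convention():
    assert g.exp_coefficient(0.070) == 1.073
    assert g.exp_coefficient(0.0) == 1.000
    assert g.exp_coefficient(-0.030) == 0.970


def _tiny_cohort(n_women=10, seed=0):
    return g.simulate_cohort(single_stratum_config("underweight", n_women, seed=seed))


def test_design_reference_profile_and_column_count():
    coh = _tiny_cohort(30, seed=2).copy()
    spec = ModelSpec(spline=SPLINE)
    # force one row to the full reference profile
    ref_cols = {"age_band": ">=35", "height_band": ">=162", "parity": "multipara",
                "smoking": "never", "previous_disease": "no"}
    for k, v in ref_cols.items():
        coh.loc[coh.index[0:4], k] = v
    design = g.build_design(coh, spec)
    expected_gamma = sum(len(lv) - 1 for lv in spec.covariates.values())
    assert len(spec.gamma_columns) == expected_gamma
    assert design.X.shape[1] == 1 + SPLINE.df + expected_gamma
    assert np.all(design.X[0, 1 + SPLINE.df:] == 0.0)

    same_woman = design.woman_index[coh["woman_id"].to_numpy() == coh["woman_id"].iloc[0]]
    assert np.all(same_woman == same_woman[0])


def test_design_rejects_unknown_levels_and_mixed_strata():
    coh = _tiny_cohort(10).copy()
    coh.loc[coh.index[0], "smoking"] = "pipe"
    with pytest.raises(DesignError, match="pipe"):
        g.build_design(coh, ModelSpec(spline=SPLINE))
    coh2 = _tiny_cohort(10).copy()
    coh2.loc[coh2.index[0], "bmi_category"] = "obese"
    with pytest.raises(DesignError):
        g.build_design(coh2, ModelSpec(spline=SPLINE))


def test_log_posterior_matches_elementwise_oracle():
    """Joint log density at fixed parameters equals a from-scratch
    elementwise computation (likelihood, random effects, every prior)."""
    coh = _tiny_cohort(10, seed=5)
    spec = ModelSpec(spline=SPLINE)
    design = g.build_design(coh, spec)
    rng = np.random.default_rng(1)
    p = design.X.shape[1]
    beta = rng.normal(0, 0.3, p)
    beta[0] = 3.1
    tau = rng.normal(0, 0.1, design.n_women)
    sigma_tau, sigma_eps, nu = 0.09, 0.05, 4.2

    ours = log_posterior(design, beta, tau, sigma_tau, sigma_eps, nu)

    pr = spec.priors
    expected = 0.0
    for i in range(design.y.size):
        mu = float(design.X[i] @ beta) + tau[design.woman_index[i]]
        expected += oracles.student_t_logpdf(design.y[i] - mu, nu, sigma_eps)
    for t in tau:
        expected += oracles.normal_logpdf(t, sigma_tau)
    expected += oracles.normal_logpdf(beta[0] - 3.0, 1.0)
    for b in beta[1:]:
        expected += oracles.normal_logpdf(b, 1.0)
    expected += oracles.half_t_logpdf(sigma_tau, 3.0, 1.0)
    expected += oracles.half_t_logpdf(sigma_eps, 3.0, 1.0)
    # truncated Gamma(2, 0.1) prior on the t degrees of freedom
    a, rate, lo = pr.error_df_shape, pr.error_df_rate, pr.error_df_min
    log_norm = math.log(1.0 - (1.0 - math.exp(-rate * lo) * (1 + rate * lo)))
    expected += ((a - 1) * math.log(nu) - rate * nu + a * math.log(rate)
                 - math.lgamma(a)) - log_norm

    assert ours == pytest.approx(expected, abs=1e-8)


def test_prior_recovery_with_no_data():
    """Sampling with an empty design returns the prior: beta0 centred at 3."""
    spec = ModelSpec(spline=SPLINE)
    empty = Design(
        X=np.zeros((0, 1 + SPLINE.df + len(spec.gamma_columns))),
        y=np.zeros(0), woman_index=np.zeros(0, dtype=int),
        columns=["intercept"] + [f"ga_spline_{k+1}" for k in range(SPLINE.df)]
        + spec.gamma_columns,
        spec=spec, n_women=0,
    )
    draws = g.fit(empty, SamplerConfig(chains=2, warmup=200, draws=1500, seed=7))
    b0 = draws.stacked("beta0")
    assert abs(np.median(b0) - 3.0) < 3 * b0.std() / math.sqrt(200)
    assert abs(b0.std() - 1.0) < 0.1
    assert (draws.stacked("sigma_eps") > 0).all()


def test_parameter_recovery_on_one_simulated_stratum(small_fit):
    """Posterior medians of the covariate effects land within 3 posterior
    SDs of the generating truth."""
    coh, design, draws = small_fit
    truth = single_stratum_config("underweight", 150, seed=101).truth["underweight"]
    summ = g.summarize(draws)
    for (factor, level), value in truth.gamma.items():
        row = summ.loc[f"{factor}[{level}]"]
        assert abs(row["median"] - value) <= 3 * row["sd"], (factor, level)
    st = summ.loc["sigma_tau"]
    assert abs(st["median"] - truth.sigma_tau) <= 4 * st["sd"]


def test_fit_is_reproducible_and_order_invariant(small_fit):
    coh, design, draws = small_fit
    spec = design.spec
    again = g.fit(g.build_design(coh, spec),
                  SamplerConfig(chains=2, warmup=300, draws=500, seed=11))
    pd.testing.assert_frame_equal(g.summarize(draws), g.summarize(again))

    shuffled = coh.sample(frac=1.0, random_state=4).reset_index(drop=True)
    draws_shuffled = g.fit(g.build_design(shuffled, spec),
                           SamplerConfig(chains=2, warmup=300, draws=500, seed=11))
    a, b = g.summarize(draws), g.summarize(draws_shuffled)
    # medians agree up to Monte-Carlo error (scaled by each posterior SD)
    diff = np.abs(a["median"].to_numpy() - b["median"].to_numpy())
    tol = 0.3 * a["sd"].to_numpy() + 2e-3
    assert np.all(diff <= tol), dict(zip(a.index[diff > tol], diff[diff > tol]))


def test_diagnostics_on_constructed_chains():
    rng = np.random.default_rng(0)
    iid = {"x": rng.normal(size=(4, 5000))}
    table = g.diagnostics(iid, ess_min=0)
    assert 0.999 <= table.loc["x", "rhat"] <= 1.01
    assert table.attrs["divergences"] == 0

    ess_iid = g.diagnostics({"x": rng.normal(size=(4, 5000))}, ess_min=0)
    assert abs(ess_iid.loc["x", "ess_bulk"] - 20_000) < 0.2 * 20_000

    stuck = {"x": rng.normal(size=(4, 500)) + np.array([[0.0], [5.0], [10.0], [15.0]])}
    assert g.diagnostics(stuck, ess_min=0).loc["x", "rhat"] > 1.1

    with pytest.raises(DiagnosticsError):
        g.diagnostics({"x": rng.normal(size=(1, 100))})


def test_hdi_properties():
    rng = np.random.default_rng(1)
    sym = rng.normal(size=40_000)
    lo, hi = g.hdi(sym, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.06)
    assert hi == pytest.approx(1.96, abs=0.06)

    assert g.hdi(np.full(50, 2.5)) == (2.5, 2.5)

    skew = np.exp(rng.normal(size=40_000))
    lo, hi = g.hdi(skew, 0.95)
    eq_lo, eq_hi = np.quantile(skew, [0.025, 0.975])
    assert (hi - lo) < (eq_hi - eq_lo)
    assert lo <= np.median(skew) <= hi


def test_summary_of_constant_draws():
    spec = ModelSpec(spline=SplineSpec(df=1, interior_knots=(),
                                       boundary_knots=(8.0, 40.0)))
    post = {
        "beta0": np.full((2, 20), 3.25),
        "spline": np.full((2, 20, 1), 0.5),
        "gamma": np.zeros((2, 20, len(spec.gamma_columns))),
        "sigma_tau": np.full((2, 20), 0.1),
        "sigma_eps": np.full((2, 20), 0.05),
    }
    draws = PosteriorDraws(posterior=post,
                           columns=["intercept", "ga_spline_1"] + spec.gamma_columns,
                           spec=spec, config=SamplerConfig(), n_women=0)
    summ = g.summarize(draws)
    row = summ.loc["beta0"]
    assert row["median"] == 3.25 and row["sd"] == 0.0
    assert (row["hdi_low"], row["hdi_high"]) == (3.25, 3.25)


def test_exponentiation_consistency_with_published_table():
    """exp of every published log-scale median reproduces the published
    multiplicative effect to 3 decimals."""
    ref = load_reference_effects()
    rows = ref[ref["factor"] != "sd_intercept"]
    diffs = [
        abs(g.exp_coefficient(r.median_log) - r.exp_median)
        for r in rows.itertuples(index=False)
    ]
    assert max(diffs) < 5e-4


def test_save_and_load_round_trip(tmp_path, small_fit):
    _, _, draws = small_fit
    path = tmp_path / "draws.npz"
    save_draws(draws, path)
    again = load_draws(path)
    assert again.columns == draws.columns
    assert again.spec.spline == draws.spec.spline
    for k, v in draws.posterior.items():
        np.testing.assert_array_equal(again.posterior[k], v)
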