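import json

import numpy as np
import pandas as pd
import pytest

import gwgcharts as g
from gwgcharts.cohort import (
    DEFAULT_TRUTH_SPLINE,
    ConfigurationError,
    DomainError,
    TruthParams,
    default_truth,
    median_curve,
    smooth_anchor_projection,
    write_cohort,
)
from gwgcharts.splines import SplineSpec, evaluate_basis

from .conftest import single_stratum_config


@pytest.fixture(scope="module")
def big_cohort():
    return g.simulate_cohort(g.GeneratorConfig(n_women=10_000, seed=2024))


def test_generator_is_deterministic_under_seed():
    cfg = g.GeneratorConfig(n_women=60, seed=5)
    a = g.simulate_cohort(cfg)
    b = g.simulate_cohort(g.GeneratorConfig(n_women=60, seed=5))
    pd.testing.assert_frame_equal(a, b)
    c = g.simulate_cohort(g.GeneratorConfig(n_women=60, seed=6))
    assert not a["gwg_kg"].equals(c["gwg_kg"])


def test_single_woman_and_degenerate_proportions():
    one = g.sample_population(g.GeneratorConfig(n_women=1, seed=9))
    assert len(one) == 1
    for col in ("age_band", "height_band", "parity", "smoking", "previous_disease"):
        assert one[col].notna().all()

    cfg = single_stratum_config("underweight", 50, seed=1)
    pop = g.sample_population(cfg)
    assert (pop["bmi_category"] == "underweight").all()


def test_invalid_configs_name_the_offending_field():
    with pytest.raises(ConfigurationError, match="n_women"):
        g.GeneratorConfig(n_women=0)
    with pytest.raises(ConfigurationError, match="bmi_proportions"):
        g.GeneratorConfig(bmi_proportions={"underweight": 0.5, "normal": 0.6,
                                           "overweight": 0.0, "obese": 0.0})
    with pytest.raises(ConfigurationError, match="missingness"):
        g.GeneratorConfig(missingness={"complete": 0.9, "missing_delivery": 0.2,
                                       "missing_third": 0.0, "missing_second": 0.0,
                                       "missing_first": 0.0})
    with pytest.raises(ConfigurationError, match="visit_timing"):
        g.GeneratorConfig(visit_timing={**g.GeneratorConfig().visit_timing,
                                        "early": (11.1, 0.0)})


def test_category_and_timing_moments_match_configuration(big_cohort):
    """At n=10,000 every configured frequency / timing mean is matched
    within 3 Monte-Carlo standard errors."""
    women = big_cohort.drop_duplicates("woman_id")
    n = len(women)
    for cat, p in g.GeneratorConfig().bmi_proportions.items():
        obs = (women["bmi_category"] == cat).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= 3 * se, (cat, obs, p)

    for visit, (mean, sd) in g.GeneratorConfig().visit_timing.items():
        ga = big_cohort.loc[big_cohort["visit_label"] == visit, "ga_weeks"]
        se = ga.std() / np.sqrt(len(ga))
        assert abs(ga.mean() - mean) <= 3 * se, (visit, ga.mean(), mean)


def test_completeness_pattern_and_visit_ordering(big_cohort):
    sizes = big_cohort.groupby("woman_id").size()
    assert sizes.min() >= 3
    frac4 = (sizes == 4).mean()
    se = np.sqrt(0.86 * 0.14 / len(sizes))
    assert abs(frac4 - 0.86) <= 3 * se

    ga_diff = big_cohort.groupby("woman_id")["ga_weeks"].diff().dropna()
    assert (ga_diff > 0).all()


def test_visits_stay_inside_clinical_windows(big_cohort):
    lab = big_cohort.set_index("visit_label")["ga_weeks"]
    assert lab.loc["early"].between(1, 15).all()
    assert lab.loc["mid"].between(16, 28).all()
    assert lab.loc["delivery"].between(32, 43).all()
    assert (lab.loc["late"] >= 29).all()


def test_calibrate_median_spline_interpolates_printed_medians():
    """With 4 anchors and a 5-df basis the least-squares fit interpolates:
    the back-transformed curve reproduces every anchor to < 0.01 kg."""
    anchors = [(10.0, 0.8), (20.0, 3.8), (30.0, 7.8), (40.0, 11.5)]
    beta0, coefs = g.calibrate_median_spline(anchors, DEFAULT_TRUTH_SPLINE)
    curve = median_curve(beta0, coefs, DEFAULT_TRUTH_SPLINE, [a[0] for a in anchors])
    np.testing.assert_allclose(curve, [a[1] for a in anchors], atol=0.01)


def test_calibrate_median_spline_round_trip_recovers_coefficients():
    spline = DEFAULT_TRUTH_SPLINE
    rng = np.random.default_rng(8)
    true_beta0, true_coefs = 3.1, rng.normal(0, 0.2, spline.df)
    weeks = np.linspace(1.0, 41.0, 12)
    gwg = np.exp(true_beta0 + evaluate_basis(spline, weeks) @ true_coefs) - 20.0
    beta0, coefs = g.calibrate_median_spline(list(zip(weeks, gwg)), spline)
    assert abs(beta0 - true_beta0) < 1e-6
    np.testing.assert_allclose(coefs, true_coefs, atol=1e-6)


def test_calibrate_median_spline_edge_cases():
    beta0, coefs = g.calibrate_median_spline([(20.0, 5.0)], spline=None)
    assert coefs.size == 0
    assert np.exp(beta0) - 20.0 == pytest.approx(5.0)
    with pytest.raises(DomainError):
        g.calibrate_median_spline([(10.0, -25.0), (20.0, 1.0)], DEFAULT_TRUTH_SPLINE)
    with pytest.raises(DomainError):
        g.calibrate_median_spline([(10.0, 1.0)], DEFAULT_TRUTH_SPLINE)


def test_default_truth_median_curves_stay_near_published_anchors():
    from gwgcharts.cohort import DEFAULT_MEDIAN_ANCHORS

    for stratum, anchors in DEFAULT_MEDIAN_ANCHORS.items():
        t = default_truth(stratum)
        weeks = [a[0] for a in anchors]
        curve = median_curve(t.beta0, t.spline_coefs, DEFAULT_TRUTH_SPLINE, weeks)
        np.testing.assert_allclose(curve, [a[1] for a in anchors], atol=0.15)
        # gains after the first trimester increase monotonically
        grid = median_curve(t.beta0, t.spline_coefs, DEFAULT_TRUTH_SPLINE,
                            np.arange(10.0, 43.0))
        assert np.all(np.diff(grid) > 0)


def test_noise_free_limit_reproduces_the_median_curve():
    cfg = single_stratum_config("normal", 40, seed=3)
    base = cfg.truth["normal"]
    quiet = TruthParams(
        beta0=base.beta0, spline_coefs=base.spline_coefs, gamma={},
        sigma_tau=1e-12, sigma_eps=1e-12, error_df=3.0,
    )
    cfg.truth["normal"] = quiet
    coh = g.simulate_cohort(cfg)
    expected = median_curve(
        quiet.beta0, quiet.spline_coefs, cfg.spline, coh["ga_weeks"].to_numpy()
    )
    np.testing.assert_allclose(coh["gwg_kg"].to_numpy(), expected, atol=1e-6)


def test_between_woman_log_scale_intercept_sd_matches_truth():
    """With residual noise suppressed, per-woman mean log-residuals estimate
    the random-intercept draws; their SD matches the configured 0.080."""
    cfg = single_stratum_config("underweight", 10_000, seed=55)
    base = cfg.truth["underweight"]
    cfg.truth["underweight"] = TruthParams(
        beta0=base.beta0, spline_coefs=base.spline_coefs, gamma=base.gamma,
        sigma_tau=base.sigma_tau, sigma_eps=1e-12, error_df=3.0,
    )
    coh = g.simulate_cohort(cfg)
    mu = base.beta0 + evaluate_basis(cfg.spline, coh["ga_weeks"].to_numpy()) @ np.array(
        base.spline_coefs
    )
    for (f, l), v in base.gamma.items():
        mu += v * (coh[f] == l).to_numpy(dtype=float)
    resid = np.log(coh["gwg_kg"].to_numpy() + 20.0) - mu
    per_woman = pd.Series(resid).groupby(coh["woman_id"].to_numpy()).mean()
    n = per_woman.size
    mc_se = 0.080 / np.sqrt(2 * (n - 1))
    assert abs(per_woman.std(ddof=1) - 0.080) <= 3 * mc_se
    assert (coh["gwg_kg"] > -20).all()


def test_ineligible_injection_produces_two_visit_women():
    cfg = single_stratum_config("normal", 200, seed=12, ineligible_fraction=0.1)
    coh = g.simulate_cohort(cfg)
    sizes = coh.groupby("woman_id").size()
    assert (sizes == 2).sum() == 20


def test_cohort_csv_and_truth_sidecar_round_trip(tmp_path):
    cfg = single_stratum_config("obese", 30, seed=4)
    coh = g.simulate_cohort(cfg)
    csv, sidecar = tmp_path / "c.csv", tmp_path / "t.json"
    write_cohort(coh, cfg, csv, sidecar)
    back = pd.read_csv(csv)
    assert len(back) == len(coh)
    meta = json.loads(sidecar.read_text())
    truth = TruthParams.from_dict(meta["truth"]["obese"])
    assert truth == cfg.truth["obese"]
    spline = SplineSpec(df=meta["spline"]["df"],
                        interior_knots=tuple(meta["spline"]["interior_knots"]),
                        boundary_knots=tuple(meta["spline"]["boundary_knots"]))
    assert spline == cfg.spline
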