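import numpy as np
import pandas as pd
import pytest

import gwgcharts as g
from gwgcharts.model import PosteriorDraws, SamplerConfig


def single_stratum_config(stratum: str, n_women: int, seed: int, **kwargs):
    props = {c: 0.0 for c in ("underweight", "normal", "overweight", "obese")}
    props[stratum] = 1.0
    return g.GeneratorConfig(
        n_women=n_women, seed=seed, bmi_proportions=props, **kwargs
    )


@pytest.fixture(scope="session")
def small_underweight_cohort():
    return g.simulate_cohort(single_stratum_config("underweight", 150, seed=101))


@pytest.fixture(scope="session")
def small_fit(small_underweight_cohort):
    coh = small_underweight_cohort
    spec = g.ModelSpec(spline=g.build_spec(coh["ga_weeks"].to_numpy(), df=5))
    design = g.build_design(coh, spec)
    draws = g.fit(design, SamplerConfig(chains=2, warmup=300, draws=500, seed=11))
    return coh, design, draws


def truth_point_draws(truth, spline, error_family: str = "student_t") -> PosteriorDraws:
    """A degenerate 'posterior' concentrated at the generator truth — used to
    exercise chart/band machinery without an MCMC run."""
    spec = g.ModelSpec(spline=spline, error_family=error_family)
    cols = (
        ["intercept"]
        + [f"ga_spline_{k + 1}" for k in range(spline.df)]
        + spec.gamma_columns
    )
    gamma = np.array(
        [truth.gamma.get(tuple(c[:-1].split("[", 1)), 0.0) for c in spec.gamma_columns]
    )
    c, d = 2, 10
    post = {
        "beta0": np.full((c, d), truth.beta0),
        "spline": np.tile(np.array(truth.spline_coefs), (c, d, 1)),
        "gamma": np.tile(gamma, (c, d, 1)),
        "sigma_tau": np.full((c, d), truth.sigma_tau),
        "sigma_eps": np.full((c, d), truth.sigma_eps),
        "error_df": np.full((c, d), truth.error_df),
    }
    return PosteriorDraws(
        posterior=post, columns=cols, spec=spec, config=SamplerConfig(), n_women=0
    )


def reference_profile_frame() -> pd.DataFrame:
    from gwgcharts.model import REFERENCE_LEVELS

    out = pd.DataFrame({k: [v] for k, v in REFERENCE_LEVELS.items()})
    out["weight"] = 1.0
    return out
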