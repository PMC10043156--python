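"""Hold-out validation of a chart and a prior/error-family sensitivity run.

Trains on 80% of a simulated stratum, checks on the held-out 20% that the
fraction of observations under each percentile curve matches its nominal
level (binomial confidence intervals), then refits under a wider
coefficient prior and a normal error family and reports how much the
answers move.
"""

import numpy as np

import gwgcharts as g
from gwgcharts.model import ModelSpec, PriorSpec, SamplerConfig
from gwgcharts.validation import Variant

props = {"underweight": 0.0, "normal": 1.0, "overweight": 0.0, "obese": 0.0}
cohort = g.simulate_cohort(g.GeneratorConfig(n_women=800, seed=19,
                                             bmi_proportions=props))
train, test = g.split_cohort(cohort, train_fraction=0.8, seed=1)
print(f"{train['woman_id'].nunique()} training / "
      f"{test['woman_id'].nunique()} held-out women")

spec = ModelSpec(spline=g.build_spec(train["ga_weeks"].to_numpy(), df=5))
sampler = SamplerConfig(chains=4, warmup=400, draws=800, seed=2)
draws = g.fit(g.build_design(train, spec), sampler)
chart = g.build_chart(draws, train, "normal", n_samples=10_000, seed=3)

report = g.coverage_report(chart, test)
print("\nHeld-out coverage (observed fraction below each percentile curve):")
print(report.round(3).to_string(index=False))
print("verdict — curves fit the held-out data:", report.attrs["fit"])

variants = [
    Variant("wide-coefficient-priors", priors=PriorSpec(gamma_sd=10.0)),
    Variant("normal-errors", error_family="normal"),
]
table = g.sensitivity_run(train, spec, variants,
                          sampler=SamplerConfig(chains=2, warmup=300, draws=500,
                                                seed=4),
                          ga_grid=np.arange(10.0, 41.0))
print("\nSensitivity analysis (max changes vs baseline):")
print(table.round(4).to_string())
print("\nSmall coefficient deltas mean the data, not the prior, drive the "
      "estimates; the p50-curve delta is in kg across weeks 10-40.")
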