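"""Build a GWG percentile chart and its guideline trajectory band.

Simulates a normal-weight stratum, fits the model, draws new-woman
posterior-predictive samples across weeks 8-42, reads off the
10/25/50/75/90th percentile curves, and inverts the chart into the corridor
of trajectories that ends inside the 2021 JSOG recommendation
(10-13 kg at 40 weeks for normal-weight women).
"""

import numpy as np

import gwgcharts as g
from gwgcharts.model import SamplerConfig

props = {"underweight": 0.0, "normal": 1.0, "overweight": 0.0, "obese": 0.0}
cfg = g.GeneratorConfig(n_women=600, seed=11, bmi_proportions=props)
cohort = g.simulate_cohort(cfg)

spec = g.ModelSpec(spline=g.build_spec(cohort["ga_weeks"].to_numpy(), df=5))
draws = g.fit(g.build_design(cohort, spec),
              SamplerConfig(chains=4, warmup=500, draws=1000, seed=2))

chart = g.build_chart(draws, cohort, "normal", n_samples=10_000, seed=3)
print("Percentile chart (kg of weight gain):")
print(f"{'week':>6} " + " ".join(f"P{lv:<4.0f}" for lv in chart.levels))
for week in (10, 20, 30, 40):
    vals = [chart.value_at(week, lv) for lv in chart.levels]
    print(f"{week:>6} " + " ".join(f"{v:5.1f}" for v in vals))

band = g.build_band(chart)
print(f"\nTrajectory band anchored at the JSOG 10-13 kg interval at 40 weeks")
print(f"(follows the {band.q_low:.0f}th and {band.q_high:.0f}th percentile curves):")
for week in (10, 20, 30, 40):
    lo = np.interp(week, band.ga_grid, band.lower_kg)
    hi = np.interp(week, band.ga_grid, band.upper_kg)
    print(f"  week {week:>2}: {lo:5.1f} to {hi:5.1f} kg")

frac = g.fraction_within_band(cohort, band)
print(f"\n{100 * frac:.0f}% of the simulated women end inside the corridor "
      f"(the band spans {band.q_high - band.q_low:.0f}% of the population "
      "by construction).")
print("A woman tracking between the two curves is on course for the "
      "guideline range at term.")
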