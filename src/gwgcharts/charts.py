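"""Posterior-predictive GWG percentile charts.

A chart answers: for a new woman from this BMI stratum, what is the p-th
percentile of weight gain at each gestational week?  Samples are drawn from
the *new-woman* posterior predictive — parameter draw from the posterior, a
covariate profile from the stratum mix, a fresh random intercept
tau* ~ N(0, sigma_tau), residual noise from the error family — and
back-transformed to kg.  Percentiles are then read off per week and
optionally smoothed across weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .model import PosteriorDraws, back_transform

DEFAULT_GA_GRID = np.arange(8.0, 43.0)  # integer weeks 8..42
DEFAULT_LEVELS = (10.0, 25.0, 50.0, 75.0, 90.0)


class ChartError(ValueError):
    pass


@dataclass
class PercentileChart:
    """Per-week GWG percentile values (kg) for one BMI stratum."""

    bmi_category: str
    ga_grid: np.ndarray
    levels: tuple[float, ...]
    values: np.ndarray  # (n_weeks, n_levels)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ga_grid = np.asarray(self.ga_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ga_grid.size, len(self.levels)):
            raise ChartError("values must be (n_weeks, n_levels)")

    def is_monotone(self) -> bool:
        """True when percentile values are non-decreasing in the level at
        every week (the chart's hard invariant)."""
        return bool(np.all(np.diff(self.values, axis=1) >= -1e-12))

    def value_at(self, week: float, level: float) -> float:
        """Chart value with linear interpolation in both week and level."""
        col = np.array(
            [np.interp(week, self.ga_grid, self.values[:, j])
             for j in range(len(self.levels))]
        )
        return float(np.interp(level, self.levels, col))

    def curve(self, level: float) -> np.ndarray:
        """Percentile curve across the week grid (interpolated in level)."""
        return np.array(
            [float(np.interp(level, self.levels, row)) for row in self.values]
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {"week": w, "percentile": lv, "gwg_kg": self.values[i, j]}
            for i, w in enumerate(self.ga_grid)
            for j, lv in enumerate(self.levels)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, bmi_category: str = "") -> "PercentileChart":
        wide = df.pivot(index="week", columns="percentile", values="gwg_kg").sort_index()
        return cls(
            bmi_category=bmi_category,
            ga_grid=wide.index.to_numpy(dtype=float),
            levels=tuple(float(c) for c in wide.columns),
            values=wide.to_numpy(),
        )


def empirical_profiles(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate profiles with empirical per-woman weights for one stratum."""
    factors = ["age_band", "height_band", "parity", "smoking", "previous_disease"]
    women = cohort.drop_duplicates("woman_id")
    counts = women.groupby(factors, observed=True).size().reset_index(name="n")
    counts["weight"] = counts["n"] / counts["n"].sum()
    return counts.drop(columns="n")


def reference_profile(draws: PosteriorDraws) -> pd.DataFrame:
    """Single all-reference-levels profile (every dummy zero)."""
    refs = {f: [r] for f, r in draws.spec.reference_levels.items()}
    out = pd.DataFrame(refs)
    out["weight"] = 1.0
    return out


def _profile_dummies(profiles: pd.DataFrame, draws: PosteriorDraws) -> np.ndarray:
    cols = draws.spec.gamma_columns
    Z = np.zeros((len(profiles), len(cols)))
    for j, col in enumerate(cols):
        factor, level = col[:-1].split("[", 1)
        Z[:, j] = (profiles[factor] == level).to_numpy(dtype=float)
    return Z


def posterior_predict(
    draws: PosteriorDraws,
    profiles: pd.DataFrame,
    ga_grid=DEFAULT_GA_GRID,
    n_samples: int = 4000,
    seed: int = 0,
) -> np.ndarray:
    """New-woman posterior-predictive GWG samples, shape (n_weeks, n_samples).

    ``profiles`` holds covariate levels plus a ``weight`` column (a
    distribution over profiles; typically :func:`empirical_profiles`).
    """
    if profiles is None or len(profiles) == 0:
        raise ChartError("profiles must be a nonempty profile table")
    w = profiles["weight"].to_numpy(dtype=float)
    if not np.all(w >= 0) or w.sum() <= 0:
        raise ChartError("profile weights must be nonnegative and sum > 0")
    w = w / w.sum()

    rng = np.random.default_rng([4, seed])
    ga = np.asarray(ga_grid, dtype=float)
    from .splines import evaluate_basis

    basis = evaluate_basis(draws.spec.spline, ga)  # (G, df)
    beta0 = draws.stacked("beta0")
    spline = draws.stacked("spline")
    gamma = draws.stacked("gamma")
    sigma_tau = draws.stacked("sigma_tau")
    sigma_eps = draws.stacked("sigma_eps")
    student = draws.spec.error_family == "student_t"
    nu = draws.stacked("error_df") if student else None
    total = beta0.size

    Z = _profile_dummies(profiles, draws)
    gamma_contrib = gamma @ Z.T  # (total, n_profiles)

    out = np.empty((ga.size, n_samples))
    for g in range(ga.size):
        idx = rng.integers(total, size=n_samples)
        prof = rng.choice(len(profiles), size=n_samples, p=w)
        mu = beta0[idx] + spline[idx] @ basis[g] + gamma_contrib[idx, prof]
        tau_star = sigma_tau[idx] * rng.standard_normal(n_samples)
        if student:
            eps = sigma_eps[idx] * rng.standard_t(nu[idx])
        else:
            eps = sigma_eps[idx] * rng.standard_normal(n_samples)
        out[g] = back_transform(mu + tau_star + eps, draws.spec.offset_constant)
    return out


def percentile_curves(
    samples: np.ndarray,
    levels=DEFAULT_LEVELS,
    ga_grid=DEFAULT_GA_GRID,
    bmi_category: str = "",
    provenance: dict | None = None,
) -> PercentileChart:
    """Empirical percentiles per week (linear-interpolation estimator).

    Percentiles of a common sample set are monotone in the level by
    construction, so the chart invariant holds exactly here.
    """
    samples = np.asarray(samples, dtype=float)
    levels = tuple(float(l) for l in levels)
    n = samples.shape[1] if samples.ndim == 2 else 0
    if levels:
        extreme = min(min(levels), 100 - max(levels))
        if extreme > 0 and n < 10 / (extreme / 100):
            warnings.warn(
                f"{n} samples is few for the {extreme}th percentile",
                stacklevel=2,
            )
    vals = np.percentile(samples, levels, axis=1).T  # (G, L)
    return PercentileChart(
        bmi_category=bmi_category,
        ga_grid=np.asarray(ga_grid, dtype=float),
        levels=levels,
        values=vals,
        provenance=dict(provenance or {}),
    )


def smooth_curves(chart: PercentileChart, smoothing: float | None = None) -> PercentileChart:
    """Smooth each percentile curve across weeks with a cubic smoothing spline.

    The smoothing parameter defaults to a per-curve noise estimate from
    second differences.  If smoothing breaks the cross-percentile ordering,
    an isotonic repair is applied (with a warning).  The maximum absolute
    change from the raw values is recorded in the provenance.
    """
    weeks = chart.ga_grid
    if weeks.size < 5:
        return PercentileChart(
            bmi_category=chart.bmi_category,
            ga_grid=weeks,
            levels=chart.levels,
            values=chart.values.copy(),
            provenance={**chart.provenance, "max_smoothing_change": 0.0},
        )
    out = np.empty_like(chart.values)
    for j in range(len(chart.levels)):
        y = chart.values[:, j]
        if smoothing is None:
            # third differences cancel smooth trend up to quadratics, leaving
            # ~N(0, 20 sigma^2) under iid sampling noise
            d3 = np.diff(y, 3)
            noise_var = float(np.median(d3**2)) / 20.0
            s = weeks.size * noise_var
        else:
            s = smoothing
        spl = UnivariateSpline(weeks, y, k=3, s=s)
        out[:, j] = spl(weeks)
    max_change = float(np.max(np.abs(out - chart.values)))
    if np.any(np.diff(out, axis=1) < 0):
        warnings.warn("smoothing broke percentile ordering; isotonic repair applied",
                      stacklevel=2)
        out = np.maximum.accumulate(out, axis=1)
    return PercentileChart(
        bmi_category=chart.bmi_category,
        ga_grid=weeks,
        levels=chart.levels,
        values=out,
        provenance={**chart.provenance, "max_smoothing_change": max_change},
    )


def build_chart(
    draws: PosteriorDraws,
    cohort: pd.DataFrame,
    bmi_category: str,
    ga_grid=DEFAULT_GA_GRID,
    levels=DEFAULT_LEVELS,
    n_samples: int = 4000,
    seed: int = 0,
    smooth: bool = True,
) -> PercentileChart:
    """Predictive samples -> raw percentiles -> smoothed chart, one stratum."""
    profiles = empirical_profiles(cohort)
    samples = posterior_predict(draws, profiles, ga_grid, n_samples, seed)
    lo, hi = draws.spec.spline.boundary_knots
    grid = np.asarray(ga_grid, dtype=float)
    chart = percentile_curves(
        samples, levels, ga_grid, bmi_category,
        provenance={
            "seed": seed,
            "n_samples": n_samples,
            "spline": draws.spec.spline.to_json(),
            # weeks beyond the fitted GA range rely on linear extrapolation
            "extrapolated_weeks": [float(w) for w in grid[(grid < lo) | (grid > hi)]],
        },
    )
    return smooth_curves(chart) if smooth else chart


def plot_chart(chart: PercentileChart, ax=None):
    """Matplotlib rendering of the percentile chart (optional output)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for j, lv in enumerate(chart.levels):
        ax.plot(chart.ga_grid, chart.values[:, j], label=f"P{lv:g}")
    ax.set_xlabel("gestational age (weeks)")
    ax.set_ylabel("gestational weight gain (kg)")
    ax.set_title(chart.bmi_category)
    ax.legend()
    return ax
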