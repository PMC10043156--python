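"""Trajectory bands: the week-by-week GWG corridor that meets a guideline.

The 2021 JSOG guideline states a total-gain interval at 40 weeks per
pre-pregnancy BMI category.  A trajectory band inverts the percentile chart
at week 40 — which percentile does each guideline endpoint correspond
to? — and then follows those two percentile curves back through pregnancy.
A woman tracking inside the band is, under the fitted population model, on
course to land inside the guideline interval at 40 weeks.  The obese
guideline is one-sided (at most 5 kg), so its band has an upper curve only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charts import PercentileChart


class BandError(ValueError):
    pass


class UndefinedProportionError(RuntimeError):
    """No woman has a qualifying terminal measurement."""


def load_guidelines(path=None) -> dict:
    """Guideline targets from a YAML file (default: the bundled JSOG 2021
    set), as {bmi_category: (lower_or_None, upper)} in kg at 40 weeks."""
    import yaml

    if path is None:
        from importlib import resources

        with resources.files("gwgcharts.data").joinpath(
            "guidelines_jsog2021.yaml"
        ).open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {k: (None if v[0] is None else float(v[0]), float(v[1]))
            for k, v in raw.items()}


#: JSOG 2021 recommended total GWG at 40 weeks, kg: (lower, upper);
#: ``None`` lower bound means the recommendation is one-sided (at most).
JSOG_2021 = load_guidelines()


@dataclass(frozen=True)
class GuidelineSpec:
    targets: dict = field(default_factory=lambda: dict(JSOG_2021))
    anchor_week: float = 40.0

    def __post_init__(self):
        for cat, (lo, hi) in self.targets.items():
            if lo is not None and not lo < hi:
                raise BandError(f"guideline for {cat!r}: lower must be < upper")


@dataclass
class TrajectoryBand:
    bmi_category: str
    ga_grid: np.ndarray
    upper_kg: np.ndarray
    lower_kg: np.ndarray | None  # None for a one-sided (upper-only) band
    q_low: float | None
    q_high: float
    anchor_week: float = 40.0

    def bounds_at(self, week) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) interpolated at arbitrary weeks; lower is -inf
        for a one-sided band."""
        week = np.asarray(week, dtype=float)
        upper = np.interp(week, self.ga_grid, self.upper_kg)
        if self.lower_kg is None:
            lower = np.full_like(upper, -np.inf)
        else:
            lower = np.interp(week, self.ga_grid, self.lower_kg)
        return lower, upper

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.ga_grid):
            if self.lower_kg is not None:
                rows.append({"week": w, "bound": "lower", "gwg_kg": self.lower_kg[i]})
            rows.append({"week": w, "bound": "upper", "gwg_kg": self.upper_kg[i]})
        return pd.DataFrame(rows)


def invert_percentile(chart: PercentileChart, week: float, target_kg: float) -> float:
    """Percentile level q whose chart value at ``week`` equals ``target_kg``.

    Linear interpolation across the percentile dimension (the same
    interpolation used to evaluate the chart between levels, so inversion
    and evaluation are exact inverses of one another).  Targets outside the
    charted range clamp to the extreme level, with a warning.
    """
    if not chart.is_monotone():
        raise BandError("chart violates percentile monotonicity; cannot invert")
    col = np.array(
        [np.interp(week, chart.ga_grid, chart.values[:, j])
         for j in range(len(chart.levels))]
    )
    if target_kg < col[0] or target_kg > col[-1]:
        warnings.warn(
            f"target {target_kg} kg outside charted range "
            f"[{col[0]:.2f}, {col[-1]:.2f}] at week {week}; clamped",
            stacklevel=2,
        )
        return float(chart.levels[0] if target_kg < col[0] else chart.levels[-1])
    return float(np.interp(target_kg, col, np.asarray(chart.levels, dtype=float)))


def build_band(
    chart: PercentileChart,
    guideline: GuidelineSpec | None = None,
) -> TrajectoryBand:
    """Invert the guideline endpoints at the anchor week and follow the two
    percentile curves across the grid.

    By construction the band at the anchor week reproduces the guideline
    interval to interpolation precision.
    """
    guideline = guideline or GuidelineSpec()
    cat = chart.bmi_category
    if cat not in guideline.targets:
        raise BandError(f"no guideline for BMI category {cat!r}")
    lo_kg, hi_kg = guideline.targets[cat]
    week = guideline.anchor_week
    if week < chart.ga_grid[0] or week > chart.ga_grid[-1]:
        raise BandError(f"chart grid does not cover the anchor week {week}")

    col = np.array(
        [np.interp(week, chart.ga_grid, chart.values[:, j])
         for j in range(len(chart.levels))]
    )
    for target in ([hi_kg] if lo_kg is None else [lo_kg, hi_kg]):
        if target < col[0] or target > col[-1]:
            raise BandError(
                f"guideline endpoint {target} kg outside the chart's range "
                f"[{col[0]:.2f}, {col[-1]:.2f}] at week {week} for {cat!r}"
            )

    q_high = invert_percentile(chart, week, hi_kg)
    upper = chart.curve(q_high)
    if lo_kg is None:
        return TrajectoryBand(cat, chart.ga_grid.copy(), upper, None, None, q_high, week)
    q_low = invert_percentile(chart, week, lo_kg)
    lower = chart.curve(q_low)
    return TrajectoryBand(cat, chart.ga_grid.copy(), upper, lower, q_low, q_high, week)


def fraction_within_band(
    cohort: pd.DataFrame, band: TrajectoryBand, min_terminal_ga: float = 37.0
) -> float:
    """Proportion of women whose terminal GWG lies inside the band.

    The terminal measurement is each woman's last visit, required to fall at
    or after ``min_terminal_ga`` weeks; the band bounds are interpolated at
    that gestational age.
    """
    sub = cohort[cohort["bmi_category"] == band.bmi_category] if (
        "bmi_category" in cohort.columns
    ) else cohort
    last = sub.sort_values("ga_weeks").groupby("woman_id").tail(1)
    last = last[last["ga_weeks"] >= min_terminal_ga]
    if last.empty:
        raise UndefinedProportionError(
            f"no woman has a measurement at >= {min_terminal_ga} weeks"
        )
    lower, upper = band.bounds_at(last["ga_weeks"].to_numpy())
    g = last["gwg_kg"].to_numpy()
    return float(np.mean((g >= lower) & (g <= upper)))
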