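"""Hold-out validation of charts and the sensitivity-analysis harness.

Charts are trained on 80% of women and validated on the held-out 20%: for a
calibrated chart, the fraction of held-out observations falling below the
p-th percentile curve should be p/100, up to binomial error.  The split is
always by woman — a woman's visits never straddle train and test, because
her random intercept correlates them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import charts as _charts
from .charts import PercentileChart
from .model import ModelSpec, PosteriorDraws, SamplerConfig, build_design, fit, summarize


class SplitError(ValueError):
    pass


def split_cohort(
    cohort: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Woman-level train/test split; disjoint, exhaustive, reproducible."""
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must be strictly between 0 and 1")
    women = cohort["woman_id"].unique()
    n_train = int(round(train_fraction * women.size))
    if n_train == 0 or n_train == women.size:
        raise SplitError(
            f"split of {women.size} women at fraction {train_fraction} leaves "
            "an empty side"
        )
    rng = np.random.default_rng([5, seed])
    shuffled = rng.permutation(women)
    train_ids = set(shuffled[:n_train].tolist())
    in_train = cohort["woman_id"].isin(train_ids)
    return cohort[in_train].copy(), cohort[~in_train].copy()


def coverage_report(
    chart: PercentileChart,
    test_cohort: pd.DataFrame,
    levels: Sequence[float] | None = None,
    ci_prob: float = 0.95,
) -> pd.DataFrame:
    """Observed vs expected fraction of held-out observations below each
    percentile curve, with exact (Clopper-Pearson) binomial intervals.

    The frame's ``attrs['fit']`` is True when every level's confidence
    interval contains its nominal fraction — the operational reading of the
    curves 'fitting' the validation data.
    """
    levels = list(chart.levels if levels is None else levels)
    rows = []
    ga = test_cohort["ga_weeks"].to_numpy(dtype=float)
    gwg = test_cohort["gwg_kg"].to_numpy(dtype=float)
    n = ga.size
    for p in levels:
        curve = chart.curve(p)
        at_obs = np.interp(ga, chart.ga_grid, curve)
        k = int(np.sum(gwg < at_obs))
        if n:
            ci = stats.binomtest(k, n).proportion_ci(
                confidence_level=ci_prob, method="exact"
            )
            lo, hi = float(ci.low), float(ci.high)
            obs = k / n
        else:
            lo = hi = obs = np.nan
        rows.append(
            {
                "percentile": p,
                "expected": p / 100.0,
                "observed": obs,
                "n": n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["covered"] = (out["ci_low"] <= out["expected"]) & (
            out["expected"] <= out["ci_high"]
        )
        out.attrs["fit"] = bool(out["covered"].all())
    else:
        out.attrs["fit"] = True
    return out


@dataclass(frozen=True)
class Variant:
    """One sensitivity-analysis arm: prior overrides and/or error family."""

    name: str
    priors: object | None = None  # PriorSpec override
    error_family: str | None = None


def sensitivity_run(
    cohort: pd.DataFrame,
    base_spec: ModelSpec,
    variants: Sequence[Variant],
    sampler: SamplerConfig | None = None,
    ga_grid=None,
    predict_seed: int = 0,
) -> pd.DataFrame:
    """Refit under each variant and report how much the answers move.

    For every variant: the maximum absolute change in posterior medians of
    the regression coefficients, and the maximum absolute change of the
    median (50th percentile) predictive curve in kg.  A variant that fails
    is recorded in the table, not raised.
    """
    if not variants:
        raise ValueError("need at least one variant")
    sampler = sampler or SamplerConfig()
    ga_grid = _charts.DEFAULT_GA_GRID if ga_grid is None else np.asarray(ga_grid)

    def _fit_one(spec: ModelSpec) -> tuple[PosteriorDraws, pd.Series, np.ndarray]:
        design = build_design(cohort, spec)
        draws = fit(design, sampler)
        summ = summarize(draws)
        medians = summ["median"]
        profiles = _charts.empirical_profiles(cohort)
        samples = _charts.posterior_predict(
            draws, profiles, ga_grid, n_samples=2000, seed=predict_seed
        )
        curve50 = np.percentile(samples, 50.0, axis=1)
        return draws, medians, curve50

    _, base_medians, base_curve = _fit_one(base_spec)
    shared = [ix for ix in base_medians.index if not ix.startswith("tau")]

    rows = []
    for variant in variants:
        spec = base_spec
        if variant.priors is not None:
            spec = replace(spec, priors=variant.priors)
        if variant.error_family is not None:
            spec = replace(spec, error_family=variant.error_family)
        try:
            draws, medians, curve50 = _fit_one(spec)
            common = [ix for ix in shared if ix in medians.index]
            delta_coef = float(
                np.max(np.abs(medians[common].to_numpy() - base_medians[common].to_numpy()))
            )
            gamma_ix = [ix for ix in common if "[" in ix]
            delta_gamma = float(
                np.max(np.abs(medians[gamma_ix].to_numpy()
                              - base_medians[gamma_ix].to_numpy()))
            ) if gamma_ix else np.nan
            delta_curve = float(np.max(np.abs(curve50 - base_curve)))
            rows.append(
                {
                    "variant": variant.name,
                    "max_abs_delta_median": delta_coef,
                    "max_abs_delta_gamma_median": delta_gamma,
                    "max_abs_delta_p50_kg": delta_curve,
                    "converged": not any("R-hat" in w for w in draws.warnings),
                    "error": "",
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "variant": variant.name,
                    "max_abs_delta_median": np.nan,
                    "max_abs_delta_gamma_median": np.nan,
                    "max_abs_delta_p50_kg": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows).set_index("variant")
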