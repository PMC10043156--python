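"""Published JECS coefficient summaries used as generator defaults.

The bundled table holds the published posterior summaries (log-scale
medians, their exponentials, posterior SDs, 95% HDIs and ESS) of the
maternal-characteristic effects per pre-pregnancy BMI stratum from the JECS
gestational-weight-gain analysis.  The synthetic-cohort generator uses the
log-scale medians and the random-intercept SDs as its ground truth, and the
exponentiation-consistency check replays the median -> multiplicative-effect
conversion against the published pairs.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


@lru_cache(maxsize=1)
def load_reference_effects() -> pd.DataFrame:
    with resources.files("gwgcharts.data").joinpath("reference_effects.csv").open() as fh:
        return pd.read_csv(fh)


def reference_gamma(bmi_category: str) -> dict[tuple[str, str], float]:
    """Non-reference covariate coefficients (log scale) for one stratum."""
    df = load_reference_effects()
    rows = df[(df["bmi_category"] == bmi_category) & (df["factor"] != "sd_intercept")]
    if rows.empty:
        raise KeyError(f"unknown BMI category: {bmi_category!r}")
    return {
        (r.factor, r.level): float(r.median_log) for r in rows.itertuples(index=False)
    }


def reference_sigma_tau(bmi_category: str) -> float:
    """Published between-woman intercept SD (log scale) for one stratum."""
    df = load_reference_effects()
    rows = df[(df["bmi_category"] == bmi_category) & (df["factor"] == "sd_intercept")]
    if rows.empty:
        raise KeyError(f"unknown BMI category: {bmi_category!r}")
    return float(rows["median_log"].iloc[0])
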