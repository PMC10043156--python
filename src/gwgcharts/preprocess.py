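"""Raw antenatal weight records -> analysis-ready gestational weight gain.

Gestational weight gain (GWG) at a visit is the measured weight minus the
pre-pregnancy weight.  Preprocessing applies, in order: delivery/late-visit
deduplication, the implausibility filter, covariate categorisation, and the
eligibility rule (live birth, known gestational age, at least three valid
measurements).

Expected raw long format (one row per woman-visit):
``woman_id, live_birth, ga_known, prepreg_weight_kg, prepreg_height_cm,
age_years, parity, smoking, previous_disease, visit_label, ga_weeks,
weight_kg`` where ``visit_label`` is one of ``early, mid, late, delivery``
and ``smoking``/``previous_disease`` may be missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
AGE_BANDS = ("<=25", "26-34", ">=35")
HEIGHT_BANDS = ("<=155", "156-161", ">=162")
PARITY_LEVELS = ("multipara", "primipara")
SMOKING_LEVELS = ("never", "quit_before", "quit_after", "during", "missing")
DISEASE_LEVELS = ("no", "yes", "missing")

#: GWG values outside (GWG_LOWER, GWG_UPPER) kg are implausible; the bounds
#: themselves are plausible ("over 30 / under -10" read strictly).
GWG_LOWER = -10.0
GWG_UPPER = 30.0

COHORT_COLUMNS = [
    "woman_id",
    "bmi_category",
    "age_band",
    "height_band",
    "parity",
    "smoking",
    "previous_disease",
    "visit_index",
    "ga_weeks",
    "gwg_kg",
]


class ValidationError(ValueError):
    """Raw measurement outside the physically admissible range."""


class EmptyCohortError(RuntimeError):
    """No eligible women remain after the eligibility rules."""


def compute_gwg(visit_weight, prepregnancy_weight):
    """Weight gain in kg: visit/delivery measurement minus pre-pregnancy weight."""
    vw = np.asarray(visit_weight, dtype=float)
    pw = np.asarray(prepregnancy_weight, dtype=float)
    if np.any(vw <= 0) or np.any(pw <= 0):
        raise ValidationError("weights must be positive")
    return vw - pw


def filter_implausible(
    table: pd.DataFrame, lower: float = GWG_LOWER, upper: float = GWG_UPPER
) -> pd.DataFrame:
    """Drop rows with implausible GWG (strictly over ``upper`` or under ``lower``)."""
    keep = (table["gwg_kg"] >= lower) & (table["gwg_kg"] <= upper)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_implausible removed %d rows", n_removed)
    return table.loc[keep].copy()


def dedupe_delivery(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a late-pregnancy visit identical to the delivery measurement.

    When the late visit and the delivery share the same weight and
    gestational age (the late visit happened at delivery), only the delivery
    row is kept.
    """
    def _drop(group: pd.DataFrame) -> pd.DataFrame:
        late = group[group["visit_label"] == "late"]
        deliv = group[group["visit_label"] == "delivery"]
        if len(late) == 1 and len(deliv) == 1:
            same = (
                late["weight_kg"].iloc[0] == deliv["weight_kg"].iloc[0]
                and late["ga_weeks"].iloc[0] == deliv["ga_weeks"].iloc[0]
            )
            if same:
                return group.drop(index=late.index)
        return group

    parts = [_drop(g) for _, g in table.groupby("woman_id", sort=False)]
    return pd.concat(parts, ignore_index=False) if parts else table.copy()


def categorize_bmi(weight_kg, height_m):
    """Pre-pregnancy BMI category: underweight <18.5, normal 18.5-24.9,
    overweight 25.0-29.9, obese >=30 kg/m^2 (bins left-closed)."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any((h <= 1.0) | (h >= 2.2)):
        raise ValidationError("height must be in (1.0, 2.2) m")
    if np.any((w <= 25) | (w >= 200)):
        raise ValidationError("weight must be in (25, 200) kg")
    bmi = w / h**2
    idx = np.digitize(bmi, [18.5, 25.0, 30.0], right=False)
    cats = np.take(BMI_CATEGORIES, idx)
    return cats.item() if np.isscalar(weight_kg) else cats


def categorize_age(age_years) -> np.ndarray:
    a = np.asarray(age_years, dtype=float)
    idx = np.digitize(a, [25.0, 34.0], right=True)  # <=25, 26-34, >=35
    out = np.take(AGE_BANDS, idx)
    return out.item() if np.isscalar(age_years) else out


def categorize_height(height_cm) -> np.ndarray:
    # Continuous thresholds: [155, 162) is the middle band, labelled per the
    # cohort's descriptive-table convention.
    h = np.asarray(height_cm, dtype=float)
    idx = np.digitize(h, [155.0, 162.0], right=False)
    out = np.take(HEIGHT_BANDS, idx)
    return out.item() if np.isscalar(height_cm) else out


def _fill_missing_level(values, levels) -> pd.Series:
    s = pd.Series(values, dtype=object)
    s = s.where(s.notna() & (s != ""), "missing")
    bad = ~s.isin(levels)
    if bad.any():
        raise ValidationError(f"unknown level(s): {sorted(s[bad].unique())}")
    return s


def categorize_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Band continuous covariates and map absent answers to a 'missing' level.

    Missingness in smoking / previous-disease is an analysis level of its
    own, never an error: the model estimates an effect for it.
    """
    out = pd.DataFrame(index=raw.index)
    out["age_band"] = categorize_age(raw["age_years"].to_numpy())
    out["height_band"] = categorize_height(raw["prepreg_height_cm"].to_numpy())
    out["parity"] = _fill_missing_level(raw["parity"], PARITY_LEVELS)
    out["smoking"] = _fill_missing_level(raw["smoking"], SMOKING_LEVELS)
    out["previous_disease"] = _fill_missing_level(
        raw["previous_disease"], DISEASE_LEVELS
    )
    return out


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep live births with known gestational age and >= 3 valid GWG rows.

    ``records`` must already carry ``gwg_kg`` (post-filter: the measurement
    count is taken after the implausibility filter, the stricter reading).
    Returns the eligible visit rows and an exclusion tally by reason, counted
    in women with a first-matching-reason precedence
    (stillbirth > unknown gestational age > fewer than 3 measures).
    """
    tally = {"stillbirth": 0, "unknown_gestational_age": 0, "fewer_than_3_measures": 0}
    kept = []
    for _, group in records.groupby("woman_id", sort=False):
        if not bool(group["live_birth"].iloc[0]):
            tally["stillbirth"] += 1
        elif not bool(group["ga_known"].iloc[0]):
            tally["unknown_gestational_age"] += 1
        elif len(group) < 3:
            tally["fewer_than_3_measures"] += 1
        else:
            kept.append(group)
    if not kept:
        raise EmptyCohortError(f"no eligible women remain (exclusions: {tally})")
    return pd.concat(kept, ignore_index=False), tally


def preprocess_raw(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full raw-records pipeline: GWG, dedupe, filter, categorise, eligibility.

    Returns the analysis-ready cohort table (one row per woman-visit, sorted
    by woman and gestational age) and the exclusion tally.
    """
    work = raw.copy()
    work["gwg_kg"] = compute_gwg(
        work["weight_kg"].to_numpy(), work["prepreg_weight_kg"].to_numpy()
    )
    work = dedupe_delivery(work)
    work = filter_implausible(work)
    work, tally = apply_eligibility(work)

    per_woman = work.drop_duplicates("woman_id").set_index("woman_id")
    cats = categorize_covariates(per_woman)
    cats["bmi_category"] = categorize_bmi(
        per_woman["prepreg_weight_kg"].to_numpy(),
        per_woman["prepreg_height_cm"].to_numpy() / 100.0,
    )

    work = work.sort_values(["woman_id", "ga_weeks"], kind="mergesort")
    work["visit_index"] = work.groupby("woman_id", sort=False).cumcount() + 1
    work = work.drop(columns=[c for c in cats.columns if c in work.columns])
    merged = work.merge(cats, left_on="woman_id", right_index=True, how="left")
    return merged[COHORT_COLUMNS].reset_index(drop=True), tally
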