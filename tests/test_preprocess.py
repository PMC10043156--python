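import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwgcharts.preprocess import (
    BMI_CATEGORIES,
    EmptyCohortError,
    ValidationError,
    apply_eligibility,
    categorize_age,
    categorize_bmi,
    categorize_covariates,
    categorize_height,
    compute_gwg,
    dedupe_delivery,
    filter_implausible,
    preprocess_raw,
)


def test_gwg_is_visit_minus_prepregnancy_weight():
    assert compute_gwg(64.0, 53.1) == pytest.approx(10.9)
    assert compute_gwg(53.1, 53.1) == 0.0
    assert compute_gwg(58.0, 70.0) == pytest.approx(-12.0)
    with pytest.raises(ValidationError):
        compute_gwg(-1.0, 50.0)


def test_implausibility_filter_boundaries_are_strict():
    """'over 30 / under -10' keeps the bounds themselves."""
    table = pd.DataFrame({"gwg_kg": [30.0, 31.0, -10.0, -10.5, 0.0]})
    kept = filter_implausible(table)
    assert sorted(kept["gwg_kg"]) == [-10.0, 0.0, 30.0]


@given(st.lists(st.floats(-40, 60, allow_nan=False), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_implausibility_filter_is_idempotent(values):
    table = pd.DataFrame({"gwg_kg": values})
    once = filter_implausible(table)
    twice = filter_implausible(once)
    pd.testing.assert_frame_equal(once, twice)


def _visit_frame(rows):
    return pd.DataFrame(
        rows, columns=["woman_id", "visit_label", "weight_kg", "ga_weeks"]
    )


def test_identical_late_and_delivery_rows_collapse_to_delivery():
    table = _visit_frame(
        [(1, "late", 70.0, 38.0), (1, "delivery", 70.0, 38.0)]
    )
    out = dedupe_delivery(table)
    assert len(out) == 1 and out["visit_label"].iloc[0] == "delivery"

    distinct = _visit_frame([(1, "late", 69.0, 37.0), (1, "delivery", 70.0, 38.0)])
    assert len(dedupe_delivery(distinct)) == 2

    only_delivery = _visit_frame([(1, "delivery", 70.0, 38.0)])
    pd.testing.assert_frame_equal(dedupe_delivery(only_delivery), only_delivery)


@pytest.mark.parametrize(
    "bmi,expected",
    [
        (18.4, "underweight"),
        (18.5, "normal"),
        (24.9, "normal"),
        (25.0, "overweight"),
        (29.9, "overweight"),
        (30.0, "obese"),
    ],
)
def test_bmi_bin_edges(bmi, expected):
    height = 1.60
    assert categorize_bmi(bmi * height**2, height) == expected


@given(st.floats(30.0, 150.0), st.floats(1.3, 2.0))
@settings(max_examples=100, deadline=None)
def test_every_bmi_maps_to_exactly_one_category(weight, height):
    assert categorize_bmi(weight, height) in BMI_CATEGORIES


def test_anthropometry_validation():
    with pytest.raises(ValidationError):
        categorize_bmi(60.0, 0.9)
    with pytest.raises(ValidationError):
        categorize_bmi(20.0, 1.6)


def test_age_and_height_band_edges():
    assert categorize_age(25.0) == "<=25"
    assert categorize_age(26.0) == "26-34"
    assert categorize_age(34.0) == "26-34"
    assert categorize_age(35.0) == ">=35"
    assert categorize_height(154.9) == "<=155"
    assert categorize_height(155.0) == "156-161"
    assert categorize_height(161.9) == "156-161"
    assert categorize_height(162.0) == ">=162"


def test_missing_answers_become_a_level_not_an_error():
    raw = pd.DataFrame(
        {
            "age_years": [24.0, 36.0],
            "prepreg_height_cm": [150.0, 165.0],
            "parity": ["multipara", "primipara"],
            "smoking": [None, "during"],
            "previous_disease": ["yes", None],
        }
    )
    out = categorize_covariates(raw)
    assert out["smoking"].tolist() == ["missing", "during"]
    assert out["previous_disease"].tolist() == ["yes", "missing"]


def _records(women):
    rows = []
    for wid, live, ga_known, n_rows in women:
        for j in range(n_rows):
            rows.append(
                {
                    "woman_id": wid,
                    "live_birth": live,
                    "ga_known": ga_known,
                    "ga_weeks": 10.0 + 9 * j,
                    "gwg_kg": 1.0 + 3 * j,
                }
            )
    return pd.DataFrame(rows)


def test_eligibility_rules_and_tally():
    records = _records(
        [(1, 1, 1, 4), (2, 1, 1, 2), (3, 0, 1, 4), (4, 1, 0, 3), (5, 1, 1, 3)]
    )
    kept, tally = apply_eligibility(records)
    assert set(kept["woman_id"]) == {1, 5}
    assert tally == {
        "stillbirth": 1,
        "unknown_gestational_age": 1,
        "fewer_than_3_measures": 1,
    }
    n_in = records["woman_id"].nunique()
    assert n_in - kept["woman_id"].nunique() == sum(tally.values())


def test_empty_eligible_set_raises():
    with pytest.raises(EmptyCohortError):
        apply_eligibility(_records([(1, 0, 1, 4)]))


def test_preprocess_raw_end_to_end():
    rows = []
    # woman 1: four clean visits
    for label, ga, w in [("early", 10.0, 51.0), ("mid", 22.0, 55.0),
                         ("late", 33.0, 58.0), ("delivery", 39.0, 61.0)]:
        rows.append(dict(woman_id=1, live_birth=1, ga_known=1,
                         prepreg_weight_kg=50.0, prepreg_height_cm=158.0,
                         age_years=30, parity="multipara", smoking="never",
                         previous_disease="no", visit_label=label,
                         ga_weeks=ga, weight_kg=w))
    # woman 2: identical late/delivery rows plus an implausible spike
    for label, ga, w in [("early", 11.0, 46.0), ("mid", 23.0, 50.0),
                         ("late", 38.0, 90.0), ("delivery", 38.0, 90.0)]:
        rows.append(dict(woman_id=2, live_birth=1, ga_known=1,
                         prepreg_weight_kg=45.0, prepreg_height_cm=150.0,
                         age_years=24, parity="primipara", smoking=None,
                         previous_disease="no", visit_label=label,
                         ga_weeks=ga, weight_kg=w))
    cohort, tally = preprocess_raw(pd.DataFrame(rows))
    w1 = cohort[cohort["woman_id"] == 1]
    assert list(w1["gwg_kg"]) == [1.0, 5.0, 8.0, 11.0]
    assert np.all(np.diff(w1["ga_weeks"]) > 0)
    assert w1["bmi_category"].iloc[0] == "normal"
    # woman 2: dedupe keeps delivery, the +45 kg row is implausible -> 2 rows
    assert tally["fewer_than_3_measures"] == 1
    assert set(cohort["woman_id"]) == {1}
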