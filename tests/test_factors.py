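"""Categorisation of raw measurements into the protocol's risk bands."""

import warnings

import numpy as np
import pytest
import yaml

from mpras import (
    DEFAULT_THRESHOLDS,
    EyeMeasurements,
    GapWarning,
    MissingMeasurementError,
    PatientRecord,
    RiskCategory,
    RiskFactor,
    ThresholdTable,
    categorize_factor,
)

LOW, INT, HIGH = RiskCategory.LOW, RiskCategory.INTERMEDIATE, RiskCategory.HIGH


def make_record(**kw):
    defaults = dict(
        patient_id="X",
        age_at_presentation_yr=15.0,
        age_of_onset_yr=10.0,
        myopic_parents=0,
        outdoors_h_per_day=3.0,
        nearwork_h_per_day=5.0,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


def make_eye(**kw):
    defaults = dict(ser_d=-2.0)
    defaults.update(kw)
    return EyeMeasurements(**defaults)


@pytest.mark.parametrize(
    "factor, record_kw, eye_kw, expected",
    [
        # change in SER (D/yr): bands > -0.50 / [-0.75, -0.50] / < -0.75
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"ser_change_d_per_yr": -0.25}, LOW),
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"ser_change_d_per_yr": -0.50}, INT),
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"ser_change_d_per_yr": -0.75}, INT),
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"ser_change_d_per_yr": -0.76}, HIGH),
        # change in AL (mm/yr): < 0.10 / [0.10, 0.20) / >= 0.20
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"al_change_mm_per_yr": 0.05}, LOW),
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"al_change_mm_per_yr": 0.10}, INT),
        (RiskFactor.CHANGE_SER_OR_AL, {}, {"al_change_mm_per_yr": 0.20}, HIGH),
        # both signals present: the more severe wins
        (
            RiskFactor.CHANGE_SER_OR_AL,
            {},
            {"ser_change_d_per_yr": -0.10, "al_change_mm_per_yr": 0.25},
            HIGH,
        ),
        # ages: >= 18 LOW / <= 13 HIGH / between INT
        (RiskFactor.AGE_AT_PRESENTATION, {"age_at_presentation_yr": 12.0}, {}, HIGH),
        (RiskFactor.AGE_AT_PRESENTATION, {"age_at_presentation_yr": 13.0}, {}, HIGH),
        (RiskFactor.AGE_AT_PRESENTATION, {"age_at_presentation_yr": 15.0}, {}, INT),
        (RiskFactor.AGE_AT_PRESENTATION, {"age_at_presentation_yr": 17.5}, {}, INT),
        (RiskFactor.AGE_AT_PRESENTATION, {"age_at_presentation_yr": 18.0}, {}, LOW),
        (RiskFactor.AGE_OF_ONSET, {"age_of_onset_yr": 6.0}, {}, HIGH),
        (
            RiskFactor.AGE_OF_ONSET,
            {"age_of_onset_yr": 18.0, "age_at_presentation_yr": 20.0},
            {},
            LOW,
        ),
        # SER at presentation: >= -3.00 LOW / <= -6.00 HIGH
        (RiskFactor.SER_AT_PRESENTATION, {}, {"ser_d": -3.00}, LOW),
        (RiskFactor.SER_AT_PRESENTATION, {}, {"ser_d": -4.50}, INT),
        (RiskFactor.SER_AT_PRESENTATION, {}, {"ser_d": -6.00}, HIGH),
        # time outdoors: > 2 LOW / [1, 2] INT / < 1 HIGH
        (RiskFactor.TIME_OUTDOORS, {"outdoors_h_per_day": 2.01}, {}, LOW),
        (RiskFactor.TIME_OUTDOORS, {"outdoors_h_per_day": 2.0}, {}, INT),
        (RiskFactor.TIME_OUTDOORS, {"outdoors_h_per_day": 1.0}, {}, INT),
        (RiskFactor.TIME_OUTDOORS, {"outdoors_h_per_day": 0.99}, {}, HIGH),
        # RPR on the worse meridian: < .25 / [.25, .50] / > .50
        (RiskFactor.RPR_AT_PRESENTATION, {}, {"rpr_nasal_d": 0.0, "rpr_temporal_d": 0.2}, LOW),
        (RiskFactor.RPR_AT_PRESENTATION, {}, {"rpr_nasal_d": 0.25, "rpr_temporal_d": -1.0}, INT),
        (RiskFactor.RPR_AT_PRESENTATION, {}, {"rpr_nasal_d": 0.50}, INT),
        (RiskFactor.RPR_AT_PRESENTATION, {}, {"rpr_nasal_d": 0.51, "rpr_temporal_d": 0.0}, HIGH),
        # near work: <= 7 / (7, 10] / > 10
        (RiskFactor.TIME_NEARWORK, {"nearwork_h_per_day": 7.0}, {}, LOW),
        (RiskFactor.TIME_NEARWORK, {"nearwork_h_per_day": 10.0}, {}, INT),
        (RiskFactor.TIME_NEARWORK, {"nearwork_h_per_day": 10.01}, {}, HIGH),
        # near phoria: <= 2 (all exophoria) / (2, 6) / >= 6
        (RiskFactor.NEAR_ESOPHORIA, {}, {"near_phoria_pd": -10.0}, LOW),
        (RiskFactor.NEAR_ESOPHORIA, {}, {"near_phoria_pd": 2.0}, LOW),
        (RiskFactor.NEAR_ESOPHORIA, {}, {"near_phoria_pd": 4.0}, INT),
        (RiskFactor.NEAR_ESOPHORIA, {}, {"near_phoria_pd": 6.0}, HIGH),
        # accommodative error: lead and small lag LOW; > 1.00 HIGH
        (RiskFactor.ACCOMMODATIVE_LAG, {}, {"accom_error_d": -0.50}, LOW),
        (RiskFactor.ACCOMMODATIVE_LAG, {}, {"accom_error_d": 0.50}, LOW),
        (RiskFactor.ACCOMMODATIVE_LAG, {}, {"accom_error_d": 0.75}, INT),
        (RiskFactor.ACCOMMODATIVE_LAG, {}, {"accom_error_d": 1.00}, INT),
        (RiskFactor.ACCOMMODATIVE_LAG, {}, {"accom_error_d": 1.25}, HIGH),
        # parental myopia: 0 / 1 / 2
        (RiskFactor.MYOPIC_PARENTS, {"myopic_parents": 0}, {}, LOW),
        (RiskFactor.MYOPIC_PARENTS, {"myopic_parents": 1}, {}, INT),
        (RiskFactor.MYOPIC_PARENTS, {"myopic_parents": 2}, {}, HIGH),
    ],
)
def test_protocol_bands(factor, record_kw, eye_kw, expected):
    record = make_record(**record_kw)
    assert categorize_factor(factor, record, make_eye(**eye_kw)) == expected


def test_lag_gap_maps_to_intermediate_with_warning():
    rec, eye = make_record(), make_eye(accom_error_d=0.60)
    with pytest.warns(GapWarning):
        cat = categorize_factor(RiskFactor.ACCOMMODATIVE_LAG, rec, eye)
    assert cat == INT


def test_missing_measurement_names_the_factor():
    rec = make_record()
    eye = make_eye()  # only SER present
    with pytest.raises(MissingMeasurementError) as exc:
        categorize_factor(RiskFactor.CHANGE_SER_OR_AL, rec, eye)
    assert "change_ser_or_al" in str(exc.value)
    with pytest.raises(MissingMeasurementError):
        categorize_factor(RiskFactor.NEAR_ESOPHORIA, rec, eye)
    with pytest.raises(MissingMeasurementError):
        categorize_factor(RiskFactor.RPR_AT_PRESENTATION, rec, None)


FACTOR_GRIDS = {
    RiskFactor.AGE_AT_PRESENTATION: ("age", np.linspace(6, 29, 231)),
    RiskFactor.AGE_OF_ONSET: ("onset", np.linspace(0.3, 18, 178)),
    RiskFactor.SER_AT_PRESENTATION: ("ser", np.linspace(-16.5, -0.5, 321)),
    RiskFactor.TIME_OUTDOORS: ("outdoors", np.linspace(0, 8, 161)),
    RiskFactor.RPR_AT_PRESENTATION: ("rpr", np.linspace(-3, 3, 241)),
    RiskFactor.TIME_NEARWORK: ("nearwork", np.linspace(0, 16, 321)),
    RiskFactor.NEAR_ESOPHORIA: ("phoria", np.linspace(-25, 16, 411)),
    RiskFactor.ACCOMMODATIVE_LAG: ("lag", np.linspace(-1.5, 2.5, 401)),
    RiskFactor.CHANGE_SER_OR_AL: ("chg", np.linspace(-4, 0.5, 451)),
}

BOUNDARY_CONSTANTS = {
    RiskFactor.AGE_AT_PRESENTATION: [13.0, 18.0],
    RiskFactor.AGE_OF_ONSET: [13.0, 18.0],
    RiskFactor.SER_AT_PRESENTATION: [-6.0, -3.0],
    RiskFactor.TIME_OUTDOORS: [1.0, 2.0],
    RiskFactor.RPR_AT_PRESENTATION: [0.25, 0.50],
    RiskFactor.TIME_NEARWORK: [7.0, 10.0],
    RiskFactor.NEAR_ESOPHORIA: [2.0, 6.0],
    RiskFactor.ACCOMMODATIVE_LAG: [0.50, 0.75, 1.00],
    RiskFactor.CHANGE_SER_OR_AL: [-0.75, -0.50],
}


def _categorize_value(factor, v):
    rec_kw, eye_kw = {}, {}
    if factor is RiskFactor.AGE_AT_PRESENTATION:
        rec_kw = {"age_at_presentation_yr": v, "age_of_onset_yr": min(v, 5.0)}
    elif factor is RiskFactor.AGE_OF_ONSET:
        rec_kw = {"age_of_onset_yr": v, "age_at_presentation_yr": 29.0}
    elif factor is RiskFactor.SER_AT_PRESENTATION:
        eye_kw = {"ser_d": v}
    elif factor is RiskFactor.TIME_OUTDOORS:
        rec_kw = {"outdoors_h_per_day": v}
    elif factor is RiskFactor.RPR_AT_PRESENTATION:
        eye_kw = {"rpr_nasal_d": v}
    elif factor is RiskFactor.TIME_NEARWORK:
        rec_kw = {"nearwork_h_per_day": v}
    elif factor is RiskFactor.NEAR_ESOPHORIA:
        eye_kw = {"near_phoria_pd": v}
    elif factor is RiskFactor.ACCOMMODATIVE_LAG:
        eye_kw = {"accom_error_d": v}
    elif factor is RiskFactor.CHANGE_SER_OR_AL:
        eye_kw = {"ser_change_d_per_yr": v}
    return categorize_factor(factor, make_record(**rec_kw), make_eye(**eye_kw))


@pytest.mark.parametrize("factor", list(FACTOR_GRIDS))
def test_exhaustive_and_monotone_over_dense_grid(factor):
    """Every value in the physical domain maps to exactly one category,
    and the category is monotone in the risk-increasing direction."""
    from mpras import RISK_DIRECTION

    _, grid = FACTOR_GRIDS[factor]
    eps = 1e-9
    points = np.concatenate(
        [grid]
        + [
            np.array([b - eps, b, b + eps])
            for b in BOUNDARY_CONSTANTS[factor]
        ]
    )
    points = np.sort(points)
    cats = np.array([int(_categorize_value(factor, float(v))) for v in points])
    assert set(cats) <= {1, 2, 3}
    # orient so risk increases along the grid, then require non-decreasing
    orient = cats if RISK_DIRECTION[factor] > 0 else cats[::-1]
    assert np.all(np.diff(orient) >= 0)
    assert orient[0] == 1 and orient[-1] == 3


def test_threshold_config_round_trip(tmp_path):
    custom = DEFAULT_THRESHOLDS.replaced(nearwork_low=6.0, rpr_high=0.75)
    path = tmp_path / "thresholds.yaml"
    path.write_text(yaml.safe_dump(custom.to_config()))
    back = ThresholdTable.from_config(yaml.safe_load(path.read_text()))
    assert back == custom
    # identical categorisations on a random grid
    rng = np.random.default_rng(0)
    for v in rng.uniform(0, 16, 50):
        rec = make_record(nearwork_h_per_day=float(v))
        assert categorize_factor(
            RiskFactor.TIME_NEARWORK, rec, None, custom
        ) == categorize_factor(RiskFactor.TIME_NEARWORK, rec, None, back)


def test_record_invariants_rejected():
    with pytest.raises(ValueError):
        make_record(age_of_onset_yr=16.0, age_at_presentation_yr=12.0)
    with pytest.raises(ValueError):
        make_record(myopic_parents=3)
    with pytest.raises(ValueError):
        make_record(outdoors_h_per_day=-1.0)
    with pytest.raises(ValueError):
        EyeMeasurements(ser_d=+1.0)
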