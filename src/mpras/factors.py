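"""Risk-factor definitions and low/intermediate/high categorisation.

The risk protocol grades ten factors associated with myopia progression —
one optical change factor (annual change in spherical equivalent refraction
or axial length), demographics (age at presentation, age of myopia onset,
number of myopic parents), environment (daily hours outdoors and on near
work) and optics at presentation (SER, relative peripheral refraction,
near phoria, accommodative error).  Each factor maps a raw clinical
measurement onto a three-level ordinal category (LOW / INTERMEDIATE /
HIGH) using fixed boundary constants.  The boundaries ship with the
published protocol values but live in an editable :class:`ThresholdTable`
so the engine can be reused with a revised protocol.

Sign conventions
----------------
* SER is negative for myopia; a negative annual SER change means
  progression.
* Relative peripheral refraction (peripheral minus central) is positive
  for relative peripheral *hyperopia*.
* Near phoria is in prism dioptres, positive = esophoria, negative =
  exophoria.
* Accommodative error is positive for a lag, negative for a lead.
"""

from __future__ import annotations

import enum
import hashlib
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence


class RiskFactor(str, enum.Enum):
    """The ten protocol risk factors, in protocol row order."""

    CHANGE_SER_OR_AL = "change_ser_or_al"
    AGE_AT_PRESENTATION = "age_at_presentation"
    SER_AT_PRESENTATION = "ser_at_presentation"
    AGE_OF_ONSET = "age_of_onset"
    TIME_OUTDOORS = "time_outdoors"
    RPR_AT_PRESENTATION = "rpr_at_presentation"
    TIME_NEARWORK = "time_nearwork"
    NEAR_ESOPHORIA = "near_esophoria"
    ACCOMMODATIVE_LAG = "accommodative_lag"
    MYOPIC_PARENTS = "myopic_parents"


#: Protocol row order (fixed).
FACTOR_ORDER: tuple[RiskFactor, ...] = tuple(RiskFactor)

#: +1 if risk increases with the measurement value, -1 if it decreases.
#: For CHANGE_SER_OR_AL the direction refers to the SER-change signal
#: (more negative = riskier); the AL-change signal runs the other way.
RISK_DIRECTION: dict[RiskFactor, int] = {
    RiskFactor.CHANGE_SER_OR_AL: -1,
    RiskFactor.AGE_AT_PRESENTATION: -1,
    RiskFactor.SER_AT_PRESENTATION: -1,
    RiskFactor.AGE_OF_ONSET: -1,
    RiskFactor.TIME_OUTDOORS: -1,
    RiskFactor.RPR_AT_PRESENTATION: +1,
    RiskFactor.TIME_NEARWORK: +1,
    RiskFactor.NEAR_ESOPHORIA: +1,
    RiskFactor.ACCOMMODATIVE_LAG: +1,
    RiskFactor.MYOPIC_PARENTS: +1,
}


class RiskCategory(enum.IntEnum):
    """Ordinal risk category; the integer value is the base point (1/2/3)."""

    LOW = 1
    INTERMEDIATE = 2
    HIGH = 3

    @property
    def base_point(self) -> int:
        return int(self)

    @property
    def multiplier(self) -> int:
        """Category multiplier used in the two-step score aggregation."""
        return int(self)


class Decision(str, enum.Enum):
    """Binary progression-risk decision."""

    AT_RISK = "at_risk"
    LOW_RISK = "low_risk"


class MissingMeasurementError(ValueError):
    """A factor could not be categorised because its measurement is absent."""

    def __init__(self, factor: RiskFactor, detail: str = ""):
        self.factor = factor
        msg = f"missing measurement for factor '{factor.value}'"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class GapWarning(UserWarning):
    """A measurement fell strictly inside a gap between category bands.

    The protocol assumes clinically quantised measurements (0.25 D steps);
    mid-gap values are assigned INTERMEDIATE.
    """


@dataclass(frozen=True)
class EyeMeasurements:
    """Per-eye optical measurements.

    ``ser_d`` must satisfy the myopia inclusion criterion (<= -0.50 D).
    All other fields are optional; at least one of ``ser_change_d_per_yr``
    / ``al_change_mm_per_yr`` is needed to grade the change factor.
    RPR values are at +/-30 deg eccentricity, peripheral minus central.
    """

    ser_d: float
    ser_change_d_per_yr: Optional[float] = None
    al_change_mm_per_yr: Optional[float] = None
    rpr_nasal_d: Optional[float] = None
    rpr_temporal_d: Optional[float] = None
    near_phoria_pd: Optional[float] = None
    accom_error_d: Optional[float] = None

    def __post_init__(self):
        if not self.ser_d <= -0.50:
            raise ValueError(
                f"ser_d={self.ser_d:+.2f} violates the myopia inclusion "
                "criterion SER <= -0.50 D"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One person: demographics, environment, per-eye optics, labels."""

    patient_id: str
    age_at_presentation_yr: float
    age_of_onset_yr: float
    myopic_parents: int
    outdoors_h_per_day: float
    nearwork_h_per_day: float
    right_eye: Optional[EyeMeasurements] = None
    left_eye: Optional[EyeMeasurements] = None
    clinician_labels: Optional[tuple[Decision, ...]] = None
    followup_ser_change_d_per_yr: Optional[float] = None

    def __post_init__(self):
        if self.age_of_onset_yr > self.age_at_presentation_yr:
            raise ValueError(
                f"{self.patient_id}: age of onset "
                f"({self.age_of_onset_yr}) exceeds age at presentation "
                f"({self.age_at_presentation_yr})"
            )
        if self.myopic_parents not in (0, 1, 2):
            raise ValueError(
                f"{self.patient_id}: myopic_parents must be 0, 1 or 2, "
                f"got {self.myopic_parents!r}"
            )
        if self.outdoors_h_per_day < 0 or self.nearwork_h_per_day < 0:
            raise ValueError(f"{self.patient_id}: hours fields must be >= 0")

    def eye(self, side: str) -> Optional[EyeMeasurements]:
        if side in ("right", "OD"):
            return self.right_eye
        if side in ("left", "OS"):
            return self.left_eye
        raise ValueError(f"unknown eye side {side!r}")


@dataclass(frozen=True)
class ThresholdTable:
    """Category boundary constants, one block per factor.

    Shipped defaults are the published protocol values.  Boundary
    semantics (which comparisons are strict, inclusive-INTERMEDIATE at
    shared boundaries, gap handling) are fixed in
    :func:`categorize_factor`; only the constants are configurable.
    """

    # change in SER (D/yr): LOW > ser_change_low; INT in
    # [ser_change_high, ser_change_low]; HIGH < ser_change_high
    ser_change_low: float = -0.50
    ser_change_high: float = -0.75
    # change in AL (mm/yr): LOW < al_change_low; INT in
    # [al_change_low, al_change_high); HIGH >= al_change_high
    al_change_low: float = 0.10
    al_change_high: float = 0.20
    # ages (yr): LOW >= age_low; HIGH <= age_high; INT between
    age_low: float = 18.0
    age_high: float = 13.0
    # SER at presentation (D): LOW >= ser_low; HIGH <= ser_high
    ser_low: float = -3.00
    ser_high: float = -6.00
    # time outdoors (h/day): LOW > outdoors_low; INT in
    # [outdoors_high, outdoors_low]; HIGH < outdoors_high
    outdoors_low: float = 2.0
    outdoors_high: float = 1.0
    # RPR (D): LOW < rpr_low; INT in [rpr_low, rpr_high]; HIGH > rpr_high
    rpr_low: float = 0.25
    rpr_high: float = 0.50
    # near work (h/day): LOW <= nearwork_low; INT <= nearwork_high; HIGH above
    nearwork_low: float = 7.0
    nearwork_high: float = 10.0
    # near phoria (PD): LOW <= phoria_low; HIGH >= phoria_high; INT between
    phoria_low: float = 2.0
    phoria_high: float = 6.0
    # accommodative lag (D): LOW <= lag_low; INT in
    # [lag_int_lower, lag_high] (gap (lag_low, lag_int_lower) -> INT with
    # warning); HIGH > lag_high
    lag_low: float = 0.50
    lag_int_lower: float = 0.75
    lag_high: float = 1.00

    # grouping of constants into per-factor config blocks
    _BLOCKS = {
        "change_ser_or_al": (
            "ser_change_low",
            "ser_change_high",
            "al_change_low",
            "al_change_high",
        ),
        "age_at_presentation": ("age_low", "age_high"),
        "ser_at_presentation": ("ser_low", "ser_high"),
        "age_of_onset": ("age_low", "age_high"),
        "time_outdoors": ("outdoors_low", "outdoors_high"),
        "rpr_at_presentation": ("rpr_low", "rpr_high"),
        "time_nearwork": ("nearwork_low", "nearwork_high"),
        "near_esophoria": ("phoria_low", "phoria_high"),
        "accommodative_lag": ("lag_low", "lag_int_lower", "lag_high"),
    }

    def to_config(self) -> dict:
        """Nested per-factor dict of named boundary constants."""
        out: dict[str, dict[str, float]] = {}
        for block, names in self._BLOCKS.items():
            out[block] = {n: getattr(self, n) for n in names}
        return out

    @classmethod
    def from_config(cls, config: dict) -> "ThresholdTable":
        flat: dict[str, float] = {}
        valid = {f.name for f in fields(cls)}
        for block, consts in config.items():
            for name, value in consts.items():
                if name not in valid:
                    raise KeyError(
                        f"unknown threshold constant {name!r} in block {block!r}"
                    )
                if name in flat and flat[name] != value:
                    raise ValueError(
                        f"conflicting values for shared constant {name!r}"
                    )
                flat[name] = float(value)
        return cls(**flat)

    def replaced(self, **kwargs) -> "ThresholdTable":
        return replace(self, **kwargs)

    def digest(self) -> str:
        """Stable content hash, for run logs."""
        payload = ",".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in fields(self)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_THRESHOLDS = ThresholdTable()


def _gap(factor: RiskFactor, value: float) -> RiskCategory:
    warnings.warn(
        f"{factor.value}: value {value:.2f} falls in a gap between category "
        "bands; assigning INTERMEDIATE",
        GapWarning,
        stacklevel=3,
    )
    return RiskCategory.INTERMEDIATE


def _categorize_change(eye: EyeMeasurements, t: ThresholdTable) -> RiskCategory:
    sc = eye.ser_change_d_per_yr
    ac = eye.al_change_mm_per_yr
    if sc is None and ac is None:
        raise MissingMeasurementError(
            RiskFactor.CHANGE_SER_OR_AL,
            "need SER change (D/yr) or AL change (mm/yr)",
        )
    cats: list[RiskCategory] = []
    if sc is not None:
        if t.ser_change_high <= sc <= t.ser_change_low:
            cats.append(RiskCategory.INTERMEDIATE)
        elif sc > t.ser_change_low:
            cats.append(RiskCategory.LOW)
        else:
            cats.append(RiskCategory.HIGH)
    if ac is not None:
        if t.al_change_low <= ac < t.al_change_high:
            cats.append(RiskCategory.INTERMEDIATE)
        elif ac < t.al_change_low:
            cats.append(RiskCategory.LOW)
        else:
            cats.append(RiskCategory.HIGH)
    # when both signals are present the more severe category wins
    return max(cats)


def categorize_factor(
    factor: RiskFactor,
    record: PatientRecord,
    eye: Optional[EyeMeasurements] = None,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
) -> RiskCategory:
    """Map one factor's raw measurement onto LOW/INTERMEDIATE/HIGH.

    ``eye`` is required for the ocular factors (change, SER, RPR, phoria,
    accommodative error) and ignored for the demographic/environmental
    ones.  Shared boundaries resolve to INTERMEDIATE (conservative,
    higher-risk assignment at ties); values strictly inside an uncovered
    numeric gap resolve to INTERMEDIATE with a :class:`GapWarning`.

    Raises
    ------
    MissingMeasurementError
        If the measurement the factor needs is absent, naming the factor.
    """
    t = thresholds

    if factor is RiskFactor.CHANGE_SER_OR_AL:
        if eye is None:
            raise MissingMeasurementError(factor, "no eye measurements")
        return _categorize_change(eye, t)

    if factor in (RiskFactor.AGE_AT_PRESENTATION, RiskFactor.AGE_OF_ONSET):
        v = (
            record.age_at_presentation_yr
            if factor is RiskFactor.AGE_AT_PRESENTATION
            else record.age_of_onset_yr
        )
        if v >= t.age_low:
            return RiskCategory.LOW
        if v <= t.age_high:
            return RiskCategory.HIGH
        return RiskCategory.INTERMEDIATE

    if factor is RiskFactor.SER_AT_PRESENTATION:
        if eye is None:
            raise MissingMeasurementError(factor, "no eye measurements")
        v = eye.ser_d
        if v >= t.ser_low:
            return RiskCategory.LOW
        if v <= t.ser_high:
            return RiskCategory.HIGH
        return RiskCategory.INTERMEDIATE

    if factor is RiskFactor.TIME_OUTDOORS:
        v = record.outdoors_h_per_day
        if t.outdoors_high <= v <= t.outdoors_low:
            return RiskCategory.INTERMEDIATE
        if v > t.outdoors_low:
            return RiskCategory.LOW
        return RiskCategory.HIGH

    if factor is RiskFactor.RPR_AT_PRESENTATION:
        if eye is None:
            raise MissingMeasurementError(factor, "no eye measurements")
        vals = [v for v in (eye.rpr_nasal_d, eye.rpr_temporal_d) if v is not None]
        if not vals:
            raise MissingMeasurementError(
                factor, "need nasal and/or temporal RPR at +/-30 deg"
            )
        # risk is driven by the worse (more hyperopic) meridian
        v = max(vals)
        if t.rpr_low <= v <= t.rpr_high:
            return RiskCategory.INTERMEDIATE
        if v < t.rpr_low:
            return RiskCategory.LOW
        return RiskCategory.HIGH

    if factor is RiskFactor.TIME_NEARWORK:
        v = record.nearwork_h_per_day
        if v <= t.nearwork_low:
            return RiskCategory.LOW
        if v <= t.nearwork_high:
            return RiskCategory.INTERMEDIATE
        return RiskCategory.HIGH

    if factor is RiskFactor.NEAR_ESOPHORIA:
        if eye is None:
            raise MissingMeasurementError(factor, "no eye measurements")
        v = eye.near_phoria_pd
        if v is None:
            raise MissingMeasurementError(factor, "near phoria absent")
        # any exophoria (negative PD) satisfies the LOW band
        if v <= t.phoria_low:
            return RiskCategory.LOW
        if v >= t.phoria_high:
            return RiskCategory.HIGH
        return RiskCategory.INTERMEDIATE

    if factor is RiskFactor.ACCOMMODATIVE_LAG:
        if eye is None:
            raise MissingMeasurementError(factor, "no eye measurements")
        v = eye.accom_error_d
        if v is None:
            raise MissingMeasurementError(factor, "accommodative error absent")
        # a lead (negative error) is LOW
        if v <= t.lag_low:
            return RiskCategory.LOW
        if v > t.lag_high:
            return RiskCategory.HIGH
        if t.lag_int_lower <= v <= t.lag_high:
            return RiskCategory.INTERMEDIATE
        return _gap(factor, v)

    if factor is RiskFactor.MYOPIC_PARENTS:
        return {
            0: RiskCategory.LOW,
            1: RiskCategory.INTERMEDIATE,
            2: RiskCategory.HIGH,
        }[record.myopic_parents]

    raise ValueError(f"unknown factor {factor!r}")  # pragma: no cover


def factor_value(
    factor: RiskFactor,
    record: PatientRecord,
    eye: Optional[EyeMeasurements] = None,
) -> float:
    """The raw numeric measurement driving a factor's categorisation.

    Used to assemble the numeric factor table for the principal-component
    screen and permutation importance.  For the change factor this is the
    SER change (the primary signal); for RPR, the worse meridian.

    Raises :class:`MissingMeasurementError` when absent.
    """
    if factor is RiskFactor.CHANGE_SER_OR_AL:
        if eye is None or eye.ser_change_d_per_yr is None:
            raise MissingMeasurementError(factor)
        return eye.ser_change_d_per_yr
    if factor is RiskFactor.AGE_AT_PRESENTATION:
        return record.age_at_presentation_yr
    if factor is RiskFactor.SER_AT_PRESENTATION:
        if eye is None:
            raise MissingMeasurementError(factor)
        return eye.ser_d
    if factor is RiskFactor.AGE_OF_ONSET:
        return record.age_of_onset_yr
    if factor is RiskFactor.TIME_OUTDOORS:
        return record.outdoors_h_per_day
    if factor is RiskFactor.RPR_AT_PRESENTATION:
        if eye is None:
            raise MissingMeasurementError(factor)
        vals = [v for v in (eye.rpr_nasal_d, eye.rpr_temporal_d) if v is not None]
        if not vals:
            raise MissingMeasurementError(factor)
        return max(vals)
    if factor is RiskFactor.TIME_NEARWORK:
        return record.nearwork_h_per_day
    if factor is RiskFactor.NEAR_ESOPHORIA:
        if eye is None or eye.near_phoria_pd is None:
            raise MissingMeasurementError(factor)
        return eye.near_phoria_pd
    if factor is RiskFactor.ACCOMMODATIVE_LAG:
        if eye is None or eye.accom_error_d is None:
            raise MissingMeasurementError(factor)
        return eye.accom_error_d
    if factor is RiskFactor.MYOPIC_PARENTS:
        return float(record.myopic_parents)
    raise ValueError(f"unknown factor {factor!r}")  # pragma: no cover
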