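"""Score aggregation, weighted variants, sub-model presets, classification.

The total risk score aggregates the ten per-factor categories in two
algebraically identical ways:

* **Two-step view** — sum the base points (1/2/3) within each category
  level, then multiply the LOW subtotal by 1, the INTERMEDIATE subtotal
  by 2 and the HIGH subtotal by 3, and add the three products.
* **Per-factor view** — each factor contributes
  ``weight x base_point x multiplier`` where base point and multiplier
  are both 1/2/3 by category, i.e. contributions of 1, 4 or 9 under the
  unweighted model.

The per-factor contribution being ``base_point x multiplier`` (not the
base point alone) is what makes the printed full-model range 10-90 work:
10 factors x 9 = 90.  This is the single most important disambiguation
in the protocol and both views are exposed so either can be audited.

Model-2 applies three published weight rules on top: 2x on the change
factor for INTERMEDIATE/HIGH, and 0.5x on myopic parents and time
outdoors for INTERMEDIATE/HIGH when the patient is an adult (age >= 18).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .factors import (
    DEFAULT_THRESHOLDS,
    FACTOR_ORDER,
    Decision,
    EyeMeasurements,
    MissingMeasurementError,
    PatientRecord,
    RiskCategory,
    RiskFactor,
    ThresholdTable,
    categorize_factor,
)


class MissingFactorError(ValueError):
    """One or more factors required by a model cannot be computed."""

    def __init__(self, patient_id: str, factors: Sequence[RiskFactor]):
        self.patient_id = patient_id
        self.factors = tuple(factors)
        names = ", ".join(f.value for f in self.factors)
        super().__init__(
            f"{patient_id}: cannot score, missing factor(s): {names}"
        )


@dataclass(frozen=True)
class WeightRule:
    """Multiplicative weight on one factor's contribution, by category.

    ``min_age`` makes the rule conditional on
    ``age_at_presentation >= min_age`` (None = unconditional).
    """

    factor: RiskFactor
    weight_low: float = 1.0
    weight_intermediate: float = 1.0
    weight_high: float = 1.0
    min_age: Optional[float] = None

    def __post_init__(self):
        if min(self.weight_low, self.weight_intermediate, self.weight_high) <= 0:
            raise ValueError("weights must be > 0")

    def applies(self, record: Optional[PatientRecord]) -> bool:
        if self.min_age is None:
            return True
        if record is None:
            raise ValueError(
                "age-conditional weight rule needs a patient record"
            )
        return record.age_at_presentation_yr >= self.min_age

    def weight_for(self, category: RiskCategory) -> float:
        return {
            RiskCategory.LOW: self.weight_low,
            RiskCategory.INTERMEDIATE: self.weight_intermediate,
            RiskCategory.HIGH: self.weight_high,
        }[category]


@dataclass(frozen=True)
class RiskModelSpec:
    """A scoring model: factor subset, thresholds, weights, cut-off."""

    name: str
    factors: tuple[RiskFactor, ...]
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    weight_rules: tuple[WeightRule, ...] = ()
    cutoff: Optional[float] = None

    def __post_init__(self):
        if not self.factors:
            raise ValueError("model needs at least one factor")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("duplicate factors in model")

    def weight(
        self,
        factor: RiskFactor,
        category: RiskCategory,
        record: Optional[PatientRecord] = None,
    ) -> float:
        w = 1.0
        for rule in self.weight_rules:
            if rule.factor is factor and rule.applies(record):
                w *= rule.weight_for(category)
        return w

    def with_unit_weights(self) -> "RiskModelSpec":
        return replace(self, weight_rules=())

    def with_cutoff(self, cutoff: Optional[float]) -> "RiskModelSpec":
        return replace(self, cutoff=cutoff)

    def digest(self) -> str:
        payload = "|".join(
            [
                self.name,
                ",".join(f.value for f in self.factors),
                self.thresholds.digest(),
                ";".join(
                    f"{r.factor.value}:{r.weight_low}:{r.weight_intermediate}"
                    f":{r.weight_high}:{r.min_age}"
                    for r in self.weight_rules
                ),
                str(self.cutoff),
            ]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FactorScore:
    """One factor's line in the score breakdown."""

    factor: RiskFactor
    category: RiskCategory
    base_point: int
    multiplier: int
    weight: float
    contribution: float


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-factor contributions, total score and optional classification."""

    patient_id: str
    model_name: str
    eye_used: Optional[str]
    factor_scores: tuple[FactorScore, ...]
    total_score: float
    classification: Optional[Decision] = None

    def category_subtotals(self) -> dict[RiskCategory, float]:
        """Weighted base-point subtotal per category level (two-step view)."""
        sub = {c: 0.0 for c in RiskCategory}
        for fs in self.factor_scores:
            sub[fs.category] += fs.weight * fs.base_point
        return sub

    def total_from_subtotals(self) -> float:
        """Recompute the total via the two-step (category-sum) view."""
        return float(
            sum(c.multiplier * s for c, s in self.category_subtotals().items())
        )

    def categories(self) -> dict[RiskFactor, RiskCategory]:
        return {fs.factor: fs.category for fs in self.factor_scores}


def classify(total_score: float, cutoff: float) -> Decision:
    """AT_RISK iff the total score strictly exceeds the cut-off."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return Decision.AT_RISK if total_score > cutoff else Decision.LOW_RISK


def select_eye(
    record: PatientRecord,
    eye_choice: str = "random",
    seed: int = 0,
) -> tuple[Optional[str], Optional[EyeMeasurements]]:
    """Resolve the eye to score.

    ``random`` draws a stable per-patient choice from ``seed`` and the
    patient id (reproducible across runs and record orderings); if the
    drawn side is absent the other is used.  Explicit ``right``/``left``
    fail when that eye is absent.
    """
    if eye_choice == "right":
        if record.right_eye is None:
            raise ValueError(f"{record.patient_id}: right eye absent")
        return "OD", record.right_eye
    if eye_choice == "left":
        if record.left_eye is None:
            raise ValueError(f"{record.patient_id}: left eye absent")
        return "OS", record.left_eye
    if eye_choice == "random":
        if record.right_eye is None and record.left_eye is None:
            raise ValueError(f"{record.patient_id}: no eye measurements")
        h = hashlib.sha256(f"{seed}:{record.patient_id}".encode()).digest()
        pick_right = h[0] % 2 == 0
        if pick_right and record.right_eye is not None:
            return "OD", record.right_eye
        if not pick_right and record.left_eye is not None:
            return "OS", record.left_eye
        # drawn side absent: fall back to the available one
        if record.right_eye is not None:
            return "OD", record.right_eye
        return "OS", record.left_eye
    raise ValueError(f"eye_choice must be right/left/random, got {eye_choice!r}")


#: Factors whose categorisation needs per-eye measurements.
OCULAR_FACTORS = frozenset(
    {
        RiskFactor.CHANGE_SER_OR_AL,
        RiskFactor.SER_AT_PRESENTATION,
        RiskFactor.RPR_AT_PRESENTATION,
        RiskFactor.NEAR_ESOPHORIA,
        RiskFactor.ACCOMMODATIVE_LAG,
    }
)


def score(
    record: PatientRecord,
    model: RiskModelSpec,
    eye_choice: str = "random",
    seed: int = 0,
    cutoff: Optional[float] = None,
) -> ScoreBreakdown:
    """Score one patient under a model.

    ``cutoff`` overrides ``model.cutoff``; if both are None no
    classification is attached.

    Raises :class:`MissingFactorError` listing every factor in the model
    whose measurement is absent.
    """
    needs_eye = any(f in OCULAR_FACTORS for f in model.factors)
    eye_used: Optional[str] = None
    eye: Optional[EyeMeasurements] = None
    if needs_eye:
        eye_used, eye = select_eye(record, eye_choice, seed)

    categories: dict[RiskFactor, RiskCategory] = {}
    missing: list[RiskFactor] = []
    for f in model.factors:
        try:
            categories[f] = categorize_factor(f, record, eye, model.thresholds)
        except MissingMeasurementError:
            missing.append(f)
    if missing:
        raise MissingFactorError(record.patient_id, missing)

    lines = []
    for f in model.factors:
        cat = categories[f]
        w = model.weight(f, cat, record)
        lines.append(
            FactorScore(
                factor=f,
                category=cat,
                base_point=cat.base_point,
                multiplier=cat.multiplier,
                weight=w,
                contribution=w * cat.base_point * cat.multiplier,
            )
        )
    total = float(sum(fs.contribution for fs in lines))
    cut = cutoff if cutoff is not None else model.cutoff
    decision = classify(total, cut) if cut is not None else None
    return ScoreBreakdown(
        patient_id=record.patient_id,
        model_name=model.name,
        eye_used=eye_used,
        factor_scores=tuple(lines),
        total_score=total,
        classification=decision,
    )


def total_from_categories(
    categories: Mapping[RiskFactor, RiskCategory],
    model: Optional[RiskModelSpec] = None,
    record: Optional[PatientRecord] = None,
) -> float:
    """Aggregate a category assignment directly (no raw measurements).

    Useful for exhaustive enumeration over category space.  ``model``
    defaults to the unweighted full model restricted to the factors in
    ``categories``; age-conditional weight rules need ``record``.
    """
    total = 0.0
    for f, cat in categories.items():
        w = model.weight(f, cat, record) if model is not None else 1.0
        total += w * cat.base_point * cat.multiplier
    return float(total)


# ---------------------------------------------------------------------------
# Presets

#: Stepwise drop order for the sub-model sweep (first dropped first),
#: i.e. the published importance ranking read from least to most important.
SUBMODEL_DROP_ORDER: tuple[RiskFactor, ...] = (
    RiskFactor.MYOPIC_PARENTS,
    RiskFactor.ACCOMMODATIVE_LAG,
    RiskFactor.NEAR_ESOPHORIA,
    RiskFactor.TIME_NEARWORK,
    RiskFactor.RPR_AT_PRESENTATION,
    RiskFactor.TIME_OUTDOORS,
)

#: Published calibrated cut-offs shipped with the presets (random-eye
#: calibration for the full models; sub-model sweep values for 1a-1g).
PRESET_CUTOFFS: dict[str, float] = {
    "model1": 41.50,
    "model2": 41.75,
    "1a": 41.50,
    "1b": 39.50,
    "1c": 38.50,
    "1d": 37.50,
    "1e": 33.50,
    "1f": 29.50,
    "1g": 22.00,
}

MODEL2_WEIGHT_RULES: tuple[WeightRule, ...] = (
    # 2x on the change-in-refraction factor for intermediate and high risk
    WeightRule(
        RiskFactor.CHANGE_SER_OR_AL,
        weight_intermediate=2.0,
        weight_high=2.0,
    ),
    # in adults (>= 18 y) parents and outdoors matter less: 0.5x
    WeightRule(
        RiskFactor.MYOPIC_PARENTS,
        weight_intermediate=0.5,
        weight_high=0.5,
        min_age=18.0,
    ),
    WeightRule(
        RiskFactor.TIME_OUTDOORS,
        weight_intermediate=0.5,
        weight_high=0.5,
        min_age=18.0,
    ),
)

PRESET_NAMES = ("model1", "model2", "1a", "1b", "1c", "1d", "1e", "1f", "1g")


def preset_model(
    name: str, thresholds: ThresholdTable = DEFAULT_THRESHOLDS
) -> RiskModelSpec:
    """Return a named preset: ``model1``, ``model2`` or ``1a`` .. ``1g``.

    ``1a`` is the full unweighted model (identical factor set to
    ``model1``); ``1b`` .. ``1g`` drop factors stepwise per
    :data:`SUBMODEL_DROP_ORDER`, down to the four-factor ``1g``.
    """
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; valid: {', '.join(PRESET_NAMES)}"
        )
    if name == "model2":
        return RiskModelSpec(
            name="model2",
            factors=FACTOR_ORDER,
            thresholds=thresholds,
            weight_rules=MODEL2_WEIGHT_RULES,
            cutoff=PRESET_CUTOFFS["model2"],
        )
    if name == "model1":
        factors = FACTOR_ORDER
    else:
        n_drop = ord(name[1]) - ord("a")
        dropped = set(SUBMODEL_DROP_ORDER[:n_drop])
        factors = tuple(f for f in FACTOR_ORDER if f not in dropped)
    return RiskModelSpec(
        name=name,
        factors=factors,
        thresholds=thresholds,
        cutoff=PRESET_CUTOFFS[name],
    )
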