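"""Synthetic myopia-clinic cohorts for testing scoring and calibration.

Emulates the statistical structure of a tertiary myopia-clinic
population: truncated-normal marginals for the continuous risk factors
(means, SDs and ranges matching the published cohort summaries), the
printed 0/1/2 myopic-parent frequencies, correlated right/left-eye
optics via a Gaussian copula, a latent logistic progression propensity
driven by risk-direction-aligned standardised factors, a gold 1-year
SER-change outcome drawn conditional on that propensity, and simulated
clinician raters whose pairwise agreement is calibrated to a target
Cohen's kappa.

This generator is a test harness, not an epidemiological model: the
factor-outcome coupling and the conditional-independence assumption are
documented defaults chosen to make scoring, calibration and validation
exercisable, not claims about the real joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .factors import (
    Decision,
    EyeMeasurements,
    PatientRecord,
    RISK_DIRECTION,
    RiskFactor,
)


@dataclass(frozen=True)
class VariableSpec:
    """Truncated-normal marginal: underlying mean/SD and bounds."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if self.lower > self.mean + 6 * self.sd or self.upper < self.mean - 6 * self.sd:
            raise ValueError(
                "infeasible truncation: mean outside bounds by > 6 SD"
            )

    @property
    def _ab(self) -> tuple[float, float]:
        return (
            (self.lower - self.mean) / self.sd,
            (self.upper - self.mean) / self.sd,
        )

    def target_moments(self) -> tuple[float, float]:
        """Analytic mean and SD of the truncated distribution."""
        a, b = self._ab
        m, v = truncnorm.stats(a, b, loc=self.mean, scale=self.sd, moments="mv")
        return float(m), float(np.sqrt(v))

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF transform (for copula sampling)."""
        a, b = self._ab
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.from_uniform(rng.uniform(size=n))


#: Default factor-outcome coefficients on the standardised,
#: risk-direction-aligned scale; proportional to the published
#: importance ranking (change in refraction strongest, parents weakest).
DEFAULT_OUTCOME_COEFFS: dict[RiskFactor, float] = {
    RiskFactor.CHANGE_SER_OR_AL: 1.4,
    RiskFactor.AGE_AT_PRESENTATION: 0.9,
    RiskFactor.SER_AT_PRESENTATION: 0.7,
    RiskFactor.AGE_OF_ONSET: 0.7,
    RiskFactor.TIME_OUTDOORS: 0.35,
    RiskFactor.RPR_AT_PRESENTATION: 0.30,
    RiskFactor.TIME_NEARWORK: 0.30,
    RiskFactor.NEAR_ESOPHORIA: 0.25,
    RiskFactor.ACCOMMODATIVE_LAG: 0.25,
    RiskFactor.MYOPIC_PARENTS: 0.20,
}


@dataclass(frozen=True)
class CohortParams:
    """All knobs of the synthetic generator, with study-matched defaults."""

    n: int = 149
    seed: int = 0
    # marginals (mean, SD, truncation) per variable
    age_at_presentation: VariableSpec = VariableSpec(13.74, 4.89, 6.0, 29.0)
    age_of_onset: VariableSpec = VariableSpec(8.59, 3.74, 0.3, 18.0)
    ser: VariableSpec = VariableSpec(-5.02, 2.99, -16.50, -0.50)
    ser_change: VariableSpec = VariableSpec(-0.73, 0.78, -4.0, 0.5)
    nearwork: VariableSpec = VariableSpec(7.85, 3.05, 0.0, 16.0)
    outdoors: VariableSpec = VariableSpec(1.11, 1.14, 0.0, 8.0)
    rpr: VariableSpec = VariableSpec(0.66, 0.71, -3.0, 3.0)
    accom_error: VariableSpec = VariableSpec(0.53, 0.42, -1.5, 2.5)
    near_phoria: VariableSpec = VariableSpec(-2.0, 7.0, -25.0, 16.0)
    #: P(0, 1, 2 myopic parents)
    parents_probs: tuple[float, float, float] = (61 / 149, 59 / 149, 29 / 149)
    #: Gaussian-copula correlation between the two eyes of a patient
    rho_eye: float = 0.95
    #: copula correlation between nasal and temporal RPR within an eye
    rho_meridian: float = 0.7
    #: copula correlation between age at presentation and age of onset;
    #: high so the onset<=presentation clamp binds for ~1% of draws only
    rho_age_onset: float = 0.9
    #: AL change derived from SER change at ~ -0.37 mm/D plus noise
    al_per_diopter: float = -0.37
    al_noise_sd_mm: float = 0.03
    include_al_change: bool = True
    # clinician raters
    n_clinicians: int = 5
    clinician_kappa: float = 0.95
    label_prevalence: float = 114 / 149
    # latent outcome model
    outcome_prevalence: float = 16 / 36
    effect_scale: float = 1.0
    outcome_coeffs: dict[RiskFactor, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFS)
    )
    #: gold 1-year SER change, conditional on progression status
    progressor_change: VariableSpec = VariableSpec(-0.95, 0.35, -3.5, -0.55)
    nonprogressor_change: VariableSpec = VariableSpec(-0.10, 0.20, -0.45, 0.75)
    #: follow-up refraction measurement noise (D)
    followup_noise_sd: float = 0.12

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if abs(sum(self.parents_probs) - 1.0) > 1e-9:
            raise ValueError("parents_probs must sum to 1")
        for name in ("rho_eye", "rho_meridian", "rho_age_onset"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if not 0.0 < self.label_prevalence < 1.0:
            raise ValueError("label_prevalence must be in (0, 1)")

    def replaced(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    """Generated records plus latent truth and simulated raters."""

    records: list[PatientRecord]
    latent_risk: np.ndarray  # per-patient progression propensity in (0,1)
    gold_outcome: np.ndarray  # true 1-year SER change (D/yr, noise-free)
    clinician_labels: np.ndarray  # (n_raters, n) bool, True = AT_RISK
    params: CohortParams

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def gold_progression(self) -> np.ndarray:
        return self.gold_outcome <= -0.50


def _correlated_pair(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with correlation rho (shared factor)."""
    z_common = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    r = np.sqrt(rho)
    s = np.sqrt(1.0 - rho)
    return r * z_common + s * e1, r * z_common + s * e2


def _eye_pair(
    rng: np.random.Generator, n: int, spec: VariableSpec, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    zr, zl = _correlated_pair(rng, n, rho)
    return spec.from_uniform(norm.cdf(zr)), spec.from_uniform(norm.cdf(zl))


def _standardized_risk(
    params: CohortParams,
    values: dict[RiskFactor, np.ndarray],
) -> np.ndarray:
    """Sum of coefficient x standardised factor, aligned risk-positive."""
    spec_of = {
        RiskFactor.CHANGE_SER_OR_AL: params.ser_change,
        RiskFactor.AGE_AT_PRESENTATION: params.age_at_presentation,
        RiskFactor.SER_AT_PRESENTATION: params.ser,
        RiskFactor.AGE_OF_ONSET: params.age_of_onset,
        RiskFactor.TIME_OUTDOORS: params.outdoors,
        RiskFactor.RPR_AT_PRESENTATION: params.rpr,
        RiskFactor.TIME_NEARWORK: params.nearwork,
        RiskFactor.NEAR_ESOPHORIA: params.near_phoria,
        RiskFactor.ACCOMMODATIVE_LAG: params.accom_error,
    }
    lin = np.zeros(len(next(iter(values.values()))))
    for f, x in values.items():
        coeff = params.outcome_coeffs.get(f, 0.0)
        if coeff == 0.0:
            continue
        if f is RiskFactor.MYOPIC_PARENTS:
            p0, p1, p2 = params.parents_probs
            m = p1 + 2 * p2
            sd = np.sqrt(p1 + 4 * p2 - m * m)
        else:
            m, sd = spec_of[f].target_moments()
        lin += coeff * RISK_DIRECTION[f] * (x - m) / sd
    return params.effect_scale * lin


def _calibrate_intercept(lin: np.ndarray, prevalence: float) -> float:
    """Intercept making mean(sigmoid(lin + c)) equal the target."""

    def gap(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(lin + c))))) - prevalence

    lo, hi = -50.0, 50.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_cohort(params: CohortParams = CohortParams()) -> SyntheticCohort:
    """Draw a full synthetic cohort; bit-for-bit reproducible given seed."""
    n = params.n
    rng = np.random.default_rng(params.seed)

    # ages with copula correlation; ordering clamp binds rarely (see docs)
    z_age, z_onset = _correlated_pair(rng, n, params.rho_age_onset)
    age = params.age_at_presentation.from_uniform(norm.cdf(z_age))
    onset = params.age_of_onset.from_uniform(norm.cdf(z_onset))
    onset = np.minimum(onset, age)

    parents = rng.choice(3, size=n, p=params.parents_probs)
    nearwork = params.nearwork.draw(rng, n)
    outdoors = params.outdoors.draw(rng, n)

    # per-eye optics: right/left correlated through a Gaussian copula
    ser_r, ser_l = _eye_pair(rng, n, params.ser, params.rho_eye)
    chg_r, chg_l = _eye_pair(rng, n, params.ser_change, params.rho_eye)
    accom_r, accom_l = _eye_pair(rng, n, params.accom_error, params.rho_eye)
    phoria_r, phoria_l = _eye_pair(rng, n, params.near_phoria, params.rho_eye)
    rpr_nas_r, rpr_nas_l = _eye_pair(rng, n, params.rpr, params.rho_eye)

    # temporal RPR: copula-correlated with the nasal meridian within an eye
    def _temporal(nasal: np.ndarray) -> np.ndarray:
        a, b = params.rpr._ab
        u_nas = np.clip(
            truncnorm.cdf(
                nasal, a, b, loc=params.rpr.mean, scale=params.rpr.sd
            ),
            1e-12,
            1 - 1e-12,
        )
        z = np.sqrt(params.rho_meridian) * norm.ppf(u_nas) + np.sqrt(
            1 - params.rho_meridian
        ) * rng.standard_normal(n)
        return params.rpr.from_uniform(norm.cdf(z))

    rpr_tmp_r = _temporal(rpr_nas_r)
    rpr_tmp_l = _temporal(rpr_nas_l)

    if params.include_al_change:
        al_r = params.al_per_diopter * chg_r + rng.normal(
            0.0, params.al_noise_sd_mm, n
        )
        al_l = params.al_per_diopter * chg_l + rng.normal(
            0.0, params.al_noise_sd_mm, n
        )
    else:
        al_r = al_l = None

    # latent propensity from patient-level (eye-averaged) factor values
    values = {
        RiskFactor.CHANGE_SER_OR_AL: (chg_r + chg_l) / 2,
        RiskFactor.AGE_AT_PRESENTATION: age,
        RiskFactor.SER_AT_PRESENTATION: (ser_r + ser_l) / 2,
        RiskFactor.AGE_OF_ONSET: onset,
        RiskFactor.TIME_OUTDOORS: outdoors,
        RiskFactor.RPR_AT_PRESENTATION: (
            np.maximum(rpr_nas_r, rpr_tmp_r) + np.maximum(rpr_nas_l, rpr_tmp_l)
        ) / 2,
        RiskFactor.TIME_NEARWORK: nearwork,
        RiskFactor.NEAR_ESOPHORIA: (phoria_r + phoria_l) / 2,
        RiskFactor.ACCOMMODATIVE_LAG: (accom_r + accom_l) / 2,
        RiskFactor.MYOPIC_PARENTS: parents.astype(float),
    }
    lin = _standardized_risk(params, values)
    c = _calibrate_intercept(lin, params.outcome_prevalence)
    propensity = 1.0 / (1.0 + np.exp(-(lin + c)))

    progressed = rng.uniform(size=n) < propensity
    gold = np.where(
        progressed,
        params.progressor_change.draw(rng, n),
        params.nonprogressor_change.draw(rng, n),
    )

    clinician = simulate_clinicians(
        propensity,
        n_raters=params.n_clinicians,
        target_kappa=params.clinician_kappa,
        seed=int(rng.integers(0, 2**31 - 1)),
        prevalence=params.label_prevalence,
    )

    records = []
    width = len(str(n))
    for i in range(n):
        labels = tuple(
            Decision.AT_RISK if clinician[k, i] else Decision.LOW_RISK
            for k in range(params.n_clinicians)
        )
        records.append(
            PatientRecord(
                patient_id=f"SYN{i + 1:0{width}d}",
                age_at_presentation_yr=float(age[i]),
                age_of_onset_yr=float(onset[i]),
                myopic_parents=int(parents[i]),
                outdoors_h_per_day=float(outdoors[i]),
                nearwork_h_per_day=float(nearwork[i]),
                right_eye=EyeMeasurements(
                    ser_d=float(ser_r[i]),
                    ser_change_d_per_yr=float(chg_r[i]),
                    al_change_mm_per_yr=(
                        float(al_r[i]) if al_r is not None else None
                    ),
                    rpr_nasal_d=float(rpr_nas_r[i]),
                    rpr_temporal_d=float(rpr_tmp_r[i]),
                    near_phoria_pd=float(phoria_r[i]),
                    accom_error_d=float(accom_r[i]),
                ),
                left_eye=EyeMeasurements(
                    ser_d=float(ser_l[i]),
                    ser_change_d_per_yr=float(chg_l[i]),
                    al_change_mm_per_yr=(
                        float(al_l[i]) if al_l is not None else None
                    ),
                    rpr_nasal_d=float(rpr_nas_l[i]),
                    rpr_temporal_d=float(rpr_tmp_l[i]),
                    near_phoria_pd=float(phoria_l[i]),
                    accom_error_d=float(accom_l[i]),
                ),
                clinician_labels=labels,
            )
        )

    return SyntheticCohort(
        records=records,
        latent_risk=propensity,
        gold_outcome=gold,
        clinician_labels=clinician,
        params=params,
    )


def kappa_of_flip(epsilon: float, prevalence: float) -> float:
    """Expected Cohen's kappa between a rater and its eps-flipped copy.

    Closed form on the expected 2x2 table: p_o = 1 - eps, the copy's
    positive rate is pi(1-eps) + (1-pi)eps, and p_e follows from the
    marginals.
    """
    pi = prevalence
    p_o = 1.0 - epsilon
    pi2 = pi * (1.0 - epsilon) + (1.0 - pi) * epsilon
    p_e = pi * pi2 + (1.0 - pi) * (1.0 - pi2)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def flip_probability_for_kappa(
    target_kappa: float, prevalence: float
) -> float:
    """Symmetric flip probability yielding the target expected kappa."""
    if not 0.0 < target_kappa <= 1.0:
        raise ValueError("target_kappa must be in (0, 1]")
    if target_kappa == 1.0:
        return 0.0
    return float(
        brentq(
            lambda e: kappa_of_flip(e, prevalence) - target_kappa,
            0.0,
            0.5,
            xtol=1e-12,
        )
    )


def simulate_clinicians(
    latent_risk: np.ndarray,
    n_raters: int = 5,
    target_kappa: float = 0.95,
    seed: int = 0,
    prevalence: float = 114 / 149,
) -> np.ndarray:
    """Simulate raters with calibrated pairwise agreement.

    Rater 1 thresholds the latent propensity at the (1 - prevalence)
    quantile; raters 2..k copy rater 1 with a symmetric flip probability
    solved in closed form so each copy's expected kappa with rater 1
    equals ``target_kappa``.  Returns a (n_raters, n) boolean array.
    """
    p = np.asarray(latent_risk, dtype=float)
    thr = np.quantile(p, 1.0 - prevalence)
    rater1 = p > thr
    eps = flip_probability_for_kappa(target_kappa, float(rater1.mean()))
    rng = np.random.default_rng(seed)
    labels = np.empty((n_raters, p.size), dtype=bool)
    labels[0] = rater1
    for k in range(1, n_raters):
        flips = rng.uniform(size=p.size) < eps
        labels[k] = rater1 ^ flips
    return labels


def simulate_followup(
    cohort: SyntheticCohort,
    seed: Optional[int] = None,
    noise_sd: Optional[float] = None,
) -> np.ndarray:
    """Observed 1-year SER change: gold outcome plus measurement noise.

    With ``noise_sd=0`` the follow-up equals the gold outcome exactly.
    Defaults come from the cohort's params; the returned values are also
    written onto the records' follow-up field.
    """
    if seed is None:
        seed = cohort.params.seed + 1
    if noise_sd is None:
        noise_sd = cohort.params.followup_noise_sd
    rng = np.random.default_rng(seed)
    observed = cohort.gold_outcome + (
        rng.normal(0.0, noise_sd, cohort.n) if noise_sd > 0 else 0.0
    )
    cohort.records = [
        replace(rec, followup_ser_change_d_per_yr=float(v))
        for rec, v in zip(cohort.records, observed)
    ]
    return observed
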