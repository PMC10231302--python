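"""ROC calibration and agreement statistics for risk-score decisions.

Implements the statistical battery used to calibrate and appraise the
score: ROC coordinates over midpoint thresholds, trapezoidal AUC (equal
to the normalised Mann-Whitney concordance with half credit for ties)
with the Hanley-McNeil closed-form standard error, Youden's J cut-point
selection, confusion statistics at a cut-off, Cohen's kappa for
inter-rater agreement, and validation of score decisions against an
observed 1-year refraction change (progression defined as a myopic SER
change of at least 0.50 D/year).

The positive class is AT_RISK throughout and scores are oriented
"higher = riskier"; an AUC below 0.5 triggers a warning rather than a
silent flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .factors import Decision


class DegenerateRocError(ValueError):
    """ROC is undefined: only one class present in the labels."""


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    """Normalise labels to a boolean array (True = AT_RISK / positive)."""
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, Decision):
            out[i] = lab is Decision.AT_RISK
        elif isinstance(lab, str):
            key = lab.strip().lower()
            if key in ("at_risk", "at-risk", "positive", "1", "true"):
                out[i] = True
            elif key in ("low_risk", "low-risk", "negative", "0", "false"):
                out[i] = False
            else:
                raise ValueError(f"unrecognised label {lab!r}")
        elif isinstance(lab, (bool, np.bool_, int, np.integer)):
            out[i] = bool(lab)
        else:
            raise ValueError(f"unrecognised label {lab!r}")
    return out


@dataclass(frozen=True)
class RocResult:
    """ROC coordinates plus AUC, its SE, and the optimal cut-off."""

    thresholds: np.ndarray  # ascending midpoints with sentinels
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    best_cutoff: float
    best_j: float
    n_pos: int
    n_neg: int

    def confusion_at_best(self) -> "ConfusionAtCutoff":
        i = int(np.argmin(np.abs(self.thresholds - self.best_cutoff)))
        sens = float(self.sensitivity[i])
        spec = float(self.specificity[i])
        tp = round(sens * self.n_pos)
        tn = round(spec * self.n_neg)
        return ConfusionAtCutoff(
            tp=tp,
            fp=self.n_neg - tn,
            tn=tn,
            fn=self.n_pos - tp,
            sensitivity=sens,
            specificity=spec,
            youden_j=youden_j(sens, spec),
        )


@dataclass(frozen=True)
class ConfusionAtCutoff:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    youden_j: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def youden_j(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (np.isnan(v) or 0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return sensitivity + specificity - 1.0


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of a nonparametric AUC.

    SE^2 = [A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)] / (n+ n-),
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc(scores: Sequence[float], labels: Sequence) -> RocResult:
    """ROC analysis of a risk score against binary decisions.

    A subject is called positive when ``score > threshold``.  On an
    integer-valued score the candidate thresholds are the half-integers
    (one sentinel below the minimum, then each observed score + 0.5),
    so every reported cut-off is an unattainable x.50 value — the
    convention behind published cut-offs like 41.50.  On fractional
    scores the thresholds are the midpoints between consecutive
    distinct observed scores plus the two sentinels.
    The AUC is the trapezoidal area over (1-specificity, sensitivity),
    identical to the normalised Mann-Whitney statistic with half credit
    for ties; its SE is Hanley-McNeil.  Among thresholds tied on Youden's
    J the lowest is reported (maximises sensitivity — screening context).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if s.size < 2:
        raise ValueError("need at least two subjects")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateRocError(
            f"labels contain a single class (n_pos={n_pos}, n_neg={n_neg})"
        )

    uniq = np.unique(s)
    if np.allclose(uniq, np.round(uniq)):
        # integer score: cut on the half-integer grid (x.50 pattern)
        thresholds = np.concatenate(([uniq[0] - 0.5], uniq + 0.5))
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate(([uniq[0] - 0.5], mids, [uniq[-1] + 0.5]))

    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    # positives with score > t  /  negatives with score <= t
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="right") / n_pos
    spec = np.searchsorted(neg_sorted, thresholds, side="right") / n_neg

    # trapezoid over the ROC polyline; thresholds ascending => fpr descending
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    if auc < 0.5:
        warnings.warn(
            f"AUC={auc:.3f} < 0.5: the score is oriented against the "
            "positive class (no automatic flipping is applied)",
            UserWarning,
            stacklevel=2,
        )

    j = sens + spec - 1.0
    best_idx = int(np.flatnonzero(j == j.max())[0])  # lowest tied threshold
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=hanley_mcneil_se(auc, n_pos, n_neg),
        best_cutoff=float(thresholds[best_idx]),
        best_j=float(j[best_idx]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence, cutoff: float
) -> ConfusionAtCutoff:
    """Confusion statistics calling positive when ``score > cutoff``."""
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    pred = s > cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionAtCutoff(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        youden_j=sens + spec - 1.0,
    )


def cohens_kappa(rater1: Sequence, rater2: Sequence) -> float:
    """Chance-corrected agreement between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    Returns 1.0 in the degenerate p_e = 1 case (both raters constant and
    identical, hence perfect observed agreement).
    """
    a = _as_bool_labels(rater1)
    b = _as_bool_labels(rater2)
    if a.shape != b.shape:
        raise ValueError("rater label vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = float(np.mean(a == b))
    pa = float(np.mean(a))
    pb = float(np.mean(b))
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def validate_against_outcome(
    classifications: Sequence,
    ser_change_followup: Sequence[float],
    progression_threshold: float = 0.50,
) -> ConfusionAtCutoff:
    """Compare score decisions against observed 1-year progression.

    The outcome is positive when the myopic SER change is at least
    ``progression_threshold`` D/year in magnitude, i.e. a signed change
    <= -0.50 D/yr under the convention that negative = more myopic.
    Subjects with a missing follow-up value are excluded with a warning.
    A single-class outcome yields NaN for the undefined proportion, with
    a warning.
    """
    pred = _as_bool_labels(classifications)
    chg = np.asarray(
        [np.nan if v is None else float(v) for v in ser_change_followup],
        dtype=float,
    )
    if pred.shape != chg.shape:
        raise ValueError("classifications and follow-up must align")
    missing = np.isnan(chg)
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} subject(s) with missing "
            f"follow-up (indices {np.flatnonzero(missing).tolist()})",
            UserWarning,
            stacklevel=2,
        )
        pred, chg = pred[~missing], chg[~missing]
    outcome = chg <= -abs(progression_threshold)
    tp = int(np.sum(pred & outcome))
    fp = int(np.sum(pred & ~outcome))
    tn = int(np.sum(~pred & ~outcome))
    fn = int(np.sum(~pred & outcome))
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn(
            "single-class outcome: sensitivity or specificity undefined "
            "(reported as NaN)",
            UserWarning,
            stacklevel=2,
        )
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionAtCutoff(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        youden_j=sens + spec - 1.0,
    )


def auc_sample_size(
    auc_alt: float = 0.90,
    auc_null: float = 0.80,
    alpha: float = 0.05,
    power: float = 0.80,
    neg_per_pos: float = 31 / 101,
    max_n_pos: int = 100000,
) -> int:
    """Smallest total n distinguishing ``auc_alt`` from ``auc_null``.

    Normal-approximation power calculation with Hanley-McNeil variances
    under the null and alternative, two-sided ``alpha``, and a fixed
    negative:positive class ratio.  Returns the total sample size.
    """
    if not auc_alt > auc_null:
        raise ValueError("auc_alt must exceed auc_null")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    delta = auc_alt - auc_null
    for n_pos in range(2, max_n_pos + 1):
        n_neg = max(2, int(np.ceil(neg_per_pos * n_pos)))
        se0 = hanley_mcneil_se(auc_null, n_pos, n_neg)
        se1 = hanley_mcneil_se(auc_alt, n_pos, n_neg)
        if z_a * se0 + z_b * se1 <= delta:
            return n_pos + n_neg
    raise RuntimeError("sample size search did not converge")
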