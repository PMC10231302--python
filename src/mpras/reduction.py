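"""Factor ranking, stepwise sub-model sweep, and the eigenvalue screen.

Three routes to the same question — how few of the ten factors are
needed:

* :func:`permutation_importance` ranks factors by the drop in a fitted
  classifier's metric when one feature column is shuffled (classifier
  agnostic: anything with ``predict`` works).
* :func:`submodel_sweep` re-scores the cohort under the nested 10..4
  factor subsets and re-runs the ROC calibration for each, producing a
  sweep table (cut-off, J, sensitivity, specificity, AUC +/- SE).
* :func:`pca_screen` applies the Kaiser criterion (correlation-matrix
  eigenvalues > 1) to the numeric factor table.

The canonical factor ranking used for the shipped ``1a``-``1g`` presets
is the published ordering, hard-coded rather than re-derived at runtime
(the original classifier settings are unreported, so a re-derived
ranking would not be reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import RocResult, roc
from .factors import (
    FACTOR_ORDER,
    PatientRecord,
    RiskFactor,
    ThresholdTable,
    DEFAULT_THRESHOLDS,
    factor_value,
)
from .scoring import (
    SUBMODEL_DROP_ORDER,
    RiskModelSpec,
    score,
    select_eye,
)

#: Published permutation-importance ranking, most important first.
CANONICAL_RANKING: tuple[RiskFactor, ...] = tuple(
    [f for f in FACTOR_ORDER if f not in SUBMODEL_DROP_ORDER]
    + list(reversed(SUBMODEL_DROP_ORDER))
)


@dataclass(frozen=True)
class ImportanceResult:
    """Mean metric drop per feature, dispersion, and the ranking."""

    importances: dict[str, float]
    stds: dict[str, float]
    ranking: tuple[str, ...]
    baseline: float
    metric: str


@dataclass(frozen=True)
class PcaScreenResult:
    """Correlation-matrix eigenvalues and the Kaiser retention count."""

    eigenvalues: np.ndarray  # descending
    n_retained: int


def default_classifier(seed: int = 0):
    """A gradient-boosted-tree classifier with fixed hyperparameters.

    Settings are deliberately plain (200 depth-3 trees, learning rate
    0.1, single thread) so importance demos are reproducible.
    """
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=200,
        max_depth=3,
        learning_rate=0.1,
        subsample=1.0,
        colsample_bytree=1.0,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )


def _metric_fn(metric: str):
    if metric == "accuracy":
        def acc(clf, X, y):
            return float(np.mean(np.asarray(clf.predict(X)).ravel() == y))
        return acc
    if metric == "auc":
        def auc_metric(clf, X, y):
            p = np.asarray(clf.predict_proba(X))[:, 1]
            return roc(p, y.astype(bool)).auc
        return auc_metric
    raise ValueError(f"metric must be 'accuracy' or 'auc', got {metric!r}")


def permutation_importance(
    classifier,
    features,
    labels: Sequence,
    n_repeats: int = 10,
    seed: int = 0,
    metric: str = "accuracy",
    rng: Optional[np.random.Generator] = None,
) -> ImportanceResult:
    """Metric drop when each feature column is independently permuted.

    ``classifier`` must already be fitted and expose ``predict`` (and
    ``predict_proba`` for the ``auc`` metric).  ``features`` is a
    DataFrame or 2-D array; ``importance(f) = baseline - mean(metric
    over n_repeats permutations of column f)``.  ``rng`` overrides the
    seeded generator (useful for degenerate-permutation stubs).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"feature_{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; importance is undefined")

    mfn = _metric_fn(metric)
    try:
        baseline = mfn(classifier, X, y)
    except Exception as exc:  # unfitted or incompatible classifier
        raise ValueError(
            f"classifier is not usable (fitted?): {exc}"
        ) from exc

    if rng is None:
        rng = np.random.default_rng(seed)
    n = X.shape[0]
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for j, name in enumerate(names):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            drops[r] = baseline - mfn(classifier, Xp, y)
        means[name] = float(drops.mean())
        stds[name] = float(drops.std(ddof=0))
    ranking = tuple(sorted(names, key=lambda k: -means[k]))
    return ImportanceResult(
        importances=means,
        stds=stds,
        ranking=ranking,
        baseline=baseline,
        metric=metric,
    )


def factor_table(
    records: Sequence[PatientRecord],
    eye_choice: str = "random",
    seed: int = 0,
    factors: Sequence[RiskFactor] = FACTOR_ORDER,
) -> pd.DataFrame:
    """Numeric per-patient factor table (raw measurements, one eye each)."""
    rows = []
    index = []
    for rec in records:
        _, eye = select_eye(rec, eye_choice, seed)
        rows.append({f.value: factor_value(f, rec, eye) for f in factors})
        index.append(rec.patient_id)
    return pd.DataFrame(rows, index=index)


def pca_screen(features) -> PcaScreenResult:
    """Kaiser eigenvalue screen on the correlation matrix.

    Standardisation is implicit in using the correlation (not
    covariance) matrix; eigenvalues therefore sum to the number of
    variables.  Retains components with eigenvalue > 1.
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"var_{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    sd = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            "constant column(s): " + ", ".join(names[i] for i in constant)
        )
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    return PcaScreenResult(
        eigenvalues=eig, n_retained=int(np.sum(eig > 1.0))
    )


def submodel_sweep(
    records: Sequence[PatientRecord],
    gold_labels: Sequence,
    ordering: Optional[Sequence[RiskFactor]] = None,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    eye_choice: str = "random",
    seed: int = 0,
) -> pd.DataFrame:
    """Nested 10..4-factor sweep with a fresh ROC calibration per step.

    Starting from all ten factors, repeatedly drop the lowest-ranked
    remaining factor of ``ordering`` (default: the canonical published
    ranking), re-score, and re-run the ROC against ``gold_labels``.
    The first row (all factors) is by construction identical to a direct
    full-model evaluation.  Returns a sweep-table DataFrame with one row
    per sub-model.
    """
    order = tuple(ordering) if ordering is not None else CANONICAL_RANKING
    if set(order) != set(FACTOR_ORDER):
        raise ValueError("ordering must cover all 10 factors exactly once")

    # score the full model once; sub-model totals are contribution sums
    full = RiskModelSpec(
        name="model1", factors=FACTOR_ORDER, thresholds=thresholds
    )
    contribs = []
    for rec in records:
        bd = score(rec, full, eye_choice=eye_choice, seed=seed)
        contribs.append({fs.factor: fs.contribution for fs in bd.factor_scores})

    rows = []
    for i, k in enumerate(range(len(order), len(order) - 7, -1)):
        kept = set(order[:k])
        name = f"1{chr(ord('a') + i)}"
        totals = np.array(
            [sum(c[f] for f in c if f in kept) for c in contribs]
        )
        r: RocResult = roc(totals, gold_labels)
        rows.append(
            {
                "model": name,
                "n_factors": k,
                "factors": ",".join(
                    f.value for f in FACTOR_ORDER if f in kept
                ),
                "best_cutoff": r.best_cutoff,
                "youden_j": r.best_j,
                "sensitivity": float(
                    r.sensitivity[
                        np.argmin(np.abs(r.thresholds - r.best_cutoff))
                    ]
                ),
                "specificity": float(
                    r.specificity[
                        np.argmin(np.abs(r.thresholds - r.best_cutoff))
                    ]
                ),
                "auc": r.auc,
                "auc_se": r.auc_se,
            }
        )
    return pd.DataFrame(rows)
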