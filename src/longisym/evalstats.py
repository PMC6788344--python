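"""Evaluation harness: cross-validation, ROC metrics, DeLong, Monte-Carlo CIs.

Conventions:

* AUC is the rank-based (Mann-Whitney) estimator with ties counted 1/2,
  computed from midranks.
* The operating point is the empirical ROC point at minimum Euclidean
  distance from the upper-left corner (perfect sensitivity and
  specificity); ties resolve to the lowest threshold.  Balanced accuracy
  is the mean of sensitivity and specificity there.
* Paired AUCs are compared with DeLong's test via the midrank covariance
  construction.
* Confidence intervals are percentile intervals of the AUC over seeded
  Monte-Carlo subsamples (default 1000 iterations at 80% of the data,
  drawn without replacement).
* Repeated stratified 10-fold cross-validation (default 100 repeats)
  averages each subject's out-of-fold probability over repeats before a
  single ROC is built; the network uses a single stratified 10-fold scheme
  with an extra validation fold (80/10/10), and an external cohort is
  scored by averaging the 10 fold-models' probabilities per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, KFold

from .baselines import IqrScaler, fit_baseline
from .errors import (
    ConfigurationError,
    InputError,
    NumericalDegeneracyError,
    UndefinedMetricError,
)

__all__ = [
    "CvScheme",
    "ScoreSet",
    "MetricsReport",
    "make_splits",
    "auc",
    "choose_cutoff",
    "delong_test",
    "mc_confidence_interval",
    "evaluate_scores",
    "cross_validate_features",
    "ensemble_score",
]


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation scheme.

    ``repeated_10fold``: n_repeats independent stratified 10-fold splits
    (train 90% / test 10%); ``single_10fold_with_val``: one stratified
    10-fold partition where each fold serves once as test, the next fold
    as validation, the rest as training (80/10/10).
    """

    kind: str = "repeated_10fold"
    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_10fold", "single_10fold_with_val"):
            raise ConfigurationError(f"unknown scheme kind {self.kind!r}")
        if self.n_folds < 3:
            raise ConfigurationError("need at least 3 folds")


@dataclass
class ScoreSet:
    """Per-subject averaged probabilities with labels."""

    subject_ids: list[str]
    probabilities: np.ndarray
    labels: np.ndarray
    n_predictions: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.n_predictions = np.asarray(self.n_predictions, dtype=int)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise InputError("probabilities must lie in [0, 1]")
        if not (
            len(self.subject_ids)
            == len(self.probabilities)
            == len(self.labels)
            == len(self.n_predictions)
        ):
            raise InputError("ScoreSet fields must have one entry per subject")


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    cutoff: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise InputError("CI must bracket the point AUC")

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "cutoff": self.cutoff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


# ---- splits -----------------------------------------------------------------


def make_splits(labels: Sequence[int], scheme: CvScheme):
    """Fold assignments, deterministic from the scheme's seed.

    ``repeated_10fold`` returns a list (one per repeat) of lists of
    (train_idx, test_idx); ``single_10fold_with_val`` returns a list of
    (train_idx, val_idx, test_idx).
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if scheme.stratified and counts.min() < scheme.n_folds:
        raise ConfigurationError(
            f"stratified {scheme.n_folds}-fold needs >= {scheme.n_folds} subjects per "
            f"class, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    splitter_cls = StratifiedKFold if scheme.stratified else KFold

    if scheme.kind == "repeated_10fold":
        repeats = []
        for rep in range(scheme.n_repeats):
            skf = splitter_cls(
                n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + rep
            )
            repeats.append([(tr, te) for tr, te in skf.split(np.zeros_like(y), y)])
        return repeats

    skf = splitter_cls(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
    folds = [te for _, te in skf.split(np.zeros_like(y), y)]
    out = []
    for k in range(scheme.n_folds):
        test = folds[k]
        val = folds[(k + 1) % scheme.n_folds]
        train = np.concatenate(
            [folds[j] for j in range(scheme.n_folds) if j not in (k, (k + 1) % scheme.n_folds)]
        )
        out.append((np.sort(train), np.sort(val), np.sort(test)))
    return out


# ---- ROC metrics ------------------------------------------------------------


def _check_two_class(labels: np.ndarray) -> None:
    if set(np.unique(labels)) != {0, 1}:
        raise UndefinedMetricError("metric needs both classes (labels 0 and 1)")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (Mann-Whitney) with ties counted 1/2, via midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_class(y)
    ranks = stats.rankdata(s)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _operating_points(scores: np.ndarray, labels: np.ndarray):
    """(threshold, sensitivity, specificity) for each 'score >= t' rule."""
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    pos = labels == 1
    neg = ~pos
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[neg] < t).mean() for t in thresholds])
    return thresholds, sens, spec


def choose_cutoff(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """Operating point at minimum distance from the ROC's upper-left corner.

    Returns (threshold, sensitivity, specificity, balanced_accuracy); ties
    in distance resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_class(y)
    thresholds, sens, spec = _operating_points(s, y)
    dist = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
    best = int(np.argmin(dist))  # argmin takes the first = lowest threshold
    return (
        float(thresholds[best]),
        float(sens[best]),
        float(spec[best]),
        float((sens[best] + spec[best]) / 2),
    )


# ---- DeLong -----------------------------------------------------------------


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the per-positive (V10) and per-negative (V01) structural parts."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    a = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return a, v10, v01


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Two-sided DeLong comparison of two paired AUCs.

    Returns (auc_a, auc_b, p_value).  Identical score vectors give p = 1;
    a zero-variance difference with unequal AUCs is a numerical degeneracy.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise InputError("paired scores and labels must have equal length")
    _check_two_class(y)
    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        if np.isclose(delta, 0):
            return float(auc_a), float(auc_b), 1.0
        raise NumericalDegeneracyError(
            "zero DeLong variance with unequal AUCs"
        )
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# ---- Monte-Carlo CI ---------------------------------------------------------


def mc_confidence_interval(
    scores: Sequence[float],
    labels: Sequence[int],
    iters: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
) -> tuple[float, float]:
    """2.5/97.5 percentile AUC interval over subsamples without replacement.

    Subsamples that lose a class are redrawn.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_class(y)
    rng = np.random.default_rng([seed, 13])
    n = len(s)
    k = max(2, int(round(frac * n)))
    aucs = np.empty(iters)
    for i in range(iters):
        for _ in range(1000):
            idx = rng.choice(n, size=k, replace=False)
            if len(set(y[idx])) == 2:
                break
        else:  # pragma: no cover - practically unreachable
            raise NumericalDegeneracyError("could not draw a two-class subsample")
        aucs[i] = auc(s[idx], y[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_iters: int = 1000,
    ci_frac: float = 0.8,
    seed: int = 0,
) -> MetricsReport:
    """Full metrics report: AUC, min-corner operating point, Monte-Carlo CI."""
    a = auc(scores, labels)
    cutoff, sens, spec, bal = choose_cutoff(scores, labels)
    lo, hi = mc_confidence_interval(scores, labels, iters=ci_iters, frac=ci_frac, seed=seed)
    return MetricsReport(
        auc=a,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
        cutoff=cutoff,
        ci_low=min(lo, a),
        ci_high=max(hi, a),
    )


# ---- cross-validation drivers ----------------------------------------------


def cross_validate_features(
    X: np.ndarray,
    y: Sequence[int],
    kind: str,
    scheme: CvScheme,
    scale_iqr: bool = True,
    subject_ids: Sequence[str] | None = None,
) -> ScoreSet:
    """Repeated k-fold CV of a feature-based classifier with averaged probabilities.

    Per repeat, every subject is scored exactly once (in its test fold);
    the final probability is the mean over repeats.  IQR scaling, when
    enabled, is fit on each training fold only.
    """
    if scheme.kind != "repeated_10fold":
        raise ConfigurationError("cross_validate_features expects the repeated scheme")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(len(y))]
    sums = np.zeros(len(y))
    counts = np.zeros(len(y), dtype=int)
    for rep, folds in enumerate(make_splits(y, scheme)):
        for tr, te in folds:
            Xtr, Xte = X[tr], X[te]
            if scale_iqr:
                scaler = IqrScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            clf = fit_baseline(Xtr, y[tr], kind, seed=scheme.seed * 1000 + rep)
            prob = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
            sums[te] += prob
            counts[te] += 1
    return ScoreSet(ids, sums / counts, y, counts)


def ensemble_score(
    models: Sequence,
    external_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    subject_ids: Sequence[str] | None = None,
    labels: Sequence[int] | None = None,
    expected_models: int = 10,
) -> ScoreSet:
    """Average each fold-model's probability per external subject.

    ``models`` must be the complete set of fold models (default 10) from a
    finished single-10-fold run; every external subject receives the mean
    of all models' progressor probabilities.
    """
    if len(models) < expected_models:
        raise ConfigurationError(
            f"expected {expected_models} fold models, got {len(models)}"
        )
    n = len(external_pairs)
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)]
    probs = np.zeros(n)
    for model in models:
        x1 = np.stack([np.asarray(p[0], dtype=np.float32) for p in external_pairs])
        x2 = np.stack([np.asarray(p[1], dtype=np.float32) for p in external_pairs])
        probs += model.predict_proba(x1, x2)
    probs /= len(models)
    y = np.asarray(labels, dtype=int) if labels is not None else np.zeros(n, dtype=int)
    return ScoreSet(ids, probs, y, np.full(n, len(models)))
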