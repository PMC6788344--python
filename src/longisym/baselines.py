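"""Comparison models.

Two feature paths feed general-purpose classifiers:

* voxel features: the elementwise absolute difference between the two
  aligned sessions, flattened in C (row-major) voxel order, classified by a
  linear SVM or random forest;
* region-volume features: per-region volumes for each session reduced to
  their elementwise absolute longitudinal difference, scaled per column by
  training-set inter-quartile range (x - Q1) / (Q3 - Q1), classified by
  L1-regularized logistic regression.

The SVM exposes probabilities through Platt scaling of its decision
function (a calibrated decision-function mapping); quartiles use linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .errors import InputError, TrainingError
from .preproc import PreprocessedPair

__all__ = [
    "IqrScaler",
    "voxel_feature",
    "longitudinal_region_feature",
    "region_volume_features",
    "fit_baseline",
    "BASELINE_KINDS",
]

BASELINE_KINDS = ("l1_logistic", "linear_svm", "random_forest")


def voxel_feature(pair: PreprocessedPair | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Flattened |session1 - session2| in fixed C-order."""
    if isinstance(pair, PreprocessedPair):
        s1 = np.asarray(pair.session1.data, dtype=float)
        s2 = np.asarray(pair.session2.data, dtype=float)
    else:
        s1, s2 = (np.asarray(p, dtype=float) for p in pair)
    if s1.shape != s2.shape:
        raise InputError(f"session shapes differ: {s1.shape} vs {s2.shape}")
    return np.abs(s1 - s2).ravel(order="C")


def longitudinal_region_feature(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Elementwise |v1 - v2| of two per-region volume vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise InputError("region vectors must share region set and order")
    return np.abs(v1 - v2)


def region_volume_features(volume_data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-region integrated intensity, a volume proxy under intensity loss.

    Ordered by ascending region id; background label 0 excluded.
    """
    labels = np.rint(np.asarray(labels)).astype(int)
    ids = sorted(set(np.unique(labels)) - {0})
    data = np.asarray(volume_data, dtype=float)
    return np.asarray([data[labels == r].sum() for r in ids])


@dataclass
class IqrScaler:
    """Per-column inter-quartile scaling fit on training rows only."""

    q1: np.ndarray | None = None
    q3: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # columns with Q3 == Q1

    def fit(self, X: np.ndarray) -> "IqrScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 4:
            raise InputError("IQR scaling needs a 2-D matrix with >= 4 training rows")
        self.q1 = np.quantile(X, 0.25, axis=0)  # linear-interpolation quantiles
        self.q3 = np.quantile(X, 0.75, axis=0)
        self.degenerate = self.q3 <= self.q1
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.q1 is None:
            raise InputError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        denom = np.where(self.degenerate, 1.0, self.q3 - self.q1)
        out = (X - self.q1) / denom
        out[:, self.degenerate] = 0.0  # constant columns carry no signal
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_baseline(features: np.ndarray, labels: np.ndarray, kind: str, seed: int = 0):
    """Train a probability-producing baseline classifier.

    ``kind`` is one of ``l1_logistic``, ``linear_svm``, ``random_forest``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y)) < 2:
        raise TrainingError("both classes must be present to train a baseline")
    if kind == "l1_logistic":
        clf = LogisticRegression(
            penalty="l1", solver="liblinear", C=1.0, random_state=seed, max_iter=2000
        )
    elif kind == "linear_svm":
        # Platt-scaled decision function provides the probability output.
        clf = CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), method="sigmoid", cv=3,
            ensemble=False,
        )
    elif kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    else:
        raise InputError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")
    clf.fit(X, y)
    return clf
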