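"""K-nearest-neighbors validation of selected feature sets.

Small-cohort validation: leave-one-out cross-validation (one fold per
subject) and a single train/test split, both reported as 2x2 confusion
matrices with the target class as positive.  Feature columns mix scales
across five orders of magnitude (regional volumes ~1e4 vs curvature
~1e-1), so z-score standardization — fit on the training rows only,
refit inside every LOOCV fold — is the default; it can be switched off
for sensitivity analysis.

Deterministic tie rules (the study uses even k, which forces them):

* an exact distance tie for the k-th neighbor slot goes to the earlier
  training row;
* a tied plurality vote goes to the class of the single nearest
  neighbor among the tied classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .feature_table import FeatureTable

__all__ = [
    "KNNConfig",
    "ConfusionMatrix",
    "ScalingStats",
    "fit_scaling",
    "apply_scaling",
    "knn_predict",
    "loocv",
    "train_test_classify",
    "matrix_metrics",
]


@dataclass(frozen=True)
class KNNConfig:
    """Neighbor count, metric and scaling policy for one experiment."""

    k: int = 3
    distance: str = "euclidean"
    scaling: str = "zscore"
    tie_break: str = "nearest_neighbor_class"
    seed: int = 0  # reserved; the classifier itself is deterministic

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.distance not in ("euclidean", "manhattan"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.scaling not in ("zscore", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.tie_break != "nearest_neighbor_class":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class ConfusionMatrix:
    """2x2 counts with the target class as positive."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def add(self, true_positive_class: bool, predicted_positive: bool) -> None:
        if true_positive_class:
            if predicted_positive:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted_positive:
                self.fp += 1
            else:
                self.tn += 1

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


def matrix_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, PPV and recall (class coverage) of a confusion matrix.

    PPV is NaN-flagged when nothing was predicted positive.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": cm.accuracy,
        "ppv": cm.ppv,
        "ppv_defined": (cm.tp + cm.fp) > 0,
        "recall": cm.recall,
    }


@dataclass(frozen=True)
class ScalingStats:
    """Per-feature location (mean) and scale (sd) fit on training rows."""

    location: np.ndarray
    scale: np.ndarray


def fit_scaling(train: FeatureTable) -> ScalingStats:
    """Mean/sd per feature from the training rows only.

    Constant features (sd 0) fall back to scale 1 with a warning, so a
    degenerate column cannot blow up the standardization.
    """
    if train.n_subjects == 0:
        raise ValueError("cannot fit scaling on an empty table")
    loc = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=0)
    if np.any(sd == 0.0):
        flat = [train.feature_names[j] for j in np.flatnonzero(sd == 0.0)]
        warnings.warn(f"constant feature(s) {flat}: scale falls back to 1", stacklevel=2)
        sd = np.where(sd == 0.0, 1.0, sd)
    return ScalingStats(location=loc, scale=sd)


def apply_scaling(values: np.ndarray, stats: ScalingStats | None) -> np.ndarray:
    if stats is None:
        return values
    return (values - stats.location) / stats.scale


def _distances(train_X: np.ndarray, x: np.ndarray, metric: str) -> np.ndarray:
    diff = train_X - x
    if metric == "euclidean":
        return np.sqrt((diff * diff).sum(axis=1))
    return np.abs(diff).sum(axis=1)


def knn_predict(
    train: FeatureTable,
    test_row: np.ndarray | Sequence[float],
    config: KNNConfig,
    scaling: ScalingStats | None = None,
) -> str:
    """Predict one subject's label by plurality vote of its k nearest
    training subjects (tie rules in the module docstring)."""
    if config.k > train.n_subjects:
        raise ValueError(
            f"k={config.k} exceeds the {train.n_subjects} training rows"
        )
    x = np.asarray(test_row, dtype=float)
    if x.shape != (train.n_features,):
        raise ValueError(
            f"test row has {x.shape} values, train has {train.n_features} features"
        )
    if scaling is None and config.scaling == "zscore":
        scaling = fit_scaling(train)
    train_X = apply_scaling(train.values, scaling)
    xs = apply_scaling(x, scaling)
    d = _distances(train_X, xs, config.distance)
    # stable sort: among exact distance ties the earlier training row wins a slot
    order = np.argsort(d, kind="stable")[: config.k]
    votes: dict[str, int] = {}
    for i in order:
        lbl = train.outcome[i]
        votes[lbl] = votes.get(lbl, 0) + 1
    top = max(votes.values())
    tied = [lbl for lbl, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    # vote tie: class of the single nearest neighbor among the tied classes
    for i in order:
        if train.outcome[i] in tied:
            return train.outcome[i]
    raise AssertionError("unreachable: tied classes have at least one neighbor")


def loocv(table: FeatureTable, config: KNNConfig) -> tuple[ConfusionMatrix, dict[str, str]]:
    """Leave-one-out cross-validation over every subject.

    Scaling is refit on the remaining N-1 rows in each fold, so no
    information from the held-out subject leaks into the standardization.
    """
    if config.k > table.n_subjects - 1:
        raise ValueError(
            f"k={config.k} exceeds the {table.n_subjects - 1} rows available "
            "to each leave-one-out fold"
        )
    cm = ConfusionMatrix()
    predictions: dict[str, str] = {}
    for i, sid in enumerate(table.subjects):
        rest = [j for j in range(table.n_subjects) if j != i]
        train = FeatureTable(
            subjects=[table.subjects[j] for j in rest],
            features=list(table.features),
            values=table.values[rest, :],
            outcome=[table.outcome[j] for j in rest],
            target_class=table.target_class,
        )
        scaling = fit_scaling(train) if config.scaling == "zscore" else None
        pred = knn_predict(train, table.values[i], config, scaling)
        predictions[sid] = pred
        cm.add(
            true_positive_class=table.outcome[i] == table.target_class,
            predicted_positive=pred == table.target_class,
        )
    return cm, predictions


def train_test_classify(
    train: FeatureTable, test: FeatureTable, config: KNNConfig
) -> tuple[ConfusionMatrix, dict[str, str]]:
    """Fit on ``train``, predict every ``test`` subject independently."""
    if set(train.subjects) & set(test.subjects):
        raise ValueError("train and test subject sets overlap")
    if train.feature_names != test.feature_names:
        raise ValueError("train and test tables must share feature columns")
    if test.n_subjects == 0:
        raise ValueError("empty test table")
    scaling = fit_scaling(train) if config.scaling == "zscore" else None
    cm = ConfusionMatrix()
    predictions: dict[str, str] = {}
    for i, sid in enumerate(test.subjects):
        pred = knn_predict(train, test.values[i], config, scaling)
        predictions[sid] = pred
        cm.add(
            true_positive_class=test.outcome[i] == train.target_class,
            predicted_positive=pred == train.target_class,
        )
    return cm, predictions
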