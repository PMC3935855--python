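"""Difficulty-graded classification benchmark.

Scenario difficulty is defined by the similarity between the two gas
classes — a property of the input mixtures, independent of any sensor
model.  The three canonical two-class scenarios are:

==========  ==============  ==============
difficulty  class 1         class 2
==========  ==============  ==============
1           A 0.02          C 0.5
2           A 0.01, C 0.6   A 0.03, C 0.4
3           A 0.015, C 0.55 A 0.025, C 0.45
==========  ==============  ==============

The evaluation harness simulates step features with a virtual array, tunes
a PCA-preprocessed k-nearest-neighbours classifier over k in {3, 5, 7, 9}
by repeated stratified 10-fold cross-validation on the training set (PCA
fit on training folds only — no information leakage), and reports the
cross-validated training accuracy and the held-out test accuracy of the
selected model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline

from .features import extract_features, sensor_columns
from .scenario import Scenario, build_concentration_matrix

__all__ = [
    "DIFFICULTY_CLASSES",
    "BenchResult",
    "difficulty_scenario",
    "run_classification_benchmark",
]

#: Class pairs per difficulty level.
DIFFICULTY_CLASSES = {
    1: ("A 0.02", "C 0.5"),
    2: ("A 0.01, C 0.6", "A 0.03, C 0.4"),
    3: ("A 0.015, C 0.55", "A 0.025, C 0.45"),
}


@dataclass(frozen=True)
class BenchResult:
    """Outcome of one benchmark run."""

    level: int
    class1: str
    class2: str
    best_k: int
    acc_train: float
    acc_test: float
    cv_mean_accuracy: dict  # k -> mean CV accuracy
    fold_accuracies: dict   # k -> per-fold accuracies


def difficulty_scenario(level: int, n_per_class: int = 100, tunit: int = 1,
                        seed: int = 0) -> Scenario:
    """Two-class scenario at the given difficulty level.

    Both the training and the validation set contain ``n_per_class``
    pulses per class, in randomized order.
    """
    if level not in DIFFICULTY_CLASSES:
        raise ValueError(f"difficulty level must be one of {sorted(DIFFICULTY_CLASSES)}")
    c1, c2 = DIFFICULTY_CLASSES[level]
    entries = ((c1, n_per_class), (c2, n_per_class))
    return Scenario(
        train=entries, valid=entries, tunit=tunit, randomize=True, seed=seed
    )


def run_classification_benchmark(array, scenario: Scenario, ks=(3, 5, 7, 9),
                                 folds: int = 10, repeats: int = 10,
                                 seed: int = 0, var_explained: float = 0.95,
                                 feature: str = "step",
                                 workers: int = 1) -> BenchResult:
    """Simulate a scenario and evaluate the PCA+KNN classifier on it.

    The number of retained principal components is the smallest capturing
    at least ``var_explained`` of the training-fold variance.  The best k
    is the one with highest mean cross-validated accuracy; ties go to the
    smallest k (the simpler model).
    """
    conc = build_concentration_matrix(scenario)
    sdata = array.predict(conc, workers=workers)
    feats = extract_features(conc, sdata, feature)

    cols = sensor_columns(feats)
    train = feats[feats["set"] == "train"]
    test = feats[feats["set"] == "valid"]
    if len(train) == 0 or len(test) == 0:
        raise ValueError("the scenario must define both a training and a validation set")
    X_train, y_train = train[cols].to_numpy(float), train["lab"].to_numpy()
    X_test, y_test = test[cols].to_numpy(float), test["lab"].to_numpy()
    min_class = pd.Series(y_train).value_counts().min()
    if min_class < folds:
        raise ValueError(
            f"smallest training class has {min_class} samples, fewer than "
            f"{folds} folds"
        )

    def pipeline(k: int) -> Pipeline:
        return Pipeline(
            [
                ("pca", PCA(n_components=var_explained, svd_solver="full")),
                ("knn", KNeighborsClassifier(n_neighbors=k)),
            ]
        )

    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=int(seed) % (2**31)
    )
    fold_acc, cv_mean = {}, {}
    for k in ks:
        scores = cross_val_score(pipeline(k), X_train, y_train, cv=cv)
        fold_acc[k] = scores
        cv_mean[k] = float(scores.mean())

    best_k = None
    for k in sorted(ks):
        if best_k is None or cv_mean[k] > cv_mean[best_k]:
            best_k = k

    model = pipeline(best_k).fit(X_train, y_train)
    acc_test = float((model.predict(X_test) == y_test).mean())

    c1, c2 = sorted(pd.unique(y_train))
    return BenchResult(
        level=getattr(scenario, "difficulty", 0),
        class1=str(c1),
        class2=str(c2),
        best_k=int(best_k),
        acc_train=cv_mean[best_k],
        acc_test=acc_test,
        cv_mean_accuracy=cv_mean,
        fold_accuracies=fold_acc,
    )
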