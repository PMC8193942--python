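"""The seven classical classifiers for the summary-feature pipeline.

All are scikit-learn defaults (the comparison is about feature sets, not
per-classifier tuning); the only non-default is a fixed random_state so
runs are reproducible.  ``classical_suite`` picks the best (estimator, k)
feature subset per classifier by five-fold CV and fits on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .features import (FEATURE_NAMES, SelectionConfig, rank_features,
                       select_best_feature_set, zscore_fit_apply)
from .gaze_io import DataError

__all__ = ["CLASSIFIER_NAMES", "make_classifier", "FittedClassical",
           "classical_suite"]

CLASSIFIER_NAMES = ("NB", "LogReg", "RF", "knn", "linSVM", "MLP", "AdaBoost")


def make_classifier(name: str, seed: int = 0):
    """Default-settings instance of one of the seven algorithms."""
    if name == "NB":
        return GaussianNB()
    if name == "LogReg":
        return LogisticRegression(random_state=seed, max_iter=1000)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "linSVM":
        return LinearSVC(random_state=seed)
    if name == "MLP":
        return MLPClassifier(random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class FittedClassical:
    """One classifier fitted on its selected, normalized feature subset."""

    name: str
    model: object
    selection: SelectionConfig
    cv_accuracy: float
    feature_subset: list[str]
    scaler: object

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
        Xz = self.scaler.transform(X)
        Xz = pd.DataFrame(Xz, columns=list(FEATURE_NAMES))
        return self.model.predict(Xz[self.feature_subset].to_numpy())


def classical_suite(table: pd.DataFrame, labels, folds: int = 5,
                    seed: int = 0,
                    selection: SelectionConfig | None = None
                    ) -> dict[str, FittedClassical]:
    """Fit all seven classifiers, each on its best-by-CV feature subset.

    When ``selection`` is given the grid search is skipped and every
    classifier uses that fixed (estimator, k).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DataError("classical suite needs both classes")
    X = table[list(FEATURE_NAMES)]
    fitted: dict[str, FittedClassical] = {}
    for name in CLASSIFIER_NAMES:
        clf = make_classifier(name, seed)
        if selection is None:
            sel, acc, _ = select_best_feature_set(X, y, clf, folds=folds,
                                                  seed=seed)
        else:
            sel, acc = selection, float("nan")
        Xz, _, scaler = zscore_fit_apply(X)
        names, _ = rank_features(Xz, y, sel.estimator, seed=seed)
        subset = names[:sel.k]
        model = clone(clf)
        model.fit(Xz[subset].to_numpy(), y)
        fitted[name] = FittedClassical(name=name, model=model, selection=sel,
                                       cv_accuracy=acc, feature_subset=subset,
                                       scaler=scaler)
    return fitted
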