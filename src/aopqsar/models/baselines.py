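"""Baseline machine-learning battery behind one fit/predict interface."""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

BASELINE_FAMILIES = (
    "logreg",
    "dtree",
    "rforest",
    "balanced_rforest",
    "grad_boost",
    "svm",
    "knn",
    "gnb",
)


def make_estimator(family: str, hyperparameters: dict | None = None, seed: int = 0):
    hp = dict(hyperparameters or {})
    if family == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if family == "dtree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if family == "rforest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if family == "balanced_rforest":
        # balanced bootstrap emulated through per-bootstrap class weights
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(
            random_state=seed, n_jobs=1, class_weight="balanced_subsample", **hp
        )
    if family == "grad_boost":
        hp.setdefault("n_estimators", 200)
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **hp
        )
    if family == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if family == "knn":
        return KNeighborsClassifier(**hp)
    if family == "gnb":
        return GaussianNB(**hp)
    raise ValueError(f"unknown baseline family {family!r}")


class BaselineModel:
    """Uniform wrapper: fit on a matrix, emit P(active)."""

    def __init__(self, family: str, hyperparameters: dict | None = None, seed: int = 0):
        self.family = family
        self.estimator = make_estimator(family, hyperparameters, seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaselineModel":
        self.estimator.fit(np.asarray(X), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X))
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]
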