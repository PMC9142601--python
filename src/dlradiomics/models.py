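"""The five classifiers behind one fit/score contract.

Random forest, RBF support vector machine, k-nearest neighbors, Gaussian
naive Bayes and linear discriminant analysis (scikit-learn estimators) are
wrapped so the evaluation machinery can treat them interchangeably: ``fit``
returns a :class:`TrainedModel` whose ``predict_scores`` yields a continuous
class-1 score per sample (probability where the estimator provides one,
decision-function value otherwise — AUC is rank-based, so either works) and
whose ``default_threshold`` defines the sensitivity/specificity operating
point (0.5 on probabilities, 0 on decision values).

Hyperparameter defaults: RF 100 trees with sqrt(p) features per split; SVM
RBF with C=1 and gamma = 1/(p*var); KNN k=5 Euclidean; Gaussian NB; LDA with
automatic shrinkage (lsqr solver).  All overridable via ``params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

CLASSIFIERS = ("RF", "SVM", "KNN", "NB", "LDA")


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "LDA"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIERS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {CLASSIFIERS}")


def _build_estimator(spec: ClassifierSpec):
    p = dict(spec.params)
    if spec.algorithm == "RF":
        p.setdefault("n_estimators", 100)
        p.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "SVM":
        p.setdefault("kernel", "rbf")
        p.setdefault("C", 1.0)
        p.setdefault("gamma", "scale")
        return SVC(random_state=spec.seed, **p)
    if spec.algorithm == "KNN":
        p.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**p)
    if spec.algorithm == "NB":
        return GaussianNB(**p)
    p.setdefault("solver", "lsqr")
    if p["solver"] in ("lsqr", "eigen"):
        p.setdefault("shrinkage", "auto")
    return LinearDiscriminantAnalysis(**p)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    n_features: int

    @property
    def uses_probability(self) -> bool:
        return hasattr(self.estimator, "predict_proba")

    @property
    def default_threshold(self) -> float:
        return 0.5 if self.uses_probability else 0.0

    def predict_scores(self, x_test: np.ndarray) -> np.ndarray:
        x_test = np.asarray(x_test, dtype=float)
        if x_test.ndim != 2 or x_test.shape[1] != self.n_features:
            raise ValueError(
                f"X_test has {x_test.shape[1] if x_test.ndim == 2 else '?'} columns, "
                f"model was trained with {self.n_features}"
            )
        if self.uses_probability:
            proba = self.estimator.predict_proba(x_test)
            cls1 = list(self.estimator.classes_).index(1)
            scores = proba[:, cls1]
        else:
            scores = self.estimator.decision_function(x_test)
            if self.estimator.classes_[1] != 1:
                scores = -scores
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite scores")
        return scores


def fit(spec: ClassifierSpec, x_train: np.ndarray, y_train: np.ndarray) -> TrainedModel:
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train).astype(int)
    if x_train.ndim != 2:
        raise ValueError("X_train must be 2D")
    if np.unique(y_train).size < 2:
        raise ValueError("training data must contain both classes")
    est = _build_estimator(spec)
    est.fit(x_train, y_train)
    return TrainedModel(spec=spec, estimator=est, n_features=x_train.shape[1])


def predict_scores(model: TrainedModel, x_test: np.ndarray) -> np.ndarray:
    return model.predict_scores(x_test)
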