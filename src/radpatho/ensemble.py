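"""Per-modality champion models and the weighted-voting DHRPs ensemble.

Eleven probabilistic base learners (logistic regression, naive Bayes, k-NN,
random forest, SVM, extra trees, XGBoost, LightGBM, gradient boosting,
AdaBoost, multilayer perceptron) are fitted with stratified cross-validation.
Per modality, the learner with the highest mean CV AUC is the champion.  The
combined DHRPs model fits all eleven learners on the concatenated selected
features and integrates their probabilities by weighted voting with weights
proportional to each learner's CV AUC above chance:

    w_m ∝ max(AUC_m − 0.5, 0),   Σ w_m = 1,   s(x) = Σ w_m p_m(x)

so an uninformative learner gets zero weight and the ensemble score is a
convex combination of base probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

LEARNER_NAMES = (
    "LR",
    "NaiveBayes",
    "KNN",
    "RandomForest",
    "SVM",
    "ExtraTrees",
    "XGBoost",
    "LightGBM",
    "GradientBoosting",
    "AdaBoost",
    "MLP",
)


def default_learner_menu(seed: int = 0, n_estimators: int = 100) -> dict[str, object]:
    """The 11 base learners with fixed, untuned hyperparameters."""
    return {
        "LR": LogisticRegression(max_iter=2000, random_state=seed),
        "NaiveBayes": GaussianNB(),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RandomForest": RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
        "SVM": SVC(probability=True, random_state=seed),
        "ExtraTrees": ExtraTreesClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
        "XGBoost": XGBClassifier(
            n_estimators=n_estimators,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
            eval_metric="logloss",
        ),
        "LightGBM": LGBMClassifier(
            n_estimators=n_estimators,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            verbosity=-1,
            n_jobs=1,
        ),
        "GradientBoosting": GradientBoostingClassifier(
            n_estimators=n_estimators, max_depth=3, random_state=seed
        ),
        "AdaBoost": AdaBoostClassifier(n_estimators=n_estimators, random_state=seed),
        "MLP": MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=1000, random_state=seed
        ),
    }


def _cv_auc(
    estimator, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> float:
    """Mean out-of-fold AUC under stratified CV; refolds on degenerate folds."""
    for attempt in range(5):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        aucs = []
        ok = True
        for tr, te in cv.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                ok = False
                break
            m = clone(estimator)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
        if ok:
            return float(np.mean(aucs))
    raise RuntimeError("could not build non-degenerate stratified folds")


@dataclass
class ModalityModel:
    """Champion single learner for one feature block."""

    name: str
    model: object
    cv_auc: float
    cv_report: pd.Series
    features: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        return self.model.predict_proba(X[self.features].to_numpy())[:, 1]


@dataclass
class Ensemble:
    """Weighted-voting ensemble over the full learner menu."""

    models: dict[str, object]
    weights: pd.Series
    cv_report: pd.Series
    features: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        Xa = X[self.features].to_numpy()
        score = np.zeros(len(X))
        for name, w in self.weights.items():
            if w > 0:
                score += w * self.models[name].predict_proba(Xa)[:, 1]
        return score

    def manifest(self) -> dict:
        return {
            "learners": list(self.models),
            "weights": self.weights.to_dict(),
            "cv_auc": self.cv_report.to_dict(),
            "features": self.features,
        }


def fit_modality_model(
    block: pd.DataFrame,
    labels: np.ndarray,
    learner_menu: dict[str, object] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> ModalityModel:
    """Fit every learner with CV and return the champion (highest mean AUC).

    Ties break by menu order, making the champion deterministic for a fixed
    seed.
    """
    menu = learner_menu or default_learner_menu(seed)
    X, y = block.to_numpy(), np.asarray(labels)
    report = pd.Series(
        {name: _cv_auc(est, X, y, n_folds, seed) for name, est in menu.items()}
    )
    best = report.index[int(np.argmax(report.to_numpy()))]
    champion = clone(menu[best])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        champion.fit(X, y)
    return ModalityModel(
        name=best,
        model=champion,
        cv_auc=float(report[best]),
        cv_report=report,
        features=list(block.columns),
    )


def fit_dhrps(
    features: pd.DataFrame,
    labels: np.ndarray,
    learner_menu: dict[str, object] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> Ensemble:
    """Fit all learners on the concatenated selected features; weight by CV AUC.

    Weights are ``max(AUC − 0.5, 0)`` normalised to sum to one.  If every
    learner sits at or below chance the weights fall back to uniform with a
    warning.
    """
    menu = learner_menu or default_learner_menu(seed)
    X, y = features.to_numpy(), np.asarray(labels)
    report = pd.Series(
        {name: _cv_auc(est, X, y, n_folds, seed) for name, est in menu.items()}
    )
    raw = np.maximum(report.to_numpy() - 0.5, 0.0)
    if raw.sum() <= 0:
        warnings.warn("all learners at or below chance; using uniform weights")
        raw = np.ones_like(raw)
    weights = pd.Series(raw / raw.sum(), index=report.index)
    fitted = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, est in menu.items():
            m = clone(est)
            m.fit(X, y)
            fitted[name] = m
    return Ensemble(
        models=fitted, weights=weights, cv_report=report, features=list(features.columns)
    )


def ensemble_cv_auc(
    features: pd.DataFrame,
    labels: np.ndarray,
    learner_menu: dict[str, object] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Out-of-fold AUC of the weighted-voting ensemble.

    Each learner's out-of-fold probabilities are computed once over shared
    stratified folds; voting weights come from the learners' out-of-fold
    AUCs (max(AUC − 0.5, 0), normalised) and the ensemble score is the
    weighted combination of the out-of-fold probability vectors.
    """
    menu = learner_menu or default_learner_menu(seed)
    X, y = features.to_numpy(), np.asarray(labels)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    oof = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, est in menu.items():
            probs = np.zeros(len(y))
            for tr, te in folds:
                m = clone(est)
                m.fit(X[tr], y[tr])
                probs[te] = m.predict_proba(X[te])[:, 1]
            oof[name] = probs
    aucs = {name: roc_auc_score(y, probs) for name, probs in oof.items()}
    raw = np.maximum(np.array(list(aucs.values())) - 0.5, 0.0)
    if raw.sum() <= 0:
        raw = np.ones_like(raw)
    w = raw / raw.sum()
    score = sum(wi * oof[name] for wi, name in zip(w, aucs))
    return float(roc_auc_score(y, score))
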