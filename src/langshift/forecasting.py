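"""Forecasting pre-visit vs pre-random change vectors.

Each patient contributes two rows — the change vector before the true event
(label 1) and before the null event (label 0).  Evaluation uses k-fold
cross-validation with patient-exclusive folds: both rows of a patient stay
in the same fold, so no individual informs both training and testing.  Per
fold, features are standardized and reduced by PCA using train-fold
statistics only, then scored by a linear (probability-averaging) ensemble
of random forest, SVM, gradient boosting, and logistic regression; a
ridge-penalized logistic regression serves as the active control model.

AUC is implemented from the Mann-Whitney definition (ties counted half),
which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_curve
from sklearn.calibration import CalibratedClassifierCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ModelMatrix",
    "EvaluationReport",
    "SingleClassError",
    "build_model_matrix",
    "reduce_dimensions",
    "EnsembleModel",
    "fit_ensemble",
    "fit_ridge_logistic",
    "grouped_cv_evaluate",
    "ridge_logistic_control",
    "compute_auc",
]


class SingleClassError(ValueError):
    """A training fold or score set contains only one class."""


@dataclass
class ModelMatrix:
    """Design matrix for the paired classification problem.

    Exactly two rows per patient: the true-event change (label 1) and the
    null-event change (label 0), grouped by patient id for fold assignment.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    @property
    def n_patients(self) -> int:
        return np.unique(self.groups).size


def build_model_matrix(changes: pd.DataFrame) -> ModelMatrix:
    """From a change matrix indexed by (patient_id, event) to rows + labels."""
    events = changes.index.get_level_values("event")
    y = np.asarray(events == "true", dtype=int)
    groups = changes.index.get_level_values("patient_id").to_numpy()
    X = changes.reset_index(drop=True)
    return ModelMatrix(X=X, y=y, groups=groups)


def reduce_dimensions(train: np.ndarray, test: np.ndarray,
                      variance_retained: float) -> tuple[np.ndarray, np.ndarray, PCA]:
    """PCA fitted on the training rows only, applied to both matrices.

    Retains the minimal number of components whose cumulative explained
    variance reaches ``variance_retained``; 1.0 keeps the full rank.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must lie in (0, 1]")
    n_components = None if variance_retained == 1.0 else variance_retained
    pca = PCA(n_components=n_components, svd_solver="full")
    train_r = pca.fit_transform(train)
    test_r = pca.transform(test)
    return train_r, test_r, pca


@dataclass
class EnsembleModel:
    """Probability-averaging ensemble over fitted base classifiers."""

    models: list

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean class-1 probability over the base learners."""
        probs = [m.predict_proba(X)[:, 1] for m in self.models]
        return np.mean(probs, axis=0)


def _base_learners(seed: int) -> list:
    # Library-default hyperparameters, pinned seeds for the stochastic ones.
    return [
        RandomForestClassifier(random_state=seed),
        # Platt-scaled SVM so it emits class probabilities like the others.
        CalibratedClassifierCV(SVC(random_state=seed), method="sigmoid",
                               ensemble=False),
        GradientBoostingClassifier(random_state=seed),
        LogisticRegression(max_iter=2000),
    ]


def fit_ensemble(X: np.ndarray, y: np.ndarray, seed: int = 0) -> EnsembleModel:
    """Fit the four base classifiers on one training fold."""
    if np.unique(y).size < 2:
        raise SingleClassError("training fold contains a single class")
    models = []
    for model in _base_learners(seed):
        model.fit(X, y)
        models.append(model)
    return EnsembleModel(models=models)


def fit_ridge_logistic(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """The active-control model: L2-penalized logistic regression."""
    if np.unique(y).size < 2:
        raise SingleClassError("training fold contains a single class")
    model = LogisticRegression(C=1.0, max_iter=2000)  # default L2 (ridge) penalty
    model.fit(X, y)
    return model


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outscores a random negative).

    Ties count half; equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


@dataclass
class EvaluationReport:
    """Pooled out-of-fold evaluation of one model under grouped CV."""

    model: str
    auc: float
    f1: float
    roc: np.ndarray  # (n_points, 2) array of (fpr, tpr), (0,0) .. (1,1)
    fold_aucs: list[float]
    fold_f1s: list[float]
    mean_fold_auc: float
    scores: np.ndarray
    labels: np.ndarray
    n_patients: int
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "auc": self.auc,
            "f1": self.f1,
            "mean_fold_auc": self.mean_fold_auc,
            "fold_aucs": self.fold_aucs,
            "fold_f1s": self.fold_f1s,
            "n_patients": self.n_patients,
            "k": self.k,
            "seed": self.seed,
        }


def _patient_folds(groups: np.ndarray, k: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle patients, then split them into k near-equal folds."""
    patients = np.unique(groups)
    if k > patients.size:
        raise ValueError(f"k={k} exceeds the {patients.size} patients")
    shuffled = rng.permutation(patients)
    return [np.asarray(fold) for fold in np.array_split(shuffled, k)]


def _evaluate(matrix: ModelMatrix, k: int, seed: int, model_name: str,
              variance_retained: float) -> EvaluationReport:
    rng = np.random.default_rng(seed)
    folds = _patient_folds(matrix.groups, k, rng)
    X = matrix.X.to_numpy(dtype=float)
    pooled_scores = np.empty(len(matrix.y), dtype=float)
    fold_aucs, fold_f1s = [], []
    for fold_patients in folds:
        test_mask = np.isin(matrix.groups, fold_patients)
        train_mask = ~test_mask
        scaler = StandardScaler().fit(X[train_mask])
        train = scaler.transform(X[train_mask])
        test = scaler.transform(X[test_mask])
        train, test, _ = reduce_dimensions(train, test, variance_retained)
        if model_name == "ensemble":
            fitted = fit_ensemble(train, matrix.y[train_mask], seed=seed)
            scores = fitted.predict_proba(test)
        else:
            fitted = fit_ridge_logistic(train, matrix.y[train_mask], seed=seed)
            scores = fitted.predict_proba(test)[:, 1]
        pooled_scores[test_mask] = scores
        fold_aucs.append(compute_auc(scores, matrix.y[test_mask]))
        fold_f1s.append(float(f1_score(matrix.y[test_mask],
                                       (scores >= 0.5).astype(int))))
    auc = compute_auc(pooled_scores, matrix.y)
    f1 = float(f1_score(matrix.y, (pooled_scores >= 0.5).astype(int)))
    fpr, tpr, _ = roc_curve(matrix.y, pooled_scores, drop_intermediate=False)
    roc = np.column_stack([fpr, tpr])
    return EvaluationReport(
        model=model_name, auc=auc, f1=f1, roc=roc,
        fold_aucs=[float(a) for a in fold_aucs],
        fold_f1s=fold_f1s,
        mean_fold_auc=float(np.mean(fold_aucs)),
        scores=pooled_scores, labels=matrix.y.copy(),
        n_patients=matrix.n_patients, k=k, seed=seed)


def grouped_cv_evaluate(matrix: ModelMatrix, k: int = 5, seed: int = 0,
                        variance_retained: float = 0.95) -> EvaluationReport:
    """Patient-exclusive k-fold CV of the four-model averaging ensemble."""
    return _evaluate(matrix, k, seed, "ensemble", variance_retained)


def ridge_logistic_control(matrix: ModelMatrix, k: int = 5, seed: int = 0,
                           variance_retained: float = 0.95) -> EvaluationReport:
    """Same CV protocol with the single penalized linear classifier."""
    return _evaluate(matrix, k, seed, "ridge_logistic", variance_retained)
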