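"""Nested leave-one-out SVM discrimination from microstate features.

The evaluation protocol guards against the two classic leakage channels:
every preprocessing statistic (standardization, PCA retaining 95%
variance) is fitted inside the training fold only, and hyperparameters
are chosen by an inner leave-one-out grid search on the training fold
only.  Pooled outer-fold decision scores yield a single ROC/AUC.

Note: the upstream feature *selection* (group-difference tests) happens
outside the cross-validation, mirroring common practice; treat the
resulting AUC as potentially optimistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GridSearchCV, LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .recording import ParameterError, StructuralError

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(10.0**e for e in range(-2, 3))
DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(-3, 2))


@dataclass
class FeatureMatrix:
    """Subjects x features with group labels."""

    X: pd.DataFrame      # index: subject id; columns: feature names
    y: pd.Series         # group label per subject

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise StructuralError("feature matrix contains missing values")
        if self.X.columns.duplicated().any():
            raise StructuralError("feature names must be unique")


def assemble_features(tables: list[pd.DataFrame], groups: pd.Series,
                      selection: list[str] | None = None) -> FeatureMatrix:
    """Column-bind per-subject feature tables and apply a selection mask.

    Every table must be indexed by subject id and cover the same
    subjects.  ``selection`` is the upstream feature mask (computed
    outside any CV loop); an empty mask is an explicit error.
    """
    if selection is not None and len(selection) == 0:
        raise ParameterError("empty feature selection mask")
    if not tables:
        raise ParameterError("no feature tables given")
    idx = tables[0].index
    for t in tables[1:]:
        if not idx.equals(t.index):
            missing = idx.symmetric_difference(t.index)
            raise StructuralError(f"subject mismatch across feature tables: {list(missing)}")
    X = pd.concat(tables, axis=1)
    if selection is not None:
        unknown = set(selection) - set(X.columns)
        if unknown:
            raise StructuralError(f"selected features not found: {sorted(unknown)}")
        X = X[selection]
    y = groups.reindex(X.index)
    if y.isna().any():
        raise StructuralError("group label missing for some subjects")
    return FeatureMatrix(X=X, y=y)


@dataclass
class ClassificationResult:
    scores: np.ndarray            # pooled outer-fold decision scores
    y_true: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    best_params: list[dict]       # per outer fold
    fold_means: list[np.ndarray]  # training-fold feature means (leakage audit)
    skipped_folds: list[int] = field(default_factory=list)


def nested_loocv_svm(fm: FeatureMatrix, kernel: str = "linear",
                     c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                     seed: int | None = None) -> ClassificationResult:
    """Nested leave-one-out SVM with fold-local scaling + PCA (95% variance).

    The inner loop grid-searches C (and gamma for the RBF kernel) by
    leave-one-out accuracy on the training fold; ties resolve to the
    first grid point, so grids ordered ascending prefer smaller C, then
    smaller gamma.  Pooled decision scores of the outer folds give the
    ROC and AUC.
    """
    if kernel not in ("linear", "rbf"):
        raise ParameterError("kernel must be 'linear' or 'rbf'")
    X = fm.X.to_numpy(dtype=float)
    y, classes = pd.factorize(fm.y, sort=True)
    if len(classes) != 2:
        raise ParameterError("need exactly 2 classes")
    if min(np.bincount(y)) < 2:
        raise ParameterError("need >= 2 subjects per class")

    grid: dict[str, list] = {"svc__C": list(c_grid)}
    if kernel == "rbf":
        grid["svc__gamma"] = list(gamma_grid)

    scores, y_true, best_params, fold_means, skipped = [], [], [], [], []
    for i, (train, test) in enumerate(LeaveOneOut().split(X)):
        if len(np.unique(y[train])) < 2:
            logger.warning("fold %d: a class is absent from training; skipped", i)
            skipped.append(i)
            continue
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=0.95, svd_solver="full", random_state=seed)),
            ("svc", SVC(kernel=kernel, random_state=seed)),
        ])
        search = GridSearchCV(pipe, grid, scoring="accuracy", cv=LeaveOneOut())
        search.fit(X[train], y[train])
        # center the fold's score on its training-score mean: leaving a
        # subject out tilts the training class balance against it, and the
        # resulting fold-dependent offsets bias the pooled ROC pessimistically
        offset = float(search.decision_function(X[train]).mean())
        scores.append(float(search.decision_function(X[test])[0]) - offset)
        y_true.append(int(y[test][0]))
        best_params.append(search.best_params_)
        fold_means.append(X[train].mean(axis=0))

    scores = np.asarray(scores)
    y_true = np.asarray(y_true)
    fpr, tpr, _ = roc_curve(y_true, scores)
    return ClassificationResult(scores=scores, y_true=y_true, fpr=fpr, tpr=tpr,
                                auc=float(auc(fpr, tpr)), best_params=best_params,
                                fold_means=fold_means, skipped_folds=skipped)
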