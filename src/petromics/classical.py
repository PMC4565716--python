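"""Classical classifiers on the hand-crafted descriptor.

Four families — logistic regression (LR), gradient boosting (GB), random
forests (RF) and support-vector machines (SVM, polynomial kernel by
default) — are tuned by grid search with 10-fold cross-validation on
accuracy, optionally after projecting the standardized features onto their
ten largest principal components. Two SUVmax-only baselines complete the
roster: a ROC-derived threshold (maximum TPR + TNR on the training set)
and the training-median threshold; both predict *responder* when SUVmax
falls below the threshold (responding tumors are hypothesized to be less
avid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: default hyperparameter grids, keyed by family
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lr": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "gb": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [2, 3],
        "clf__learning_rate": [0.05, 0.1],
    },
    "rf": {
        "clf__n_estimators": [200, 500],
        "clf__max_features": ["sqrt", 0.3],
    },
    "svm": {
        "clf__degree": [2, 3],
        "clf__C": [0.1, 1.0, 10.0],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for one tuned classifier.

    ``use_pca`` projects standardized features onto the ``n_components``
    largest principal components (fit on training data only).
    ``stratified`` controls the CV fold scheme; stratification keeps both
    classes in every fold of an imbalanced cohort and can be switched off
    for a plain random partition.
    """

    family: str = "gb"
    use_pca: bool = False
    n_components: int = 10
    grid: Mapping[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0
    stratified: bool = True
    svm_kernel: str = "poly"

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown family {self.family!r}; use one of {list(DEFAULT_GRIDS)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is not None and len(self.grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")


def _estimator(spec: ModelSpec):
    if spec.family == "lr":
        return LogisticRegression(max_iter=5000, random_state=spec.seed)
    if spec.family == "gb":
        return GradientBoostingClassifier(random_state=spec.seed)
    if spec.family == "rf":
        return RandomForestClassifier(random_state=spec.seed)
    return SVC(kernel=spec.svm_kernel, probability=False, random_state=spec.seed)


@dataclass
class FittedClassifier:
    """A tuned model plus its provenance."""

    spec: ModelSpec
    pipeline: Pipeline
    best_params: dict[str, Any]
    cv_accuracy: float
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))


def fit_classifier(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
) -> FittedClassifier:
    """Grid-search a classifier with 10-fold CV and refit on all data.

    Features are z-scored from training statistics before LR/SVM/PCA; tree
    ensembles are scale-free but share the pipeline for uniformity. With
    PCA enabled the model consumes exactly ``n_components`` columns.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    steps: list[tuple[str, Any]] = []
    if spec.family in ("lr", "svm") or spec.use_pca:
        steps.append(("scale", StandardScaler()))
    if spec.use_pca:
        steps.append(("pca", PCA(n_components=spec.n_components, random_state=spec.seed)))
    steps.append(("clf", _estimator(spec)))
    pipe = Pipeline(steps)

    folds = min(spec.cv_folds, int(counts.min()) if spec.stratified else len(y))
    if spec.stratified:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    grid = dict(spec.grid) if spec.grid is not None else DEFAULT_GRIDS[spec.family]
    search = GridSearchCV(
        pipe, grid, scoring="accuracy", cv=cv, n_jobs=1, error_score=np.nan, refit=True
    )
    search.fit(X, y)
    return FittedClassifier(
        spec=spec,
        pipeline=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_accuracy=float(search.best_score_),
        feature_names=feature_names,
    )


# ---------------------------------------------------------------------------
# GB variable importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceReport:
    """Features ordered by relative importance, rescaled so the top = 100."""

    names: tuple[str, ...]
    importances: tuple[float, ...]

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return list(zip(self.names[:k], self.importances[:k]))


def gb_importance(model: FittedClassifier) -> ImportanceReport:
    """Relative variable importances of a fitted gradient-boosting model.

    Uses the summed squared split improvements per variable, averaged over
    the trees of the ensemble, rescaled so the largest importance is
    exactly 100. Only meaningful in feature space, so PCA models are
    rejected.
    """
    if model.spec.family != "gb":
        raise ValueError("importance report is defined for the GB family")
    if model.spec.use_pca:
        raise ValueError("importances live in feature space; refit without PCA")
    gb = model.pipeline.named_steps["clf"]
    imp = np.asarray(gb.feature_importances_, dtype=float)
    if imp.max() <= 0:
        raise ValueError("degenerate fit: all importances are zero")
    scaled = imp / imp.max() * 100.0
    order = np.argsort(-scaled)
    names = (
        model.feature_names
        if model.feature_names
        else [f"feature_{i}" for i in range(len(imp))]
    )
    return ImportanceReport(
        names=tuple(names[i] for i in order),
        importances=tuple(float(scaled[i]) for i in order),
    )


# ---------------------------------------------------------------------------
# SUVmax threshold baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SUVmaxThresholdClassifier:
    """Predict responder (1) iff SUVmax < threshold."""

    threshold: float
    method: str

    def predict(self, suvmax: np.ndarray) -> np.ndarray:
        return (np.asarray(suvmax, dtype=float) < self.threshold).astype(int)


def suvmax_roc_threshold(suvmax: np.ndarray, y: np.ndarray) -> SUVmaxThresholdClassifier:
    """ROC-optimal SUVmax threshold (maximum TPR + TNR, Youden).

    Candidate thresholds are the observed training values; prediction is
    responder iff SUVmax < threshold. Objective ties resolve to the
    smallest qualifying threshold.
    """
    suvmax = np.asarray(suvmax, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to run a ROC analysis")
    candidates = np.unique(suvmax)
    best_obj, best_thr = -np.inf, candidates[0]
    pos = y == 1
    neg = ~pos
    for thr in candidates:
        pred = suvmax < thr
        tpr = (pred & pos).sum() / pos.sum()
        tnr = (~pred & neg).sum() / neg.sum()
        obj = tpr + tnr
        if obj > best_obj + 1e-12:
            best_obj, best_thr = obj, thr
    return SUVmaxThresholdClassifier(threshold=float(best_thr), method="roc")


def suvmax_median_threshold(suvmax: np.ndarray) -> SUVmaxThresholdClassifier:
    """Baseline thresholding at the training-set median SUVmax."""
    return SUVmaxThresholdClassifier(
        threshold=float(np.median(np.asarray(suvmax, dtype=float))), method="median"
    )
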