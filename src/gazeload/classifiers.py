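"""Classical classifiers and cross-validation over the 13-feature tables.

Five model families — SVM, logistic regression, linear discriminant
analysis, k-nearest neighbors, decision tree — with the hyperparameter
variants the study enumerated; defaults reproduce its best settings
(linear-kernel SVM, linear LDA, k = 10 euclidean k-NN, Gini tree with at
most 4 splits).  Cross-validation is stratified k-fold (default k = 5) or
a stratified holdout split; features are z-scored with training-fold
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "ModelConfig",
    "CVScheme",
    "PredictionSet",
    "make_estimator",
    "cross_validate",
    "cross_validate_xy",
    "cv_splits",
    "compare_window_sizes",
]

ALGORITHMS = ("svm", "lr", "lda", "knn", "dt")


@dataclass(frozen=True)
class ModelConfig:
    """One classical model variant.

    Defaults are the best-performing settings of the emulated study:
    SVM with linear kernel; LDA with linear discriminant; k-NN with
    k = 10 and euclidean distance; decision tree on the Gini diversity
    index with at most 4 splits.
    """

    algorithm: str = "svm"
    kernel: str = "linear"  # svm: linear | gaussian | polynomial
    discriminant: str = "linear"  # lda variants
    k: int = 10
    distance: str = "euclidean"
    criterion: str = "gdi"  # dt: gdi | twoing | deviance
    max_splits: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")


@dataclass(frozen=True)
class CVScheme:
    method: str = "kfold"  # kfold | holdout
    k: int = 5
    holdout_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kfold", "holdout"):
            raise ValueError("method must be 'kfold' or 'holdout'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class PredictionSet:
    """Out-of-fold predictions with continuous decision scores.

    Under k-fold every sample receives exactly one out-of-fold prediction;
    under holdout only the held-out split is populated.  ``score`` is an
    orientation-consistent score for class 1 (signed margin for SVM,
    probability for the others).
    """

    y_true: np.ndarray
    y_pred: np.ndarray
    score: np.ndarray
    fold: np.ndarray
    index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index is None:
            self.index = np.arange(len(self.y_true))
        if not np.all(np.isfinite(self.score)):
            raise ValueError("non-finite decision scores")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "score": self.score,
                "fold": self.fold,
            }
        )


_DT_CRITERION = {"gdi": "gini", "twoing": "gini", "deviance": "entropy"}
_SVM_KERNEL = {"linear": "linear", "gaussian": "rbf", "polynomial": "poly"}


def make_estimator(config: ModelConfig):
    """Instantiate the sklearn estimator for a :class:`ModelConfig`.

    Notes: the 'twoing' tree criterion has no sklearn counterpart and maps
    to Gini (the study's best criterion was Gini anyway); 'diag'/'pseudo'
    discriminant variants map to regularised LDA/QDA solvers.
    """
    a = config.algorithm
    if a == "svm":
        return SVC(kernel=_SVM_KERNEL[config.kernel], random_state=config.seed)
    if a == "lr":
        return LogisticRegression(max_iter=2000, random_state=config.seed)
    if a == "lda":
        d = config.discriminant
        if d in ("linear",):
            return LinearDiscriminantAnalysis()
        if d in ("pseudolinear", "diaglinear"):
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        if d in ("quadratic", "pseudoquadratic", "diagquadratic"):
            return QuadraticDiscriminantAnalysis(reg_param=1e-3)
        raise ValueError(f"unknown discriminant {d!r}")
    if a == "knn":
        if config.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")
        return KNeighborsClassifier(n_neighbors=config.k, metric="euclidean")
    if a == "dt":
        return DecisionTreeClassifier(
            criterion=_DT_CRITERION[config.criterion],
            max_leaf_nodes=config.max_splits + 1,  # n internal splits
            random_state=config.seed,
        )
    raise ValueError(a)


def _score_of(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def _check_features(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    X = features[FEATURE_NAMES].to_numpy(float)
    bad = [
        FEATURE_NAMES[j]
        for j in range(X.shape[1])
        if not np.all(np.isfinite(X[:, j]))
    ]
    if bad:
        raise ValueError(f"non-finite values in feature columns: {bad}")
    y = features["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both classes")
    return X, y


def cv_splits(y: np.ndarray, cv: CVScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test index splits for a CV scheme."""
    n = len(y)
    if cv.method == "kfold":
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
        return list(splitter.split(np.zeros(n), y))
    tr, te = train_test_split(
        np.arange(n),
        test_size=cv.holdout_fraction,
        stratify=y,
        random_state=cv.seed,
    )
    return [(tr, te)]


def cross_validate_xy(
    X: np.ndarray, y: np.ndarray, estimator_factory, cv: CVScheme, standardize: bool = True
) -> PredictionSet:
    """Generic cross-validation over a numeric design matrix.

    ``estimator_factory()`` must return a fresh sklearn-style estimator.
    Standardization (z-score) is fit on each training fold only, so no
    statistics leak from validation samples.
    """
    n = len(y)
    y_pred = np.full(n, -1)
    score = np.full(n, np.nan)
    fold_of = np.full(n, -1)

    for f, (tr, te) in enumerate(cv_splits(y, cv)):
        if standardize:
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        else:
            Xtr, Xte = X[tr], X[te]
        est = estimator_factory()
        est.fit(Xtr, y[tr])
        y_pred[te] = est.predict(Xte)
        score[te] = _score_of(est, Xte)
        fold_of[te] = f

    seen = fold_of >= 0
    return PredictionSet(
        y_true=y[seen],
        y_pred=y_pred[seen],
        score=score[seen],
        fold=fold_of[seen],
        index=np.flatnonzero(seen),
    )


def cross_validate(
    features: pd.DataFrame, model: ModelConfig, cv: CVScheme
) -> PredictionSet:
    """Cross-validated out-of-fold predictions for a labeled feature table.

    Features are z-scored with training-fold statistics only.
    Deterministic given the seeds in ``model`` and ``cv``.
    """
    X, y = _check_features(features)
    return cross_validate_xy(X, y, lambda: make_estimator(model), cv)


def compare_window_sizes(
    segment_events_by_channel: dict,
    labels,
    subject_ids,
    segment_duration: float,
    models: dict[str, ModelConfig] | None = None,
    windows=(60.0, 30.0, 15.0),
    cv_methods=("kfold", "holdout"),
    seed: int = 0,
) -> pd.DataFrame:
    """F1 and accuracy for every (model, CV method, window length, channel).

    ``segment_events_by_channel`` maps channel name (e.g. "eyeT", "camera")
    to a list of per-segment event sequences aligned with ``labels``.
    Returns a tidy DataFrame with one row per grid cell and columns
    ``model, cv, window_s, channel, f1, accuracy``.
    """
    from .evaluation import confusion_from_predictions, metrics_from_counts
    from .features import WindowSpec, build_feature_table

    if models is None:
        models = {a: ModelConfig(algorithm=a, seed=seed) for a in ALGORITHMS}
    rows = []
    for window in windows:
        if window > segment_duration:
            raise ValueError("segments shorter than the largest window")
        spec = WindowSpec(length=float(window))
        for channel, seg_events in segment_events_by_channel.items():
            table = build_feature_table(
                seg_events, spec, labels, subject_ids, segment_duration=segment_duration
            )
            for name, model in models.items():
                for method in cv_methods:
                    preds = cross_validate(
                        table, model, CVScheme(method=method, seed=seed)
                    )
                    m = metrics_from_counts(confusion_from_predictions(preds))
                    rows.append(
                        {
                            "model": name,
                            "cv": method,
                            "window_s": window,
                            "channel": channel,
                            "f1": m.f1,
                            "accuracy": m.accuracy,
                        }
                    )
    return pd.DataFrame(rows)
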