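"""Classifier suite, cross-validation and ROC statistics.

Five classifier families are supported — multi-layer perceptron (MLP),
random forest (RF), logistic regression (LR), support-vector machine
(SVM, RBF kernel) and gradient boosting (GB) — each wrapped in a
pipeline that z-scores the descriptors on the training data only.
Hyperparameters are chosen by grid search with stratified 5-fold
cross-validation nested inside the training folds, and performance is
summarized as the mean AUC-ROC over repeated stratified 5-fold CV with
an interval given by the middle 95% of the repeat x fold AUCs.

``roc_auc`` and ``roc_curve`` are implemented directly from the
Mann–Whitney definition (a tied positive/negative pair counts 1/2) so
the statistic's semantics are explicit; they are cross-checked against
scikit-learn in the test suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pascdx.errors import ConfigurationError, InsufficientDataError
from pascdx.features import LabeledDescriptorTable

__all__ = [
    "DEFAULT_GRIDS",
    "ModelSpec",
    "CVReport",
    "TrainedClassifier",
    "roc_auc",
    "roc_curve",
    "cross_validate",
    "train_final",
]

# Default hyperparameter grids per family. Modest grids centred on
# library defaults; override via ModelSpec(grid=...).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "MLP": {
        "clf__hidden_layer_sizes": [(32,), (64,), (64, 32)],
        "clf__alpha": [1e-4, 1e-2],
    },
    "RF": {"clf__n_estimators": [200, 500], "clf__max_depth": [None, 10]},
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "SVM": {"clf__estimator__C": [0.1, 1.0, 10.0], "clf__estimator__gamma": ["scale"]},
    "GB": {"clf__n_estimators": [100, 300], "clf__learning_rate": [0.05, 0.1]},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameter grid.

    ``grid`` keys follow the sklearn pipeline convention
    (``clf__<param>``); ``None`` means the family's default grid. An
    empty-dict grid fits the family at its library defaults (no search),
    which is substantially faster when tuning is not the point.
    """

    family: str = "MLP"
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ConfigurationError(
                f"unknown model family {self.family!r}; choose from {sorted(DEFAULT_GRIDS)}"
            )

    @property
    def effective_grid(self) -> dict[str, list]:
        return DEFAULT_GRIDS[self.family] if self.grid is None else self.grid


def _make_estimator(family: str, seed: int) -> Any:
    if family == "MLP":
        return MLPClassifier(max_iter=2000, random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed)
    if family == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if family == "SVM":
        # RBF SVC decision values mapped to [0, 1] probabilities by
        # cross-validated calibration
        from sklearn.calibration import CalibratedClassifierCV

        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if family == "GB":
        return GradientBoostingClassifier(random_state=seed)
    raise ConfigurationError(f"unknown model family {family!r}")


def _make_pipeline(spec: ModelSpec, seed: int) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("clf", _make_estimator(spec.family, seed))]
    )


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise InsufficientDataError(
            f"both classes must be present; got classes {classes.tolist()}"
        )
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, counting ties as 1/2. Computed from
    midranks: AUC = (R_pos - n_pos (n_pos + 1)/2) / (n_pos n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    if scores.shape[0] != labels.shape[0]:
        raise ConfigurationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks handle ties as 1/2 pairwise
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve points: (fpr, tpr, thresholds).

    One point per distinct score threshold, descending; prepended with
    (0, 0) at threshold +inf. Both coordinates are monotone
    non-decreasing and the endpoints are (0,0) and (1,1); the
    trapezoidal integral of tpr over fpr equals :func:`roc_auc`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


@dataclass
class CVReport:
    """Repeated-CV performance summary for one model spec."""

    family: str
    fold_aucs: np.ndarray  # shape (n_repeats * n_folds,)
    mean_auc: float
    ci_low: float
    ci_high: float
    best_hyperparameters: dict[str, Any]
    n_folds: int
    n_repeats: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mean_auc": self.mean_auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "best_hyperparameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.best_hyperparameters.items()
            },
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
        }


def _fit_with_grid(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[Any, dict[str, Any]]:
    """Fit a pipeline on (X, y), grid-searching when the grid is non-trivial."""
    pipe = _make_pipeline(spec, seed)
    grid = spec.effective_grid
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_combos <= 1:
        if grid:
            pipe.set_params(**{k: v[0] for k, v in grid.items()})
        pipe.fit(X, y)
        params = {k: v[0] for k, v in grid.items()} if grid else {}
        return pipe, params
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=inner, refit=True, n_jobs=1)
    gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_)


def cross_validate(
    table: LabeledDescriptorTable,
    spec: ModelSpec,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV with nested grid search.

    For each outer fold, hyperparameters are grid-searched by stratified
    5-fold CV *within the training folds only* (no information from the
    held-out fold reaches model selection), the winning model is refit
    on the training folds, and AUC-ROC is computed on the held-out fold.
    The report's interval is the empirical middle 95% (2.5th–97.5th
    percentiles) of the ``n_repeats * n_folds`` fold AUCs.
    """
    X, y = table.X, _check_binary(table.y)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise InsufficientDataError(
            f"smallest class has {counts.min()} members; need >= n_folds={n_folds}"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    aucs = []
    chosen: list[tuple] = []
    for i, (train, test) in enumerate(splitter.split(X, y)):
        model, params = _fit_with_grid(spec, X[train], y[train], seed=seed + 1000 + i)
        scores = model.predict_proba(X[test])[:, 1]
        aucs.append(roc_auc(scores, y[test]))
        chosen.append(tuple(sorted(params.items())))
    aucs = np.asarray(aucs)
    modal = Counter(chosen).most_common(1)[0][0] if chosen else ()
    return CVReport(
        family=spec.family,
        fold_aucs=aucs,
        mean_auc=float(aucs.mean()),
        ci_low=float(np.percentile(aucs, 2.5)),
        ci_high=float(np.percentile(aucs, 97.5)),
        best_hyperparameters=dict(modal),
        n_folds=n_folds,
        n_repeats=n_repeats,
    )


@dataclass
class TrainedClassifier:
    """A fitted pipeline (z-scoring + classifier) with metadata.

    Standardization parameters live inside the pipeline's scaler, fit on
    the training data, and are applied identically at prediction time.
    Scores are class-1 probabilities in [0, 1]; the per-metabolite
    decision threshold defaults to 0.5.
    """

    spec: ModelSpec
    pipeline: Pipeline
    descriptor_names: list[str]
    best_hyperparameters: dict[str, Any] = field(default_factory=dict)
    threshold: float = 0.5

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.descriptor_names):
            raise ConfigurationError(
                f"descriptor vector has {X.shape[1]} dimensions; "
                f"classifier expects {len(self.descriptor_names)}"
            )
        return X

    def score(self, X: np.ndarray | LabeledDescriptorTable) -> np.ndarray:
        """Class-1 (disease-dysregulated) probability per row."""
        if isinstance(X, LabeledDescriptorTable):
            if X.descriptor_names != self.descriptor_names:
                raise ConfigurationError("descriptor columns do not match classifier")
            X = X.X
        X = self._validate(X)
        return self.pipeline.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray | LabeledDescriptorTable) -> np.ndarray:
        """Boolean per-metabolite flags: score >= threshold."""
        return self.score(X) >= self.threshold


def train_final(
    table: LabeledDescriptorTable, spec: ModelSpec, seed: int = 0
) -> TrainedClassifier:
    """Grid-search hyperparameters on the full table and refit the winner."""
    X, y = table.X, _check_binary(table.y)
    model, params = _fit_with_grid(spec, X, y, seed=seed)
    return TrainedClassifier(
        spec=spec,
        pipeline=model,
        descriptor_names=table.descriptor_names,
        best_hyperparameters=params,
    )
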