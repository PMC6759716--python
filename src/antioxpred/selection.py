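"""Max-Relevance-Max-Distance (MRMD) feature ranking and incremental
random-forest subset search.

Each feature column gets a score ``RV + DV``: a relevance term (Pearson
correlation between the feature and the 0/1 label vector) plus a distance
term (mean Euclidean distance between the feature column and every feature
column, self included, averaged over the M columns). High relevance keeps
informative features near the top; high distance keeps mutually redundant
features from crowding it.

Features are min-max scaled to [0, 1] before scoring by default — raw
Euclidean distance is otherwise dominated by feature scale — with a switch
to score the raw columns instead.

The optimal subset is found by walking the ranking: prefixes
[f'1], [f'1, f'2], ... are each evaluated with a 100-tree random forest
under stratified k-fold cross-validation, and the best-scoring prefix wins
(smallest size on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .metrics import compute_metrics, confusion_from_predictions
from .types import FeatureTable, ValidationError

SUBSET_METRICS = ("f1", "acc", "mcc")


def _as_matrix_labels(table: FeatureTable | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, FeatureTable):
        return table.matrix, table.labels
    X, y = table
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def minmax_scale_features(X: np.ndarray) -> np.ndarray:
    """Per-column min-max scaling to [0, 1]; constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    out = (X - lo) / span_safe
    out[:, span == 0] = 0.0
    return out


def relevance_values(
    X: np.ndarray, y: np.ndarray, absolute: bool = False
) -> np.ndarray:
    """Pearson correlation of each feature column with the 0/1 labels.

    Constant columns get 0 by convention (the coefficient is undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("relevance needs at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValidationError("relevance needs both classes present in the labels")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    rv = np.zeros(X.shape[1])
    ok = den > 0
    rv[ok] = num[ok] / den[ok]
    return np.abs(rv) if absolute else rv


def distance_values(X: np.ndarray) -> np.ndarray:
    """Mean Euclidean distance from each feature column to all M columns.

    The self-distance contributes 0; the denominator is M.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if m < 2:
        raise ValidationError("distance values need at least 2 features")
    dist = squareform(pdist(X.T, metric="euclidean"))
    return dist.sum(axis=1) / m


@dataclass
class MRMDResult:
    """Per-feature relevance, distance, combined score and descending ranking."""

    relevance: np.ndarray
    distance: np.ndarray
    score: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.score, self.relevance + self.distance):
            raise ValidationError("MRMD score must equal relevance + distance")
        m = self.score.shape[0]
        if sorted(self.ranking.tolist()) != list(range(m)):
            raise ValidationError("ranking must be a permutation of the feature indices")
        ordered = self.score[self.ranking]
        if np.any(np.diff(ordered) > 1e-12):
            raise ValidationError("scores along the ranking must be non-increasing")


def mrmd_scores(
    table: FeatureTable | tuple,
    normalize: bool = True,
    abs_relevance: bool = False,
) -> MRMDResult:
    """Score and rank all features by relevance + distance.

    Descending stable sort; ties broken by original feature index.
    """
    X, y = _as_matrix_labels(table)
    if normalize:
        X = minmax_scale_features(X)
    rv = relevance_values(X, y, absolute=abs_relevance)
    dv = distance_values(X)
    score = rv + dv
    ranking = np.argsort(-score, kind="stable")
    return MRMDResult(relevance=rv, distance=dv, score=score, ranking=ranking)


@dataclass
class SubsetSearchResult:
    """Record of the incremental prefix search."""

    sizes: list[int]
    metrics: list[float]
    chosen_size: int
    chosen_features: np.ndarray
    metric_name: str = "f1"
    records: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = list(zip(self.sizes, self.metrics))


def _pooled_metric(y_true: np.ndarray, y_pred: np.ndarray, metric: str) -> float:
    counts = confusion_from_predictions(y_true, y_pred)
    report = compute_metrics(counts)
    return {"f1": report.f1, "acc": report.acc, "mcc": report.mcc}[metric]


def incremental_select(
    table: FeatureTable | tuple,
    ranking: np.ndarray,
    metric: str = "f1",
    folds: int = 10,
    trees: int = 100,
    rf_seed: int = 1,
    cv_seed: int = 1,
    max_subset_size: int | None = None,
) -> SubsetSearchResult:
    """Evaluate ranking prefixes with a random forest and pick the best.

    Each prefix [f'1 .. f's] is scored by pooling stratified k-fold held-out
    predictions of a ``trees``-tree random forest (unlimited depth, sqrt
    feature subsampling, fixed seed) and computing ``metric`` on the pooled
    confusion counts. Ties go to the smallest prefix.

    ``max_subset_size`` caps the largest prefix examined (None = all M).
    """
    X, y = _as_matrix_labels(table)
    ranking = np.asarray(ranking, dtype=int)
    m = X.shape[1]
    if sorted(ranking.tolist()) != list(range(m)):
        raise ValidationError("ranking must be a permutation of the table's feature indices")
    if metric not in SUBSET_METRICS:
        raise ValidationError(f"unknown subset metric {metric!r}; use one of {SUBSET_METRICS}")
    class_counts = np.bincount(y, minlength=2)
    if folds > class_counts[class_counts > 0].min():
        raise ValidationError(
            f"folds={folds} exceeds the smallest class count {class_counts.min()}"
        )
    limit = m if max_subset_size is None else min(max_subset_size, m)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    sizes, values = [], []
    for s in range(1, limit + 1):
        clf = RandomForestClassifier(
            n_estimators=trees,
            max_depth=None,
            max_features="sqrt",
            random_state=rf_seed,
            n_jobs=1,
        )
        y_pred = cross_val_predict(clf, X[:, ranking[:s]], y, cv=cv)
        sizes.append(s)
        values.append(_pooled_metric(y, y_pred, metric))
    best = int(np.argmax(values))  # argmax takes the first (smallest) on ties
    chosen_size = sizes[best]
    return SubsetSearchResult(
        sizes=sizes,
        metrics=values,
        chosen_size=chosen_size,
        chosen_features=ranking[:chosen_size].copy(),
        metric_name=metric,
    )


class MRMDSelector(TransformerMixin, BaseEstimator):
    """Rank features by MRMD score and keep the top ``n_features``.

    Attributes after fit: ``relevance_``, ``distance_``, ``scores_``,
    ``ranking_`` (descending), ``support_`` (boolean mask over columns).

    Parameters
    ----------
    n_features : int or None
        Number of top-ranked features kept by ``transform``; None keeps all
        (the estimator then only ranks).
    normalize : bool, default True
        Min-max scale columns to [0, 1] before scoring.
    abs_relevance : bool, default False
        Use |PCC| instead of the signed coefficient.
    """

    def __init__(
        self,
        n_features: int | None = None,
        normalize: bool = True,
        abs_relevance: bool = False,
    ):
        self.n_features = n_features
        self.normalize = normalize
        self.abs_relevance = abs_relevance

    def fit(self, X, y):
        result = mrmd_scores(
            (X, y), normalize=self.normalize, abs_relevance=self.abs_relevance
        )
        self.relevance_ = result.relevance
        self.distance_ = result.distance
        self.scores_ = result.score
        self.ranking_ = result.ranking
        m = result.score.shape[0]
        k = m if self.n_features is None else min(self.n_features, m)
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[self.ranking_[:k]] = True
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        k = (
            self.n_features_in_
            if self.n_features is None
            else min(self.n_features, self.n_features_in_)
        )
        return X[:, self.ranking_[:k]]


class IncrementalSubsetSelector(TransformerMixin, BaseEstimator):
    """MRMD ranking followed by the random-forest prefix search.

    Attributes after fit: everything :class:`MRMDSelector` exposes, plus
    ``search_`` (the :class:`SubsetSearchResult`), ``chosen_size_`` and
    ``support_`` restricted to the chosen prefix.
    """

    def __init__(
        self,
        metric: str = "f1",
        folds: int = 10,
        trees: int = 100,
        rf_seed: int = 1,
        cv_seed: int = 1,
        max_subset_size: int | None = None,
        normalize: bool = True,
        abs_relevance: bool = False,
    ):
        self.metric = metric
        self.folds = folds
        self.trees = trees
        self.rf_seed = rf_seed
        self.cv_seed = cv_seed
        self.max_subset_size = max_subset_size
        self.normalize = normalize
        self.abs_relevance = abs_relevance

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        result = mrmd_scores(
            (X, y), normalize=self.normalize, abs_relevance=self.abs_relevance
        )
        self.relevance_ = result.relevance
        self.distance_ = result.distance
        self.scores_ = result.score
        self.ranking_ = result.ranking
        self.search_ = incremental_select(
            (X, y),
            result.ranking,
            metric=self.metric,
            folds=self.folds,
            trees=self.trees,
            rf_seed=self.rf_seed,
            cv_seed=self.cv_seed,
            max_subset_size=self.max_subset_size,
        )
        self.chosen_size_ = self.search_.chosen_size
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[self.search_.chosen_features] = True
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, self.search_.chosen_features]
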