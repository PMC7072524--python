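"""Dimensionality reduction over candidate CpG panels.

Four strategies, each exposed as a scikit-learn estimator so they compose
with pipelines and model selection:

* :class:`MRMDSelector` -- ranks features by a weighted sum of label
  relevance (|Pearson r| with the class) and redundancy avoidance (mean
  Euclidean distance to the other features), then picks the shortest
  top-k prefix maximizing cross-validated accuracy of a small forest.
* :class:`MRMRSelector` -- greedy minimum-redundancy maximum-relevance
  ranking on quantile-discretized features using plug-in mutual information
  (MID criterion), with the same prefix sweep.
* :class:`VariancePCA` -- principal components, keeping the smallest number
  of leading components whose cumulative explained-variance fraction reaches
  a threshold (default 0.95).
* :class:`MLFactorAnalysis` -- maximum-likelihood factor analysis with the
  factor count defaulting to the PCA component count at the same threshold.

Selectors return probe subsets; projections store training means/loadings so
held-out cohorts are transformed without refitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Serializable training-set feature representation.

    For selector methods (mrmd, mrmr) ``selected_probes`` is the ordered
    panel; for projection methods (pca, fa) ``mean``/``components`` hold the
    training transform over ``input_probes``.
    """

    method: str
    input_probes: list[str]
    selected_probes: list[str] | None = None
    mean: np.ndarray | None = None
    components: np.ndarray | None = None  # (k, len(input_probes))

    @property
    def n_features(self) -> int:
        if self.selected_probes is not None:
            return len(self.selected_probes)
        return 0 if self.components is None else self.components.shape[0]

    @property
    def required_probes(self) -> list[str]:
        return self.selected_probes if self.selected_probes is not None else self.input_probes

    def transform(self, x: pd.DataFrame) -> np.ndarray:
        """Map a samples x probes frame onto the trained representation."""
        missing = [p for p in self.required_probes if p not in x.columns]
        if missing:
            raise KeyError(f"missing probes: {missing[:10]} ({len(missing)} total)")
        if self.selected_probes is not None:
            return x.loc[:, self.selected_probes].to_numpy(dtype=float)
        z = x.loc[:, self.input_probes].to_numpy(dtype=float) - self.mean
        return z @ self.components.T

    def to_json(self, path) -> None:
        obj = {
            "method": self.method,
            "input_probes": list(self.input_probes),
            "selected_probes": self.selected_probes,
            "mean": None if self.mean is None else np.asarray(self.mean).tolist(),
            "components": None if self.components is None else np.asarray(self.components).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FeatureSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            method=obj["method"],
            input_probes=obj["input_probes"],
            selected_probes=obj["selected_probes"],
            mean=None if obj["mean"] is None else np.asarray(obj["mean"]),
            components=None if obj["components"] is None else np.asarray(obj["components"]),
        )


def _feature_names(est, x) -> list[str]:
    names = getattr(est, "feature_names_in_", None)
    if names is not None:
        return [str(n) for n in names]
    return [str(i) for i in range(x.shape[1])]


def _sweep_cv(n_splits: int, y: np.ndarray, random_state: int) -> StratifiedKFold:
    _, counts = np.unique(y, return_counts=True)
    k = min(n_splits, int(counts.min()))
    if k < n_splits:
        logger.warning("reducing CV folds %d -> %d (smallest class)", n_splits, k)
    return StratifiedKFold(n_splits=max(2, k), shuffle=True, random_state=random_state)


def prefix_cv_sweep(
    x: np.ndarray,
    y: np.ndarray,
    ranked_idx: np.ndarray,
    max_subset: int = 20,
    cv: int = 10,
    random_state: int = 0,
    estimator=None,
) -> tuple[int, np.ndarray]:
    """Mean CV accuracy of each top-k prefix; returns the smallest best k."""
    if estimator is None:
        estimator = RandomForestClassifier(n_estimators=100, random_state=random_state)
    splitter = _sweep_cv(cv, y, random_state)
    kmax = min(max_subset, len(ranked_idx))
    accs = np.empty(kmax)
    for k in range(1, kmax + 1):
        accs[k - 1] = cross_val_score(
            estimator, x[:, ranked_idx[:k]], y, cv=splitter, scoring="accuracy"
        ).mean()
    best_k = int(np.argmax(accs)) + 1  # argmax -> first (smallest) maximizer
    return best_k, accs


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def mrmd_rank(
    x: np.ndarray,
    y: np.ndarray,
    relevance_weight: float = 1.0,
    distance_weight: float = 1.0,
    feature_names: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Relevance-plus-distance feature ranking.

    score(f) = w_r * minmax(|pearson(f, y)|) + w_d * minmax(mean Euclidean
    distance from f to all other features); constant features get relevance 0.
    Ties break by feature name ascending.
    """
    x = np.asarray(x, dtype=float)
    yv = np.asarray(pd.factorize(np.asarray(y))[0], dtype=float)
    n, p = x.shape
    if p < 2:
        raise ValueError("mrmd_rank needs >= 2 features")
    names = feature_names or [str(i) for i in range(p)]
    xc = x - x.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where((sx > 0) & (sy > 0), np.abs(xc.T @ yc) / (sx * sy), 0.0)
    if np.any(sx == 0):
        logger.info("mrmd_rank: %d constant features, relevance set to 0", int((sx == 0).sum()))
    gram = x.T @ x
    sq = np.diag(gram)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0)
    mean_dist = np.sqrt(d2).sum(axis=1) / (p - 1)
    score = relevance_weight * _minmax(corr) + distance_weight * _minmax(mean_dist)
    order = np.lexsort((np.asarray(names, dtype=str), -score))
    detail = pd.DataFrame(
        {"feature": np.asarray(names, dtype=object), "relevance": corr, "mean_distance": mean_dist, "score": score}
    ).iloc[order].reset_index(drop=True)
    return order, detail


def mutual_information(a, b) -> float:
    """Plug-in mutual information (bits) of two equal-length discrete vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = len(a)
    ai = pd.factorize(a)[0]
    bi = pd.factorize(b)[0]
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log2(pij / (pi * pj))
    return float(np.nansum(terms))


def discretize_quantiles(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Per-column quantile discretization into at most ``n_bins`` levels."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(x.shape[1]):
        edges = np.unique(np.quantile(x[:, j], qs))
        out[:, j] = np.searchsorted(edges, x[:, j], side="right")
    return out


def mrmr_rank(
    xd: np.ndarray, y: np.ndarray, max_subset: int | None = None
) -> tuple[np.ndarray, list[float]]:
    """Greedy MID ranking on discretized features.

    First pick maximizes I(f; y); each later pick maximizes
    I(f; y) - mean_{s in selected} I(f; s).  Ties break on the smaller
    column index.  Returns (ranked column indices, greedy scores).
    """
    xd = np.asarray(xd)
    n, p = xd.shape
    kmax = p if max_subset is None else min(max_subset, p)
    rel = np.array([mutual_information(xd[:, j], y) for j in range(p)])
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for _ in range(kmax):
        crit = np.where(
            remaining, rel - (red_sum / max(len(selected), 1) if selected else 0.0), -np.inf
        )
        j = int(np.argmax(crit))  # argmax -> smallest index on ties
        selected.append(j)
        scores.append(float(crit[j]))
        remaining[j] = False
        if remaining.any():
            mi_new = np.array(
                [mutual_information(xd[:, j], xd[:, f]) if remaining[f] else 0.0 for f in range(p)]
            )
            red_sum += mi_new
    return np.asarray(selected), scores


class _PanelSelector(SelectorMixin, BaseEstimator):
    """Shared fit plumbing for the two panel selectors."""

    def _finalize(self, x, y, order):
        best_k, accs = prefix_cv_sweep(
            x, y, order, max_subset=self.max_subset, cv=self.cv, random_state=self.random_state
        )
        self.ranking_ = order
        self.sweep_accuracy_ = accs
        self.n_features_selected_ = best_k
        self.selected_idx_ = order[:best_k]
        mask = np.zeros(x.shape[1], dtype=bool)
        mask[self.selected_idx_] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def feature_set(self, method: str) -> FeatureSet:
        check_is_fitted(self)
        names = [str(n) for n in getattr(self, "feature_names_in_", np.arange(self.n_features_in_))]
        return FeatureSet(
            method=method,
            input_probes=names,
            selected_probes=[names[i] for i in self.selected_idx_],
        )


class MRMDSelector(_PanelSelector):
    """Relevance/distance panel selection with a CV prefix sweep."""

    def __init__(
        self,
        relevance_weight: float = 1.0,
        distance_weight: float = 1.0,
        max_subset: int = 20,
        cv: int = 10,
        random_state: int = 0,
    ):
        self.relevance_weight = relevance_weight
        self.distance_weight = distance_weight
        self.max_subset = max_subset
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        names = _feature_names(self, X)
        order, self.rank_detail_ = mrmd_rank(
            X, y, self.relevance_weight, self.distance_weight, feature_names=names
        )
        return self._finalize(X, y, order)

    def as_feature_set(self) -> FeatureSet:
        return self.feature_set("mrmd")


class MRMRSelector(_PanelSelector):
    """Greedy MID panel selection on quantile-discretized features."""

    def __init__(self, n_bins: int = 3, max_subset: int = 20, cv: int = 10, random_state: int = 0):
        self.n_bins = n_bins
        self.max_subset = max_subset
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        xd = discretize_quantiles(X, self.n_bins)
        # rank deep enough for the sweep, not the full feature space
        order, self.greedy_scores_ = mrmr_rank(xd, y, max_subset=min(X.shape[1], self.max_subset))
        return self._finalize(X, y, order)

    def as_feature_set(self) -> FeatureSet:
        return self.feature_set("mrmr")


class VariancePCA(TransformerMixin, BaseEstimator):
    """PCA keeping the fewest components reaching a cumulative variance goal."""

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        X = validate_data(self, X)
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples")
        pca = PCA(svd_solver="full")
        pca.fit(X)
        ratios = pca.explained_variance_ratio_
        if not np.isfinite(ratios).all() or ratios.sum() <= 0:
            raise ValueError("zero-variance input; PCA is degenerate")
        k = int(np.searchsorted(np.cumsum(ratios), self.variance_threshold - 1e-12) + 1)
        k = min(k, len(ratios))
        self.n_components_ = k
        self.mean_ = pca.mean_
        self.components_ = pca.components_[:k]
        self.explained_variance_ratio_ = ratios[:k]
        self.all_explained_variance_ratio_ = ratios
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return (X - self.mean_) @ self.components_.T

    def as_feature_set(self) -> FeatureSet:
        check_is_fitted(self)
        names = [str(n) for n in getattr(self, "feature_names_in_", np.arange(self.n_features_in_))]
        return FeatureSet(method="pca", input_probes=names, mean=self.mean_, components=self.components_)


class IterationLimitError(RuntimeError):
    """Factor-analysis EM failed to converge within the iteration cap."""


class MLFactorAnalysis(TransformerMixin, BaseEstimator):
    """Maximum-likelihood factor analysis with a PCA-derived default factor count."""

    def __init__(
        self,
        n_factors: int | None = None,
        variance_threshold: float = 0.95,
        max_iter: int = 2000,
        tol: float = 1e-3,
    ):
        self.n_factors = n_factors
        self.variance_threshold = variance_threshold
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = validate_data(self, X)
        k = self.n_factors
        if k is None:
            k = VariancePCA(self.variance_threshold).fit(X).n_components_
        if k >= X.shape[1]:
            raise ValueError(f"n_factors={k} must be < n_features={X.shape[1]}")
        fa = FactorAnalysis(n_components=k, tol=self.tol, max_iter=self.max_iter)
        fa.fit(X)
        if fa.n_iter_ >= self.max_iter:
            raise IterationLimitError(
                f"factor analysis hit the {self.max_iter}-iteration cap "
                f"(final loglik {fa.loglike_[-1]:.4g})"
            )
        self.n_factors_ = k
        self.estimator_ = fa
        self.mean_ = fa.mean_
        self.loadings_ = fa.components_  # (k, p)
        self.noise_variance_ = fa.noise_variance_
        # linear score transform: z = (x - mean) @ W.T with W from the FA posterior
        ih = fa.components_ / fa.noise_variance_
        cov_z = np.linalg.inv(np.eye(k) + ih @ fa.components_.T)
        self.score_weights_ = cov_z @ ih  # (k, p)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return (X - self.mean_) @ self.score_weights_.T

    def as_feature_set(self) -> FeatureSet:
        check_is_fitted(self)
        names = [str(n) for n in getattr(self, "feature_names_in_", np.arange(self.n_features_in_))]
        return FeatureSet(method="fa", input_probes=names, mean=self.mean_, components=self.score_weights_)


def make_reducer(method: str, random_state: int = 0, **kw):
    """Factory over the four strategies: mrmd, mrmr, pca, fa."""
    method = method.lower()
    if method == "mrmd":
        return MRMDSelector(random_state=random_state, **kw)
    if method == "mrmr":
        return MRMRSelector(random_state=random_state, **kw)
    if method == "pca":
        return VariancePCA(**kw)
    if method == "fa":
        return MLFactorAnalysis(**kw)
    raise ValueError(f"unknown reduction method {method!r}")
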