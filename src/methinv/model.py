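"""Random Forest invasiveness classifiers and hierarchical clustering.

Two binary forests are trained on M-values of the reduced feature
representations: one separating normal tissue from tumor, one separating
invasive from noninvasive tumors.  Cohort prediction is two-stage: the
normal-vs-tumor gate runs first and samples called tumor are then split by
the invasiveness model.  Complete-linkage hierarchical clustering over the
selected sites provides the unsupervised sanity check that the two tumor
groups separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .matrix import BetaMatrix
from .diffmeth import m_value_frame
from .reduce import FeatureSet

logger = logging.getLogger(__name__)


class ProbeGapError(KeyError):
    """A cohort lacks probes the trained models require."""


@dataclass
class CVReport:
    """Stratified k-fold cross-validation summary."""

    fold_accuracy: list[float]
    per_class_accuracy: dict
    mean_accuracy: float
    fold_assignments: pd.Series  # sample position -> fold
    n_splits: int
    seed: int


def train_rf(x, y, n_trees: int = 500, seed: int = 0) -> RandomForestClassifier:
    """Seeded forest; refuses single-class training sets."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError(f"training labels contain a single class: {np.unique(y)}")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(np.asarray(x, dtype=float), y)
    return rf


def cross_validate_model(
    x, y, k: int = 10, seed: int = 0, n_trees: int = 500
) -> CVReport:
    """Stratified k-fold CV with per-class and overall accuracy.

    k is reduced (with a warning) when the smallest class has fewer than k
    members.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_splits = min(k, int(counts.min()))
    if n_splits < k:
        logger.warning("cross_validate: reducing folds %d -> %d", k, n_splits)
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    pred = np.empty(len(y), dtype=object)
    fold_acc = []
    for f, (tr, te) in enumerate(skf.split(x, y)):
        folds[te] = f
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        rf.fit(x[tr], y[tr])
        yhat = rf.predict(x[te])
        pred[te] = yhat
        fold_acc.append(float((yhat == y[te]).mean()))
    per_class = {
        str(c): float((pred[y == c] == c).mean()) for c in classes
    }
    return CVReport(
        fold_accuracy=fold_acc,
        per_class_accuracy=per_class,
        mean_accuracy=float((pred == y).mean()),
        fold_assignments=pd.Series(folds),
        n_splits=n_splits,
        seed=seed,
    )


@dataclass
class ClassifierBundle:
    """The two trained forests plus the feature transforms they expect."""

    model_normal: RandomForestClassifier
    features_normal: FeatureSet
    model_invasive: RandomForestClassifier
    features_invasive: FeatureSet
    n_trees: int = 500
    seed: int = 0
    epsilon: float = 1e-6

    def _design(self, cohort: BetaMatrix, fs: FeatureSet) -> np.ndarray:
        missing = [p for p in fs.required_probes if p not in cohort.probe_ids]
        if missing:
            raise ProbeGapError(
                f"cohort lacks {len(missing)} required probes, e.g. {missing[:10]}"
            )
        sub = cohort.select_probes(fs.required_probes)
        if sub.data.isna().any().any():
            raise ValueError("cohort has missing values among required probes; preprocess first")
        mv = m_value_frame(sub, self.epsilon)
        return fs.transform(mv.T)

    def predict_cohort(self, cohort: BetaMatrix) -> tuple[pd.DataFrame, dict]:
        """Two-stage calls per sample plus summary counts.

        Stage 1 gates normal vs tumor; stage 2 assigns invasive/noninvasive
        to the tumor calls.  Raw per-model outputs are both reported.
        """
        if cohort.n_samples == 0:
            empty = pd.DataFrame(columns=["call_stage1", "call_stage2", "call"])
            return empty, {"normal": 0, "invasive": 0, "noninvasive": 0}
        s1 = self.model_normal.predict(self._design(cohort, self.features_normal))
        s2 = self.model_invasive.predict(self._design(cohort, self.features_invasive))
        call = np.where(s1 == "normal", "normal", s2)
        out = pd.DataFrame(
            {"call_stage1": s1, "call_stage2": s2, "call": call},
            index=cohort.sample_ids,
        )
        counts = {
            lab: int((call == lab).sum()) for lab in ("normal", "invasive", "noninvasive")
        }
        return out, counts


def fit_bundle(
    mvals: pd.DataFrame,
    labels: pd.Series,
    features_normal: FeatureSet,
    features_invasive: FeatureSet,
    n_trees: int = 500,
    seed: int = 0,
    epsilon: float = 1e-6,
) -> ClassifierBundle:
    """Train both forests from a probes x samples M-value frame and labels."""
    lab = labels.reindex(mvals.columns)
    tumor = lab.isin(["invasive", "noninvasive"])
    normal_y = np.where(tumor, "tumor", "normal")
    keep_n = tumor | (lab == "normal")
    xn = features_normal.transform(mvals.loc[:, keep_n].T)
    model_normal = train_rf(xn, normal_y[keep_n.to_numpy()], n_trees=n_trees, seed=seed)
    keep_i = tumor
    xi = features_invasive.transform(mvals.loc[:, keep_i].T)
    model_invasive = train_rf(xi, lab[keep_i].to_numpy(), n_trees=n_trees, seed=seed)
    return ClassifierBundle(
        model_normal=model_normal,
        features_normal=features_normal,
        model_invasive=model_invasive,
        features_invasive=features_invasive,
        n_trees=n_trees,
        seed=seed,
        epsilon=epsilon,
    )


def hierarchical_cluster(
    x, linkage: str = "complete", n_clusters: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering on Euclidean distances.

    Returns the scipy linkage matrix and the flat ``n_clusters``-cut labels.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    z = hierarchy.linkage(x, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, labels


def linkage_to_newick(z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
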