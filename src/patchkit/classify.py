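"""Electrophysiological typing: Ward clustering, forest importance, PCA map.

Cells are clustered on their standardized feature matrix with Ward's
minimum-variance agglomerative method on Euclidean distances and typed
by cutting the dendrogram into k clusters (k = 3 by default, matching
the three canonical interneuron firing phenotypes).  A random-forest
classifier trained on the cluster labels quantifies each feature's
contribution to cluster allocation (impurity importances, normalized to
sum to one) with stratified cross-validated accuracy; PCA of the same
matrix gives a factor map of feature loadings on the leading components.

Features are z-scored before clustering: they span four orders of
magnitude (pA vs dimensionless ratios) and unscaled Euclidean/Ward
distances would be dominated by the largest unit.  The boolean rebound
flag is encoded 0/1; the burst-or-adaptive category is encoded either as
two 0/1 dummy columns (default, giving a 19-column matrix) or as one
ordinal column {neither: 0, adaptive: 0.5, burst: 1} (strict 18-column
mode).  Missing values are imputed by the feature median and flagged;
constant features are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    cross_val_score,
)

from .io import FEATURE_COLUMNS

__all__ = [
    "ClusterResult",
    "ImportanceReport",
    "PCAResult",
    "prepare_matrix",
    "ward_cluster",
    "rf_importance",
    "pca_map",
    "plot_dendrogram",
    "plot_factor_map",
]

logger = logging.getLogger("patchkit")

_PATTERN_ORDINAL = {"neither": 0.0, "adaptive": 0.5, "burst": 1.0}


def prepare_matrix(vectors, encoding: str = "dummies") -> pd.DataFrame:
    """Standardized (z-scored) feature matrix from per-cell vectors.

    Accepts a list of :class:`~patchkit.features.FeatureVector` or a
    DataFrame with the standard feature columns.  Returns a DataFrame of
    z-scored columns (mean 0, SD 1 over cells), indexed by cell id, with
    imputation flags recorded in ``frame.attrs["imputed"]``.
    """
    if isinstance(vectors, pd.DataFrame):
        frame = vectors.copy()
        if "cell_id" in frame.columns:
            frame = frame.set_index("cell_id")
    else:
        frame = pd.DataFrame([v.as_dict() for v in vectors])
        frame = frame.set_index("cell_id")
    if len(frame) < 2:
        raise ValueError("need at least 2 cells")

    frame = frame[[c for c in FEATURE_COLUMNS if c in frame.columns]]
    frame["rebound"] = frame["rebound"].astype(float)
    pattern = frame.pop("burst_or_adaptive")
    if encoding == "dummies":
        frame["burst"] = (pattern == "burst").astype(float)
        frame["adaptive"] = (pattern == "adaptive").astype(float)
    elif encoding == "ordinal":
        frame["burst_or_adaptive"] = pattern.map(_PATTERN_ORDINAL)
    else:
        raise ValueError("encoding must be 'dummies' or 'ordinal'")
    frame = frame.astype(float)

    imputed = {}
    for col in frame.columns:
        mask = frame[col].isna()
        if mask.any():
            med = frame[col].median()
            frame.loc[mask, col] = med
            imputed[col] = list(frame.index[mask])
            logger.warning(
                "feature %s: imputed median for %d cell(s)", col, mask.sum()
            )
    constant = [c for c in frame.columns if frame[c].std(ddof=0) == 0
                or frame[c].isna().all()]
    if constant:
        logger.warning("dropping constant feature(s): %s", constant)
        frame = frame.drop(columns=constant)
    z = (frame - frame.mean()) / frame.std(ddof=0)
    z.attrs["imputed"] = imputed
    z.attrs["dropped_constant"] = constant
    return z


@dataclass
class ClusterResult:
    """Ward linkage, cluster labels at the chosen cut, and summaries."""

    linkage: np.ndarray
    labels: np.ndarray
    k: int
    feature_means: pd.DataFrame
    index: list = field(default_factory=list)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size (ties by first occurrence)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[x] for x in labels])


def ward_cluster(matrix: pd.DataFrame | np.ndarray, k: int = 3
                 ) -> ClusterResult:
    """Ward minimum-variance clustering cut into k groups.

    Merge heights are nondecreasing; labels are renumbered by descending
    cluster size so label 1 is always the largest cluster.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        index = list(matrix.index)
        cols = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        index = list(range(len(X)))
        cols = [f"f{i}" for i in range(X.shape[1])]
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of cells ({len(X)})")
    Z = linkage(X, method="ward")
    labels = _renumber_by_size(fcluster(Z, t=k, criterion="maxclust"))
    means = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=[f"cluster_{c}" for c in range(1, k + 1)],
        columns=cols,
    )
    return ClusterResult(
        linkage=Z, labels=labels, k=k, feature_means=means, index=index
    )


@dataclass
class ImportanceReport:
    importances: pd.Series
    cv_accuracy: float
    cv_method: str
    n_trees: int
    seed: int


def rf_importance(matrix: pd.DataFrame | np.ndarray, labels: np.ndarray,
                  n_trees: int = 500, seed: int = 0) -> ImportanceReport:
    """Random-forest feature importance for cluster allocation.

    Impurity-based importances normalized to sum to 1, with stratified
    5-fold cross-validated accuracy.  If any class has fewer than 5
    members, accuracy falls back to leave-one-out and the report says so.
    Deterministic given the seed.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    min_class = np.bincount(pd.factorize(y)[0]).min()
    if min_class < 5:
        cv = LeaveOneOut()
        cv_method = "leave-one-out (a class has < 5 members)"
    else:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        cv_method = "stratified 5-fold"
    acc = float(cross_val_score(clf, X, y, cv=cv).mean())
    clf.fit(X, y)
    imp = clf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return ImportanceReport(
        importances=pd.Series(imp, index=names).sort_values(ascending=False),
        cv_accuracy=acc,
        cv_method=cv_method,
        n_trees=n_trees,
        seed=seed,
    )


@dataclass
class PCAResult:
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    scores: np.ndarray


def pca_map(matrix: pd.DataFrame | np.ndarray,
            n_components: int | None = None) -> PCAResult:
    """Principal axes of the standardized feature matrix.

    Loadings are signed so each component's largest-magnitude loading is
    positive (a fixed sign convention); explained fractions are
    nonincreasing and sum to 1 over all components.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    n_max = min(X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    if n_components is None:
        n_components = n_max
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comps = pca.components_
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    loadings = pd.DataFrame(
        comps.T, index=names,
        columns=[f"PC{i + 1}" for i in range(comps.shape[0])],
    )
    return PCAResult(
        loadings=loadings,
        explained_fraction=pca.explained_variance_ratio_,
        scores=scores,
    )


def plot_dendrogram(result: ClusterResult, ax=None):
    """Basic dendrogram of the Ward linkage."""
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    dendrogram(result.linkage, labels=result.index, ax=ax)
    ax.set_ylabel("Ward merge height")
    return ax


def plot_factor_map(result: PCAResult, ax=None):
    """Vector factor map of feature loadings on PC1/PC2."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for name, row in result.loadings.iterrows():
        ax.annotate(
            "", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:blue"),
        )
        ax.text(row["PC1"], row["PC2"], str(name), fontsize=8)
    ef = result.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * ef[0]:.1f}%)")
    if len(ef) > 1:
        ax.set_ylabel(f"PC2 ({100 * ef[1]:.1f}%)")
    lim = float(np.abs(result.loadings[["PC1", "PC2"]].to_numpy()).max())
    ax.set_xlim(-1.1 * lim, 1.1 * lim)
    ax.set_ylim(-1.1 * lim, 1.1 * lim)
    return ax
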