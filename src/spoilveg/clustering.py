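"""Unsupervised land-cover clustering of the feature stack.

Features are standardized (zero mean, unit SD) before both k-means and PCA:
vegetation height is in meters while indices live on [-1, 1], so Euclidean
distances on the raw scale would be dominated by a single feature. The
number of clusters is chosen by the elbow method on the total
within-cluster sum of squares (WSS) curve; the default rule picks the k
with maximum curvature (largest second difference of WSS), an alternative
picks the smallest k whose relative WSS drop to k+1 falls below a
threshold. Cluster labels are arbitrary: all downstream joins are by label
value and every statistic is invariant to label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .rasters import ClassifiedRaster, FeatureStack


@dataclass
class Standardization:
    """Column means/SDs used for z-scoring; constant columns are dropped."""

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray          # indices of retained (non-constant) columns
    dropped: list[int] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.means) / self.sds

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sds + self.means


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardization]:
    """Z-score columns of an (n, p) matrix; drops zero-variance columns."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    kept = np.flatnonzero(sds > 0)
    if kept.size == 0:
        raise ValueError("all features are constant")
    params = Standardization(
        means=means[kept], sds=sds[kept], kept=kept,
        dropped=[int(i) for i in np.flatnonzero(sds == 0)],
    )
    return params.apply(X), params


@dataclass
class ClusterModel:
    """Fitted k-means in standardized feature space."""

    centroids: np.ndarray          # (k, p) standardized coordinates
    standardization: Standardization
    feature_names: tuple[str, ...]
    inertia: float
    seed: int
    n_init: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class ElbowProfile:
    ks: np.ndarray
    wss: np.ndarray
    selected_k: int
    rule: str
    low_confidence: bool = False


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    standardization: Standardization | None = None,
    feature_names: tuple[str, ...] = (),
) -> ClusterModel:
    """k-means++ / Lloyd, best of ``n_init`` restarts by inertia."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    if standardization is None:
        standardization = Standardization(
            means=np.zeros(X.shape[1]), sds=np.ones(X.shape[1]),
            kept=np.arange(X.shape[1]),
        )
    return ClusterModel(
        centroids=km.cluster_centers_, standardization=standardization,
        feature_names=tuple(feature_names), inertia=float(km.inertia_),
        seed=seed, n_init=n_init,
    )


def wss_curve(
    X: np.ndarray, k_range: range = range(2, 21), seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Total within-cluster sum of squares for each k (shared seed)."""
    ks = np.array(list(k_range))
    if ks.size == 0:
        raise ValueError("empty k range")
    wss = np.array(
        [KMeans(n_clusters=int(k), n_init=n_init, random_state=seed).fit(X).inertia_
         for k in ks]
    )
    return ks, wss


def select_k_from_wss(
    ks: np.ndarray, wss: np.ndarray, rule: str = "curvature", drop_threshold: float = 0.10
) -> ElbowProfile:
    """Apply an elbow rule to a precomputed WSS curve.

    "curvature": k maximizing the second difference of log WSS (endpoints
    excluded) — the relative drop into k minus the relative drop out of k.
    Working on the log scale makes the rule scale-invariant: the WSS of
    well-clustered data decays roughly geometrically before the elbow, so
    raw second differences would always peak at the smallest k.
    "relative_drop": smallest k whose WSS decrease to k+1, as a share of the
    curve's starting WSS, falls below ``drop_threshold`` (normalizing by the
    first WSS rather than the current one keeps the rule scale-free: after
    the true elbow, splitting one of k noise clusters always removes about
    1/(2k) of the remaining WSS no matter how tight the clusters are).
    A flat (near-linear) curve is flagged low-confidence and yields the
    smallest k.
    """
    ks = np.asarray(ks)
    wss = np.asarray(wss, dtype=float)
    low_conf = False
    if rule == "curvature":
        if ks.size < 3:
            sel, low_conf = int(ks[0]), True
        else:
            floor = max(wss.max(), np.finfo(float).tiny) * 1e-12
            lw = np.log(np.maximum(wss, floor))
            curv = lw[:-2] - 2 * lw[1:-1] + lw[2:]
            if curv.max() < 0.05:  # no discernible elbow
                sel, low_conf = int(ks[0]), True
            else:
                sel = int(ks[1:-1][np.argmax(curv)])
    elif rule == "relative_drop":
        scale = max(wss[0], np.finfo(float).tiny)
        drops = (wss[:-1] - wss[1:]) / scale
        below = np.flatnonzero(drops < drop_threshold)
        if below.size:
            sel = int(ks[below[0]])
        else:
            sel, low_conf = int(ks[-1]), True
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ElbowProfile(ks=ks, wss=wss, selected_k=sel, rule=rule, low_confidence=low_conf)


def elbow_select(
    X: np.ndarray,
    k_range: range = range(2, 21),
    rule: str = "curvature",
    seed: int = 0,
    n_init: int = 10,
    sample_size: int | None = None,
    drop_threshold: float = 0.10,
) -> ElbowProfile:
    """Choose k by the elbow method on the WSS curve.

    ``sample_size`` optionally subsamples rows (seeded) before the k sweep;
    with tens of thousands of pixels the curve shape is stable under
    subsampling and the sweep cost drops accordingly.
    """
    X = np.asarray(X, dtype=float)
    if sample_size is not None and X.shape[0] > sample_size:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=sample_size, replace=False)]
    ks, wss = wss_curve(X, k_range, seed=seed, n_init=n_init)
    return select_k_from_wss(ks, wss, rule=rule, drop_threshold=drop_threshold)


def classify(model: ClusterModel, stack: FeatureStack) -> ClassifiedRaster:
    """Label every valid pixel by its nearest centroid (ties -> lowest label)."""
    if model.feature_names and tuple(stack.feature_names) != tuple(model.feature_names):
        raise ValueError("feature order mismatch between model and stack")
    X, valid = stack.to_matrix()
    Z = model.standardization.apply(X)
    d = cdist(Z, model.centroids)
    lab = d.argmin(axis=1) + 1          # argmin returns first minimum: lowest label
    labels = np.zeros(stack.data.shape[1:], dtype=int)
    labels[valid] = lab
    return ClassifiedRaster(labels=labels, georef=stack.georef)


@dataclass
class PcaSummary:
    eigenvalues: np.ndarray
    proportion: np.ndarray
    loadings: np.ndarray      # (p, p) columns = axes
    scores: np.ndarray        # (n, p)


def pca_summary(Z: np.ndarray) -> PcaSummary:
    """PCA of standardized data = eigendecomposition of the correlation matrix."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[1] < 2:
        raise ValueError("need an (n>=2, p>=2) matrix")
    corr = (Z - Z.mean(axis=0)).T @ (Z - Z.mean(axis=0)) / Z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("rank-0 input")
    return PcaSummary(
        eigenvalues=evals, proportion=evals / total,
        loadings=evecs, scores=(Z - Z.mean(axis=0)) @ evecs,
    )
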