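"""Two-level gene pooling: IIC ranking, K-means clustering, GCS-based filtering.

The first-level pool is the top genes by the multi-class information index to
classification (IIC),

    d(g) = sum over unordered class pairs (j, k) of |mu_j - mu_k| / (sigma_j + sigma_k),

a signal-to-noise filter score generalized from the two-class case. Pooled
genes are then clustered by K-means on their expression profiles; clusters
whose best gene is weak relative to the best cluster are dropped, and within
surviving clusters only genes at or above the cluster-mean GCS are kept. The
survivors form the second-level pool handed to the swarm search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .core_data import ExpressionDataset, ValidationError
from .gcs import GCSProfile


@dataclass
class IICScores:
    d: np.ndarray  # per-gene score, >= 0 (may be +inf for zero-variance splits)
    mu: np.ndarray  # genes x classes means
    sigma: np.ndarray  # genes x classes standard deviations
    n_classes: int
    gene_ids: list[str]


@dataclass
class GeneClustering:
    """Cluster assignment of pooled genes plus keep-flags set by the filters."""

    assignment: np.ndarray  # cluster index per pooled gene
    centers: np.ndarray
    n_clusters: int
    cost: float  # K-means square-error cost J
    cluster_kept: np.ndarray  # bool per cluster
    gene_kept: np.ndarray  # bool per pooled gene

    def kept_gene_indices(self) -> np.ndarray:
        """Pool-local indices of the second-level pool."""
        return np.flatnonzero(self.gene_kept)


def iic_scores(ds: ExpressionDataset) -> IICScores:
    """Multi-class IIC score per gene on the (training) dataset.

    Degenerate pairs with sigma_j + sigma_k = 0 contribute +inf when the means
    differ (a perfect separator ranks first) and 0 when they are equal.
    """
    c = ds.n_classes
    mu = np.empty((ds.n_genes, c))
    sigma = np.empty((ds.n_genes, c))
    for k in range(c):
        cols = ds.X[:, ds.y == k]
        if cols.shape[1] < 2:
            raise ValidationError("IIC needs >=2 samples per class")
        mu[:, k] = cols.mean(axis=1)
        sigma[:, k] = cols.std(axis=1, ddof=1)
    d = np.zeros(ds.n_genes)
    for j in range(c):
        for k in range(j + 1, c):
            num = np.abs(mu[:, j] - mu[:, k])
            den = sigma[:, j] + sigma[:, k]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = num / den
            term[(den == 0) & (num == 0)] = 0.0
            term[(den == 0) & (num > 0)] = np.inf
            d += term
    return IICScores(d=d, mu=mu, sigma=sigma, n_classes=c, gene_ids=list(ds.gene_ids))


DEFAULT_POOL_SIZE = 300


def first_level_pool(scores: IICScores, pool_size: int = DEFAULT_POOL_SIZE) -> np.ndarray:
    """Indices of the ``pool_size`` genes with largest IIC, ties to lower index."""
    n = scores.d.size
    if not 1 <= pool_size <= n:
        raise ValidationError(f"pool_size must be in [1, {n}]")
    order = np.argsort(-scores.d, kind="stable")
    return np.sort(order[:pool_size])


def kmeans_genes(X_pool: np.ndarray, n_clusters: int, seed: int) -> GeneClustering:
    """Cluster pooled genes on their expression profiles (rows of ``X_pool``).

    Lloyd's algorithm with k-means++ seeding, 10 restarts, best-of by cost.
    """
    X_pool = np.asarray(X_pool, dtype=float)
    if n_clusters > X_pool.shape[0]:
        raise ValidationError("more clusters than pooled genes")
    km = KMeans(n_clusters=n_clusters, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(X_pool)
    return GeneClustering(
        assignment=labels,
        centers=km.cluster_centers_,
        n_clusters=n_clusters,
        cost=float(km.inertia_),
        cluster_kept=np.ones(n_clusters, dtype=bool),
        gene_kept=np.ones(X_pool.shape[0], dtype=bool),
    )


def variance_ratio(X_pool: np.ndarray, n_clusters: int, seed: int) -> float:
    """Between-group variance over total variance for a K-means solution."""
    X_pool = np.asarray(X_pool, dtype=float)
    sst = float(((X_pool - X_pool.mean(axis=0)) ** 2).sum())
    if sst == 0:
        return 1.0
    ssw = kmeans_genes(X_pool, n_clusters, seed).cost
    return 1.0 - ssw / sst


def select_num_clusters(
    X_pool: np.ndarray,
    candidates,
    method: str = "cv",
    seed: int = 0,
    gain_threshold: float = 0.05,
    cv_evaluator=None,
) -> int:
    """Pick the number of gene clusters.

    "elbow": scan candidates in increasing order and return the last count
    before the between-group/total variance-ratio gain drops below
    ``gain_threshold``. "cv": score each candidate with ``cv_evaluator`` (a
    callable returning a cross-validation accuracy, supplied by the pipeline
    layer) and return the argmax, ties to the smaller count.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates or candidates[0] < 2:
        raise ValidationError("candidates must be >= 2")
    if method == "elbow":
        ratios = [variance_ratio(X_pool, nc, seed) for nc in candidates]
        for i in range(1, len(candidates)):
            if ratios[i] - ratios[i - 1] < gain_threshold:
                return candidates[i - 1]
        return candidates[-1]
    if method == "cv":
        if cv_evaluator is None:
            raise ValidationError("method='cv' requires a cv_evaluator callable")
        scores = [cv_evaluator(nc) for nc in candidates]
        return candidates[int(np.argmax(scores))]
    raise ValidationError(f"unknown method {method!r}")


def cluster_max_gcs(clustering: GeneClustering, gcs_values: np.ndarray) -> np.ndarray:
    """Max GCS over each cluster's member genes."""
    out = np.zeros(clustering.n_clusters)
    for c in range(clustering.n_clusters):
        members = clustering.assignment == c
        out[c] = gcs_values[members].max() if members.any() else 0.0
    return out


def filter_clusters(
    clustering: GeneClustering, gcs: GCSProfile | np.ndarray, theta_c: float = 0.5
) -> GeneClustering:
    """Drop clusters whose maximum GCS is much smaller than the best cluster's.

    Cluster i is kept iff max-GCS(i) >= theta_c * max over clusters; the
    cluster holding the global maximum is always kept.
    """
    if not 0.0 < theta_c < 1.0:
        raise ValidationError("theta_c must be in (0, 1)")
    values = gcs.gcs if isinstance(gcs, GCSProfile) else np.asarray(gcs, dtype=float)
    maxima = cluster_max_gcs(clustering, values)
    kept = maxima >= theta_c * maxima.max()
    kept[int(np.argmax(maxima))] = True
    gene_kept = clustering.gene_kept & kept[clustering.assignment]
    return replace(clustering, cluster_kept=kept, gene_kept=gene_kept)


def filter_genes_within_clusters(
    clustering: GeneClustering, gcs: GCSProfile | np.ndarray
) -> GeneClustering:
    """Within each kept cluster keep genes with GCS >= the cluster mean.

    A constant-GCS cluster keeps all its genes (>= mean is never strict), so
    every kept cluster contributes at least its maximum-GCS gene.
    """
    values = gcs.gcs if isinstance(gcs, GCSProfile) else np.asarray(gcs, dtype=float)
    gene_kept = clustering.gene_kept.copy()
    for c in np.flatnonzero(clustering.cluster_kept):
        members = np.flatnonzero(clustering.assignment == c)
        if members.size == 0:
            continue
        mean = values[members].mean()
        gene_kept[members] &= values[members] >= mean
    gene_kept &= clustering.cluster_kept[clustering.assignment]
    return replace(clustering, gene_kept=gene_kept)
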