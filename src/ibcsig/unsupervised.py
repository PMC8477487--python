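"""Unsupervised signature checks: hierarchical clustering with the
Caliński–Harabasz criterion for the number of clusters, and PCA projection.

Both operations see only the expression values restricted to the signature
genes — never the class annotations — so they provide a label-blind check
that a signature separates the sample groups. Samples are clustered on
per-gene z-scored values (average linkage, Euclidean distance by default,
both configurable), the convention of expression heatmaps.

The Caliński–Harabasz index for a partition of n samples into k clusters is

    CH(k) = [B / (k - 1)] / [W / (n - k)]

with B the between-cluster and W the within-cluster sum of squared
distances to the respective centroids; the optimal cluster number is the
argmax over k. A partition with W = 0 (all points coincide within clusters)
has an undefined index and is reported as NaN rather than infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io_core import CohortError, ExpressionCohort, GeneSignature


def zscore_genes(values: np.ndarray) -> np.ndarray:
    """Per-row (gene) z-score; constant rows map to zero."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Caliński–Harabasz variance-ratio index of a flat partition.

    ``X`` is samples x features. Returns NaN when the index is undefined
    (k = 1, k = n, or zero within-cluster scatter).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        return float("nan")
    grand = X.mean(axis=0)
    between = within = 0.0
    for c in ks:
        pts = X[labels == c]
        cen = pts.mean(axis=0)
        between += len(pts) * float(((cen - grand) ** 2).sum())
        within += float(((pts - cen) ** 2).sum())
    if within <= 0:
        return float("nan")
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples on signature genes."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray  # scipy linkage encoding (merge order + heights)
    dendrogram_order: list[str]
    flat_labels: dict[int, np.ndarray]  # k -> label per sample
    ch_scores: dict[int, float]

    @property
    def optimal_k(self) -> int:
        defined = {k: v for k, v in self.ch_scores.items() if np.isfinite(v)}
        if not defined:
            raise CohortError("Caliński–Harabasz index undefined for every k")
        return max(sorted(defined), key=lambda k: defined[k])


def hier_cluster(
    cohort: ExpressionCohort,
    sig: GeneSignature,
    k_max: int = 8,
    method: str = "average",
    metric: str = "euclidean",
    zscore: bool = True,
) -> ClusteringResult:
    """Cluster the cohort samples on the signature genes and score every
    candidate cluster number with the Caliński–Harabasz index."""
    if cohort.n_samples < 3:
        raise CohortError("clustering needs at least 3 samples")
    if k_max >= cohort.n_samples:
        raise CohortError(f"k_max={k_max} must be < n_samples={cohort.n_samples}")
    if k_max < 2:
        raise CohortError("k_max must be >= 2")
    expr = cohort.values[cohort.gene_indices(sig.genes), :]
    if zscore:
        expr = zscore_genes(expr)
    X = expr.T  # samples x genes

    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    flat_labels: dict[int, np.ndarray] = {}
    ch_scores: dict[int, float] = {}
    for k in range(2, k_max + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        flat_labels[k] = labels
        # maxclust can return fewer groups on degenerate data; CH handles it
        ch_scores[k] = calinski_harabasz(X, labels)
    return ClusteringResult(
        sample_ids=list(cohort.sample_ids),
        linkage_matrix=Z,
        dendrogram_order=[cohort.sample_ids[i] for i in order],
        flat_labels=flat_labels,
        ch_scores=ch_scores,
    )


@dataclass
class PcaProjection:
    """Sample coordinates on the first m principal components."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise CohortError("explained-variance fractions must be non-increasing, sum <= 1")


def pca_project(
    cohort: ExpressionCohort,
    sig: GeneSignature,
    m: int = 2,
    zscore: bool = True,
) -> PcaProjection:
    """Project samples onto the first m principal components of the
    signature-gene expression.

    Mean-centered; each component's sign is fixed so its largest-magnitude
    gene loading is positive, making the projection deterministic and
    invariant to gene order.
    """
    if m > min(cohort.n_samples - 1, len(sig.genes)):
        raise CohortError(
            f"m={m} exceeds min(n_samples-1, n_signature_genes)="
            f"{min(cohort.n_samples - 1, len(sig.genes))}"
        )
    # fix gene order for the loading-sign convention regardless of input order
    genes = sorted(sig.genes)
    expr = cohort.values[cohort.gene_indices(genes), :]
    if zscore:
        expr = zscore_genes(expr)
    X = expr.T

    pca = PCA(n_components=m, svd_solver="full")
    coords = pca.fit_transform(X)
    for c in range(m):
        loadings = pca.components_[c]
        top = int(np.argmax(np.abs(loadings)))
        if loadings[top] < 0:
            coords[:, c] *= -1
    return PcaProjection(
        sample_ids=list(cohort.sample_ids),
        coordinates=coords,
        explained_variance_ratio=np.asarray(pca.explained_variance_ratio_),
    )
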