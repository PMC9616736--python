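"""Marker-based major-class assignment and cluster-tree fusion.

Clusters are assigned to one of the major fly-brain cell classes by
marker expression (VAChT cholinergic, VGlut glutamatergic, Gad1
GABAergic, ey/Dop1R2/Pka-C1/mub Kenyon cells, Vmat monoaminergic,
CG10433 glia), then arranged in a dendrogram of their centroids in
embedding (PC) space.  Sibling leaves separated by fewer than
``min_de_genes`` differentially expressed protein-coding genes
(two-sample Wilcoxon rank-sum test, Benjamini-Hochberg adjusted
p < alpha) are fused; the tree is rebuilt and the procedure repeated
until no pair fuses.

The rank-sum (Mann-Whitney) test is used for the unpaired
cluster-vs-cluster comparison; a paired signed-rank test is not
applicable to clusters of unequal, unmatched cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import linkage
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "DEFAULT_CLASS_RULES",
    "FusionConfig",
    "ClusterTree",
    "assign_major_class",
    "build_cluster_tree",
    "sibling_leaf_pairs",
    "count_de_genes",
    "fuse_clusters",
]

# (label, markers that must all exceed threshold), in priority order.
# Kenyon cells are evaluated first because they also express the
# cholinergic marker.
DEFAULT_CLASS_RULES = (
    ("Kenyon", ("ey", "Dop1R2", "Pka-C1", "mub")),
    ("cholinergic", ("VAChT",)),
    ("glutamatergic", ("VGlut",)),
    ("GABAergic", ("Gad1",)),
    ("monoaminergic", ("Vmat",)),
    ("glia", ("CG10433",)),
)


@dataclass
class FusionConfig:
    min_de_genes: int = 10
    alpha: float = 0.05
    protein_coding: Optional[set] = None  # None = all genes are eligible
    min_cells_per_cluster: int = 3

    def __post_init__(self):
        if self.min_de_genes < 1:
            raise DataError("min_de_genes must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise DataError("alpha must be in (0, 1)")


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over cluster centroids.

    ``linkage_`` is a scipy linkage matrix whose leaf indices refer to
    ``leaves`` (sorted cluster ids); ``centroids`` are the per-cluster
    mean embeddings, aligned with ``leaves``.
    """

    linkage_: np.ndarray
    leaves: list
    centroids: np.ndarray


def assign_major_class(
    cluster_means: pd.DataFrame,
    rules: Sequence = DEFAULT_CLASS_RULES,
    thresholds=1.0,
) -> pd.Series:
    """Assign each cluster (row of mean scaled expression) a class label.

    The first rule whose markers are all strictly above threshold wins;
    clusters matching no rule are labelled ``"other"``.  ``thresholds``
    is a scalar or a per-gene dict.
    """
    needed = {g for _, markers in rules for g in markers}
    missing = sorted(needed - set(cluster_means.columns))
    if missing:
        raise DataError(f"marker gene(s) absent from cluster means: {missing}")

    def thr(g):
        return thresholds.get(g, 1.0) if isinstance(thresholds, dict) else thresholds

    labels = []
    for _, row in cluster_means.iterrows():
        label = "other"
        for name, markers in rules:
            if all(row[g] > thr(g) for g in markers):
                label = name
                break
        labels.append(label)
    return pd.Series(labels, index=cluster_means.index, name="major_class")


def build_cluster_tree(embedding: np.ndarray, labels) -> ClusterTree:
    """Average-linkage tree on cluster centroids in embedding space.

    Invariant under permutation of cell order; raises on empty clusters.
    """
    embedding = np.asarray(embedding, float)
    labels = np.asarray(labels)
    if embedding.shape[0] != labels.shape[0]:
        raise DataError("embedding rows must align with labels")
    leaves = sorted(pd.unique(labels).tolist())
    if len(leaves) < 2:
        raise DataError("need at least 2 clusters to build a tree")
    centroids = np.vstack([embedding[labels == c].mean(axis=0) for c in leaves])
    for c, cen in zip(leaves, centroids):
        if not np.all(np.isfinite(cen)):
            raise DataError(f"cluster {c} has a non-finite centroid (empty cluster?)")
    Z = linkage(centroids, method="average", metric="euclidean")
    return ClusterTree(linkage_=Z, leaves=leaves, centroids=centroids)


def sibling_leaf_pairs(tree: ClusterTree):
    """Pairs of leaves merged directly together, sorted by merge height
    (most similar first)."""
    n = len(tree.leaves)
    pairs = []
    for a, b, height, _ in tree.linkage_:
        if a < n and b < n:
            pairs.append((tree.leaves[int(a)], tree.leaves[int(b)], float(height)))
    pairs.sort(key=lambda t: t[2])
    return pairs


def _to_dense(X):
    return X.toarray() if sparse.issparse(X) else np.asarray(X, float)


def count_de_genes(Xa, Xb, gene_names, cfg: FusionConfig):
    """Number of (protein-coding) genes differentially expressed between
    two cell groups on the normalized layer.

    Genes tested: protein-coding genes detected in at least one cell of
    the pair.  Returns ``(n_de, tested_genes, padj)``.
    """
    Xa, Xb = _to_dense(Xa), _to_dense(Xb)
    gene_names = np.asarray(gene_names)
    eligible = np.ones(len(gene_names), dtype=bool)
    if cfg.protein_coding is not None:
        eligible &= np.isin(gene_names, list(cfg.protein_coding))
    detected = (Xa > 0).any(axis=0) | (Xb > 0).any(axis=0)
    test = eligible & detected
    if not test.any():
        return 0, gene_names[test], np.array([])
    A, B = Xa[:, test], Xb[:, test]
    # genes constant across both groups carry no rank information
    const = (A.max(axis=0) == A.min(axis=0)) & (B.max(axis=0) == B.min(axis=0)) & (
        A[0] == B[0]
    )
    pvals = np.ones(A.shape[1])
    if (~const).any():
        res = mannwhitneyu(A[:, ~const], B[:, ~const], axis=0, method="asymptotic")
        pvals[~const] = res.pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    return int((padj < cfg.alpha).sum()), gene_names[test], padj


def fuse_clusters(
    X,
    gene_names,
    labels,
    embedding: np.ndarray,
    cfg: FusionConfig = None,
):
    """Iteratively fuse sibling clusters with too few DE genes.

    ``X`` is the cells x genes normalized expression layer.  Returns
    ``(new_labels, log)`` where the log records every tested pair, its
    DE-gene count, and the decision.  Cluster count never increases and
    the loop terminates after at most (initial clusters - 1) rounds.
    """
    cfg = cfg or FusionConfig()
    labels = np.asarray(labels, dtype=object).copy()
    log = []
    n_initial = len(pd.unique(labels))
    for _ in range(max(n_initial - 1, 1)):
        if len(pd.unique(labels)) < 2:
            break
        tree = build_cluster_tree(embedding, labels)
        fused_any = False
        touched = set()
        for a, b, height in sibling_leaf_pairs(tree):
            if a in touched or b in touched:
                continue
            ia, ib = labels == a, labels == b
            if min(ia.sum(), ib.sum()) < cfg.min_cells_per_cluster:
                log.append(
                    dict(cluster_a=a, cluster_b=b, height=height, n_de=np.nan,
                         decision="skipped:too_few_cells")
                )
                continue
            n_de, _, _ = count_de_genes(X[ia], X[ib], gene_names, cfg)
            fuse = n_de < cfg.min_de_genes
            log.append(
                dict(cluster_a=a, cluster_b=b, height=height, n_de=n_de,
                     decision="fused" if fuse else "kept")
            )
            if fuse:
                labels[ib] = a
                touched.update((a, b))
                fused_any = True
        if not fused_any:
            break
    return labels, pd.DataFrame(
        log, columns=["cluster_a", "cluster_b", "height", "n_de", "decision"]
    )
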