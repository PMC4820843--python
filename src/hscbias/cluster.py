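"""PCA over variable genes, top-loading gene selection, hierarchical clustering.

The clustering recipe: gene-centered PCA of log2(CPM+1) over cells; each
gene scored by its highest absolute Pearson correlation with the first
three component score vectors; the 100 top-scoring genes define the feature
space for complete-linkage agglomeration under correlation distance
(1 - Pearson r between cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .qc import ExpressionMatrix


@dataclass
class PcaResult:
    """Scores (cell x component), loadings as gene-to-score Pearson
    correlations (gene x component), and explained variance fractions."""

    cell_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray


@dataclass
class Dendrogram:
    """Cell merge tree: scipy linkage matrix plus the metric labels."""

    cell_ids: list[str]
    linkage: np.ndarray
    distance: str = "pearson correlation"
    method: str = "complete"

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.cell_ids, (int(l) for l in labels)))

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.cell_ids[node.id]
            left, right = node.get_left(), node.get_right()
            ldist = node.dist - left.dist
            rdist = node.dist - right.dist
            return f"({walk(left)}:{ldist:.6g},{walk(right)}:{rdist:.6g})"

        return walk(tree) + ";"


def run_pca(X: ExpressionMatrix, n_components: int = 3) -> PcaResult:
    """Gene-centered (unscaled) PCA of cells; loadings are correlations.

    Cells are observations, genes features. Component signs are fixed so
    that each score vector's largest-magnitude entry is positive.
    """
    if X.scale != "log2cpm1":
        raise ValueError(f"PCA expects log2cpm1 input, got {X.scale!r}")
    n_cells, n_genes = len(X.cell_ids), len(X.gene_ids)
    if n_components > min(n_genes, n_cells):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells)="
            f"{min(n_genes, n_cells)}"
        )
    mat = X.values.T  # cells x genes
    centered = mat - mat.mean(axis=0)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    scores = (u * s)[:, :n_components]
    # deterministic sign: largest-|.| entry of each score vector positive
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    total_var = (s**2).sum()
    explained = (s[:n_components] ** 2) / total_var if total_var > 0 else s[:n_components] * 0
    loadings = _gene_score_correlations(centered, scores)
    return PcaResult(
        cell_ids=list(X.cell_ids),
        gene_ids=list(X.gene_ids),
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
    )


def _gene_score_correlations(centered: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of each gene's (centered) expression with each score vector.

    Constant genes and constant score vectors yield correlation 0 rather
    than NaN so they never rank above informative genes.
    """
    sc = scores - scores.mean(axis=0)
    gene_norm = np.sqrt((centered**2).sum(axis=0))
    score_norm = np.sqrt((sc**2).sum(axis=0))
    denom = np.outer(gene_norm, score_norm)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (centered.T @ sc) / denom
    return np.where(denom > 0, corr, 0.0)


def top_loading_genes(
    pca: PcaResult, n_components: int = 3, k: int = 100, aggregate: str = "max"
) -> list[str]:
    """The k genes most correlated with any of the first components.

    Each gene's score is an aggregate over the first ``n_components`` of its
    absolute loadings: ``max`` (default), ``l2``, or ``union`` (per-component
    top-(k / n_components) lists merged). Ties break lexicographically on
    gene id, descending score first.
    """
    if n_components > pca.loadings.shape[1]:
        raise ValueError("n_components exceeds available components")
    if k > len(pca.gene_ids):
        raise ValueError(f"k={k} exceeds {len(pca.gene_ids)} genes")
    absl = np.abs(pca.loadings[:, :n_components])
    if aggregate == "max":
        score = absl.max(axis=1)
    elif aggregate == "l2":
        score = np.sqrt((absl**2).sum(axis=1))
    elif aggregate == "union":
        per = max(1, int(np.ceil(k / n_components)))
        chosen: list[str] = []
        for j in range(n_components):
            order = sorted(
                range(len(pca.gene_ids)), key=lambda i: (-absl[i, j], pca.gene_ids[i])
            )
            for i in order[:per]:
                if pca.gene_ids[i] not in chosen:
                    chosen.append(pca.gene_ids[i])
        return sorted(chosen)[:k] if len(chosen) > k else chosen
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    order = sorted(range(len(pca.gene_ids)), key=lambda i: (-score[i], pca.gene_ids[i]))
    return [pca.gene_ids[i] for i in order[:k]]


def hierarchical_cluster(X: ExpressionMatrix, genes: list[str]) -> Dendrogram:
    """Complete-linkage clustering of cells under 1 - Pearson r distance,
    computed over the selected genes only."""
    if len(X.cell_ids) < 2:
        raise ValueError("clustering needs at least 2 cells")
    idx = [X.gene_ids.index(g) for g in genes]
    sub = X.values[idx, :].T  # cells x genes
    sd = sub.std(axis=1)
    constant = [X.cell_ids[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        raise ValueError(
            f"cells constant across selected genes (correlation undefined): "
            f"{constant[:5]}"
        )
    dist = pdist(sub, metric="correlation")  # == 1 - Pearson r
    linkage = sch.linkage(dist, method="complete")
    return Dendrogram(cell_ids=list(X.cell_ids), linkage=linkage)


def cluster_concordance(cluster_labels, group_labels) -> float:
    """Purity: mean over cells of the majority-group fraction in each cluster."""
    cluster_labels, group_labels = list(cluster_labels), list(group_labels)
    if len(cluster_labels) != len(group_labels):
        raise ValueError("label vectors differ in length")
    n = len(cluster_labels)
    total = 0
    for cl in set(cluster_labels):
        groups = [g for c, g in zip(cluster_labels, group_labels) if c == cl]
        total += max(groups.count(g) for g in set(groups))
    return total / n
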