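"""Hierarchical clustering of DE genes and heatmap-ready matrices.

Genes are clustered agglomeratively on the one-minus-Pearson-correlation
distance (d = 1 - r, ranging 0..2) with average linkage; for display the
expression rows are z-scored and the genes reordered by dendrogram leaf
order, while samples are grouped by response (complete responders first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .normalization import NormalizedMatrix
from .synthetic import SampleAnnotation

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")


def pearson_distance_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; requires nonconstant rows."""
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    if A.shape[0] == 1:
        return np.zeros((1, 1))
    sd = A.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"rows with zero variance: {bad.tolist()[:5]}")
    r = np.corrcoef(A)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf order."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    leaf_order: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..n_clusters) for each leaf."""
        if self.n_leaves == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")

    def merges(self) -> list[tuple[frozenset[int], frozenset[int], float]]:
        """Merge sequence as (leaf-set, leaf-set, height) triples."""
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(self.n_leaves)}
        out = []
        for step, (i, j, h, _size) in enumerate(self.linkage_matrix):
            a, b = members[int(i)], members[int(j)]
            out.append((a, b, float(h)))
            members[self.n_leaves + step] = a | b
        return out


def hierarchical_cluster(D: np.ndarray, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n == 1:
        return Dendrogram(linkage_matrix=np.empty((0, 4)), leaf_order=(0,))
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = tuple(int(i) for i in hierarchy.leaves_list(Z))
    return Dendrogram(linkage_matrix=Z, leaf_order=order)


@dataclass(frozen=True)
class HeatmapData:
    """Row-standardized matrix with display orders for genes and samples."""

    matrix: pd.DataFrame  # z-scored, genes x samples, display order
    gene_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    sample_response: dict[str, str]
    gene_dendrogram: Dendrogram | None


def build_heatmap_matrix(
    norm: NormalizedMatrix,
    de_genes: Sequence[str],
    annotations: Sequence[SampleAnnotation],
    linkage: str = "average",
) -> HeatmapData:
    """Heatmap input for a DE gene list over pre-treatment samples.

    Rows are z-scored (mean 0, sd 1, ddof=1); gene order comes from
    average-linkage clustering on 1 - Pearson distance; samples are ordered
    CR first then IR, by patient id within each group. Constant rows are
    dropped with a warning (they carry no clustering signal).
    """
    if not de_genes:
        raise ValueError("empty gene list")
    pre = [a for a in annotations if a.timepoint == "pre" and a.sample_id in norm.values.columns]
    if not pre:
        raise ValueError("no pre-treatment samples available")
    order_key = {"CR": 0, "IR": 1, "unknown": 2}
    pre_sorted = sorted(pre, key=lambda a: (order_key[a.response], a.patient_id))
    sample_order = tuple(a.sample_id for a in pre_sorted)
    sample_response = {a.sample_id: a.response for a in pre_sorted}

    X = norm.log_values()
    genes = [g for g in de_genes if g in X.index]
    missing = set(de_genes) - set(genes)
    if missing:
        logger.warning("%d requested genes absent from the matrix", len(missing))
    if not genes:
        raise ValueError("none of the requested genes are in the matrix")
    sub = X.loc[genes, list(sample_order)]
    sd = sub.std(axis=1, ddof=1)
    constant = list(sub.index[sd == 0])
    if constant:
        logger.warning("dropping %d constant genes before clustering", len(constant))
        sub = sub.drop(index=constant)
        sd = sd.drop(index=constant)
    if sub.shape[0] == 0:
        raise ValueError("all requested genes are constant across samples")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)

    if z.shape[0] == 1:
        gene_order = tuple(z.index)
        dend = None
    else:
        D = pearson_distance_matrix(z.to_numpy())
        dend = hierarchical_cluster(D, linkage=linkage)
        gene_order = tuple(z.index[i] for i in dend.leaf_order)
    return HeatmapData(
        matrix=z.loc[list(gene_order)],
        gene_order=gene_order,
        sample_order=sample_order,
        sample_response=sample_response,
        gene_dendrogram=dend,
    )
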