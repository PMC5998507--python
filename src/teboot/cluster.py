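"""Sample clustering of expression profiles: UPGMA, Ward.D2 and PCA.

Samples are clustered on log2(TPM + 1) vectors over the ortholog gene
universe (clustering needs complete vectors, hence the pseudocount; the
bootstrap statistic instead uses log2(TPM) with zeros omitted). UPGMA is
average linkage on a configurable dissimilarity (Euclidean by default,
Spearman correlation distance available); Ward.D2 operates on Euclidean
distances with squared-distance bookkeeping, heights on the distance scale.
Trees are cut at a fixed number of clusters (defaults: 5 for UPGMA, 7 for
Ward.D2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .models import ExpressionTable, OrthologTable, ValidationError

DEFAULT_CUTS = {"upgma": 5, "ward_d2": 7}


@dataclass
class SampleDistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    metric: str

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy (n-1, 4) merge list with heights
    labels: pd.Series  # sample_id -> cluster 1..k
    method: str
    k: int


def ortholog_expression_matrix(
    expr: ExpressionTable, orthologs: OrthologTable
) -> pd.DataFrame:
    """Ortholog-group x sample TPM matrix across species.

    For each sample, each group's value is the TPM of the group's member
    gene in that sample's species. Groups missing the species (or whose
    member gene lacks a value) are dropped so that all vectors are complete.
    """
    meta = expr.sample_meta
    cols = {}
    for sample in expr.sample_ids:
        sp = meta.loc[sample, "species"]
        if sp not in orthologs.table.columns:
            raise ValidationError(f"sample {sample!r}: species {sp!r} not in "
                                  "ortholog table")
        members = orthologs.table[sp]
        cols[sample] = expr.values[sample].reindex(members.to_numpy()).to_numpy()
    mat = pd.DataFrame(cols, index=orthologs.table.index)
    return mat.dropna(axis=0)


def expression_distance(
    matrix: pd.DataFrame,
    transform: str = "log2p1",
    metric: str = "euclidean",
) -> SampleDistanceMatrix:
    """Pairwise sample distances on transformed expression vectors.

    ``matrix`` is genes/groups x samples (TPM). ``transform`` is ``log2p1``
    (log2(TPM + 1)) or ``none``; ``metric`` is ``euclidean`` or ``spearman``
    (1 - Spearman rank correlation).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples to compute distances")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    if np.isnan(X).any():
        raise ValidationError("expression matrix for clustering has missing values")
    if transform == "log2p1":
        X = np.log2(X + 1.0)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    zero_rows = np.nonzero(~X.any(axis=1))[0]
    if zero_rows.size:
        import warnings

        warnings.warn(
            f"{zero_rows.size} sample(s) have all-zero expression", stacklevel=2
        )
    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "spearman":
        rho = spearmanr(X.T).statistic
        rho = np.atleast_2d(rho)
        D = 1.0 - rho
        np.fill_diagonal(D, 0.0)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return SampleDistanceMatrix(
        sample_ids=list(matrix.columns), matrix=D, metric=metric
    )


def hierarchical_cluster(
    d: SampleDistanceMatrix, method: str = "upgma", k: int | None = None
) -> ClusteringResult:
    """Agglomerate and cut at exactly ``k`` clusters.

    ``upgma`` = average linkage on the given dissimilarities; ``ward_d2`` =
    Ward's minimum-variance criterion treating the dissimilarities as
    Euclidean distances.
    """
    n = len(d.sample_ids)
    if k is None:
        k = min(DEFAULT_CUTS.get(method, 2), n)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of samples ({n})")
    if method == "upgma":
        Z = hierarchy.linkage(d.condensed(), method="average")
    elif method == "ward_d2":
        Z = hierarchy.linkage(d.condensed(), method="ward")
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=d.sample_ids, name="cluster")
    return ClusteringResult(linkage=Z, labels=labels, method=method, k=int(k))


def cophenetic_matrix(result: ClusteringResult) -> np.ndarray:
    return squareform(hierarchy.cophenet(result.linkage))


def to_newick(result: ClusteringResult, sample_ids: list[str]) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{sample_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def pca_samples(
    matrix: pd.DataFrame, n_components: int = 2, transform: str = "log2p1"
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on per-gene-centered log2(TPM + 1).

    Returns (coordinates: samples x components, variance fractions). A
    constant matrix yields zero coordinates and zero variance fractions.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples for PCA")
    X = matrix.to_numpy(dtype=float).T
    if transform == "log2p1":
        X = np.log2(X + 1.0)
    Xc = X - X.mean(axis=0, keepdims=True)  # center each gene across samples
    n_components = min(n_components, min(Xc.shape))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0.0:
        coords = np.zeros((X.shape[0], n_components))
        frac = np.zeros(n_components)
    else:
        coords = (U * s)[:, :n_components]
        frac = (s[:n_components] ** 2) / total
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), frac
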