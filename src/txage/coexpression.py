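"""Co-expression metagene analysis.

Genes are clustered on 1 - TOM, where TOM is the topological overlap of the
unsigned correlation network: two genes are similar if they are directly
correlated and share correlated neighbours. Clusters found by cutting the
average-linkage tree are collapsed to metagenes (the mean per-gene z-score
across cluster members, per sample) and compared between healthy controls
and cases with Welch's t-test, BH-adjusted across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator, ClusterMixin

from .datamodel import SampleMetadata, ValidationError
from .de import bh_adjust


@dataclass
class ClusterSet:
    """Disjoint gene clusters of at least ``min_size`` members."""

    clusters: dict[int, list[str]]
    cut_height: float
    min_size: int

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> pd.Series:
        rows = {g: cid for cid, genes in self.clusters.items() for g in genes}
        return pd.Series(rows, name="cluster")


def batch_regress(expr: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove additive batch effects: per gene, subtract batch means and add
    back the grand mean. A linear stand-in for empirical-Bayes batch
    correction; with a single batch it is the identity (with a warning)."""
    batch = batch.loc[expr.columns]
    if batch.nunique() < 2:
        warnings.warn("single batch: batch correction is the identity")
        return expr.copy()
    grand = expr.mean(axis=1)
    out = expr.copy()
    for level in batch.unique():
        cols = expr.columns[batch == level]
        out[cols] = expr[cols].sub(expr[cols].mean(axis=1), axis=0)
    return out.add(grand, axis=0)


def filter_coexpression_genes(
    expr: pd.DataFrame, min_mean: float = 10.0, max_cv: float = 0.15
) -> list[str]:
    """Keep well-expressed, stable genes: mean > ``min_mean`` and
    coefficient of variation (sd/mean) < ``max_cv``."""
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (mean > min_mean) & (cv < max_cv)
    if not keep.any():
        raise ValidationError("no genes pass the co-expression expression/CV filter")
    return list(expr.index[keep])


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency with zero diagonal:
    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj and k_i the node connectivity; TOM_ii = 1."""
    adjacency = np.asarray(adjacency, dtype=float)
    shared = adjacency @ adjacency
    k = adjacency.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adjacency
    tom = (shared + adjacency) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_matrix(expr: pd.DataFrame, genes=None, beta: float = 1.0) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned correlation network,
    adjacency a_ij = |Pearson(g_i, g_j)|^beta (zero diagonal)."""
    if genes is not None:
        expr = expr.loc[list(genes)]
    if expr.shape[0] < 3 or expr.shape[1] < 3:
        raise ValidationError("TOM needs at least 3 genes and 3 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValidationError(f"constant gene {bad!r}: correlation undefined")
    adjacency = np.abs(np.corrcoef(values)) ** beta
    np.fill_diagonal(adjacency, 0.0)
    tom = tom_from_adjacency(adjacency)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def cut_clusters(
    tom: pd.DataFrame, cut_height: float = 0.95, min_size: int = 50
) -> ClusterSet:
    """Average-linkage tree on 1 - TOM, cut at ``cut_height``; clusters below
    ``min_size`` are discarded. Surviving clusters are renumbered 1..k by
    decreasing size."""
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip(dissim, 0.0, None), checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    clusters = {}
    for label in np.unique(labels):
        members = list(tom.index[labels == label])
        if len(members) >= min_size:
            clusters[label] = members
    if not clusters:
        warnings.warn("no co-expression cluster reaches min_size")
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
    return ClusterSet(
        {i + 1: members for i, members in enumerate(ordered)},
        cut_height=cut_height,
        min_size=min_size,
    )


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (sample sd, n-1); zero-variance genes
    come back as NaN rows."""
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = expr.sub(mean, axis=0).div(sd, axis=0)
    return z.where(np.isfinite(z))


def metagenes(expr: pd.DataFrame, clusters: ClusterSet) -> pd.DataFrame:
    """Cluster x sample metagene matrix: mean member-gene z-score per sample."""
    z = zscore_genes(expr)
    rows = {}
    for cid, members in clusters.clusters.items():
        missing = set(members) - set(expr.index)
        if missing:
            raise ValidationError(
                f"cluster {cid} members absent from expression: {sorted(missing)[:5]}"
            )
        sub = z.loc[members]
        degenerate = sub.isna().all(axis=1)
        if degenerate.any():
            warnings.warn(
                f"cluster {cid}: {int(degenerate.sum())} zero-variance genes "
                "excluded from the metagene"
            )
            sub = sub.loc[~degenerate]
        rows[cid] = sub.mean(axis=0)
    return pd.DataFrame(rows).T.rename_axis("cluster")


def cluster_group_test(
    metagene_matrix: pd.DataFrame,
    metadata: SampleMetadata,
    group_a: str = "HC",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-cluster group-A vs rest comparison (Welch two-tailed t by default),
    BH-adjusted across clusters."""
    groups = metadata.table.loc[metagene_matrix.columns, "group"]
    in_a = (groups == group_a).to_numpy()
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValidationError("both groups need at least 2 samples")
    a = metagene_matrix.loc[:, in_a].to_numpy()
    b = metagene_matrix.loc[:, ~in_a].to_numpy()
    t, p = ttest_ind(a, b, axis=1, equal_var=equal_var)
    out = pd.DataFrame(
        {"t": t, "p": p, "p_adj": bh_adjust(p)}, index=metagene_matrix.index
    )
    return out


class TOMCoexpression(BaseEstimator, ClusterMixin):
    """TOM-based gene clustering as an sklearn-style clusterer.

    fit(X) clusters the ROWS of X (genes), with columns as samples —
    the orientation of a genes x samples expression matrix. ``labels_``
    gives each gene's cluster id, with -1 for genes in no surviving cluster.
    """

    def __init__(self, beta=1.0, cut_height=0.95, min_size=50):
        self.beta = beta
        self.cut_height = cut_height
        self.min_size = min_size

    def fit(self, X, y=None):
        expr = pd.DataFrame(X)
        tom = tom_matrix(expr, beta=self.beta)
        clusters = cut_clusters(tom, self.cut_height, self.min_size)
        membership = clusters.membership()
        labels = np.full(expr.shape[0], -1)
        for i, gene in enumerate(expr.index):
            if gene in membership.index:
                labels[i] = membership[gene]
        self.tom_ = tom
        self.clusters_ = clusters
        self.labels_ = labels
        return self

    def transform(self, X):
        """Metagene matrix (clusters x samples) for the fitted clusters."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "clusters_")
        return metagenes(pd.DataFrame(X), self.clusters_)
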