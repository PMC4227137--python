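"""Average-linkage clustering of samples over signature genes.

Distances follow the Eisen/TreeView convention: one minus the Pearson
correlation between samples computed over per-gene median-centered
signature expression. The dendrogram is cut at the root into two clusters;
the cluster with the higher parous fraction is labelled "predicted parous"
and per-class accuracies are computed against the annotated parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .preprocess import impute_missing, median_center_genes
from ._utils import parous_mask

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    """Linkage tree, two-way partition and the samples it covers."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    labels: np.ndarray  # cluster ids 1/2 aligned with sample_ids
    excluded_samples: list[str]


def cluster_samples(
    matrix: pd.DataFrame,
    distance: str = "one_minus_pearson",
    linkage_method: str = "average",
) -> ClusterReport:
    """Agglomerate samples over the (already signature-restricted) matrix.

    Genes are median-centered before distances are computed. Samples with
    zero variance across the genes (undefined correlation) are excluded with
    a warning. Merge heights are non-decreasing for average linkage.
    """
    if distance != "one_minus_pearson":
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage_method != "average":
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    matrix = impute_missing(matrix)
    centered = median_center_genes(matrix)
    values = centered.to_numpy(dtype=float)
    # a flat sample carries no correlation information (its centered vector is
    # the negated gene-median profile, identical for every flat sample), and a
    # centered-constant sample has an undefined Pearson correlation outright
    raw_sd = matrix.to_numpy(dtype=float).std(axis=0)
    sd = values.std(axis=0)
    keep = (sd > 0) & (raw_sd > 0)
    excluded = [str(s) for s in matrix.columns[~keep]]
    if excluded:
        logger.warning("excluding %d zero-variance samples from clustering: %s",
                       len(excluded), excluded[:5])
    values = values[:, keep]
    samples = [str(s) for s in matrix.columns[keep]]
    if len(samples) < 2:
        raise ValueError("need >= 2 usable samples to cluster")
    corr = np.corrcoef(values.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    return ClusterReport(samples, Z, labels, excluded)


def parity_accuracy(report: ClusterReport, ann: pd.DataFrame) -> tuple[float, float]:
    """Per-class parity prediction accuracy from the two-way partition.

    The cluster with the higher parous fraction is "predicted parous" (ties
    go to the larger cluster, then to cluster 1). Returns
    ``(parous_accuracy, nulliparous_accuracy)``.
    """
    labels = np.asarray(report.labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("degenerate single-cluster tree; cannot predict parity")
    parity = parous_mask(ann.loc[report.sample_ids, "parity"].to_numpy())
    frac = {c: parity[labels == c].mean() for c in uniq}
    size = {c: int((labels == c).sum()) for c in uniq}
    predicted_parous = sorted(uniq, key=lambda c: (-frac[c], -size[c], c))[0]
    pred = labels == predicted_parous
    n_par = int(parity.sum())
    n_nul = int((~parity).sum())
    if n_par == 0 or n_nul == 0:
        raise ValueError("both parity classes must be present to score accuracy")
    parous_acc = float((pred & parity).sum() / n_par)
    nulliparous_acc = float((~pred & ~parity).sum() / n_nul)
    return parous_acc, nulliparous_acc


class SignatureClustering(BaseEstimator):
    """Estimator wrapper: ``fit(X)`` with samples x genes input.

    ``genes`` optionally restricts the matrix to signature genes before
    clustering. Fitted attributes: ``linkage_``, ``labels_``,
    ``sample_ids_``, ``excluded_samples_``.
    """

    def __init__(self, genes=None, distance: str = "one_minus_pearson",
                 linkage_method: str = "average"):
        self.genes = genes
        self.distance = distance
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SignatureClustering needs a DataFrame with gene columns")
        matrix = X.T
        if self.genes is not None:
            present = [g for g in self.genes if g in matrix.index]
            if not present:
                raise ValueError("none of the requested genes are in the matrix")
            matrix = matrix.loc[present]
        report = cluster_samples(matrix, self.distance, self.linkage_method)
        self.report_ = report
        self.linkage_ = report.linkage_matrix
        self.labels_ = report.labels
        self.sample_ids_ = report.sample_ids
        self.excluded_samples_ = report.excluded_samples
        return self

    def score_parity(self, ann: pd.DataFrame) -> tuple[float, float]:
        return parity_accuracy(self.report_, ann)
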