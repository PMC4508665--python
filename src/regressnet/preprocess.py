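"""Noisy-gene filtering and unsupervised sample clustering.

The pipeline starts from a summarized log2 expression matrix, so uninformative
genes are removed with an across-sample variance filter: probe-level
informative/non-informative calls require raw probe data and are out of scope.
Sample clustering uses 1 - Pearson correlation distance with average linkage,
the convention of coexpression-network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ExpressionDataset, FilterReport


def filter_noninformative(
    data: ExpressionDataset,
    keep_fraction: float | None = None,
    min_variance: float | None = None,
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop low-variance genes; exactly one criterion must be given.

    ``keep_fraction`` keeps the top fraction of genes by across-sample
    variance (ties broken by input order); ``min_variance`` keeps genes with
    variance >= the threshold.  Survivor order is preserved.
    """
    if (keep_fraction is None) == (min_variance is None):
        raise ValueError("give exactly one of keep_fraction or min_variance")
    variances = data.values.var(axis=1, ddof=1)
    if keep_fraction is not None:
        if not 0 < keep_fraction <= 1:
            raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
        n_keep = max(1, int(round(keep_fraction * data.n_genes)))
        # stable sort: among tied variances the earlier gene wins
        order = np.argsort(-variances.to_numpy(), kind="stable")[:n_keep]
        kept_mask = np.zeros(data.n_genes, dtype=bool)
        kept_mask[order] = True
        threshold = float(variances.iloc[order].min())
    else:
        if min_variance < 0:
            raise ValueError(f"min_variance must be >= 0, got {min_variance}")
        kept_mask = (variances >= min_variance).to_numpy()
        threshold = float(min_variance)
    kept = [g for g, keep in zip(data.gene_ids, kept_mask) if keep]
    dropped = [g for g, keep in zip(data.gene_ids, kept_mask) if not keep]
    if not kept:
        raise ValueError("variance filter dropped every gene; lower the threshold")
    report = FilterReport(kept, dropped, variances, threshold)
    return data.subset_genes(kept), report


@dataclass
class SampleClustering:
    """Average-linkage merge tree over samples in correlation distance."""

    linkage: np.ndarray
    sample_ids: list[str]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree at k clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({walk(left)}:{ld:.6g},{walk(right)}:{rd:.6g})"

        return walk(tree) + ";"


def sample_dendrogram(data: ExpressionDataset) -> SampleClustering:
    """Cluster samples by 1 - Pearson correlation, average linkage."""
    if data.n_samples < 3:
        raise ValueError("sample clustering needs at least 3 samples")
    values = data.values.to_numpy()
    sds = values.std(axis=0)
    constant = [s for s, sd in zip(data.sample_ids, sds) if sd == 0]
    if constant:
        raise ValueError(
            f"constant samples have undefined correlation: {constant}"
        )
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return SampleClustering(linkage, data.sample_ids)
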