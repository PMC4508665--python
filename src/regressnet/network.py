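"""Weighted gene coexpression network construction and module detection.

The pipeline follows the standard WGCNA recipe: a soft-thresholding power is
chosen by the scale-free topology criterion, pairwise Pearson correlations are
raised to that power to form the adjacency, the topological overlap matrix
(TOM) credits shared neighbourhoods, and average-linkage clustering of
1 - TOM followed by a static height cut yields modules.  Each module is
summarized by its eigengene (first principal component of the standardized
module submatrix), close modules are merged by eigengene correlation, and
per-gene connectivity (kTotal, kWithin) identifies hub candidates.

Dense matrix algebra throughout; TOM is O(n^3), so gene counts are capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ExpressionDataset

logger = logging.getLogger("regressnet")

MAX_GENES = 20000


@dataclass
class NetworkParams:
    """Tuning parameters of network construction.

    ``power`` left as None triggers automatic selection over
    ``candidate_powers`` using the scale-free fit threshold ``rsq_target``.
    """

    power: float | None = None
    network_type: str = "signed"
    candidate_powers: tuple = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 30
    cut_height_quantile: float = 0.8
    merge_cut_height: float = 0.25
    pam_stage: bool = True

    def __post_init__(self) -> None:
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"network_type must be unsigned or signed, got {self.network_type!r}")
        if self.power is not None and self.power < 1:
            raise ValueError(f"power must be >= 1, got {self.power}")
        if not 0 < self.cut_height_quantile <= 1:
            raise ValueError("cut_height_quantile must be in (0, 1]")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")


@dataclass
class CoexpressionResult:
    """Outputs of the network stage."""

    power: float
    power_diagnostics: pd.DataFrame
    module_of_gene: pd.Series
    module_eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: pd.Series
    k_total: pd.Series
    k_within: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in set(self.module_of_gene) if m != 0)

    def genes_in_module(self, module: int) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])


def _correlation(data: ExpressionDataset) -> np.ndarray:
    values = data.values.to_numpy()
    if values.shape[0] > MAX_GENES:
        raise ValueError(
            f"{values.shape[0]} genes exceeds the dense-network cap of {MAX_GENES}; "
            "filter more aggressively"
        )
    sds = values.std(axis=1)
    constant = [g for g, sd in zip(data.gene_ids, sds) if sd == 0]
    if constant:
        raise ValueError(f"constant genes have undefined correlation: {constant[:5]}")
    corr = np.corrcoef(values)
    return np.clip(corr, -1.0, 1.0)


def _adjacency_from_corr(corr: np.ndarray, power: float, network_type: str) -> np.ndarray:
    if network_type == "signed":
        adj = ((1.0 + corr) / 2.0) ** power
    else:
        adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def adjacency(data: ExpressionDataset, power: float, network_type: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta."""
    corr = _correlation(data)
    adj = _adjacency_from_corr(corr, power, network_type)
    return pd.DataFrame(adj, index=data.gene_ids, columns=data.gene_ids)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree distribution fit, plus the slope."""
    if np.allclose(k, k[0]):
        raise ValueError("degenerate network: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        freqs.append(mask.mean())
        means.append(k[mask].mean())
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs))
    if len(x) < 2 or np.allclose(x, x[0]):
        raise ValueError("degenerate degree distribution; cannot assess scale-free fit")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rsq = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return rsq * (-np.sign(slope)), float(slope)


def pick_soft_threshold(
    data: ExpressionDataset, params: NetworkParams | None = None
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-thresholding power by scale-free topology fit.

    For each candidate power the per-gene connectivity distribution is binned
    (10 bins), log10 frequency is regressed on log10 mean connectivity, and
    the fit R^2 is signed by the negated slope sign.  The smallest power
    reaching ``rsq_target`` wins; if none does, the power maximizing the
    signed R^2 is returned.
    """
    params = params or NetworkParams()
    if data.n_samples < 4:
        raise ValueError("soft-threshold selection needs at least 4 samples")
    corr = _correlation(data)
    rows = []
    for beta in params.candidate_powers:
        adj = _adjacency_from_corr(corr, beta, params.network_type)
        k = adj.sum(axis=0) - 1.0
        signed_rsq, slope = _scale_free_fit(k)
        rows.append(
            {"power": beta, "signed_rsq": signed_rsq, "slope": slope, "mean_k": k.mean()}
        )
    diag = pd.DataFrame(rows)
    passing = diag[diag["signed_rsq"] >= params.rsq_target]
    if len(passing):
        chosen = float(passing["power"].iloc[0])
    else:
        chosen = float(diag.loc[diag["signed_rsq"].idxmax(), "power"])
    return chosen, diag


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + A_ij) / (min(k_i,k_j) + 1 - A_ij).

    l_ij sums A_iu * A_uj over shared neighbours u; k_i is the connectivity
    of gene i.  Entries lie in [0, 1] with unit diagonal; 1 - TOM is the
    module-detection dissimilarity.
    """
    is_frame = isinstance(adj, pd.DataFrame)
    a = adj.to_numpy() if is_frame else np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    # l_ij = (A^2)_ij - 2 A_ij because the diagonal is 1
    l = a @ a - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    # the diagonal divides by k_i (0 for an isolated gene); it is overwritten
    np.fill_diagonal(denom, 1.0)
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame, params: NetworkParams | None = None
) -> pd.Series:
    """Cluster 1 - TOM (average linkage) and cut at a static height.

    The cut height is the ``cut_height_quantile`` of the merge heights;
    clusters smaller than ``min_module_size`` fall back to module 0
    (unassigned).  With ``pam_stage`` enabled (default), each unassigned
    gene is then attached to the module with the smallest average
    dissimilarity, provided that distance stays below the cut height — the
    same refinement dynamic tree cutting applies after its core detection.
    Surviving modules are labelled 1..M by decreasing size, ties broken by
    the position of each module's first gene.
    """
    params = params or NetworkParams()
    gene_ids = list(tom.index)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    linkage = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = linkage[:, 2]
    cut_height = float(np.quantile(heights, params.cut_height_quantile))
    raw = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    labels = _relabel_by_size(raw, gene_ids, params.min_module_size)
    if params.pam_stage:
        arr = labels.to_numpy()
        modules = sorted(set(arr) - {0})
        unassigned = np.where(arr == 0)[0]
        if modules and len(unassigned):
            mod_dist = np.stack([diss[:, arr == m].mean(axis=1) for m in modules])
            nearest = mod_dist[:, unassigned].argmin(axis=0)
            nearest_dist = mod_dist[:, unassigned].min(axis=0)
            for pos, g in enumerate(unassigned):
                if nearest_dist[pos] < cut_height:
                    arr[g] = modules[nearest[pos]]
            labels = _relabel_by_size(arr, gene_ids, 1)
    return labels


def _relabel_by_size(raw_labels: np.ndarray, gene_ids: list[str], min_size: int) -> pd.Series:
    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, lab in enumerate(raw_labels):
        if lab == 0:  # already unassigned
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first_pos.setdefault(lab, pos)
    keepers = [lab for lab, n in sizes.items() if n >= min_size]
    if not keepers:
        logger.warning("no cluster reached min_module_size; all genes unassigned")
    keepers.sort(key=lambda lab: (-sizes[lab], first_pos[lab]))
    mapping = {lab: i + 1 for i, lab in enumerate(keepers)}
    labels = np.array([mapping.get(lab, 0) for lab in raw_labels])
    return pd.Series(labels, index=gene_ids, name="module")


def module_eigengenes(
    data: ExpressionDataset, module_of_gene: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each standardized module submatrix.

    Genes are standardized to mean 0 / sd 1 across samples; the eigengene is
    the first right-singular vector (unit norm over samples), sign-oriented so
    that its correlation with the module's mean standardized profile is
    non-negative.  Also returns the fraction of variance explained.
    """
    eigengenes, varexp = {}, {}
    for m in sorted(set(module_of_gene) - {0}):
        genes = list(module_of_gene.index[module_of_gene == m])
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        x = data.values.loc[genes].to_numpy()
        sds = x.std(axis=1, ddof=1)
        if (sds == 0).any():
            bad = [g for g, sd in zip(genes, sds) if sd == 0]
            raise ValueError(f"module {m} contains constant genes: {bad[:5]}")
        z = (x - x.mean(axis=1, keepdims=True)) / sds[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eigengenes[f"M{m}"] = e
        varexp[f"M{m}"] = float(s[0] ** 2 / (s**2).sum())
    me = pd.DataFrame(eigengenes, index=data.sample_ids).T
    return me, pd.Series(varexp, name="variance_explained")


def merge_close_modules(
    data: ExpressionDataset, module_of_gene: pd.Series, merge_cut_height: float = 0.25
) -> pd.Series:
    """Iteratively merge modules whose eigengene dissimilarity is below the cut.

    Dissimilarity is 1 - correlation of eigengenes; the closest pair merges
    first and eigengenes are recomputed after each merge.  Final labels are
    reassigned 1..M by decreasing size.
    """
    labels = module_of_gene.copy()
    while True:
        ids = sorted(set(labels) - {0})
        if len(ids) < 2:
            break
        me, _ = module_eigengenes(data, labels)
        e = me.to_numpy()
        corr = np.corrcoef(e)
        best, best_diss = None, merge_cut_height
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                diss = 1.0 - corr[i, j]
                if diss < best_diss:
                    best, best_diss = (ids[i], ids[j]), diss
        if best is None:
            break
        keep, absorb = best
        labels[labels == absorb] = keep
    return _relabel_by_size(labels.to_numpy(), list(labels.index), 1)


def intramodular_connectivity(
    adj: pd.DataFrame, module_of_gene: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """kTotal (whole-network) and kWithin (own-module) connectivity per gene."""
    genes = list(adj.index)
    a = adj.to_numpy()
    k_total = a.sum(axis=0) - 1.0
    labels = module_of_gene.loc[genes].to_numpy()
    k_within = np.zeros(len(genes))
    for m in set(labels):
        if m == 0:
            continue
        mask = labels == m
        sub = a[np.ix_(mask, mask)]
        k_within[mask] = sub.sum(axis=0) - 1.0
    return (
        pd.Series(k_total, index=genes, name="kTotal"),
        pd.Series(k_within, index=genes, name="kWithin"),
    )


def build_network(
    data: ExpressionDataset, params: NetworkParams | None = None
) -> CoexpressionResult:
    """Full network stage: power selection through connectivity."""
    params = params or NetworkParams()
    if params.power is None:
        power, diag = pick_soft_threshold(data, params)
    else:
        power, diag = float(params.power), pd.DataFrame()
    adj = adjacency(data, power, params.network_type)
    tom = tom_similarity(adj)
    modules = detect_modules(tom, params)
    if (modules != 0).any() and params.merge_cut_height > 0:
        modules = merge_close_modules(data, modules, params.merge_cut_height)
    if (modules != 0).any():
        me, varexp = module_eigengenes(data, modules)
    else:
        me = pd.DataFrame(columns=data.sample_ids)
        varexp = pd.Series(dtype=float)
    k_total, k_within = intramodular_connectivity(adj, modules)
    return CoexpressionResult(
        power=power,
        power_diagnostics=diag,
        module_of_gene=modules,
        module_eigengenes=me,
        variance_explained=varexp,
        k_total=k_total,
        k_within=k_within,
    )
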