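"""Hub-gene prioritization within response-associated modules.

Two independent strategies, mirroring the dual analysis that can surface the
same gene from both expression data and prior knowledge:

1. coexpression ranking — a gene must sit in the upper-right corner of the
   (differential expression, intramodular connectivity) plane, scored by the
   minimum of its within-module percentile ranks on |t| and kWithin;
2. prior-knowledge degree — nodes of the interaction graph ranked by how many
   distinct module genes they connect to (direction ignored).

The consensus intersects the top-k of both rankings.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import PriorKnowledgeGraph
from .differential import DifferentialResult
from .network import CoexpressionResult

logger = logging.getLogger("regressnet")


def rank_hubs_wgcna(
    coexpr: CoexpressionResult,
    diff: DifferentialResult,
    module_id: int,
    combine: str = "min",
) -> pd.DataFrame:
    """Rank module genes by joint extremity in kWithin and |moderated t|.

    Percentile ranks (average method, scaled to (0, 1]) are computed within
    the module for both axes and combined by ``min`` (default: a hub must be
    extreme on BOTH axes) or ``product``.  Ties in the final ordering break
    by kWithin, then gene id.
    """
    genes = coexpr.genes_in_module(module_id)
    if not genes:
        raise ValueError(f"unknown or empty module: {module_id}")
    if combine not in ("min", "product"):
        raise ValueError(f"combine must be 'min' or 'product', got {combine!r}")
    kw = coexpr.k_within.loc[genes]
    abs_t = diff.table.loc[genes, "t_mod"].abs()
    n = len(genes)
    pct_k = kw.rank(method="average") / n
    pct_t = abs_t.rank(method="average") / n
    if combine == "min":
        score = pd.concat([pct_k, pct_t], axis=1).min(axis=1)
    else:
        score = pct_k * pct_t
    out = pd.DataFrame(
        {
            "gene": genes,
            "kWithin": kw.to_numpy(),
            "abs_t": abs_t.to_numpy(),
            "pct_kWithin": pct_k.to_numpy(),
            "pct_abs_t": pct_t.to_numpy(),
            "wgcna_score": score.to_numpy(),
        }
    )
    out = out.sort_values(
        by=["wgcna_score", "kWithin", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["wgcna_rank"] = range(1, len(out) + 1)
    return out


def rank_hubs_degree(graph: PriorKnowledgeGraph, module_genes) -> pd.DataFrame:
    """Rank nodes by the number of distinct module genes they connect to.

    The induced neighbourhood covers the module genes plus any regulator
    touching them; edge direction is ignored for counting, and a node never
    counts itself.  Nodes connected to no module gene are excluded.
    """
    module_set = set(module_genes)
    neighbours: dict[str, set[str]] = {}
    for row in graph.edges.itertuples(index=False):
        if row.target in module_set and row.source != row.target:
            neighbours.setdefault(row.source, set()).add(row.target)
        if row.source in module_set and row.target != row.source:
            neighbours.setdefault(row.target, set()).add(row.source)
    rows = [
        {"gene": node, "prior_degree": len(hits)}
        for node, hits in neighbours.items()
        if hits
    ]
    if not rows:
        logger.warning("no graph edges touch the module; degree ranking is empty")
        return pd.DataFrame(columns=["gene", "prior_degree", "degree_rank"])
    out = pd.DataFrame(rows).sort_values(
        by=["prior_degree", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    out["degree_rank"] = range(1, len(out) + 1)
    return out


def consensus_hubs(
    wgcna: pd.DataFrame, degree: pd.DataFrame, k: int = 10
) -> pd.DataFrame:
    """Genes in the top-k of both rankings, ordered by summed rank."""
    top_w = wgcna[wgcna["wgcna_rank"] <= k].set_index("gene")
    top_d = degree[degree["degree_rank"] <= k].set_index("gene")
    common = [g for g in top_w.index if g in top_d.index]
    out = pd.DataFrame(
        {
            "gene": common,
            "wgcna_rank": [int(top_w.loc[g, "wgcna_rank"]) for g in common],
            "degree_rank": [int(top_d.loc[g, "degree_rank"]) for g in common],
        }
    )
    out["rank_sum"] = out["wgcna_rank"] + out["degree_rank"]
    out = out.sort_values(by=["rank_sum", "gene"]).reset_index(drop=True)
    out["consensus_rank"] = range(1, len(out) + 1)
    return out
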