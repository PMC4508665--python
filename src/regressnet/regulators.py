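"""Upstream-regulator analysis over a signed prior-knowledge graph.

Each regulator is scored two ways against the differentially expressed
response-module genes:

* overlap p-value — right-tail hypergeometric enrichment of its known
  targets among the DE genes, within the universe of genes present in both
  the expression data and the graph;
* activation z-score — directional consistency between the observed up/down
  changes and the changes the regulator's edge signs predict under an
  "activated" state: z = sum(w_i x_i) / sqrt(sum(w_i^2)) with x_i = +1 for a
  consistent target (activating edge & target up, or inhibiting edge & target
  down) and -1 otherwise.

|z| >= the threshold (default 2) predicts an activated or inhibited state.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PriorKnowledgeGraph
from .differential import DifferentialResult, bh_adjust

logger = logging.getLogger("regressnet")


def overlap_pvalue(targets, de_genes, universe) -> float:
    """Right-tail hypergeometric P(X >= k) for target/DE-set overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets, de = set(targets), set(de_genes)
    stray = (targets | de) - universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)[:5]}")
    k = len(targets & de)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(targets), len(de)))


def activation_zscore(
    edges: dict[str, int],
    observed_direction: dict[str, int],
    weights: dict[str, float] | None = None,
) -> float | None:
    """Directional-consistency z over targets with an observed direction.

    ``edges`` maps target -> edge sign (+1 activating, -1 inhibiting);
    ``observed_direction`` maps gene -> observed sign.  Targets without an
    observed direction are excluded; with none left the state is
    undetermined and None is returned.
    """
    num, denom = 0.0, 0.0
    for target, sign in edges.items():
        direction = observed_direction.get(target)
        if direction is None or direction == 0:
            continue
        w = 1.0 if weights is None else weights.get(target, 1.0)
        x = 1.0 if sign * direction > 0 else -1.0
        num += w * x
        denom += w * w
    if denom == 0:
        logger.warning("no scorable targets; activation state undetermined")
        return None
    return num / math.sqrt(denom)


def regulator_table(
    graph: PriorKnowledgeGraph,
    diff: DifferentialResult,
    module_of_gene: pd.Series,
    response_modules,
    alpha: float = 0.05,
    z_threshold: float = 2.0,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Score every regulator with >= 1 target in the universe.

    The universe is the intersection of the expression genes and the graph
    nodes.  The DE set is the response-module genes at q < alpha; observed
    directions are the signs of their moderated t.  Returns a table sorted by
    overlap p (ties by regulator id) with BH-adjusted q and the predicted
    activation state.
    """
    response_modules = set(response_modules)
    expr_genes = set(diff.table.index)
    universe = expr_genes & graph.nodes
    if not universe:
        raise ValueError("no overlap between expression genes and graph nodes")
    labels = module_of_gene
    de_genes = {
        g
        for g in universe
        if labels.get(g) in response_modules and diff.table.loc[g, "q"] < alpha
    }
    observed = {g: int(np.sign(diff.table.loc[g, "t_mod"])) for g in de_genes}

    weight_of: dict[tuple[str, str], float] = {}
    if use_weights and "weight" in graph.edges.columns:
        weight_of = {
            (r.source, r.target): float(r.weight)
            for r in graph.edges.itertuples(index=False)
        }

    rows = []
    for reg in graph.regulators:
        edge_signs = graph.targets_of(reg)
        targets_in_universe = {t: s for t, s in edge_signs.items() if t in universe}
        if not targets_in_universe:
            continue
        p = overlap_pvalue(targets_in_universe, de_genes, universe)
        weights = {t: weight_of.get((reg, t), 1.0) for t in targets_in_universe}
        if any(t in observed for t in targets_in_universe):
            z = activation_zscore(
                targets_in_universe, observed, weights if weight_of else None
            )
        else:
            z = None  # no DE target carries a direction: expected for decoys
        if z is None:
            state = "undetermined"
        elif z >= z_threshold:
            state = "activated"
        elif z <= -z_threshold:
            state = "inhibited"
        else:
            state = "undetermined"
        rows.append(
            {
                "regulator": reg,
                "n_targets_in_universe": len(targets_in_universe),
                "n_overlap": len(set(targets_in_universe) & de_genes),
                "overlap_p": p,
                "activation_z": np.nan if z is None else z,
                "predicted_state": state,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["overlap_q"] = bh_adjust(out["overlap_p"].to_numpy())
        out = out.sort_values(by=["overlap_p", "regulator"]).reset_index(drop=True)
    return out
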