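"""Connectivity-map style drug-signature matching.

A query signature (up/down probe tag sets, built from the response-module
genes and mapped into the human probe space through the ortholog table) is
scored against each drug instance of a rank database with the two-sided
Kolmogorov-Smirnov enrichment statistic.  Instance scores are scaled to
[-1, 1], aggregated per drug, and ranked; permutation over random tag sets
gives an empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .datatypes import DrugSignatureDB, OrthologMap
from .differential import DifferentialResult

logger = logging.getLogger("regressnet")


@dataclass
class QuerySignature:
    """Up/down probe tag sets with provenance of the selection rule."""

    up_tags: list[str]
    down_tags: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.up_tags or not self.down_tags:
            raise ValueError("both tag sets must be nonempty; loosen the selection rule")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValueError(f"tags in both sets: {sorted(overlap)[:5]}")


@dataclass
class ConnectivityResult:
    """Per-instance KS scores and per-drug aggregated connectivity."""

    instance_table: pd.DataFrame  # instance, drug, ks_up, ks_down, s, c
    drug_table: pd.DataFrame  # drug, mean_c, rank[, perm_p]
    polarity: str = "mimic"


def build_query_signature(
    diff: DifferentialResult,
    module_of_gene: pd.Series,
    response_modules,
    ortholog_map: OrthologMap,
    rule: tuple[str, float] = ("fdr", 0.05),
    min_tags: int = 10,
    max_tags: int = 500,
) -> QuerySignature:
    """Select response-module genes, split by t sign, expand to probe tags.

    ``rule`` is ``("fdr", alpha)`` (genes with q < alpha) or ``("top", n)``
    (top n by |t| per direction).  A gene with k ortholog probes contributes
    k tags.  If one probe is reachable from both directions (multi-mapped
    orthologs), it goes to the side whose gene has the larger |t|.
    """
    response_modules = list(response_modules)
    genes = [g for g in diff.table.index if module_of_gene.get(g) in response_modules]
    sub = diff.table.loc[genes]
    kind, value = rule
    if kind == "fdr":
        up_genes = sub.index[(sub["q"] < value) & (sub["t_mod"] > 0)]
        down_genes = sub.index[(sub["q"] < value) & (sub["t_mod"] < 0)]
    elif kind == "top":
        n = int(value)
        up = sub[sub["t_mod"] > 0].sort_values("t_mod", ascending=False)
        down = sub[sub["t_mod"] < 0].sort_values("t_mod")
        up_genes, down_genes = up.index[:n], down.index[:n]
    else:
        raise ValueError(f"unknown selection rule {kind!r}; use 'fdr' or 'top'")

    claim: dict[str, tuple[int, float]] = {}  # probe -> (direction, |t|)
    unmapped = 0
    collisions = 0
    for direction, gene_list in ((1, up_genes), (-1, down_genes)):
        for g in gene_list:
            probes = ortholog_map.probes_for(g)
            if not probes:
                unmapped += 1
                continue
            t_abs = abs(diff.table.loc[g, "t_mod"])
            for p in probes:
                if p in claim:
                    if claim[p][0] != direction:
                        collisions += 1
                        if t_abs > claim[p][1]:
                            claim[p] = (direction, t_abs)
                else:
                    claim[p] = (direction, t_abs)
    if collisions:
        logger.info("%d probe direction collisions resolved by larger |t|", collisions)
    up_tags = [p for p, (d, _) in claim.items() if d == 1]
    down_tags = [p for p, (d, _) in claim.items() if d == -1]
    for name, tags in (("up", up_tags), ("down", down_tags)):
        if len(tags) > max_tags:
            raise ValueError(f"{name} tag set exceeds {max_tags} probes; tighten the rule")
        if len(tags) < min_tags:
            raise ValueError(f"{name} tag set below {min_tags} probes; loosen the rule")
    return QuerySignature(
        sorted(up_tags),
        sorted(down_tags),
        provenance={
            "modules": response_modules,
            "rule": list(rule),
            "n_unmapped_genes": unmapped,
            "n_collisions": collisions,
        },
    )


def ks_statistic(tags, ranked_instance: pd.Series, n_probes: int | None = None) -> float:
    """Two-sided KS enrichment of a tag set within one ranked instance.

    With sorted tag ranks V(1) < ... < V(t) in a list of n probes,
    a = max_j [j/t - V(j)/n] and b = max_j [V(j)/n - (j-1)/t]; the score is
    a if a > b, else -b.  Positive scores mean the tags sit near the top
    (most up-regulated end) of the instance.
    """
    n = int(n_probes) if n_probes is not None else len(ranked_instance)
    missing = [t for t in tags if t not in ranked_instance.index]
    if missing:
        raise ValueError(f"tags not in the probe universe: {missing[:10]}")
    v = np.sort(ranked_instance.loc[list(tags)].to_numpy(dtype=float))
    t = len(v)
    if t == 0:
        raise ValueError("empty tag set")
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def _ks_matrix(tag_ranks: np.ndarray, n: int) -> np.ndarray:
    """Vectorized KS over columns; tag_ranks is (t, n_instances)."""
    v = np.sort(tag_ranks, axis=0).astype(float)
    t = v.shape[0]
    j = np.arange(1, t + 1)[:, None]
    a = (j / t - v / n).max(axis=0)
    b = (v / n - (j - 1) / t).max(axis=0)
    return np.where(a > b, a, -b)


def instance_connectivity(sig: QuerySignature, db: DrugSignatureDB) -> pd.DataFrame:
    """KS scores and raw connectivity s for every instance.

    s = ks_up - ks_down when the two scores have opposite signs, else 0
    (a drug must push the up-tags and down-tags apart to count).
    """
    ranks = db.ranks
    for tags in (sig.up_tags, sig.down_tags):
        missing = [t for t in tags if t not in ranks.index]
        if missing:
            raise ValueError(f"tags not in the database probe universe: {missing[:10]}")
    n = ranks.shape[0]
    ks_up = _ks_matrix(ranks.loc[sig.up_tags].to_numpy(), n)
    ks_down = _ks_matrix(ranks.loc[sig.down_tags].to_numpy(), n)
    s = np.where(ks_up * ks_down > 0, 0.0, ks_up - ks_down)
    return pd.DataFrame(
        {
            "instance": db.instance_ids,
            "drug": db.drug_of_instance.to_numpy(),
            "ks_up": ks_up,
            "ks_down": ks_down,
            "s": s,
        }
    )


def scale_and_aggregate(
    instance_scores: pd.DataFrame,
    polarity: str = "mimic",
) -> ConnectivityResult:
    """Scale raw scores to connectivity c in [-1, 1] and aggregate per drug.

    Positive raw scores are divided by the maximum s, negative by |min s|.
    A drug's score is the mean c of its instances.  ``polarity`` controls the
    ranking direction: ``mimic`` puts the most positively connected drugs
    (those reproducing the query signature) first, ``reverse`` the most
    negatively connected (signature reversers).
    """
    if polarity not in ("mimic", "reverse"):
        raise ValueError(f"polarity must be 'mimic' or 'reverse', got {polarity!r}")
    if len(instance_scores) == 0:
        raise ValueError("no instances to aggregate")
    s = instance_scores["s"].to_numpy(dtype=float)
    if np.all(s == 0):
        logger.warning("all raw connectivity scores are zero")
        c = np.zeros_like(s)
    else:
        smax, smin = s.max(), s.min()
        c = np.zeros_like(s)
        if smax > 0:
            c[s > 0] = s[s > 0] / smax
        if smin < 0:
            c[s < 0] = s[s < 0] / abs(smin)
    inst = instance_scores.assign(c=c)
    drug = (
        inst.groupby("drug", sort=False)["c"]
        .mean()
        .rename("mean_c")
        .reset_index()
    )
    ascending = polarity == "reverse"
    drug = drug.sort_values(by=["mean_c", "drug"], ascending=[ascending, True]).reset_index(
        drop=True
    )
    drug["rank"] = range(1, len(drug) + 1)
    return ConnectivityResult(instance_table=inst, drug_table=drug, polarity=polarity)


def permutation_pvalue(
    sig: QuerySignature,
    db: DrugSignatureDB,
    drug: str,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for one drug's mean raw connectivity score.

    B random up/down tag-set pairs of matching sizes are drawn uniformly from
    the probe universe and scored against the drug's instances;
    p = (1 + #{|score_perm| >= |score_obs|}) / (B + 1).  The test statistic
    is the drug's mean UNCLAMPED KS difference ks_up - ks_down rather than
    the reported connectivity c, for two reasons: the scaling to c divides
    every instance by the database-wide extreme, coupling a drug's score to
    unrelated instances, and the same-sign clamp puts an atom at zero; both
    would distort the permutation null away from uniformity.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 permutations, got {B}")
    inst = instance_connectivity(sig, db)
    drug_mask = (inst["drug"] == drug).to_numpy()
    if not drug_mask.any():
        raise ValueError(f"unknown drug: {drug}")
    observed = float((inst.loc[drug_mask, "ks_up"] - inst.loc[drug_mask, "ks_down"]).mean())

    rng = np.random.default_rng(seed)
    ranks = db.ranks.to_numpy()[:, drug_mask]
    n = ranks.shape[0]
    n_up, n_down = len(sig.up_tags), len(sig.down_tags)
    hits = 0
    for _ in range(B):
        pick = rng.choice(n, size=n_up + n_down, replace=False)
        ks_up = _ks_matrix(ranks[pick[:n_up]], n)
        ks_down = _ks_matrix(ranks[pick[n_up:]], n)
        if abs(float((ks_up - ks_down).mean())) >= abs(observed):
            hits += 1
    return (1 + hits) / (B + 1)
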