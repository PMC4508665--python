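"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on four kinds of input: a log2 expression matrix with
sample group labels, a signed directed prior-knowledge graph, a drug-signature
database of per-instance probe rankings, and a mouse-gene to human-probe
ortholog map.  Each container validates its own invariants on construction so
that downstream stages can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("responder", "nonresponder", "untreated")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes x samples) with sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Must be complete (no missing values).
    groups
        Series mapping sample id -> group label, one of
        ``responder``, ``nonresponder``, ``untreated``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing values in genes: {bad[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group annotation: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        unknown = sorted(set(self.groups) - set(VALID_GROUPS))
        if unknown:
            raise ValidationError(
                f"unknown group labels {unknown}; valid labels are {VALID_GROUPS}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_genes(self, genes) -> "ExpressionDataset":
        """Return a dataset restricted to ``genes``, preserving their order."""
        return ExpressionDataset(self.values.loc[list(genes)], self.groups.copy())


@dataclass
class PriorKnowledgeGraph:
    """Signed directed regulator->target edge list.

    ``edges`` has columns ``source``, ``target``, ``sign`` (+1 activating,
    -1 inhibiting) and optionally ``weight``.  Self-loops are rejected;
    duplicate (source, target) pairs are collapsed, with conflicting signs
    treated as an error.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"source", "target", "sign"}
        if not required.issubset(self.edges.columns):
            raise ValidationError(f"edge table must have columns {sorted(required)}")
        if "weight" not in self.edges.columns:
            self.edges = self.edges.assign(weight=1.0)
        loops = self.edges[self.edges["source"] == self.edges["target"]]
        if len(loops):
            raise ValidationError(f"self-loops not allowed: {loops['source'].tolist()[:5]}")
        bad_sign = self.edges[~self.edges["sign"].isin([1, -1])]
        if len(bad_sign):
            raise ValidationError("edge signs must be +1 or -1")
        grouped = self.edges.groupby(["source", "target"], sort=False)["sign"].nunique()
        conflicts = grouped[grouped > 1]
        if len(conflicts):
            raise ValidationError(f"conflicting signs for edges: {list(conflicts.index)[:5]}")
        self.edges = self.edges.drop_duplicates(subset=["source", "target"]).reset_index(
            drop=True
        )

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])

    @property
    def regulators(self) -> list[str]:
        """Nodes with at least one outgoing edge, in first-seen order."""
        return list(dict.fromkeys(self.edges["source"]))

    def targets_of(self, regulator: str) -> dict[str, int]:
        """Map target -> edge sign for one regulator."""
        sub = self.edges[self.edges["source"] == regulator]
        return dict(zip(sub["target"], sub["sign"]))


@dataclass
class DrugSignatureDB:
    """Probe x instance rank matrix plus an instance -> drug assignment.

    Each column of ``ranks`` must be a permutation of 1..n_probes
    (rank 1 = most up-regulated probe in that instance).
    """

    ranks: pd.DataFrame
    drug_of_instance: pd.Series

    def __post_init__(self) -> None:
        n = self.ranks.shape[0]
        expected = np.arange(1, n + 1)
        arr = self.ranks.to_numpy()
        for j, inst in enumerate(self.ranks.columns):
            col = np.sort(arr[:, j])
            if not np.array_equal(col, expected):
                raise ValidationError(
                    f"instance {inst!r}: rank column is not a permutation of 1..{n}"
                )
        missing = [i for i in self.ranks.columns if i not in self.drug_of_instance.index]
        if missing:
            raise ValidationError(f"instances without drug assignment: {missing[:5]}")
        self.drug_of_instance = self.drug_of_instance.loc[self.ranks.columns]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def instance_ids(self) -> list[str]:
        return list(self.ranks.columns)

    @property
    def drugs(self) -> list[str]:
        return list(dict.fromkeys(self.drug_of_instance))


@dataclass
class OrthologMap:
    """Mouse gene -> human probe pairs (one gene may map to several probes)."""

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mouse_gene", "human_probe"}
        if not required.issubset(self.pairs.columns):
            raise ValidationError(f"ortholog table must have columns {sorted(required)}")
        if self.pairs.duplicated(subset=["mouse_gene", "human_probe"]).any():
            raise ValidationError("duplicate (mouse_gene, human_probe) pairs")
        self._by_gene: dict[str, list[str]] = {}
        for g, p in zip(self.pairs["mouse_gene"], self.pairs["human_probe"]):
            self._by_gene.setdefault(g, []).append(p)

    def probes_for(self, gene: str) -> list[str]:
        return list(self._by_gene.get(gene, []))

    @property
    def mapped_genes(self) -> set[str]:
        return set(self._by_gene)

    @property
    def probes(self) -> set[str]:
        return set(self.pairs["human_probe"])


@dataclass
class FilterReport:
    """Outcome of the noisy-gene variance filter."""

    kept_genes: list[str]
    dropped_genes: list[str]
    statistic: pd.Series = field(repr=False)
    threshold: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        kept = set(self.kept_genes)
        return pd.DataFrame(
            {
                "gene": self.statistic.index,
                "variance": self.statistic.to_numpy(),
                "kept": [g in kept for g in self.statistic.index],
            }
        )
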