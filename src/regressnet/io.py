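"""Readers and writers for every text format the pipeline touches.

Formats: expression TSV or GCT, sample annotation TSV, SIF edge lists,
rank-matrix TSV with an instance table, ortholog TSV, GMT gene sets, and
YAML/JSON run configuration.  All outputs are UTF-8, tab-separated, with
deterministic column order; readers preserve the row/column order of the file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import (
    DrugSignatureDB,
    ExpressionDataset,
    OrthologMap,
    PriorKnowledgeGraph,
    ValidationError,
)

logger = logging.getLogger("regressnet")

SIF_RELATIONS = {"activates": 1, "inhibits": -1}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(levelname)s %(name)s: %(message)s"
    )
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# expression


def read_expression(path, annotation_path) -> ExpressionDataset:
    """Read an expression matrix (TSV or GCT) plus its annotation table.

    The TSV layout is: header row of sample ids, first column gene ids.
    GCT files carry a two-line header (``#1.2`` then dimensions) and a
    ``Description`` column, both of which are ignored beyond validation.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        values = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if values.columns[0].lower() == "description":
            values = values.drop(columns=values.columns[0])
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    groups = read_annotation(annotation_path)
    try:
        return ExpressionDataset(values, groups)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_annotation(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if list(tab.columns[:2]) != ["sample_id", "group"]:
        raise ParseError(f"{path}: expected columns sample_id, group")
    return pd.Series(tab["group"].to_numpy(), index=tab["sample_id"], name="group")


def write_expression(data: ExpressionDataset, path, annotation_path) -> None:
    data.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    pd.DataFrame({"sample_id": data.sample_ids, "group": data.groups.to_numpy()}).to_csv(
        annotation_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SIF edge list


def read_edge_list(path) -> PriorKnowledgeGraph:
    """Parse a SIF file: ``source <tab> relation <tab> target [<tab> weight]``.

    The relation vocabulary is restricted to ``activates`` / ``inhibits``;
    anything else is an error rather than a guessed sign.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ParseError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
            src, rel, tgt = parts[:3]
            if rel not in SIF_RELATIONS:
                raise ParseError(
                    f"{path}:{lineno}: unknown relation {rel!r}; "
                    f"expected one of {sorted(SIF_RELATIONS)}"
                )
            weight = float(parts[3]) if len(parts) == 4 else 1.0
            rows.append((src, tgt, SIF_RELATIONS[rel], weight))
    edges = pd.DataFrame(rows, columns=["source", "target", "sign", "weight"])
    try:
        return PriorKnowledgeGraph(edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_edge_list(graph: PriorKnowledgeGraph, path) -> None:
    inv = {1: "activates", -1: "inhibits"}
    with open(path, "w", encoding="utf-8") as fh:
        for row in graph.edges.itertuples(index=False):
            fh.write(f"{row.source}\t{inv[row.sign]}\t{row.target}\t{row.weight:g}\n")


# ---------------------------------------------------------------------------
# drug-signature database


def read_rank_matrix(path, instance_table) -> DrugSignatureDB:
    ranks = pd.read_csv(path, sep="\t", index_col=0)
    ranks.index = ranks.index.astype(str)
    ranks.index.name = None
    ranks.columns.name = None
    inst = pd.read_csv(instance_table, sep="\t", dtype=str)
    if list(inst.columns[:2]) != ["instance_id", "drug_name"]:
        raise ParseError(f"{instance_table}: expected columns instance_id, drug_name")
    drug_of_instance = pd.Series(
        inst["drug_name"].to_numpy(), index=inst["instance_id"], name="drug_name"
    )
    try:
        return DrugSignatureDB(ranks.astype(int), drug_of_instance)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_rank_matrix(db: DrugSignatureDB, path, instance_table) -> None:
    db.ranks.to_csv(path, sep="\t", index_label="probe_id")
    pd.DataFrame(
        {"instance_id": db.instance_ids, "drug_name": db.drug_of_instance.to_numpy()}
    ).to_csv(instance_table, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog table


def read_ortholog_table(path) -> OrthologMap:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if list(tab.columns[:2]) != ["mouse_gene", "human_probe"]:
        raise ParseError(f"{path}: expected columns mouse_gene, human_probe")
    try:
        return OrthologMap(tab)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ortholog_table(omap: OrthologMap, path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# run configuration


CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    # (type, default); None default means "derive at run time"
    "n_genes": (int, 2000),
    "n_modules": (int, 5),
    "module_size": (int, 100),
    "n_responder": (int, 10),
    "n_nonresponder": (int, 10),
    "n_untreated": (int, 10),
    "up_effect": (float, 2.0),
    "down_effect": (float, -2.0),
    "noise_sd": (float, 1.0),
    "hub_loading": (float, 1.0),
    "n_drugs": (int, 100),
    "n_reversers": (int, 3),
    "instances_per_drug": (int, 2),
    "n_probes": (int, 5000),
    "keep_fraction": (float, 0.5),
    "power": (object, None),
    "network_type": (str, "signed"),
    "min_module_size": (int, 30),
    "cut_height_quantile": (float, 0.8),
    "merge_cut_height": (float, 0.25),
    "alpha_module": (float, 0.001),
    "alpha_signature": (float, 0.05),
    "alpha_regulator": (float, 0.05),
    "z_threshold": (float, 2.0),
    "top_k_hubs": (int, 10),
    "polarity": (str, "mimic"),
    "permutations": (int, 0),
    "seed": (int, 0),
}

_RANGE_CHECKS = {
    "keep_fraction": lambda v: 0 < v <= 1,
    "cut_height_quantile": lambda v: 0 < v <= 1,
    "merge_cut_height": lambda v: 0 <= v <= 1,
    "noise_sd": lambda v: v >= 0,
    "power": lambda v: v is None or v >= 1,
    "network_type": lambda v: v in ("unsigned", "signed"),
    "polarity": lambda v: v in ("mimic", "reverse"),
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON run configuration, filling defaults.

    Unknown keys and out-of-range values are rejected with an error listing
    the offending keys.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ParseError(f"unknown configuration keys: {unknown}")
    config = {k: default for k, (_, default) in CONFIG_SCHEMA.items()}
    for k, v in raw.items():
        typ, _ = CONFIG_SCHEMA[k]
        if typ in (int, float) and v is not None:
            v = typ(v)
        config[k] = v
    bad = [
        k for k, check in _RANGE_CHECKS.items() if k in config and not check(config[k])
    ]
    for k in ("n_genes", "n_modules", "module_size", "n_drugs", "n_probes",
              "instances_per_drug", "min_module_size"):
        if config[k] <= 0:
            bad.append(k)
    if bad:
        raise ParseError(f"configuration values out of range: {sorted(set(bad))}")
    return config
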