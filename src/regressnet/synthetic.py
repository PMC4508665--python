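"""Synthetic data with known planted structure.

Emulates the design of a 30-array two-flank tumour study: three groups of ten
samples (responders, non-responders, untreated controls), a few thousand
genes, and a handful of coexpressed modules.  Two modules carry opposite
responder-vs-nonresponder shifts — an up-shifted "immune-like" module and a
down-shifted "cancer-like" module — each with a designated maximal-loading hub
gene.  Companion generators plant matching structure in a prior-knowledge
graph (one strongly wired regulator per response module among decoys), a
drug-signature database (a few drugs whose instances reverse the responder
signature among random decoys), and a mouse-to-human ortholog map.

The generative model is a latent factor model: each module m has a latent
eigengene score e_mj ~ Normal(mu_mg, 1) per sample j in group g, where the
responder and non-responder means differ by the module's effect delta_m and
the untreated mean is 0.  Gene i of module m is x_ij = beta_i * e_mj + eps_ij
with loadings beta_i in ``loading_range`` (the hub gets ``hub_loading``) and
eps ~ Normal(0, noise_sd^2).  Background genes are pure Normal(0, 1) noise.
Because a module eigengene is itself a first principal component, recovery of
the planted scores by the network stage is analytically expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DrugSignatureDB,
    ExpressionDataset,
    OrthologMap,
    PriorKnowledgeGraph,
)
from . import io as rio


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    ``response_effects`` gives the responder-minus-nonresponder eigengene
    mean shift per module; by default the first module is shifted +2
    (up in responders), the second -2, and the rest are null.
    """

    n_genes: int = 2000
    n_modules: int = 5
    module_size: int = 100
    groups: dict[str, int] = field(
        default_factory=lambda: {"responder": 10, "nonresponder": 10, "untreated": 10}
    )
    response_effects: dict[int, float] = field(default_factory=lambda: {1: 2.0, 2: -2.0})
    treatment_effect: float = 0.0
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 1.0
    hub_loading: float = 1.0
    n_drugs: int = 100
    n_reversers: int = 3
    instances_per_drug: int = 2
    n_probes: int = 5000
    rank_noise_sd: float = 100.0
    regulator_connect_fraction: float = 0.6
    n_decoy_regulators: int = 20
    ortholog_multi_fraction: float = 0.1
    ortholog_unmapped_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_drugs": self.n_drugs,
            "instances_per_drug": self.instances_per_drug,
            "n_probes": self.n_probes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise SimulationConfigError(f"{name} must be positive, got {value}")
        if self.n_modules * self.module_size > self.n_genes:
            raise SimulationConfigError(
                "n_modules * module_size exceeds n_genes "
                f"({self.n_modules} * {self.module_size} > {self.n_genes})"
            )
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise SimulationConfigError(
                f"loading_range must lie in (0, 1], got {self.loading_range}"
            )
        if self.hub_loading < hi:
            raise SimulationConfigError(
                "hub_loading must be at least the upper bound of loading_range"
            )
        if self.noise_sd < 0:
            raise SimulationConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_reversers < 0 or self.n_reversers > self.n_drugs:
            raise SimulationConfigError("n_reversers must be in [0, n_drugs]")
        if not (0 <= self.regulator_connect_fraction <= 1):
            raise SimulationConfigError("regulator_connect_fraction must be in [0, 1]")
        bad_modules = [m for m in self.response_effects if not 1 <= m <= self.n_modules]
        if bad_modules:
            raise SimulationConfigError(
                f"response_effects refers to unknown modules: {bad_modules}"
            )
        for name, frac in (
            ("ortholog_multi_fraction", self.ortholog_multi_fraction),
            ("ortholog_unmapped_fraction", self.ortholog_unmapped_fraction),
        ):
            if not 0 <= frac <= 1:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {frac}")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside each simulated dataset."""

    module_of_gene: dict[str, int]
    hub_of_module: dict[int, str]
    response_module_ids: dict[int, int]  # module id -> sign of its shift
    eigengene_scores: pd.DataFrame  # true e_m, modules x samples
    reverser_drugs: set[str] = field(default_factory=set)
    regulator_truth: dict[str, dict] = field(default_factory=dict)

    def genes_in_module(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]

    def signature_direction(self) -> dict[str, int]:
        """True responder-vs-nonresponder direction of each response-module gene."""
        out = {}
        for m, sign in self.response_module_ids.items():
            for g in self.genes_in_module(m):
                out[g] = sign
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so adding one does not shift another
    return np.random.default_rng([config.seed, stream])


def generate_expression(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the expression matrix and return it with its ground truth."""
    config.validate()
    rng = _rng(config, 1)

    sample_ids, labels = [], []
    prefix = {"responder": "RS", "nonresponder": "NR", "untreated": "UT"}
    for group, count in config.groups.items():
        for i in range(count):
            sample_ids.append(f"{prefix.get(group, group[:2].upper())}{i + 1:02d}")
            labels.append(group)
    n_samples = len(sample_ids)
    groups = pd.Series(labels, index=sample_ids, name="group")

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    module_of_gene: dict[str, int] = {g: 0 for g in gene_ids}
    hub_of_module: dict[int, str] = {}
    values = rng.standard_normal((config.n_genes, n_samples))

    eig = np.zeros((config.n_modules, n_samples))
    for m in range(1, config.n_modules + 1):
        delta = config.response_effects.get(m, 0.0)
        mu = np.zeros(n_samples)
        for j, g in enumerate(labels):
            if g == "responder":
                mu[j] = config.treatment_effect + delta / 2.0
            elif g == "nonresponder":
                mu[j] = config.treatment_effect - delta / 2.0
        eig[m - 1] = mu + rng.standard_normal(n_samples)

        start = (m - 1) * config.module_size
        genes = gene_ids[start : start + config.module_size]
        lo, hi = config.loading_range
        betas = rng.uniform(lo, hi, size=len(genes))
        betas[0] = config.hub_loading  # first gene of each module is its hub
        hub_of_module[m] = genes[0]
        for g, beta in zip(genes, betas):
            module_of_gene[g] = m
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))
        values[start : start + config.module_size] = (
            betas[:, None] * eig[m - 1][None, :] + noise
        )

    data = ExpressionDataset(pd.DataFrame(values, index=gene_ids, columns=sample_ids), groups)
    truth = GroundTruth(
        module_of_gene=module_of_gene,
        hub_of_module=hub_of_module,
        response_module_ids={
            m: int(np.sign(d)) for m, d in config.response_effects.items() if d != 0
        },
        eigengene_scores=pd.DataFrame(
            eig, index=[f"M{m}" for m in range(1, config.n_modules + 1)], columns=sample_ids
        ),
    )
    return data, truth


def generate_prior_graph(truth: GroundTruth, config: SimulationConfig) -> PriorKnowledgeGraph:
    """Plant one strongly wired regulator per response module among decoys.

    The planted regulator of module m is connected to
    ``regulator_connect_fraction`` of that module's genes with edge signs
    matching the module's shift direction, so that under an "activated" state
    it predicts the observed expression changes.  Decoy regulators have the
    same out-degree but hit random genes with random signs.
    """
    config.validate()
    rng = _rng(config, 2)
    all_genes = list(truth.module_of_gene)
    rows: list[tuple[str, str, int]] = []
    planted_degrees: list[int] = []

    for m, sign in sorted(truth.response_module_ids.items()):
        reg = f"REG_M{m}"
        genes = truth.genes_in_module(m)
        k = int(round(config.regulator_connect_fraction * len(genes)))
        chosen = [genes[i] for i in sorted(rng.choice(len(genes), size=k, replace=False))]
        for g in chosen:
            rows.append((reg, g, sign))
        planted_degrees.append(k)
        truth.regulator_truth[reg] = {
            "targets": chosen,
            "signs": [sign] * k,
            "state": "activated",
            "module": m,
        }

    fallback_degree = int(round(config.regulator_connect_fraction * config.module_size))
    for i in range(config.n_decoy_regulators):
        reg = f"DECOY_R{i + 1:02d}"
        k = int(rng.choice(planted_degrees)) if planted_degrees else fallback_degree
        chosen = [
            all_genes[j] for j in sorted(rng.choice(len(all_genes), size=k, replace=False))
        ]
        signs = rng.choice([1, -1], size=k)
        rows.extend((reg, g, int(s)) for g, s in zip(chosen, signs))

    edges = pd.DataFrame(rows, columns=["source", "target", "sign"])
    return PriorKnowledgeGraph(edges)


def generate_ortholog_map(genes, config: SimulationConfig) -> OrthologMap:
    """Map mouse genes onto a human probe universe.

    Each gene is unmapped with probability ``ortholog_unmapped_fraction``;
    mapped genes get one probe, plus a second with probability
    ``ortholog_multi_fraction``.  Probes are never shared between genes, so a
    zero multi-map fraction yields a bijection onto a subset of probes.
    """
    genes = list(genes)
    if not genes:
        raise SimulationConfigError("gene list must be nonempty")
    config.validate()
    rng = _rng(config, 3)
    probes = probe_universe(config)
    order = rng.permutation(len(probes))
    rows = []
    cursor = 0
    for g in genes:
        if rng.random() < config.ortholog_unmapped_fraction:
            continue
        n_probes = 2 if rng.random() < config.ortholog_multi_fraction else 1
        for _ in range(n_probes):
            if cursor >= len(probes):
                raise SimulationConfigError(
                    "probe universe too small for the requested ortholog map"
                )
            rows.append((g, probes[order[cursor]]))
            cursor += 1
    return OrthologMap(pd.DataFrame(rows, columns=["mouse_gene", "human_probe"]))


def probe_universe(config: SimulationConfig) -> list[str]:
    width = max(5, len(str(config.n_probes)))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_probes)]


def generate_drug_database(
    truth: GroundTruth,
    diff_direction: dict[str, int],
    ortholog_map: OrthologMap,
    config: SimulationConfig,
) -> DrugSignatureDB:
    """Build a rank-matrix drug database with planted signature reversers.

    ``diff_direction`` maps each signature gene to its responder-vs-
    nonresponder sign.  In a reverser instance the human probes of
    responder-up genes are placed near the bottom of the ranking and the
    probes of responder-down genes near the top, with Gaussian jitter of
    ``rank_noise_sd`` positions before re-ranking; decoy instances are
    uniform random permutations.
    """
    config.validate()
    rng = _rng(config, 4)
    probes = probe_universe(config)
    probe_pos = {p: i for i, p in enumerate(probes)}

    missing = sorted(p for p in ortholog_map.probes if p not in probe_pos)
    if missing:
        raise ValueError(
            f"ortholog map references probes outside the universe: {missing[:10]}"
        )

    up_probes, down_probes = [], []
    for gene, sign in diff_direction.items():
        for p in ortholog_map.probes_for(gene):
            (up_probes if sign > 0 else down_probes).append(p)
    up_probes = list(dict.fromkeys(up_probes))
    down_probes = list(dict.fromkeys(down_probes))

    n = config.n_probes
    n_up, n_down = len(up_probes), len(down_probes)
    drug_names = [f"DRUG_{i + 1:03d}" for i in range(config.n_drugs)]
    truth.reverser_drugs = set(drug_names[: config.n_reversers])

    columns: dict[str, np.ndarray] = {}
    drug_of_instance = {}
    for d, drug in enumerate(drug_names):
        is_reverser = d < config.n_reversers
        for k in range(config.instances_per_drug):
            inst = f"{drug}_i{k + 1}"
            drug_of_instance[inst] = drug
            if is_reverser:
                key = np.empty(n)
                middle = rng.uniform(n_down, n - n_up, size=n)
                key[:] = middle
                for j, p in enumerate(down_probes):
                    key[probe_pos[p]] = j + config.rank_noise_sd * rng.standard_normal()
                for j, p in enumerate(up_probes):
                    key[probe_pos[p]] = (
                        n - n_up + j + config.rank_noise_sd * rng.standard_normal()
                    )
                order = np.argsort(key, kind="stable")
            else:
                order = rng.permutation(n)
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            columns[inst] = ranks

    ranks = pd.DataFrame(columns, index=probes)
    return DrugSignatureDB(ranks, pd.Series(drug_of_instance, name="drug_name"))


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator and return all artifacts keyed by name."""
    data, truth = generate_expression(config)
    graph = generate_prior_graph(truth, config)
    orthologs = generate_ortholog_map(list(truth.module_of_gene), config)
    db = generate_drug_database(truth, truth.signature_direction(), orthologs, config)
    return {
        "expression": data,
        "truth": truth,
        "graph": graph,
        "orthologs": orthologs,
        "drug_db": db,
    }


def write_dataset(artifacts: dict, out_dir) -> dict[str, str]:
    """Write every simulated artifact as text files; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "edges": out / "prior_graph.sif",
        "ranks": out / "drug_ranks.tsv",
        "instances": out / "drug_instances.tsv",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "ground_truth.json",
    }
    rio.write_expression(artifacts["expression"], paths["expression"], paths["annotation"])
    rio.write_edge_list(artifacts["graph"], paths["edges"])
    rio.write_rank_matrix(artifacts["drug_db"], paths["ranks"], paths["instances"])
    rio.write_ortholog_table(artifacts["orthologs"], paths["orthologs"])
    truth: GroundTruth = artifacts["truth"]
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "module_of_gene": truth.module_of_gene,
                "hub_of_module": {str(k): v for k, v in truth.hub_of_module.items()},
                "response_module_ids": {
                    str(k): v for k, v in truth.response_module_ids.items()
                },
                "reverser_drugs": sorted(truth.reverser_drugs),
                "regulator_truth": truth.regulator_truth,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return {k: str(v) for k, v in paths.items()}


def config_from_dict(config: dict) -> SimulationConfig:
    """Build a SimulationConfig from the flat run-configuration mapping."""
    return SimulationConfig(
        n_genes=config["n_genes"],
        n_modules=config["n_modules"],
        module_size=config["module_size"],
        groups={
            "responder": config["n_responder"],
            "nonresponder": config["n_nonresponder"],
            "untreated": config["n_untreated"],
        },
        response_effects={1: config["up_effect"], 2: config["down_effect"]},
        noise_sd=config["noise_sd"],
        hub_loading=config["hub_loading"],
        n_drugs=config["n_drugs"],
        n_reversers=config["n_reversers"],
        instances_per_drug=config["instances_per_drug"],
        n_probes=config["n_probes"],
        seed=config["seed"],
    )
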