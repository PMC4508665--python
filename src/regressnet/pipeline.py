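"""End-to-end orchestration with full provenance.

Stages run in the order of the analysis: simulate-or-load, variance filter,
sample clustering, coexpression network, differential response, module
association, hub ranking (both strategies plus consensus), connectivity-map
drug scoring, and upstream-regulator scoring.  Every artifact is written as a
deterministic text file and recorded in a run report with SHA-256 checksums,
so two runs from the same inputs and seed produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import cmap as cmap_mod
from . import differential, hubs, network, preprocess, regulators, synthetic
from . import io as rio
from .datatypes import DrugSignatureDB, ExpressionDataset, OrthologMap, PriorKnowledgeGraph

logger = logging.getLogger("regressnet")

FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are preserved."""


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages,
             "files": self.files},
            indent=1,
            sort_keys=True,
        )

    def to_text(self) -> str:
        lines = [f"regressnet run (seed={self.seed})", ""]
        for stage, summary in self.stages.items():
            lines.append(f"[{stage}]")
            for key, value in summary.items():
                lines.append(f"  {key}: {value}")
            lines.append("")
        return "\n".join(lines)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(report: RunReport, frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, **kwargs)
    report.files[path.name] = _checksum(path)


def run_all(
    config: dict,
    out_dir,
    simulate: bool = True,
    inputs: dict | None = None,
) -> RunReport:
    """Execute every stage; ``simulate`` generates inputs, else paths in
    ``inputs`` (expression, annotation, edges, ranks, instances, orthologs)
    are loaded."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report = RunReport(config=dict(config), seed=seed)

    stage = "simulate" if simulate else "load"
    try:
        if simulate:
            sim_config = synthetic.config_from_dict(config)
            artifacts = synthetic.simulate_all(sim_config)
            for name, path in synthetic.write_dataset(artifacts, out / "inputs").items():
                report.files[f"inputs/{Path(path).name}"] = _checksum(Path(path))
            data: ExpressionDataset = artifacts["expression"]
            graph: PriorKnowledgeGraph = artifacts["graph"]
            orthologs: OrthologMap = artifacts["orthologs"]
            drug_db: DrugSignatureDB = artifacts["drug_db"]
        else:
            required = ["expression", "annotation", "edges", "ranks", "instances", "orthologs"]
            missing = [k for k in required if not inputs or k not in inputs]
            if missing:
                raise StageError(f"stage 'load': missing input files: {missing}")
            data = rio.read_expression(inputs["expression"], inputs["annotation"])
            graph = rio.read_edge_list(inputs["edges"])
            drug_db = rio.read_rank_matrix(inputs["ranks"], inputs["instances"])
            orthologs = rio.read_ortholog_table(inputs["orthologs"])
        report.stages[stage] = {
            "n_genes": data.n_genes,
            "n_samples": data.n_samples,
        }

        stage = "filter"
        data_f, filt = preprocess.filter_noninformative(
            data, keep_fraction=config["keep_fraction"]
        )
        _write(report, filt.to_frame(), out / "filter_report.tsv", index=False)
        report.stages[stage] = {"kept": len(filt.kept_genes), "dropped": len(filt.dropped_genes)}

        stage = "cluster-samples"
        clust = preprocess.sample_dendrogram(data_f)
        (out / "sample_dendrogram.nwk").write_text(clust.to_newick(), encoding="utf-8")
        report.files["sample_dendrogram.nwk"] = _checksum(out / "sample_dendrogram.nwk")
        cut = clust.cut(3)
        report.stages[stage] = {"k3_sizes": sorted(cut.value_counts().tolist(), reverse=True)}

        stage = "network"
        params = network.NetworkParams(
            power=config["power"],
            network_type=config["network_type"],
            min_module_size=config["min_module_size"],
            cut_height_quantile=config["cut_height_quantile"],
            merge_cut_height=config["merge_cut_height"],
        )
        net = network.build_network(data_f, params)
        _write(report, net.module_of_gene.rename("module").to_frame(), out / "modules.tsv",
               index_label="gene")
        _write(report, net.module_eigengenes, out / "eigengenes.tsv", index_label="module")
        conn = pd.DataFrame({"kTotal": net.k_total, "kWithin": net.k_within})
        _write(report, conn, out / "connectivity.tsv", index_label="gene")
        if len(net.power_diagnostics):
            _write(report, net.power_diagnostics, out / "soft_threshold.tsv", index=False)
        rio.write_gmt(
            {f"module_{m}": net.genes_in_module(m) for m in net.module_ids},
            out / "modules.gmt",
        )
        report.files["modules.gmt"] = _checksum(out / "modules.gmt")
        sizes = {m: len(net.genes_in_module(m)) for m in net.module_ids}
        report.stages[stage] = {"power": net.power, "n_modules": len(sizes),
                                "module_sizes": sizes}

        stage = "diffexp"
        diff = differential.moderated_t_test(data_f)
        _write(report, diff.table, out / "differential.tsv", index_label="gene")
        assoc = differential.module_association(
            diff, net.module_of_gene, alpha=config["alpha_module"]
        )
        _write(report, assoc.table, out / "module_association.tsv")
        response_modules = [
            m for m in (assoc.top_up_module, assoc.top_down_module) if m is not None
        ]
        directions = {
            int(m): assoc.table.loc[m, "direction"] for m in response_modules
        }
        report.stages[stage] = {
            "d0": diff.d0,
            "s0_sq": diff.s0_sq,
            "response_modules": directions,
        }

        stage = "hubs"
        hub_summary = {}
        for m in response_modules:
            wg = hubs.rank_hubs_wgcna(net, diff, m)
            _write(report, wg, out / f"hubs_wgcna_module{m}.tsv", index=False)
            dg = hubs.rank_hubs_degree(graph, net.genes_in_module(m))
            _write(report, dg, out / f"hubs_degree_module{m}.tsv", index=False)
            cons = hubs.consensus_hubs(wg, dg, k=config["top_k_hubs"])
            _write(report, cons, out / f"hubs_consensus_module{m}.tsv", index=False)
            hub_summary[str(m)] = {
                "top_wgcna": wg["gene"].head(10).tolist(),
                "top_degree": dg["gene"].head(10).tolist(),
                "consensus": cons["gene"].tolist(),
            }
        report.stages[stage] = hub_summary

        stage = "cmap"
        try:
            sig = cmap_mod.build_query_signature(
                diff,
                net.module_of_gene,
                response_modules,
                orthologs,
                rule=("fdr", config["alpha_signature"]),
            )
        except ValueError:
            # too few significant genes in one direction: fall back to top-n
            logger.info("FDR rule gave too few tags; falling back to top-100 by |t|")
            sig = cmap_mod.build_query_signature(
                diff, net.module_of_gene, response_modules, orthologs, rule=("top", 100)
            )
        inst = cmap_mod.instance_connectivity(sig, drug_db)
        conn_result = cmap_mod.scale_and_aggregate(inst, polarity=config["polarity"])
        drug_table = conn_result.drug_table.copy()
        n_perm = int(config.get("permutations") or 0)
        if n_perm >= 100:
            drug_table["perm_p"] = [
                cmap_mod.permutation_pvalue(sig, drug_db, d, B=n_perm, seed=seed)
                for d in drug_table["drug"]
            ]
        _write(report, conn_result.instance_table, out / "cmap_instances.tsv", index=False)
        _write(report, drug_table, out / "cmap_drugs.tsv", index=False)
        report.stages[stage] = {
            "n_up_tags": len(sig.up_tags),
            "n_down_tags": len(sig.down_tags),
            "top_drugs": drug_table["drug"].head(10).tolist(),
        }

        stage = "regulators"
        reg = regulators.regulator_table(
            graph,
            diff,
            net.module_of_gene,
            response_modules,
            alpha=config["alpha_regulator"],
            z_threshold=config["z_threshold"],
        )
        _write(report, reg, out / "regulators.tsv", index=False)
        top = reg.head(5)
        report.stages[stage] = {
            "n_regulators": len(reg),
            "top_regulators": top["regulator"].tolist(),
            "top_states": top["predicted_state"].tolist(),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    (out / "report.txt").write_text(report.to_text(), encoding="utf-8")
    return report
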