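import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regressnet.synthetic import (
    GroundTruth,
    SimulationConfig,
    SimulationConfigError,
    generate_drug_database,
    generate_expression,
    generate_ortholog_map,
    generate_prior_graph,
    probe_universe,
    simulate_all,
    write_dataset,
)
from regressnet.network import module_eigengenes


class TestConfigValidation:
    def test_module_budget_exceeding_genes_names_field(self):
        cfg = SimulationConfig(n_genes=100, n_modules=5, module_size=50)
        with pytest.raises(SimulationConfigError, match="n_genes"):
            cfg.validate()

    def test_hub_loading_below_range_rejected(self):
        cfg = SimulationConfig(hub_loading=0.7, loading_range=(0.5, 0.9))
        with pytest.raises(SimulationConfigError, match="hub_loading"):
            cfg.validate()

    @pytest.mark.parametrize("field,value", [("n_genes", 0), ("noise_sd", -1.0)])
    def test_bad_scalars_rejected(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(SimulationConfigError, match=field):
            cfg.validate()


class TestGenerateExpression:
    def test_zero_noise_single_module_rows_equal_eigengene(self):
        cfg = SimulationConfig(
            n_genes=20, n_modules=1, module_size=10, noise_sd=0.0,
            loading_range=(1.0, 1.0), hub_loading=1.0, seed=3,
            response_effects={1: 2.0},
        )
        data, truth = generate_expression(cfg)
        e = truth.eigengene_scores.loc["M1"].to_numpy()
        for g in truth.genes_in_module(1):
            np.testing.assert_allclose(data.values.loc[g].to_numpy(), e, atol=1e-12)

    def test_same_seed_identical_different_seed_not(self):
        cfg1 = SimulationConfig(seed=1)
        a, _ = generate_expression(cfg1)
        b, _ = generate_expression(SimulationConfig(seed=1))
        c, _ = generate_expression(SimulationConfig(seed=2))
        pd.testing.assert_frame_equal(a.values, b.values)
        assert not a.values.equals(c.values)

    def test_null_effects_give_nonsignificant_eigengene_contrast(self, tiny_config):
        """With every module shift at 0, the responder/nonresponder contrast on
        the latent scores is null: a two-sample t at alpha=0.001 should almost
        never reject."""
        rejections = 0
        n_runs = 200
        for seed in range(n_runs):
            cfg = SimulationConfig(
                n_genes=60, n_modules=2, module_size=20, response_effects={}, seed=seed
            )
            data, truth = generate_expression(cfg)
            rs = data.samples_in_group("responder")
            nr = data.samples_in_group("nonresponder")
            for m in ("M1", "M2"):
                e = truth.eigengene_scores.loc[m]
                p = stats.ttest_ind(e[rs], e[nr]).pvalue
                if p < 0.001:
                    rejections += 1
        assert rejections / (2 * n_runs) <= 0.05

    def test_group_design_matches_study_layout(self, default_artifacts):
        data = default_artifacts["expression"]
        assert data.values.shape == (2000, 30)
        counts = data.groups.value_counts()
        assert counts["responder"] == counts["nonresponder"] == counts["untreated"] == 10

    def test_planted_eigengene_recovered_by_first_pc(self):
        """Each planted module's first principal component tracks the latent
        score at |r| >= 0.95 (median over seeds)."""
        cors = []
        for seed in range(20):
            data, truth = generate_expression(SimulationConfig(seed=seed))
            labels = pd.Series(truth.module_of_gene)
            me, _ = module_eigengenes(data, labels)
            for m in range(1, 6):
                r = np.corrcoef(me.loc[f"M{m}"], truth.eigengene_scores.loc[f"M{m}"])[0, 1]
                cors.append(abs(r))
        assert np.median(cors) >= 0.95


class TestGeneratePriorGraph:
    def test_planted_regulator_out_degree(self, default_artifacts):
        truth = default_artifacts["truth"]
        graph = default_artifacts["graph"]
        for m in truth.response_module_ids:
            targets = graph.targets_of(f"REG_M{m}")
            module_genes = set(truth.genes_in_module(m))
            assert len(targets) == 60  # 0.6 connect fraction x 100 genes
            assert set(targets) <= module_genes

    def test_planted_edge_signs_match_module_direction(self, default_artifacts):
        truth = default_artifacts["truth"]
        graph = default_artifacts["graph"]
        for m, sign in truth.response_module_ids.items():
            signs = set(graph.targets_of(f"REG_M{m}").values())
            assert signs == {sign}

    def test_decoy_overlap_matches_hypergeometric_expectation(self):
        """A decoy with degree d hits a 100-gene module d*100/2000 = 3 times on
        average (hypergeometric mean)."""
        overlaps = []
        for seed in range(30):
            cfg = SimulationConfig(seed=seed)
            data, truth = generate_expression(cfg)
            graph = generate_prior_graph(truth, cfg)
            module_genes = set(truth.genes_in_module(3))  # a null module
            for reg in graph.regulators:
                if reg.startswith("DECOY"):
                    overlaps.append(
                        len(set(graph.targets_of(reg)) & module_genes)
                    )
        assert abs(np.mean(overlaps) - 3.0) < 0.5

    def test_no_response_modules_gives_decoys_only(self):
        cfg = SimulationConfig(
            n_genes=60, n_modules=2, module_size=20, response_effects={}, seed=0
        )
        data, truth = generate_expression(cfg)
        graph = generate_prior_graph(truth, cfg)
        assert all(r.startswith("DECOY") for r in graph.regulators)


class TestGenerateOrthologMap:
    def test_zero_multimap_is_bijection_onto_probe_subset(self):
        cfg = SimulationConfig(ortholog_multi_fraction=0.0, seed=5)
        data, truth = generate_expression(cfg)
        omap = generate_ortholog_map(data.gene_ids, cfg)
        assert len(omap.pairs) == len(omap.mapped_genes) == 2000
        assert len(omap.probes) == 2000  # distinct probes, no sharing

    def test_unmapped_fraction_within_binomial_noise(self):
        cfg = SimulationConfig(ortholog_unmapped_fraction=0.1, seed=7)
        data, truth = generate_expression(cfg)
        omap = generate_ortholog_map(data.gene_ids, cfg)
        n_unmapped = 2000 - len(omap.mapped_genes)
        # 200 +- 4 sd, sd = sqrt(2000 * 0.1 * 0.9) ~ 13.4
        assert 146 <= n_unmapped <= 254

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=11)
        data, _ = generate_expression(cfg)
        a = generate_ortholog_map(data.gene_ids, cfg)
        b = generate_ortholog_map(data.gene_ids, cfg)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)


class TestGenerateDrugDatabase:
    def test_column_count_is_drugs_times_instances(self, default_artifacts):
        db = default_artifacts["drug_db"]
        assert db.ranks.shape[1] == 200  # 100 drugs x 2 instances

    def test_zero_noise_reverser_orders_up_below_down(self):
        cfg = SimulationConfig(
            n_genes=60, n_modules=2, module_size=20, n_drugs=3, n_reversers=1,
            n_probes=300, rank_noise_sd=0.0, seed=2,
        )
        data, truth = generate_expression(cfg)
        omap = generate_ortholog_map(data.gene_ids, cfg)
        direction = truth.signature_direction()
        db = generate_drug_database(truth, direction, omap, cfg)
        up = {p for g, s in direction.items() if s > 0 for p in omap.probes_for(g)}
        down = {p for g, s in direction.items() if s < 0 for p in omap.probes_for(g)}
        reverser = next(iter(truth.reverser_drugs))
        for inst in db.instance_ids:
            if db.drug_of_instance[inst] != reverser:
                continue
            col = db.ranks[inst]
            assert col.loc[list(up)].min() > col.loc[list(down)].max()

    def test_decoy_ranks_uncorrelated_with_signature(self):
        """Mean Spearman correlation between decoy tag ranks and the ideal
        reversal ordering stays within +-0.1 of zero."""
        cors = []
        for seed in range(100):
            cfg = SimulationConfig(
                n_genes=60, n_modules=2, module_size=20, n_drugs=2, n_reversers=1,
                n_probes=300, rank_noise_sd=0.0, seed=seed,
            )
            data, truth = generate_expression(cfg)
            omap = generate_ortholog_map(data.gene_ids, cfg)
            direction = truth.signature_direction()
            db = generate_drug_database(truth, direction, omap, cfg)
            tag_probes, ideal = [], []
            for g, s in direction.items():
                for p in omap.probes_for(g):
                    tag_probes.append(p)
                    ideal.append(s)
            decoy_inst = [
                i for i in db.instance_ids
                if db.drug_of_instance[i] not in truth.reverser_drugs
            ][0]
            cors.append(stats.spearmanr(db.ranks[decoy_inst].loc[tag_probes], ideal)[0])
        assert abs(np.mean(cors)) <= 0.1

    def test_missing_probe_errors_with_names(self):
        cfg = SimulationConfig(
            n_genes=60, n_modules=2, module_size=20, n_probes=300, seed=2
        )
        data, truth = generate_expression(cfg)
        pairs = pd.DataFrame({"mouse_gene": data.gene_ids[:1], "human_probe": ["BOGUS"]})
        from regressnet.datatypes import OrthologMap

        with pytest.raises(ValueError, match="BOGUS"):
            generate_drug_database(truth, truth.signature_direction(), OrthologMap(pairs), cfg)


class TestWriteDataset:
    def test_all_artifacts_written_and_loadable(self, tmp_path, tiny_config):
        from regressnet import io as rio

        artifacts = simulate_all(tiny_config)
        paths = write_dataset(artifacts, tmp_path)
        data = rio.read_expression(paths["expression"], paths["annotation"])
        assert data.n_genes == tiny_config.n_genes
        graph = rio.read_edge_list(paths["edges"])
        assert len(graph.nodes) > 0
        db = rio.read_rank_matrix(paths["ranks"], paths["instances"])
        assert db.ranks.shape[0] == tiny_config.n_probes
        omap = rio.read_ortholog_table(paths["orthologs"])
        assert len(omap.mapped_genes) > 0
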