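import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regressnet.datatypes import ExpressionDataset
from regressnet.network import (
    NetworkParams,
    _scale_free_fit,
    adjacency,
    detect_modules,
    intramodular_connectivity,
    merge_close_modules,
    module_eigengenes,
    pick_soft_threshold,
    tom_similarity,
)


def _dataset(values):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    groups = pd.Series(["responder"] * values.shape[1], index=frame.columns)
    return ExpressionDataset(frame, groups)


class TestAdjacency:
    def test_unsigned_hand_value(self):
        # construct y with cor(x, y) = exactly -0.8 from an orthogonal residual
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u = (x - x.mean()) / np.linalg.norm(x - x.mean())
        resid = np.array([1.0, -2.0, 0.0, 2.0, -1.0])
        resid = resid - resid.mean()
        resid = resid - (resid @ u) * u
        v = resid / np.linalg.norm(resid)
        y = -0.8 * u + 0.6 * v
        data = _dataset([x, y])
        adj = adjacency(data, power=6, network_type="unsigned")
        assert adj.iloc[0, 1] == pytest.approx(abs(-0.8) ** 6, abs=1e-12)

    def test_signed_perfect_anticorrelation_is_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        data = _dataset([x, -x])
        adj = adjacency(data, power=2, network_type="signed")
        assert adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_pairwise_pearson(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((4, 8))
        data = _dataset(values)
        adj = adjacency(data, power=3, network_type="unsigned").to_numpy()
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                r = np.corrcoef(values[i], values[j])[0, 1]
                assert adj[i, j] == pytest.approx(abs(r) ** 3, abs=1e-12)

    def test_constant_gene_rejected(self):
        data = _dataset([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="constant"):
            adjacency(data, power=2)

    def test_raising_power_never_increases_offdiagonal(self):
        rng = np.random.default_rng(1)
        data = _dataset(rng.standard_normal((6, 10)))
        low = adjacency(data, power=2).to_numpy()
        high = adjacency(data, power=5).to_numpy()
        off = ~np.eye(6, dtype=bool)
        assert np.all(high[off] <= low[off] + 1e-15)


class TestTom:
    def test_two_gene_full_adjacency(self):
        a = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        tom = tom_similarity(a)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.eye(3)
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.0)

    def test_three_gene_hand_evaluation(self):
        # all pairwise adjacency 0.5: l_12 = 0.25, k = 1.0, TOM = 0.75/1.5 = 0.5
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(tom[off], 0.5, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_adjacency_gives_valid_tom(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)


class TestSoftThreshold:
    def test_exact_power_law_fits_perfectly(self):
        # connectivities at 1,2,3,6 with counts 6,3,2,1: freq proportional to
        # 1/k exactly, so the log-log fit has R^2 = 1 and negative slope
        k = np.array([1.0] * 6 + [2.0] * 3 + [3.0] * 2 + [6.0] * 1)
        signed_rsq, slope = _scale_free_fit(k)
        assert signed_rsq == pytest.approx(1.0, abs=1e-10)
        assert slope == pytest.approx(-1.0, abs=1e-10)

    def test_zero_target_returns_smallest_candidate(self):
        rng = np.random.default_rng(0)
        data = _dataset(rng.standard_normal((40, 10)))
        params = NetworkParams(rsq_target=0.0, candidate_powers=(2, 4, 6))
        power, diag = pick_soft_threshold(data, params)
        first = diag.iloc[0]
        if first["slope"] < 0:
            assert power == 2

    def test_diagnostics_cover_all_candidates(self):
        rng = np.random.default_rng(3)
        data = _dataset(rng.standard_normal((30, 12)))
        power, diag = pick_soft_threshold(data, NetworkParams(candidate_powers=(1, 2, 3)))
        assert diag["power"].tolist() == [1, 2, 3]


class TestDetectModules:
    def _block_tom(self, sizes, within=0.9, between=0.05):
        n = sum(sizes)
        tom = np.full((n, n), between)
        start = 0
        for size in sizes:
            tom[start : start + size, start : start + size] = within
            start += size
        np.fill_diagonal(tom, 1.0)
        return pd.DataFrame(tom, index=[f"g{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(n)])

    def test_two_clean_blocks_found(self):
        tom = self._block_tom([5, 4])
        labels = detect_modules(tom, NetworkParams(min_module_size=3))
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]
        assert labels.iloc[0] == 1  # larger block gets label 1

    def test_min_size_above_n_gives_all_unassigned(self):
        tom = self._block_tom([5, 4])
        labels = detect_modules(tom, NetworkParams(min_module_size=100))
        assert (labels == 0).all()

    def test_gene_order_permutation_is_consistent(self):
        tom = self._block_tom([5, 4])
        labels = detect_modules(tom, NetworkParams(min_module_size=3))
        perm = np.random.default_rng(0).permutation(9)
        tom_p = tom.iloc[perm, perm]
        labels_p = detect_modules(tom_p, NetworkParams(min_module_size=3))
        # same partition after undoing the permutation
        for i in range(9):
            for j in range(9):
                same = labels.iloc[i] == labels.iloc[j]
                same_p = labels_p[tom.index[i]] == labels_p[tom.index[j]]
                assert same == same_p


class TestEigengenes:
    def test_identical_genes_full_variance_explained(self):
        profile = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        data = _dataset([profile, profile, profile])
        labels = pd.Series([1, 1, 1], index=data.gene_ids)
        me, varexp = module_eigengenes(data, labels)
        assert varexp["M1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(me.loc["M1"], z)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_flipping_all_genes_leaves_eigengene_unchanged(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((4, 6)) + np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.0])
        data_pos = _dataset(values)
        data_neg = _dataset(-values)
        labels = pd.Series([1] * 4, index=data_pos.gene_ids)
        me_pos, _ = module_eigengenes(data_pos, labels)
        me_neg, _ = module_eigengenes(data_neg, labels)
        r = np.corrcoef(me_pos.loc["M1"], me_neg.loc["M1"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_unit_norm(self, small_dataset):
        labels = pd.Series([1] * 4 + [2] * 4, index=small_dataset.gene_ids)
        me, _ = module_eigengenes(small_dataset, labels)
        norms = np.linalg.norm(me.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestMergeModules:
    def test_zero_cut_is_identity(self, small_dataset):
        labels = pd.Series([1] * 4 + [2] * 4, index=small_dataset.gene_ids)
        merged = merge_close_modules(small_dataset, labels, merge_cut_height=0.0)
        # partition unchanged (labels may be renumbered by size)
        assert (merged.iloc[:4].nunique(), merged.iloc[4:].nunique()) == (1, 1)
        assert merged.iloc[0] != merged.iloc[4]

    def test_split_halves_of_one_module_remerge(self):
        rng = np.random.default_rng(5)
        e = rng.standard_normal(12)
        values = np.array([b * e + 0.1 * rng.standard_normal(12) for b in
                           [0.9, 0.8, 1.0, 0.85, 0.95, 0.9]])
        data = _dataset(values)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=data.gene_ids)
        merged = merge_close_modules(data, labels, merge_cut_height=0.25)
        assert merged.nunique() == 1

    def test_single_module_passthrough(self, small_dataset):
        labels = pd.Series([1] * 8, index=small_dataset.gene_ids)
        merged = merge_close_modules(small_dataset, labels, merge_cut_height=0.25)
        assert (merged == 1).all()


class TestConnectivity:
    def test_three_gene_module_hand_value(self):
        a = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(a.values, 1.0)
        labels = pd.Series([1, 1, 1], index=list("abc"))
        k_total, k_within = intramodular_connectivity(a, labels)
        np.testing.assert_allclose(k_within.to_numpy(), 1.0)
        np.testing.assert_allclose(k_total.to_numpy(), 1.0)

    def test_unassigned_gene_has_zero_k_within(self):
        a = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        labels = pd.Series([0, 0], index=list("ab"))
        _, k_within = intramodular_connectivity(a, labels)
        assert (k_within == 0).all()

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(9)
        n = 10
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i}" for i in range(n)]
        adf = pd.DataFrame(a, index=genes, columns=genes)
        labels = pd.Series(rng.integers(1, 3, n), index=genes)
        k_total, k_within = intramodular_connectivity(adf, labels)
        for i in range(n):
            kt = sum(a[i, j] for j in range(n) if j != i)
            kw = sum(
                a[i, j] for j in range(n) if j != i and labels.iloc[j] == labels.iloc[i]
            )
            assert k_total.iloc[i] == pytest.approx(kt, abs=1e-12)
            assert k_within.iloc[i] == pytest.approx(kw, abs=1e-12)
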