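import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import triostage as ts
from triostage.core_io import UsageError
from triostage.network import _decode_pairs, _sample_pair_indices

from conftest import make_expression


def _expr_from_matrix(x: np.ndarray, genes=None):
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    fpkm = pd.DataFrame(
        x, index=pd.Index(genes, name="gene_id"),
        columns=[f"s{j}" for j in range(x.shape[1])],
    )
    return make_expression(fpkm)


def _full_correlations(expr):
    z = np.log2(expr.fpkm.to_numpy() + 1.0)
    return np.corrcoef(z)


class TestPairSampling:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(n=st.integers(2, 60))
    def test_decode_covers_all_pairs(self, n):
        total = n * (n - 1) // 2
        i, j = _decode_pairs(np.arange(total), n)
        got = set(zip(i.tolist(), j.tolist()))
        assert got == set(itertools.combinations(range(n), 2))

    def test_sampling_distinct_and_deterministic(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        a = _sample_pair_indices(10_000_000, 5_000, rng1)
        b = _sample_pair_indices(10_000_000, 5_000, rng2)
        assert len(set(a.tolist())) == len(a)
        assert np.array_equal(a, b)

    def test_sample_size_rule(self):
        assert ts.planned_sample_size(29_733, 0.01) == 4_420_108


class TestCorrelationThresholds:
    def test_single_pair_degenerate(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, size=(2, 10))
        expr = _expr_from_matrix(x)
        thr = ts.correlation_thresholds(expr, sample_fraction=1.0, seed=0)
        r = _full_correlations(expr)[0, 1]
        assert thr.lower == pytest.approx(r)
        assert thr.upper == pytest.approx(r)

    def test_full_sample_equals_brute_force_quantiles(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 50, size=(80, 12))
        expr = _expr_from_matrix(x)
        tail = 0.02
        thr = ts.correlation_thresholds(expr, sample_fraction=1.0, tail_fraction=tail, seed=0)
        r = _full_correlations(expr)
        vals = np.sort(r[np.triu_indices(80, k=1)])
        k = len(vals)
        assert thr.lower == pytest.approx(vals[int(np.ceil(tail * k)) - 1])
        assert thr.upper == pytest.approx(vals[int(np.ceil((1 - tail) * k)) - 1])

    def test_constant_gene_treated_as_zero(self, caplog):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 5, size=(5, 8))
        x[0] = 2.0  # constant gene
        expr = _expr_from_matrix(x)
        with caplog.at_level("WARNING", logger="triostage"):
            thr = ts.correlation_thresholds(expr, sample_fraction=1.0, tail_fraction=0.4, seed=0)
        assert "constant" in caplog.text

    def test_spearman_option(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=(30, 9))
        expr = _expr_from_matrix(x)
        thr = ts.correlation_thresholds(expr, sample_fraction=1.0, seed=0, method="spearman")
        assert -1 <= thr.lower <= thr.upper <= 1


class TestBuildNetwork:
    def _simple_graph(self, upper, lower=-2.0):
        # three genes: g0 ~ g1 perfectly, g2 independent-ish
        x = np.array(
            [[1, 2, 3, 4, 5, 6.0],
             [2, 4, 6, 8, 10, 12.0],
             [5, 1, 4, 2, 6, 3.0]]
        )
        expr = _expr_from_matrix(x)
        thr = ts.ThresholdPair(lower=lower, upper=upper, sample_size=3,
                               sample_fraction=1.0, tail_fraction=0.1)
        return expr, ts.build_network(expr, thr)

    def test_inclusive_upper_boundary(self):
        x = np.vstack([np.linspace(1, 6, 6), np.linspace(2, 12, 6)])
        expr = _expr_from_matrix(x)
        r = float(_full_correlations(expr)[0, 1])
        thr = ts.ThresholdPair(r, r, 1, 1.0, 0.1)
        g = ts.build_network(expr, thr)
        assert g.has_edge("g0", "g1")  # r == upper retained
        thr2 = ts.ThresholdPair(-2.0, r + 1e-9, 1, 1.0, 0.1)
        g2 = ts.build_network(expr, thr2)
        assert not g2.has_edge("g0", "g1")  # r just below upper dropped

    def test_edges_match_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 20, size=(200, 10))
        expr = _expr_from_matrix(x)
        thr = ts.correlation_thresholds(expr, sample_fraction=1.0, tail_fraction=0.01, seed=0)
        g = ts.build_network(expr, thr)
        r = _full_correlations(expr)
        expected = set()
        for i in range(200):
            for j in range(i + 1, 200):
                if r[i, j] >= thr.upper or r[i, j] <= thr.lower:
                    expected.add(frozenset((f"g{i}", f"g{j}")))
        got = set(map(frozenset, g.edges))
        assert got == expected

    def test_blockwise_equals_naive(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 20, size=(150, 8))
        expr = _expr_from_matrix(x)
        thr = ts.ThresholdPair(-0.8, 0.8, 1, 1.0, 0.1)
        g1 = ts.build_network(expr, thr, block_size=1000)
        g2 = ts.build_network(expr, thr, block_size=32)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))
        for u, v in g1.edges:
            assert g1.edges[u, v]["r"] == pytest.approx(g2.edges[u, v]["r"], abs=1e-10)

    def test_edge_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 20, size=(60, 8))
        expr = _expr_from_matrix(x)
        counts = []
        for upper in (0.5, 0.7, 0.9):
            thr = ts.ThresholdPair(-1.01, upper, 1, 1.0, 0.1)
            counts.append(ts.build_network(expr, thr).number_of_edges())
        assert counts[0] >= counts[1] >= counts[2]

    def test_no_self_loops_or_duplicates(self, expr, de_results):
        part = ts.venn_partition(de_results)
        thr = ts.ThresholdPair(-0.95, 0.95, 1, 1.0, 0.1)
        g = ts.build_network(expr, thr, partition=part)
        assert all(u != v for u, v in g.edges)


class TestSubclusters:
    def _module_expr(self, seed, n_module=20, n_bg=100, rho_noise=0.02):
        """Counts-level module: n_module genes are noisy copies of a driver."""
        rng = np.random.default_rng(seed)
        n_samples = 30
        driver = rng.uniform(2, 8, size=n_samples)
        x = rng.uniform(0, 10, size=(n_module + n_bg, n_samples))
        for i in range(n_module):
            x[i] = driver * np.exp(rng.normal(0, rho_noise, n_samples))
        return _expr_from_matrix(x)

    def test_planted_module_recovered_exactly(self):
        expr = self._module_expr(seed=0)
        thr = ts.ThresholdPair(-2.0, 0.95, 1, 1.0, 0.1)
        g = ts.build_network(expr, thr)
        clusters = ts.extract_subclusters(g, min_r=0.95)
        assert clusters, "no cluster found"
        assert clusters[0].size == 20
        assert set(clusters[0].genes) == {f"g{i}" for i in range(20)}

    def test_only_negative_edges_no_clusters(self):
        x = np.vstack([np.linspace(1, 6, 6), np.linspace(6, 1, 6)])
        expr = _expr_from_matrix(x)
        thr = ts.ThresholdPair(-0.9, 1.1, 1, 1.0, 0.1)
        g = ts.build_network(expr, thr)
        assert g.number_of_edges() == 1
        assert ts.extract_subclusters(g, min_r=0.95) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_disjoint_modules_never_merge(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_samples = 25
        d1, d2 = rng.uniform(2, 8, size=(2, n_samples))
        x = rng.uniform(0, 10, size=(30, n_samples))
        for i in range(10):
            x[i] = d1 * np.exp(rng.normal(0, 0.02, n_samples))
            x[10 + i] = d2 * np.exp(rng.normal(0, 0.02, n_samples))
        expr = _expr_from_matrix(x)
        thr = ts.ThresholdPair(-2.0, 0.95, 1, 1.0, 0.1)
        clusters = ts.extract_subclusters(ts.build_network(expr, thr), min_r=0.95)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [10, 10]


class TestAntisensePairs:
    def test_planted_pairs_recovered(self, expr, cohort, de_results):
        _, _, ann, truth = cohort
        part = ts.venn_partition(de_results)
        thr = ts.ThresholdPair(-2.0, 0.95, 1, 1.0, 0.1)
        g = ts.build_network(expr, thr, partition=part, annotation=ann)
        clusters = ts.extract_subclusters(g, min_r=0.95)
        out = ts.antisense_pairs(expr, ann, clusters)
        planted = truth.genes_of_class("antisense_pair")
        assert len(out) == len(planted)
        assert (out["r"] >= 0.95).mean() >= 0.9
        assert out["co_member"].mean() >= 0.9

    def test_unexpressed_partner_excluded(self, cohort):
        counts, sheet, ann, truth = cohort
        expr = ts.compute_fpkm(counts, ann)
        ts.filter_expressed(expr, sheet)
        partner = truth.df.loc[truth.genes_of_class("antisense_pair")[0], "antisense_partner"]
        expr.expressed.loc[partner] = False
        out = ts.antisense_pairs(expr, ann, [])
        assert partner not in set(out["sense_partner"])

    def test_independent_pair_not_co_member(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, size=(10, 20))
        genes = [f"g{i}" for i in range(10)]
        expr = _expr_from_matrix(x, genes)
        ann = ts.GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_name": genes,
                    "biotype": ["antisense"] + ["protein_coding"] * 9,
                    "chrom": "chr1",
                    "start": [100] * 2 + list(range(10_000, 10_008 * 80, 8_000))[:8],
                    "end": [600] * 2 + [i + 500 for i in range(10_000, 10_008 * 80, 8_000)][:8],
                    "strand": ["-"] + ["+"] * 9,
                    "exonic_length": 400,
                    "antisense_partner": ["g1"] + [None] * 9,
                },
                index=pd.Index(genes, name="gene_id"),
            )
        )
        out = ts.antisense_pairs(expr, ann, [])
        assert len(out) == 1
        assert abs(out["r"].iloc[0]) < 0.9
        assert not out["co_member"].iloc[0]
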