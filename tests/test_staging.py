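import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import triostage as ts
from triostage.core_io import UsageError

from conftest import fake_contrast


def log_gamma_hypergeom_tail(k, K, n, N) -> float:
    """Independent upper-tail hypergeometric: sum_{i>=k} C(K,i)C(N-K,n-i)/C(N,n)."""
    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    hi = min(K, n)
    terms = [
        log_comb(K, i) + log_comb(N - K, n - i) - log_comb(N, n)
        for i in range(k, hi + 1)
        if n - i <= N - K
    ]
    if not terms:
        return 0.0
    m = max(terms)
    return math.exp(m) * sum(math.exp(t - m) for t in terms)


class TestVennPartition:
    def _random_results(self, seed, n=500):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
        return {
            c: fake_contrast(c, pd.Series(rng.random(n) < 0.3, index=idx))
            for c in ("NvD", "DvT", "NvT")
        }

    def test_early_membership(self):
        idx = pd.Index(["g"], name="gene_id")
        res = {
            "NvD": fake_contrast("NvD", pd.Series([True], index=idx)),
            "DvT": fake_contrast("DvT", pd.Series([False], index=idx)),
            "NvT": fake_contrast("NvT", pd.Series([True], index=idx)),
        }
        part = ts.venn_partition(res)
        assert part.table.at["g", "membership"] == "NvD&NvT"
        assert part.table.at["g", "stage"] == "early"

    def test_nowhere_de_is_none(self):
        idx = pd.Index(["g"], name="gene_id")
        res = {c: fake_contrast(c, pd.Series([False], index=idx)) for c in ("NvD", "DvT", "NvT")}
        assert ts.venn_partition(res).table.at["g", "membership"] == "none"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_classes_disjoint_exhaustive(self, seed):
        res = self._random_results(seed)
        part = ts.venn_partition(res)
        assert part.counts.sum() == len(part.table)
        # the early-event identity: |NvD not DvT| = |NvD-only| + |NvD&NvT|
        flags = part.table
        lhs = int((flags["de_NvD"] & ~flags["de_DvT"]).sum())
        assert lhs == part.counts["NvD-only"] + part.counts["NvD&NvT"]
        # brute-force reassignment from the flags reproduces the partition
        for _, row in part.table.sample(50, random_state=0).iterrows():
            triple = (row["de_NvD"], row["de_DvT"], row["de_NvT"])
            recomputed = {
                (False, False, False): "none",
                (True, False, False): "NvD-only",
                (False, True, False): "DvT-only",
                (False, False, True): "NvT-only",
                (True, True, False): "NvD&DvT",
                (True, False, True): "NvD&NvT",
                (False, True, True): "DvT&NvT",
                (True, True, True): "all-three",
            }[triple]
            assert row["membership"] == recomputed

    def test_universe_mismatch_rejected(self):
        res = self._random_results(3)
        res["NvT"] = fake_contrast(
            "NvT", res["NvT"].table["de"].iloc[:-1]
        )
        with pytest.raises(UsageError):
            ts.venn_partition(res)


class TestTransientGenes:
    def _results_with_lfc(self, de, lfc1, lfc2):
        idx = pd.Index(list(de), name="gene_id")
        return {
            "NvD": fake_contrast("NvD", pd.Series([de[g][0] for g in de], index=idx),
                                 pd.Series(lfc1, index=idx)),
            "DvT": fake_contrast("DvT", pd.Series([de[g][1] for g in de], index=idx),
                                 pd.Series(lfc2, index=idx)),
            "NvT": fake_contrast("NvT", pd.Series([de[g][2] for g in de], index=idx)),
        }

    def test_opposite_signed_flagged(self):
        res = self._results_with_lfc(
            {"up_down": (True, True, False), "both_up": (True, True, False)},
            [2.0, 1.5], [-2.0, 1.5],
        )
        part = ts.venn_partition(res)
        out = ts.transient_genes(part, res)
        assert bool(out.at["up_down", "opposite"]) is True
        assert (out.at["up_down", "sign_NvD"], out.at["up_down", "sign_DvT"]) == (1, -1)
        assert bool(out.at["both_up", "opposite"]) is False  # listed, not flagged

    def test_empty_class_empty_list(self):
        res = self._results_with_lfc({"g": (True, False, False)}, [1.0], [0.0])
        out = ts.transient_genes(ts.venn_partition(res), res)
        assert len(out) == 0

    def test_planted_transient_recovered(self, de_results, cohort):
        truth = cohort[3]
        part = ts.venn_partition(de_results)
        out = ts.transient_genes(part, de_results)
        planted = truth.genes_of_class("transient_up_down")
        hits = out.index.intersection(planted)
        assert len(hits) >= 0.8 * len(planted)
        assert out.loc[hits, "opposite"].all()


class TestSetEnrichment:
    def test_extreme_case_closed_form(self):
        """All 10 set members in a 10-gene list from N=1000: p = 1/C(1000,10)."""
        bg = [f"g{i}" for i in range(1000)]
        members = bg[:10]
        gs = ts.GeneSet("S", "", members)
        res = ts.set_enrichment(members, gs, bg)
        assert res.p == pytest.approx(1.0 / math.comb(1000, 10), rel=1e-9)

    def test_empty_list_p_one(self):
        bg = [f"g{i}" for i in range(100)]
        res = ts.set_enrichment([], ts.GeneSet("S", "", bg[:5]), bg)
        assert res.p == 1.0

    def test_hox_style_table_matches_tail_summation(self):
        """k=7 of K=26 in n=601 from N=29733 equals the exact tail sum."""
        p = ts.hypergeom_enrichment_p(7, 26, 601, 29_733)
        oracle = log_gamma_hypergeom_tail(7, 26, 601, 29_733)
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_relabelling_outside_set_invariant(self):
        bg = [f"g{i}" for i in range(200)]
        gs = ts.GeneSet("S", "", bg[:20])
        lst = bg[:5] + bg[100:110]
        p1 = ts.set_enrichment(lst, gs, bg).p
        relabel = {g: (g if g in set(gs.members) | set(lst) else f"x_{g}") for g in bg}
        p2 = ts.set_enrichment(lst, gs, [relabel[g] for g in bg]).p
        assert p1 == p2

    def test_empty_restricted_set_rejected(self):
        with pytest.raises(UsageError):
            ts.set_enrichment(["a"], ts.GeneSet("S", "", ["zzz"]), ["a", "b"])

    def test_matches_fisher_exact(self):
        """One-sided hypergeometric equals Fisher's exact on the 2x2 table."""
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(9)
        for _ in range(50):
            N = int(rng.integers(50, 2000))
            K = int(rng.integers(1, N // 2))
            n = int(rng.integers(1, N // 2))
            k = int(rng.integers(0, min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            if min(min(row) for row in table) < 0:
                continue
            p_fisher = fisher_exact(table, alternative="greater")[1]
            assert ts.hypergeom_enrichment_p(k, K, n, N) == pytest.approx(p_fisher, rel=1e-9)


class TestCisWindowControl:
    def _annotation(self, positions, chrom="chrZ"):
        n = len(positions)
        return ts.GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_name": list(positions),
                    "biotype": ["protein_coding"] * n,
                    "chrom": [chrom] * n,
                    "start": [p[0] for p in positions.values()],
                    "end": [p[1] for p in positions.values()],
                    "strand": ["+"] * n,
                    "exonic_length": [min(1000, p[1] - p[0] + 1) for p in positions.values()],
                    "antisense_partner": [None] * n,
                },
                index=pd.Index(list(positions), name="gene_id"),
            )
        )

    def test_boundary_gene_included(self):
        """A gene starting exactly at cluster_end + 2 Mb is inside the window."""
        fam_start, fam_end = 5_000_000, 5_100_000
        ann = self._annotation(
            {
                "fam": (fam_start, fam_end),
                "edge": (fam_end + 2_000_000, fam_end + 2_000_500),
                "outside": (fam_end + 2_000_001, fam_end + 2_001_000),
            }
        )
        idx = pd.Index(["fam", "edge", "outside"], name="gene_id")
        res = {"NvD": fake_contrast("NvD", pd.Series([True, True, True], index=idx))}
        out = ts.cis_window_control("chrZ", fam_start, fam_end, ann, res, ["fam"])
        assert out["NvD"].n_window_genes == 1  # edge in, outside out, fam excluded

    def test_no_neighbours_not_evaluable(self):
        ann = self._annotation({"fam": (1_000_000, 1_001_000)})
        idx = pd.Index(["fam"], name="gene_id")
        res = {"NvD": fake_contrast("NvD", pd.Series([True], index=idx))}
        out = ts.cis_window_control("chrZ", 1_000_000, 1_001_000, ann, res, ["fam"])
        assert out["NvD"].evaluable is False

    def test_unknown_chromosome_rejected(self):
        ann = self._annotation({"fam": (1, 10)})
        with pytest.raises(UsageError):
            ts.cis_window_control("chrQ", 1, 10, ann, {}, ["fam"])

    def test_family_effect_does_not_leak_into_window(self):
        """Planted family-only effect: family enriched, +-2 Mb control quiet."""
        quiet = 0
        n_reps = 25
        for rep in range(n_reps):
            cfg = ts.SimulationConfig(
                seed=900 + rep, n_genes=1000,
                effect_fractions={"early_up": 0.02},
                infiltration={}, n_antisense=0, frac_unexpressed=0.0,
            )
            counts, sheet, ann, truth = ts.simulate_trios(cfg)
            expr = ts.compute_fpkm(counts, ann)
            ts.filter_expressed(expr, sheet)
            res = ts.paired_de(expr, sheet, "NvD")
            fam = truth.family_genes
            enr = ts.set_enrichment(
                res.de_genes, ts.GeneSet("FAM", "", fam.tolist()), expr.expressed_genes
            )
            assert enr.p < 1e-4
            coords = ann.df.loc[fam]
            ctrl = ts.cis_window_control(
                "chrC1", int(coords["start"].min()), int(coords["end"].max()),
                ann, {"NvD": res}, fam,
            )["NvD"]
            if ctrl.evaluable and ctrl.p_enrichment > 0.05 and ctrl.p_sign > 0.05:
                quiet += 1
        assert quiet >= 0.9 * n_reps
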