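"""Sweep calling: outlier quantiles, the combined criterion, gene overlap."""

import numpy as np
import pandas as pd
import pytest

from popsweep.popgen import Window
from popsweep.sweeps import (GeneModel, ScanConfig, combined_fst_pi,
                             empirical_outliers, gene_length, genes_in_bins,
                             pi_ratio, protein_length, read_gff3_genes, scan)


class TestPiRatio:
    def _stats(self, pi1, pi2):
        return pd.DataFrame({"pi_pop1": pi1, "pi_pop2": pi2})

    def test_equal_diversity(self):
        r = pi_ratio(self._stats([1e-4], [1e-4]), ("pop1", "pop2"))
        assert r.iloc[0] == pytest.approx(1.0)

    def test_simple_division(self):
        r = pi_ratio(self._stats([4e-4], [1e-4]), ("pop1", "pop2"))
        assert r.iloc[0] == pytest.approx(4.0)

    def test_zero_denominator_excluded_from_distribution(self):
        """Complete-fixation windows are not part of the finite ratio set."""
        r = pi_ratio(self._stats([1e-4, 2e-4], [0.0, 1e-4]), ("pop1", "pop2"))
        assert np.isposinf(r.iloc[0])
        assert np.isfinite(r.iloc[1])

    def test_zero_both_is_undefined(self):
        r = pi_ratio(self._stats([0.0], [0.0]), ("pop1", "pop2"))
        assert np.isnan(r.iloc[0])


class TestEmpiricalOutliers:
    def test_top1_of_hundred(self):
        values = np.arange(1, 101, dtype=float)
        mask = empirical_outliers(values, 0.01)
        assert list(values[mask]) == [100.0]

    def test_top5_of_hundred(self):
        values = np.arange(1, 101, dtype=float)
        mask = empirical_outliers(values, 0.05)
        assert list(values[mask]) == [96.0, 97.0, 98.0, 99.0, 100.0]

    def test_all_equal_degenerate(self):
        mask = empirical_outliers(np.ones(10), 0.01)
        assert mask.all()

    def test_ties_at_threshold_expand(self):
        values = np.array([1.0, 2.0, 5.0, 5.0, 5.0])
        mask = empirical_outliers(values, 0.2)  # k = 1 but three-way tie
        assert mask.sum() == 3

    def test_inf_always_selected_but_never_threshold(self):
        values = np.array([np.inf, 1.0, 2.0, 3.0, np.nan] + [0.5] * 95)
        mask = empirical_outliers(values, 0.01)
        assert mask[0] and mask[3]
        assert not mask[4]

    def test_top1_subset_of_top5(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=500)
        m1 = empirical_outliers(values, 0.01)
        m5 = empirical_outliers(values, 0.05)
        assert not np.any(m1 & ~m5)


class TestCombined:
    def test_hand_intersection(self):
        ratio = np.zeros(20, bool)
        fst = np.zeros(20, bool)
        ratio[[3, 7]] = True
        fst[[7, 11]] = True
        sel = combined_fst_pi(ratio, fst)
        assert list(np.flatnonzero(sel)) == [7]

    def test_disjoint_and_identical(self):
        a = np.array([True, False]); b = np.array([False, True])
        assert not combined_fst_pi(a, b).any()
        assert list(combined_fst_pi(a, a)) == list(a)

    def test_always_subset_of_both(self):
        rng = np.random.default_rng(2)
        a = rng.random(200) < 0.1
        b = rng.random(200) < 0.1
        sel = combined_fst_pi(a, b)
        assert not np.any(sel & ~a) and not np.any(sel & ~b)


class TestGenesInBins:
    def test_overlap_rules(self):
        genes = [GeneModel("g1", "c", 10, 20), GeneModel("g2", "c", 60, 70),
                 GeneModel("g3", "c", 45, 55)]
        windows = [Window("c", 1, 50), Window("c", 51, 100)]
        per_window, union = genes_in_bins(genes, windows)
        assert per_window[0] == ["g1", "g3"]
        assert per_window[1] == ["g2", "g3"]
        assert union == ["g1", "g3", "g2"]  # g3 deduplicated

    def test_chromosome_mismatch(self):
        genes = [GeneModel("g1", "other", 10, 20)]
        per_window, union = genes_in_bins(genes, [Window("c", 1, 50)])
        assert per_window == [[]] and union == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(40):
            s = int(rng.integers(1, 9_000))
            genes.append(GeneModel(f"g{i}", f"c{rng.integers(1, 3)}", s,
                                   s + int(rng.integers(1, 500))))
        windows = [Window(f"c{c}", s, s + 999) for c in (1, 2)
                   for s in range(1, 10_000, 1000)]
        per_window, union = genes_in_bins(genes, windows)
        expect_union = []
        for w, got in zip(windows, per_window):
            expect = [g.gene_id for g in genes
                      if g.chrom == w.chrom
                      and max(g.start, w.start) <= min(g.end, w.end)]
            assert got == expect
            expect_union.extend(x for x in expect if x not in expect_union)
        assert union == expect_union


class TestGeneArithmetic:
    @pytest.mark.parametrize("start,end,expected", [
        (124604550, 124606754, 2205),
        (23043462, 23044569, 1108),
        (7, 7, 1),
    ])
    def test_gene_length(self, start, end, expected):
        assert gene_length(start, end) == expected

    @pytest.mark.parametrize("cds,expected", [(2205, 735), (1020, 340),
                                              (792, 264)])
    def test_protein_length(self, cds, expected):
        assert protein_length(cds) == expected

    def test_protein_length_excluding_stop(self):
        assert protein_length(2205, include_stop=False) == 734

    def test_protein_length_rejects_partial_codons(self):
        with pytest.raises(ValueError):
            protein_length(1000)


class TestScan:
    def _toy_stats(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        pi1 = rng.uniform(1e-4, 5e-4, n)
        pi2 = rng.uniform(1e-4, 5e-4, n)
        fst = rng.uniform(0, 0.4, n)
        # window 5 is an extreme sweep candidate in pop2 with high fst
        pi2[5] = 1e-6
        fst[5] = 0.95
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000 + 1,
            "end": (np.arange(n) + 1) * 1000,
            "pi_pop1": pi1, "pi_pop2": pi2, "fst": fst,
            "dxy": rng.uniform(0, 0.3, n)})

    def test_flags_consistent_and_planted_window_found(self):
        df = scan(self._toy_stats(), ScanConfig(window_size=1000,
                                                ratio_direction=("pop1", "pop2")))
        assert df["ratio_top1"].iloc[5]
        assert df["combined_top1"].iloc[5]
        assert not np.any(df["ratio_top1"] & ~df["ratio_top5"])
        assert not np.any(df["combined_top1"] & ~df["fst_top1"])

    def test_gff_round_trip_annotation(self, tmp_path):
        from popsweep.simulate import simulate_gene_models

        simulate_gene_models(10, {"chr1": 100_000}, seed=4,
                             out_path=tmp_path / "g.gff3")
        genes = read_gff3_genes(tmp_path / "g.gff3")
        assert len(genes) == 10
        for g in genes:
            assert g.cds_length % 3 == 0
        df = scan(self._toy_stats(), ScanConfig(window_size=1000,
                                                ratio_direction=("pop1", "pop2")),
                  genes=genes)
        assert "genes" in df.columns
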