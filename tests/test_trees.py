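"""Genotype distances and neighbor-joining correctness."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from popsweep.simulate import SimPanelConfig, simulate_two_pop_panel
from popsweep.trees import (genotype_distance, has_bipartition, nj_tree,
                            read_newick, tree_distances, write_newick)
from popsweep.variants import MISSING, filter_snps

from conftest import make_table


class TestGenotypeDistance:
    def test_identical_samples(self):
        table = make_table([[1, 1], [2, 2], [0, 0]])
        assert genotype_distance(table)[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        table = make_table([[0, 2], [2, 0]])
        assert genotype_distance(table)[0, 1] == 1.0

    def test_single_het_difference(self):
        g = [[0, 1]] + [[0, 0]] * 9
        assert genotype_distance(make_table(g))[0, 1] == pytest.approx(0.05)

    def test_no_cocalled_sites_raises(self):
        table = make_table([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="s01"):
            genotype_distance(table)

    def test_semimetric(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 3, size=(30, 6)).astype(np.int8))
        dm = genotype_distance(table)
        d = np.asarray(dm.data)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0) and np.all(d >= 0)


def random_additive_tree(n, rng):
    """A random binary tree with positive branch lengths; NJ must recover it."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        merged = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    for node in nodes:
        node.length = float(rng.uniform(0.1, 2.0))
    return TreeNode(children=nodes)


class TestNeighborJoining:
    def test_three_taxon_two_point_solution(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                            ids=["A", "B", "C"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_worked_matrix(self):
        # additive distances of tree ((A:1,B:2):5,(C:3,D:4))
        d = [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]]
        dm = DistanceMatrix(d, ids=["A", "B", "C", "D"])
        tree = nj_tree(dm)
        assert has_bipartition(tree, {"A", "B"})
        internal = [n for n in tree.children if not n.is_tip()]
        assert len(internal) == 1 and internal[0].length == pytest.approx(5.0)
        got = tree_distances(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert got[a, b] == pytest.approx(d[i][j])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_on_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        source = random_additive_tree(n, rng)
        dm = source.tip_tip_distances()
        recovered = nj_tree(DistanceMatrix(np.asarray(dm.data), ids=dm.ids))
        got = tree_distances(recovered)
        for a in dm.ids:
            for b in dm.ids:
                assert got[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_ultrametric_additivity(self):
        dm = DistanceMatrix((np.ones((4, 4)) - np.eye(4)) * 2,
                            ids=list("ABCD"))
        got = tree_distances(nj_tree(dm))
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert got[a, b] == pytest.approx(2.0)

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["A", "B"]))

    def test_agrees_with_reference_nj(self):
        """Topology matches scikit-bio's own NJ on a random matrix."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        source = random_additive_tree(8, rng)
        dm0 = source.tip_tip_distances()
        dm = DistanceMatrix(np.asarray(dm0.data), ids=dm0.ids)
        ours = tree_distances(nj_tree(dm))
        theirs = skbio_nj(dm).tip_tip_distances()
        for a in dm.ids:
            for b in dm.ids:
                assert ours[a, b] == pytest.approx(theirs[a, b], abs=1e-6)


class TestNewick:
    def test_round_trip(self):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                            ids=["A", "B", "C"])
        tree = nj_tree(dm)
        text = write_newick(tree)
        back = read_newick(text)
        orig = {t.name: t.length for t in tree.tips()}
        got = {t.name: t.length for t in back.tips()}
        assert got == pytest.approx(orig)

    def test_quoted_labels_survive(self):
        text = "('taxon one':1.5,'taxon two':2.5,c:1.0);\n"
        tree = read_newick(text)
        assert {t.name for t in tree.tips()} == {"taxon one", "taxon two", "c"}

    def test_malformed_input_raises(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:2;")

    def test_file_round_trip(self, tmp_path):
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                            ids=["A", "B", "C"])
        tree = nj_tree(dm)
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert {t.name for t in back.tips()} == {"A", "B", "C"}


class TestLineageRecovery:
    def test_two_population_bipartition(self):
        """NJ splits a F=0.25 panel into the two simulated populations."""
        hits = 0
        seeds = range(1, 9)
        for seed in seeds:
            cfg = SimPanelConfig(seed=seed, n_sites=800, chrom_length=100_000)
            table, popmap, _ = simulate_two_pop_panel(cfg)
            tree = nj_tree(genotype_distance(filter_snps(table)))
            if has_bipartition(tree, set(popmap.samples_for("pop1"))):
                hits += 1
        assert hits / len(seeds) >= 0.95
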