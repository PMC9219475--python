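import numpy as np
import pytest

import dendropy

from snpdiv.distance_nj import (
    DistanceMatrix,
    OverlapError,
    asd_matrix,
    nj_tree,
    to_newick,
)
from snpdiv.genotype_io import MISSING
from snpdiv.simdata import SimulationConfig, simulate_dataset

from _util import (
    make_gm,
    random_additive_tree,
    tree_bipartitions,
    tree_path_lengths,
)


def dm_from_values(values, labels=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = labels or [f"L{i}" for i in range(n)]
    return DistanceMatrix(
        labels=labels,
        populations=["P"] * n,
        values=values,
        n_overlap=np.full((n, n), 100),
    )


class TestAsdMatrix:
    def test_identical_vectors_distance_zero(self):
        calls = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (2, 1))
        gm = make_gm(calls, list("PP"))
        dm = asd_matrix(gm, min_overlap=1)
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm([[0, 0, 0], [2, 2, 2]], list("PP"))
        assert asd_matrix(gm, min_overlap=1).values[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        gm = make_gm([[2], [1]], list("PP"))
        assert asd_matrix(gm, min_overlap=1).values[0, 1] == 0.5

    def test_pairwise_complete_loci(self):
        calls = np.array([[0, MISSING, 2], [0, 1, 0]], dtype=np.int8)
        gm = make_gm(calls, list("PP"))
        dm = asd_matrix(gm, min_overlap=1)
        assert dm.n_overlap[0, 1] == 2
        assert dm.values[0, 1] == pytest.approx(0.5)  # mean of (0, 1)

    def test_overlap_guard_names_pair(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        gm = make_gm(calls, list("PP"))
        with pytest.raises(OverlapError, match="S0.*S1"):
            asd_matrix(gm, min_overlap=1)

    def test_semimetric_properties_randomized(self, rng):
        for _ in range(25):
            n, m = int(rng.integers(4, 12)), int(rng.integers(50, 120))
            calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.1] = MISSING
            gm = make_gm(calls, ["P"] * n)
            dm = asd_matrix(gm, min_overlap=5)
            assert np.array_equal(dm.values, dm.values.T)
            assert (np.diag(dm.values) == 0).all()
            assert (dm.values >= 0).all() and (dm.values <= 1).all()

    def test_within_less_than_between_under_structure(self):
        within, between = [], []
        for seed in range(20):
            config = SimulationConfig(
                n_pops=2, pop_sizes=(8, 8), n_loci=300, bn_F=(0.15, 0.15),
                fis=(0.0, 0.0), seed=seed,
            )
            gm, _ = simulate_dataset(config)
            dm = asd_matrix(gm, min_overlap=10)
            pops = np.array(dm.populations)
            same = (pops[:, None] == pops[None, :]) & ~np.eye(16, dtype=bool)
            diff = pops[:, None] != pops[None, :]
            within.append(dm.values[same].mean())
            between.append(dm.values[diff].mean())
        assert all(w < b for w, b in zip(within, between))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = nj_tree(dm_from_values(d))
        lengths = {
            tree.leaf_labels[leaf]: tree.adjacency[leaf][0][1] for leaf in range(3)
        }
        # three-point formulas: l0=(3+4-5)/2=1, l1=(3+5-4)/2=2, l2=(4+5-3)/2=3
        assert lengths == {"L0": 1.0, "L1": 2.0, "L2": 3.0}
        assert np.allclose(tree.path_lengths(), d)

    def test_additive_matrix_recovery(self, rng):
        for _ in range(10):
            adjacency, n = random_additive_tree(8, rng)
            d = tree_path_lengths(adjacency, n)
            labels = [f"L{i}" for i in range(n)]
            tree = nj_tree(dm_from_values(d, labels))
            assert tree.bipartitions() == tree_bipartitions(adjacency, n, labels)
            assert np.allclose(tree.path_lengths(), d, atol=1e-9)

    def test_rejects_asymmetric_matrix(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            dm_from_values(d)
        dm = dm_from_values(np.zeros((3, 3)))
        dm.values = d  # corrupt after construction: nj_tree must re-check
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(dm)

    def test_rejects_negative_entries(self):
        dm = dm_from_values(np.zeros((3, 3)))
        dm.values = np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="negative"):
            nj_tree(dm)

    def test_branch_lengths_non_negative(self, rng):
        for _ in range(10):
            n = 7
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = nj_tree(dm_from_values(d))
            tree.validate()

    def test_perfect_population_split(self):
        config = SimulationConfig(
            n_pops=2, pop_sizes=(10, 10), n_loci=500, bn_F=(0.3, 0.3),
            fis=(0.0, 0.0), seed=17,
        )
        gm, _ = simulate_dataset(config)
        tree = nj_tree(asd_matrix(gm, min_overlap=10))
        pop1 = frozenset(s for s, p in zip(gm.sample_ids, gm.population_labels)
                         if p == "POP1")
        assert pop1 in tree.bipartitions()

    def test_deterministic_on_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(dm_from_values(d))
        t2 = nj_tree(dm_from_values(d))
        assert to_newick(t1) == to_newick(t2)


class TestToNewick:
    def test_three_leaf_round_trip(self):
        d = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        newick = to_newick(nj_tree(dm_from_values(d)))
        assert newick.endswith(";")
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "L0", "L1", "L2"
        }

    def test_external_parser_preserves_topology_and_paths(self, rng):
        adjacency, n = random_additive_tree(9, rng)
        d = tree_path_lengths(adjacency, n)
        labels = [f"L{i}" for i in range(n)]
        tree = nj_tree(dm_from_values(d, labels))
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                got = pdm.distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(d[i, j], rel=1e-4)

    def test_label_quoting(self):
        d = [[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]]
        newick = to_newick(nj_tree(dm_from_values(d, ["a b", "it's", "plain"])))
        assert "'a b'" in newick
        assert "'it''s'" in newick
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "a b", "it's", "plain"
        }
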