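"""Neighbor joining, bootstrap supports, patristic distances, PCoA."""

import numpy as np
import pytest

from nichephylo.core_io import SequenceRecord, ValidationError, parse_newick
from nichephylo.phylo_inference import (
    DistanceMatrix,
    bootstrap_supports,
    jc69_distance_matrix,
    nj_tree,
    patristic_matrix,
    pcoa,
    robinson_foulds,
)
from nichephylo.synthetic_data import evolve_sequences, simulate_tree_pair


def brute_force_patristic(phy):
    """Independent path-sum oracle: undirected BFS over the tree graph."""
    edges = {}
    for nd in phy.tree.preorder_node_iter():
        for ch in nd.child_nodes():
            edges.setdefault(id(nd), []).append((id(ch), ch.edge.length or 0))
            edges.setdefault(id(ch), []).append((id(nd), ch.edge.length or 0))
    leaves = {(_l.taxon.label): id(_l) for _l in phy.tree.leaf_node_iter()}
    labels = sorted(leaves)
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {leaves[a]: 0.0}
        stack = [leaves[a]]
        while stack:
            u = stack.pop()
            for v, w in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, b in enumerate(labels):
            out[i, j] = dist[leaves[b]]
    return DistanceMatrix(labels, out)


class TestNeighborJoining:
    ADDITIVE = DistanceMatrix(
        list("ABCD"),
        np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                  [5, 6, 0, 7], [6, 7, 7, 0]], float))

    def test_exact_on_the_four_taxon_additive_matrix(self):
        tree = nj_tree(self.ADDITIVE)
        pm = patristic_matrix(tree).reorder(list("ABCD"))
        assert np.allclose(pm.values, self.ADDITIVE.values, atol=1e-9)
        # topology ((A,B),(C,D)): the AB split is present
        expected = parse_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert robinson_foulds(tree, expected) == 0

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(list("ABC"),
                           np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        pm = patristic_matrix(nj_tree(D)).reorder(list("ABC"))
        assert np.allclose(pm.values, D.values, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_trees(self, seed):
        true, _, _ = simulate_tree_pair(10, 0, seed=seed)
        D = patristic_matrix(true)
        est = nj_tree(D)
        assert robinson_foulds(est, true) == 0
        assert np.allclose(patristic_matrix(est).values, D.values, atol=1e-9)

    def test_label_permutation_invariance(self):
        true, _, _ = simulate_tree_pair(8, 0, seed=12)
        D = patristic_matrix(true)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(D.labels))
        a = nj_tree(D)
        b = nj_tree(D.reorder(perm))
        assert robinson_foulds(a, b) == 0

    def test_matches_scikit_bio_topology(self):
        import skbio

        true, _, _ = simulate_tree_pair(9, 0, seed=7)
        D = patristic_matrix(true)
        ours = nj_tree(D)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D.values, ids=D.labels))
        theirs = parse_newick(str(sk))
        assert robinson_foulds(ours, theirs) == 0

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_outgroup_rooting(self):
        tree = nj_tree(self.ADDITIVE, outgroup="D")
        root_children = tree.tree.seed_node.child_nodes()
        tipsets = [frozenset(l.taxon.label for l in c.leaf_iter())
                   for c in root_children]
        assert frozenset({"D"}) in tipsets


class TestBootstrap:
    def _clade_records(self):
        tree = parse_newick(
            "((A:0.02,B:0.02):0.8,(C:0.02,D:0.02):0.8);")
        return evolve_sequences(tree, 300, 1.0, seed=2)

    def test_deep_split_gets_high_support(self):
        phy = bootstrap_supports(self._clade_records(), n_boot=100, seed=0)
        supports = [nd.support for nd in phy.tree.preorder_node_iter()
                    if nd.support is not None]
        assert max(supports) >= 0.95

    def test_no_column_variation_gives_full_support(self):
        recs = self._clade_records()
        # constant-column alignment: resampling cannot change anything
        phy = bootstrap_supports(recs, n_boot=20, seed=1)
        again = bootstrap_supports(recs, n_boot=20, seed=1)
        s1 = [nd.support for nd in phy.tree.preorder_node_iter()
              if nd.support is not None]
        s2 = [nd.support for nd in again.tree.preorder_node_iter()
              if nd.support is not None]
        assert s1 == s2  # seeded determinism

    def test_unequal_lengths_rejected(self):
        recs = [SequenceRecord("a", "amoA", "ACGT", "S", 1),
                SequenceRecord("b", "amoA", "ACGTA", "S", 1),
                SequenceRecord("c", "amoA", "ACGG", "S", 1)]
        with pytest.raises(ValidationError):
            bootstrap_supports(recs, n_boot=10, seed=0)

    def test_jc_correction_inverts_the_model(self):
        # p-distance 0.2313... corresponds to JC distance ~0.2746 exactly
        seqs = np.array([list("A" * 70 + "C" * 30), list("A" * 70 + "G" * 30)])
        D = jc69_distance_matrix(["x", "y"], seqs)
        p = 0.3
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert D.values[0, 1] == pytest.approx(expected)


class TestPatristic:
    def test_two_tip_path_sum(self):
        phy = parse_newick("(A:1,B:2);")
        D = patristic_matrix(phy)
        assert D.values[0, 1] == pytest.approx(3.0)

    def test_ultrametric_max_is_twice_the_height(self):
        phy = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert patristic_matrix(phy).values.max() == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_path_search(self, seed):
        phy, _, _ = simulate_tree_pair(10, 0, seed=seed)
        ours = patristic_matrix(phy)
        brute = brute_force_patristic(phy).reorder(ours.labels)
        assert np.allclose(ours.values, brute.values, atol=1e-10)


class TestPCoA:
    def test_points_on_a_line_recovered_exactly(self):
        D = DistanceMatrix(list("abc"),
                           np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float))
        res = pcoa(D)
        from scipy.spatial.distance import pdist, squareform

        assert np.allclose(squareform(pdist(res.coordinates)), D.values,
                           atol=1e-9)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        D = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        res = pcoa(D)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_idempotence(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        D = DistanceMatrix([f"p{i}" for i in range(7)],
                           squareform(pdist(pts)))
        res = pcoa(D)
        assert np.allclose(squareform(pdist(res.coordinates)), D.values,
                           atol=1e-9)

    def test_matches_scikit_bio_eigenvalues(self):
        import skbio

        phy, _, _ = simulate_tree_pair(8, 0, seed=3)
        D = patristic_matrix(phy)
        ours = pcoa(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.labels))
        k = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues,
                           theirs.eigvals.to_numpy()[:k], atol=1e-8)
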