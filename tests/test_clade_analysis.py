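"""Clade delineation rule, preference profiles, pH niche classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nichephylo.clade_analysis import (
    CladeCluster,
    annotate_read_fractions,
    clade_abundance_matrix,
    classify_ph_category,
    cluster_preference,
    delineate_clusters,
    ph_response_fit,
    preference_table,
)
from nichephylo.core_io import (
    AbundanceMatrix,
    EnvTable,
    SequenceRecord,
    ValidationError,
    parse_newick,
)


def set_supports(phy, value):
    for nd in phy.tree.preorder_node_iter():
        if not nd.is_leaf() and nd.parent_node is not None:
            nd.support = value


class TestDelineation:
    def test_uniform_clade_emitted_whole(self):
        phy = parse_newick("((A:1,B:1)1.0:1,(C:1,D:1)1.0:1);")
        clusters = delineate_clusters(phy, lambda a, b: 1.0)
        assert len(clusters) == 1
        assert clusters[0].member_tips == frozenset("ABCD")
        assert not clusters[0].unplaced

    def test_divergent_tip_left_unplaced(self):
        # D is distant from A, B, C; the inner triple is well supported
        phy = parse_newick("(((A:1,B:1)0.9:1,C:1)0.9:1,D:4);")
        ident = {frozenset(p): 0.95 for p in itertools.combinations("ABC", 2)}

        def fn(a, b):
            return ident.get(frozenset((a, b)), 0.80)

        clusters = delineate_clusters(phy, fn)
        tipsets = sorted((sorted(c.member_tips) for c in clusters), key=len)
        assert tipsets == [["D"], ["A", "B", "C"]]
        assert [c.unplaced for c in clusters
                if c.member_tips == frozenset("D")] == [True]

    def test_impossible_support_threshold_unplaces_everything(self):
        phy = parse_newick("((A:1,B:1)0.99:1,(C:1,D:1)0.99:1);")
        clusters = delineate_clusters(phy, lambda a, b: 1.0,
                                      support_thresh=1.0)
        assert all(c.unplaced for c in clusters)
        assert len(clusters) == 4

    def test_missing_sequence_raises(self):
        phy = parse_newick("((A:1,B:1)1.0:1,C:1);")

        def fn(a, b):
            raise KeyError(a)

        with pytest.raises(KeyError):
            delineate_clusters(phy, fn)

    @pytest.mark.parametrize("seed", range(5))
    def test_clusters_are_maximal_disjoint_clades(self, seed, amoa_toolkit):
        from nichephylo.clustering import pairwise_identity
        from nichephylo.synthetic_data import (evolve_sequences,
                                               simulate_tree_pair)

        phy, _, _ = simulate_tree_pair(10, 0, seed=seed)
        seqs = {r.id: r.residues
                for r in evolve_sequences(phy, 150, 0.08, seed=seed)}
        fn = lambda a, b: pairwise_identity(seqs[a], seqs[b])
        clusters = delineate_clusters(phy, fn)
        # exhaustive enumerator of all clades and the qualifying subset
        nodes = [nd for nd in phy.tree.preorder_node_iter()
                 if not nd.is_leaf()]
        def qualifies(nd):
            tips = [l.taxon.label for l in nd.leaf_iter()]
            mpi = min((fn(a, b)
                       for a, b in itertools.combinations(tips, 2)),
                      default=1.0)
            sup = 1.0 if getattr(nd, "support", None) is None else nd.support
            return mpi > 0.90 and sup > 0.70
        qualifying = {frozenset(l.taxon.label for l in nd.leaf_iter())
                      for nd in nodes if qualifies(nd)}
        maximal = {q for q in qualifying
                   if not any(q < other for other in qualifying)}
        emitted = {c.member_tips for c in clusters if not c.unplaced}
        assert emitted == maximal
        placed = [t for c in emitted for t in c]
        assert len(placed) == len(set(placed))  # disjoint
        unplaced = {t for c in clusters if c.unplaced for t in c.member_tips}
        assert unplaced == set(phy.tip_labels) - set(placed)


class TestPreference:
    def _setup(self, weights, ph):
        soils = [f"S{i}" for i in range(len(ph))]
        data = pd.DataFrame({"c1": weights}, index=soils)
        other = 100 - data["c1"]
        data["c2"] = other
        mat = AbundanceMatrix(data)
        env = EnvTable(pd.DataFrame({"pH": ph}, index=soils))
        cl = CladeCluster(id="c1", member_tips=frozenset({"t1"}),
                          root_support=1.0, min_pairwise_identity=1.0,
                          total_read_fraction=0.2)
        return cl, mat, env

    def test_single_soil_support_point(self):
        cl, mat, env = self._setup([100.0, 0.0], [4.5, 7.0])
        prof = cluster_preference(cl, mat, env)
        assert prof.weighted_mean["pH"] == pytest.approx(4.5)
        assert prof.category == "acidophilic"

    def test_equal_weights_average(self):
        cl, mat, env = self._setup([50.0, 50.0], [4.0, 6.0])
        assert cluster_preference(cl, mat, env).weighted_mean["pH"] == \
            pytest.approx(5.0)

    def test_weighted_average_75_25(self):
        cl, mat, env = self._setup([75.0, 25.0], [4.0, 8.0])
        assert cluster_preference(cl, mat, env).weighted_mean["pH"] == \
            pytest.approx(5.0)

    def test_absent_cluster_rejected(self):
        cl, mat, env = self._setup([50.0, 50.0], [4.0, 6.0])
        cl.id = "c9"
        with pytest.raises(ValidationError):
            cluster_preference(cl, mat, env)

    def test_read_fraction_annotation(self):
        clusters = [
            CladeCluster("x", frozenset({"t1"}), 1.0, 1.0),
            CladeCluster("y", frozenset({"t2"}), 1.0, 1.0),
        ]
        recs = [SequenceRecord("t1.S1", "amoA", "ACGT", "S1", 60),
                SequenceRecord("t2.S1", "amoA", "ACGT", "S1", 40)]
        annotate_read_fractions(clusters, recs)
        assert clusters[0].total_read_fraction == pytest.approx(0.6)
        assert clusters[1].total_read_fraction == pytest.approx(0.4)


class TestPhCategory:
    @pytest.mark.parametrize("ph,cat", [
        (4.2, "acidophilic"),
        (7.8, "alkalinophilic"),
        (5.5, "neutrophilic"),   # closed lower boundary
        (7.0, "neutrophilic"),
        (5.49, "acidophilic"),
    ])
    def test_boundaries(self, ph, cat):
        assert classify_ph_category(ph) == cat


class TestPhResponseFit:
    def _mat_env(self, y, ph):
        soils = [f"S{i}" for i in range(len(ph))]
        data = pd.DataFrame({"c1": y}, index=soils)
        data["c2"] = 100 - data["c1"]
        return (AbundanceMatrix(data),
                EnvTable(pd.DataFrame({"pH": ph}, index=soils)))

    def test_noiseless_quadratic_recovered(self):
        ph = np.linspace(4, 8, 12)
        y = 50 - 3 * (ph - 6) ** 2
        mat, env = self._mat_env(y, ph)
        fit = ph_response_fit("c1", mat, env)
        assert fit.degree == 2
        assert fit.rss < 1e-10

    def test_pure_noise_prefers_the_linear_model(self):
        chosen = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            ph = np.linspace(3.6, 8.4, 40)
            y = np.clip(20 + rng.normal(0, 3, 40), 0, None)
            mat, env = self._mat_env(y, ph)
            chosen.append(ph_response_fit("c1", mat, env).degree)
        assert np.mean(np.array(chosen) == 1) >= 0.8

    def test_monotone_data_monotone_linear_fit(self):
        ph = np.linspace(4, 8, 10)
        y = 2 + 5 * (ph - 4)
        mat, env = self._mat_env(y, ph)
        fit = ph_response_fit("c1", mat, env)
        pred = fit.predict(ph)
        assert (np.diff(pred) >= -1e-9).all()

    def test_too_few_points_suggests_weighted_mean(self):
        mat, env = self._mat_env([10.0, 20, 30, 40, 50], np.linspace(4, 8, 5))
        with pytest.raises(ValidationError, match="weighted-mean"):
            ph_response_fit("c1", mat, env)


class TestCladeAbundance:
    def test_preference_table_roundtrip(self, amoa_toolkit):
        from nichephylo.clustering import pairwise_identity

        seqs = amoa_toolkit["seqs"]
        clusters = delineate_clusters(
            amoa_toolkit["tree"],
            lambda a, b: pairwise_identity(seqs[a], seqs[b]))
        annotate_read_fractions(clusters, amoa_toolkit["records"])
        mat = clade_abundance_matrix(clusters, amoa_toolkit["records"])
        assert np.allclose(mat.data.sum(axis=1), 100.0)
        tab = preference_table(clusters, mat, amoa_toolkit["env"],
                               factors=["pH", "water_content"])
        assert {"cluster", "read_fraction", "category",
                "mean_pH"} <= set(tab.columns)
        assert tab["read_fraction"].sum() == pytest.approx(1.0, abs=1e-6)
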