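"""Correspondence matrix construction and the ParaFit global test."""

import numpy as np
import pandas as pd
import pytest

from nichephylo.congruence import (
    ClusterAnnotation,
    CorrespondenceMatrix,
    build_correspondence,
    congruence_report,
    identity_links,
    parafit_global,
)
from nichephylo.core_io import ValidationError
from nichephylo.phylo_inference import DistanceMatrix, patristic_matrix, pcoa
from nichephylo.synthetic_data import simulate_tree_pair


def parafit_stat_oracle(D_host, D_par, A):
    """Fully explicit ParaFit statistic: element-by-element loops over the
    principal coordinates, no matrix shortcuts."""
    B = pcoa(D_host).coordinates
    C = pcoa(D_par).coordinates
    total = 0.0
    for i in range(C.shape[1]):
        for j in range(B.shape[1]):
            d_ij = 0.0
            for k in range(A.shape[0]):
                for l in range(A.shape[1]):
                    d_ij += C[k, i] * A[k, l] * B[l, j]
            total += d_ij ** 2
    return total


class TestBuildCorrespondence:
    def ann(self, cid, rf, ph, refs=()):
        return ClusterAnnotation(id=cid, read_fraction=rf, mean_ph=ph,
                                 references=frozenset(refs))

    def test_shared_reference_anchors_regardless_of_abundance(self):
        A = build_correspondence(
            [self.ann("a1", 0.001, 4.0, {"Nitrosotalea"})],
            [self.ann("s1", 0.5, 7.9, {"Nitrosotalea"})])
        assert A.tier[("a1", "s1")] == "reference_anchored"

    def test_similar_abundance_and_ph_suggest_a_link(self):
        A = build_correspondence(
            [self.ann("a1", 0.30, 4.1)], [self.ann("s1", 0.29, 4.2)])
        assert A.tier[("a1", "s1")] == "suggested"

    def test_ph_gap_blocks_a_link_despite_abundance_match(self):
        A = build_correspondence(
            [self.ann("a1", 0.30, 4.0)], [self.ann("s1", 0.29, 6.0)])
        assert A.links == []

    def test_rare_clusters_never_get_suggested_links(self):
        A = build_correspondence(
            [self.ann("a1", 0.01, 5.0)], [self.ann("s1", 0.01, 5.0)])
        assert A.links == []

    def test_tier2_is_one_to_one_with_ph_tie_break(self):
        A = build_correspondence(
            [self.ann("a1", 0.30, 5.0)],
            [self.ann("s1", 0.30, 5.4), self.ann("s2", 0.30, 5.1)])
        assert A.links == [("a1", "s2")]

    def test_reference_in_two_clusters_of_one_marker_rejected(self):
        with pytest.raises(ValidationError, match="two clusters"):
            build_correspondence(
                [self.ann("a1", 0.1, 5.0, {"ref"}),
                 self.ann("a2", 0.1, 5.0, {"ref"})],
                [self.ann("s1", 0.1, 5.0, {"ref"})])

    def test_many_to_one_reference_links_allowed(self):
        # three 16S clusters anchored to one amoA cluster
        A = build_correspondence(
            [self.ann("a1", 0.3, 6.5, {"r1", "r2", "r3"})],
            [self.ann("s1", 0.1, 6.4, {"r1"}),
             self.ann("s2", 0.1, 6.5, {"r2"}),
             self.ann("s3", 0.1, 6.6, {"r3"})])
        assert len(A.links) == 3
        assert all(t == "reference_anchored" for t in A.tier.values())


class TestParaFit:
    def test_all_zero_association_rejected(self):
        phy, _, _ = simulate_tree_pair(4, 0, seed=0)
        D = patristic_matrix(phy)
        zero = CorrespondenceMatrix(
            pd.DataFrame(np.zeros((4, 4), dtype=int),
                         index=D.labels, columns=D.labels))
        with pytest.raises(ValidationError, match="zeros"):
            parafit_global(D, D, zero, nperm=99)

    @pytest.mark.parametrize("seed", range(4))
    def test_statistic_matches_explicit_oracle(self, seed):
        a, _, _ = simulate_tree_pair(5, 0, seed=seed)
        b, _, _ = simulate_tree_pair(6, 0, seed=seed + 40)
        Dh = patristic_matrix(a)
        Dp = patristic_matrix(b)
        rng = np.random.default_rng(seed)
        mat = (rng.random((6, 5)) < 0.4).astype(int)
        mat[0, 0] = 1
        A = CorrespondenceMatrix(pd.DataFrame(
            mat, index=Dp.labels, columns=Dh.labels))
        res = parafit_global(Dh, Dp, A, nperm=99, seed=seed)
        assert res.global_stat == pytest.approx(
            parafit_stat_oracle(Dh, Dp, mat), abs=1e-8)

    def test_single_link_statistic_on_three_tip_trees(self):
        a, _, _ = simulate_tree_pair(3, 0, seed=1)
        b, _, _ = simulate_tree_pair(3, 0, seed=2)
        Dh, Dp = patristic_matrix(a), patristic_matrix(b)
        mat = np.zeros((3, 3), dtype=int)
        mat[1, 2] = 1
        A = CorrespondenceMatrix(pd.DataFrame(
            mat, index=Dp.labels, columns=Dh.labels))
        res = parafit_global(Dh, Dp, A, nperm=99, seed=0)
        B = pcoa(Dh).coordinates
        C = pcoa(Dp).coordinates
        expected = float(np.sum(np.outer(C[1], B[2]) ** 2))
        assert res.global_stat == pytest.approx(expected, abs=1e-10)

    def test_perfect_congruence_hits_the_p_floor(self):
        phy, copy, _ = simulate_tree_pair(16, 0, seed=9)
        D1 = patristic_matrix(phy)
        D2 = patristic_matrix(copy)
        A = identity_links(D1.labels)
        res = parafit_global(D1, D2, A, nperm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)

    def test_relabelling_invariance(self):
        a, b, _ = simulate_tree_pair(8, 0, seed=3)
        Dh, Dp = patristic_matrix(a), patristic_matrix(b)
        A = identity_links(Dh.labels)
        res1 = parafit_global(Dh, Dp, A, nperm=99, seed=5)
        relabel = {l: f"x{i}" for i, l in enumerate(Dh.labels)}
        Dh2 = DistanceMatrix([relabel[l] for l in Dh.labels], Dh.values)
        Dp2 = DistanceMatrix([relabel[l] for l in Dp.labels], Dp.values)
        A2 = identity_links(list(Dh2.labels))
        res2 = parafit_global(Dh2, Dp2, A2, nperm=99, seed=5)
        assert res1.global_stat == pytest.approx(res2.global_stat)
        assert res1.p_value == res2.p_value

    def test_seeded_reproducibility(self):
        a, b, _ = simulate_tree_pair(8, 1, seed=6)
        Dh, Dp = patristic_matrix(a), patristic_matrix(b)
        A = identity_links(Dh.labels)
        r1 = parafit_global(Dh, Dp, A, nperm=199, seed=7)
        r2 = parafit_global(Dh, Dp, A, nperm=199, seed=7)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_stats, r2.null_stats)


class TestReport:
    def test_report_has_one_row_per_link(self):
        phy, copy, _ = simulate_tree_pair(7, 0, seed=2)
        D = patristic_matrix(phy)
        labels = D.labels[:7]
        A = identity_links(labels)
        res = parafit_global(D, patristic_matrix(copy), A, nperm=99, seed=0)
        ann = {l: ClusterAnnotation(id=l, read_fraction=0.1, mean_ph=6.0)
               for l in labels}
        rep = congruence_report(A, res, ann, ann)
        assert len(rep) == 7
        assert (rep["tier"] == "reference_anchored").all()
        assert (rep["p_value"] == res.p_value).all()

    def test_tier1_only_report_is_valid(self):
        A = CorrespondenceMatrix(
            pd.DataFrame([[1]], index=["a1"], columns=["s1"]),
            {("a1", "s1"): "reference_anchored"})
        from nichephylo.congruence import ParaFitResult

        res = ParaFitResult(global_stat=1.0, p_value=0.5, nperm=99)
        ann_a = {"a1": ClusterAnnotation("a1", 0.2, 4.0)}
        ann_s = {"s1": ClusterAnnotation("s1", 0.2, 4.1)}
        rep = congruence_report(A, res, ann_a, ann_s)
        assert len(rep) == 1
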