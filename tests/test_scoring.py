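import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hetbench.core import (
    GERMLINE,
    HardAssignment,
    InvalidInputError,
    SoftAssignment,
    build_cocluster,
    build_relationship_matrices,
)
from hetbench.scoring import (
    ClusterProfile,
    profile_from_truth,
    reconcile_prediction,
    reconcile_cocluster,
    reconcile_hard,
    reconcile_profile,
    reconcile_relationship_matrices,
    reconcile_soft,
    score_1a,
    score_1b,
    score_1c,
    score_2,
    score_3,
)
from tests._oracles import (
    ajsd_pairwise,
    aupr_by_threshold_enumeration,
    emd_lp,
    pcc_stacked,
    relationship_matrices_by_enumeration,
)
from tests.conftest import make_truth


class TestScore1A:
    @pytest.mark.parametrize(
        "rho,c,expected", [(0.7, 0.7, 1.0), (1.0, 0.0, 0.0), (0.8, 0.6, 0.8)]
    )
    def test_values(self, rho, c, expected):
        assert score_1a(rho, c) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            score_1a(1.2, 0.5)
        with pytest.raises(InvalidInputError):
            score_1a(0.5, -0.1)


class TestScore1B:
    @pytest.mark.parametrize(
        "L,kappa,expected", [(3, 3, 1.0), (2, 100, 0.0), (4, 2, 0.6)]
    )
    def test_values(self, L, kappa, expected):
        assert score_1b(L, kappa) == pytest.approx(expected)

    def test_invalid_L(self):
        with pytest.raises(InvalidInputError):
            score_1b(0, 1)

    @given(st.integers(1, 10))
    def test_monotone_then_flat(self, L):
        # non-increasing in |kappa - L| and constant once the cap binds
        scores = [score_1b(L, k) for k in range(L, L + 2 * L + 5)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert score_1b(L, 2 * L + 1) == score_1b(L, 5 * L + 50)
        assert min(score_1b(L, k) for k in range(0, 8 * L)) >= 0.0


class TestScore1C:
    def test_identical_profiles(self):
        p = ClusterProfile([(1, 60, 0.9), (2, 40, 0.4)])
        assert score_1c(p, p).score == pytest.approx(1.0)

    def test_single_cluster_shift(self):
        t = ClusterProfile([(1, 100, 0.8)])
        p = ClusterProfile([(1, 100, 0.6)])
        r = score_1c(t, p)
        assert r.emd == pytest.approx(0.2)
        assert r.score == pytest.approx(0.8)

    def test_split_versus_merged(self):
        t = ClusterProfile([(1, 50, 1.0), (2, 50, 0.5)])
        p = ClusterProfile([(1, 100, 0.75)])
        r = score_1c(t, p)
        assert r.emd == pytest.approx(
            emd_lp(t.cps, t.masses, p.cps, p.masses), abs=1e-9
        )
        assert r.score == pytest.approx(0.75)

    def test_matches_transport_lp_on_random_profiles(self, rng):
        for _ in range(100):
            def rand_profile():
                k = rng.integers(1, 7)
                return ClusterProfile(
                    [(i + 1, int(rng.integers(1, 50)), float(rng.uniform(0, 1)))
                     for i in range(k)]
                )
            t, p = rand_profile(), rand_profile()
            assert score_1c(t, p).emd == pytest.approx(
                emd_lp(t.cps, t.masses, p.cps, p.masses), abs=1e-9
            )


class TestScore2:
    def test_perfect_prediction(self):
        t = HardAssignment(np.array([1, 1, 2, 2, 3]))
        assert score_2(t, t).score == pytest.approx(1.0)

    def test_worse_extreme_normalizes_to_zero(self):
        t = HardAssignment(np.array([1, 1, 1, 2, 2]))
        n = t.n_snvs
        one_cluster = HardAssignment(np.ones(n, dtype=int))
        singletons = HardAssignment(np.arange(1, n + 1))
        scores = [score_2(t, one_cluster), score_2(t, singletons)]
        # the worse extreme anchors each component at 0
        worst_aupr = min(s.aupr_raw for s in scores)
        worst_ajsd = max(s.ajsd_raw for s in scores)
        for s in scores:
            if s.aupr_raw == worst_aupr:
                assert s.aupr_norm == pytest.approx(0.0)
            if s.ajsd_raw == worst_ajsd:
                assert s.ajsd_norm == pytest.approx(0.0)

    def test_matches_pairwise_enumeration_oracle(self):
        t = HardAssignment(np.array([1, 1, 2, 2]))
        p = HardAssignment(np.array([1, 2, 1, 2]))
        r = score_2(t, p)
        tc, pc = build_cocluster(t), build_cocluster(p)
        iu = np.triu_indices(4, k=1)
        assert r.aupr_raw == pytest.approx(
            aupr_by_threshold_enumeration(tc[iu] > 0.5, pc[iu])
        )
        assert r.ajsd_raw == pytest.approx(ajsd_pairwise(pc, tc), abs=1e-12)

    def test_soft_path_equals_hard_path_for_indicator(self):
        t = HardAssignment(np.array([1, 1, 2, 2, 3, 3]))
        p = HardAssignment(np.array([1, 1, 1, 2, 3, 3]))
        w = np.zeros((6, 3))
        w[np.arange(6), p.labels - 1] = 1.0
        assert score_2(t, p).score == pytest.approx(
            score_2(t, SoftAssignment(w)).score
        )

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(InvalidInputError):
            score_2(HardAssignment(np.array([1, 2])), HardAssignment(np.array([1, 2, 3])))

    def test_snv_order_invariance(self, rng):
        t = rng.integers(1, 4, size=20)
        p = rng.integers(1, 4, size=20)
        perm = rng.permutation(20)
        s1 = score_2(HardAssignment(t), HardAssignment(p)).score
        s2 = score_2(HardAssignment(t[perm]), HardAssignment(p[perm])).score
        assert s1 == pytest.approx(s2)


class TestScore3:
    def test_perfect_prediction(self, branching_truth):
        m = build_relationship_matrices(branching_truth)
        assert score_3(branching_truth, m).score == pytest.approx(1.0, abs=1e-12)

    def test_relabeled_clusters_score_one(self, branching_truth):
        relabel = {1: 4, 2: 9, 3: 2}
        tree = {relabel[c]: relabel.get(p, GERMLINE)
                for c, p in branching_truth.parent_map.items()}
        labels = np.array([relabel[l] for l in branching_truth.hard_assignment().labels])
        m = build_relationship_matrices(tree, HardAssignment(labels))
        assert score_3(branching_truth, m).score == pytest.approx(1.0, abs=1e-12)

    def test_single_cluster_matches_enumeration_oracle(self, branching_truth):
        n = branching_truth.n_snvs
        pred_tree = {1: GERMLINE}
        pred_labels = np.ones(n, dtype=int)
        pm = build_relationship_matrices(pred_tree, HardAssignment(pred_labels))
        r = score_3(branching_truth, pm)
        truth_o = relationship_matrices_by_enumeration(
            branching_truth.parent_map, branching_truth.hard_assignment().labels
        )
        pred_o = relationship_matrices_by_enumeration(pred_tree, pred_labels)
        assert r.score == pytest.approx(pcc_stacked(truth_o, pred_o), abs=1e-12)

    def test_zero_variance_scores_zero(self, branching_truth):
        n = branching_truth.n_snvs
        # constant half-probability everywhere: no variance in the prediction
        from hetbench.core import RelationshipMatrices

        half = np.full((n, n), 0.25)
        pred = RelationshipMatrices(half, half, half)
        r = score_3(branching_truth, pred)
        assert r.score == 0.0 and r.degenerate


class TestReconciliation:
    def test_identity_when_sets_match(self):
        pred, _ = reconcile_hard(
            HardAssignment(np.array([1, 1, 2])), [1, 2, 3], [1, 2, 3]
        )
        assert pred.labels.tolist() == [1, 1, 2]

    def test_fn_added_fp_excluded(self):
        # pred over {1..4} + FP {6}; truth {1..5}
        pred, fn_label = reconcile_hard(
            HardAssignment(np.array([1, 1, 2, 2, 3])), [1, 2, 3, 4, 6], [1, 2, 3, 4, 5]
        )
        assert pred.n_snvs == 5
        assert pred.labels[4] == fn_label  # SNV 5 in the new cluster
        assert fn_label not in pred.labels[:4]

    def test_multiple_fns_share_one_cluster(self):
        pred, fn_label = reconcile_hard(
            HardAssignment(np.array([1])), [1], [1, 2, 3]
        )
        assert pred.labels.tolist() == [1, fn_label, fn_label]

    def test_profile_fn_cluster_cp_zero(self):
        prof = ClusterProfile([(1, 4, 0.8)])
        out = reconcile_profile(prof, [1, 2, 3, 4], [1, 2, 3, 4, 5, 6])
        fn = [c for c in out.clusters if c[2] == 0.0]
        assert len(fn) == 1 and fn[0][1] == 2

    def test_profile_fp_dropped_with_labels(self):
        prof = ClusterProfile([(1, 2, 0.8), (2, 2, 0.4)])
        out = reconcile_profile(prof, [1, 2, 3, 6], [1, 2, 3], labels=[1, 1, 2, 2])
        assert sorted(out.clusters) == [(1, 2, 0.8), (2, 1, 0.4)]

    def test_dispatcher_routes_by_type(self, branching_truth):
        tids = branching_truth.snv_ids
        hard = reconcile_prediction(
            HardAssignment(np.array([1] * 5)), branching_truth, tids[:5]
        )
        assert hard.n_snvs == len(tids)
        prof = reconcile_prediction(
            ClusterProfile([(1, 6, 0.8)]), branching_truth, tids
        )
        assert prof.total_ssms == 6
        with pytest.raises(InvalidInputError):
            reconcile_prediction("nonsense", branching_truth, tids)

    def test_no_overlap_rejected(self):
        with pytest.raises(InvalidInputError):
            reconcile_hard(HardAssignment(np.array([1])), [9], [1, 2])

    def test_soft_fn_gets_new_column(self):
        soft = SoftAssignment(np.array([[0.7, 0.3], [0.2, 0.8]]))
        out = reconcile_soft(soft, [1, 2], [1, 2, 3])
        assert out.weights.shape == (3, 3)
        assert out.weights[2].tolist() == [0.0, 0.0, 1.0]

    def test_cocluster_fn_block(self):
        mat = np.ones((2, 2))
        out = reconcile_cocluster(mat, [1, 2], [1, 2, 3, 4])
        assert out[2, 3] == 1.0 and out[0, 2] == 0.0 and out[0, 1] == 1.0

    def test_fn_snvs_are_cousins_in_sc3(self, branching_truth):
        # drop SNVs 5, 6 from the prediction; they must become cousins of all
        tids = branching_truth.snv_ids
        m = build_relationship_matrices(branching_truth)
        from hetbench.core import RelationshipMatrices

        sub = np.ix_(range(4), range(4))
        pred = RelationshipMatrices(
            m.cocluster[sub], m.ancestor_descendant[sub], m.cousin[sub]
        )
        out = reconcile_relationship_matrices(pred, tids[:4], tids)
        assert np.all(out.cousin[4:, :4] == 1.0)
        assert np.all(out.cousin[:4, 4:] == 1.0)
        assert out.cocluster[4, 5] == 1.0


class TestPerfectScoresAcrossMetrics:
    def test_all_seven_metrics_perfect_for_truth(self, branching_truth):
        t = branching_truth
        assert score_1a(t.purity, t.purity) == 1.0
        assert score_1b(t.n_subclones, t.n_subclones) == 1.0
        p = profile_from_truth(t)
        assert score_1c(p, p).score == pytest.approx(1.0)
        h = t.hard_assignment()
        assert score_2(h, h).score == pytest.approx(1.0)
        m = build_relationship_matrices(t)
        assert score_3(t, m).score == pytest.approx(1.0, abs=1e-12)
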