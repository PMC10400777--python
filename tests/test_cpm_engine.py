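"""Edge selection, strength models, LOOCV, permutation and sensitivity."""

import numpy as np
import pytest
from scipy import stats

from scn_cpm.cpm_engine import (
    SignedEdgeMasks,
    confound_sensitivity,
    edge_score_correlation,
    fit_predict_fold,
    network_strength,
    permutation_test,
    run_cpm,
    run_cpm_loocv,
    select_edges,
)
from scn_cpm.scn_builder import EdgeIndex, IndividualSCN


def make_iscn(theta: np.ndarray) -> IndividualSCN:
    """Wrap a subjects x edges matrix as an IndividualSCN for CPM tests."""
    E = theta.shape[1]
    # smallest N with at least E edges
    N = 2
    while N * (N - 1) // 2 < E:
        N += 1
    full = np.zeros(N * (N - 1) // 2)
    pad = np.zeros((theta.shape[0], full.size))
    pad[:, :E] = theta
    return IndividualSCN(
        pseudovalues=pad,
        edge_index=EdgeIndex(N),
        r_full=full,
        r_loo=np.zeros_like(pad),
    )


class TestEdgeScoreCorrelation:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        score = rng.normal(5, 2, 20)
        edges = np.column_stack([score, -score])
        r, p = edge_score_correlation(edges, score)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert p[0] < 1e-12 and p[1] < 1e-12

    def test_matches_pearsonr_oracle(self):
        rng = np.random.default_rng(1)
        edges = rng.normal(size=(20, 30))
        score = rng.normal(size=20)
        r, p = edge_score_correlation(edges, score)
        for e in range(30):
            ref = stats.pearsonr(edges[:, e], score)
            assert r[e] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[e] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_edge_gets_r0_p1(self):
        rng = np.random.default_rng(2)
        score = rng.normal(size=10)
        edges = np.column_stack([rng.normal(size=10), np.full(10, 3.0)])
        r, p = edge_score_correlation(edges, score)
        assert r[1] == 0.0 and p[1] == 1.0

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            edge_score_correlation(np.random.default_rng(3).normal(size=(8, 2)), np.full(8, 5.0))


class TestSelectEdges:
    def test_sign_split_rule(self):
        masks = select_edges(
            np.array([0.9, -0.9, 0.01]), np.array([0.001, 0.001, 0.9]), 0.01
        )
        np.testing.assert_array_equal(masks.positive, [True, False, False])
        np.testing.assert_array_equal(masks.negative, [False, True, False])

    def test_nothing_significant(self):
        masks = select_edges(np.array([0.5, -0.5]), np.array([0.5, 0.5]), 0.01)
        assert not masks.positive.any() and not masks.negative.any()

    def test_threshold_is_strict(self):
        masks = select_edges(np.array([0.5]), np.array([0.01]), 0.01)
        assert not masks.positive.any()

    def test_disjoint_masks_enforced(self):
        with pytest.raises(ValueError, match="both"):
            SignedEdgeMasks(np.array([True]), np.array([True]), 0.01)


class TestNetworkStrength:
    @pytest.mark.parametrize(
        "row,mask,expected",
        [
            ([0.2, 0.3, 0.5], [False, False, False], 0.0),
            ([0.2, 0.3, 0.5], [True, True, True], 1.0),
            ([1.0, 9.9, -0.5], [True, False, True], 0.5),
        ],
    )
    def test_masked_sums(self, row, mask, expected):
        assert network_strength(np.array(row), np.array(mask)) == pytest.approx(expected)


class TestFitPredictFold:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(4)
        score = rng.normal(5, 2, 12)
        theta = np.zeros((12, 4))
        theta[:, 1] = 2.0 * score - 3.0  # one informative edge, zero noise
        pred = fit_predict_fold(theta[1:], score[1:], theta[0], mode="positive")
        assert pred == pytest.approx(score[0], abs=1e-8)

    def test_no_selection_falls_back_to_train_mean(self):
        rng = np.random.default_rng(5)
        train = rng.normal(size=(10, 3))
        score = rng.normal(size=10)
        pred = fit_predict_fold(train, score, rng.normal(size=3), threshold_p=1e-12)
        assert pred == pytest.approx(score.mean())

    def test_negative_mode_matches_polyfit_oracle(self):
        # 6-subject set with one strongly anti-correlated edge
        score = np.array([9.0, 7.0, 6.0, 4.0, 3.0, 1.0])
        edge = np.array([-8.5, -7.2, -5.9, -4.1, -2.8, -1.2])
        noise = np.array([0.3, -0.1, 0.2, 0.0, -0.3, 0.1])
        train = np.column_stack([edge, noise])
        test_row = np.array([-5.0, 0.05])
        r, p = edge_score_correlation(train, score)
        assert (p[0] < 0.01) and (r[0] < 0)  # the oracle trains on edge 0 only
        assert p[1] >= 0.01  # the noise edge must stay unselected
        slope, intercept = np.polyfit(edge, score, 1)
        expected = slope * test_row[0] + intercept
        got = fit_predict_fold(train, score, test_row, mode="negative")
        assert got == pytest.approx(expected, abs=1e-10)


class TestLOOCV:
    def test_matches_reference_fold_fit(self):
        rng = np.random.default_rng(6)
        n = 18
        score = rng.normal(5, 2, n)
        theta = rng.normal(size=(n, 12)) + 0.4 * score[:, None]
        iscn = make_iscn(theta)
        for mode in ("positive", "negative", "combined"):
            res = run_cpm_loocv(iscn, score, threshold_p=0.05, mode=mode)
            for f in range(n):
                tr = np.arange(n) != f
                ref = fit_predict_fold(
                    iscn.pseudovalues[tr], score[tr], iscn.pseudovalues[f],
                    threshold_p=0.05, mode=mode,
                )
                assert res.predicted[f] == pytest.approx(ref, abs=1e-8), mode

    def test_subject_shuffle_equivariance(self):
        rng = np.random.default_rng(7)
        n = 15
        score = rng.normal(5, 2, n)
        theta = rng.normal(size=(n, 8)) + 0.5 * score[:, None]
        res = run_cpm_loocv(make_iscn(theta), score)
        perm = rng.permutation(n)
        res2 = run_cpm_loocv(make_iscn(theta[perm]), score[perm])
        np.testing.assert_allclose(res2.predicted, res.predicted[perm], atol=1e-8)
        assert res2.performance_r == pytest.approx(res.performance_r, abs=1e-10)

    def test_combined_with_empty_negative_equals_positive_mode(self):
        rng = np.random.default_rng(8)
        n = 16
        score = rng.normal(5, 2, n)
        # all informative edges positively coupled: negative mask stays empty
        theta = rng.normal(scale=0.1, size=(n, 5)) + score[:, None]
        iscn = make_iscn(theta)
        combined = run_cpm_loocv(iscn, score, mode="combined")
        positive = run_cpm_loocv(iscn, score, mode="positive")
        assert not combined.fold_negative.any()
        np.testing.assert_array_equal(combined.predicted, positive.predicted)
        neg_c = run_cpm_loocv(iscn, -score + 10.0, mode="combined")
        neg_s = run_cpm_loocv(iscn, -score + 10.0, mode="negative")
        assert not neg_c.fold_positive.any()
        np.testing.assert_array_equal(neg_c.predicted, neg_s.predicted)

    def test_consensus_is_intersection_of_folds(self):
        rng = np.random.default_rng(9)
        n = 14
        score = rng.normal(5, 2, n)
        theta = rng.normal(size=(n, 10)) + 0.6 * score[:, None]
        res = run_cpm_loocv(make_iscn(theta), score)
        np.testing.assert_array_equal(res.consensus.positive, res.fold_positive.all(axis=0))
        np.testing.assert_array_equal(res.consensus.negative, res.fold_negative.all(axis=0))


class TestPermutation:
    def _perfect_iscn(self, n=12, seed=10):
        rng = np.random.default_rng(seed)
        score = rng.normal(5, 2, n)
        theta = np.zeros((n, 3))
        theta[:, 0] = score
        return make_iscn(theta), score

    def test_minimal_attainable_p(self):
        iscn, score = self._perfect_iscn()
        p, null_r = permutation_test(iscn, score, mode="positive", n_perm=99, seed=1)
        assert p == pytest.approx(1.0 / 100.0)
        assert null_r.size == 99

    def test_true_r_below_all_null_gives_p_one(self):
        iscn, score = self._perfect_iscn()
        p, _ = permutation_test(iscn, score, mode="positive", n_perm=50, seed=2, true_r=-2.0)
        assert p == 1.0

    def test_add_one_flag(self):
        iscn, score = self._perfect_iscn()
        p, _ = permutation_test(
            iscn, score, mode="positive", n_perm=49, seed=3, add_one=False
        )
        assert p == 0.0

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(11)
        score = rng.normal(5, 2, 10)
        theta = rng.normal(size=(10, 6)) + 0.3 * score[:, None]
        iscn = make_iscn(theta)
        p1, n1 = permutation_test(iscn, score, n_perm=30, seed=7)
        p2, n2 = permutation_test(iscn, score, n_perm=30, seed=7)
        assert p1 == p2
        np.testing.assert_array_equal(n1, n2)

    def test_p_decreases_with_true_r(self):
        rng = np.random.default_rng(12)
        score = rng.normal(5, 2, 10)
        theta = rng.normal(size=(10, 6))
        iscn = make_iscn(theta)
        ps = [
            permutation_test(iscn, score, n_perm=60, seed=5, true_r=tr)[0]
            for tr in (-0.5, 0.0, 0.5, 0.99)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_run_cpm_attaches_permutation(self):
        iscn, score = self._perfect_iscn()
        res = run_cpm(iscn, score, mode="positive", n_perm=49, seed=4)
        assert res.performance_r == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1.0 / 50.0)
        assert res.null_r.size == 49
        assert res.seed == 4


class TestConfoundSensitivity:
    def test_self_constant_and_oracle(self):
        rng = np.random.default_rng(13)
        score = rng.normal(5, 2, 15)
        theta = np.zeros((15, 3))
        theta[:, 0] = score
        res = run_cpm_loocv(make_iscn(theta), score, mode="positive")
        cov = rng.normal(size=15)
        out = confound_sensitivity(
            res, {"self": res.predicted, "flat": np.full(15, 2.0), "x": cov}
        )
        assert out["self"][0] == pytest.approx(1.0)
        assert np.isnan(out["flat"][0]) and np.isnan(out["flat"][1])
        ref = stats.pearsonr(res.predicted, cov)
        assert out["x"][0] == pytest.approx(ref.statistic, abs=1e-12)
        assert out["x"][1] == pytest.approx(ref.pvalue, abs=1e-10)
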