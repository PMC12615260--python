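"""Core-model operations: trimming, binarization, enrichment scores,
normalization, the forward pass and serialization."""

import itertools

import numpy as np
import pytest
from scipy import sparse

from potencynet.constants import T_VEC
from potencynet.gsbn import (
    BackgroundMap,
    NormStats,
    ams_score,
    binarize,
    build_background_map,
    compute_tau,
    core_forward,
    load_model,
    normalize_scores,
    save_model,
    trim_ranks,
    ucell_score,
)
from potencynet.io import dual_representation
from potencynet.training import initialize_model

from conftest import tiny_hyperparameters, tiny_split


class TestElementaryOps:
    def test_trim_ranks(self):
        R = np.array([[7, 3], [5, 9]])
        np.testing.assert_array_equal(trim_ranks(R, 5), [[5, 3], [5, 5]])
        np.testing.assert_array_equal(trim_ranks(R, 100), R)

    def test_binarize_strict_at_threshold(self):
        np.testing.assert_array_equal(binarize(np.array([-0.1, 0.0, 0.2])), [0, 0, 1])
        W = np.random.default_rng(0).normal(size=(5, 3))
        np.testing.assert_array_equal(binarize(binarize(W)), binarize(W))
        assert binarize(np.full((4, 1), -1.0)).sum() == 0

    @pytest.mark.parametrize(
        "tau_m,smax,expected", [(-0.3, 500, 510), (0.5, 500, 1010), (0.0, 0, 10)]
    )
    def test_compute_tau(self, tau_m, smax, expected):
        assert compute_tau(tau_m, np.array([smax])) == expected


class TestUcellScore:
    def test_top_ranked_set_scores_one(self):
        # set of S genes occupying ranks 1..S gives the analytic maximum 1
        W_B = np.zeros((6, 1))
        W_B[:3, 0] = 1
        T = np.arange(1, 7, dtype=float)[:, None]
        np.testing.assert_allclose(ucell_score(T, W_B, tau=13), [[1.0]])

    def test_printed_example(self):
        # S=2, tau=5, trimmed ranks {3, 5}: 1 + (6 - 16)/20 = 0.5
        W_B = np.array([[1.0], [1.0], [0.0]])
        T = np.array([[3.0], [5.0], [1.0]])
        np.testing.assert_allclose(ucell_score(T, W_B, tau=5), [[0.5]])

    def test_all_trimmed_gives_minimum(self):
        tau = 12
        W_B = np.array([[1.0], [1.0], [0.0], [0.0]])
        T = np.full((4, 1), float(tau))
        np.testing.assert_allclose(ucell_score(T, W_B, tau), [[(2 + 1) / (2 * tau)]])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ucell_score(np.ones((3, 1)), np.zeros((3, 1)), tau=11)

    def test_brute_force_enumeration(self):
        # independent per-gene oracle over every permutation of ranks,
        # N=6, S in {1, 2, 3}
        N = 6
        for S in (1, 2, 3):
            W_B = np.zeros((N, 1))
            W_B[:S, 0] = 1
            tau = compute_tau(0.0, W_B.sum(axis=0))
            lo, hi = (S + 1) / (2 * tau), 1.0
            for perm in itertools.permutations(range(1, N + 1)):
                T = np.minimum(np.array(perm, dtype=float), tau)[:, None]
                rank_sum = sum(T[i, 0] for i in range(N) if W_B[i, 0] == 1)
                oracle = 1 + (S * (S + 1) - 2 * rank_sum) / (2 * tau * S)
                got = ucell_score(T, W_B, tau)[0, 0]
                assert got == pytest.approx(oracle, abs=1e-12)
                assert lo - 1e-12 <= got <= hi + 1e-12

    def test_monotone_in_rank_improvement(self):
        W_B = np.array([[1.0], [1.0], [0.0], [0.0]])
        base = ucell_score(np.array([[4.0], [2.0], [1.0], [3.0]]), W_B, tau=12)
        better = ucell_score(np.array([[3.0], [2.0], [1.0], [4.0]]), W_B, tau=12)
        assert better[0, 0] > base[0, 0]


class TestBackgroundMap:
    def test_background_stays_in_own_bin_and_excludes_self(self):
        mean = np.arange(120.0)
        bm = build_background_map(mean, n_bins=4, n_sample=10, seed=0)
        order = np.argsort(-mean, kind="stable")
        bins = np.array_split(order, 4)
        bin_of = {}
        for b, members in enumerate(bins):
            for g in members:
                bin_of[g] = b
        B = bm.B.toarray()
        assert np.all(np.diag(B) == 0)
        assert (B.sum(axis=1) >= 1).all()
        rows, cols = np.nonzero(B)
        assert all(bin_of[i] == bin_of[j] for i, j in zip(rows, cols))

    def test_mean_background_count_matches_n_sample(self):
        # counts ~ Gaussian(mean=n_sample, var=n_sample(s_bin-n_sample)/s_bin)
        n, n_bins, n_sample = 4800, 24, 100
        bm = build_background_map(np.random.default_rng(0).normal(size=n),
                                  n_bins=n_bins, n_sample=n_sample, seed=1)
        counts = np.asarray(bm.B.sum(axis=1)).ravel()
        s_bin = n // n_bins
        sem = np.sqrt(n_sample * (s_bin - n_sample) / s_bin / n)
        assert abs(counts.mean() - n_sample) < 5 * sem

    def test_degenerate_configurations_rejected(self):
        with pytest.raises(ValueError, match="more genes"):
            build_background_map(np.arange(10.0), n_bins=10, n_sample=2)
        with pytest.raises(ValueError, match="n_sample"):
            build_background_map(np.arange(50.0), n_bins=25, n_sample=10)

    def test_deterministic_given_seed(self):
        mean = np.random.default_rng(3).normal(size=100)
        a = build_background_map(mean, n_bins=4, n_sample=5, seed=7)
        b = build_background_map(mean, n_bins=4, n_sample=5, seed=7)
        assert (a.B != b.B).nnz == 0


class TestAmsScore:
    def _map(self):
        # genes 0,1 in the set; gene 0's background is {2}, gene 1's is {3}
        B = np.zeros((4, 4))
        B[0, 2] = B[1, 3] = 1
        return BackgroundMap(sparse.csr_matrix(B), n_bins=1, n_sample=1)

    def test_constant_expression_scores_zero(self):
        W_B = np.array([[1.0], [1.0], [0.0], [0.0]])
        L = np.full((4, 2), 3.0)
        np.testing.assert_allclose(ams_score(L, W_B, self._map()), 0.0)

    def test_unit_contrast(self):
        W_B = np.array([[1.0], [1.0], [0.0], [0.0]])
        L = np.array([[2.0], [2.0], [1.0], [1.0]])
        np.testing.assert_allclose(ams_score(L, W_B, self._map()), [[1.0]])

    def test_homogeneity_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        W_B = np.array([[1.0], [1.0], [0.0], [0.0]])
        L = rng.gamma(2.0, 1.0, size=(4, 3))
        base = ams_score(L, W_B, self._map())
        np.testing.assert_allclose(ams_score(2 * L, W_B, self._map()), 2 * base)
        np.testing.assert_allclose(
            ams_score(L + 5.0, W_B, self._map()), base, atol=1e-12
        )


class TestNormalizeScores:
    def test_train_mode_standardizes(self):
        stats = NormStats.empty(2)
        K = np.random.default_rng(0).normal(2.0, 3.0, size=(50, 2))
        out = normalize_scores(K, stats, "train")
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.var(axis=0), 1.0, rtol=1e-4)
        assert stats.fitted

    def test_infer_mode_uses_stored_stats(self):
        stats = NormStats(mean=np.array([2.0]), var=np.array([4.0]), fitted=True)
        out = normalize_scores(np.array([[4.0]]), stats, "infer")
        assert out[0, 0] == pytest.approx(1.0, abs=1e-5)

    def test_constant_column_finite(self):
        stats = NormStats.empty(1)
        out = normalize_scores(np.full((10, 1), 7.0), stats, "train")
        assert np.isfinite(out).all()

    def test_infer_without_fit_rejected(self):
        with pytest.raises(ValueError, match="not been fitted"):
            normalize_scores(np.ones((2, 1)), NormStats.empty(1), "infer")


class TestCoreForward:
    @pytest.fixture(scope="class")
    def setup(self):
        H, labels, H_val, _ = tiny_split(0)
        hp = tiny_hyperparameters()
        bg = build_background_map(H.L.mean(axis=1), hp.n_bins, hp.n_sample, seed=0)
        model = initialize_model(hp, H.n_features, 0, bg)
        # fit normalization stats with one train-mode pass
        core_forward(model, H, mode="train", rng=np.random.default_rng(0))
        return model, H

    def test_row_stochastic_and_bounded(self, setup):
        model, H = setup
        _, pred = core_forward(model, H)
        np.testing.assert_allclose(pred.P.sum(axis=1), 1.0, atol=1e-6)
        assert ((pred.RPS >= 0) & (pred.RPS <= 1)).all()
        np.testing.assert_array_equal(pred.y_hat, np.argmax(pred.P, axis=1) + 1)

    def test_rps_is_expectation_of_anchors(self, setup):
        model, H = setup
        _, pred = core_forward(model, H)
        np.testing.assert_allclose(pred.RPS, pred.P @ T_VEC)

    def test_inference_bitwise_deterministic(self, setup):
        model, H = setup
        _, a = core_forward(model, H)
        _, b = core_forward(model, H)
        assert np.array_equal(a.P, b.P)

    def test_serialization_round_trip(self, setup, tmp_path):
        model, H = setup
        path = tmp_path / "model.zip"
        save_model(path, model)
        back = load_model(path)
        _, a = core_forward(model, H)
        _, b = core_forward(back, H)
        np.testing.assert_array_equal(a.P, b.P)
        for m1, m2 in zip(model.modules, back.modules):
            np.testing.assert_array_equal(m1.W, m2.W)
            assert m1.tau_m == m2.tau_m
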