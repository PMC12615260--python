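"""Loss components, sampling, early stopping, determinism and ensembling."""

import numpy as np
import pandas as pd
import pytest

from potencynet.gsbn import build_background_map, core_forward
from potencynet.training import (
    EnsembleModel,
    Hyperparameters,
    NAdam,
    ensemble_predict,
    gene_set_size_penalty,
    hierarchical_loss_weights,
    initialize_gene_set_weights,
    initialize_model,
    make_sampler,
    prediction_loss,
    ste_backward,
    train_model,
    weighted_accuracy,
)

from conftest import tiny_hyperparameters, tiny_split


def labels_frame(cats, phens, dss):
    return pd.DataFrame(
        {"broad_category": cats, "phenotype": phens, "dataset": dss,
         "cell_id": [f"c{i}" for i in range(len(cats))]}
    )


class TestHierarchicalWeights:
    def test_uniform_case(self):
        lab = labels_frame(
            ["differentiated"] * 2 + ["totipotent"] * 2,
            ["p1", "p1", "p2", "p2"],
            ["d"] * 4,
        )
        np.testing.assert_allclose(hierarchical_loss_weights(lab), 0.25)

    def test_unbalanced_phenotypes(self):
        # category A has 2 phenotypes, B has 1: B's phenotype carries mass
        # 0.5, each A phenotype 0.25
        lab = labels_frame(
            ["differentiated"] * 4 + ["totipotent"] * 2,
            ["a1", "a1", "a2", "a2", "b1", "b1"],
            ["d"] * 6,
        )
        w = hierarchical_loss_weights(lab)
        assert w[0] + w[1] == pytest.approx(0.25)
        assert w[2] + w[3] == pytest.approx(0.25)
        assert w[4] + w[5] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sums_to_one_for_random_hierarchies(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        lab = labels_frame(
            rng.choice(["differentiated", "unipotent", "multipotent"], n),
            rng.choice(["p1", "p2", "p3"], n),
            rng.choice(["d1", "d2"], n),
        )
        lab["phenotype"] = lab["broad_category"] + "_" + lab["phenotype"]
        assert hierarchical_loss_weights(lab).sum() == pytest.approx(1.0)


class TestPredictionLoss:
    def test_uniform_likelihoods_give_log_six(self):
        Q = np.zeros((4, 6))
        y = np.array([1, 3, 5, 6])
        v = np.full(4, 0.25)
        assert prediction_loss(Q, y, v) == pytest.approx(np.log(6))

    def test_confident_correct_prediction_vanishes(self):
        Q = np.full((2, 6), -50.0)
        Q[0, 0] = Q[1, 5] = 50.0
        assert prediction_loss(Q, np.array([1, 6]), np.ones(2)) < 1e-12

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(5, 6))
        y = rng.integers(1, 7, size=5)
        v = rng.random(5)
        assert prediction_loss(Q, y, 2 * v) == pytest.approx(
            2 * prediction_loss(Q, y, v)
        )

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="1..6"):
            prediction_loss(np.zeros((1, 6)), np.array([7]), np.ones(1))


class TestGeneSetSizePenalty:
    def test_formula_evaluation(self):
        W_B = np.zeros((100, 1))
        W_B[:10, 0] = 1
        val = gene_set_size_penalty([W_B], lam=0.01, M=1, N=100)
        assert val == pytest.approx(np.sqrt(12) * 0.01 * 0.1)

    def test_empty_sets_zero(self):
        assert gene_set_size_penalty([np.zeros((50, 3))] * 6, 0.01, 3, 50) == 0.0

    def test_anchor_at_m_twelve(self):
        assert np.sqrt(12.0 / 12) == 1.0

    @pytest.mark.parametrize("M", [1, 12, 24])
    def test_invariant_to_gene_set_count_at_equal_sizes(self, M):
        # with every set the same size, a = sqrt(12/M) cancels the sqrt(M)
        # growth of the norm, so J_S is independent of M
        N, S = 120, 7
        W_B = np.zeros((N, M))
        W_B[:S, :] = 1
        val = gene_set_size_penalty([W_B], lam=0.01, M=M, N=N)
        assert val == pytest.approx(np.sqrt(12) * 0.01 * S / N)


class TestSteBackward:
    def test_hardtanh_window(self):
        W = np.array([0.5, 1.5, -0.9, -2.0])
        g = np.array([1.0, 1.0, 2.0, 2.0])
        np.testing.assert_array_equal(ste_backward(g, W), [1.0, 0.0, 2.0, 0.0])

    def test_zero_gradient_propagates_zero(self):
        np.testing.assert_array_equal(
            ste_backward(np.zeros(3), np.array([0.1, 0.5, 2.0])), 0.0
        )


class TestInitialization:
    def test_positive_count_matches_gaussian_tail(self):
        hp = Hyperparameters(M=1)
        counts = [
            (initialize_gene_set_weights(hp, 14271, np.random.default_rng(s)) > 0).sum()
            for s in range(30)
        ]
        # N * P(Normal(-0.1, 0.055) > 0) ~= 493 -- "approximately 500"
        assert abs(np.mean(counts) - 493) < 20

    def test_vanishing_sd_empties_gene_sets(self):
        hp = Hyperparameters(init_sd=1e-12)
        W = initialize_gene_set_weights(hp, 200, np.random.default_rng(0))
        assert (W > 0).sum() == 0

    def test_seed_reproducible(self):
        hp = tiny_hyperparameters()
        bg = build_background_map(np.arange(60.0), 4, 3, seed=0)
        a = initialize_model(hp, 60, 5, bg)
        b = initialize_model(hp, 60, 5, bg)
        for ma, mb in zip(a.modules, b.modules):
            np.testing.assert_array_equal(ma.W, mb.W)
            assert ma.tau_m == mb.tau_m
            np.testing.assert_array_equal(ma.V, mb.V)


class TestSampler:
    def test_balances_unequal_phenotypes(self):
        lab = labels_frame(
            ["differentiated"] * 1000,
            ["rare"] * 10 + ["common"] * 990,
            ["d"] * 1000,
        )
        sampler = make_sampler(lab, batch_size=500, seed=0)
        counts = np.zeros(2)
        for _ in range(10):
            for idx in sampler():
                counts[0] += (idx < 10).sum()
                counts[1] += (idx >= 10).sum()
        assert abs(counts[0] / counts.sum() - 0.5) < 0.05

    def test_single_phenotype_uniform(self):
        lab = labels_frame(["unipotent"] * 50, ["p"] * 50, ["d"] * 50)
        idx = next(iter(make_sampler(lab, 1000, seed=1)()))
        freq = np.bincount(idx, minlength=50) / idx.size
        assert freq.std() < 3 * np.sqrt(0.02 * 0.98 / idx.size)

    def test_seed_fixes_batch_sequence(self):
        lab = labels_frame(["unipotent"] * 20, ["p"] * 20, ["d"] * 20)
        a = [idx.tolist() for idx in make_sampler(lab, 8, seed=3)()]
        b = [idx.tolist() for idx in make_sampler(lab, 8, seed=3)()]
        assert a == b


class TestWeightedAccuracy:
    def test_perfect_and_worst(self):
        lab = labels_frame(
            ["differentiated", "totipotent"], ["p1", "p2"], ["d", "d"]
        )
        assert weighted_accuracy(np.array([1, 6]), lab) == 1.0
        assert weighted_accuracy(np.array([6, 1]), lab) == 0.0

    def test_hierarchical_aggregation(self):
        # two phenotypes of one category with group F1 0.8 and 0.6 -> 0.7;
        # within a pure group F1 = 2r/(1+r) so recall 2/3 gives 0.8 and
        # recall 3/7 gives 0.6
        lab = labels_frame(
            ["differentiated"] * 10, ["pa"] * 3 + ["pb"] * 7, ["d"] * 10
        )
        pred = np.array([1, 1, 2] + [1, 1, 1, 2, 2, 2, 2])
        assert weighted_accuracy(pred, lab) == pytest.approx(0.7)


class TestNAdamAndTraining:
    def test_nadam_descends_quadratic(self):
        theta = np.array([5.0, -3.0])
        opt = NAdam(lr=0.1)
        for _ in range(300):
            opt.step([theta], [2 * theta])
        assert np.abs(theta).max() < 1e-2

    def test_zero_learning_rate_keeps_weights(self):
        H_tr, l_tr, H_val, l_val = tiny_split(0)
        hp = tiny_hyperparameters(lr=0.0, max_epochs=2)
        model = train_model((H_tr, l_tr), (H_val, l_val), hp=hp, seed=4)
        bg = build_background_map(
            H_tr.L.mean(axis=1), hp.n_bins, hp.n_sample, seed=4
        )
        init = initialize_model(hp, H_tr.n_features, 4, bg)
        for ma, mb in zip(model.modules, init.modules):
            np.testing.assert_array_equal(ma.W, mb.W)
            assert ma.tau_m == mb.tau_m

    def test_same_seed_identical_checkpoint(self):
        H_tr, l_tr, H_val, l_val = tiny_split(0)
        hp = tiny_hyperparameters()
        a = train_model((H_tr, l_tr), (H_val, l_val), hp=hp, seed=9)
        b = train_model((H_tr, l_tr), (H_val, l_val), hp=hp, seed=9)
        for ma, mb in zip(a.modules, b.modules):
            np.testing.assert_array_equal(ma.W, mb.W)
            np.testing.assert_array_equal(ma.V, mb.V)
            assert ma.tau_m == mb.tau_m
            np.testing.assert_array_equal(ma.norm_stats.mean, mb.norm_stats.mean)

    def test_empty_split_rejected(self):
        H_tr, l_tr, H_val, l_val = tiny_split(0)
        with pytest.raises(ValueError, match="nonempty"):
            train_model((H_tr, l_tr.iloc[:0]), (H_val, l_val),
                        hp=tiny_hyperparameters(), seed=0)


class TestEnsemble:
    def test_single_member_identity(self, standard_run):
        model, H = standard_run["model"], standard_run["H_val"]
        _, single = core_forward(model, H)
        ens = ensemble_predict(EnsembleModel(members=[model]), H)
        np.testing.assert_array_equal(single.P, ens.P)
        np.testing.assert_array_equal(single.y_hat, ens.y_hat)

    def test_mean_of_one_hot_rows(self):
        # two members predicting adjacent one-hot rows average to
        # (0.5, 0.5, 0, ...) and RPS = 0.1
        from potencynet.constants import T_VEC

        P1 = np.zeros((1, 6)); P1[0, 0] = 1
        P2 = np.zeros((1, 6)); P2[0, 1] = 1
        P = (P1 + P2) / 2
        assert P @ T_VEC == pytest.approx(0.1)
        np.testing.assert_allclose(P[0], [0.5, 0.5, 0, 0, 0, 0])

    def test_ensemble_rows_sum_to_one(self, standard_run):
        model, H = standard_run["model"], standard_run["H_val"]
        ens = ensemble_predict([model, model], H)
        np.testing.assert_allclose(ens.P.sum(axis=1), 1.0, atol=1e-9)

    def test_mismatched_members_rejected(self, standard_run):
        model = standard_run["model"]
        other = model.copy()
        other.modules = [m.copy() for m in other.modules]
        for m in other.modules:
            m.W = m.W[:-1]
        with pytest.raises(ValueError, match="feature space"):
            EnsembleModel(members=[model, other])


class TestLearning:
    def test_loss_decreases_on_separable_data(self, standard_run):
        losses = [h[1] for h in standard_run["model"].training_history]
        assert np.mean(losses[-5:]) < 0.5 * np.mean(losses[:5])
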