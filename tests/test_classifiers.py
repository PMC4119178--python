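"""LDA, the Rprop/StdBP network, prediction scoring, consensus voting."""

import numpy as np
import pytest

from mutacyp.classifiers import (
    NeuralNet,
    Prediction,
    TrainConfig,
    consensus,
    labels_to_bool,
    lda_train,
    load_model,
    nn_train,
)

D, B = "deleterious", "benign"

XOR_X = np.array(
    [[0, 0, 0, 0, 0], [0, 1, 0, 0, 0], [1, 0, 0, 0, 0], [1, 1, 0, 0, 0]],
    dtype=float,
)
XOR_Y = [B, D, D, B]


def _gaussian_pair(rng, n_d=100, n_b=80, sep=1.0, dim=5):
    Xd = rng.normal(sep, 1.0, (n_d, dim))
    Xb = rng.normal(0.0, 1.0, (n_b, dim))
    return np.vstack([Xd, Xb]), [D] * n_d + [B] * n_b


class TestLDA:
    def test_separable_clouds_reach_perfect_training_accuracy(self, rng):
        X, y = _gaussian_pair(rng, sep=8.0)
        model = lda_train(X, y)
        assert [p.label for p in model.predict(X)] == y

    def test_mirror_symmetric_data_splits_at_the_mirror_point(self):
        X = np.array([[1.0], [2.0], [3.0], [-1.0], [-2.0], [-3.0]])
        model = lda_train(X, [D] * 3 + [B] * 3)
        # the decision value at the mirror point (0) must be 0
        assert model.decision_values(np.array([[0.0]]))[0] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_direction_matches_closed_form_pooled_covariance(self, rng):
        X, y = _gaussian_pair(rng, sep=1.0)
        model = lda_train(X, y)
        yb = labels_to_bool(y)
        Z = model.standardizer.transform(X)
        zd, zb = Z[yb], Z[~yb]
        S = (
            np.cov(zd, rowvar=False) * (len(zd) - 1)
            + np.cov(zb, rowvar=False) * (len(zb) - 1)
        ) / (len(Z) - 2)
        S += np.eye(5) * (1e-6 * np.trace(S) / 5)
        w_ref = np.linalg.solve(S, zd.mean(0) - zb.mean(0))
        cos = (model.weights @ w_ref) / (
            np.linalg.norm(model.weights) * np.linalg.norm(w_ref)
        )
        assert cos >= 1 - 1e-9

    def test_affine_equivariance_via_standardization(self, rng):
        X, y = _gaussian_pair(rng)
        m1 = lda_train(X, y)
        X2 = X.copy()
        X2[:, 2] = X2[:, 2] * 37.5 - 4.0
        m2 = lda_train(X2, y)
        np.testing.assert_allclose(
            m1.predict_scores(X), m2.predict_scores(X2), atol=1e-9
        )

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="both classes"):
            lda_train(X, [D] * 20)

    def test_persistence_round_trip(self, rng, tmp_path):
        X, y = _gaussian_pair(rng)
        model = lda_train(X, y)
        path = tmp_path / "model.json"
        path.write_text(model.to_json())
        loaded = load_model(path.read_text())
        np.testing.assert_array_equal(
            model.predict_scores(X), loaded.predict_scores(X)
        )


class TestNeuralNet:
    def test_xor_trains_to_zero_errors_with_rprop(self):
        net = NeuralNet.initialize((5, 10, 5, 2), seed=1)
        trained, log = nn_train(
            net, XOR_X, XOR_Y, XOR_X, XOR_Y,
            TrainConfig(max_epochs=1000, patience=1000),
        )
        assert [p.label for p in trained.predict(XOR_X)] == XOR_Y

    def test_linearly_separable_set_reaches_mcc_one(self, rng):
        X, y = _gaussian_pair(rng, n_d=120, n_b=80, sep=6.0)
        net = NeuralNet.initialize((5, 10, 5, 2), seed=3)
        trained, log = nn_train(net, X, y, X, y, TrainConfig())
        assert log.best_val_mcc == 1.0

    def test_stdbp_also_learns_a_separable_problem(self, rng):
        X, y = _gaussian_pair(rng, n_d=60, n_b=60, sep=6.0)
        net = NeuralNet.initialize((5, 10, 5, 2), seed=2)
        trained, log = nn_train(
            net, X, y, X, y,
            TrainConfig(algorithm="stdbp", learning_rate=0.05, max_epochs=500),
        )
        assert log.best_val_mcc == 1.0

    def test_same_seed_gives_bitwise_identical_training(self, rng):
        X, y = _gaussian_pair(rng, sep=1.0)
        runs = []
        for _ in range(2):
            net = NeuralNet.initialize((5, 10, 5, 2), seed=9)
            trained, log = nn_train(net, X, y, X, y, TrainConfig(max_epochs=50,
                                                                patience=50))
            runs.append((trained, tuple(log.sse)))
        assert runs[0][1] == runs[1][1]
        for W1, W2 in zip(runs[0][0].weights, runs[1][0].weights):
            np.testing.assert_array_equal(W1, W2)

    def test_rprop_step_sizes_stay_within_bounds(self, rng):
        X, y = _gaussian_pair(rng, sep=0.5)
        cfg = TrainConfig(max_epochs=200, patience=200)
        net = NeuralNet.initialize((5, 10, 5, 2), seed=4)
        _, log = nn_train(net, X, y, X, y, cfg)
        assert min(log.step_min) >= cfg.delta_min
        assert max(log.step_max) <= cfg.delta_max

    def test_feature_count_mismatch_is_a_shape_error(self):
        net = NeuralNet.initialize((5, 10, 5, 2), seed=0)
        with pytest.raises(ValueError, match="expected 5"):
            net.raw_outputs(np.zeros((3, 4)))

    def test_persistence_round_trip(self, rng, tmp_path):
        X, y = _gaussian_pair(rng, sep=2.0)
        net = NeuralNet.initialize((5, 10, 5, 2), seed=6)
        trained, _ = nn_train(net, X, y, X, y, TrainConfig(max_epochs=40,
                                                           patience=40))
        loaded = load_model(trained.to_json())
        np.testing.assert_array_equal(
            trained.predict_scores(X), loaded.predict_scores(X)
        )


class TestScoreNormalization:
    def test_tie_scores_half_and_calls_deleterious(self):
        assert Prediction.from_score(0.5).label == D

    def test_output_normalization_is_monotone_in_deleterious_node(self):
        o_ben = 0.37
        scores = [o / (o + o_ben) for o in np.linspace(0.01, 0.99, 50)]
        assert all(b > a for a, b in zip(scores, scores[1:]))
        assert scores[-1] <= 1.0


class TestConsensus:
    def _preds(self, labels):
        return [Prediction(1.0 if l == D else 0.0, l) for l in labels]

    def test_majority_examples(self):
        votes = [[Prediction(1.0 if c == "D" else 0.0, D if c == "D" else B)]
                 for c in "DDBBD"]
        assert consensus(votes, "majority") == [D]

    def test_union_vs_majority(self):
        votes = [[Prediction(1.0, D) if c == "D" else Prediction(0.0, B)]
                 for c in "BBD"]
        assert consensus(votes, "union") == [D]
        assert consensus(votes, "majority") == [B]

    def test_even_split_breaks_deleterious(self):
        votes = [[Prediction(1.0, D)], [Prediction(0.0, B)]]
        assert consensus(votes, "majority") == [D]

    def test_matches_hand_tally_on_fixture(self, rng):
        """Five CV-fold prediction sets over 20 rows vs a by-hand vote."""
        fold_calls = rng.random((5, 20)) > 0.5
        preds = [
            [Prediction(1.0 if c else 0.0, D if c else B) for c in row]
            for row in fold_calls
        ]
        expected = [
            D if sum(col) * 2 >= 5 else B for col in fold_calls.T
        ]
        assert consensus(preds, "majority") == expected
        expected_union = [D if any(col) else B for col in fold_calls.T]
        assert consensus(preds, "union") == expected_union

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            consensus([[Prediction(1.0, D)], [Prediction(1.0, D)] * 2])
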