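import numpy as np
import pytest

from smilesaug.errors import ConfigError
from smilesaug.model import (
    EncodedDataset,
    ModelConfig,
    TrainConfig,
    TrainedModel,
    _fit_one,
    aggregate_by_molecule,
    build_model,
    make_folds,
    predict,
    train_cv,
)
from smilesaug.nn.autodiff import Tensor, bce_with_logits_loss, mse_loss

SMALL = dict(conv_kernel=3, conv_channels=8, rnn_hidden=12, dense_units=16, dropout_rate=0.0)


class TestBuildModel:
    def test_cnn_rnn_parameter_count_closed_form(self):
        config = ModelConfig(variant="cnn_rnn", gate="gru", **SMALL)
        max_len, vocab, n_out = 37, 9, 1
        net = build_model(config, (max_len, vocab), n_out, "regression")
        k, c, h, d = 3, 8, 12, 16
        expected = (
            k * vocab * c + c                     # convolution
            + 3 * (c * h + h * h + h)             # GRU gates
            + h * d + d                           # dense
            + d * n_out + n_out                   # head
        )
        assert net.n_parameters() == expected

    def test_lstm_has_four_gates(self):
        gru = build_model(ModelConfig(variant="rnn1", gate="gru", **SMALL), (10, 5), 1, "regression")
        lstm = build_model(ModelConfig(variant="rnn1", gate="lstm", **SMALL), (10, 5), 1, "regression")
        h, v = 12, 5
        assert lstm.n_parameters() - gru.n_parameters() == (v * h + h * h + h)

    def test_rnn2_adds_exactly_one_recurrent_layer(self):
        one = build_model(ModelConfig(variant="rnn1", gate="gru", **SMALL), (10, 5), 1, "regression")
        two = build_model(ModelConfig(variant="rnn2", gate="gru", **SMALL), (10, 5), 1, "regression")
        h = 12
        assert two.n_parameters() - one.n_parameters() == 3 * (h * h + h * h + h)

    def test_single_task_regression_output_dimension(self):
        net = build_model(ModelConfig(variant="rnn1", gate="gru", **SMALL), (10, 5), 1, "regression")
        out = net.forward(np.zeros((4, 10, 5)))
        assert out.data.shape == (4, 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(variant="transformer")
        with pytest.raises(ConfigError):
            ModelConfig(dropout_rate=1.0)


class TestGradients:
    @pytest.mark.parametrize("variant,gate", [("rnn1", "gru"), ("rnn2", "lstm"), ("cnn_rnn", "gru")])
    def test_backprop_matches_finite_differences(self, variant, gate, rng):
        config = ModelConfig(variant=variant, gate=gate, conv_kernel=3,
                             conv_channels=4, rnn_hidden=5, dense_units=6,
                             dropout_rate=0.0)
        net = build_model(config, (6, 4), 2, "regression", seed=3)
        X = rng.random((3, 6, 4))
        y = rng.random((3, 2))
        loss = mse_loss(net.forward(X), y)
        loss.backward()
        for param in net.parameters():
            flat, grad = param.data.ravel(), param.grad.ravel()
            for idx in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps, orig = 1e-6, flat[idx]
                flat[idx] = orig + eps
                up = mse_loss(net.forward(X), y).data
                flat[idx] = orig - eps
                down = mse_loss(net.forward(X), y).data
                flat[idx] = orig
                assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-6)

    def test_bce_gradient_is_sigmoid_minus_target(self, rng):
        logits = Tensor(rng.normal(size=(5, 1)), requires_grad=True)
        y = rng.integers(0, 2, size=(5, 1)).astype(float)
        loss = bce_with_logits_loss(logits, y)
        loss.backward()
        prob = 1 / (1 + np.exp(-logits.data))
        assert logits.grad == pytest.approx((prob - y) / 5)


class TestFolds:
    def test_folds_partition_parents_without_leakage(self):
        parents = np.repeat(np.arange(23), 4)
        folds = make_folds(parents, 5, seed=0)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(23))
        for i in range(len(folds)):
            for j in range(i + 1, len(folds)):
                assert not set(folds[i]) & set(folds[j])

    def test_same_seed_same_folds(self):
        parents = np.arange(31)
        first = make_folds(parents, 4, seed=9)
        second = make_folds(parents, 4, seed=9)
        assert all((a == b).all() for a, b in zip(first, second))

    def test_fewer_parents_than_folds_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(np.arange(3), 5, seed=0)


@pytest.fixture(scope="module")
def cv_runs(encoded_regression_dataset):
    dataset, spec = encoded_regression_dataset
    model_config = ModelConfig(variant="cnn_rnn", gate="gru", **SMALL)
    train_config = TrainConfig(epochs=10, batch_size=32, n_folds=3,
                               early_stopping_patience=10, seed=5,
                               task="regression")
    return train_cv(dataset, model_config, train_config, encoding_spec=spec)


@pytest.fixture(scope="module")
def classification_model():
    # separable toy: class = which input channel fires
    rng = np.random.default_rng(2)
    n, t, v = 60, 8, 3
    X = np.zeros((n, t, v))
    y = rng.integers(0, 2, size=(n, 1)).astype(float)
    for i in range(n):
        X[i, :, int(y[i, 0])] = 1.0
    dataset = EncodedDataset(X, y, np.arange(n), np.zeros(n, dtype=int), ["active"])
    config = TrainConfig(epochs=80, batch_size=16, n_folds=2, seed=2,
                         early_stopping_patience=80, task="classification")
    runs = train_cv(dataset, ModelConfig(variant="rnn1", gate="gru", **SMALL), config)
    return runs[0].model, dataset


class TestTraining:
    def test_training_loss_decreases(self, cv_runs):
        for run in cv_runs:
            history = run.model.history
            assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_beats_mean_predictor_at_molecule_level(self, cv_runs, encoded_regression_dataset):
        dataset, _ = encoded_regression_dataset
        label_sd = float(np.std(dataset.y[dataset.variant_index == 0]))
        mean_rmse = np.mean([run.metrics["rmse"] for run in cv_runs])
        assert mean_rmse < label_sd

    def test_no_molecule_leaks_across_folds(self, cv_runs):
        for i, a in enumerate(cv_runs):
            for b in cv_runs[i + 1 :]:
                assert not set(a.test_parent_ids) & set(b.test_parent_ids)

    def test_early_stopping_restores_best_validation_weights(self, encoded_regression_dataset):
        dataset, _ = encoded_regression_dataset
        rng = np.random.default_rng(0)
        parents = np.unique(dataset.parent_ids)
        val_mask = np.isin(dataset.parent_ids, parents[:6])
        train_set = dataset.subset(~val_mask)
        val_set = dataset.subset(val_mask)
        config = TrainConfig(epochs=8, batch_size=32, n_folds=2, seed=1,
                             early_stopping_patience=8, task="regression")
        net = build_model(ModelConfig(variant="rnn1", gate="gru", **SMALL),
                          dataset.X.shape[1:], 1, "regression", seed=1)
        weights, history = _fit_one(net, train_set, val_set, config, rng)
        net.set_weights(weights)
        restored_val = mse_loss(net.forward(val_set.X), val_set.y).data
        assert restored_val == pytest.approx(history.val_loss.min(), rel=1e-9)

    def test_same_seed_identical_fold_assignment(self, encoded_regression_dataset):
        dataset, _ = encoded_regression_dataset
        a = make_folds(dataset.parent_ids, 3, seed=5)
        b = make_folds(dataset.parent_ids, 3, seed=5)
        assert all((x == y).all() for x, y in zip(a, b))


class TestPredict:
    def test_duplicate_inputs_get_identical_scores(self, classification_model):
        model, dataset = classification_model
        X = np.repeat(dataset.X[:1], 2, axis=0)
        scores = predict(model, X)
        assert (scores[0] == scores[1]).all()

    def test_classification_scores_bounded(self, classification_model):
        model, dataset = classification_model
        scores = predict(model, dataset)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_trained_model_separates_the_classes(self, classification_model):
        model, dataset = classification_model
        scores = predict(model, dataset).ravel()
        pos, neg = scores[dataset.y.ravel() == 1], scores[dataset.y.ravel() == 0]
        assert pos.mean() > neg.mean()

    def test_shape_mismatch_rejected(self, classification_model):
        model, dataset = classification_model
        with pytest.raises(ConfigError):
            predict(model, np.zeros((2, 5, 7)))


class TestAggregateByMolecule:
    def test_single_variant_identity(self):
        parents, scores = aggregate_by_molecule(np.array([3, 1, 2]), np.array([0.3, 0.1, 0.2]))
        assert parents.tolist() == [1, 2, 3]
        assert scores.ravel().tolist() == [0.1, 0.2, 0.3]

    def test_mean_over_variants(self):
        parents, scores = aggregate_by_molecule(np.array([7, 7]), np.array([0.2, 0.4]))
        assert parents.tolist() == [7]
        assert scores.ravel()[0] == pytest.approx(0.3)

    def test_mean_of_equal_scores_is_that_score(self):
        _, scores = aggregate_by_molecule(np.array([1, 1, 1]), np.array([0.5, 0.5, 0.5]))
        assert scores.ravel()[0] == 0.5

    def test_empty_input_is_an_error(self):
        with pytest.raises(ConfigError):
            aggregate_by_molecule(np.array([]), np.array([]))
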