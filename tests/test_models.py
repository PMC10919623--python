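"""Model architecture contracts, training behavior, prediction properties."""

import numpy as np
import pytest

from wearsite.models import (ModelConfig, SequenceClassifier, build_model,
                             predict, run_experiment_grid, train)
from wearsite.nn.layers import (Bidirectional, Conv1D, Dense, Dropout, LSTM,
                                MaxPool1D)
from wearsite.windowing import split

from tests.conftest import toy_window_set


class TestArchitecture:
    def test_lstm_has_three_learnable_layers(self):
        net = build_model(ModelConfig(architecture="lstm", task="site2"))
        learnable = [l for l in net.layers if l.params]
        assert len(learnable) == 3
        assert isinstance(learnable[0], LSTM)
        assert isinstance(learnable[1], Dense)
        assert learnable[1].activation == "relu"
        assert isinstance(learnable[2], Dense)

    def test_bilstm_layer_order(self):
        net = build_model(ModelConfig(architecture="bilstm", task="site3"))
        types = [type(l) for l in net.feature_layers]
        assert types == [Conv1D, MaxPool1D, Bidirectional, LSTM, LSTM]
        head = [type(l) for l in net.head_layers]
        assert head == [Dense, Dropout, Dense]

    def test_output_width_matches_task(self):
        for task, k in (("site2", 2), ("site3", 3), ("intensity4", 4)):
            net = build_model(ModelConfig(task=task))
            assert net.head_layers[-1].params["W"].shape[1] == k

    def test_covariates_widen_dense_input_by_three(self):
        base = build_model(ModelConfig(architecture="lstm", task="intensity4"))
        cov = build_model(ModelConfig(architecture="lstm", task="intensity4",
                                      use_covariates=True))
        w0 = base.head_layers[0].params["W"].shape[0]
        w1 = cov.head_layers[0].params["W"].shape[0]
        assert w1 == w0 + 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture="transformer")
        with pytest.raises(ValueError):
            ModelConfig(task="site5")
        with pytest.raises(ValueError):
            ModelConfig(epochs=0)


@pytest.fixture(scope="module")
def toy_split():
    full = toy_window_set(500, seed=0)
    return split(full, 0.9, seed=1)


class TestTraining:
    def test_learns_linearly_separable_toy_set(self, toy_split):
        """A mean-threshold oracle scores 1.0 on this construction; the
        network must reach at least 0.95 validation accuracy."""
        tr, va = toy_split
        oracle = (va.windows[:, :, 0].mean(axis=1) > 0)
        oracle_labels = np.where(oracle, "hip", "wrist")
        assert (oracle_labels == va.site).mean() == 1.0
        cfg = ModelConfig(architecture="lstm", task="site2", epochs=5, seed=2)
        model = train(build_model(cfg), tr, va, cfg)
        assert model.final_val_accuracy >= 0.95

    def test_training_is_deterministic_given_seed(self, toy_split):
        tr, va = toy_split
        cfg = ModelConfig(architecture="lstm", task="site2", epochs=2, seed=5)
        m1 = train(build_model(cfg), tr, va, cfg)
        m2 = train(build_model(cfg), tr, va, cfg)
        assert m1.history == m2.history
        for l1, l2 in zip(m1.network.layers, m2.network.layers):
            for k in l1.params:
                assert np.array_equal(l1.params[k], l2.params[k])

    def test_label_shuffle_gives_chance_accuracy(self):
        """Shuffled labels on featureless windows are unlearnable, so
        validation accuracy sits at chance.  (Windows must carry no class
        signal: with a separable feature, training on shuffled labels can
        still align with truth by amplifying the sampled label imbalance
        within each feature cluster.)"""
        full = toy_window_set(500, seed=4, separation=0.0)
        tr, va = split(full, 0.9, seed=1)
        rng = np.random.default_rng(0)
        shuffled = tr.subset(np.arange(len(tr)))
        shuffled.site = rng.permutation(shuffled.site)
        cfg = ModelConfig(architecture="lstm", task="site2", epochs=3, seed=3)
        model = train(build_model(cfg), shuffled, va, cfg)
        assert abs(model.final_val_accuracy - 0.5) <= 0.1

    def test_history_length_equals_epochs(self, toy_split):
        tr, va = toy_split
        cfg = ModelConfig(architecture="lstm", task="site2", epochs=4, seed=1)
        model = train(build_model(cfg), tr, va, cfg)
        for series in model.history.values():
            assert len(series) == 4

    def test_single_class_training_rejected(self, toy_split):
        tr, va = toy_split
        mono = tr.subset(np.where(tr.site == "hip")[0])
        cfg = ModelConfig(architecture="lstm", task="site2", epochs=1)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), mono, va, cfg)


@pytest.fixture(scope="module")
def fitted(toy_split):
    tr, va = toy_split
    cfg = ModelConfig(architecture="lstm", task="site2", epochs=3, seed=2)
    return train(build_model(cfg), tr, va, cfg), va


class TestPredict:
    def test_probability_rows_sum_to_one(self, fitted):
        model, va = fitted
        probs, _ = predict(model, va.windows)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(probs >= 0)

    def test_duplicated_window_gets_identical_rows(self, fitted):
        model, va = fitted
        dup = np.repeat(va.windows[:1], 3, axis=0)
        probs, labels = predict(model, dup)
        assert np.allclose(probs[0], probs[1]) and np.allclose(probs[0],
                                                               probs[2])
        assert labels[0] == labels[1] == labels[2]

    def test_argmax_tie_breaks_to_lowest_class_index(self):
        assert np.argmax(np.array([0.5, 0.5])) == 0  # contract we rely on

    def test_shape_mismatch_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="windows"):
            predict(model, np.zeros((2, 50, 3), dtype=np.float32))


class TestExperimentGrid:
    def test_grid_layout_and_filters(self, cohort_windows):
        profiles, full = cohort_windows
        cfg = ModelConfig(epochs=1, recurrent_units=4, dense_units=4,
                          conv_filters=2, batch_size=256)
        rng = np.random.default_rng(0)
        sub = full.subset(rng.choice(len(full), 600, replace=False))
        grid = run_experiment_grid(
            sub, profiles, seed=1, base_config=cfg,
            architectures=("lstm",), groups=("adult", "combined"),
            purposes=("wear_site", "intensity_covariates"),
            scopes=("two_site",))
        assert len(grid) == 2 * 2 * 1 * 1
        assert set(grid.purpose) == {"wear_site", "intensity_covariates"}
        adult_rows = grid[grid.group == "adult"]
        assert (adult_rows.n_windows < grid[grid.group == "combined"]
                .n_windows.values).all()
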