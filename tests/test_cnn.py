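"""Architecture contract, sizing arithmetic and training behavior of the CNN."""

import numpy as np
import pytest

from netage import nn
from netage.cnn import (
    ArchSpec,
    SizingError,
    TrainedCnn,
    TrainingConfig,
    build_cnn,
    feature_map_shape,
    parameter_count,
    predict_cnn,
    train_cnn,
)


class TestFeatureMapShape:
    @pytest.mark.parametrize(
        "dims,stacks,expect",
        [
            ((121, 145, 121), 5, (3, 4, 3)),
            ((16, 16, 16), 4, (1, 1, 1)),
            ((32, 48, 32), 5, (1, 1, 1)),
            ((10, 10, 10), 0, (10, 10, 10)),
        ],
    )
    def test_floor_halving(self, dims, stacks, expect):
        assert feature_map_shape(dims, stacks) == expect

    @pytest.mark.parametrize("dims", [(8, 8, 8), (16, 16, 16)])
    def test_collapse_raises(self, dims):
        # 8: 8->4->2->1->0 at stack 4; 16: the fifth pool halves 1 to 0
        with pytest.raises(SizingError):
            feature_map_shape(dims, 5)


class TestArchitecture:
    def test_default_channel_schedule_doubles_from_eight(self):
        arch = ArchSpec()
        assert arch.channel_schedule == (8, 16, 32, 64, 128)

    def test_layer_ordering_per_stack(self):
        arch = ArchSpec(input_dims=(32, 32, 32), base_channels=4)
        model = build_cnn(arch, seed=0)
        stack_types = [type(x) for x in model.layers[:6]]
        assert stack_types == [
            nn.Conv3d, nn.ReLU, nn.Conv3d, nn.BatchNorm3d, nn.ReLU,
            nn.MaxPool3d,
        ]
        # five stacks, then flatten and three fully connected layers
        assert len(model.layers) == 5 * 6 + 1 + 5
        fc = [l for l in model.layers if isinstance(l, nn.Linear)]
        assert len(fc) == 3
        assert fc[-1].n_out == 1

    def test_conv_biases_zero_and_bn_identity_at_init(self):
        model = build_cnn(ArchSpec(input_dims=(32, 32, 32), base_channels=4),
                          seed=0)
        for layer in model.layers:
            if isinstance(layer, nn.Conv3d):
                assert (layer.b.value == 0).all()
            if isinstance(layer, nn.BatchNorm3d):
                assert (layer.gamma.value == 1).all()
                assert (layer.beta.value == 0).all()

    def test_too_small_input_raises_at_arch_construction(self):
        with pytest.raises(SizingError):
            ArchSpec(input_dims=(8, 8, 8), n_stacks=5)

    def test_default_arch_accepts_full_grid_batch(self):
        """The published input grid (121 x 145 x 121) maps to one scalar."""
        arch = ArchSpec(input_dims=(121, 145, 121), base_channels=1,
                        fc_widths=(4, 2))
        model = build_cnn(arch, seed=0)
        x = np.zeros((2, 121, 145, 121, 1), dtype=np.float32)
        out = model.forward(x, train=False)
        assert out.shape == (2, 1)


class TestParameterCount:
    def test_first_conv_closed_form(self):
        # one stack, one input channel, 8 output: 27*1*8 + 8 = 224 for conv1
        arch = ArchSpec(input_dims=(4, 4, 4), n_stacks=1, base_channels=8,
                        fc_widths=(2, 2))
        conv1 = 27 * 1 * 8 + 8
        assert conv1 == 224
        model = build_cnn(arch, seed=0)
        assert model.layers[0].w.value.size + model.layers[0].b.value.size == 224

    def test_closed_form_equals_introspection_oracle(self):
        for arch in (
            ArchSpec(input_dims=(32, 32, 32), base_channels=4),
            ArchSpec(input_dims=(16, 16, 16), n_stacks=3, base_channels=8,
                     fc_widths=(10, 5)),
            ArchSpec(input_dims=(121, 145, 121), base_channels=8),
        ):
            model = build_cnn(arch, seed=0)
            assert parameter_count(arch) == model.n_parameters()

    def test_zero_channels_invalid(self):
        with pytest.raises(ValueError):
            ArchSpec(input_dims=(32, 32, 32), base_channels=0)


class TestLearningRateSchedule:
    def test_step_decay_every_ten_epochs(self):
        cfg = TrainingConfig()
        assert cfg.lr_at(0) == pytest.approx(0.01)
        assert cfg.lr_at(9) == pytest.approx(0.01)
        assert cfg.lr_at(10) == pytest.approx(0.001)
        assert cfg.lr_at(25) == pytest.approx(0.0001)

    def test_one_time_decay_mode(self):
        cfg = TrainingConfig(lr_decay_mode="once")
        assert cfg.lr_at(9) == pytest.approx(0.01)
        assert cfg.lr_at(10) == pytest.approx(0.001)
        assert cfg.lr_at(40) == pytest.approx(0.001)


class TestTraining:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_problem():
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 90, 64)
        x = np.zeros((64, 8, 8, 8), dtype=np.float32)
        # mean intensity carries the age signal
        x += 1.0 - 0.01 * (ages[:, None, None, None] - 54)
        x += 0.05 * rng.standard_normal(x.shape).astype(np.float32)
        arch = ArchSpec(input_dims=(8, 8, 8), n_stacks=2, base_channels=2,
                        fc_widths=(8, 4))
        return x, ages.astype(np.float32), arch

    def test_loss_decreases_on_learnable_signal(self, tiny_problem):
        x, ages, arch = tiny_problem
        cfg = TrainingConfig(epochs=30, seed=1)
        trained = train_cnn(build_cnn(arch, seed=1), x, ages, cfg, arch)
        assert trained.history[-1]["train_mae"] < trained.history[0]["train_mae"]

    def test_zero_epochs_returns_initialized_model(self, tiny_problem):
        x, ages, arch = tiny_problem
        cfg = TrainingConfig(epochs=0, seed=1)
        model = build_cnn(arch, seed=1)
        before = [p.value.copy() for p in model.params]
        trained = train_cnn(model, x, ages, cfg, arch)
        assert trained.history == []
        for b, p in zip(before, trained.model.params):
            np.testing.assert_array_equal(b, p.value)

    def test_nan_ages_rejected_before_training(self, tiny_problem):
        x, ages, arch = tiny_problem
        bad = ages.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_cnn(build_cnn(arch, seed=1), x, bad,
                      TrainingConfig(epochs=1), arch)

    def test_training_is_bit_reproducible(self, tiny_problem):
        x, ages, arch = tiny_problem
        cfg = TrainingConfig(epochs=3, seed=9)
        t1 = train_cnn(build_cnn(arch, seed=9), x, ages, cfg, arch)
        t2 = train_cnn(build_cnn(arch, seed=9), x, ages, cfg, arch)
        for p1, p2 in zip(t1.model.params, t2.model.params):
            np.testing.assert_array_equal(p1.value, p2.value)
        assert t1.history == t2.history


class TestPrediction:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained_tiny():
        rng = np.random.default_rng(2)
        arch = ArchSpec(input_dims=(8, 8, 8), n_stacks=2, base_channels=2,
                        fc_widths=(8, 4))
        x = rng.random((40, 8, 8, 8)).astype(np.float32)
        ages = rng.uniform(18, 90, 40).astype(np.float32)
        trained = train_cnn(build_cnn(arch, seed=0), x, ages,
                            TrainingConfig(epochs=2, seed=0), arch)
        return trained, x

    def test_duplicate_inputs_get_identical_predictions(self, trained_tiny):
        trained, x = trained_tiny
        batch = np.stack([x[0], x[0], x[1]])
        pred = predict_cnn(trained, batch)
        assert pred[0] == pred[1]

    def test_prediction_independent_of_batch_composition(self, trained_tiny):
        trained, x = trained_tiny
        whole = predict_cnn(trained, x[:8], batch_size=8)
        single = np.array(
            [predict_cnn(trained, x[i : i + 1], batch_size=1)[0] for i in range(8)]
        )
        np.testing.assert_allclose(whole, single, atol=1e-5)

    def test_untrained_model_outputs_finite(self):
        arch = ArchSpec(input_dims=(8, 8, 8), n_stacks=2, base_channels=2,
                        fc_widths=(8, 4))
        model = build_cnn(arch, seed=5)
        x = np.random.default_rng(0).random((4, 8, 8, 8)).astype(np.float32)
        assert np.isfinite(predict_cnn(model, x, arch=arch)).all()

    def test_shape_mismatch_raises(self, trained_tiny):
        trained, _ = trained_tiny
        with pytest.raises(ValueError, match="images must be"):
            predict_cnn(trained, np.zeros((2, 9, 8, 8), dtype=np.float32))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(4)
        arch = ArchSpec(input_dims=(8, 8, 8), n_stacks=2, base_channels=2,
                        fc_widths=(8, 4))
        x = rng.random((20, 8, 8, 8)).astype(np.float32)
        ages = rng.uniform(18, 90, 20).astype(np.float32)
        trained = train_cnn(build_cnn(arch, seed=0), x, ages,
                            TrainingConfig(epochs=2, seed=0), arch)
        trained.save(tmp_path / "model")
        back = TrainedCnn.load(tmp_path / "model")
        np.testing.assert_allclose(
            predict_cnn(trained, x), predict_cnn(back, x), atol=1e-6
        )
        assert back.history == trained.history
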