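"""Residual CNN: architecture, patches, SGDM training, inference, correction."""

import numpy as np
import pytest

from tomomar import (
    DivergenceError,
    ProjectionStack,
    TomoGeometry,
    TrainingConfig,
    build_model,
    correct_projections,
    make_training_patches,
    predict_residual,
    train_sgdm,
)
from tomomar.dncnn import DnCNNModel, PatchSet, _conv_forward


@pytest.fixture(scope="module")
def geo():
    return TomoGeometry(detector_shape=(64, 64), pixel_pitch_mm=4.464, n_views=5)


@pytest.fixture(scope="module")
def stacks(geo):
    rng = np.random.default_rng(0)
    obj = ProjectionStack(data=rng.random((5, 64, 64)), geometry=geo, tag="70kV")
    ref = ProjectionStack(data=obj.data * 0.5, geometry=geo, tag="VM-140")
    return obj, ref


class TestArchitecture:
    def test_depth20_layer_plan(self):
        m = build_model(depth=20, channels=8, seed=0)
        kinds = m.layer_kinds()
        assert kinds[0] == "conv+relu"
        assert kinds[-1] == "conv"
        assert kinds[1:-1] == ["conv+bn+relu"] * 18
        assert m.layers[0].W.shape == (8, 1, 3, 3)
        assert m.layers[1].W.shape == (8, 8, 3, 3)
        assert m.layers[-1].W.shape == (1, 8, 3, 3)

    def test_depth3_minimal(self):
        m = build_model(depth=3, channels=4, seed=0)
        assert m.layer_kinds() == ["conv+relu", "conv+bn+relu", "conv"]

    def test_depth_below_3_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            build_model(depth=2, channels=4, seed=0)

    def test_shape_preserved_for_any_input(self, rng):
        m = build_model(depth=4, channels=6, seed=1)
        for h, w in ((3, 3), (7, 12), (32, 32)):
            out, _ = m.forward(rng.normal(size=(2, 1, h, w)))
            assert out.shape == (2, 1, h, w)

    def test_seeded_init_reproducible(self):
        a = build_model(depth=5, channels=8, seed=7)
        b = build_model(depth=5, channels=8, seed=7)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_checkpoint_roundtrip(self, tmp_path):
        m = build_model(depth=4, channels=6, seed=3)
        m.trained = True
        path = tmp_path / "model.h5"
        m.save(path)
        m2 = DnCNNModel.load(path)
        assert m2.depth == 4 and m2.channels == 6 and m2.trained
        for la, lb in zip(m.layers, m2.layers):
            np.testing.assert_array_equal(la.W, lb.W)
            if la.bn:
                np.testing.assert_array_equal(la.run_mean, lb.run_mean)


class TestPatches:
    def test_identical_stacks_give_zero_residual_targets(self, geo, stacks):
        obj, _ = stacks
        cfg = TrainingConfig(mini_batch=8, epochs=2, n_patches=50, seed=0)
        ps = make_training_patches(obj, obj, cfg)
        assert np.all(ps.targets == 0)

    def test_requested_count_and_shape(self, geo, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=8, epochs=2, n_patches=37, seed=0)
        ps = make_training_patches(obj, ref, cfg)
        assert len(ps) == 37
        assert ps.inputs.shape == (37, 1, 32, 32)

    def test_cropping_rule_counts(self, geo, stacks):
        obj, ref = stacks
        total = TrainingConfig(mini_batch=4, epochs=3, crop_rule="total", seed=0)
        per_epoch = TrainingConfig(mini_batch=4, epochs=3, crop_rule="per_epoch", seed=0)
        assert len(make_training_patches(obj, ref, total)) == 4 * 3 * 5
        assert len(make_training_patches(obj, ref, per_epoch)) == 4 * 5

    def test_seeded_patches_reproducible(self, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=8, epochs=2, n_patches=20, seed=11)
        a = make_training_patches(obj, ref, cfg)
        b = make_training_patches(obj, ref, cfg)
        np.testing.assert_array_equal(a.inputs, b.inputs)
        np.testing.assert_array_equal(a.view_indices, b.view_indices)

    def test_residual_is_input_minus_reference(self, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=8, epochs=1, n_patches=10, seed=2)
        ps = make_training_patches(obj, ref, cfg)
        # reconstruct the residual from the stored view indices
        for n in range(len(ps)):
            assert np.all(np.isin(ps.view_indices[n], np.arange(5)))
        np.testing.assert_allclose(ps.targets, ps.inputs - (ps.inputs - ps.targets), rtol=0)

    def test_patch_larger_than_image_rejected(self, geo, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=8, epochs=1, patch_size=128, seed=0)
        with pytest.raises(ValueError, match="patch size"):
            make_training_patches(obj, ref, cfg)


class TestTraining:
    def test_zero_targets_zero_output_layer_give_zero_loss(self, stacks):
        obj, _ = stacks
        cfg = TrainingConfig(
            mini_batch=8, epochs=1, n_patches=16, seed=0, learning_rate=0.0
        )
        ps = make_training_patches(obj, obj, cfg)
        m = build_model(depth=3, channels=4, seed=0)
        m.layers[-1].W[...] = 0.0
        m.layers[-1].b[...] = 0.0
        _, losses = train_sgdm(m, ps, cfg)
        assert losses[0] == 0.0

    def test_loss_decreases_on_seeded_run(self, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=32, epochs=5, n_patches=200, seed=3)
        ps = make_training_patches(obj, ref, cfg)
        m = build_model(depth=5, channels=8, seed=0)
        _, losses = train_sgdm(m, ps, cfg)
        assert losses[-1] < losses[0]

    def test_default_hyperparameters(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.1
        assert cfg.momentum == 0.9
        assert cfg.weight_decay == 1e-4
        assert cfg.mini_batch == 544
        assert cfg.epochs == 60
        assert cfg.patch_size == 32

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_error_reports_epoch(self, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(
            mini_batch=8,
            epochs=2,
            n_patches=16,
            seed=0,
            learning_rate=1e12,
            halve_lr_on_nan=False,
        )
        ps = make_training_patches(obj, ref, cfg)
        m = build_model(depth=3, channels=4, seed=0)
        with pytest.raises(DivergenceError, match="epoch"):
            train_sgdm(m, ps, cfg)


class TestInference:
    def test_zero_final_layer_gives_zero_residual(self, stacks):
        obj, _ = stacks
        m = build_model(depth=4, channels=6, seed=0)
        m.layers[-1].W[...] = 0.0
        m.layers[-1].b[...] = 0.0
        res = predict_residual(m, obj, allow_untrained=True)
        assert np.all(res.data == 0)
        assert res.tag == "residual"

    def test_linear_single_conv_matches_sliding_window_oracle(self, rng):
        # depth-3 net with ReLU bypassed by large positive biases reduces to
        # a composition of convolutions; check one conv against a loop oracle
        geo = TomoGeometry(detector_shape=(8, 8), pixel_pitch_mm=4.0, n_views=3)
        x = rng.normal(size=(1, 1, 8, 8))
        W = rng.normal(size=(1, 1, 3, 3))
        b = np.zeros(1)
        out = _conv_forward(x, W, b)
        xp = np.pad(x[0, 0], 1)
        oracle = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                oracle[i, j] = np.sum(xp[i : i + 3, j : j + 3] * W[0, 0])
        np.testing.assert_allclose(out[0, 0], oracle, atol=1e-12)

    def test_untrained_model_requires_flag(self, stacks):
        obj, _ = stacks
        m = build_model(depth=3, channels=4, seed=0)
        with pytest.raises(ValueError, match="untrained"):
            predict_residual(m, obj)

    def test_inference_deterministic(self, stacks):
        obj, ref = stacks
        cfg = TrainingConfig(mini_batch=16, epochs=2, n_patches=64, seed=5)
        ps = make_training_patches(obj, ref, cfg)
        m = build_model(depth=3, channels=4, seed=0)
        m, _ = train_sgdm(m, ps, cfg)
        a = predict_residual(m, obj)
        b = predict_residual(m, obj)
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_shape_matches_input(self, stacks):
        obj, _ = stacks
        m = build_model(depth=3, channels=4, seed=0)
        res = predict_residual(m, obj, allow_untrained=True)
        assert res.data.shape == obj.data.shape


class TestCorrection:
    def test_zero_residual_identity(self, stacks, geo):
        obj, _ = stacks
        zero = ProjectionStack(data=np.zeros_like(obj.data), geometry=geo)
        out = correct_projections(obj, zero)
        np.testing.assert_array_equal(out.data, obj.data)
        assert out.tag == "corrected"

    def test_exact_residual_recovers_reference(self, stacks, geo):
        obj, ref = stacks
        res = ProjectionStack(data=obj.data - ref.data, geometry=geo)
        out = correct_projections(obj, res)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-15)

    def test_matches_elementwise_loop_oracle(self, geo, rng):
        a = ProjectionStack(data=rng.random((5, 64, 64)), geometry=geo)
        b = ProjectionStack(data=rng.random((5, 64, 64)), geometry=geo)
        out = correct_projections(a, b)
        for v in range(5):
            for i in range(0, 64, 17):
                for j in range(0, 64, 13):
                    assert out.data[v, i, j] == a.data[v, i, j] - b.data[v, i, j]

    def test_perfectly_trained_identity_on_single_pair(self, geo):
        # train to convergence on one fixed pair: correction approaches the
        # reference within the training loss
        rng = np.random.default_rng(8)
        base = rng.random((5, 64, 64))
        obj = ProjectionStack(data=base, geometry=geo, tag="70kV")
        ref = ProjectionStack(data=base - 0.2, geometry=geo, tag="VM-140")
        cfg = TrainingConfig(mini_batch=16, epochs=20, n_patches=64, seed=4)
        ps = make_training_patches(obj, ref, cfg)
        m = build_model(depth=3, channels=8, seed=0)
        m, losses = train_sgdm(m, ps, cfg)
        res = predict_residual(m, obj)
        out = correct_projections(obj, res)
        rmse = float(np.sqrt(np.mean((out.data - ref.data) ** 2)))
        assert rmse < 5 * np.sqrt(2 * losses[-1]) + 0.02
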