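"""Shallow CNN classifier: architecture, augmentation, training, persistence."""

import dataclasses

import numpy as np
import pytest

from dropsort.classifier import (
    AugmentParams,
    ModelLoadError,
    TrainConfig,
    ViabilityCNN,
    build_cnn,
    augment,
    cross_validate,
    load_model,
    normalize_crops,
)
from dropsort.cnn import ShallowCNN, weighted_bce


class TestArchitecture:
    @pytest.mark.parametrize("conv,fc", [(4, 32), (32, 128)])
    def test_canonical_specs(self, conv, fc):
        spec = build_cnn(conv, fc)
        assert spec.name == f"CNN-{conv}/{fc}"
        assert spec.input_shape == (55, 55, 1)
        assert spec.n_conv_layers == 2
        layers = spec.layers()
        assert sum("conv" in l for l in layers) == 2
        assert sum("maxpool" in l for l in layers) == 2
        assert sum("dense" in l for l in layers) == 2  # hidden FC + sigmoid out
        assert "sigmoid" in layers[-1]

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(0, 32)
        with pytest.raises(ValueError):
            ShallowCNN(4, 0)

    def test_zero_weights_give_half_probability(self):
        net = ShallowCNN(4, 32, seed=0)
        for k in net.params:
            net.params[k] = np.zeros_like(net.params[k])
        p = net.predict_proba(np.random.default_rng(0).uniform(size=(3, 55, 55, 1)))
        np.testing.assert_allclose(p, 0.5)


class TestAugment:
    CROP = np.arange(55.0 * 55).reshape(55, 55) / (55 * 55)

    def test_all_off_is_identity(self):
        off = AugmentParams(False, False, False, 0, 0.0)
        out = augment(self.CROP, off, np.random.default_rng(0))
        np.testing.assert_array_equal(out, self.CROP)

    def test_hflip_is_involution(self):
        flipped = self.CROP[:, ::-1]
        np.testing.assert_array_equal(flipped[:, ::-1], self.CROP)

    def test_shift_composition_restores_interior(self):
        params = AugmentParams(False, False, False, 0, 0.0)
        # manual shifts: +2 then -2 along rows restores all interior content
        shifted = np.full_like(self.CROP, np.median(self.CROP))
        shifted[2:, :] = self.CROP[:-2, :]
        back = np.full_like(self.CROP, np.median(self.CROP))
        back[:-2, :] = shifted[2:, :]
        np.testing.assert_array_equal(back[:-2, :], self.CROP[:-2, :])

    def test_output_always_55(self):
        params = AugmentParams()
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert augment(self.CROP, params, rng).shape == (55, 55)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((54, 54)), AugmentParams(), np.random.default_rng(0))

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValueError):
            AugmentParams(max_shift_px=9)


class TestClassWeights:
    def test_default_weights_mean_one(self):
        crops = np.zeros((10, 55, 55))
        labels = ["viable"] * 3 + ["dead"] * 7
        model = ViabilityCNN(crops, labels)
        w = model.class_weights(TrainConfig())
        assert w.mean() == pytest.approx(1.0)
        assert w[0] == pytest.approx(10 / 6) and w[-1] == pytest.approx(10 / 14)

    def test_weighted_loss_of_calibrated_constant_matches_balanced_unweighted(self):
        # with w_c = N/(2 N_c), a constant predictor's weighted loss equals its
        # unweighted loss on a balanced set: -(log p + log(1-p))/2
        p = 0.3
        logit = np.log(p / (1 - p))
        y = np.array([1.0] * 2 + [0.0] * 8)
        w = np.where(y == 1, 10 / 4, 10 / 16)
        weighted = weighted_bce(np.full((10, 1), logit), y, w)
        balanced = -(np.log(p) + np.log(1 - p)) / 2
        assert weighted == pytest.approx(balanced, rel=1e-12)


class TestTraining:
    def test_single_class_rejected(self):
        crops = np.zeros((6, 55, 55))
        with pytest.raises(ValueError):
            ViabilityCNN(crops, ["viable"] * 6)

    def test_history_and_iterations_bookkeeping(self, small_dataset):
        manifest, crops = small_dataset
        model = ViabilityCNN(crops, manifest["label"].to_numpy(),
                             split=manifest["split"].to_numpy())
        res = model.fit(TrainConfig(epochs=3, batch_size=16, seed=0))
        assert len(res.history) == 3
        assert set(res.history.columns) == {"epoch", "train_loss", "val_loss"}
        assert res.provenance["n_train"] + res.provenance["n_val"] == len(crops)

    def test_deterministic_given_seed(self, small_dataset):
        manifest, crops = small_dataset
        labels = manifest["label"].to_numpy()
        probe = crops[:8]
        runs = []
        for _ in range(2):
            model = ViabilityCNN(crops, labels, split=manifest["split"].to_numpy())
            res = model.fit(TrainConfig(epochs=2, seed=5))
            runs.append((res.history.copy(), res.predict(probe)))
        assert runs[0][0].equals(runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_predictions_in_unit_interval(self, trained_model, bench_dataset):
        _, crops = bench_dataset
        p = trained_model.predict(crops[:32])
        assert np.all(np.isfinite(p)) and np.all((0 <= p) & (p <= 1))

    def test_separable_classes_get_separated(self, trained_model, bench_dataset):
        manifest, crops = bench_dataset
        y = manifest["label"].to_numpy() == "viable"
        p = trained_model.predict(crops)
        assert p[y].mean() > p[~y].mean()

    def test_wrong_crop_size_rejected(self, trained_model):
        with pytest.raises(ValueError):
            trained_model.predict(np.zeros((2, 54, 54)))

    def test_normalization_maps_background_to_half(self):
        x = normalize_crops(np.array([[[-600.0, 0.0, 600.0]]]))
        np.testing.assert_allclose(x.ravel(), [0.0, 0.5, 1.0])


class TestPersistence:
    def test_save_load_roundtrip_bitwise(self, trained_model, bench_dataset, tmp_path):
        _, crops = bench_dataset
        probe = crops[:16]
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = load_model(path)
        np.testing.assert_array_equal(trained_model.predict(probe), loaded.predict(probe))
        assert loaded.spec == trained_model.spec
        assert loaded.provenance["train_config"] == trained_model.provenance["train_config"]
        assert loaded.provenance["normalization"] == trained_model.provenance["normalization"]

    def test_truncated_file_raises_load_error(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_garbage_file_raises_load_error(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a model container")
        with pytest.raises(ModelLoadError):
            load_model(path)


class TestCrossValidation:
    def test_folds_partition_dataset(self, small_dataset):
        manifest, crops = small_dataset
        df = cross_validate(
            build_cnn(2, 8), crops, manifest["label"].to_numpy(), k=5,
            cfg=TrainConfig(epochs=1, seed=0),
        )
        folds = df[df["fold"] != "mean"]
        assert len(folds) == 5
        assert folds["n_val"].sum() == len(crops)  # union covers, disjoint by count
        assert folds["n_val"].tolist() == [len(crops) // 5] * 5
        mean_row = df[df["fold"] == "mean"].iloc[0]
        assert mean_row["ACC"] == pytest.approx(folds["ACC"].mean())

    def test_k_larger_than_dataset_rejected(self):
        crops = np.zeros((4, 55, 55))
        with pytest.raises(ValueError):
            cross_validate(build_cnn(2, 8), crops, ["viable", "dead"] * 2, k=10)

    def test_separable_data_reaches_high_mean_auc(self, bench_dataset):
        manifest, crops = bench_dataset
        sub = np.arange(120)
        df = cross_validate(
            build_cnn(4, 32), crops[sub], manifest["label"].to_numpy()[sub], k=3,
            cfg=TrainConfig(epochs=10, seed=2),
        )
        assert df[df["fold"] == "mean"].iloc[0]["AUC"] >= 0.95
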