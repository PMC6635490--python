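"""3-D U-net: architecture contracts, gradients, training behaviour."""

import numpy as np
import pytest

from deepdose import PatchIndex, PatchSet, TrainConfig, UNetConfig, Volume, build_unet, make_folds, predict, train
from deepdose.network import l1_loss

VOXEL = (2.67, 2.67, 5.0)


def constant_patchset(rng, n=32, dims=(8, 8, 8)):
    pet = np.abs(rng.normal(1.0, 0.3, size=(n,) + dims))
    ct = rng.normal(0.0, 300.0, size=(n,) + dims)
    dose = 2.0 * pet
    idx = [PatchIndex((0, 0, 0), dims)] * n
    return PatchSet(idx, pet, ct, dose)


class TestArchitecture:
    def test_feature_widths_double_then_halve(self):
        model = build_unet(UNetConfig(base_features=14, depth=4))
        down_widths = [b.layers[0].w.shape[0] for b in model.down_blocks]
        assert down_widths == [14, 28, 56, 112]
        up_widths = [b.layers[0].w.shape[0] for b in model.up_blocks]
        assert up_widths == [56, 28, 14]

    def test_parameter_count_deterministic(self):
        a = build_unet(UNetConfig(base_features=6, depth=3, seed=0))
        b = build_unet(UNetConfig(base_features=6, depth=3, seed=99))
        assert a.parameter_count() == b.parameter_count()

    def test_minimal_network_hand_counted(self):
        # depth 1, base 1, 2 input channels:
        #   conv 3x3x3 (2->1): 54 + 1 bias; BN: 2; conv 3x3x3 (1->1): 27 + 1; BN: 2
        #   final conv 1x1x1 (1->1): 1 + 1
        model = build_unet(UNetConfig(in_channels=2, base_features=1, depth=1))
        assert model.parameter_count() == 54 + 1 + 2 + 27 + 1 + 2 + 1 + 1

    @pytest.mark.parametrize("base,depth,dims", [
        (2, 1, (4, 4, 4)), (3, 2, (6, 6, 4)), (4, 3, (16, 16, 8)), (2, 4, (16, 16, 8)),
    ])
    def test_output_shape_matches_input(self, base, depth, dims, rng):
        model = build_unet(UNetConfig(2, base, depth, seed=1))
        x = rng.normal(size=(2, 2) + dims)
        y = model.forward(x)
        assert y.shape == (2, 1) + dims

    def test_indivisible_patch_dims_rejected(self, rng):
        model = build_unet(UNetConfig(2, 2, depth=4))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.normal(size=(1, 2, 20, 20, 10)))

    def test_save_load_round_trip(self, rng, tmp_path):
        model = build_unet(UNetConfig(2, 3, 2, seed=5))
        model.scales = {"pet": 2.0, "ct": 1000.0, "dose": 0.5}
        x = rng.normal(size=(1, 2, 8, 8, 8))
        y1 = model.forward(x)
        model.save(tmp_path / "m.npz")
        loaded = type(model).load(tmp_path / "m.npz")
        np.testing.assert_array_equal(loaded.forward(x), y1)
        assert loaded.scales == model.scales


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        model = build_unet(UNetConfig(2, 2, 2, seed=0))
        x = rng.normal(size=(2, 2, 4, 4, 4))
        y = rng.normal(size=(2, 1, 4, 4, 4))
        pred = model.forward(x, train=True)
        _, dpred = l1_loss(pred, y)
        model.backward(dpred)
        eps = 1e-6
        for layer in model._all_layers():
            for (name, p), g in zip(layer.params(), layer.grads()):
                idx = tuple(0 for _ in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = l1_loss(model.forward(x, train=True), y)[0]
                p[idx] = orig - eps
                lm = l1_loss(model.forward(x, train=True), y)[0]
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(g[idx], rel=1e-3, abs=1e-7), (
                    f"{type(layer).__name__}.{name}")

    def test_loss_scale_equivariance(self, rng):
        pred = rng.normal(size=(2, 1, 4, 4, 4))
        target = rng.normal(size=(2, 1, 4, 4, 4))
        base, _ = l1_loss(pred, target)
        scaled, _ = l1_loss(3.0 * pred, 3.0 * target)
        assert scaled == pytest.approx(3.0 * base)


class TestTraining:
    def test_memorization_drives_loss_down(self, rng):
        # one identical input->target pair repeated: loss must collapse
        ps = constant_patchset(rng, n=32)
        ps.pet[:] = ps.pet[0]
        ps.ct[:] = ps.ct[0]
        ps.dose[:] = ps.dose[0]
        model = build_unet(UNetConfig(2, 4, 2, seed=1))
        history = train(model, ps, TrainConfig(lr=3e-3, batch_size=4, epochs=10, seed=1))
        # L1 training converges slowly near its non-smooth optimum; assert a
        # strong sustained decrease rather than an absolute floor
        assert np.mean(history[-8:]) < 0.25 * np.mean(history[:8])

    def test_deterministic_history(self, rng):
        ps = constant_patchset(rng, n=16)
        cfg = TrainConfig(lr=1e-3, batch_size=4, epochs=2, seed=7)
        h1 = train(build_unet(UNetConfig(2, 2, 2, seed=3)), ps, cfg)
        h2 = train(build_unet(UNetConfig(2, 2, 2, seed=3)), ps, cfg)
        assert h1 == h2

    def test_empty_patchset_rejected(self):
        ps = PatchSet([], np.empty((0, 0, 0, 0)), np.empty((0, 0, 0, 0)),
                      np.empty((0, 0, 0, 0)))
        with pytest.raises(ValueError, match="non-empty"):
            train(build_unet(UNetConfig()), ps, TrainConfig())

    def test_zero_activity_input_predicts_near_zero(self, rng):
        # a third of the training patches are all-zero (air); a trained net
        # must map zero activity to near-zero dose rate.  Tested without batch
        # normalisation: BN running statistics keep a small constant offset on
        # fully out-of-distribution all-zero inputs.
        ps = constant_patchset(rng, n=48)
        ps.pet[:16] = 0.0
        ps.dose[:16] = 0.0
        ps.ct[:16] = 0.0
        model = build_unet(UNetConfig(2, 4, 2, batch_norm=False, seed=2))
        train(model, ps, TrainConfig(lr=3e-3, batch_size=4, epochs=30, seed=2))
        pet = Volume(np.zeros((8, 8, 8)), VOXEL, "Bq/mL")
        ct = Volume(np.zeros((8, 8, 8)), VOXEL, "HU")
        rate = predict(model, pet, ct, (8, 8, 8))
        assert rate.data.max() < 1e-3 * ps.dose.max()

    def test_predict_requires_scales(self, rng):
        model = build_unet(UNetConfig(2, 2, 2))
        pet = Volume(np.zeros((8, 8, 8)), VOXEL, "Bq/mL")
        ct = Volume(np.zeros((8, 8, 8)), VOXEL, "HU")
        with pytest.raises(ValueError, match="scaling constants"):
            predict(model, pet, ct, (8, 8, 8))

    def test_predict_covers_whole_volume(self, rng):
        ps = constant_patchset(rng, n=8)
        model = build_unet(UNetConfig(2, 2, 2, seed=0))
        train(model, ps, TrainConfig(batch_size=4, epochs=1, seed=0))
        pet = Volume(np.abs(rng.normal(size=(20, 12, 10))), VOXEL, "Bq/mL")
        ct = Volume(np.zeros((20, 12, 10)), VOXEL, "HU")
        rate = predict(model, pet, ct, (8, 8, 8))  # dims not multiples of 8
        assert rate.shape == (20, 12, 10)
        assert np.isfinite(rate.data).all()


class TestCrossValidation:
    def test_each_dataset_tested_exactly_once(self, rng):
        from deepdose import crossvalidate
        from deepdose.volumes import DoseMap

        dims = (8, 8, 8)
        datasets = []
        for i in range(4):
            pet = np.abs(rng.normal(1.0, 0.2, size=dims))
            dose = 2.0 * pet
            patches = PatchSet([PatchIndex((0, 0, 0), dims)] * 8,
                               np.repeat(pet[None], 8, axis=0),
                               np.zeros((8,) + dims),
                               np.repeat(dose[None], 8, axis=0))
            datasets.append({
                "pet": Volume(pet, VOXEL, "Bq/mL"),
                "ct": Volume(np.zeros(dims), VOXEL, "HU"),
                "reference": DoseMap(dose, VOXEL, "Gy/s"),
                "patches": patches,
            })
        table = crossvalidate(datasets, UNetConfig(2, 2, 2, seed=0),
                              TrainConfig(batch_size=4, epochs=2, seed=0),
                              k=2, patch_dims=dims)
        assert sorted(table["dataset"]) == [0, 1, 2, 3]
        assert set(table["fold"]) == {0, 1}
        assert (table["mean_voxel_pct_err"] >= 0).all()


class TestFolds:
    def test_ten_datasets_five_folds(self):
        folds = make_folds(10, 5, seed=1)
        assert all(len(f) == 2 for f in folds)
        tested = np.concatenate(folds)
        assert sorted(tested.tolist()) == list(range(10))

    def test_leave_one_out(self):
        folds = make_folds(5, 5, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 5)

    def test_seeded_reproducible(self):
        a = make_folds(10, 5, seed=42)
        b = make_folds(10, 5, seed=42)
        assert all((x == y).all() for x, y in zip(a, b))
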