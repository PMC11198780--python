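import json

import numpy as np
import pytest

from cephalo3d.hourglass3d import NetworkConfig
from cephalo3d.imaging_io import LandmarkSet, Volume
from cephalo3d.phantom import generate_case, toy8_spec
from cephalo3d.training_inference import (
    Checkpoint,
    TrainConfig,
    TrainingError,
    augment,
    bce_loss,
    predict,
    train,
)


def _identity_cfg(**overrides) -> TrainConfig:
    from dataclasses import replace

    return replace(TrainConfig().without_augmentation(), **overrides)


@pytest.fixture
def blob_volume(rng):
    """A 24^3 1.6 mm volume with a Gaussian blob and its centre landmark."""
    shape = (24, 24, 24)
    center = np.array([19.2, 20.8, 17.6])
    ax = [np.arange(n) * 1.6 for n in shape]
    g = np.meshgrid(*ax, indexing="ij")
    d2 = sum((gi - ci) ** 2 for gi, ci in zip(g, center))
    data = np.exp(-d2 / (2 * 3.0**2)) + 0.01 * rng.normal(size=shape)
    vol = Volume(data, spacing=(1.6, 1.6, 1.6))
    lms = LandmarkSet({"P": center}, ("P",))
    return vol, lms


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(crop_max_fraction=1.0)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)

    def test_without_augmentation_zeroes_every_range(self):
        cfg = TrainConfig().without_augmentation()
        assert cfg.crop_max_fraction == 0.0
        assert cfg.rotation_range == (0.0, 0.0)
        assert cfg.translation_range == (0.0, 0.0)
        assert cfg.elastic_max_displacement == 0.0
        assert cfg.contrast_range == (1.0, 1.0)
        assert cfg.brightness_range == (0.0, 0.0)


class TestAugment:
    def test_zero_ranges_exact_identity(self, blob_volume, rng):
        vol, lms = blob_volume
        avol, alms = augment(vol, lms, rng, _identity_cfg())
        np.testing.assert_array_equal(avol.data, vol.data)
        np.testing.assert_array_equal(avol.origin, vol.origin)
        np.testing.assert_array_equal(alms.get("P"), lms.get("P"))

    def test_rotation_moves_landmark_by_analytic_formula(self, blob_volume, rng):
        vol, lms = blob_volume
        cfg = _identity_cfg(rotation_range=(10.0, 10.0))  # fixed 10 deg on each axis
        avol, alms = augment(vol, lms, rng, cfg)
        from cephalo3d.training_inference import _rotation_matrix

        rot = _rotation_matrix(np.radians([10.0, 10.0, 10.0]))
        center = vol.voxel_to_world((np.array(vol.shape) - 1) / 2.0)
        expected = rot @ (lms.get("P") - center) + center
        np.testing.assert_allclose(alms.get("P"), expected, atol=1e-9)

    def test_rotated_image_peak_follows_landmark(self, blob_volume, rng):
        vol, lms = blob_volume
        cfg = _identity_cfg(rotation_range=(12.0, 12.0))
        avol, alms = augment(vol, lms, rng, cfg)
        peak_world = avol.voxel_to_world(
            np.unravel_index(np.argmax(avol.data), avol.shape)
        )
        assert np.linalg.norm(peak_world - alms.get("P")) < 1.6 * np.sqrt(3)

    def test_translation_is_pure_shift(self, blob_volume, rng):
        vol, lms = blob_volume
        cfg = _identity_cfg(translation_range=(0.05, 0.05))
        avol, alms = augment(vol, lms, rng, cfg)
        extent = (np.array(vol.shape) - 1) * vol.spacing
        np.testing.assert_allclose(alms.get("P"), lms.get("P") + 0.05 * extent, atol=1e-9)

    def test_crop_is_contiguous_window_with_correct_origin(self, blob_volume):
        vol, lms = blob_volume
        cfg = _identity_cfg(crop_max_fraction=0.5)
        found_smaller = False
        for trial in range(20):
            avol, alms = augment(vol, lms, np.random.default_rng(trial), cfg)
            shape = avol.shape
            lo = np.round(vol.world_to_voxel(avol.origin)).astype(int)
            window = vol.data[
                lo[0] : lo[0] + shape[0], lo[1] : lo[1] + shape[1], lo[2] : lo[2] + shape[2]
            ]
            np.testing.assert_array_equal(avol.data, window)
            if alms.is_present("P"):
                np.testing.assert_allclose(alms.get("P"), lms.get("P"), atol=1e-9)
                assert avol.contains_world(alms.get("P"))
            else:
                assert not avol.contains_world(lms.get("P"))
            found_smaller |= shape != vol.shape
        assert found_smaller

    def test_contrast_brightness_affine_in_intensity(self, blob_volume, rng):
        vol, lms = blob_volume
        cfg = _identity_cfg(contrast_range=(1.2, 1.2), brightness_range=(0.1, 0.1))
        avol, _ = augment(vol, lms, rng, cfg)
        m, s = vol.data.mean(), vol.data.std()
        np.testing.assert_allclose(avol.data, 1.2 * (vol.data - m) + m + 0.1 * s, atol=1e-9)

    def test_elastic_transports_landmarks_consistently(self, blob_volume):
        vol, lms = blob_volume
        cfg = _identity_cfg(elastic_max_displacement=1.5)
        for trial in range(5):
            avol, alms = augment(vol, lms, np.random.default_rng(trial), cfg)
            if not alms.is_present("P"):
                continue
            peak_world = avol.voxel_to_world(
                np.unravel_index(np.argmax(avol.data), avol.shape)
            )
            assert np.linalg.norm(peak_world - alms.get("P")) < 2 * 1.6 * np.sqrt(3)

    def test_geometry_image_agreement_through_heatmap_codec(self, blob_volume):
        # encoding the transformed landmarks on the transformed grid and
        # decoding again must reproduce the transformed coordinates
        from cephalo3d.heatmap_codec import GridGeometry, decode, encode

        vol, lms = blob_volume
        cfg = _identity_cfg(rotation_range=(8.0, 8.0), translation_range=(0.02, 0.02))
        avol, alms = augment(vol, lms, np.random.default_rng(11), cfg)
        geom = GridGeometry(avol.shape, np.asarray(avol.spacing), np.asarray(avol.origin))
        decoded, _ = decode(encode(alms, geom))
        np.testing.assert_allclose(decoded.get("P"), alms.get("P"), atol=0.8)

    def test_deterministic_given_rng_state(self, blob_volume):
        vol, lms = blob_volume
        cfg = TrainConfig()
        a = augment(vol, lms, np.random.default_rng(5), cfg)
        b = augment(vol, lms, np.random.default_rng(5), cfg)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        for lid in a[1].present_ids():
            np.testing.assert_array_equal(a[1].get(lid), b[1].get(lid))


class TestBCELoss:
    def _stack(self, maps, mask):
        from cephalo3d.heatmap_codec import GridGeometry, HeatmapStack

        maps = np.asarray(maps, dtype=np.float32)
        geom = GridGeometry(maps.shape[1:], np.full(3, 1.6), np.zeros(3))
        ids = tuple(f"L{i}" for i in range(maps.shape[0]))
        return HeatmapStack(maps, geom, ids, np.asarray(mask, dtype=bool))

    def test_uniform_half_against_zero_target_is_ln2(self):
        pred = self._stack(np.full((2, 4, 4, 4), 0.5), [True, True])
        target = self._stack(np.zeros((2, 4, 4, 4)), [True, True])
        assert bce_loss(pred, target) == pytest.approx(np.log(2.0), rel=1e-6)

    def test_perfect_prediction_is_tiny(self):
        t = np.zeros((1, 4, 4, 4))
        t[0, 1, 1, 1] = 1.0
        assert bce_loss(self._stack(t, [True]), self._stack(t, [True])) < 1e-5

    def test_matches_explicit_loop_oracle(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(3, 3, 3, 3))
        target = rng.uniform(0, 1, size=(3, 3, 3, 3))
        mask = [True, False, True]
        got = bce_loss(self._stack(pred, mask), self._stack(target, mask))
        total, count = 0.0, 0
        for c in (0, 2):  # explicit double-loop oracle over unmasked channels
            for p, t in zip(pred[c].ravel(), target[c].ravel()):
                total += -(t * np.log(p) + (1 - t) * np.log(1 - p))
                count += 1
        assert got == pytest.approx(total / count, rel=1e-6)

    def test_masked_channel_is_ignored(self, rng):
        pred_a = rng.uniform(0.1, 0.9, size=(2, 4, 4, 4))
        pred_b = pred_a.copy()
        pred_b[1] = rng.uniform(0.1, 0.9, size=(4, 4, 4))  # differs only when masked
        target = np.zeros((2, 4, 4, 4))
        mask = [True, False]
        a = bce_loss(self._stack(pred_a, mask), self._stack(target, mask))
        b = bce_loss(self._stack(pred_b, mask), self._stack(target, mask))
        assert a == b

    def test_all_masked_raises(self):
        z = np.zeros((2, 4, 4, 4))
        with pytest.raises(TrainingError, match="masked"):
            bce_loss(self._stack(z, [False, False]), self._stack(z, [False, False]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bce_loss(
                self._stack(np.zeros((1, 4, 4, 4)), [True]),
                self._stack(np.zeros((1, 8, 8, 8)), [True]),
            )


class TestTrainPredict:
    def _sets(self, n_train=3, n_val=1):
        spec = toy8_spec(seed=5)
        cases = [generate_case(spec, i) for i in range(n_train + n_val)]
        return cases[:n_train], cases[n_train:]

    def _tc(self, **over):
        base = dict(seed=0, learning_rate=0.003, max_epochs=3, patience=3, min_peak=0.0)
        base.update(over)
        return _identity_cfg(**base)

    def test_out_channel_schema_mismatch(self, toy_net_config):
        train_set, val_set = self._sets()
        bad = NetworkConfig(
            out_channels=5, stem_features=8, block_features=(8, 8, 16), gn_groups=4, depth=2
        )
        with pytest.raises(ValueError, match="out_channels"):
            train(train_set, val_set, bad, self._tc())

    def test_empty_validation_rejected(self, toy_net_config):
        train_set, _ = self._sets()
        with pytest.raises(ValueError, match="validation"):
            train(train_set, [], toy_net_config, self._tc())

    def test_loss_decreases_and_log_is_written(self, toy_net_config, tmp_path):
        train_set, val_set = self._sets()
        log = tmp_path / "log.jsonl"
        ckpt = train(train_set, val_set, toy_net_config, self._tc(max_epochs=4), log_path=log)
        rows = [json.loads(line) for line in log.read_text().splitlines()]
        assert len(rows) == 4
        assert rows[-1]["loss"] < rows[0]["loss"]
        assert np.isfinite(ckpt.best_val_distance)

    def test_training_is_bitwise_deterministic(self, toy_net_config):
        train_set, val_set = self._sets(2, 1)
        tc = self._tc(max_epochs=2)
        a = train(train_set, val_set, toy_net_config, tc)
        b = train(train_set, val_set, toy_net_config, tc)
        np.testing.assert_array_equal(
            a.network.parameter_vector(), b.network.parameter_vector()
        )
        assert a.best_val_distance == b.best_val_distance

    def test_checkpoint_round_trip_and_predict_determinism(self, toy_net_config, tmp_path):
        train_set, val_set = self._sets(2, 1)
        ckpt = train(train_set, val_set, toy_net_config, self._tc(max_epochs=1))
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        back = Checkpoint.load(path)
        assert back.schema_ids == ckpt.schema_ids
        assert back.train_config == ckpt.train_config
        assert back.best_val_distance == ckpt.best_val_distance
        vol, _ = val_set[0]
        p1, c1 = predict(ckpt, vol)
        p2, c2 = predict(back, vol)
        assert c1 == c2
        for lid in p1.present_ids():
            np.testing.assert_array_equal(p1.get(lid), p2.get(lid))

    def test_predict_pads_odd_sized_volume(self, toy_net_config):
        train_set, val_set = self._sets(2, 1)
        ckpt = train(train_set, val_set, toy_net_config, self._tc(max_epochs=1))
        vol, _ = val_set[0]
        odd = Volume(vol.data[:41, :43, :45], vol.spacing, vol.origin)
        lms, conf = predict(ckpt, odd)
        assert set(conf) == set(ckpt.schema_ids)
        for lid in lms.present_ids():
            assert np.all(np.isfinite(lms.get(lid)))

    def test_max_epochs_zero_returns_untrained_baseline(self, toy_net_config):
        from cephalo3d.hourglass3d import Network

        train_set, val_set = self._sets(1, 1)
        ckpt = train(train_set, val_set, toy_net_config, self._tc(max_epochs=0))
        assert ckpt.best_epoch == -1
        assert np.isfinite(ckpt.best_val_distance)
        fresh = Network(toy_net_config)
        np.testing.assert_array_equal(
            ckpt.network.parameter_vector(), fresh.parameter_vector()
        )

    def test_single_volume_overfit_localizes_within_two_voxels(self):
        from cephalo3d.phantom import PhantomSpec

        spec = PhantomSpec(
            landmark_ids=("P1", "P2", "P3"),
            template_positions={
                "P1": np.array([12.0, 14.0, 16.0]),
                "P2": np.array([22.0, 20.0, 12.0]),
                "P3": np.array([16.0, 24.0, 22.0]),
            },
            grid_size=(24, 24, 24),
            spacing=1.6,
            seed=3,
        )
        case = generate_case(spec, 0)
        net_cfg = NetworkConfig(
            out_channels=3, stem_features=8, block_features=(8, 8, 16),
            gn_groups=4, depth=2, seed=0,
        )
        tc = self._tc(learning_rate=0.01, max_epochs=200, patience=200)
        baseline = train([case], [case], net_cfg, self._tc(max_epochs=0))
        ckpt = train([case], [case], net_cfg, tc)
        assert ckpt.best_val_distance < baseline.best_val_distance
        lms, _ = predict(ckpt, case[0])
        for lid in case[1].present_ids():
            assert lms.is_present(lid)
            err = np.linalg.norm(lms.get(lid) - case[1].get(lid))
            assert err <= 2 * spec.spacing  # within two voxels

    def test_max_epochs_zero_with_unusable_baseline_raises(self, toy_net_config):
        train_set, val_set = self._sets(1, 1)
        # default min_peak 0.1: the untrained network detects nothing
        tc = _identity_cfg(seed=0, max_epochs=0)
        with pytest.raises(TrainingError):
            train(train_set, val_set, toy_net_config, tc)
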