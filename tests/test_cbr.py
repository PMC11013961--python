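import dataclasses

import numpy as np
import pytest

from tasselcount.cbr import (
    CounterConfig,
    TrainingPatch,
    bootstrap_mae,
    build_density_map,
    extract_patches,
    load_model,
    predict_count,
    save_model,
    train_counter,
)
from tasselcount.core_io import PointAnnotation, RgbImage
from tasselcount.errors import ValidationError

FAST = CounterConfig(
    seed=9, max_epochs=2, widths=(4, 8, 8, 8), batch_size=64, learning_rate=1e-3
)


def zero_image(h, w):
    return RgbImage(np.zeros((h, w, 3), dtype=np.uint8), "z")


class ConstantModel:
    def __init__(self, k):
        self.k = k

    def predict_patches(self, x):
        return np.full(x.shape[0], self.k, dtype=float)


class TestDensityMap:
    def test_zero_points(self):
        dm = build_density_map(PointAnnotation("a", []), (30, 30), 8.0)
        assert dm.values.sum() == 0 and dm.source_points == 0

    def test_center_point_mass_and_peak(self):
        dm = build_density_map(PointAnnotation("a", [(50.0, 50.0)]), (100, 100), 8.0)
        assert dm.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(dm.values.argmax(), dm.values.shape) == (50, 50)

    def test_corner_kernel_renormalized(self):
        dm = build_density_map(
            PointAnnotation("a", [(0.0, 0.0), (50.0, 50.0)]), (100, 100), 8.0
        )
        assert dm.values.sum() == pytest.approx(2.0, abs=1e-6)

    def test_mass_conservation_random_point_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(0, 40))
            h, w = int(rng.integers(33, 90)), int(rng.integers(33, 90))
            pts = [
                (float(rng.uniform(0, h - 1e-9)), float(rng.uniform(0, w - 1e-9)))
                for _ in range(n)
            ]
            # force some boundary points
            if n >= 2:
                pts[0] = (0.0, 0.0)
                pts[1] = (float(h - 1), float(w - 1))
            dm = build_density_map(PointAnnotation("a", pts), (h, w), 8.0)
            assert abs(dm.values.sum() - n) < 1e-6

    def test_point_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            build_density_map(PointAnnotation("a", [(50.0, 5.0)]), (30, 30), 8.0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            build_density_map(PointAnnotation("a", []), (30, 30), 0.0)


class TestExtractPatches:
    def test_default_grid_on_64(self):
        dm = build_density_map(PointAnnotation("a", [(32.0, 32.0)]), (64, 64), 8.0)
        patches = extract_patches(zero_image(64, 64), dm, CounterConfig())
        assert len(patches) == 25

    def test_single_window_target_is_total_mass(self):
        dm = build_density_map(PointAnnotation("a", [(16.0, 16.0)]), (32, 32), 8.0)
        patches = extract_patches(zero_image(32, 32), dm, CounterConfig())
        assert len(patches) == 1
        assert patches[0].target == pytest.approx(1.0, abs=1e-6)

    def test_too_small_image_rejected(self):
        dm = build_density_map(PointAnnotation("a", []), (31, 64), 8.0)
        with pytest.raises(ValidationError):
            extract_patches(zero_image(31, 64), dm, CounterConfig())

    def test_patch_count_matches_offset_enumeration(self):
        """Patch counts equal brute-force enumeration of valid window offsets."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            h = int(rng.integers(32, 100))
            w = int(rng.integers(32, 100))
            stride = int(rng.integers(1, 17))
            cfg = CounterConfig(stride=stride)
            dm = build_density_map(PointAnnotation("a", []), (h, w), 8.0)
            patches = extract_patches(zero_image(h, w), dm, cfg)
            expected = sum(
                1
                for r in range(0, h + 1, stride)
                for c in range(0, w + 1, stride)
                if r + 32 <= h and c + 32 <= w
            )
            assert len(patches) == expected

    def test_targets_sum_over_footprint(self, small_scene):
        cfg = CounterConfig(stride=16)
        dm = build_density_map(small_scene.points, small_scene.image.shape, 8.0)
        patches = extract_patches(small_scene.image, dm, cfg)
        # check a few targets against direct slicing
        offs = [
            (r, c)
            for r in range(0, 128 - 31, 16)
            for c in range(0, 256 - 31, 16)
        ]
        for i in (0, len(offs) // 2, len(offs) - 1):
            r, c = offs[i]
            assert patches[i].target == pytest.approx(
                dm.values[r : r + 32, c : c + 32].sum(), abs=1e-9
            )


def noise_patches(n, target, seed=0):
    rng = np.random.default_rng(seed)
    return [
        TrainingPatch(rng.random((32, 32, 3)).astype(np.float32), target)
        for _ in range(n)
    ]


class TestTrainCounter:
    def test_constant_target_is_learned(self):
        """With every target equal to c, the trained model predicts ≈ c."""
        c = 3.0
        patches = noise_patches(200, c)
        cfg = dataclasses.replace(
            FAST, max_epochs=30, patience=30, learning_rate=1e-2
        )
        model = train_counter(patches, cfg)
        preds = model.predict_patches(
            np.stack([p.patch for p in noise_patches(50, c, seed=1)])
        )
        assert np.abs(preds - c).mean() < 0.2 * c

    def test_early_stopping_cuts_training_short(self):
        patches = noise_patches(100, 1.0)
        cfg = dataclasses.replace(FAST, max_epochs=50, patience=1)
        model = train_counter(patches, cfg)
        assert len(model.training_log) < 50

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            train_counter([], FAST)

    def test_training_is_deterministic(self):
        patches = noise_patches(80, 2.0)
        m1 = train_counter(patches, FAST)
        m2 = train_counter(patches, FAST)
        for a, b in zip(m1.net.get_state(), m2.net.get_state()):
            np.testing.assert_array_equal(a, b)

    def test_beats_constant_predictor_on_separable_patches(self, tiny_scenes):
        """Tassel vs. empty patches: validation L1 below the best constant."""
        cfg = dataclasses.replace(
            FAST, max_epochs=20, patience=20, learning_rate=3e-3, widths=(8, 16, 16, 16)
        )
        patches = []
        for s in tiny_scenes[:6]:
            dm = build_density_map(s.points, s.image.shape, cfg.bandwidth)
            patches.extend(extract_patches(s.image, dm, cfg))
        model = train_counter(patches, cfg)
        targets = np.array([p.target for p in patches])
        const_l1 = np.abs(targets - np.median(targets)).mean()
        assert model.training_log[-1]["val_l1"] < const_l1


class TestPredictCount:
    def test_zero_model_gives_zero(self):
        count, heatmap, _ = predict_count(ConstantModel(0.0), zero_image(64, 64), FAST)
        assert count == 0.0 and (heatmap == 0).all()

    def test_single_window_identity(self):
        count, _, _ = predict_count(
            ConstantModel(7.0), zero_image(32, 32), CounterConfig()
        )
        assert count == pytest.approx(7.0)

    def test_constant_model_matches_accumulator_simulation(self):
        """Prediction equals a brute-force simulation of redistribute-and-normalize."""
        cfg = CounterConfig()
        k = 5.0
        for h, w in ((64, 64), (40, 72), (32, 100)):
            count, heatmap, acc = predict_count(ConstantModel(k), zero_image(h, w), cfg)
            c_sum = np.zeros((h, w))
            visits = np.zeros((h, w))
            for r in range(0, h - 31, 8):
                for c in range(0, w - 31, 8):
                    c_sum[r : r + 32, c : c + 32] += k / 1024.0
                    visits[r : r + 32, c : c + 32] += 1
            expected = (c_sum[visits > 0] / visits[visits > 0]).sum()
            assert count == pytest.approx(expected, abs=1e-9)
            # the normalized heatmap is constant at k per window area
            assert heatmap[visits > 0] == pytest.approx(k / 1024.0)
            np.testing.assert_array_equal(acc.visit_count, visits)

    def test_negative_outputs_clamped(self):
        count, _, _ = predict_count(ConstantModel(-3.0), zero_image(64, 64), FAST)
        assert count == 0.0

    def test_window_sum_oracle_conserves_total_count(self, small_scene):
        """A model that returns each window's true density mass reproduces
        the image's total count through redistribution."""
        cfg = CounterConfig()
        dm = build_density_map(small_scene.points, small_scene.image.shape, 8.0)

        class OracleModel:
            def __init__(self):
                self.i = 0
                h, w = dm.values.shape
                self.sums = [
                    dm.values[r : r + 32, c : c + 32].sum()
                    for r in range(0, h - 31, 8)
                    for c in range(0, w - 31, 8)
                ]

            def predict_patches(self, x):
                out = np.array(self.sums[self.i : self.i + x.shape[0]])
                self.i += x.shape[0]
                return out

        # redistribution near borders (pixels covered by fewer windows) biases
        # the total slightly; conservation holds to ~10% at this image size
        count, _, _ = predict_count(OracleModel(), small_scene.image, cfg)
        assert count == pytest.approx(len(small_scene.points), rel=0.1)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            predict_count(ConstantModel(1.0), zero_image(16, 64), CounterConfig())


class TestPersistence:
    def test_save_load_round_trip_is_bit_exact(self, tmp_path):
        patches = noise_patches(60, 1.5)
        model = train_counter(patches, FAST)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = np.stack([p.patch for p in noise_patches(10, 0.0, seed=2)])
        np.testing.assert_array_equal(model.predict_patches(x), back.predict_patches(x))


class TestBootstrap:
    def test_degenerate_mode_has_zero_width(self, tiny_scenes):
        cfg = dataclasses.replace(FAST, max_epochs=1)
        patches = []
        for s in tiny_scenes[:3]:
            dm = build_density_map(s.points, s.image.shape, cfg.bandwidth)
            patches.extend(extract_patches(s.image, dm, cfg))
        imgs = [s.image for s in tiny_scenes[3:5]]
        truth = [len(s.points) for s in tiny_scenes[3:5]]
        mean, (lo, hi) = bootstrap_mae(
            patches, imgs, truth, cfg, n_replicates=2, resample=False
        )
        assert lo == pytest.approx(hi) and mean == pytest.approx(lo)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_mae(noise_patches(10, 1.0), [], [], FAST, n_replicates=1)
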