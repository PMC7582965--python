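"""Patch bookkeeping, normalization, training mechanics, tiled inference."""

import numpy as np
import pytest

from skinmpm.restore import (
    RestorationConfig,
    RestorationMetrics,
    Restorer,
    denormalize,
    evaluate,
    extract_patches,
    normalize,
    restore_image,
    split_train_val,
    ssim_pair,
    train_restorer,
)


def _smooth_field(rng, n):
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.normal(0, 1, (n, n)), 6.0) * 3.0 + 0.5


def _structured_field(rng, n):
    """Smooth background plus sharp bright disks: blurring must trade noise
    against edges, so a learned denoiser can beat it."""
    from scipy.ndimage import gaussian_filter

    base = gaussian_filter(rng.normal(0, 1, (n, n)), 5.0) * 2.0 + 0.5
    for _ in range(6):
        cy, cx = rng.integers(8, n - 8, 2)
        r = rng.integers(3, 7)
        yy, xx = np.ogrid[:n, :n]
        base[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] += 2.0
    return base


@pytest.fixture(scope="module")
def tiny_trained_model():
    """A noise-to-noise model trained on structured toy fields.

    Inputs and targets share the raw intensity scale, so inference in these
    tests passes ``normalized=True``.
    """
    rng = np.random.default_rng(0)
    clean = np.stack(
        [_structured_field(rng, 64) for _ in range(48)]
    ).astype(np.float32)
    noisy = (clean + rng.normal(0, 0.3, clean.shape)).astype(np.float32)
    noisy2 = (clean + rng.normal(0, 0.3, clean.shape)).astype(np.float32)
    cfg = RestorationConfig(
        patch_px=64, epochs=20, steps_per_epoch=15, batch_size=8,
        base_features=8, n_scales=2, seed=3,
    )
    train = (noisy[:40], noisy2[:40])
    val = (noisy[40:], noisy2[40:])
    return train_restorer(train, val, cfg), clean, noisy


class TestPatchBookkeeping:
    def test_grid_count_per_image(self):
        img = np.zeros((256, 256), dtype=np.float32)
        xs, ys = extract_patches([(img, img)], 64)
        assert len(xs) == 16  # 4x4 grid

    def test_patch_equals_image_single_crop(self):
        rng = np.random.default_rng(1)
        img = rng.random((64, 64))
        xs, ys = extract_patches([(img, img + 1)], 64)
        assert len(xs) == 1
        assert np.array_equal(xs[0], img)
        assert np.array_equal(ys[0], img + 1)

    def test_instrument_scale_bookkeeping(self):
        """One 1024x1024 pair yields 64 patches of 128 px; 550 pairs pool to
        35,200, split 10% into 3,520 validation / 31,680 training."""
        img = np.zeros((1024, 1024), dtype=np.float32)
        xs, _ = extract_patches([(img, img)], 128)
        per_image = len(xs)
        assert per_image == 64
        total = per_image * 550
        assert total == 35_200
        tr, va = split_train_val(np.arange(total), 0.10, seed=0)
        assert len(va) == 3_520
        assert len(tr) == 31_680

    def test_registration_preserved(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((128, 128)), rng.random((128, 128))
        xs, ys = extract_patches([(a, b)], 64, seed=5)
        for xp, yp in zip(xs, ys):
            found = False
            for y0 in range(0, 65, 64):
                for x0 in range(0, 65, 64):
                    if np.array_equal(xp, a[y0: y0 + 64, x0: x0 + 64]):
                        found = np.array_equal(yp, b[y0: y0 + 64, x0: x0 + 64])
            assert found

    def test_image_smaller_than_patch_raises(self):
        with pytest.raises(ValueError):
            extract_patches([(np.zeros((32, 32)), np.zeros((32, 32)))], 64)


class TestSplit:
    @pytest.mark.parametrize("n,n_val", [(10, 1), (101, 10), (35_200, 3_520)])
    def test_floor_split_sizes(self, n, n_val):
        tr, va = split_train_val(np.arange(n), 0.10, seed=1)
        assert len(va) == n_val and len(tr) == n - n_val

    def test_disjoint_and_exhaustive(self):
        tr, va = split_train_val(np.arange(100), 0.25, seed=2)
        assert sorted(np.concatenate([tr, va])) == list(range(100))

    def test_too_few_patches(self):
        with pytest.raises(ValueError):
            split_train_val(np.arange(1))


class TestNormalize:
    def test_percentiles_map_to_unit_interval(self):
        rng = np.random.default_rng(0)
        img = rng.random((200, 200)) * 50 + 7
        out, params = normalize(img, 0.1, 99.9)
        lo, hi = np.percentile(img, [0.1, 99.9])
        assert np.isclose(out[np.isclose(img, lo)].mean(), 0.0, atol=1e-6)
        assert np.allclose(denormalize(out, params), img, atol=1e-6)

    def test_constant_image_warns_identity(self):
        with pytest.warns(UserWarning, match="constant"):
            out, params = normalize(np.full((8, 8), 3.0))
        assert params == (0.0, 1.0)
        assert np.array_equal(out, np.full((8, 8), 3.0))


class TestTraining:
    def test_learns_identity_below_noise_floor(self):
        """With identical input/target patches the regressor's validation MSE
        falls far below the patch variance within a few epochs."""
        rng = np.random.default_rng(4)
        data = np.stack([_smooth_field(rng, 32) for _ in range(24)]).astype(
            np.float32
        )
        cfg = RestorationConfig(patch_px=64, epochs=4, steps_per_epoch=10,
                                batch_size=8, base_features=8, seed=0)
        model = train_restorer((data[:16], data[:16]), (data[16:], data[16:]), cfg)
        assert model.history[-1]["val_mse"] < 0.1 * float(np.var(data))

    def test_validation_loss_decreases_on_denoising_task(self, tiny_trained_model):
        model, _, _ = tiny_trained_model
        assert model.history[-1]["val_mse"] < model.history[0]["val_mse"]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        x = rng.random((8, 32, 32)).astype(np.float32)
        cfg = RestorationConfig(patch_px=64, epochs=1, steps_per_epoch=3,
                                batch_size=4, base_features=4, seed=9)
        m1 = train_restorer((x[:6], x[:6]), (x[6:], x[6:]), cfg)
        m2 = train_restorer((x[:6], x[:6]), (x[6:], x[6:]), cfg)
        for l1, l2 in zip(m1.net.layers, m2.net.layers):
            assert np.array_equal(l1.w, l2.w)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train_restorer((np.zeros((0, 8, 8)), np.zeros((0, 8, 8))),
                           (np.zeros((1, 8, 8)), np.zeros((1, 8, 8))))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RestorationConfig(patch_px=100)
        with pytest.raises(ValueError):
            RestorationConfig(val_fraction=1.5)


class TestRestoreImage:
    def test_output_shape_matches_input(self, tiny_trained_model):
        model, _, noisy = tiny_trained_model
        out = restore_image(model, noisy[0], tile_px=32, tile_overlap_px=8,
                            normalized=True)
        assert out.shape == noisy[0].shape

    def test_tiled_matches_full_inference(self, tiny_trained_model):
        """Overlap-blended tiled inference agrees with whole-image inference
        away from machine precision (the blending weights sum to one)."""
        model, _, _ = tiny_trained_model
        rng = np.random.default_rng(5)
        big = (_structured_field(rng, 128)
               + rng.normal(0, 0.3, (128, 128))).astype(np.float32)
        full = restore_image(model, big, tile_px=128, normalized=True)
        tiled = restore_image(model, big, tile_px=64, tile_overlap_px=32,
                              normalized=True)
        scale = np.percentile(big, 99.9) - np.percentile(big, 0.1)
        rms = np.sqrt(np.mean(((full - tiled) / scale) ** 2))
        assert rms < 1e-3

    def test_restores_toward_clean_field(self, tiny_trained_model):
        model, clean, noisy = tiny_trained_model
        out = restore_image(model, noisy[0], tile_px=64, normalized=True)
        assert np.mean((out - clean[0]) ** 2) < 0.5 * np.mean(
            (noisy[0] - clean[0]) ** 2
        )

    def test_blur_baseline_outperformed(self, tiny_trained_model):
        """The trained regressor beats Gaussian smoothing at its best sigma
        when the target is a known smooth field."""
        from scipy.ndimage import gaussian_filter

        model, clean, noisy = tiny_trained_model
        out = restore_image(model, noisy[0], tile_px=64, normalized=True)
        net_mse = np.mean((out - clean[0]) ** 2)
        blur_best = min(
            np.mean((gaussian_filter(noisy[0], s) - clean[0]) ** 2)
            for s in (0.5, 1.0, 1.5, 2.0, 3.0, 4.5)
        )
        assert net_mse < blur_best


class TestEvaluateAndSsim:
    def test_identical_images_perfect_scores(self):
        img = np.random.default_rng(0).random((64, 64))
        m = evaluate([img], [img], [img])
        assert m["restored"].mse[0] == pytest.approx(0.0, abs=1e-12)
        assert m["restored"].mae[0] == pytest.approx(0.0, abs=1e-12)
        assert m["restored"].ssim[0] == pytest.approx(1.0)

    def test_ssim_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((64, 64)), rng.random((64, 64))
        assert ssim_pair(a, b, 1.0) == pytest.approx(ssim_pair(b, a, 1.0))

    def test_ssim_decreases_with_noise(self):
        rng = np.random.default_rng(2)
        base = _smooth_field(rng, 96)
        vals = []
        for sigma in (0.05, 0.2, 0.6):
            noisy = base + rng.normal(0, sigma, base.shape)
            vals.append(ssim_pair(noisy, base))
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([np.zeros((4, 4))], [np.zeros((4, 4))], [np.zeros((8, 8))])

    def test_metrics_invariants(self):
        with pytest.raises(ValueError):
            RestorationMetrics(mse=(-1.0, 0.0), mae=(0.0, 0.0), ssim=(0.5, 0.1))
        with pytest.raises(ValueError):
            RestorationMetrics(mse=(0.0, 0.0), mae=(0.0, 0.0), ssim=(1.5, 0.1))


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_trained_model, tmp_path):
        model, _, noisy = tiny_trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = Restorer.load(path)
        a = restore_image(model, noisy[1], tile_px=64, normalized=True)
        b = restore_image(back, noisy[1], tile_px=64, normalized=True)
        assert np.allclose(a, b)
        assert back.config == model.config
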