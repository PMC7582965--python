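"""Virtual-channel gating, corrected-red subtraction, 3-D melanin staining."""

import numpy as np
import pytest

from skinmpm.gating import (
    ChannelImage,
    compose_color,
    corrected_red,
    gate_frame,
    integrate_channels,
    melanin_recovery_score,
    melanin_stain_3d,
)
from skinmpm.photonsim import TimeBinnedFrame, simulate_frame
from skinmpm.timetag import GateWindows, Irf, PulseTrainConfig, decay_bin_probs


def _frame(counts: np.ndarray) -> TimeBinnedFrame:
    return TimeBinnedFrame(
        counts=counts, n_accum=1, dwell_us_per_frame=0.122, depth_um=0.0,
        pulse_cfg=PulseTrainConfig(), provenance={},
    )


class TestIntegrateChannels:
    def test_counts_in_bin0_are_red_only(self):
        counts = np.zeros((4, 4, 16), dtype=np.int64)
        counts[..., 0] = 7
        red, green = integrate_channels(_frame(counts))
        assert np.all(red == 7)
        assert np.all(green == 0)

    def test_counts_in_overlap_bin_land_in_both(self):
        counts = np.zeros((4, 4, 16), dtype=np.int64)
        counts[..., 1] = 5
        red, green = integrate_channels(_frame(counts))
        assert np.all(red == 5)
        assert np.all(green == 5)

    def test_zero_frame_zero_channels(self):
        red, green = integrate_channels(_frame(np.zeros((3, 3, 16), dtype=int)))
        assert not red.any() and not green.any()

    def test_bin_mismatch_raises(self):
        counts = np.zeros((2, 2, 4), dtype=int)
        frame = TimeBinnedFrame(
            counts=counts, n_accum=1, dwell_us_per_frame=0.122, depth_um=0.0,
            pulse_cfg=PulseTrainConfig(), provenance={},
        )
        # a 16-bin gate layout cannot address a 4-bin frame
        with pytest.raises(ValueError):
            integrate_channels(frame, GateWindows())


class TestCorrectedRed:
    @pytest.mark.parametrize("r,g,expected", [(5, 8, 0), (10, 4, 6), (3, 3, 0)])
    def test_subtraction_with_zero_clipping(self, r, g, expected):
        out = corrected_red(np.full((2, 2), r), np.full((2, 2), g))
        assert np.all(out == expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            corrected_red(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_channel_image_invariants_enforced(self):
        with pytest.raises(ValueError):
            ChannelImage(
                red=np.ones((2, 2)), green=np.ones((2, 2)),
                corrected_red=np.full((2, 2), 2.0), windows=GateWindows(),
            )


class TestComposeColor:
    def test_zero_channels_black_image(self):
        z = np.zeros((4, 4))
        ch = ChannelImage(red=z, green=z, corrected_red=z, windows=GateWindows(),
                          shg=z)
        assert not compose_color(ch).any()

    def test_shg_only_is_pure_blue(self):
        z = np.zeros((4, 4))
        shg = np.arange(16.0).reshape(4, 4)
        ch = ChannelImage(red=z, green=z, corrected_red=z, windows=GateWindows(),
                          shg=shg)
        rgb = compose_color(ch)
        assert rgb[..., 2].max() > 0
        assert not rgb[..., 0].any() and not rgb[..., 1].any()

    def test_melanin_pixels_red_dominant_in_mixed_tissue(self):
        """Half-melanin, half-long-lifetime tissue simulated through the full
        chain: melanin pixels must come out R-dominant in the composite."""
        cfg = PulseTrainConfig()
        p_mel = decay_bin_probs([(0.2, 1.0)], Irf(), cfg)
        p_long = decay_bin_probs([(2.5, 1.0)], Irf(), cfg)
        expected = np.empty((16, 16, 16))
        expected[:, :8] = 300.0 * p_mel
        expected[:, 8:] = 300.0 * p_long
        frame = simulate_frame(expected, 15, 3)
        rgb = compose_color(gate_frame(frame))
        mel_px = rgb[:, :8].reshape(-1, 3).mean(axis=0)
        assert mel_px[0] > mel_px[1] and mel_px[0] > mel_px[2]


class TestCorrectedRedStatistics:
    def test_long_lifetime_ratio_below_one_percent(self):
        """Pure tau = 2.5 ns tissue: mean corrected-red over mean total
        converges to ~0 (clipping bias only) at high counts."""
        probs = decay_bin_probs([(2.5, 1.0)], Irf(), PulseTrainConfig())
        expected = np.broadcast_to(1e4 * probs, (100, 100, 16))
        frame = simulate_frame(expected, 1, 5)
        ch = gate_frame(frame)
        ratio = ch.corrected_red.mean() / frame.total.mean()
        assert ratio < 0.01

    def test_melanin_ratio_matches_analytic_within_3_se(self):
        """Pure melanin: corrected-red fraction of total counts converges to
        the analytic (red - green) gate-mass difference."""
        cfg = PulseTrainConfig()
        probs = decay_bin_probs([(0.2, 1.0)], Irf(), cfg)
        from skinmpm.timetag import window_to_bins

        w = GateWindows()
        rmass = probs[sorted(window_to_bins(w.red, cfg))].sum()
        gmass = probs[sorted(window_to_bins(w.green, cfg))].sum()
        analytic = rmass - gmass
        assert analytic > 0
        n_pix, mean_counts = 150**2, 2000.0
        expected = np.broadcast_to(mean_counts * probs, (150, 150, 16))
        frame = simulate_frame(expected, 1, 8)
        ch = gate_frame(frame)
        ratio = ch.corrected_red.mean() / mean_counts
        # corrected_red variance per pixel ~= Var(R - G); SE of the mean ratio
        var_rg = mean_counts * (rmass + gmass - 2 * probs[1])
        se = np.sqrt(var_rg / n_pix) / mean_counts
        assert abs(ratio - analytic) <= 3 * se

    def test_more_melanin_never_lowers_expected_corrected_red(self):
        cfg = PulseTrainConfig()
        probs = decay_bin_probs([(0.2, 1.0)], Irf(), cfg)
        means = []
        for level in (100.0, 300.0, 900.0):
            expected = np.broadcast_to(level * probs, (80, 80, 16))
            ch = gate_frame(simulate_frame(expected, 1, 13))
            means.append(ch.corrected_red.mean())
        assert means[0] < means[1] < means[2]


class TestMelaninStain3d:
    def _stack(self, corrected_values):
        images = []
        for v in corrected_values:
            cr = np.asarray(v, dtype=float)
            images.append(
                ChannelImage(red=cr, green=np.zeros_like(cr), corrected_red=cr,
                             windows=GateWindows())
            )
        return images

    def test_melanin_slab_and_melanin_free_planes(self):
        """Simulated stack: pure-melanin slab planes stain >90% positive,
        pure long-lifetime planes stay <1% (clipping noise only)."""
        cfg = PulseTrainConfig()
        p_mel = decay_bin_probs([(0.2, 1.0)], Irf(), cfg)
        p_long = decay_bin_probs([(2.5, 1.0)], Irf(), cfg)
        stack, depths = [], []
        for k, probs in enumerate([p_mel, p_mel, p_long, p_long]):
            expected = np.broadcast_to(200.0 * probs, (48, 48, 16))
            frame = simulate_frame(expected, 15, 100 + k)
            stack.append(gate_frame(frame))
            depths.append(5.0 * (k + 1))
        _, fractions, _ = melanin_stain_3d(stack, depths)
        assert fractions[:2].min() > 0.9
        assert fractions[2:].max() < 0.01

    def test_empty_counts_all_negative(self):
        stack = self._stack([np.zeros((8, 8))] * 2)
        mask, fractions, _ = melanin_stain_3d(stack, [5, 10])
        assert not mask.any()

    def test_explicit_threshold_and_errors(self):
        stack = self._stack([np.arange(16.0).reshape(4, 4)])
        mask, _, thr = melanin_stain_3d(stack, [5.0], threshold=10.0)
        assert thr == 10.0
        assert mask.sum() == 5
        with pytest.raises(ValueError):
            melanin_stain_3d([], [])
        with pytest.raises(ValueError):
            melanin_stain_3d(stack * 2, [5.0, 4.0])


class TestRecoveryScore:
    def test_dice_extremes(self):
        truth = np.zeros((4, 4, 4), dtype=bool)
        truth[:2] = True
        dice, _ = melanin_recovery_score(truth, truth)
        assert dice == 1.0
        dice, _ = melanin_recovery_score(~truth, truth)
        assert dice == 0.0

    def test_auc_matches_brute_force_threshold_sweep(self):
        rng = np.random.default_rng(3)
        truth = rng.random((20, 20)) < 0.3
        scores = truth * 1.0 + rng.normal(0, 0.7, truth.shape)
        _, auc = melanin_recovery_score(scores > 0.5, truth, scores=scores)
        # brute-force AUC: Mann-Whitney rank statistic over all thresholds
        pos, neg = scores[truth], scores[~truth]
        gt = (pos[:, None] > neg[None, :]).sum()
        eq = (pos[:, None] == neg[None, :]).sum()
        brute = (gt + 0.5 * eq) / (len(pos) * len(neg))
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_degenerate_truth_raises(self):
        truth = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="one class"):
            melanin_recovery_score(truth, truth, scores=np.ones((4, 4)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            melanin_recovery_score(np.ones((2, 2), bool), np.ones((3, 3), bool))
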