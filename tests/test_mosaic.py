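"""Scan planners, strip/tile stitching, rebinning, flat-field correction."""

import numpy as np
import pytest

from skinmpm.mosaic import (
    TileScanPlan,
    flat_field_correct,
    plan_strip_scan,
    plan_tile_scan,
    plan_zstack,
    rebin_aspect,
    simulate_strips,
    split_mosaic_into_tiles,
    stitch_strips,
    stitch_tiles,
)


class TestPlanners:
    def test_strip_plan_printed_geometry(self):
        plan = plan_strip_scan(12.0, 10.0)
        assert plan.n_strips == 16
        assert plan.width_mm == pytest.approx(12.0)
        assert plan.strip_length_mm == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "width,expected", [(0.5, 1), (0.75, 1), (2.0, 3), (12.0, 16)]
    )
    def test_strip_count_covers_width(self, width, expected):
        plan = plan_strip_scan(width, 5.0)
        assert plan.n_strips == expected
        assert plan.width_mm >= width
        assert plan.width_mm - width < plan.strip_width_mm

    def test_strip_travel_limit_enforced(self):
        with pytest.raises(ValueError, match="13"):
            plan_strip_scan(5.0, 14.0)

    def test_serpentine_alternates(self):
        plan = plan_strip_scan(3.0, 5.0)
        assert plan.directions == (1, -1, 1, -1)
        assert np.allclose(np.diff(plan.offsets_mm), plan.strip_width_mm)

    @pytest.mark.parametrize(
        "area,grid,mpx", [((4.5, 4.5), (5, 5), 25), ((6.3, 6.3), (7, 7), 49),
                          ((0.5, 0.5), (1, 1), 1)]
    )
    def test_tile_plan_printed_geometry(self, area, grid, mpx):
        plan = plan_tile_scan(*area)
        assert plan.grid == grid
        assert plan.nominal_megapixels == mpx

    def test_tile_overlap_shrinks_step(self):
        plan = plan_tile_scan(4.5, 4.5, overlap_fraction=0.1)
        assert plan.grid == (6, 6)
        with pytest.raises(ValueError):
            plan_tile_scan(1.0, 1.0, overlap_fraction=0.5)

    @pytest.mark.parametrize(
        "rng,step,planes", [(150, 5, 30), (147, 5, 29), (150, 150, 1), (100, 150, 1)]
    )
    def test_zstack_plane_counts(self, rng, step, planes):
        plan = plan_zstack(rng, step)
        assert plan.n_planes == planes

    def test_zstack_depths_start_one_step_down(self):
        plan = plan_zstack(150, 5)
        assert plan.depths_um[0] == pytest.approx(5.0)
        assert plan.depths_um[-1] == pytest.approx(150.0)


class TestStripSimulation:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(3)
        plan = plan_strip_scan(3.0, 2.0, pixel_pitch_along_um=10,
                               pixel_pitch_across_um=10)
        truth = rng.random((210, 310))
        return truth, plan

    def test_jitter_free_round_trip_is_exact(self, setup):
        truth, plan = setup
        strips = simulate_strips(truth, (10, 10), plan, jitter_um=0.0, seed=0)
        mosaic = stitch_strips(strips, plan)
        assert np.array_equal(mosaic, truth[:200, :300])

    def test_jitter_reproducible_and_degrades_rms(self, setup):
        truth, plan = setup
        a = simulate_strips(truth, (10, 10), plan, jitter_um=25.0, seed=5)
        b = simulate_strips(truth, (10, 10), plan, jitter_um=25.0, seed=5)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa, sb)
        mosaic = stitch_strips(a, plan)
        rms = np.sqrt(np.mean((mosaic - truth[:200, :300]) ** 2))
        assert rms > 0

    def test_single_strip_identity(self):
        plan = plan_strip_scan(0.75, 1.0, pixel_pitch_along_um=10,
                               pixel_pitch_across_um=10)
        truth = np.random.default_rng(0).random((100, 75))
        strips = simulate_strips(truth, (10, 10), plan, 0.0, 0)
        assert len(strips) == 1
        assert np.array_equal(stitch_strips(strips, plan), truth)

    def test_sixteen_strips_make_12mm(self):
        plan = plan_strip_scan(12.0, 10.0)
        assert plan.n_strips * plan.strip_width_mm == pytest.approx(12.0)

    def test_truth_too_small_raises(self, setup):
        _, plan = setup
        with pytest.raises(ValueError, match="smaller"):
            simulate_strips(np.zeros((50, 50)), (10, 10), plan, 0.0, 0)

    def test_strip_count_mismatch_raises(self, setup):
        truth, plan = setup
        strips = simulate_strips(truth, (10, 10), plan, 0.0, 0)
        with pytest.raises(ValueError):
            stitch_strips(strips[:-1], plan)


class TestRebinAspect:
    def test_64_to_80_megapixel_proportions(self):
        # 1.25 pitch ratio: the along axis upsamples by 5/4, as in the
        # instrument's 64 -> 80 MPx rebin
        img = np.random.default_rng(0).random((160, 160))
        out = rebin_aspect(img, 1.25, 1.0)
        assert out.shape == (200, 160)
        assert out.shape[0] * out.shape[1] == int(160 * 160 * 1.25)

    def test_equal_pitch_identity_bit_equal(self):
        img = np.random.default_rng(1).random((30, 40))
        assert rebin_aspect(img, 2.0, 2.0) is img

    def test_constant_preserved(self):
        out = rebin_aspect(np.full((40, 40), 2.5), 1.25, 1.0)
        assert np.allclose(out, 2.5, atol=1e-9)


class TestTiles:
    def test_round_trip_and_shape(self):
        truth = np.random.default_rng(2).random((96, 96))
        plan = TileScanPlan(grid=(3, 3), tile_pixels=(32, 32))
        tiles = list(split_mosaic_into_tiles(truth, (32, 32)))
        mosaic = stitch_tiles(tiles, plan)
        assert mosaic.shape == (96, 96)
        assert np.allclose(mosaic, truth)

    def test_single_tile_identity(self):
        t = np.random.default_rng(0).random((16, 16))
        assert np.allclose(stitch_tiles([t], TileScanPlan(grid=(1, 1))), t)

    def test_overlap_blending_preserves_constant(self):
        plan = TileScanPlan(grid=(2, 2), overlap_fraction=0.25)
        tiles = [np.full((20, 20), 4.2) for _ in range(4)]
        assert np.allclose(stitch_tiles(tiles, plan), 4.2)

    def test_tile_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            stitch_tiles([np.zeros((8, 8))] * 3, TileScanPlan(grid=(2, 2)))


class TestFlatField:
    def test_flat_input_gain_near_one(self):
        tiles = np.full((6, 32, 32), 5.0)
        corrected, gain = flat_field_correct(tiles)
        assert np.allclose(gain, 1.0, atol=1e-9)
        assert np.allclose(corrected, tiles)

    def test_recovers_known_vignette_within_5pct(self):
        rng = np.random.default_rng(4)
        y, x = np.meshgrid(np.linspace(-1, 1, 48), np.linspace(-1, 1, 48),
                           indexing="ij")
        vignette = 1.0 - 0.35 * (y**2 + x**2)
        vignette /= vignette.mean()
        flat_scenes = 8.0 + rng.random((9, 48, 48))
        tiles = flat_scenes * vignette
        _, gain = flat_field_correct(tiles)
        rel_rms = np.sqrt(np.mean((gain - vignette) ** 2)) / vignette.mean()
        assert rel_rms < 0.05

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(5)
        tiles = rng.random((5, 24, 24)) + 1.0
        _, g1 = flat_field_correct(tiles)
        _, g2 = flat_field_correct(tiles * 123.4)
        assert np.allclose(g1, g2, atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            flat_field_correct(np.ones((3, 8, 8)))  # too few tiles
        with pytest.raises(ValueError):
            flat_field_correct(np.zeros((5, 8, 8)))  # degenerate
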