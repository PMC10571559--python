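"""Stitching and background correction against generator ground truth."""

import numpy as np
import pytest

from clonoscope import tilescan
from clonoscope.simulate import SimParams, generate_well, illumination_field


def noise_free_params(**kw):
    defaults = dict(seed=5, tile_grid=(2, 2), tile_size_px=(512, 512),
                    seeded_cells_per_well=0, background_level=0.0,
                    gauss_sigma=0.0, poisson_gain=0.0,
                    illumination_amplitude=0.0, cells_per_clone_median=5.0,
                    clone_dispersion_px=30.0, min_nucleus_spacing_px=16.0)
    defaults.update(kw)
    return SimParams(**defaults)


# clone centers pinned on every tile boundary of the 2x2 / 512px / 10% layout
BORDER_CENTERS = np.array([[486, 240], [486, 730], [240, 486],
                           [730, 486], [486, 486]], dtype=float)


class TestRoughMosaic:
    def test_single_tile_scan_is_downsampled_copy(self):
        rng = np.random.default_rng(0)
        tile = rng.uniform(0, 100, (1, 1, 1, 64, 64))
        scan = tilescan.TileScan(tile, 0.1, ("dna",))
        mosaic = tilescan.rough_mosaic(scan, downsample=4)
        assert mosaic.shape == (16, 16)
        assert mosaic[0, 0] == pytest.approx(tile[0, 0, 0, :4, :4].mean())

    def test_uniform_tiles_stay_uniform_in_overlap(self):
        tiles = np.full((1, 2, 1, 64, 64), 7.0)
        scan = tilescan.TileScan(tiles, 0.1, ("dna",))
        mosaic = tilescan.rough_mosaic(scan, downsample=1)
        assert np.all(mosaic == 7.0)

    def test_clone_centroid_recovered_within_downsample_tolerance(self):
        params = noise_free_params()
        center = np.array([[200.0, 300.0]])
        scan, truth = generate_well(params, clone_centers=center)
        mosaic = tilescan.rough_mosaic(scan, downsample=4)
        fg = mosaic > mosaic.max() * 0.1
        ys, xs = np.nonzero(fg)
        true_x = truth.nuclei["x"].mean()
        true_y = truth.nuclei["y"].mean()
        assert abs(xs.mean() * 4 - true_x) < 8
        assert abs(ys.mean() * 4 - true_y) < 8


class TestLocateCloneTiles:
    def test_blank_well_returns_empty_set(self):
        scan, _ = generate_well(noise_free_params())
        mosaic = tilescan.rough_mosaic(scan)
        assert tilescan.locate_clone_tiles(mosaic, scan) == set()

    def test_clone_inside_one_tile_marks_that_tile(self):
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=np.array([[200.0, 200.0]]))
        mosaic = tilescan.rough_mosaic(scan)
        assert tilescan.locate_clone_tiles(mosaic, scan) == {(0, 0)}

    def test_cross_border_clone_marks_both_tiles(self):
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=np.array([[486.0, 200.0]]))
        mosaic = tilescan.rough_mosaic(scan)
        hits = tilescan.locate_clone_tiles(mosaic, scan)
        assert {(0, 0), (0, 1)} <= hits


class TestRefineOffsets:
    def test_zero_misalignment_recovers_nominal_offsets(self):
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=BORDER_CENTERS)
        mosaic = tilescan.rough_mosaic(scan)
        hits = tilescan.locate_clone_tiles(mosaic, scan)
        result = tilescan.refine_offsets(scan, hits, max_shift=20)
        assert np.array_equal(result.offsets, scan.nominal_origins)

    def test_injected_integer_shift_recovered_exactly(self):
        jitter = np.zeros((2, 2, 2), dtype=int)
        jitter[0, 1] = (-2, 3)
        jitter[1, 0] = (4, -1)
        jitter[1, 1] = (-3, -3)
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=BORDER_CENTERS,
                                origin_jitter=jitter)
        mosaic = tilescan.rough_mosaic(scan)
        hits = tilescan.locate_clone_tiles(mosaic, scan)
        result = tilescan.refine_offsets(scan, hits, max_shift=20)
        assert np.array_equal(result.offsets, scan.nominal_origins + jitter)

    def test_blank_strips_keep_nominal_and_warn_per_pair(self):
        tiles = np.zeros((2, 2, 1, 512, 512), dtype=np.uint16)
        scan = tilescan.TileScan(tiles, 0.1, ("dna",))
        all_tiles = {(0, 0), (0, 1), (1, 0), (1, 1)}
        with pytest.warns(UserWarning, match="no usable signal"):
            result = tilescan.refine_offsets(scan, all_tiles, max_shift=20)
        assert np.array_equal(result.offsets, scan.nominal_origins)
        assert len(result.skipped_pairs) == 4

    def test_max_shift_larger_than_overlap_rejected(self):
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=BORDER_CENTERS)
        with pytest.raises(ValueError, match="max_shift"):
            tilescan.refine_offsets(scan, {(0, 0), (0, 1)}, max_shift=30)


class TestStitch:
    def test_single_tile_stitch_is_identity(self):
        rng = np.random.default_rng(1)
        tiles = rng.uniform(0, 100, (1, 1, 2, 64, 64))
        scan = tilescan.TileScan(tiles, 0.1, ("a", "b"))
        well = tilescan.stitch(scan)
        assert np.array_equal(well.image, tiles[0, 0])
        assert np.all(well.provenance == 0)

    def test_gap_between_tiles_raises(self):
        tiles = np.zeros((1, 2, 1, 64, 64))
        scan = tilescan.TileScan(tiles, 0.1, ("dna",))
        offsets = scan.nominal_origins.copy()
        offsets[0, 1, 1] += 20        # push beyond tile width
        with pytest.raises(ValueError, match="gap"):
            tilescan.stitch(scan, offsets)

    def test_foreground_area_never_exceeds_tile_sum(self):
        scan, _ = generate_well(noise_free_params(),
                                clone_centers=BORDER_CENTERS)
        well = tilescan.stitch(scan)
        fg_stitched = (well.image.sum(axis=0) > 0).sum()
        fg_tiles = sum((scan.signal(r, c) > 0).sum()
                       for r in range(2) for c in range(2))
        assert fg_stitched <= fg_tiles

    def test_cross_border_nuclei_counted_once(self):
        from clonoscope import segmentation

        params = noise_free_params()
        scan, truth = generate_well(params, clone_centers=BORDER_CENTERS)
        well = tilescan.stitch(scan)
        nuclei = segmentation.segment_well(well.image, scan.channel_names)
        assert len(nuclei) == len(truth.nuclei)


class TestBackground:
    def test_uniform_image_returns_constant_surface(self):
        image = np.full((128, 128), 42.0)
        surface = tilescan.estimate_background(image)
        assert np.allclose(surface, 42.0)

    def test_radial_gradient_recovered_within_two_percent(self):
        params = SimParams(seed=0, seeded_cells_per_well=0, tile_grid=(1, 1),
                          tile_size_px=(512, 512), illumination_amplitude=0.2)
        scan, _ = generate_well(params)
        tile = scan.tiles[0, 0, 0].astype(float)
        true_surface = params.background_level * illumination_field(
            (512, 512), 0.2)
        surface = tilescan.estimate_background(tile)
        amplitude = params.background_level * 0.2
        assert np.abs(surface - true_surface).max() < 0.02 * amplitude

    def test_residual_after_subtraction_below_noise_sigma(self):
        params = SimParams(seed=1, seeded_cells_per_well=0, tile_grid=(1, 1),
                          tile_size_px=(512, 512), illumination_amplitude=0.2)
        scan, _ = generate_well(params)
        tile = scan.tiles[0, 0, 0].astype(float)
        surface = tilescan.estimate_background(tile)
        corrected = tilescan.subtract_background(tile, surface)
        sigma = np.sqrt(params.gauss_sigma ** 2
                        + params.background_level * params.poisson_gain)
        assert np.abs(corrected).mean() < sigma

    def test_fully_covered_image_falls_back_to_global_median(self):
        rng = np.random.default_rng(0)
        # one huge bright object with a dim corner: nearly no free pixels
        image = np.full((128, 128), 1000.0) + rng.normal(0, 1, (128, 128))
        image[:2, :32] = 10.0
        with pytest.warns(UserWarning, match="global median"):
            surface = tilescan.estimate_background(image, n_points=20)
        assert surface.std() == 0

    def test_subtract_clips_at_zero_and_checks_shapes(self):
        image = np.full((8, 8), 5.0)
        assert np.array_equal(
            tilescan.subtract_background(image, np.zeros((8, 8))), image)
        assert np.all(tilescan.subtract_background(image, image) == 0)
        assert np.all(tilescan.subtract_background(
            image, np.full((8, 8), 9.0)) == 0)
        with pytest.raises(ValueError, match="shape mismatch"):
            tilescan.subtract_background(image, np.zeros((4, 4)))


class TestTileIO:
    def test_tiff_write_read_round_trip(self, tmp_path):
        scan, _ = generate_well(SimParams(
            seed=8, seeded_cells_per_well=5, tile_grid=(2, 2),
            tile_size_px=(384, 384)))
        scan.write(tmp_path)
        back = tilescan.TileScan.read(tmp_path, 0.10, scan.channel_names)
        assert np.array_equal(back.tiles, scan.tiles)

    def test_missing_tile_file_named_in_error(self, tmp_path):
        scan, _ = generate_well(SimParams(
            seed=8, seeded_cells_per_well=5, tile_grid=(2, 2),
            tile_size_px=(384, 384)))
        scan.write(tmp_path)
        (tmp_path / "r1_c0_g.tif").unlink()
        with pytest.raises(FileNotFoundError, match=r"\(1, 0\)"):
            tilescan.TileScan.read(tmp_path, 0.10, scan.channel_names)
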