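"""Nucleus detection, watershed splitting and feature measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from clonoscope import segmentation, tilescan
from clonoscope.simulate import SimParams, generate_well


def disk_mask(r, shape=(64, 64), center=None):
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestThreshold:
    def test_all_zero_image_gives_empty_mask(self):
        assert not segmentation.threshold_nuclei(np.zeros((64, 64))).any()

    def test_isolated_nuclei_counted_exactly(self):
        params = SimParams(seed=6, seeded_cells_per_well=50, tile_grid=(2, 2),
                           tile_size_px=(640, 640), cells_per_clone_median=1.0,
                           cells_per_clone_sigma=0.0, background_level=0.0,
                           gauss_sigma=0.0, poisson_gain=0.0,
                           illumination_amplitude=0.0,
                           min_nucleus_spacing_px=40.0)
        scan, truth = generate_well(params)
        well = tilescan.stitch(scan)
        mask = segmentation.threshold_nuclei(well.image.sum(axis=0))
        _, n = ndi.label(mask)
        assert n == len(truth.nuclei)

    def test_small_objects_removed(self):
        image = np.zeros((64, 64))
        image[10, 10] = 100.0                 # single-pixel speck
        image[30:40, 30:40] = 100.0           # real object
        mask = segmentation.threshold_nuclei(image, min_object_px=9)
        _, n = ndi.label(mask)
        assert n == 1
        assert not mask[10, 10]


class TestSplitTouching:
    def test_single_disk_gets_one_label(self):
        labels = segmentation.split_touching(disk_mask(10))
        assert labels.max() == 1

    def test_two_overlapping_disks_split_along_true_chord(self):
        # 20% radius overlap: centers 1.8 r apart; the split boundary must
        # follow the perpendicular bisector within 2 px
        rng = np.random.default_rng(7)
        r = 12
        for _ in range(20):
            theta = rng.uniform(0, np.pi)
            c1 = np.array([40.0, 40.0])
            c2 = c1 + 1.8 * r * np.array([np.cos(theta), np.sin(theta)])
            yy, xx = np.mgrid[0:80, 0:80].astype(float)
            mask = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= r * r) | \
                   ((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= r * r)
            labels = segmentation.split_touching(mask, h_min=5.0)
            assert labels.max() == 2
            boundary = np.zeros_like(mask)
            for lab in (1, 2):
                boundary |= ndi.binary_dilation(labels == lab) & \
                    (labels == 3 - lab)
            ys, xs = np.nonzero(boundary)
            mid = (c1 + c2) / 2
            u = (c2 - c1) / np.linalg.norm(c2 - c1)
            dist = np.abs((ys - mid[0]) * u[0] + (xs - mid[1]) * u[1])
            assert dist.max() <= 2.0

    def test_labels_partition_the_mask(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((96, 96), dtype=bool)
        for _ in range(6):
            cy, cx = rng.integers(15, 80, 2)
            mask |= disk_mask(rng.integers(5, 10), (96, 96), (cy, cx))
        labels = segmentation.split_touching(mask)
        assert np.array_equal(labels > 0, mask)

    def test_empty_mask_gives_empty_labels(self):
        labels = segmentation.split_touching(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 0


class TestMeasure:
    def test_disk_is_round_and_circular(self):
        mask = disk_mask(20, (64, 64))
        labels = mask.astype(np.int32)
        df = segmentation.measure_nuclei(labels, {"dna": mask.astype(float)})
        assert 0.9 <= df.loc[0, "roundness"] <= 1.05
        assert 0.9 <= df.loc[0, "circularity"] <= 1.05

    def test_rectangle_roundness_matches_moment_oracle(self):
        # analytic oracle: a discrete 10x40 rectangle has second-moment
        # variance (L^2 - 1)/12 along its length, so the moment-equivalent
        # major axis is 4*sqrt((40^2 - 1)/12) = 46.17 px and
        # roundness = 4*400 / (pi * 46.17^2) = 0.239
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:30, 10:50] = True
        df = segmentation.measure_nuclei(mask.astype(np.int32),
                                         {"dna": mask.astype(float)})
        major_oracle = 4 * np.sqrt((40 ** 2 - 1) / 12)
        expected = 4 * 400 / (np.pi * major_oracle ** 2)
        assert df.loc[0, "major_axis"] == pytest.approx(major_oracle, abs=0.5)
        assert df.loc[0, "roundness"] == pytest.approx(expected, abs=0.03)

    def test_intensity_scales_linearly_but_shape_does_not(self):
        mask = disk_mask(10)
        img = mask * 7.0
        a = segmentation.measure_nuclei(mask.astype(np.int32), {"dna": img})
        b = segmentation.measure_nuclei(mask.astype(np.int32),
                                        {"dna": 2 * img})
        assert b.loc[0, "intensity_dna"] == 2 * a.loc[0, "intensity_dna"]
        assert b.loc[0, "roundness"] == a.loc[0, "roundness"]
        assert b.loc[0, "circularity"] == a.loc[0, "circularity"]

    def test_intensity_conserved_over_labels(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (96, 96))
        mask = np.zeros((96, 96), dtype=bool)
        mask |= disk_mask(8, (96, 96), (25, 25))
        mask |= disk_mask(8, (96, 96), (70, 60))
        labels, _ = ndi.label(mask)
        df = segmentation.measure_nuclei(labels, {"dna": img})
        assert df["intensity_dna"].sum() == pytest.approx(img[mask].sum(),
                                                          rel=1e-6)

    def test_sub_minimum_labels_dropped_and_tallied(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:4, 2:4] = 1                 # 4 px, below minimum
        labels[10:20, 10:20] = 2
        df = segmentation.measure_nuclei(labels, {"dna": labels * 1.0})
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_shape_sanity_on_segmented_well(self, small_lego_well):
        _, _, nuclei, _ = small_lego_well
        assert (nuclei["roundness"] <= 1.05).all()
        assert (nuclei["circularity"] <= 1.05).all()
        assert (nuclei["area"] > 0).all()


class TestNormalize:
    def test_single_record_normalizes_to_one(self):
        df = pd.DataFrame({"area": [50.0], "intensity_dna": [1000.0],
                           "color_class": ["UNSET"]})
        out = segmentation.normalize_features(df, "dna")
        assert out.loc[0, "norm_intensity"] == 1.0
        assert out.loc[0, "norm_area"] == 1.0

    def test_median_scaling(self):
        df = pd.DataFrame({"area": [10.0, 20.0, 30.0],
                           "intensity_dna": [50.0, 100.0, 300.0],
                           "color_class": ["UNSET"] * 3})
        out = segmentation.normalize_features(df, "dna")
        assert list(out["norm_intensity"]) == [0.5, 1.0, 3.0]
        assert np.median(out["norm_area"]) == 1.0

    def test_trash_excluded_from_medians(self):
        df = pd.DataFrame({"area": [10.0, 10.0, 1000.0],
                           "intensity_dna": [100.0, 100.0, 9.0],
                           "color_class": ["R", "G", "TRASH"]})
        out = segmentation.normalize_features(df, "dna")
        assert out.loc[0, "norm_intensity"] == 1.0
        assert out.loc[2, "norm_area"] == 100.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segmentation.normalize_features(
                pd.DataFrame(columns=["area", "intensity_dna"]))


class TestCountRecovery:
    def test_sparse_well_count_error_below_two_percent(self):
        params = SimParams(seed=12, seeded_cells_per_well=40, tile_grid=(2, 2),
                           tile_size_px=(768, 768), clone_dispersion_px=50.0,
                           cells_per_clone_median=4.0,
                           min_nucleus_spacing_px=20.0)
        scan, truth = generate_well(params)
        corrected = tilescan.correct_tiles(scan)
        well = tilescan.stitch(scan, None, corrected)
        nuclei = segmentation.segment_well(well.image, scan.channel_names)
        err = abs(len(nuclei) - len(truth.nuclei)) / len(truth.nuclei)
        assert err < 0.02

    def test_touching_well_count_error_below_five_percent(self):
        # dispersion on the order of the nucleus major axis: nuclei touch
        # inside clones and the watershed must recover the count
        params = SimParams(seed=13, seeded_cells_per_well=40, tile_grid=(2, 2),
                           tile_size_px=(768, 768), clone_dispersion_px=12.0,
                           cells_per_clone_median=4.0)
        scan, truth = generate_well(params)
        corrected = tilescan.correct_tiles(scan)
        well = tilescan.stitch(scan, None, corrected)
        nuclei = segmentation.segment_well(well.image, scan.channel_names)
        err = abs(len(nuclei) - len(truth.nuclei)) / len(truth.nuclei)
        assert err < 0.05
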