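"""Shared fixtures: small synthetic wells and an independent DBSCAN oracle."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from clonoscope import barcode, clones as clone_mod, segmentation, tilescan
from clonoscope.simulate import SimParams, generate_well

warnings.filterwarnings("ignore", category=UserWarning)


def run_image_pipeline(params: SimParams, color_constrained: bool | None = None):
    """Full stitch -> segment -> classify -> cluster pipeline on one well."""
    scan, truth = generate_well(params)
    corrected = tilescan.correct_tiles(scan)
    mosaic = tilescan.rough_mosaic(scan)
    clone_tiles = tilescan.locate_clone_tiles(mosaic, scan)
    refine = tilescan.refine_offsets(scan, clone_tiles, 20,
                                     corrected.sum(axis=2))
    well = tilescan.stitch(scan, refine.offsets, corrected)
    nuclei = segmentation.segment_well(well.image, scan.channel_names)
    if params.assay == "lego":
        nuclei = barcode.classify_nuclei_rule_based(nuclei)
    nuclei = segmentation.normalize_features(nuclei)
    if color_constrained is None:
        color_constrained = params.assay == "lego"
    nuclei, clones = clone_mod.call_clones(
        nuclei, color_constrained=color_constrained)
    return truth, nuclei, clones


def brute_force_dbscan(pts: np.ndarray, eps: float, min_samples: int):
    """Independent DBSCAN by explicit density reachability.

    Returns ``(core_labels, is_core, border_options)``: cluster ids over
    core points (-1 elsewhere), the core mask, and for every non-core point
    the set of cluster ids it is directly reachable from (empty = noise).
    """
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps * eps               # self included
    is_core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not is_core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.nonzero(neigh[j] & is_core)[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    border_options = {}
    for i in np.nonzero(~is_core)[0]:
        reach = set(labels[np.nonzero(neigh[i] & is_core)[0]].tolist())
        border_options[i] = reach
    return labels, is_core, border_options


def assert_matches_oracle(records: pd.DataFrame, clustered: pd.DataFrame,
                          eps: float, min_samples: int) -> None:
    """Check cluster_clones_dbscan output against the brute-force oracle.

    Core-point partitions must agree exactly; noise points (empty reach
    set) must come out as flagged singletons; border points may join any
    cluster they are directly reachable from (their assignment is
    order-dependent by DBSCAN's own definition).
    """
    pts = records[["x", "y"]].to_numpy(dtype=np.float64)
    oracle, is_core, border_options = brute_force_dbscan(pts, eps, min_samples)
    got = clustered["clone_id"].to_numpy()
    noise = clustered["unclustered"].to_numpy()

    # map oracle cluster -> implementation cluster via core points
    mapping: dict[int, int] = {}
    for i in np.nonzero(is_core)[0]:
        assert not noise[i], f"core point {i} flagged as noise"
        o = oracle[i]
        if o in mapping:
            assert mapping[o] == got[i], \
                f"core points of oracle cluster {o} split across clusters"
        else:
            mapping[o] = got[i]
    assert len(set(mapping.values())) == len(mapping), \
        "distinct oracle clusters merged by implementation"

    for i, reach in border_options.items():
        if not reach:
            assert noise[i], f"point {i} should be noise"
        else:
            assert not noise[i], f"border point {i} flagged as noise"
            allowed = {mapping[o] for o in reach}
            assert got[i] in allowed, \
                f"border point {i} assigned outside its reachable clusters"


@pytest.fixture(scope="session")
def small_lego_well():
    """A small but complete barcoded well with its ground truth."""
    params = SimParams(seed=3, seeded_cells_per_well=60, tile_grid=(2, 2),
                       tile_size_px=(640, 640))
    truth, nuclei, clones = run_image_pipeline(params)
    return params, truth, nuclei, clones


@pytest.fixture(scope="session")
def sparse_dna_well():
    """Noise-free single-stain well with well-separated nuclei and fragments."""
    params = SimParams(seed=4, assay="dna", seeded_cells_per_well=60,
                       tile_grid=(2, 2), tile_size_px=(768, 768),
                       clone_dispersion_px=55.0, cells_per_clone_median=3.5,
                       cells_per_clone_sigma=0.3, fragment_rate=0.2,
                       min_nucleus_spacing_px=20.0, gauss_sigma=0.0,
                       poisson_gain=0.0, background_level=0.0,
                       illumination_amplitude=0.0)
    scan, truth = generate_well(params)
    well = tilescan.stitch(scan)
    nuclei = segmentation.segment_well(well.image, scan.channel_names)
    nuclei = segmentation.normalize_features(nuclei, "dna")
    return params, truth, nuclei
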