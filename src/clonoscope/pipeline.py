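"""Composition of the analysis stages into one reproducible run.

Stage order: (optional) simulate -> rough mosaic / clone location ->
per-tile background correction -> offset refinement -> stitch ->
segment -> (optional) color classification -> clone calling -> well
summary.  A run manifest (config hash, stage timings, QC tallies) is
written even when a stage fails, with the failure recorded.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path

import pandas as pd

from clonoscope import barcode, clones as clone_mod, segmentation, simulate, \
    survival, tilescan
from clonoscope.config import PipelineConfig


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and well id."""

    def __init__(self, stage: str, well_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for well {well_id!r}: {cause}")
        self.stage = stage
        self.well_id = well_id


def process_well(scan: tilescan.TileScan, config: PipelineConfig,
                 well_id: str = "well") -> dict:
    """Run stitching, segmentation, classification and clone calling on
    one tile scan; returns a dict of tables and intermediate products."""
    timings: dict[str, float] = {}

    def _timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:          # noqa: BLE001 - rewrap with context
            raise StageError(stage, well_id, exc) from exc
        timings[stage] = time.perf_counter() - t0
        return result

    sc = config.stitch
    mosaic = _timed("mosaic", tilescan.rough_mosaic, scan, sc.downsample)
    clone_tiles = _timed("locate", tilescan.locate_clone_tiles, mosaic, scan,
                         sc.downsample)
    corrected = _timed("background", tilescan.correct_tiles, scan,
                       sc.n_background_points, sc.background_patch)
    refine = _timed("refine", tilescan.refine_offsets, scan, clone_tiles,
                    sc.max_shift, corrected.sum(axis=2))
    well = _timed("stitch", tilescan.stitch, scan, refine.offsets, corrected)

    seg = config.segment
    nuclei = _timed("segment", segmentation.segment_well, well.image,
                    scan.channel_names, seg.reference_channel, seg.h_min,
                    seg.min_object_px)

    if config.classify.enabled and len(nuclei):
        if config.classify.model_path:
            model = barcode.ColorModel.load(config.classify.model_path)
            nuclei = _timed("classify", barcode.classify_nuclei, nuclei, model)
        else:
            nuclei = _timed("classify", barcode.classify_nuclei_rule_based,
                            nuclei, config.classify.on_fraction)

    if len(nuclei):
        nuclei = segmentation.normalize_features(nuclei)
        cl = config.clones
        nuclei, clone_table = _timed(
            "clones", clone_mod.call_clones, nuclei, cl.eps, cl.min_samples,
            cl.color_constrained)
    else:
        clone_table = pd.DataFrame(columns=clone_mod.CLONE_COLUMNS)

    sv = config.survival
    cfg = survival.ThresholdConfig(
        min_cells_per_clone=sv.min_cells_per_clone,
        small_intensity_max=sv.small_intensity_max,
        large_intensity_range=tuple(sv.large_intensity_range),
        small_area_max=sv.small_area_max,
        large_area_range=tuple(sv.large_area_range),
        low_roundness_max=sv.low_roundness_max,
        low_circularity_max=sv.low_circularity_max)
    summary = _timed("survive", survival.summarize_well, well_id, nuclei,
                     clone_table, sv.seeded_cells, cfg, sv.dna_histogram)
    return {
        "well_id": well_id,
        "mosaic": mosaic,
        "clone_tiles": clone_tiles,
        "stitched": well,
        "nuclei": nuclei,
        "clones": clone_table,
        "summary": summary,
        "timings": timings,
        "qc": {
            "n_dropped_small": int(nuclei.attrs.get("n_dropped", 0))
            if hasattr(nuclei, "attrs") else 0,
            "n_skipped_pairs": len(refine.skipped_pairs),
            "n_clone_tiles": len(clone_tiles),
        },
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a full configured run; returns the output directory.

    Re-running with an identical config and inputs reproduces identical
    CSV outputs.  The run manifest is always written, including on failure.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": config.version,
        "status": "running",
        "wells": [],
    }
    t_start = time.perf_counter()
    try:
        if config.simulate.enabled:
            params = simulate.SimParams(**{"seed": config.seed,
                                           **config.simulate.params})
            scan, truth = simulate.generate_well(params)
            truth.nuclei.to_csv(outdir / "truth_nuclei.csv", index=False)
            truth.clones.to_csv(outdir / "truth_clones.csv", index=False)
        elif config.input_dir:
            scan = tilescan.TileScan.read(config.input_dir,
                                          config.stitch.overlap_frac,
                                          tuple(config.channels))
        else:
            raise FileNotFoundError(
                "config provides neither input_dir nor simulate.enabled")

        result = process_well(scan, config)
        result["nuclei"].to_csv(outdir / "nuclei.csv", index=False)
        result["clones"].to_csv(outdir / "clones.csv", index=False)
        pd.DataFrame([result["summary"].to_row()]).to_csv(
            outdir / "well_summary.csv", index=False)
        if result["summary"].dna_histogram is not None:
            pd.DataFrame({
                "bin_left": result["summary"].dna_bin_edges[:-1],
                "bin_right": result["summary"].dna_bin_edges[1:],
                "frequency": result["summary"].dna_histogram,
            }).to_csv(outdir / "histograms.csv", index=False)
        manifest["wells"].append({
            "well_id": result["well_id"],
            "timings_s": {k: round(v, 4) for k, v in
                          result["timings"].items()},
            "qc": result["qc"],
            "n_nuclei": int(len(result["nuclei"])),
            "n_clones": int(len(result["clones"])),
        })
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = {"message": str(exc),
                             "traceback": traceback.format_exc()}
        raise
    finally:
        manifest["elapsed_s"] = round(time.perf_counter() - t_start, 3)
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
    return outdir
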