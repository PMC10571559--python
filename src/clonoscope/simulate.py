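"""Synthetic clonogenic-assay plate generator with exhaustive ground truth.

Every downstream stage of the pipeline (stitching, segmentation, color
classification, clone calling, survival statistics) is validated against
wells produced here, where the identity, position, shape, intensity and
clone membership of every nucleus is known exactly.

The model: each seeded cell survives to found a clone with probability
``survival_prob``; surviving clones receive a log-normal number of member
cells and one of six additive RGB color classes (R, G, B, RG, RB, GB).
Member nuclei are scattered uniformly in a disk around the clone center
(radius growing with the square root of cell count, floored at
``clone_dispersion_px``, with a soft minimum nucleus spacing) and rendered
as anisotropic Gaussian-profile ellipses into the channels dictated by
their color class.  Tiles are cut
from a single noise-free scene (so overlap strips agree exactly), then a
radial illumination gradient, Poisson-Gaussian camera noise and 16-bit
quantization are applied per tile, mirroring the camera's order of effects.

Two assay arms are supported: ``assay="lego"`` renders r/g/b channels with
color barcoding, ``assay="dna"`` renders a single DNA-stain channel where
total intensity is proportional to DNA content (with an optional G2
sub-population at twice the G1 intensity for cell-cycle histogram tests).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clonoscope.tilescan import TileScan

COLOR_CLASSES: tuple[str, ...] = ("R", "G", "B", "RG", "RB", "GB")
CLASS_CHANNELS: dict[str, tuple[int, ...]] = {
    "R": (0,), "G": (1,), "B": (2,),
    "RG": (0, 1), "RB": (0, 2), "GB": (1, 2),
}


@dataclass
class SimParams:
    """Study conditions for one simulated well.

    Geometry defaults emulate a 10x tile scan of one multiwell-plate well:
    a 3x3 grid of 768x768 px tiles with 10% overlap, 200 seeded cells (the
    optimal seeding density for stable clone counts), nuclei of 12x9 px,
    and compact early-timepoint clones (median 8 cells) that occupy a disk
    growing with cell count.  Noise and illumination amplitudes are free
    parameters of the instrument, not of the assay; defaults are plausible
    wide-field camera values and are meant to be overridden from config.
    """

    seeded_cells_per_well: int = 200
    survival_prob: float = 1.0
    cells_per_clone_median: float = 8.0
    cells_per_clone_sigma: float = 0.35
    clone_dispersion_px: float = 8.0
    nucleus_axes_px: tuple[float, float] = (12.0, 9.0)
    color_mix: tuple[float, ...] = (1 / 6,) * 6
    fragment_rate: float = 0.0
    tile_grid: tuple[int, int] = (3, 3)
    tile_size_px: tuple[int, int] = (768, 768)
    overlap_frac: float = 0.10
    illumination_amplitude: float = 0.15
    background_level: float = 500.0
    gauss_sigma: float = 3.0
    poisson_gain: float = 0.25
    intensity_scale: float = 1500.0
    intensity_sigma: float = 0.15
    g2_fraction: float = 0.0
    min_nucleus_spacing_px: float | None = None
    assay: str = "lego"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ValueError("survival_prob must be in [0, 1]")
        if not 0.0 <= self.fragment_rate <= 1.0:
            raise ValueError("fragment_rate must be in [0, 1]")
        if not 0.0 < self.overlap_frac < 0.5:
            raise ValueError("overlap_frac must be in (0, 0.5)")
        if min(self.tile_size_px) <= 0 or min(self.tile_grid) <= 0:
            raise ValueError("tile dimensions must be positive")
        mix = np.asarray(self.color_mix, dtype=np.float64)
        if len(mix) != 6 or (mix < 0).any() or (mix > 1).any():
            raise ValueError("color_mix must be 6 fractions in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("color_mix must sum to 1")
        if not 0.0 <= self.illumination_amplitude < 1.0:
            raise ValueError("illumination_amplitude must be in [0, 1)")
        if self.assay not in ("lego", "dna"):
            raise ValueError("assay must be 'lego' or 'dna'")
        major, minor = self.nucleus_axes_px
        if minor > major:
            raise ValueError("nucleus_axes_px must be (major, minor)")
        h, w = self.tile_size_px
        if self.clone_dispersion_px * 6 + major > min(h, w):
            raise ValueError("clone dispersion or nucleus size exceeds tile "
                             "size: impossible geometry")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return ("r", "g", "b") if self.assay == "lego" else ("dna",)

    @property
    def scene_shape(self) -> tuple[int, int]:
        rows, cols = self.tile_grid
        h, w = self.tile_size_px
        dy = int(round(h * (1 - self.overlap_frac)))
        dx = int(round(w * (1 - self.overlap_frac)))
        return (dy * (rows - 1) + h, dx * (cols - 1) + w)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("nucleus_axes_px", "color_mix", "tile_grid", "tile_size_px"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Exhaustive truth for one simulated well.

    ``nuclei`` has one row per rendered nucleus (id, clone id, stitched
    centroid, analytic area / axes / roundness / circularity, per-channel
    total intensity, fragment flag, color class); ``clones`` one row per
    surviving clone.
    """

    nuclei: pd.DataFrame
    clones: pd.DataFrame
    seeded_cells: int
    surviving_clones: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(outdir / "nuclei.csv", index=False)
        self.clones.to_csv(outdir / "clones.csv", index=False)


def _ellipse_circularity(a: float, b: float) -> float:
    """4*pi*A/P^2 with Ramanujan's perimeter approximation (semi-axes a, b)."""
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return float(4 * np.pi * (np.pi * a * b) / perim ** 2)


def sample_ground_truth(params: SimParams, rng: np.random.Generator,
                        clone_centers: np.ndarray | None = None) -> GroundTruth:
    """Sample clone and nucleus ground truth without rendering images.

    ``clone_centers`` optionally pins clone centers (stitched (x, y) px),
    overriding both the survival draw and uniform placement — used to build
    fixtures such as clones straddling tile borders.
    """
    H, W = params.scene_shape
    major, minor = params.nucleus_axes_px
    margin = 3 * params.clone_dispersion_px + major

    if clone_centers is not None:
        centers = np.asarray(clone_centers, dtype=np.float64)
        n_clones = len(centers)
    else:
        survive = rng.random(params.seeded_cells_per_well) < params.survival_prob
        n_clones = int(survive.sum())
        centers = np.column_stack([
            rng.uniform(margin, W - margin, n_clones),
            rng.uniform(margin, H - margin, n_clones),
        ])

    mu = np.log(params.cells_per_clone_median)
    sizes = np.maximum(1, np.round(
        rng.lognormal(mu, params.cells_per_clone_sigma, n_clones))).astype(int)
    if params.assay == "lego":
        classes = rng.choice(len(COLOR_CLASSES), size=n_clones,
                             p=np.asarray(params.color_mix))
        class_names = [COLOR_CLASSES[i] for i in classes]
    else:
        class_names = ["UNSET"] * n_clones

    rows = []
    nid = 0
    # cells in a monolayer exclude each other regardless of clone
    # membership: the minimum center spacing applies across clones too
    # (nuclei may touch but not stack); fixtures can raise it to guarantee
    # fully resolvable cells
    dmin = params.min_nucleus_spacing_px
    if dmin is None:
        dmin = 0.85 * minor
    placed_all: list[np.ndarray] = []
    for ci in range(n_clones):
        exclude = np.concatenate(placed_all) if placed_all else None
        if clone_centers is None and exclude is not None:
            # the founder takes the clone center verbatim, so the center
            # itself must keep clear of already-placed nuclei
            for _try in range(100):
                d2 = ((exclude - centers[ci]) ** 2).sum(axis=1)
                if d2.min() >= dmin * dmin:
                    break
                centers[ci] = (rng.uniform(margin, W - margin),
                               rng.uniform(margin, H - margin))
        pts = _place_members(centers[ci], sizes[ci],
                             params.clone_dispersion_px, dmin, rng,
                             exclude=exclude)
        pts[:, 0] = np.clip(pts[:, 0], major, W - major - 1)
        pts[:, 1] = np.clip(pts[:, 1], major, H - major - 1)
        placed_all.append(pts)
        for k in range(sizes[ci]):
            area = np.pi * (major / 2) * (minor / 2)
            ploidy = 2.0 if rng.random() < params.g2_fraction else 1.0
            intensity = (params.intensity_scale * area * ploidy
                         * rng.lognormal(0.0, params.intensity_sigma))
            rows.append({
                "nucleus_id": nid, "clone_id": ci,
                "x": pts[k, 0], "y": pts[k, 1],
                "area": area, "major_axis": major, "minor_axis": minor,
                "theta": rng.uniform(0, np.pi),
                "intensity": intensity,
                "roundness": minor / major,
                "circularity": _ellipse_circularity(major / 2, minor / 2),
                "is_fragment": False,
                "color_class": class_names[ci],
            })
            nid += 1
    nuclei = pd.DataFrame(rows, columns=[
        "nucleus_id", "clone_id", "x", "y", "area", "major_axis", "minor_axis",
        "theta", "intensity", "roundness", "circularity", "is_fragment",
        "color_class"])
    if params.fragment_rate > 0 and len(nuclei):
        nuclei = plant_fragments(nuclei, params.fragment_rate, rng)
    clones = pd.DataFrame({
        "clone_id": np.arange(n_clones),
        "x": centers[:, 0], "y": centers[:, 1],
        "color_class": class_names,
        "n_cells": [int((nuclei["clone_id"] == i).sum()) for i in range(n_clones)],
    })
    return GroundTruth(nuclei=nuclei, clones=clones,
                       seeded_cells=params.seeded_cells_per_well,
                       surviving_clones=n_clones)


def _place_members(center: np.ndarray, n: int, dispersion: float,
                   dmin: float, rng: np.random.Generator,
                   exclude: np.ndarray | None = None) -> np.ndarray:
    """Grow clone member centroids by sequential attachment.

    Colonies form by cell division, so daughters sit adjacent to existing
    cells: the first cell takes the clone center and every further cell
    attaches one step away from a randomly chosen existing member, at a
    random angle, respecting a minimum center separation ``dmin`` (nuclei
    may touch but not stack; bounded rejection tries).  The step is
    1.5 x ``dmin`` (a cytoplasm-width gap between nuclei) or
    ``dispersion``, whichever is larger, so sparse fixtures can spread
    cells out.  The resulting cluster is compact and connected, with
    neighbour gaps bounded by ~2 steps — clones do not leave stray
    outliers that no density-based clustering could attribute.
    ``exclude`` optionally adds foreign points (other clones' nuclei) that
    must also be respected.
    """
    step = max(1.5 * dmin, dispersion)

    def clear(cand: np.ndarray, pts: list[np.ndarray]) -> bool:
        if pts and min(float(((cand - p) ** 2).sum())
                       for p in pts) < dmin * dmin:
            return False
        if exclude is not None and len(exclude):
            if float(((exclude - cand) ** 2).sum(axis=1).min()) < dmin * dmin:
                return False
        return True

    pts: list[np.ndarray] = [center.astype(np.float64).copy()]
    for _ in range(n - 1):
        # among several valid attachment sites keep the one closest to the
        # clone center: colonies fill inward gaps before sprawling outward
        best = None
        best_d2 = np.inf
        tries = 0
        while tries < 60 and (best is None or tries < 12):
            tries += 1
            parent = pts[int(rng.integers(len(pts)))]
            phi = rng.uniform(0, 2 * np.pi)
            r = step * (1.0 + 0.3 * rng.random())
            cand = parent + r * np.array([np.cos(phi), np.sin(phi)])
            if not clear(cand, pts):
                continue
            d2 = float(((cand - center) ** 2).sum())
            if d2 < best_d2:
                best, best_d2 = cand, d2
        if best is None:
            best = cand
        pts.append(best)
    return np.asarray(pts)


def plant_fragments(nuclei: pd.DataFrame, fragment_rate: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Replace a fraction of nuclei with 2-4 small fragments each.

    Emulates fragmented nuclei, DNA fragments and micronuclei: each selected
    nucleus is replaced by 2-4 pieces with areas drawn uniformly from
    [0.15, 0.42]x the well's median nucleus area (below 0.15x a piece would
    be sub-resolution at this pixel scale; the upper bound keeps every
    piece under half a nucleus), with total intensity reduced in proportion
    to area.  Pieces are spread around the parent position with a minimum
    spacing so fragments stay resolvable.  Fragments are flagged
    ``is_fragment`` and keep the parent's clone and color class.
    """
    if not 0.0 <= fragment_rate <= 1.0:
        raise ValueError("fragment_rate must be in [0, 1]")
    if fragment_rate == 0 or len(nuclei) == 0:
        return nuclei
    median_area = float(nuclei["area"].median())
    cap = 0.42 * median_area
    floor = 0.15 * median_area
    pick = rng.random(len(nuclei)) < fragment_rate
    kept = nuclei[~pick].copy()
    out = [kept]
    next_id = int(nuclei["nucleus_id"].max()) + 1
    frag_rows = []
    # fragments must stay clear of every intact nucleus: micronuclei sit in
    # free cytoplasmic space, and fusing them onto neighbours would create
    # objects that exist in neither the truth table nor reality
    others = kept[["x", "y"]].to_numpy(dtype=np.float64)
    for _, parent in nuclei[pick].iterrows():
        k = int(rng.integers(2, 5))
        areas = rng.uniform(floor, cap, k)
        aspect = parent["major_axis"] / parent["minor_axis"]
        placed: list[np.ndarray] = []
        sep = 0.9 * parent["major_axis"]
        clear = 1.1 * parent["major_axis"]
        center = np.array([parent["x"], parent["y"]])
        for fa in areas:
            fminor = 2 * np.sqrt(fa / (np.pi * aspect))
            fmajor = aspect * fminor
            offset = rng.normal(0, 1.3 * parent["major_axis"], 2)
            for _try in range(60):
                ok = (not placed or min(
                    float(((offset - p) ** 2).sum())
                    for p in placed) >= sep * sep)
                if ok and len(others):
                    d2 = ((others - (center + offset)) ** 2).sum(axis=1)
                    ok = bool(d2.min() >= clear * clear)
                if ok:
                    break
                offset = rng.normal(0, 1.3 * parent["major_axis"], 2)
            placed.append(offset)
            frag_rows.append({
                "nucleus_id": next_id, "clone_id": parent["clone_id"],
                "x": parent["x"] + offset[0], "y": parent["y"] + offset[1],
                "area": fa, "major_axis": fmajor, "minor_axis": fminor,
                "theta": rng.uniform(0, np.pi),
                "intensity": parent["intensity"] * fa / parent["area"],
                "roundness": fminor / fmajor,
                "circularity": _ellipse_circularity(fmajor / 2, fminor / 2),
                "is_fragment": True,
                "color_class": parent["color_class"],
            })
            next_id += 1
    out.append(pd.DataFrame(frag_rows, columns=nuclei.columns))
    result = pd.concat(out, ignore_index=True)
    return result.sort_values("nucleus_id", ignore_index=True)


def render_scene(truth: GroundTruth, params: SimParams) -> np.ndarray:
    """Noise-free stitched scene, shape (n_channels, H, W).

    Each nucleus is an anisotropic Gaussian blob with sigma = semi-axis / 2
    (so the nominal ellipse is the 2-sigma contour) and unit-normalized
    integral scaled to its total intensity, added to every channel of its
    color class (channel additivity: an RG nucleus carries its full
    intensity in both R and G).
    """
    H, W = params.scene_shape
    nch = len(params.channel_names)
    scene = np.zeros((nch, H, W), dtype=np.float64)
    for row in truth.nuclei.itertuples():
        sa, sb = row.major_axis / 4.0, row.minor_axis / 4.0
        half = int(np.ceil(4.5 * sa)) + 1
        cx, cy = row.x, row.y
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0c, x1c = max(0, x0), min(W, x1)
        y0c, y1c = max(0, y0), min(H, y1)
        if x0c >= x1c or y0c >= y1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        dx, dy = xx - cx, yy - cy
        ct, st = np.cos(row.theta), np.sin(row.theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        amp = row.intensity / (2 * np.pi * sa * sb)
        blob = amp * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
        if params.assay == "dna":
            channels = (0,)
        else:
            channels = CLASS_CHANNELS.get(row.color_class, ())
        for ci in channels:
            scene[ci, y0c:y1c, x0c:x1c] += blob
    return scene


def illumination_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Radial gain field: 1 at tile center, (1 - amplitude) at the corners."""
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must be in [0, 1)")
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return 1.0 - amplitude * d2 / (cy ** 2 + cx ** 2)


def render_illumination(tile: np.ndarray, amplitude: float) -> np.ndarray:
    """Apply the radial illumination gradient to one tile."""
    return tile * illumination_field(tile.shape, amplitude)


def _apply_camera(tile: np.ndarray, params: SimParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Illumination, Poisson-Gaussian noise and uint16 quantization."""
    out = tile + params.background_level
    if params.illumination_amplitude > 0:
        out = render_illumination(out, params.illumination_amplitude)
    if params.poisson_gain > 0:
        photons = np.clip(out, 0, None) / params.poisson_gain
        out = rng.poisson(photons) * params.poisson_gain
    if params.gauss_sigma > 0:
        out = out + rng.normal(0, params.gauss_sigma, out.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def generate_well(params: SimParams,
                  clone_centers: np.ndarray | None = None,
                  origin_jitter: np.ndarray | None = None,
                  ) -> tuple[TileScan, GroundTruth]:
    """Simulate one well: ground truth plus the tile scan imaging it.

    ``origin_jitter`` is an optional (rows, cols, 2) integer array of (y, x)
    errors added to each tile's true cut position, emulating stage
    repeatability error; the stitcher should recover it.  Identical params
    (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    truth = sample_ground_truth(params, rng, clone_centers=clone_centers)
    scene = render_scene(truth, params)

    rows, cols = params.tile_grid
    h, w = params.tile_size_px
    nch = scene.shape[0]
    dy = int(round(h * (1 - params.overlap_frac)))
    dx = int(round(w * (1 - params.overlap_frac)))

    pad = 0
    if origin_jitter is not None:
        origin_jitter = np.asarray(origin_jitter, dtype=int)
        if origin_jitter.shape != (rows, cols, 2):
            raise ValueError("origin_jitter must have shape (rows, cols, 2)")
        pad = int(np.abs(origin_jitter).max())
        scene = np.pad(scene, ((0, 0), (pad, pad), (pad, pad)))

    tiles = np.zeros((rows, cols, nch, h, w), dtype=np.uint16)
    for r in range(rows):
        for c in range(cols):
            oy, ox = r * dy + pad, c * dx + pad
            if origin_jitter is not None:
                oy += origin_jitter[r, c, 0]
                ox += origin_jitter[r, c, 1]
            for ci in range(nch):
                raw = scene[ci, oy:oy + h, ox:ox + w]
                tiles[r, c, ci] = _apply_camera(raw, params, rng)
    scan = TileScan(tiles=tiles, overlap_frac=params.overlap_frac,
                    channel_names=params.channel_names)
    return scan, truth


def write_well(scan: TileScan, truth: GroundTruth, params: SimParams,
               outdir: str | Path) -> None:
    """Write tiles as TIFF, ground truth as CSV and params as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan.write(outdir)
    truth.write(outdir)
    params.to_yaml(outdir / "sim.yaml")


def sample_color_nuclei(n_per_class: int, crosstalk: float = 0.05,
                        include_trash: bool = False,
                        nucleus_axes_px: tuple[float, float] = (12.0, 9.0),
                        intensity_scale: float = 1500.0,
                        intensity_sigma: float = 0.15,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Labeled nucleus intensity table for training / evaluating classifiers.

    Each class contributes ``n_per_class`` nuclei whose on-channels carry the
    full (log-normally varying) intensity and whose off-channels receive
    ``crosstalk`` x intensity x Uniform(0, 1) spectral bleed-through.  With
    ``include_trash`` an extra TRASH class of small dim fragments is added.
    """
    rng = np.random.default_rng() if rng is None else rng
    major, minor = nucleus_axes_px
    base_area = np.pi * (major / 2) * (minor / 2)
    rows = []
    classes = list(COLOR_CLASSES) + (["TRASH"] if include_trash else [])
    for cname in classes:
        for _ in range(n_per_class):
            if cname == "TRASH":
                area = base_area * rng.uniform(0.05, 0.4)
                circ = rng.uniform(0.4, 0.8)
                on = (int(rng.integers(0, 3)),)
            else:
                area = base_area * rng.lognormal(0, 0.1)
                circ = rng.uniform(0.92, 1.0)
                on = CLASS_CHANNELS[cname]
            total = intensity_scale * area * rng.lognormal(0, intensity_sigma)
            chan = np.zeros(3)
            for ci in on:
                chan[ci] = total
            for ci in range(3):
                if ci not in on:
                    chan[ci] = crosstalk * total * rng.random()
            rows.append({
                "intensity_r": chan[0], "intensity_g": chan[1],
                "intensity_b": chan[2], "area": area, "circularity": circ,
                "color_class": cname,
            })
    return pd.DataFrame(rows)
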