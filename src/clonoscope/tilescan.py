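"""Whole-well assembly from overlapping microscope tiles.

Low cell density is the defining property of clonogenic assay plates: most
tile overlap strips carry no signal at all, which defeats generic stitching
software.  The strategy here is therefore clone-guided: a cheap unaligned
mosaic locates the clones, and only tiles that actually contain clone signal
are aligned against their neighbours using normalized cross-correlation in
the overlap strips.  Tiles without signal keep their nominal stage
positions — misaligning an empty tile costs nothing.

Coordinates are 0-based pixel indices, ``(x right, y down)``, with the
origin at the top-left corner of tile (0, 0).  Offsets and origins are
stored ``(y, x)`` to match NumPy indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator
from skimage.feature import match_template
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import downscale_local_mean


@dataclass
class TileScan:
    """A rectangular grid of overlapping image tiles.

    Parameters
    ----------
    tiles : ndarray, shape (rows, cols, n_channels, h, w)
        Pixel data for every tile and channel.
    overlap_frac : float
        Nominal fraction of each tile shared with its neighbour, in (0, 0.5).
    channel_names : tuple of str
        Channel identifiers, e.g. ``("r", "g", "b")`` or ``("dna",)``.
    """

    tiles: np.ndarray
    overlap_frac: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tiles.ndim != 5:
            raise ValueError("tiles must have shape (rows, cols, channels, h, w)")
        if not 0.0 < self.overlap_frac < 0.5:
            raise ValueError("overlap_frac must be in (0, 0.5)")
        if self.tiles.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must match tile channel axis")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tiles.shape[:2]

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles.shape[3:]

    @property
    def step(self) -> tuple[int, int]:
        """Nominal stage step between neighbouring tiles, (dy, dx)."""
        h, w = self.tile_shape
        return (int(round(h * (1 - self.overlap_frac))),
                int(round(w * (1 - self.overlap_frac))))

    @property
    def nominal_origins(self) -> np.ndarray:
        """(rows, cols, 2) array of nominal (y, x) tile origins."""
        rows, cols = self.grid_shape
        dy, dx = self.step
        oy, ox = np.meshgrid(np.arange(rows) * dy, np.arange(cols) * dx,
                             indexing="ij")
        return np.stack([oy, ox], axis=-1)

    def signal(self, row: int, col: int) -> np.ndarray:
        """Channel-summed float image of one tile."""
        return self.tiles[row, col].astype(np.float64).sum(axis=0)

    # ---- I/O -----------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        """Write one 16-bit grayscale TIFF per tile per channel.

        Files are named ``r{row}_c{col}_{channel}.tif``; float data is
        clipped into the uint16 range.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows, cols = self.grid_shape
        for r in range(rows):
            for c in range(cols):
                for ci, ch in enumerate(self.channel_names):
                    img = np.clip(self.tiles[r, c, ci], 0, 65535)
                    tifffile.imwrite(outdir / f"r{r}_c{c}_{ch}.tif",
                                     img.astype(np.uint16))

    @classmethod
    def read(cls, indir: str | Path, overlap_frac: float,
             channel_names: tuple[str, ...]) -> "TileScan":
        """Read tiles written by :meth:`write` from a directory."""
        indir = Path(indir)
        files = sorted(indir.glob("r*_c*_*.tif"))
        if not files:
            raise FileNotFoundError(f"no tile TIFFs found in {indir}")
        coords = set()
        for f in files:
            r, c, _ = f.stem.split("_", 2)
            coords.add((int(r[1:]), int(c[1:])))
        rows = max(r for r, _ in coords) + 1
        cols = max(c for _, c in coords) + 1
        first = tifffile.imread(indir / f"r0_c0_{channel_names[0]}.tif")
        tiles = np.zeros((rows, cols, len(channel_names)) + first.shape,
                         dtype=first.dtype)
        for r in range(rows):
            for c in range(cols):
                for ci, ch in enumerate(channel_names):
                    path = indir / f"r{r}_c{c}_{ch}.tif"
                    if not path.exists():
                        raise FileNotFoundError(
                            f"missing tile at grid position ({r}, {c}): {path}")
                    tiles[r, c, ci] = tifffile.imread(path)
        return cls(tiles=tiles, overlap_frac=overlap_frac,
                   channel_names=tuple(channel_names))

    @classmethod
    def from_manifest(cls, manifest_csv: str | Path,
                      overlap_frac: float) -> "TileScan":
        """Build a scan from a manifest CSV with columns path,row,col,channel."""
        df = pd.read_csv(manifest_csv)
        required = {"path", "row", "col", "channel"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        channels = tuple(pd.unique(df["channel"]))
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        base = Path(manifest_csv).parent
        first = tifffile.imread(_resolve(base, df.iloc[0]["path"]))
        tiles = np.zeros((rows, cols, len(channels)) + first.shape,
                         dtype=first.dtype)
        seen = np.zeros((rows, cols, len(channels)), dtype=bool)
        for _, rec in df.iterrows():
            ci = channels.index(rec["channel"])
            tiles[int(rec["row"]), int(rec["col"]), ci] = tifffile.imread(
                _resolve(base, rec["path"]))
            seen[int(rec["row"]), int(rec["col"]), ci] = True
        if not seen.all():
            r, c, ci = np.argwhere(~seen)[0]
            raise ValueError(
                f"missing tile at grid position ({r}, {c}) channel {channels[ci]}")
        return cls(tiles=tiles, overlap_frac=overlap_frac, channel_names=channels)


def _resolve(base: Path, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else base / path


@dataclass
class StitchedWell:
    """Full-resolution composite of one well.

    ``image`` has shape (n_channels, H, W); ``provenance`` maps every output
    pixel to the flat index ``row * cols + col`` of the tile that owns it, so
    each physical object is taken from exactly one tile.
    """

    image: np.ndarray
    channel_names: tuple[str, ...]
    tile_offsets: np.ndarray
    provenance: np.ndarray
    background_surface: np.ndarray | None = None


@dataclass
class RefineResult:
    offsets: np.ndarray                       # (rows, cols, 2) int
    skipped_pairs: list = field(default_factory=list)
    aligned_pairs: list = field(default_factory=list)


def rough_mosaic(scan: TileScan, downsample: int = 4) -> np.ndarray:
    """Unaligned low-resolution mosaic used to locate clones.

    Tiles are placed at their nominal origins; overlap regions take the
    per-pixel maximum so that double-covered signal is not inflated.  The
    result is downsampled by block averaging.
    """
    rows, cols = scan.grid_shape
    h, w = scan.tile_shape
    origins = scan.nominal_origins
    H = origins[:, :, 0].max() + h
    W = origins[:, :, 1].max() + w
    canvas = np.zeros((H, W), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            oy, ox = origins[r, c]
            region = canvas[oy:oy + h, ox:ox + w]
            np.maximum(region, scan.signal(r, c), out=region)
    if downsample > 1:
        canvas = downscale_local_mean(canvas, (downsample, downsample))
    return canvas


def locate_clone_tiles(mosaic: np.ndarray, scan: TileScan,
                       downsample: int = 4) -> set[tuple[int, int]]:
    """Grid positions of tiles whose area intersects mosaic foreground.

    Foreground is defined by an Otsu threshold on the mosaic; each connected
    foreground component marks every tile rectangle its bounding box
    intersects.  A blank well yields the empty set.
    """
    if mosaic.max() <= mosaic.min():
        return set()
    fg = mosaic > threshold_otsu(mosaic)
    if not fg.any():
        return set()
    rows, cols = scan.grid_shape
    h, w = scan.tile_shape
    origins = scan.nominal_origins
    hits: set[tuple[int, int]] = set()
    for comp in regionprops(label(fg)):
        y0, x0, y1, x1 = (np.array(comp.bbox) * downsample)
        for r in range(rows):
            for c in range(cols):
                oy, ox = origins[r, c]
                if y0 < oy + h and y1 > oy and x0 < ox + w and x1 > ox:
                    hits.add((r, c))
    return hits


def _pair_shift(sig_a: np.ndarray, sig_b: np.ndarray, step: int,
                overlap: int, max_shift: int, axis: int) -> tuple[int, int] | None:
    """Integer (dy, dx) of tile B's origin relative to nominal, w.r.t. A.

    ``axis=1`` means B is right of A, ``axis=0`` below A.  Returns None when
    the overlap strip carries no usable signal.
    """
    if axis == 0:                     # vertical pair: work on transposed tiles
        sig_a, sig_b = sig_a.T, sig_b.T
    h, w = sig_a.shape
    m = max_shift
    if overlap - 2 * m < 3:
        raise ValueError(
            f"max_shift={m} too large for an overlap of {overlap} px")
    template = sig_b[m:h - m, m:overlap - m]
    search = sig_a[:, step:w]
    if template.std() < 1e-9 or search.std() < 1e-9:
        return None
    corr = match_template(search, template)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[peak] < 0.2:              # no coherent signal in the strip
        return None
    dy, dx = peak[0] - m, peak[1] - m
    return (dx, dy) if axis == 0 else (dy, dx)


def refine_offsets(scan: TileScan, clone_tiles: set[tuple[int, int]],
                   max_shift: int = 20,
                   tile_images: np.ndarray | None = None) -> RefineResult:
    """Signal-guided alignment of the tiles that contain clones.

    For each adjacent pair within ``clone_tiles`` the integer shift
    maximizing normalized cross-correlation over ±``max_shift`` px is
    estimated from the shared overlap strip.  Shifts are propagated through
    a spanning tree of successfully aligned pairs, anchored at the smallest
    grid position of each connected component (which keeps its nominal
    origin).  All other tiles keep nominal origins.  Pairs whose strips have
    no signal are skipped and reported in ``skipped_pairs``.

    ``tile_images`` optionally supplies background-corrected per-tile signal
    images of shape (rows, cols, h, w); by default the raw channel sum is
    used.
    """
    rows, cols = scan.grid_shape
    h, w = scan.tile_shape
    sy, sx = scan.step
    offsets = scan.nominal_origins.copy()
    result = RefineResult(offsets=offsets)

    def sig(r: int, c: int) -> np.ndarray:
        if tile_images is not None:
            return np.asarray(tile_images[r, c], dtype=np.float64)
        return scan.signal(r, c)

    pairs = []                      # ((rA,cA), (rB,cB), axis)
    for (r, c) in sorted(clone_tiles):
        if (r, c + 1) in clone_tiles:
            pairs.append(((r, c), (r, c + 1), 1))
        if (r + 1, c) in clone_tiles:
            pairs.append(((r, c), (r + 1, c), 0))

    edges: dict[tuple, list] = {t: [] for t in clone_tiles}
    for a, b, axis in pairs:
        step = sx if axis == 1 else sy
        overlap = (w - sx) if axis == 1 else (h - sy)
        shift = _pair_shift(sig(*a), sig(*b), step, overlap, max_shift, axis)
        if shift is None:
            result.skipped_pairs.append((a, b))
            warnings.warn(f"overlap strip between tiles {a} and {b} has no "
                          "usable signal; keeping nominal offsets")
            continue
        result.aligned_pairs.append((a, b, shift))
        edges[a].append((b, np.array(shift)))
        edges[b].append((a, -np.array(shift)))

    # propagate through each connected component from its smallest tile
    visited: set[tuple[int, int]] = set()
    nominal = scan.nominal_origins
    for root in sorted(clone_tiles):
        if root in visited:
            continue
        visited.add(root)
        queue = [root]
        while queue:
            cur = queue.pop(0)
            for nxt, shift in edges[cur]:
                if nxt in visited:
                    continue
                visited.add(nxt)
                delta = nominal[nxt[0], nxt[1]] - nominal[cur[0], cur[1]]
                offsets[nxt[0], nxt[1]] = offsets[cur[0], cur[1]] + delta + shift
                queue.append(nxt)
    return result


def stitch(scan: TileScan, offsets: np.ndarray | None = None,
           tiles: np.ndarray | None = None) -> StitchedWell:
    """Compose tiles into a full-resolution well image.

    In overlap regions every output pixel is taken from the tile whose
    center is nearest, so each physical object appears exactly once (no
    blending — blending would distort total-intensity measurements used for
    DNA content).  ``tiles`` optionally substitutes corrected pixel data of
    the same shape as ``scan.tiles``.
    """
    if offsets is None:
        offsets = scan.nominal_origins
    offsets = np.asarray(offsets, dtype=int)
    data = scan.tiles if tiles is None else tiles
    rows, cols = scan.grid_shape
    nch = data.shape[2]
    h, w = scan.tile_shape

    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols and offsets[r, c + 1, 1] - offsets[r, c, 1] > w:
                raise ValueError(f"gap between tiles ({r},{c}) and ({r},{c+1})")
            if r + 1 < rows and offsets[r + 1, c, 0] - offsets[r, c, 0] > h:
                raise ValueError(f"gap between tiles ({r},{c}) and ({r+1},{c})")

    shift = offsets.reshape(-1, 2).min(axis=0)
    offsets = offsets - shift
    H = offsets[:, :, 0].max() + h
    W = offsets[:, :, 1].max() + w

    image = np.zeros((nch, H, W), dtype=np.float64)
    best = np.full((H, W), np.inf)
    prov = np.full((H, W), -1, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    local_dist = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2
    for r in range(rows):
        for c in range(cols):
            oy, ox = offsets[r, c]
            sl = (slice(oy, oy + h), slice(ox, ox + w))
            closer = local_dist < best[sl]
            best[sl][closer] = local_dist[closer]
            prov[sl][closer] = r * cols + c
            for ci in range(nch):
                image[ci][sl][closer] = data[r, c, ci].astype(np.float64)[closer]
    return StitchedWell(image=image, channel_names=scan.channel_names,
                        tile_offsets=offsets, provenance=prov)


def estimate_background(image: np.ndarray, n_points: int = 20,
                        patch: int = 15) -> np.ndarray:
    """Smooth background surface sampled at object-free locations.

    Objects are masked by rough Otsu thresholding; ``n_points`` sample
    locations are chosen on a spatially spread grid (one per grid cell,
    nearest object-free pixel to the cell center).  The local background at
    each location is the median of the object-free pixels in a
    ``patch``×``patch`` window.  A quadratic polynomial surface is fitted to
    the samples and a smoothed thin-plate-spline correction captures any
    non-quadratic residual; beyond the sampled region the residual is
    extended flat while the polynomial extends smoothly.

    With fewer than 4 object-free samples the surface falls back to the
    global median with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() <= image.min():
        return np.full_like(image, np.median(image))

    # rough object mask by Otsu; on an object-free tile Otsu merely splits
    # the background gradient in half, so only treat the bright class as
    # objects when it is markedly brighter than the dark class.  The mask
    # is dilated generously: the soft tails of nuclei extend well past the
    # Otsu boundary and would silently lift "object-free" samples
    thr = threshold_otsu(image)
    free = image <= thr
    if free.any() and (~free).any():
        if image[~free].mean() < 1.5 * image[free].mean():
            free = np.ones_like(free)
        else:
            from scipy import ndimage as ndi
            free = ~ndi.binary_dilation(~free, iterations=patch // 2 + 3)
            if not free.any():
                free = image <= thr
    else:
        free = np.ones_like(free)
    pts, vals = _sample_background(image, free, n_points, patch)
    if len(pts) < 4:
        warnings.warn("fewer than 4 object-free background samples; "
                      "falling back to global median background")
        fallback = np.median(image[free]) if free.any() else np.median(image)
        return np.full_like(image, fallback)

    pts = np.asarray(pts, dtype=np.float64)
    vals = np.asarray(vals, dtype=np.float64)

    # quadratic trend fitted by least squares
    def design(p):
        y, x = p[:, 0] / h, p[:, 1] / w
        return np.column_stack([np.ones_like(y), y, x, y * x, y ** 2, x ** 2])

    coef, *_ = np.linalg.lstsq(design(pts), vals, rcond=None)
    # sigma-clip gross outliers: a sample landing in the faint skirt of a
    # clone can sit hundreds of counts above the true background even
    # though it passed the object mask
    for _ in range(2):
        resid = vals - design(pts) @ coef
        center = np.median(resid)
        mad = 1.4826 * np.median(np.abs(resid - center))
        keep = np.abs(resid - center) <= 4.0 * max(mad, 1e-9)
        if keep.all() or keep.sum() < 6:
            break
        pts, vals = pts[keep], vals[keep]
        coef, *_ = np.linalg.lstsq(design(pts), vals, rcond=None)
    resid = vals - design(pts) @ coef

    ny = (np.arange(h, dtype=np.float64) / h)[:, None]
    nx = (np.arange(w, dtype=np.float64) / w)[None, :]
    surface = (coef[0] + coef[1] * ny + coef[2] * nx + coef[3] * ny * nx
               + coef[4] * ny ** 2 + coef[5] * nx ** 2)

    # a smoothed thin-plate-spline correction captures non-quadratic
    # structure, but fitting pure sample noise would add spurious bumps —
    # apply it only when the residuals exceed what patch-median sampling
    # noise alone would produce
    sigma_sample = 1.253 * _pixel_noise(image, free) / np.sqrt(patch ** 2)
    resid_rms = float(np.sqrt((resid ** 2).mean()))
    if resid_rms > 2.0 * sigma_sample:
        grid_step = max(4, min(h, w) // 64)
        gy = np.arange(0, h, grid_step, dtype=np.float64)
        gx = np.arange(0, w, grid_step, dtype=np.float64)
        if gy[-1] < h - 1:
            gy = np.append(gy, h - 1)
        if gx[-1] < w - 1:
            gx = np.append(gx, w - 1)
        # clamped coordinates: the residual extends flat beyond the samples
        cy = np.clip(gy, pts[:, 0].min(), pts[:, 0].max())
        cx = np.clip(gx, pts[:, 1].min(), pts[:, 1].max())
        mesh = np.stack(np.meshgrid(cy, cx, indexing="ij"),
                        axis=-1).reshape(-1, 2)
        rbf = RBFInterpolator(pts, resid, kernel="thin_plate_spline",
                              smoothing=float(len(pts)))
        coarse = rbf(mesh).reshape(len(gy), len(gx))
        interp = RegularGridInterpolator((gy, gx), coarse, method="linear")
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        full = np.stack([yy.ravel(), xx.ravel()], axis=-1)
        surface += interp(full).reshape(h, w)
    return surface


def _pixel_noise(image: np.ndarray, free: np.ndarray) -> float:
    """Robust pixel noise sigma from horizontal first differences of
    object-free pixels (the smooth background cancels at pixel scale)."""
    pair = free[:, 1:] & free[:, :-1]
    if not pair.any():
        return 0.0
    diffs = (image[:, 1:] - image[:, :-1])[pair]
    if diffs.size > 100_000:                 # subsample: the MAD is stable
        diffs = diffs[:: diffs.size // 100_000 + 1]
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _sample_background(image: np.ndarray, free: np.ndarray, n_points: int,
                       patch: int) -> tuple[list, list]:
    """Spread-maximizing object-free sample points and their local medians."""
    h, w = image.shape
    best, shape = None, None
    for gr in range(1, n_points + 1):
        gc = int(np.ceil(n_points / gr))
        score = abs(gr / gc - h / w) + 0.05 * (gr * gc - n_points)
        if best is None or score < best:
            best, shape = score, (gr, gc)
    gr, gc = shape
    half = patch // 2
    # ideal sample positions span the whole tile, borders included, so the
    # interpolant never has to extrapolate far beyond the outermost samples
    ty = np.linspace(half, h - 1 - half, gr)
    tx = np.linspace(half, w - 1 - half, gc)
    pts, vals = [], []
    for i in range(gr):
        for j in range(gc):
            if len(pts) >= n_points:
                break
            y0, y1 = int(i * h / gr), int((i + 1) * h / gr)
            x0, x1 = int(j * w / gc), int((j + 1) * w / gc)
            cell = free[y0:y1, x0:x1]
            if not cell.any():
                continue
            cy, cx = ty[i] - y0, tx[j] - x0
            ys, xs = np.nonzero(cell)
            k = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            py, px = y0 + ys[k], x0 + xs[k]
            wy0, wy1 = max(0, py - half), min(h, py + half + 1)
            wx0, wx1 = max(0, px - half), min(w, px + half + 1)
            window = image[wy0:wy1, wx0:wx1]
            winfree = free[wy0:wy1, wx0:wx1]
            sample = window[winfree] if winfree.any() else window.ravel()
            pts.append((py, px))
            vals.append(np.median(sample))
    return pts, vals


def subtract_background(image: np.ndarray, surface: np.ndarray) -> np.ndarray:
    """Pixelwise subtraction of the background surface, clipped at zero."""
    image = np.asarray(image, dtype=np.float64)
    surface = np.asarray(surface, dtype=np.float64)
    if image.shape != surface.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs surface {surface.shape}")
    return np.clip(image - surface, 0.0, None)


def correct_tiles(scan: TileScan, n_points: int = 20,
                  patch: int = 15) -> np.ndarray:
    """Background-correct every tile and channel; returns float tile data."""
    rows, cols = scan.grid_shape
    corrected = scan.tiles.astype(np.float64)
    for r in range(rows):
        for c in range(cols):
            for ci in range(scan.tiles.shape[2]):
                img = corrected[r, c, ci]
                surface = estimate_background(img, n_points=n_points, patch=patch)
                corrected[r, c, ci] = subtract_background(img, surface)
    return corrected
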