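"""Clonogenic-survival quantities and nucleus-population statistics.

Implements the classical assay arithmetic — plating efficiency (clones
counted / cells seeded) and surviving fraction (treated PE / control PE)
with the conventional 50-cell clone threshold — plus the nucleus-level
readouts that make the assay high-content: DNA-content histograms from
normalized total stain intensity, and the fractions of anomalously small /
large / dim / bright / misshapen nuclei that report on cell fate
(fragmentation, micronuclei, senescence, cell-cycle arrest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class ThresholdConfig:
    """Cutoffs for clone counting and nucleus anomaly fractions.

    Defaults follow assay convention: a cluster of >= 50 cells counts as a
    clone in the classical readout; "small" nuclei fall below 0.5 of the
    well-median normalized intensity or area, "large" nuclei lie in the 3-10
    band of normalized intensity or the 2-4 band of normalized area;
    misshapen nuclei have roundness < 0.5 and a-circular nuclei have
    circularity < 0.9.
    """

    min_cells_per_clone: int = 50
    small_intensity_max: float = 0.5
    large_intensity_range: tuple[float, float] = (3.0, 10.0)
    small_area_max: float = 0.5
    large_area_range: tuple[float, float] = (2.0, 4.0)
    low_roundness_max: float = 0.5
    low_circularity_max: float = 0.9

    def __post_init__(self) -> None:
        for name in ("large_intensity_range", "large_area_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lower < upper")
        for name in ("min_cells_per_clone", "small_intensity_max",
                     "small_area_max", "low_roundness_max",
                     "low_circularity_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def count_clones(clones: pd.DataFrame, min_cells: int = 50) -> int:
    """Number of clones with at least ``min_cells`` member cells."""
    if len(clones) == 0:
        return 0
    return int((clones["n_cells"] >= min_cells).sum())


def plating_efficiency(clone_count: int, seeded_cells: int) -> float:
    """Clones counted / cells seeded; warns when above 1."""
    if seeded_cells <= 0:
        raise ValueError("seeded_cells must be positive")
    pe = clone_count / seeded_cells
    if pe > 1:
        warnings.warn(f"plating efficiency {pe:.3f} exceeds 1; more clones "
                      "counted than cells seeded")
    return pe


def survival_fraction(pe_treated: float, pe_control: float) -> float:
    """Treated plating efficiency over control plating efficiency."""
    if pe_control <= 0:
        raise ValueError("surviving fraction undefined: control plating "
                         "efficiency is zero")
    return pe_treated / pe_control


def dna_content_histogram(records: pd.DataFrame, bins: int = 80,
                          value_range: tuple[float, float] = (0.0, 4.0),
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of normalized total stain intensity (DNA content proxy).

    Stain intensity is proportional to total DNA, so the normalized
    intensity distribution exposes cell-cycle structure: a G1 mode near 1
    and a G2/M mode near 2.  Returns ``(frequencies, bin_edges)`` with
    frequencies summing to 1 over the in-range records.
    """
    if len(records) == 0:
        raise ValueError("cannot histogram an empty record table")
    values = records["norm_intensity"].to_numpy(dtype=np.float64)
    counts, edges = np.histogram(values, bins=bins, range=value_range)
    total = counts.sum()
    if total == 0:
        raise ValueError("no records fall inside the histogram range")
    return counts / total, edges


def histogram_modes(freqs: np.ndarray, edges: np.ndarray,
                    min_prominence: float = 0.01,
                    smooth_bins: float = 1.0) -> list[float]:
    """Subpixel positions of local maxima of a histogram.

    Peaks are located on the binned frequencies and refined by a parabolic
    fit through the peak bin and its neighbours, which removes most of the
    bin-width quantization from mode-position ratios.  Modes are returned
    in order of decreasing prominence, so the G1 and G2 modes of a DNA
    histogram are the first two entries.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth_bins > 0:                 # suppress counting-noise shoulders
        freqs = gaussian_filter1d(freqs, smooth_bins)
    peaks, props = find_peaks(freqs, prominence=min_prominence)
    peaks = peaks[np.argsort(props["prominences"])[::-1]]
    modes = []
    for p in peaks:
        if 0 < p < len(freqs) - 1:
            y0, y1, y2 = freqs[p - 1], freqs[p], freqs[p + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            modes.append(float(centers[p] + delta * (centers[1] - centers[0])))
        else:
            modes.append(float(centers[p]))
    return modes


def anomaly_fractions(records: pd.DataFrame,
                      cfg: ThresholdConfig | None = None) -> dict[str, float]:
    """Six anomaly fractions over all non-TRASH records.

    Fractions of nuclei that are dim (norm_intensity below the small
    cutoff), bright (within the large-intensity band), small or large in
    normalized area, low-roundness and low-circularity — every fraction
    over the same denominator.
    """
    cfg = cfg or ThresholdConfig()
    if len(records) == 0:
        raise ValueError("cannot compute anomaly fractions of an empty table")
    use = records
    if "color_class" in records.columns:
        keep = records["color_class"] != "TRASH"
        if keep.any():
            use = records[keep]
    n = len(use)
    ni = use["norm_intensity"].to_numpy(dtype=np.float64)
    na = use["norm_area"].to_numpy(dtype=np.float64)
    rd = use["roundness"].to_numpy(dtype=np.float64)
    ci = use["circularity"].to_numpy(dtype=np.float64)
    ilo, ihi = cfg.large_intensity_range
    alo, ahi = cfg.large_area_range
    return {
        "frac_small_intensity": float((ni < cfg.small_intensity_max).sum() / n),
        "frac_large_intensity": float(((ni >= ilo) & (ni <= ihi)).sum() / n),
        "frac_small_area": float((na < cfg.small_area_max).sum() / n),
        "frac_large_area": float(((na >= alo) & (na <= ahi)).sum() / n),
        "frac_low_roundness": float((rd < cfg.low_roundness_max).sum() / n),
        "frac_low_circularity": float((ci < cfg.low_circularity_max).sum() / n),
    }


@dataclass
class WellSummary:
    """Per-well aggregate readouts."""

    well_id: str
    seeded_cells: int
    clone_count_at_threshold: int
    clone_count_all: int
    plating_efficiency: float
    fractions: dict[str, float] = field(default_factory=dict)
    dna_histogram: np.ndarray | None = None
    dna_bin_edges: np.ndarray | None = None

    def to_row(self) -> dict:
        row = {
            "well_id": self.well_id,
            "seeded_cells": self.seeded_cells,
            "clone_count_at_threshold": self.clone_count_at_threshold,
            "clone_count_all": self.clone_count_all,
            "plating_efficiency": self.plating_efficiency,
        }
        row.update(self.fractions)
        return row


def summarize_well(well_id: str, nuclei: pd.DataFrame, clones: pd.DataFrame,
                   seeded_cells: int, cfg: ThresholdConfig | None = None,
                   with_dna_histogram: bool = False) -> WellSummary:
    """Assemble the per-well summary from nucleus and clone tables.

    Both the thresholded clone count (classical readout) and the total
    clone count are reported; plating efficiency uses the thresholded
    count.  The DNA histogram is only meaningful for DNA-stained wells
    (barcode marker intensity does not track DNA content).
    """
    cfg = cfg or ThresholdConfig()
    at_thr = count_clones(clones, cfg.min_cells_per_clone)
    all_cnt = count_clones(clones, 1)
    pe = plating_efficiency(at_thr, seeded_cells)
    fractions = anomaly_fractions(nuclei, cfg) if len(nuclei) else {}
    hist = edges = None
    if with_dna_histogram and len(nuclei):
        hist, edges = dna_content_histogram(nuclei)
    return WellSummary(well_id=well_id, seeded_cells=seeded_cells,
                       clone_count_at_threshold=at_thr,
                       clone_count_all=all_cnt, plating_efficiency=pe,
                       fractions=fractions, dna_histogram=hist,
                       dna_bin_edges=edges)


def select_seeding_density(counts: pd.DataFrame, tol: float = 0.15,
                           ) -> tuple[float, pd.DataFrame]:
    """Highest seeding density whose clone count is stable across days.

    ``counts`` must have columns ``density``, ``day`` and ``clone_count``
    (replicates are averaged).  Stability per density is the maximum over
    days of |count - day-mean| / day-mean; densities with stability within
    ``tol`` qualify and the highest qualifying density is returned, along
    with the per-density stability table.  When no density qualifies the
    lowest density is returned with a warning: clone merging at high
    density makes counts fall over time, and lower seeding is then the
    safe choice.
    """
    if len(counts) == 0:
        raise ValueError("empty density/day table")
    for col in ("density", "day", "clone_count"):
        if col not in counts.columns:
            raise ValueError(f"table lacks column {col}")
    per = counts.groupby(["density", "day"])["clone_count"].mean().reset_index()
    rows = []
    for density, grp in per.groupby("density"):
        if grp["day"].nunique() < 2:
            raise ValueError(f"density {density} has fewer than 2 days")
        mean = grp["clone_count"].mean()
        stability = float(np.max(np.abs(grp["clone_count"] - mean)) / mean) \
            if mean > 0 else np.inf
        rows.append({"density": density, "stability": stability})
    table = pd.DataFrame(rows).sort_values("density", ignore_index=True)
    ok = table[table["stability"] <= tol]
    if len(ok):
        return float(ok["density"].max()), table
    warnings.warn("no seeding density met the stability tolerance; "
                  "returning the lowest density")
    return float(table["density"].min()), table
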