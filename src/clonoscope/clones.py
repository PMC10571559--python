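"""Grouping nuclei into clones and computing clone-level metrics.

Clones are recovered from nucleus centroids by DBSCAN.  In the barcoded
(LeGO) arm the clustering runs independently per color class — two
overlapping clones of different colors stay separate, which is the whole
point of the barcoding — while the classical single-stain arm uses one
global run.  DBSCAN noise points are kept as singleton clones rather than
discarded: clones far below the classical 50-cell threshold are still real
clones and must remain countable.

``eps`` and ``min_samples`` are the assay's day-to-day tuning knobs; an
automatic ``eps`` is derived from the knee of the sorted k-distance curve
with a floor of twice the median nucleus major axis (so coincident or
touching nuclei cannot collapse the estimate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

CLONE_COLUMNS = [
    "clone_id", "n_cells", "area_px2", "norm_area", "compactness",
    "color_class", "x", "y", "is_noise",
]


def cluster_clones_dbscan(records: pd.DataFrame, eps: float,
                          min_samples: int = 3,
                          color_constrained: bool = True) -> pd.DataFrame:
    """Assign a ``clone_id`` to every non-TRASH nucleus.

    Standard DBSCAN core/border/noise semantics with Euclidean distance on
    stitched centroids.  With ``color_constrained`` the algorithm runs
    independently within each color class and clone ids are disjoint across
    classes.  Noise points become singleton clones flagged ``unclustered``;
    TRASH records keep ``clone_id = -1``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    out = records.copy()
    out["clone_id"] = -1
    out["unclustered"] = False
    usable = out["color_class"] != "TRASH"
    next_id = 0
    if color_constrained:
        groups = [g for _, g in out[usable].groupby("color_class", sort=True)]
    else:
        groups = [out[usable]]
    for grp in groups:
        if len(grp) == 0:
            continue
        pts = grp[["x", "y"]].to_numpy(dtype=np.float64)
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
        ids = np.full(len(grp), -1, dtype=np.int64)
        for lab in np.unique(labels):
            if lab == -1:
                continue
            ids[labels == lab] = next_id
            next_id += 1
        noise = labels == -1
        for i in np.nonzero(noise)[0]:
            ids[i] = next_id
            next_id += 1
        out.loc[grp.index, "clone_id"] = ids
        out.loc[grp.index, "unclustered"] = noise
    out.attrs.update(records.attrs)
    return out


def estimate_eps(records: pd.DataFrame, min_samples: int = 3,
                 floor: float | None = None,
                 headroom: float = 1.0) -> tuple[float, np.ndarray]:
    """Automatic DBSCAN radius from the sorted k-distance curve.

    The knee of the ascending k-distance curve (k = min_samples), found as
    the point of maximum distance to the chord joining the curve's
    endpoints, marks the upper edge of the within-clone neighbour-distance
    distribution and is the operating radius (scaled by ``headroom``,
    default 1).  A floor of twice the median nucleus major axis (the
    intensity-weighted axis when available) guards against degenerate
    collapse: it replaces the knee only when the knee falls below half the
    floor, as happens with duplicated or stacked points — within-clone
    spacing in confluent colonies is about one nucleus length, so a healthy
    knee legitimately sits below 2x the axis and must not be overridden.
    Returns ``(eps, curve)`` so the curve can be audited.
    """
    pts = records[["x", "y"]].to_numpy(dtype=np.float64)
    if len(pts) < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} records, got {len(pts)}")
    nn = NearestNeighbors(n_neighbors=min_samples).fit(pts)
    dists, _ = nn.kneighbors(pts)
    curve = np.sort(dists[:, -1])
    if floor is None:
        floor = 0.0
        axis_col = "weighted_major_axis" \
            if "weighted_major_axis" in records.columns else "major_axis"
        if axis_col in records.columns and len(records):
            floor = 2.0 * float(records[axis_col].median())
    n = len(curve)
    if n < 3 or curve[-1] == curve[0]:
        eps = float(curve[-1])
    else:
        x = np.arange(n, dtype=np.float64) / (n - 1)
        y = (curve - curve[0]) / (curve[-1] - curve[0])
        # distance from each point to the chord y = x
        eps = headroom * float(curve[int(np.argmax(x - y))])
    if eps < 0.5 * floor:
        eps = floor
    return eps, curve


def clone_metrics(records: pd.DataFrame, median_nucleus_area: float,
                  clone_col: str = "clone_id") -> pd.DataFrame:
    """Clone-level table from clustered nucleus records.

    Clone area is the convex-hull area of member centroids for three or
    more non-collinear members, otherwise the summed member nucleus area;
    ``norm_area`` divides by the well's median nucleus area and
    ``compactness`` is cells per normalized clone area.  The dominant color
    class of the members is reported per clone.
    """
    rows = []
    usable = records[records[clone_col] >= 0]
    for cid, grp in usable.groupby(clone_col, sort=True):
        pts = grp[["x", "y"]].to_numpy(dtype=np.float64)
        n = len(grp)
        area = _hull_area(pts)
        if area is None or area <= 0:
            area = float(grp["area"].sum())
        norm_area = area / median_nucleus_area if median_nucleus_area > 0 \
            else np.nan
        compactness = n / norm_area if norm_area and norm_area > 0 else np.nan
        color = "UNSET"
        if "color_class" in grp:
            counts = grp["color_class"].value_counts()
            if len(counts):
                color = str(counts.index[0])
        rows.append({
            "clone_id": int(cid), "n_cells": n, "area_px2": area,
            "norm_area": norm_area, "compactness": compactness,
            "color_class": color,
            "x": float(pts[:, 0].mean()), "y": float(pts[:, 1].mean()),
            "is_noise": bool(grp["unclustered"].all())
            if "unclustered" in grp else False,
        })
    return pd.DataFrame(rows, columns=CLONE_COLUMNS)


def _hull_area(pts: np.ndarray) -> float | None:
    if len(pts) < 3:
        return None
    try:
        return float(ConvexHull(pts).volume)   # 2-D: volume is the area
    except QhullError:
        return None                            # collinear members


def call_clones(records: pd.DataFrame, eps: float | None = None,
                min_samples: int = 3, color_constrained: bool = True,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster nuclei and compute clone metrics in one step.

    ``eps=None`` triggers automatic estimation.  Returns the augmented
    nucleus table and the clone table.
    """
    usable = records[records["color_class"] != "TRASH"]
    if eps is None:
        eps, _ = estimate_eps(usable, min_samples=min_samples)
    clustered = cluster_clones_dbscan(records, eps=eps,
                                      min_samples=min_samples,
                                      color_constrained=color_constrained)
    keep = clustered["color_class"] != "TRASH"
    median_area = float(clustered.loc[keep, "area"].median()) if keep.any() \
        else float("nan")
    clones = clone_metrics(clustered, median_area)
    clones.attrs["eps"] = eps
    clones.attrs["min_samples"] = min_samples
    return clustered, clones


def longitudinal_link(daily_clones: dict[object, pd.DataFrame]) -> pd.DataFrame:
    """Per-day clone counts and size distributions for one well over time.

    No cross-day identity tracking is attempted: the assay compares counts
    and per-day distributions of cells per clone (and their median), which
    is what longitudinal imaging of live barcoded cultures supports without
    a lineage model.
    """
    rows = []
    for day in sorted(daily_clones):
        clones = daily_clones[day]
        sizes = clones["n_cells"].to_numpy()
        rows.append({
            "day": day,
            "clone_count": int(len(clones)),
            "median_cells_per_clone": float(np.median(sizes)) if len(sizes)
            else np.nan,
            "cells_per_clone": sizes.tolist(),
        })
    return pd.DataFrame(rows, columns=["day", "clone_count",
                                       "median_cells_per_clone",
                                       "cells_per_clone"])
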