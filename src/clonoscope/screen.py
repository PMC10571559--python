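"""Multi-treatment screen analytics on per-well clone and nucleus tables.

Turns a plate of treated wells into the screen readouts: per-treatment
survival fraction, normalized median nuclei per clone, clone-size
heterogeneity (IQR of cells per clone), normalized median nucleus size and
circularity; hierarchical clustering of treatments on the standardized
metric matrix; and metric-versus-survival correlation.

Normalization is to the plate-matched untreated control of the same cell
line: every metric of a treatment is divided by the control's value, so
control rows read exactly 1.  Replicates are aggregated as the mean of
per-replicate medians before normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.stats import pearsonr, spearmanr

METRIC_COLUMNS = [
    "survival_fraction",
    "norm_median_nuclei_per_clone",
    "norm_iqr_heterogeneity",
    "norm_median_nucleus_size",
    "norm_median_circularity",
]


def clone_heterogeneity_iqr(clone_sizes) -> float:
    """Interquartile range of cells per clone (linear-interpolated quartiles).

    A wide IQR means clone sizes within the condition are heterogeneous —
    some clones kept proliferating while others stalled.
    """
    sizes = np.asarray(clone_sizes, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("need at least one clone")
    q1, q3 = np.percentile(sizes, [25, 75], method="linear")
    return float(q3 - q1)


def normalize_to_control(treated: dict[str, float],
                         control: dict[str, float]) -> dict[str, float]:
    """Divide each treated metric by the same-plate untreated control value."""
    out = {}
    for name, value in treated.items():
        ctrl = control.get(name)
        if ctrl is None or ctrl == 0:
            raise ValueError(f"control metric {name!r} is zero or missing; "
                             "cannot normalize")
        out[name] = value / ctrl
    return out


def cluster_treatments(table: pd.DataFrame, k: int = 3,
                       metric_columns: list[str] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of treatments into ``k`` classes.

    Columns are standardized to zero mean and unit variance across
    treatments (constant columns are dropped with a warning), treatments
    are clustered by Ward linkage on Euclidean distance and the tree is cut
    at ``k`` clusters.  Returns ``(labels, leaf_order)``; labels span 1..k
    and the leaf order is the dendrogram ordering for heatmap rendering.
    Deterministic for a given row order.
    """
    cols = metric_columns or [c for c in METRIC_COLUMNS if c in table.columns]
    if len(table) < k:
        raise ValueError(f"need at least k={k} treatments, got {len(table)}")
    X = table[cols].to_numpy(dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("metric matrix contains missing values")
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.all():
        dropped = [c for c, k_ in zip(cols, keep) if not k_]
        warnings.warn(f"constant metric columns dropped from clustering: "
                      f"{dropped}")
    if not keep.any():
        raise ValueError("all metric columns are constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    link = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(link, t=k, criterion="maxclust")
    order = np.asarray(dendrogram(link, no_plot=True)["leaves"], dtype=int)
    return labels, order


def correlate_metrics_with_survival(table: pd.DataFrame,
                                    metric_columns: list[str] | None = None,
                                    ) -> pd.DataFrame:
    """Pearson and Spearman correlation of each metric vs survival fraction.

    Zero-variance metrics yield NaN coefficients (undefined, not zero).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 treatments for correlation")
    cols = metric_columns or [c for c in METRIC_COLUMNS
                              if c in table.columns
                              and c != "survival_fraction"]
    sf = table["survival_fraction"].to_numpy(dtype=np.float64)
    rows = []
    for col in cols:
        x = table[col].to_numpy(dtype=np.float64)
        if np.std(x) == 0 or np.std(sf) == 0:
            rows.append({"metric": col, "pearson_r": np.nan,
                         "spearman_rho": np.nan, "n": len(x)})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = pearsonr(x, sf)[0]
            sr = spearmanr(x, sf)[0]
        rows.append({"metric": col, "pearson_r": float(pr),
                     "spearman_rho": float(sr), "n": len(x)})
    return pd.DataFrame(rows, columns=["metric", "pearson_r", "spearman_rho",
                                       "n"])


def treatment_metrics(clones: pd.DataFrame, nuclei: pd.DataFrame,
                      clone_count: int, seeded_cells: int) -> dict[str, float]:
    """Raw (un-normalized) per-well screen metrics."""
    return {
        "plating_efficiency": clone_count / seeded_cells,
        "median_nuclei_per_clone": float(clones["n_cells"].median()),
        "iqr_heterogeneity": clone_heterogeneity_iqr(clones["n_cells"]),
        "median_nucleus_size": float(nuclei["area"].median()),
        "median_circularity": float(nuclei["circularity"].median()),
    }


def build_screen_table(per_well: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-well raw metrics into a normalized treatment table.

    ``per_well`` needs columns ``cell_line``, ``treatment``, ``is_control``,
    ``replicate`` and the raw metric columns from
    :func:`treatment_metrics`.  Replicates are averaged, then every
    treatment row (controls included) is divided by its cell line's control
    row, yielding the normalized ScreenTable with columns
    ``survival_fraction``, ``norm_median_nuclei_per_clone``,
    ``norm_iqr_heterogeneity``, ``norm_median_nucleus_size`` and
    ``norm_median_circularity``.
    """
    raw_cols = ["plating_efficiency", "median_nuclei_per_clone",
                "iqr_heterogeneity", "median_nucleus_size",
                "median_circularity"]
    agg = (per_well.groupby(["cell_line", "treatment", "is_control"])[raw_cols]
           .mean().reset_index())
    rows = []
    for line, grp in agg.groupby("cell_line"):
        ctrl = grp[grp["is_control"]]
        if len(ctrl) != 1:
            raise ValueError(f"cell line {line!r} needs exactly one control "
                             f"treatment, found {len(ctrl)}")
        ctrl = ctrl.iloc[0]
        for _, rec in grp.iterrows():
            rows.append({
                "cell_line": line,
                "treatment": rec["treatment"],
                "is_control": bool(rec["is_control"]),
                "survival_fraction":
                    rec["plating_efficiency"] / ctrl["plating_efficiency"],
                "norm_median_nuclei_per_clone":
                    rec["median_nuclei_per_clone"]
                    / ctrl["median_nuclei_per_clone"],
                "norm_iqr_heterogeneity":
                    rec["iqr_heterogeneity"] / ctrl["iqr_heterogeneity"],
                "norm_median_nucleus_size":
                    rec["median_nucleus_size"] / ctrl["median_nucleus_size"],
                "norm_median_circularity":
                    rec["median_circularity"] / ctrl["median_circularity"],
            })
    return pd.DataFrame(rows)


#: effect tiers for the mock screen, per dose (1x, 2x): survival
#: probability, clone-growth multiplier (median cells per clone) and
#: nucleus-size multiplier (cell-cycle arrest enlarges nuclei)
SCREEN_EFFECTS = {
    "none": {1.0: (1.0, 1.0, 1.0), 2.0: (1.0, 1.0, 1.0)},
    "moderate": {1.0: (0.7, 0.85, 1.08), 2.0: (0.5, 0.7, 1.15)},
    "strong": {1.0: (0.3, 0.6, 1.15), 2.0: (0.1, 0.45, 1.25)},
}


def simulate_screen(n_drugs: int = 20, doses: tuple[float, ...] = (1.0, 2.0),
                    cell_lines: tuple[str, ...] = ("line-A", "line-B"),
                    replicates: int = 3, seeded_cells: int = 150,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mock multi-treatment screen with known effect sizes.

    Drugs cycle through three effect tiers (no effect / moderate /
    strong kill) that scale both the survival probability and clone growth.
    Every well is simulated at the clone/nucleus level (no image
    rendering), clones are re-called with color-constrained DBSCAN and the
    per-well raw screen metrics are measured, so the tabular screen
    analytics run on the same machinery as imaged wells.

    Returns ``(per_well, drug_truth)``: the per-well raw-metric table ready
    for :func:`build_screen_table`, and the drug-to-tier assignment.
    """
    from clonoscope import clones as clone_mod
    from clonoscope.simulate import SimParams, sample_ground_truth

    tiers = list(SCREEN_EFFECTS)
    drugs = [(f"D{i + 1:02d}", tiers[i % len(tiers)]) for i in range(n_drugs)]
    rows = []
    rng = np.random.default_rng(seed)
    for line in cell_lines:
        conditions = [("control", None, None)] + [
            (drug, tier, dose) for drug, tier in drugs for dose in doses]
        for treatment, tier, dose in conditions:
            for rep in range(replicates):
                if tier is None:
                    sp, growth, nscale = 1.0, 1.0, 1.0
                    name = "control"
                else:
                    sp, growth, nscale = SCREEN_EFFECTS[tier][dose]
                    name = f"{treatment}@{dose:g}"
                params = SimParams(
                    seeded_cells_per_well=seeded_cells, survival_prob=sp,
                    cells_per_clone_median=8.0 * growth,
                    nucleus_axes_px=(12.0 * nscale, 9.0 * nscale),
                    seed=int(rng.integers(0, 2 ** 31)))
                truth = sample_ground_truth(
                    params, np.random.default_rng(params.seed))
                nuclei = truth.nuclei
                if len(nuclei) == 0:
                    continue
                called, clone_table = clone_mod.call_clones(
                    nuclei.assign(clone_id=-1), color_constrained=True)
                metrics = treatment_metrics(
                    clone_table, nuclei,
                    clone_count=int((clone_table["n_cells"] >= 1).sum()),
                    seeded_cells=seeded_cells)
                rows.append({
                    "cell_line": line, "treatment": name,
                    "is_control": tier is None, "replicate": rep,
                    **metrics,
                })
    per_well = pd.DataFrame(rows)
    drug_truth = pd.DataFrame(
        [{"treatment": f"{d}@{dose:g}", "tier": t}
         for d, t in drugs for dose in doses])
    return per_well, drug_truth


def plot_screen_heatmap(table: pd.DataFrame, labels: np.ndarray,
                        order: np.ndarray, path) -> None:
    """Render the clustered treatment-by-metric heatmap to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in METRIC_COLUMNS if c in table.columns]
    data = table.iloc[order][cols].to_numpy(dtype=np.float64)
    fig, ax = plt.subplots(figsize=(6, max(4, 0.25 * len(table))))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=45, ha="right", fontsize=7)
    names = [f"{t} ({l})" for t, l in
             zip(table.iloc[order]["treatment"], labels[order])]
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(names, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized metric")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
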