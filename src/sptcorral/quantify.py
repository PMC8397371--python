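"""Corral-wise and nuclear intensity quantification.

Per-corral mean intensities are background-subtracted and expressed as
channel ratios (signal over ligand), averaged per cell and region so that
each cell contributes one paired (mobile, immobile) data point.  Time-lapse
recruitment series are normalized to a per-cell maximum for heat-map
display and summarized by the maximum and the time-integrated (cumulative)
intensity per ligand within an observation window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .regions import RegionMask

TABLE_COLUMNS = [
    "cell_id", "corral_id", "region_class", "timepoint", "channel",
    "mean_intensity", "background", "net_intensity",
]


def corral_mean_intensity(
    image: np.ndarray,
    mask: RegionMask,
    background_mode: str = "global",
    cell_id: int = 0,
    channel: str = "signal",
    timepoint: float = 0.0,
) -> pd.DataFrame:
    """Background-subtracted mean intensity of each corral.

    ``background_mode`` "global" uses the median of all off-pattern pixels;
    "local" uses, per corral, the median of a 3-px annulus starting 1 px
    outside the corral (restricted to background).  Net intensity is
    floored at zero.  Corrals with no pixels are excluded.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.labels.shape:
        raise ValueError("image and mask shapes differ")
    if background_mode not in ("global", "local"):
        raise ValueError("background_mode must be 'global' or 'local'")
    off = mask.labels == 0
    global_bg = float(np.median(img[off])) if off.any() else 0.0
    rows = []
    for cid in mask.corral_ids:
        sel = mask.labels == cid
        if not sel.any():
            continue
        mean = float(img[sel].mean())
        if background_mode == "global":
            bg = global_bg
        else:
            inner = ndi.binary_dilation(sel, disk(1))
            outer = ndi.binary_dilation(sel, disk(4))
            ring = outer & ~inner & off
            bg = float(np.median(img[ring])) if ring.any() else global_bg
        rows.append(
            (
                cell_id, cid, mask.region_class.get(cid, "unassigned"),
                timepoint, channel, mean, bg, max(mean - bg, 0.0),
            )
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def channel_ratio_per_cell(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-corral ratio of two channels and its per-cell, per-region mean.

    Channel A is the signal (e.g. receptor or adaptor stain), channel B the
    reference (ligand).  Corrals whose reference net intensity is ≤ 0 are
    excluded; the count of exclusions is returned.  The per-cell table (one
    row per cell × region, column ``mean_ratio``) feeds the paired
    region comparison.
    """
    keys = ["cell_id", "corral_id"]
    a = table_a[keys + ["region_class", "net_intensity"]].rename(
        columns={"net_intensity": "net_a"}
    )
    b = table_b[keys + ["net_intensity"]].rename(columns={"net_intensity": "net_b"})
    merged = a.merge(b, on=keys, how="inner")
    bad = merged["net_b"] <= 0
    n_excluded = int(bad.sum())
    merged = merged[~bad].copy()
    merged["ratio"] = merged["net_a"] / merged["net_b"]
    per_cell = (
        merged.groupby(["cell_id", "region_class"], as_index=False)["ratio"]
        .mean()
        .rename(columns={"ratio": "mean_ratio"})
    )
    return per_cell, merged, n_excluded


def timelapse_heatmap(series: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Corral × time matrix normalized to the per-cell maximum.

    Every intensity is divided by the single highest net intensity over all
    corrals and times of that cell, so the maximum entry is exactly 1
    whenever any intensity is positive.  Expects a table for one cell
    (column ``net_intensity``); returns (matrix, all_zero_flag).
    """
    if len(series) == 0:
        raise ValueError("empty intensity series")
    if series["cell_id"].nunique() > 1:
        raise ValueError("heatmap normalization is per cell; pass one cell")
    pivot = series.pivot_table(
        index="corral_id", columns="timepoint", values="net_intensity",
        aggfunc="mean",
    ).sort_index()
    peak = float(np.nanmax(pivot.to_numpy()))
    if peak <= 0:
        return pivot * 0.0, True
    return pivot / peak, False


def max_and_cumulative(
    series: pd.DataFrame,
    window: float,
    ligand: dict | pd.Series,
) -> pd.DataFrame:
    """Maximum and cumulative (time-integrated) intensity per ligand.

    Within ``window`` seconds from the first timepoint, each corral's
    maximal net intensity and its trapezoid time-integral are divided by
    that corral's ligand intensity.  Corrals missing a ligand value are
    excluded.  Returns one row per corral with columns ``max_per_ligand``
    and ``cumulative_per_ligand`` (units: intensity and intensity·s per
    ligand count).
    """
    if len(series) == 0:
        raise ValueError("empty intensity series")
    t0 = float(series["timepoint"].min())
    duration = float(series["timepoint"].max()) - t0
    if window > duration + 1e-9:
        raise ValueError(f"window {window}s exceeds series duration {duration}s")
    rows = []
    for (cell, cid), g in series.groupby(["cell_id", "corral_id"]):
        key = (cell, cid) if (cell, cid) in ligand else cid
        if key not in ligand:
            continue
        lig = float(ligand[key])
        if lig <= 0:
            continue
        g = g.sort_values("timepoint")
        tt = g["timepoint"].to_numpy(dtype=float)
        vv = g["net_intensity"].to_numpy(dtype=float)
        in_win = tt <= t0 + window + 1e-9
        rows.append(
            (
                cell, cid, g["region_class"].iloc[0],
                float(vv[in_win].max()) / lig,
                float(np.trapezoid(vv[in_win], tt[in_win])) / lig,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "corral_id", "region_class",
                 "max_per_ligand", "cumulative_per_ligand"],
    )


def nuclear_ratio(
    signal_image: np.ndarray,
    nuclear_mask: np.ndarray,
    ligand_reference: float,
    background: float | None = None,
) -> float:
    """Mean nuclear net intensity divided by the substrate ligand intensity.

    The nuclear mask is an input (nuclear segmentation is upstream of this
    analysis); ``background`` defaults to the median intensity outside the
    mask.  Net intensity is floored at zero, so a signal equal to
    background gives ratio 0.
    """
    img = np.asarray(signal_image, dtype=float)
    m = np.asarray(nuclear_mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("signal image and nuclear mask shapes differ")
    if not m.any():
        raise ValueError("empty nuclear mask")
    if ligand_reference <= 0:
        raise ValueError("ligand_reference must be positive")
    if background is None:
        outside = ~m
        background = float(np.median(img[outside])) if outside.any() else 0.0
    net = max(float(img[m].mean()) - background, 0.0)
    return net / ligand_reference


def percent_increase(mobile_mean: float, immobile_mean: float) -> float:
    """Percent by which the mobile mean exceeds the immobile mean."""
    if immobile_mean == 0:
        raise ValueError("immobile mean is zero; percent increase undefined")
    return 100.0 * (mobile_mean / immobile_mean - 1.0)


def save_heatmap_png(matrix: pd.DataFrame, path, cmap: str = "inferno") -> None:
    """Render a corral × time recruitment heat map to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap,
                   vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xlabel("time point")
    ax.set_ylabel("corral")
    fig.colorbar(im, ax=ax, label="normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
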