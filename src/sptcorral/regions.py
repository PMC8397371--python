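"""Corral masks from the ligand reference channel and region assignment.

The pre-acquired ligand image defines where mobile and immobile corrals
are: a global threshold followed by connected-component filtering yields
one label per corral, the per-corral intensity concentration separates
clustered (mobile) from uniform (immobile) ligand, and each trajectory is
assigned the region of its first-appearance position.  Automated
segmentation is a reconstruction of a manual outlining step, so
user-supplied masks and class maps always override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import expand_labels

from .synthetic import PatternLayout
from .tracking import Trajectory


@dataclass
class RegionMask:
    """Label image of corrals plus per-corral class, area and ligand intensity."""

    labels: np.ndarray                       # 0 = background, k = corral k
    region_class: dict[int, str] = field(default_factory=dict)
    area_um2: dict[int, float] = field(default_factory=dict)
    mean_ligand: dict[int, float] = field(default_factory=dict)
    pixel_size: float = 1.0                  # µm / pixel
    empty: bool = False

    def __post_init__(self):
        ids = set(np.unique(self.labels)) - {0}
        for cid in self.region_class:
            if cid not in ids:
                raise ValueError(f"corral id {cid} missing from label image")

    @property
    def corral_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def class_area(self, region: str) -> float:
        return sum(
            a for cid, a in self.area_um2.items()
            if self.region_class.get(cid) == region
        )


def segment_corrals(
    ligand_image: np.ndarray,
    expected_radius: float,
    pixel_size: float,
    circularity_min: float = 0.6,
    area_bounds: tuple[float, float] = (0.5, 2.0),
) -> RegionMask:
    """Segment corrals in the ligand channel.

    Global threshold → connected components → keep components whose area is
    within ``area_bounds`` × the expected disk area and whose circularity
    (4πA/P²) is at least ``circularity_min``; kept components are dilated by
    one pixel so rim-trapped ligand clusters stay inside their corral.

    The threshold is the lowest of a three-class Otsu on the smoothed
    log-intensity.  Clustered (mobile) corrals concentrate most of their
    ligand into one bright punctum, leaving the corral body an order of
    magnitude dimmer than an immobile corral; a plain two-class Otsu then
    cuts between the two corral populations and loses the mobile bodies,
    while the three-class split keeps background vs. dim body vs. bright
    separated.
    """
    if expected_radius <= 0:
        raise ValueError("expected_radius must be positive")
    img = np.asarray(ligand_image, dtype=float)
    mask = RegionMask(labels=np.zeros(img.shape, dtype=np.int32),
                      pixel_size=pixel_size, empty=True)
    if img.max() <= img.min():
        warnings.warn("ligand image is constant; returning empty mask")
        return mask
    sm = gaussian(img, 1.0)
    scale = max(float(np.median(np.abs(sm - np.median(sm)))), 1e-9)
    logim = np.log1p(np.clip(sm, 0, None) / scale)
    try:
        thr_log = threshold_multiotsu(logim, classes=3)[0]
    except ValueError:           # degenerate histogram: fall back to Otsu
        thr_log = threshold_otsu(logim)
    # components are found on the smoothed image (noise-robust), then each
    # kept component is refined by the same threshold on the raw image so
    # the blurred boundary does not inflate the corral area
    thr = scale * np.expm1(thr_log)
    lab = sk_label(sm > thr)
    raw_fg = img > thr
    exp_area_px = np.pi * (expected_radius / pixel_size) ** 2
    keep = np.zeros_like(lab)
    next_id = 1
    for rp in regionprops(lab):
        area = rp.area
        per = rp.perimeter if rp.perimeter > 0 else 1.0
        circ = 4 * np.pi * area / per**2
        if area_bounds[0] * exp_area_px <= area <= area_bounds[1] * exp_area_px \
                and circ >= circularity_min:
            comp = lab == rp.label
            refined = ndi.binary_fill_holes(comp & raw_fg)
            if refined.sum() >= area_bounds[0] * exp_area_px:
                keep[refined] = next_id
                next_id += 1
    if next_id == 1:
        warnings.warn("no corral-like components found; returning empty mask")
        return mask
    # areas are the physical (pre-dilation) component areas; the 1-px
    # dilation only widens the capture footprint for rim-trapped clusters
    areas_px = {cid: int((keep == cid).sum()) for cid in range(1, next_id)}
    keep = expand_labels(keep, distance=1)
    out = RegionMask(labels=keep.astype(np.int32), pixel_size=pixel_size)
    for cid in out.corral_ids:
        sel = keep == cid
        out.area_um2[cid] = float(areas_px[cid]) * pixel_size**2
        out.mean_ligand[cid] = float(img[sel].mean())
    return out


def classify_corral_mobility(
    ligand_image: np.ndarray,
    mask: RegionMask,
    index_threshold: float = 3.0,
    layout: PatternLayout | None = None,
) -> dict[int, str]:
    """Classify each corral as mobile (clustered ligand) or immobile (uniform).

    The clustering index is the 99th-percentile over mean intensity inside
    the corral: ≈ 1 for a uniform disk, large when the ligand is condensed
    into a punctum.  Corrals above ``index_threshold`` are "mobile".  A
    user-supplied ``layout`` overrides the image-based classification by
    nearest ground-truth corral center.  Updates and returns
    ``mask.region_class``.
    """
    if mask.empty or not mask.corral_ids:
        raise ValueError("cannot classify an empty mask")
    img = np.asarray(ligand_image, dtype=float)
    classes: dict[int, str] = {}
    if layout is not None:
        for cid in mask.corral_ids:
            rows, cols = np.nonzero(mask.labels == cid)
            cx = (cols.mean() + 0.5) * mask.pixel_size
            cy = (rows.mean() + 0.5) * mask.pixel_size
            j = int(np.argmin(np.hypot(layout.centers[:, 0] - cx,
                                       layout.centers[:, 1] - cy)))
            classes[cid] = str(layout.region_class[j])
    else:
        for cid in mask.corral_ids:
            vals = img[mask.labels == cid]
            mean = vals.mean()
            idx = np.percentile(vals, 99) / mean if mean > 0 else 1.0
            classes[cid] = "mobile" if idx > index_threshold else "immobile"
    mask.region_class = classes
    return classes


def assign_region(tracks: list[Trajectory], mask: RegionMask) -> list[Trajectory]:
    """Assign each trajectory the region of its first-appearance position.

    The binding location defines the signaling region, so the label under
    the first localization decides; tracks starting on background become
    "unassigned" and are excluded from region kinetics downstream.
    Mutates and returns ``tracks``.
    """
    h, w = mask.labels.shape
    for t in tracks:
        x0, y0 = t.first_position()
        r, c = int(round(y0)), int(round(x0))
        if 0 <= r < h and 0 <= c < w and mask.labels[r, c] > 0:
            cid = int(mask.labels[r, c])
            t.corral_id = cid
            t.region_class = mask.region_class.get(cid, "unassigned")
        else:
            t.corral_id = -1
            t.region_class = "unassigned"
    return tracks


def mask_from_layout(layout: PatternLayout, ligand_image: np.ndarray | None = None
                     ) -> RegionMask:
    """Ground-truth mask rasterized directly from a pattern layout."""
    shape = layout.shape_px
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    xum = (xx + 0.5) * layout.pixel_size
    yum = (yy + 0.5) * layout.pixel_size
    out = RegionMask(labels=labels, pixel_size=layout.pixel_size)
    for i in range(layout.n_corrals):
        cid = int(layout.corral_id[i]) + 1
        cx, cy = layout.centers[i]
        disk = (xum - cx) ** 2 + (yum - cy) ** 2 <= layout.radii[i] ** 2
        labels[disk] = cid
        out.region_class[cid] = str(layout.region_class[i])
        out.area_um2[cid] = float(disk.sum()) * layout.pixel_size**2
        if ligand_image is not None:
            out.mean_ligand[cid] = float(np.asarray(ligand_image)[disk].mean())
    out.empty = layout.n_corrals == 0
    return out
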