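"""Anatomical region masks: labeling, gap filling, ROI assignment, tallies.

Manually drawn region masks arrive as label rasters with unlabeled gaps
between regions (drawing seams) and occasional small artifact blobs. This
module

1. labels the mask (input label values are preserved when already labeled;
   a binary mask is connected-component labeled);
2. optionally refines each region's outer boundary with a concave hull;
3. propagates labels into unlabeled gaps: every unlabeled pixel within a
   distance cap (default 100 px) of a labeled pixel receives the label of
   its nearest labeled pixel (exact Euclidean distance; ties broken toward
   the lowest label id);
4. removes regions smaller than an area floor (default 2000 um^2).

ROIs are then assigned to regions by centroid lookup, and per-region counts,
densities (cells/mm^2) and double-positive proportions are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology as skmorph

from .imaging import DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "CellTally",
    "RegionMap",
    "assign_rois_to_regions",
    "process_region_mask",
    "summarize_counts",
]


@dataclass
class RegionMap:
    """Labeled raster of anatomical regions with physical calibration."""

    labels: np.ndarray  # int raster, 0 = unlabeled
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    names: dict = field(default_factory=dict)  # label -> region name

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for lab in self.region_labels():
            self.names.setdefault(lab, f"region_{lab}")

    def region_labels(self) -> list:
        return sorted(int(v) for v in np.unique(self.labels) if v > 0)

    def area_um2(self, label: int) -> float:
        return float(np.sum(self.labels == label)) * self.pixel_size_um**2

    def name(self, label: int) -> str:
        return self.names.get(label, f"region_{label}")


def _concave_hull_fill(labels: np.ndarray, ratio: float = 0.3) -> np.ndarray:
    """Fill each label out to the concave hull of its boundary pixels.

    Only currently-unlabeled pixels are claimed; existing labels are never
    overwritten. Non-critical refinement: the subsequent propagation step
    dominates gap filling.
    """
    import shapely

    out = labels.copy()
    for lab in sorted(int(v) for v in np.unique(labels) if v > 0):
        mask = labels == lab
        boundary = mask & ~skmorph.erosion(mask)
        rr, cc = np.nonzero(boundary)
        if len(rr) < 4:
            continue
        pts = shapely.multipoints(np.column_stack([cc, rr]))
        hull = shapely.concave_hull(pts, ratio=ratio)
        if hull.geom_type != "Polygon" or hull.is_empty:
            continue
        verts = np.asarray(hull.exterior.coords)
        fr, fc = skdraw.polygon(verts[:, 1], verts[:, 0], shape=labels.shape)
        fill = np.zeros_like(mask)
        fill[fr, fc] = True
        out[fill & (out == 0)] = lab
    return out


def propagate_labels(labels: np.ndarray, max_gap_px: float = 100.0) -> np.ndarray:
    """Nearest-label fill of unlabeled pixels within ``max_gap_px``.

    Distances are exact Euclidean distances to the nearest pixel of each
    label; equidistant pixels go to the lowest label id. Pixels farther than
    ``max_gap_px`` from every label stay unlabeled.
    """
    out = labels.copy()
    labs = sorted(int(v) for v in np.unique(labels) if v > 0)
    if not labs:
        return out
    dists = np.stack([ndimage.distance_transform_edt(labels != lab) for lab in labs])
    nearest = np.argmin(dists, axis=0)  # first minimum -> lowest label id
    mindist = np.take_along_axis(dists, nearest[None], axis=0)[0]
    fill = (labels == 0) & (mindist <= max_gap_px)
    out[fill] = np.asarray(labs)[nearest[fill]]
    return out


def process_region_mask(
    raw_mask: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    max_gap_px: float = 100.0,
    min_area_um2: float = 2000.0,
    names: dict | None = None,
    use_concave_hull: bool = True,
    hull_ratio: float = 0.3,
) -> RegionMap:
    """Turn a raw region mask into a gap-filled, artifact-filtered RegionMap.

    See the module docstring for the four processing steps. The label
    propagation is a single pass measured from the input-labeled pixels; on
    masks whose unlabeled pixels are either within the gap cap or beyond it
    by more than the cap again, re-application is a no-op.
    """
    raw = np.asarray(raw_mask)
    if not (raw > 0).any():
        raise ValueError("empty region mask")
    positives = np.unique(raw[raw > 0])
    if len(positives) > 1:
        labels = raw.astype(int)  # already labeled: preserve the label values
    else:
        labels, _ = ndimage.label(raw > 0)
    if use_concave_hull:
        labels = _concave_hull_fill(labels, ratio=hull_ratio)
    drawn = labels.copy()  # pre-propagation extent of each region
    labels = propagate_labels(labels, max_gap_px=max_gap_px)
    # artifact floor judged on the drawn (pre-propagation) area, so a small
    # artifact cannot rescue itself by claiming gap pixels; removal clears
    # everything the artifact claimed
    min_px = min_area_um2 / pixel_size_um**2
    for lab in np.unique(drawn[drawn > 0]):
        if np.sum(drawn == lab) < min_px:
            labels[labels == lab] = 0
    return RegionMap(labels=labels, pixel_size_um=pixel_size_um,
                     names=dict(names or {}))


def assign_rois_to_regions(rois: list, region_map: RegionMap) -> list:
    """Assign each ROI the region label at its centroid pixel.

    Centroids on unlabeled background or outside the raster become
    "unassigned". Mutates and returns the ROI list.
    """
    h, w = region_map.labels.shape
    for roi in rois:
        r, c = (int(round(v)) for v in roi.centroid_rc)
        if 0 <= r < h and 0 <= c < w:
            lab = int(region_map.labels[r, c])
            roi.region = region_map.name(lab) if lab > 0 else "unassigned"
        else:
            roi.region = "unassigned"
    return rois


@dataclass
class CellTally:
    """Per-region cell counts, densities and double-positive proportions."""

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.table.to_string(index=False)


def summarize_counts(
    gfp_rois: list,
    fos_rois: list,
    double_positive: dict,
    region_map: RegionMap,
) -> CellTally:
    """Tabulate per-region class counts, densities, and proportions.

    ``double_positive`` maps FOS roi_id -> matched GFP roi_id (from
    :func:`photoloc.coloc.classify_double_positive`). A double-positive cell
    is tallied in the region of its GFP ROI (the reporter-labeled cell body).
    Densities are cells per mm^2 of post-processing region area; the
    double-positive proportion is relative to the region's GFP count and NaN
    (flagged) where no GFP cell exists.
    """
    dp_gfp_ids = set(double_positive.values())
    dp_fos_ids = set(double_positive.keys())
    rows = []
    regions = [(lab, region_map.name(lab)) for lab in region_map.region_labels()]
    regions.append((0, "unassigned"))
    for lab, name in regions:
        if lab > 0:
            area_um2 = region_map.area_um2(lab)
            if area_um2 == 0:
                raise ValueError(f"region {name!r} has zero area")
            area_mm2 = area_um2 / 1e6
        else:
            area_mm2 = np.nan
        gfp_here = [r for r in gfp_rois if r.region == name]
        fos_here = [r for r in fos_rois if r.region == name]
        n_gfp = len(gfp_here)
        n_double = sum(1 for r in gfp_here if r.roi_id in dp_gfp_ids)
        n_fos_only = sum(1 for r in fos_here if r.roi_id not in dp_fos_ids)
        rows.append({
            "region": name,
            "n_gfp": n_gfp,
            "n_fos_only": n_fos_only,
            "n_double_positive": n_double,
            "area_mm2": area_mm2,
            "gfp_density_per_mm2": n_gfp / area_mm2 if lab > 0 else np.nan,
            "double_density_per_mm2": n_double / area_mm2 if lab > 0 else np.nan,
            "double_over_gfp": n_double / n_gfp if n_gfp > 0 else np.nan,
        })
    return CellTally(pd.DataFrame(rows))
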