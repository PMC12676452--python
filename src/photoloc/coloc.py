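"""FOS/GFP ROI colocalization by exact polygon overlap.

Candidate pairs are pre-filtered by axis-aligned bounding-box intersection,
then scored with exact polygon geometry: intersection area, IoU
(intersection / union), and fractional overlap relative to each ROI's own
area. A FOS ROI is called double-positive when more than 80% of its area lies
inside some GFP ROI (strict inequality); a FOS ROI qualifying against several
GFP ROIs is counted once and attached to the GFP ROI with maximal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from shapely.geometry import Polygon

__all__ = [
    "OverlapRecord",
    "bbox_prefilter",
    "classify_double_positive",
    "polygon_overlap_metrics",
]


@dataclass
class OverlapRecord:
    """Overlap metrics for one (FOS, GFP) ROI pair."""

    roi_a: int  # channel-1 (FOS) roi_id
    roi_b: int  # channel-2 (GFP) roi_id
    intersection_area_px: float
    iou: float
    frac_a: float  # intersection / area(a)
    frac_b: float  # intersection / area(b)


def _bounds(roi) -> tuple:
    if hasattr(roi, "bounds"):
        b = roi.bounds
        return b() if callable(b) else b
    return Polygon(roi).bounds


def bbox_prefilter(rois_a: list, rois_b: list) -> list:
    """Index pairs whose axis-aligned bounding boxes intersect.

    A cheap superset of the truly overlapping pairs; boxes that merely touch
    are kept (they can still share boundary-degenerate overlap of area 0).
    """
    boxes_a = [_bounds(r) for r in rois_a]
    boxes_b = [_bounds(r) for r in rois_b]
    pairs = []
    for i, (ax0, ay0, ax1, ay1) in enumerate(boxes_a):
        for j, (bx0, by0, bx1, by1) in enumerate(boxes_b):
            if ax0 <= bx1 and bx0 <= ax1 and ay0 <= by1 and by0 <= ay1:
                pairs.append((i, j))
    return pairs


def _as_polygon(roi) -> Polygon:
    if hasattr(roi, "shapely"):
        return roi.shapely()
    p = roi if isinstance(roi, Polygon) else Polygon(roi)
    if not p.is_valid:
        p = p.buffer(0)
    return p


def polygon_overlap_metrics(roi_a, roi_b, id_a: int = -1, id_b: int = -1) -> OverlapRecord:
    """Exact polygon intersection area, IoU and per-ROI fractional overlap."""
    pa, pb = _as_polygon(roi_a), _as_polygon(roi_b)
    if pa.is_empty or pb.is_empty or pa.area == 0 or pb.area == 0:
        raise ValueError("invalid or degenerate polygon")
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    if id_a < 0 and hasattr(roi_a, "roi_id"):
        id_a = roi_a.roi_id
    if id_b < 0 and hasattr(roi_b, "roi_id"):
        id_b = roi_b.roi_id
    return OverlapRecord(
        roi_a=id_a,
        roi_b=id_b,
        intersection_area_px=float(inter),
        iou=float(inter / union) if union > 0 else 0.0,
        frac_a=float(inter / pa.area),
        frac_b=float(inter / pb.area),
    )


def overlap_records(rois_fos: list, rois_gfp: list) -> list:
    """Bounding-box prefilter followed by exact overlap metrics per pair."""
    records = []
    for i, j in bbox_prefilter(rois_fos, rois_gfp):
        records.append(
            polygon_overlap_metrics(rois_fos[i], rois_gfp[j],
                                    id_a=getattr(rois_fos[i], "roi_id", i),
                                    id_b=getattr(rois_gfp[j], "roi_id", j))
        )
    return records


def classify_double_positive(records: list, frac_threshold: float = 0.80) -> dict:
    """Double-positive FOS ROIs: ``frac_a > frac_threshold`` for some GFP ROI.

    Returns ``{fos_roi_id: gfp_roi_id}`` where each qualifying FOS ROI is
    counted once, attached to the GFP ROI with the maximal fractional
    overlap. The threshold comparison is strict, so a fractional overlap of
    exactly 0.80 does not qualify.
    """
    best: dict = {}
    for rec in records:
        if rec.frac_a > frac_threshold:
            cur = best.get(rec.roi_a)
            if cur is None or rec.frac_a > cur[1]:
                best[rec.roi_a] = (rec.roi_b, rec.frac_a)
    return {fos: gfp for fos, (gfp, _) in best.items()}
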