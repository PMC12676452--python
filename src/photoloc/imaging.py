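"""Two-channel histology preprocessing, segmentation, ROI metrics and QC.

Pipeline for FOS / GFP fluorescence sections:

* pixel-size calibration to a common physical scale (0.3785 um/pixel);
* white top-hat background removal (disc radius 10 px) and 3x3 median
  denoising, saved conceptually as 8-bit channels;
* cell segmentation behind a pluggable interface — a builtin
  threshold + connected-components segmenter for fully reproducible runs,
  or an external Cellpose adapter (flow threshold 0.4, cell probability
  threshold 0, minimum size 30 px) when that package is available;
* per-ROI morphometrics (shoelace area, perimeter, circularity
  4*pi*A/P^2, solidity A/A_hull, second-moment-ellipse aspect ratio) and
  interior / 3-px contour-band intensity statistics;
* the QC cascade: circularity > 0.4, aspect ratio < 3, solidity > 0.6,
  area in [80, 1000] px, median interior intensity > 10 (both channels),
  and for FOS additionally signal-above-background > 0.03 * 255 = 7.65.

Pixel convention: 0-based indices, pixel centers at integer coordinates,
polygons in continuous (x = column, y = row) pixel units; interior
membership by pixel-center-in-polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import transform as sktransform

__all__ = [
    "CalibratedImage",
    "QCThresholds",
    "Roi",
    "SegmenterSpec",
    "apply_qc_filters",
    "calibrate_pixel_size",
    "compute_morphometrics",
    "measure_intensity",
    "median_filter",
    "rasterize_polygon",
    "segment",
    "tophat",
]

DEFAULT_PIXEL_SIZE_UM = 0.3785


@dataclass
class CalibratedImage:
    """Multi-channel 8-bit image on a known physical pixel grid."""

    data: np.ndarray  # (n_channels, rows, cols)
    pixel_size_um: float
    channel_roles: dict = field(default_factory=lambda: {"fos": 0, "gfp": 1})
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def channel(self, role: str) -> np.ndarray:
        return self.data[self.channel_roles[role]]


@dataclass
class Roi:
    """A polygonal cell detection with morphometric and intensity attributes."""

    polygon: np.ndarray  # (n, 2) vertices as (x=col, y=row)
    channel: str
    roi_id: int = -1
    area_px: float = np.nan
    perimeter_px: float = np.nan
    centroid_rc: tuple = (np.nan, np.nan)
    circularity: float = np.nan
    aspect_ratio: float = np.nan
    solidity: float = np.nan
    mean_interior: float = np.nan
    median_interior: float = np.nan
    mean_background: float = np.nan
    median_background: float = np.nan
    passes_qc: bool = False
    qc_reason: str = ""
    region: str = "unassigned"

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")

    def shapely(self) -> Polygon:
        p = Polygon(self.polygon)
        if not p.is_valid:
            p = p.buffer(0)
        return p

    @property
    def signal_above_background(self) -> float:
        return self.mean_interior - self.mean_background

    @property
    def bounds(self) -> tuple:
        xs, ys = self.polygon[:, 0], self.polygon[:, 1]
        return (xs.min(), ys.min(), xs.max(), ys.max())


@dataclass
class SegmenterSpec:
    """Which segmentation backend to use and its parameters."""

    backend: str = "builtin_threshold"
    threshold: float | None = None  # builtin: None -> Otsu
    min_size_px: int = 30
    flow_threshold: float = 0.4  # external (Cellpose) parameters
    cellprob_threshold: float = 0.0
    estimate_diameter: bool = True


@dataclass
class QCThresholds:
    """The ROI quality-control cascade thresholds (8-bit intensity units)."""

    circularity_min: float = 0.4  # strict >
    aspect_ratio_max: float = 3.0  # strict <
    solidity_min: float = 0.6  # strict >
    area_min_px: float = 80.0  # inclusive
    area_max_px: float = 1000.0  # inclusive
    median_intensity_min: float = 10.0  # strict >, both channels
    fos_signal_above_bg_min: float = 0.03 * 255.0  # strict >, FOS only
    signal_metric: str = "mean"  # or "median": interior minus background


def calibrate_pixel_size(
    image: np.ndarray,
    native_um_per_px: float,
    target_um_per_px: float = DEFAULT_PIXEL_SIZE_UM,
) -> np.ndarray:
    """Resample an image so that one pixel spans ``target_um_per_px``.

    Output dimensions are ``round(native_dims * native/target)``. When native
    and target calibration agree the input is returned bit-identically.
    """
    if native_um_per_px is None or native_um_per_px <= 0:
        raise ValueError("native pixel calibration must be known and positive")
    if native_um_per_px == target_um_per_px:
        return image.copy()
    scale = native_um_per_px / target_um_per_px
    out_shape = tuple(int(round(s * scale)) for s in image.shape[:2])
    out = sktransform.resize(
        image.astype(float), out_shape, order=1, mode="edge",
        anti_aliasing=scale < 1, preserve_range=True,
    )
    return out


def tophat(image: np.ndarray, disc_radius_px: int = 10) -> np.ndarray:
    """White top-hat: image minus its morphological opening with a disc.

    Removes smooth background while preserving objects smaller than the disc.
    Output is non-negative.
    """
    if disc_radius_px <= 0:
        raise ValueError("structuring-element radius must be positive")
    return skmorph.white_tophat(image, footprint=skmorph.disk(disc_radius_px))


def median_filter(image: np.ndarray, kernel_px: int = 3) -> np.ndarray:
    """Median denoising with an odd square kernel and replicated borders."""
    if kernel_px % 2 == 0 or kernel_px < 1:
        raise ValueError("kernel size must be odd and positive")
    return ndimage.median_filter(image, size=kernel_px, mode="nearest")


def _component_polygon(mask: np.ndarray, offset_rc: tuple) -> np.ndarray | None:
    """Sub-pixel outline of a binary component as (x, y) vertices."""
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # (row, col) in padded frame
    rows = contour[:, 0] - 1 + offset_rc[0]
    cols = contour[:, 1] - 1 + offset_rc[1]
    verts = np.column_stack([cols, rows])
    if len(verts) < 3:
        return None
    return verts


def segment(image: np.ndarray, spec: SegmenterSpec | None = None) -> list:
    """Segment cells in one preprocessed channel into ROI polygons.

    ``builtin_threshold``: global threshold (Otsu unless given), connected
    components, sub-pixel contour extraction, discarding components smaller
    than ``min_size_px``. Touching cells may merge — a documented limitation
    of the baseline backend. ``external_adapter`` calls Cellpose when
    installed and otherwise raises, pointing at the builtin backend.
    """
    spec = spec or SegmenterSpec()
    if spec.backend == "external_adapter":
        return _segment_cellpose(image, spec)
    if spec.backend != "builtin_threshold":
        raise ValueError(f"unknown segmentation backend {spec.backend!r}")

    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return []
    thr = spec.threshold
    if thr is None:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(img)
    labels, n = ndimage.label(img > thr)
    polys = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        mask = labels[sl] == lab
        if mask.sum() < spec.min_size_px:
            continue
        verts = _component_polygon(mask, (sl[0].start, sl[1].start))
        if verts is None:
            continue
        polys.append(verts)
    return [Roi(polygon=v, roi_id=i, channel="") for i, v in enumerate(polys)]


def _segment_cellpose(image: np.ndarray, spec: SegmenterSpec) -> list:
    try:
        from cellpose import models  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "the external segmentation backend requires the 'cellpose' package, "
            "which is not installed; use SegmenterSpec(backend='builtin_threshold')"
        ) from exc
    model = models.CellposeModel(gpu=False)
    masks = model.eval(
        image,
        flow_threshold=spec.flow_threshold,
        cellprob_threshold=spec.cellprob_threshold,
        diameter=None if spec.estimate_diameter else 30,
    )[0]
    polys = []
    for sl, lab in zip(ndimage.find_objects(masks), range(1, masks.max() + 1)):
        if sl is None:
            continue
        mask = masks[sl] == lab
        if mask.sum() < spec.min_size_px:
            continue
        verts = _component_polygon(mask, (sl[0].start, sl[1].start))
        if verts is not None:
            polys.append(verts)
    return [Roi(polygon=v, roi_id=i, channel="") for i, v in enumerate(polys)]


def _polygon_moments(verts: np.ndarray) -> tuple:
    """Signed area, centroid and central second moments of a polygon."""
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central moments (about the centroid), normalized by area
    mxx = iyy / a - cx * cx
    myy = ixx / a - cy * cy
    mxy = ixy / a - cx * cy
    return a, (cx, cy), (mxx, myy, mxy)


def compute_morphometrics(roi: Roi) -> Roi:
    """Fill the geometric attribute fields of an ROI.

    Area by the shoelace formula, perimeter as polygon arc length,
    circularity = 4*pi*A/P^2, solidity = A / convex-hull area, aspect ratio
    from the eigenvalues of the polygon's second-moment (best-fit-ellipse)
    covariance.
    """
    p = roi.shapely()
    if p.is_empty or p.area == 0:
        raise ValueError("degenerate polygon (zero area)")
    a, (cx, cy), (mxx, myy, mxy) = _polygon_moments(roi.polygon)
    area = abs(a)
    perim = p.length
    cov = np.array([[mxx, mxy], [mxy, myy]])
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 1e-12, None)
    roi.area_px = float(area)
    roi.perimeter_px = float(perim)
    roi.centroid_rc = (float(cy), float(cx))
    roi.circularity = float(4 * np.pi * area / perim**2)
    roi.solidity = float(area / p.convex_hull.area)
    roi.aspect_ratio = float(np.sqrt(lam[1] / lam[0]))
    return roi


def rasterize_polygon(verts: np.ndarray, shape: tuple) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    rr, cc = skdraw.polygon(verts[:, 1], verts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def measure_intensity(
    roi: Roi,
    image: np.ndarray,
    contour_px: int = 3,
    all_rois: list | None = None,
    exclude_other_interiors: bool = True,
) -> Roi:
    """Fill interior and contour-background intensity statistics of an ROI.

    Interior: pixels whose centers fall inside the polygon. Background: the
    band within ``contour_px`` outward dilation of the interior, excluding
    (by default) the interiors of all other candidate ROIs so neighboring
    cells do not contaminate the background estimate.
    """
    shape = image.shape
    interior = rasterize_polygon(roi.polygon, shape)
    if not interior.any():
        raise ValueError("empty ROI interior after rasterization")
    band = skmorph.dilation(interior, skmorph.disk(contour_px)) & ~interior
    if exclude_other_interiors and all_rois:
        for other in all_rois:
            if other is roi:
                continue
            x0, y0, x1, y1 = other.bounds
            bx0, by0, bx1, by1 = roi.bounds
            if x1 < bx0 - contour_px or x0 > bx1 + contour_px \
                    or y1 < by0 - contour_px or y0 > by1 + contour_px:
                continue
            band &= ~rasterize_polygon(other.polygon, shape)
    vals_in = image[interior].astype(float)
    roi.mean_interior = float(vals_in.mean())
    roi.median_interior = float(np.median(vals_in))
    if band.any():
        vals_bg = image[band].astype(float)
        roi.mean_background = float(vals_bg.mean())
        roi.median_background = float(np.median(vals_bg))
    else:
        roi.mean_background = roi.median_background = np.nan
    return roi


def apply_qc_filters(
    rois: list, thresholds: QCThresholds | None = None
) -> tuple:
    """Apply the morphological and intensity QC cascade.

    Keeps ROIs satisfying every rule; rejected ROIs are labeled with the
    first failing rule (evaluated in the printed order: circularity, aspect
    ratio, solidity, area, median intensity, FOS signal-above-background).
    Raises when a metric field needed by a rule is unpopulated (NaN).
    """
    thr = thresholds or QCThresholds()
    kept, rejected = [], []
    for roi in rois:
        checks = [
            ("circularity", roi.circularity, lambda v: v > thr.circularity_min),
            ("aspect_ratio", roi.aspect_ratio, lambda v: v < thr.aspect_ratio_max),
            ("solidity", roi.solidity, lambda v: v > thr.solidity_min),
            ("area_below_min", roi.area_px, lambda v: v >= thr.area_min_px),
            ("area_above_max", roi.area_px, lambda v: v <= thr.area_max_px),
            ("median_intensity", roi.median_interior,
             lambda v: v > thr.median_intensity_min),
        ]
        if roi.channel == "fos":
            sab = (roi.median_interior - roi.median_background
                   if thr.signal_metric == "median"
                   else roi.signal_above_background)
            checks.append(("signal_above_background", sab,
                           lambda v: v > thr.fos_signal_above_bg_min))
        reason = ""
        for name, value, ok in checks:
            if value is None or not np.isfinite(value):
                raise ValueError(
                    f"ROI {roi.roi_id}: metric {name!r} unpopulated; run "
                    "compute_morphometrics/measure_intensity first"
                )
            if not ok(value):
                reason = name
                break
        roi.passes_qc = reason == ""
        roi.qc_reason = reason
        (kept if roi.passes_qc else rejected).append(roi)
    return kept, rejected
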