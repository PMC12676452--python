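"""Readers and writers for the pipeline's file formats.

* photometry CSV — the frame-stream export dialect: ``FrameCounter,
  Timestamp, ChannelFlag, Fiber0`` where the LED-state flag maps
  {1 -> 470 nm, 2 -> 415 nm, 4 -> 560 nm} by default (overridable, since the
  flag table varies by rig configuration);
* tracking CSV — ``Time, X, Y`` and/or ``Compartment`` columns; labels are
  passed through verbatim when present, otherwise derived from XY via the
  apparatus geometry;
* ImageJ ROI zip — polygon ROIs in the ImageJ binary ``.roi`` format inside
  a zip archive, one entry per ROI (integer-pixel vertex convention);
* multi-page TIFF for images and label rasters;
* YAML run configuration with unknown-key rejection, and a JSON run manifest
  (inputs, config hash, seeds, versions) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import ApparatusGeometry, BehaviorTrack, assign_compartments
from .imaging import Roi
from .photometry import PhotometrySession

__all__ = [
    "DEFAULT_FLAG_MAP",
    "read_photometry_csv",
    "read_region_tiff",
    "read_roi_zip",
    "read_tracking_csv",
    "load_config",
    "save_config",
    "write_manifest",
    "write_photometry_csv",
    "write_region_tiff",
    "write_roi_zip",
    "write_tracking_csv",
    "write_zdff_csv",
]

DEFAULT_FLAG_MAP = {1: "470", 2: "415", 4: "560"}

PHOTOMETRY_COLUMNS = ("FrameCounter", "Timestamp", "ChannelFlag", "Fiber0")


class FormatError(ValueError):
    """A file does not match the dialect the paired writer produces."""


# --------------------------------------------------------------------------
# photometry CSV
# --------------------------------------------------------------------------


def write_photometry_csv(session: PhotometrySession, path,
                         flag_map: dict | None = None) -> None:
    flag_map = flag_map or DEFAULT_FLAG_MAP
    inv = {v: k for k, v in flag_map.items()}
    df = pd.DataFrame({
        "FrameCounter": session.frame_index,
        "Timestamp": session.timestamp_s,
        "ChannelFlag": [inv[str(c)] for c in session.channel],
        "Fiber0": session.fluorescence,
    })
    df.to_csv(path, index=False)


def read_photometry_csv(path, fs_total: float = 78.0,
                        flag_map: dict | None = None) -> PhotometrySession:
    """Parse a photometry frame-stream CSV into a session.

    Raises :class:`FormatError` with the offending column or line for missing
    columns, unknown LED flags, or non-monotone timestamps.
    """
    flag_map = flag_map or DEFAULT_FLAG_MAP
    df = pd.read_csv(path)
    missing = [c for c in PHOTOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    ts = df["Timestamp"].to_numpy(dtype=float)
    if len(ts) > 1:
        bad = np.nonzero(np.diff(ts) <= 0)[0]
        if len(bad):
            raise FormatError(
                f"{path}: non-monotone Timestamp at data line {int(bad[0]) + 2}"
            )
    flags = df["ChannelFlag"].to_numpy()
    unknown = [f for f in np.unique(flags) if int(f) not in flag_map]
    if unknown:
        line = int(np.argmax(np.isin(flags, unknown))) + 2
        raise FormatError(f"{path}: unknown ChannelFlag {unknown[0]} at line {line}")
    channels = np.array([flag_map[int(f)] for f in flags], dtype=object)
    return PhotometrySession(
        frame_index=df["FrameCounter"].to_numpy(dtype=int),
        timestamp_s=ts,
        channel=channels,
        fluorescence=df["Fiber0"].to_numpy(dtype=float),
        fs_total=fs_total,
    )


# --------------------------------------------------------------------------
# tracking CSV
# --------------------------------------------------------------------------


def write_tracking_csv(track: BehaviorTrack, path,
                       x: np.ndarray | None = None,
                       y: np.ndarray | None = None) -> None:
    cols = {"Time": track.time_s}
    if x is not None:
        cols["X"] = x
        cols["Y"] = y
    cols["Compartment"] = track.compartment
    pd.DataFrame(cols).to_csv(path, index=False)


def read_tracking_csv(path, geometry: ApparatusGeometry | None = None,
                      frame_rate: float | None = None,
                      phase: str = "pretest") -> BehaviorTrack:
    """Parse a tracking export into a labeled track.

    A ``Compartment`` column is used verbatim when present; otherwise ``X``
    and ``Y`` plus an apparatus geometry are required.
    """
    df = pd.read_csv(path)
    if "Time" not in df.columns:
        raise FormatError(f"{path}: missing required column 'Time'")
    try:
        time_s = df["Time"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed Time column: {exc}") from exc
    if frame_rate is None:
        if len(time_s) < 2:
            raise FormatError(f"{path}: cannot infer frame rate from <2 rows")
        frame_rate = 1.0 / float(np.median(np.diff(time_s)))
    if "Compartment" in df.columns:
        return BehaviorTrack(time_s, df["Compartment"].to_numpy(dtype=object),
                             frame_rate, phase)
    if {"X", "Y"} <= set(df.columns):
        if geometry is None:
            raise FormatError(
                f"{path}: XY tracking requires an apparatus geometry"
            )
        return assign_compartments(time_s, df["X"].to_numpy(float),
                                   df["Y"].to_numpy(float), geometry,
                                   frame_rate, phase)
    raise FormatError(
        f"{path}: need either a Compartment column or X and Y columns"
    )


def write_zdff_csv(zdff, path, sidecar_path=None) -> None:
    """Tidy z(dF/F) CSV plus optional JSON sidecar with diagnostics and log."""
    pd.DataFrame({"time_s": zdff.time_s, "zdff": zdff.zdff}).to_csv(path,
                                                                    index=False)
    if sidecar_path is not None:
        payload = {"diagnostics": zdff.diagnostics,
                   "processing_log": zdff.processing_log,
                   "signal_channel": zdff.signal_channel,
                   "reference_channel": zdff.reference_channel}
        Path(sidecar_path).write_text(json.dumps(payload, indent=2, default=float))


# --------------------------------------------------------------------------
# ImageJ ROI zip
# --------------------------------------------------------------------------

_IJ_VERSION = 228
_IJ_POLYGON = 0
_HEADER_SIZE = 64


def _encode_roi(verts: np.ndarray) -> bytes:
    """Encode a polygon as an ImageJ .roi blob (integer-pixel convention)."""
    xs = np.round(verts[:, 0]).astype(int)
    ys = np.round(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, _IJ_VERSION)
    header[6] = _IJ_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(header) + body


def _decode_roi(blob: bytes) -> np.ndarray:
    if blob[0:4] != b"Iout":
        raise FormatError("not an ImageJ ROI (bad magic)")
    roi_type = blob[6]
    if roi_type != _IJ_POLYGON:
        raise FormatError(f"unsupported ImageJ ROI type {roi_type} (want polygon)")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", blob, 8)
    (n,) = struct.unpack_from(">h", blob, 16)
    xs = np.array(struct.unpack_from(f">{n}h", blob, _HEADER_SIZE)) + left
    ys = np.array(struct.unpack_from(f">{n}h", blob, _HEADER_SIZE + 2 * n)) + top
    return np.column_stack([xs, ys]).astype(float)


def write_roi_zip(rois: list, path) -> None:
    """Write polygon ROIs as an ImageJ-compatible zip, one .roi per entry."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for k, roi in enumerate(rois):
            verts = roi.polygon if isinstance(roi, Roi) else np.asarray(roi)
            name = f"{k:04d}-{getattr(roi, 'channel', '') or 'roi'}.roi"
            zf.writestr(name, _encode_roi(verts))


def read_roi_zip(path) -> list:
    """Read an ImageJ ROI zip back into :class:`~photoloc.imaging.Roi` objects."""
    rois = []
    try:
        with zipfile.ZipFile(path) as zf:
            for k, name in enumerate(sorted(zf.namelist())):
                verts = _decode_roi(zf.read(name))
                channel = ""
                stem = Path(name).stem
                if "-" in stem:
                    channel = stem.split("-", 1)[1]
                    if channel == "roi":
                        channel = ""
                rois.append(Roi(polygon=verts, roi_id=k, channel=channel))
    except zipfile.BadZipFile as exc:
        raise FormatError(f"{path}: corrupt ROI archive: {exc}") from exc
    return rois


# --------------------------------------------------------------------------
# TIFF
# --------------------------------------------------------------------------


def write_region_tiff(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32))


def read_region_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


# --------------------------------------------------------------------------
# configuration and manifest
# --------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "photometry": {"filter_order", "cutoff_hz", "lowess_frac", "lowess_it",
                   "mad_scale", "signal_channel", "reference_channel"},
    "behavior": {"min_run_frames", "max_epoch_s", "side_width", "center_width",
                 "depth", "cocaine_side", "tolerance"},
    "perievent": {"window_pre_s", "window_post_s", "baseline_pre_s",
                  "baseline_post_s", "reference_floor"},
    "imaging": {"pixel_size_um", "tophat_radius_px", "median_kernel_px",
                "threshold", "min_size_px", "circularity_min",
                "aspect_ratio_max", "solidity_min", "area_min_px",
                "area_max_px", "median_intensity_min",
                "fos_signal_above_bg_min", "contour_px"},
    "coloc": {"frac_threshold", "max_gap_px", "min_area_um2", "hull_ratio"},
    "run": {"seed", "log_level", "inputs", "outputs"},
}


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown sections/keys."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in cfg.items():
        if section not in KNOWN_CONFIG_KEYS:
            raise FormatError(f"{path}: unknown config section {section!r}")
        unknown = set(values or {}) - KNOWN_CONFIG_KEYS[section]
        if unknown:
            raise FormatError(
                f"{path}: unknown key(s) {sorted(unknown)} in section {section!r}"
            )
    return cfg


def save_config(cfg: dict, path) -> None:
    for section, values in cfg.items():
        if section not in KNOWN_CONFIG_KEYS:
            raise ValueError(f"unknown config section {section!r}")
        unknown = set(values or {}) - KNOWN_CONFIG_KEYS[section]
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in {section!r}")
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def write_manifest(path, inputs: list, config: dict, seeds: dict) -> dict:
    """JSON manifest capturing inputs, config hash, seeds and versions."""
    import photoloc

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "inputs": [str(p) for p in inputs],
        "config_sha256": cfg_hash,
        "seeds": seeds,
        "versions": {
            "photoloc": photoloc.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
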