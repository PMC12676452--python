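"""Synthetic raw data with known ground truth.

Generates the three kinds of raw input the analysis pipelines consume, with
the statistical structure the corrections are designed for:

* **Photometry sessions** — interleaved 470/560/415 nm frame streams where
  both channels share an exponential photobleach envelope and brief
  biexponential motion artifacts, while exponential-decay calcium transients
  appear only in the 470 nm channel:
  ``F470(t) = B(t) * (1 + a*c(t) + m*g(t)) + eps`` and
  ``F415(t) = B'(t) * (1 + m*g(t)) + eps'``.
* **CPP trajectories** — a semi-Markov walk over saline <-> center <->
  cocaine with exponential dwell times and a controllable probability of
  choosing the cocaine side when leaving the center; direct side-to-side
  jumps are never generated.
* **Two-channel histology images** — disc-like GFP cells, a controlled
  fraction of which receive a FOS disc placed inside them (>= 90% contained),
  plus FOS-only cells outside all GFP cells, on a labeled region layout.

Every generator draws from one seeded ``numpy.random.Generator`` per call, so
identical configs and seeds yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .behavior import BehaviorTrack, CENTER, COCAINE, SALINE
from .photometry import PhotometrySession
from .regions import RegionMap

__all__ = [
    "BehaviorSimConfig",
    "GroundTruth",
    "HistoSimConfig",
    "PhotometrySimConfig",
    "make_region_mask_fixture",
    "simulate_behavior_track",
    "simulate_histology_image",
    "simulate_photometry_session",
    "simulate_place_modulated_session",
]


@dataclass
class GroundTruth:
    """Tables of what was actually generated, for validating the pipelines."""

    transients: pd.DataFrame | None = None  # time_s, amplitude
    trajectory: pd.DataFrame | None = None  # time_s, compartment
    cells: pd.DataFrame | None = None  # center, radius, channels, region, dp flag
    extras: dict = field(default_factory=dict)  # e.g. sampled artifact traces


# --------------------------------------------------------------------------
# photometry
# --------------------------------------------------------------------------

CHANNEL_CYCLE = ("470", "560", "415")


@dataclass
class PhotometrySimConfig:
    """Forward model of a dual-wavelength recording.

    ``transient_amplitude`` may be a scalar (shared by all transients) or a
    sequence aligned with ``transient_times_s``; amplitudes are fractions of
    the instantaneous baseline. ``bleach_tau_ratio`` lets the isosbestic
    bleach envelope decay with a different time constant (tau' = ratio*tau)
    to exercise the per-channel detrending.
    """

    duration_s: float = 60.0
    fs_total: float = 78.0
    n_channels_interleaved: int = 3
    baseline_470: float = 100.0
    baseline_415: float = 70.0
    bleach_tau_s: float = 120.0
    bleach_tau_ratio: float = 1.0
    transient_times_s: tuple = ()
    transient_amplitude: float | tuple = 0.05
    transient_decay_s: float = 0.5
    motion_amplitude: float = 0.0
    motion_events_s: tuple = ()
    motion_rise_s: float = 0.05
    motion_decay_s: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_total <= 0:
            raise ValueError("fs_total must be positive")
        amps = np.atleast_1d(np.asarray(self.transient_amplitude, dtype=float))
        if np.any(amps < 0):
            raise ValueError("transient_amplitude must be non-negative")
        for t in tuple(self.transient_times_s) + tuple(self.motion_events_s):
            if not 0 <= t <= self.duration_s:
                raise ValueError(f"event time {t} outside [0, duration_s]")


def _transient_wave(t: np.ndarray, times: np.ndarray, amps: np.ndarray,
                    decay_s: float) -> np.ndarray:
    c = np.zeros_like(t)
    for t0, a in zip(times, amps):
        m = t >= t0
        c[m] += a * np.exp(-(t[m] - t0) / decay_s)
    return c


def _motion_wave(t: np.ndarray, times: np.ndarray, rise_s: float,
                 decay_s: float) -> np.ndarray:
    """Sum of biexponential bumps, each normalized to unit peak."""
    g = np.zeros_like(t)
    if len(times) == 0:
        return g
    tp = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    for t0 in times:
        m = t >= t0
        dt = t[m] - t0
        g[m] += (np.exp(-dt / decay_s) - np.exp(-dt / rise_s)) / peak
    return g


def simulate_photometry_session(
    cfg: PhotometrySimConfig,
) -> tuple[PhotometrySession, GroundTruth]:
    """Generate an interleaved photometry session and its ground truth.

    Frames are emitted in a repeating 470/560/415 cycle at ``fs_total``; each
    channel is sampled at its own frame times. The ground truth records the
    injected transients and the motion artifact evaluated at the 470 nm and
    415 nm frame times.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.fs_total))
    t_all = np.arange(n_frames) / cfg.fs_total
    cycle = np.array(CHANNEL_CYCLE[: cfg.n_channels_interleaved], dtype=object)
    channels = cycle[np.arange(n_frames) % len(cycle)]

    times = np.asarray(cfg.transient_times_s, dtype=float)
    amps = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.transient_amplitude, dtype=float)),
        times.shape,
    ).copy()
    motion_times = np.asarray(cfg.motion_events_s, dtype=float)

    def bleach(t: np.ndarray, b0: float, tau: float) -> np.ndarray:
        return b0 * np.exp(-t / tau)

    g_all = cfg.motion_amplitude * _motion_wave(
        t_all, motion_times, cfg.motion_rise_s, cfg.motion_decay_s
    )
    c_all = _transient_wave(t_all, times, amps, cfg.transient_decay_s)

    fluor = np.empty(n_frames, dtype=float)
    for ch, b0, tau, with_transients in (
        ("470", cfg.baseline_470, cfg.bleach_tau_s, True),
        ("560", 0.5 * cfg.baseline_470, cfg.bleach_tau_s, False),
        ("415", cfg.baseline_415, cfg.bleach_tau_s * cfg.bleach_tau_ratio, False),
    ):
        sel = channels == ch
        if not sel.any():
            continue
        b = bleach(t_all[sel], b0, tau)
        mod = 1.0 + g_all[sel]
        if with_transients:
            mod = mod + c_all[sel]
        fluor[sel] = b * mod
    fluor += cfg.noise_sd * cfg.baseline_470 * rng.standard_normal(n_frames)

    session = PhotometrySession(
        frame_index=np.arange(n_frames),
        timestamp_s=t_all,
        channel=channels,
        fluorescence=fluor,
        fs_total=cfg.fs_total,
    )
    # amplitude is a fraction of the instantaneous baseline, so the injected
    # absolute amplitude at onset is a * B(t0)
    amps_au = amps * bleach(times, cfg.baseline_470, cfg.bleach_tau_s)
    gt = GroundTruth(
        transients=pd.DataFrame({"time_s": times, "amplitude": amps,
                                 "amplitude_au": amps_au}),
        extras={
            "motion_470": g_all[channels == "470"],
            "motion_415": g_all[channels == "415"] if "415" in channels else None,
            "time_470": t_all[channels == "470"],
        },
    )
    return session, gt


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------


@dataclass
class BehaviorSimConfig:
    """Semi-Markov walk over the three-chamber apparatus."""

    duration_s: float = 600.0
    frame_rate: float = 25.0
    mean_dwell_s: float = 20.0
    cocaine_bias: float = 0.5
    center_transit_s: float = 2.0
    start: str = CENTER
    phase: str = "pretest"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cocaine_bias <= 1.0:
            raise ValueError("cocaine_bias must be in [0, 1]")
        if self.mean_dwell_s <= 0 or self.center_transit_s <= 0:
            raise ValueError("dwell and transit times must be positive")
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")


def simulate_behavior_track(
    cfg: BehaviorSimConfig,
) -> tuple[BehaviorTrack, GroundTruth]:
    """Generate a compartment-label trajectory.

    Side dwell times are exponential with mean ``mean_dwell_s``; center
    transits are exponential with mean ``center_transit_s`` (both floored at
    two frames). Leaving the center, the cocaine side is chosen with
    probability ``cocaine_bias`` regardless of origin, so same-side returns
    occur; saline and cocaine are never adjacent in the label sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate
    labels = np.empty(n, dtype=object)
    i, state = 0, cfg.start
    while i < n:
        mean = cfg.center_transit_s if state == CENTER else cfg.mean_dwell_s
        dur = max(2, int(round(rng.exponential(mean) / dt)))
        labels[i : i + dur] = state
        i += dur
        if state == CENTER:
            state = COCAINE if rng.random() < cfg.cocaine_bias else SALINE
        else:
            state = CENTER
    time_s = np.arange(n) * dt
    track = BehaviorTrack(time_s, labels, cfg.frame_rate, cfg.phase)
    gt = GroundTruth(trajectory=pd.DataFrame({"time_s": time_s,
                                              "compartment": labels}))
    return track, gt


def simulate_place_modulated_session(
    track: BehaviorTrack,
    amplitude_by_compartment: dict | None = None,
    transient_rate_hz: float = 0.4,
    base_amplitude: float = 0.05,
    photometry_cfg: PhotometrySimConfig | None = None,
    seed: int = 0,
) -> tuple[PhotometrySession, GroundTruth]:
    """Photometry session whose transient amplitudes depend on the compartment.

    Transient onsets are drawn as a homogeneous Poisson process over the
    track duration; each transient's amplitude is ``base_amplitude`` scaled
    by ``amplitude_by_compartment[label at onset]`` (default scale 1). Used
    to emulate context-dependent neural activity across CPP phases.
    """
    rng = np.random.default_rng(seed)
    scales = amplitude_by_compartment or {}
    duration = float(track.time_s[-1]) + 1.0 / track.frame_rate
    n_ev = rng.poisson(transient_rate_hz * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_ev))
    labels = track.compartment[
        np.clip(np.searchsorted(track.time_s, onsets), 0, len(track.time_s) - 1)
    ]
    amps = np.array([base_amplitude * scales.get(lab, 1.0) for lab in labels])
    base = photometry_cfg or PhotometrySimConfig()
    cfg = PhotometrySimConfig(
        duration_s=duration,
        fs_total=base.fs_total,
        baseline_470=base.baseline_470,
        baseline_415=base.baseline_415,
        bleach_tau_s=base.bleach_tau_s,
        bleach_tau_ratio=base.bleach_tau_ratio,
        transient_times_s=tuple(onsets),
        transient_amplitude=tuple(amps),
        transient_decay_s=base.transient_decay_s,
        motion_amplitude=base.motion_amplitude,
        motion_events_s=base.motion_events_s,
        noise_sd=base.noise_sd,
        seed=seed + 1,
    )
    session, gt = simulate_photometry_session(cfg)
    gt.transients = gt.transients.assign(compartment=labels)
    return session, gt


# --------------------------------------------------------------------------
# histology
# --------------------------------------------------------------------------


@dataclass
class HistoSimConfig:
    """Two-channel image of disc-like cells with known colocalization."""

    image_shape: tuple = (512, 512)
    pixel_size_um: float = 0.3785
    n_gfp_cells: int = 50
    coloc_fraction: float = 0.4
    fos_only_cells: int = 10
    cell_radius_px: float = 9.0
    fos_radius_px: float = 6.0
    min_separation_px: float = 10.0
    background_level: int = 5
    gfp_level: int = 200
    fos_level: int = 200
    region_layout: tuple = ()  # (name, (r0, c0, r1, c1)) rectangles
    seed: int = 0
    max_retries: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        area = np.pi * self.cell_radius_px**2
        if not 80 <= area <= 1000:
            raise ValueError(
                "cell_radius_px must give a disc area inside the QC window "
                f"[80, 1000] px (got {area:.0f})"
            )


def _place_discs(rng, n, radius, shape, min_sep, existing, max_retries):
    centers = list(existing)
    placed = []
    margin = radius + 4
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {n} discs of radius {radius} in {shape} "
                f"after {max_retries} retries (packing infeasible)"
            )
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= (min_sep + radius + rad) ** 2
               for rr, cc, rad in centers):
            centers.append((r, c, radius))
            placed.append((r, c))
    return placed, centers


def simulate_histology_image(
    cfg: HistoSimConfig,
) -> tuple[np.ndarray, RegionMap, GroundTruth]:
    """Generate a (2, H, W) uint8 image, a region map and a cell table.

    Channel 0 is FOS, channel 1 is GFP. ``round(n_gfp_cells *
    coloc_fraction)`` GFP cells (a seed-fixed subset) receive a concentric
    FOS disc fully contained in the GFP disc; ``fos_only_cells`` additional
    FOS discs are placed outside every GFP disc.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.image_shape)
    gfp_centers, occupied = _place_discs(
        rng, cfg.n_gfp_cells, cfg.cell_radius_px, shape,
        cfg.min_separation_px, [], cfg.max_retries,
    )
    fos_only_centers, _ = _place_discs(
        rng, cfg.fos_only_cells, cfg.fos_radius_px, shape,
        cfg.min_separation_px, occupied, cfg.max_retries,
    )
    n_dp = int(round(cfg.n_gfp_cells * cfg.coloc_fraction))
    dp_idx = set(rng.permutation(cfg.n_gfp_cells)[:n_dp].tolist())

    img = np.full((2,) + shape, cfg.background_level, dtype=np.uint8)
    rows = []
    for i, (r, c) in enumerate(gfp_centers):
        rr, cc = skdraw.disk((r, c), cfg.cell_radius_px, shape=shape)
        img[1][rr, cc] = cfg.gfp_level
        is_dp = i in dp_idx
        if is_dp:
            fr, fc = skdraw.disk((r, c), cfg.fos_radius_px, shape=shape)
            img[0][fr, fc] = cfg.fos_level
        rows.append({"cell_id": i, "row": r, "col": c,
                     "radius_px": cfg.cell_radius_px, "channel": "gfp",
                     "is_double_positive": is_dp})
    for j, (r, c) in enumerate(fos_only_centers):
        rr, cc = skdraw.disk((r, c), cfg.fos_radius_px, shape=shape)
        img[0][rr, cc] = cfg.fos_level
        rows.append({"cell_id": cfg.n_gfp_cells + j, "row": r, "col": c,
                     "radius_px": cfg.fos_radius_px, "channel": "fos_only",
                     "is_double_positive": False})

    if cfg.region_layout:
        region_map = make_region_mask_fixture(cfg.region_layout, shape,
                                              cfg.pixel_size_um)
    else:
        region_map = RegionMap(np.ones(shape, dtype=int),
                               pixel_size_um=cfg.pixel_size_um,
                               names={1: "field"})
    cells = pd.DataFrame(rows)
    labels = region_map.labels
    cells["region"] = [
        region_map.name(int(labels[int(round(r.row)), int(round(r.col))]))
        if labels[int(round(r.row)), int(round(r.col))] > 0 else "unassigned"
        for r in cells.itertuples()
    ]
    return img, region_map, GroundTruth(cells=cells)


def make_region_mask_fixture(
    layout,
    shape: tuple,
    pixel_size_um: float = 0.3785,
    gaps: tuple = (),
    artifacts: tuple = (),
) -> RegionMap:
    """Labeled raster from named, non-overlapping rectangles.

    ``layout`` is a sequence of ``(name, (r0, c0, r1, c1))`` half-open
    rectangles. ``gaps`` are ``(r0, c0, r1, c1)`` rectangles forced back to
    unlabeled (to test propagation); ``artifacts`` are ``(name, (row, col),
    area_um2)`` discs injected as separate labels (to test size filtering).
    Overlapping layout rectangles are an error.
    """
    labels = np.zeros(shape, dtype=int)
    names = {}
    for k, (name, (r0, c0, r1, c1)) in enumerate(layout, start=1):
        block = labels[r0:r1, c0:c1]
        if (block != 0).any():
            raise ValueError(f"region {name!r} overlaps a previous region")
        labels[r0:r1, c0:c1] = k
        names[k] = name
    for r0, c0, r1, c1 in gaps:
        labels[r0:r1, c0:c1] = 0
    next_label = len(layout) + 1
    for name, (row, col), area_um2 in artifacts:
        radius_px = np.sqrt((area_um2 / pixel_size_um**2) / np.pi)
        rr, cc = skdraw.disk((row, col), radius_px, shape=shape)
        labels[rr, cc] = next_label
        names[next_label] = name
        next_label += 1
    return RegionMap(labels=labels, pixel_size_um=pixel_size_um, names=names)
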