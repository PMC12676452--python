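"""Peri-event and compartment-resolved quantification of z(dF/F).

Aligns the normalized photometry trace to behavioral events (one row per
event, t = 0 at event onset), integrates signal with linear interpolation
(trapezoidal AUC), and computes the context-discrimination index
(Coc/Sal AUC Ratio): per-second-normalized AUC accumulated while the animal
occupies the cocaine-paired compartment divided by the same quantity on the
saline-paired side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .behavior import BehaviorTrack, EntryEvent, occupancy_runs
from .photometry import NormalizedTrace

__all__ = [
    "AUCResult",
    "DiscriminationResult",
    "PeriEventMatrix",
    "auc_linear",
    "behavior_correlation",
    "compartment_auc",
    "discrimination_ratio",
    "extract_perievent",
]


@dataclass
class PeriEventMatrix:
    """Event-aligned z(dF/F) rows on a common time grid (t = 0 at onset)."""

    time_s: np.ndarray  # grid relative to event onset
    data: np.ndarray  # (n_events, n_grid)
    events: list
    window: tuple
    baseline_window: tuple
    n_dropped: int = 0

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def sem(self) -> np.ndarray:
        n = self.data.shape[0]
        return self.data.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(self.time_s)


@dataclass
class AUCResult:
    """Trapezoidal area under the trace over an interval (z-units x seconds)."""

    value: float
    t_start_s: float
    t_end_s: float
    n_samples: int


@dataclass
class DiscriminationResult:
    """Coc/Sal AUC Ratio and its ingredients."""

    auc_cocaine_per_s: float
    auc_saline_per_s: float
    ratio: float
    occupancy_cocaine_s: float
    occupancy_saline_s: float
    valid: bool


def extract_perievent(
    zdff: NormalizedTrace,
    events: list,
    window: tuple = (-5.0, 5.0),
    baseline_window: tuple | None = None,
    grid_hz: float | None = None,
    full_transitions_only: bool = True,
) -> PeriEventMatrix:
    """Extract the z(dF/F) signal around event onsets onto a common grid.

    Events may be :class:`EntryEvent` objects or bare onset times (seconds).
    Entry events are admitted only when ``is_full_transition`` (the default;
    disable for non-entry events). Rows whose window falls outside the trace
    span are dropped and counted. Raises if no admissible event remains.
    """
    pre_s, post_s = window
    if baseline_window is None:
        baseline_window = (pre_s, 0.0)
    if grid_hz is None:
        grid_hz = 1.0 / float(np.median(np.diff(zdff.time_s)))
    grid = np.arange(pre_s, post_s + 0.5 / grid_hz, 1.0 / grid_hz)

    onsets, kept_events = [], []
    for ev in events:
        if isinstance(ev, EntryEvent):
            if full_transitions_only and not ev.is_full_transition:
                continue
            onsets.append(ev.t0_s)
        else:
            onsets.append(float(ev))
        kept_events.append(ev)

    t0, t1 = zdff.time_s[0], zdff.time_s[-1]
    rows, used, dropped = [], [], 0
    for ev, onset in zip(kept_events, onsets):
        if onset + pre_s < t0 or onset + post_s > t1:
            dropped += 1
            continue
        rows.append(np.interp(onset + grid, zdff.time_s, zdff.zdff))
        used.append(ev)
    if not rows:
        raise ValueError("no admissible events with a full peri-event window")
    return PeriEventMatrix(
        time_s=grid,
        data=np.vstack(rows),
        events=used,
        window=window,
        baseline_window=baseline_window,
        n_dropped=dropped,
    )


def auc_linear(time_s: np.ndarray, values: np.ndarray, interval: tuple) -> AUCResult:
    """Trapezoidal integral of the linearly interpolated signal over an interval.

    Endpoints not on the sample grid are linearly interpolated, so the result
    is exact for piecewise-linear signals with breakpoints on sample times.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    a, b = float(interval[0]), float(interval[1])
    if a >= b:
        raise ValueError("interval must have positive length")
    if a < time_s[0] or b > time_s[-1]:
        raise ValueError(
            f"interval [{a}, {b}] outside trace span [{time_s[0]}, {time_s[-1]}]"
        )
    inside = (time_s > a) & (time_s < b)
    t = np.concatenate(([a], time_s[inside], [b]))
    v = np.concatenate((
        [np.interp(a, time_s, values)],
        values[inside],
        [np.interp(b, time_s, values)],
    ))
    if len(t) < 2:
        raise ValueError("need at least 2 samples in the interval")
    return AUCResult(float(np.trapezoid(v, t)), a, b, int(inside.sum()) + 2)


def _sync_track_to_trace(zdff: NormalizedTrace, track: BehaviorTrack) -> np.ndarray:
    """Nearest-timestamp join of track labels onto photometry sample times.

    Raises when the nearest tracking frame is further than one photometry
    sample period from any photometry sample (clock desynchronization).
    """
    dt = float(np.median(np.diff(zdff.time_s)))
    idx = np.searchsorted(track.time_s, zdff.time_s)
    idx = np.clip(idx, 1, len(track.time_s) - 1)
    left, right = track.time_s[idx - 1], track.time_s[idx]
    use_left = (zdff.time_s - left) <= (right - zdff.time_s)
    nearest = np.where(use_left, idx - 1, idx)
    skew = np.abs(track.time_s[nearest] - zdff.time_s)
    if skew.max() > dt:
        raise ValueError(
            f"track/trace clock skew {skew.max():.4g}s exceeds one photometry "
            f"sample period ({dt:.4g}s); check TTL synchronization"
        )
    return track.compartment[nearest]


def compartment_auc(
    zdff: NormalizedTrace, track: BehaviorTrack, side: str
) -> tuple:
    """Per-second-normalized AUC accumulated over all visits to one side.

    Returns ``(auc_per_s, total_auc, occupancy_s, runs)`` where ``runs`` is a
    list of per-visit :class:`AUCResult`. Zero occupancy yields
    ``(nan, 0, 0, [])``.
    """
    labels = _sync_track_to_trace(zdff, track)
    pseudo = BehaviorTrack(zdff.time_s, labels,
                           frame_rate=1.0 / float(np.median(np.diff(zdff.time_s))),
                           phase=track.phase)
    runs = [r for r in occupancy_runs(pseudo, min_run_frames=2) if r[0] == side]
    results, total, occ = [], 0.0, 0.0
    for _, s, e in runs:
        if e - s < 2:
            continue
        t0, t1 = float(zdff.time_s[s]), float(zdff.time_s[e - 1])
        if t1 <= t0:
            continue
        res = auc_linear(zdff.time_s, zdff.zdff, (t0, t1))
        results.append(res)
        total += res.value
        occ += t1 - t0
    if occ == 0.0:
        return float("nan"), 0.0, 0.0, []
    return total / occ, total, occ, results


def discrimination_ratio(
    zdff: NormalizedTrace,
    track: BehaviorTrack,
    reference_floor: float = 1e-3,
) -> DiscriminationResult:
    """Coc/Sal AUC Ratio: cocaine-side over saline-side per-second AUC.

    Per-second normalization prevents unequal occupancy from masquerading as
    a signal change. The result is flagged invalid (ratio = nan) when either
    side is unoccupied or the saline-side per-second AUC magnitude is below
    ``reference_floor``; no exception is raised for a degenerate denominator.
    """
    coc_per_s, _, coc_occ, _ = compartment_auc(zdff, track, "cocaine")
    sal_per_s, _, sal_occ, _ = compartment_auc(zdff, track, "saline")
    valid = (
        coc_occ > 0 and sal_occ > 0
        and np.isfinite(sal_per_s) and abs(sal_per_s) > reference_floor
    )
    ratio = coc_per_s / sal_per_s if valid else float("nan")
    return DiscriminationResult(
        auc_cocaine_per_s=coc_per_s,
        auc_saline_per_s=sal_per_s,
        ratio=ratio,
        occupancy_cocaine_s=coc_occ,
        occupancy_saline_s=sal_occ,
        valid=bool(valid),
    )


def behavior_correlation(x, y) -> tuple:
    """Pearson correlation between two per-animal metrics.

    Returns ``(r, p, (slope, intercept))`` with the least-squares line for
    plotting. Requires >= 3 paired finite observations with nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the metrics")
    r, p = sstats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(p), (float(slope), float(intercept))
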