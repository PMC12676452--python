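"""Compartment occupancy, entry events, and CPP scoring.

Operates on exported tracking data from a three-chamber conditioned place
preference (CPP) apparatus: two side chambers (28 x 24 cm) flanking a center
chamber (11.5 x 24 cm). One side is paired with cocaine during conditioning;
the behavioral readouts are

* CPP score = time on the cocaine-paired side (post-test) minus the same
  time on the pre-test;
* Paired - Unpaired Time = cocaine-side time minus saline-side time within
  one phase;
* entry events into either side, where only *full transitions*
  (saline -> center -> cocaine, or cocaine -> center -> saline) are admitted
  to peri-event photometry analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ApparatusGeometry",
    "BehaviorTrack",
    "CPPSummary",
    "EntryEvent",
    "assign_compartments",
    "cpp_score",
    "detect_entries",
    "occupancy_runs",
    "paired_unpaired_time",
    "stimulation_epochs",
    "summarize_phase",
]

SALINE, CENTER, COCAINE, UNKNOWN = "saline", "center", "cocaine", "unknown"
SIDES = (SALINE, COCAINE)


@dataclass
class BehaviorTrack:
    """Frame-indexed compartment occupancy for one session phase."""

    time_s: np.ndarray
    compartment: np.ndarray  # str labels: saline/center/cocaine/unknown
    frame_rate: float
    phase: str = "pretest"
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.compartment = np.asarray(self.compartment, dtype=object)
        if len(self.time_s) != len(self.compartment):
            raise ValueError("time and compartment vectors must have equal length")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) < 0):
            raise ValueError("timestamps must be non-decreasing")
        bad = set(self.compartment) - {SALINE, CENTER, COCAINE, UNKNOWN}
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.frame_rate


@dataclass
class EntryEvent:
    """A side-compartment entry; t0 is the first frame inside the destination."""

    t0_s: float
    destination: str
    origin: str
    is_full_transition: bool


@dataclass
class CPPSummary:
    """Per-phase compartment occupancy times (seconds)."""

    phase: str
    time_saline_s: float
    time_center_s: float
    time_cocaine_s: float
    time_unknown_s: float = 0.0

    @property
    def total_s(self) -> float:
        return (self.time_saline_s + self.time_center_s
                + self.time_cocaine_s + self.time_unknown_s)


@dataclass
class ApparatusGeometry:
    """Three-chamber box geometry in tracking units (cm by default).

    The long axis is x: left side chamber, center chamber, right side chamber.
    ``cocaine_side`` names which side chamber is cocaine-paired.
    """

    side_width: float = 28.0
    center_width: float = 11.5
    depth: float = 24.0
    cocaine_side: str = "right"
    tolerance: float = 1.0

    @property
    def total_width(self) -> float:
        return 2 * self.side_width + self.center_width


def assign_compartments(
    time_s: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    geometry: ApparatusGeometry,
    frame_rate: float,
    phase: str = "pretest",
) -> BehaviorTrack:
    """Label every tracked point with the compartment containing it.

    Boundaries are half-open toward the center chamber: a point exactly on a
    side/center boundary is labeled center. Points outside the apparatus
    beyond ``geometry.tolerance`` are labeled unknown and counted.
    """
    time_s = np.asarray(time_s, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = geometry
    left_edge, right_edge = g.side_width, g.side_width + g.center_width

    labels = np.full(len(x), CENTER, dtype=object)
    labels[x < left_edge] = COCAINE if g.cocaine_side == "left" else SALINE
    labels[x > right_edge] = COCAINE if g.cocaine_side == "right" else SALINE

    out = ((x < -g.tolerance) | (x > g.total_width + g.tolerance)
           | (y < -g.tolerance) | (y > g.depth + g.tolerance)
           | ~np.isfinite(x) | ~np.isfinite(y))
    labels[out] = UNKNOWN
    return BehaviorTrack(time_s, labels, frame_rate, phase,
                         n_out_of_bounds=int(out.sum()))


def occupancy_runs(track: BehaviorTrack, min_run_frames: int = 2) -> list:
    """Run-length encode the compartment labels, with debouncing.

    Runs shorter than ``min_run_frames`` (default 2, guarding against
    single-frame tracking jitter) are discarded; adjacent surviving runs with
    the same label are merged. Returns ``(label, start_idx, end_idx)`` tuples
    with ``end_idx`` exclusive; indices refer to original frames.
    """
    labels = track.compartment
    n = len(labels)
    if n == 0:
        return []
    raw = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            raw.append((labels[start], start, i))
            start = i
    kept = [r for r in raw if r[2] - r[1] >= min_run_frames]
    merged: list = []
    for lab, s, e in kept:
        if merged and merged[-1][0] == lab:
            merged[-1] = (lab, merged[-1][1], e)
        else:
            merged.append((lab, s, e))
    return merged


def detect_entries(track: BehaviorTrack, min_run_frames: int = 2) -> list:
    """Detect side-compartment entries and flag full transitions.

    An entry is the start of a saline or cocaine occupancy run preceded by a
    run of a different label. It is a full transition iff the preceding run is
    center AND the run before that is the opposite side. Unknown-labeled runs
    break the chain (a transition through unknown is never full). t0 is the
    timestamp of the first frame of the (debounced) destination run.
    """
    runs = occupancy_runs(track, min_run_frames=min_run_frames)
    events = []
    for k in range(1, len(runs)):
        lab, s, _ = runs[k]
        if lab not in SIDES:
            continue
        origin = runs[k - 1][0]
        full = (
            origin == CENTER
            and k >= 2
            and runs[k - 2][0] == (SALINE if lab == COCAINE else COCAINE)
        )
        events.append(
            EntryEvent(
                t0_s=float(track.time_s[s]),
                destination=str(lab),
                origin=str(origin),
                is_full_transition=bool(full),
            )
        )
    return events


def summarize_phase(track: BehaviorTrack) -> CPPSummary:
    """Total occupancy time per compartment; one frame period per frame."""
    dt = 1.0 / track.frame_rate
    labels = track.compartment
    t = {lab: float(np.sum(labels == lab)) * dt
         for lab in (SALINE, CENTER, COCAINE, UNKNOWN)}
    return CPPSummary(track.phase, t[SALINE], t[CENTER], t[COCAINE], t[UNKNOWN])


def cpp_score(pre: CPPSummary, post: CPPSummary) -> float:
    """CPP score: cocaine-side time on the post-test minus on the pre-test."""
    if pre is None or post is None:
        raise ValueError("both pre-test and post-test summaries are required")
    return post.time_cocaine_s - pre.time_cocaine_s


def paired_unpaired_time(phase: CPPSummary) -> float:
    """Paired - Unpaired Time: cocaine-side minus saline-side occupancy."""
    return phase.time_cocaine_s - phase.time_saline_s


def stimulation_epochs(
    track: BehaviorTrack, max_epoch_s: float = 300.0, min_run_frames: int = 2
) -> list:
    """Entry-locked stimulation bookkeeping windows.

    One window per side visit, opening at entry and closing at
    ``min(entry + max_epoch_s, exit)`` (stimulation is capped at five minutes
    per entry and never delivered without an entry). Returns
    ``(start_s, end_s, side)`` tuples.
    """
    runs = occupancy_runs(track, min_run_frames=min_run_frames)
    dt = 1.0 / track.frame_rate
    epochs = []
    for lab, s, e in runs:
        if lab not in SIDES:
            continue
        start = float(track.time_s[s])
        exit_t = float(track.time_s[e - 1]) + dt
        epochs.append((start, min(start + max_epoch_s, exit_t), str(lab)))
    return epochs
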