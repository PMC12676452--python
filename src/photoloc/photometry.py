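"""Dual-wavelength fiber-photometry normalization.

Transforms raw interleaved photometry frames (470 nm calcium-dependent signal,
415 nm isosbestic reference, optional 560 nm secondary) into a motion- and
bleach-corrected z(dF/F) trace:

1. deinterleave the frame stream into per-channel traces;
2. smooth each channel with a zero-phase 4th-order 5 Hz lowpass Butterworth
   filter;
3. remove photobleaching and slow drift by subtracting a LOWESS baseline fit
   per channel;
4. standardize each channel with a robust z-score
   ``z(F) = (F - median(F)) / MAD(F)`` (MAD scaled by 1.4826);
5. fit the standardized isosbestic channel to the standardized signal channel
   by Huber robust regression;
6. z(dF/F) = standardized signal minus fitted reference.

Steps 5-6 remove motion artifacts and autofluorescence, which are shared
between the two excitation wavelengths, while the calcium transients (present
only at 470 nm) survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "ChannelTrace",
    "NormalizedTrace",
    "PhotometrySession",
    "compute_dff",
    "deinterleave",
    "detrend_baseline",
    "fit_reference_channel",
    "lowpass_filter",
    "preprocess_session",
    "robust_zscore",
]

#: default scale constant making the MAD a consistent estimator of the
#: standard deviation under normality (1/qnorm(0.75))
MAD_SCALE = 1.4826


class DegenerateTraceError(ValueError):
    """Raised when a trace is constant or too short for the requested step."""


@dataclass
class ChannelTrace:
    """A single-channel fluorescence time series with a processing log."""

    time_s: np.ndarray
    values: np.ndarray
    channel: str
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time_s and values must have equal length")

    @property
    def fs(self) -> float:
        """Effective sampling rate (Hz) estimated from the median time step."""
        if len(self.time_s) < 2:
            raise ValueError("need >= 2 samples to estimate sampling rate")
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def _derive(self, values: np.ndarray, step: str, **params) -> "ChannelTrace":
        log = list(self.processing_log) + [{"step": step, **params}]
        return ChannelTrace(self.time_s.copy(), values, self.channel, log)


@dataclass
class NormalizedTrace:
    """The normalized z(dF/F) trace with fit diagnostics and provenance."""

    time_s: np.ndarray
    zdff: np.ndarray
    signal_channel: str
    reference_channel: str
    diagnostics: dict = field(default_factory=dict)
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.zdff = np.asarray(self.zdff, dtype=float)
        if self.time_s.shape != self.zdff.shape:
            raise ValueError("time_s and zdff must have equal length")
        if not np.all(np.isfinite(self.zdff)):
            raise ValueError("z(dF/F) contains non-finite samples")


@dataclass
class PhotometrySession:
    """Raw interleaved photometry frames.

    ``frames`` is a record array / DataFrame-like mapping with columns
    ``frame_index``, ``timestamp_s``, ``channel`` (str, e.g. "470") and
    ``fluorescence``. ``fs_total`` is the total (all-channel) frame rate.
    """

    frame_index: np.ndarray
    timestamp_s: np.ndarray
    channel: np.ndarray
    fluorescence: np.ndarray
    fs_total: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
        self.channel = np.asarray(self.channel, dtype=object)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        n = len(self.frame_index)
        for arr in (self.timestamp_s, self.channel, self.fluorescence):
            if len(arr) != n:
                raise ValueError("frame columns must have equal length")
        if n > 1 and np.any(np.diff(self.timestamp_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.fs_total <= 0:
            raise ValueError("fs_total must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def channels(self) -> list:
        seen: list = []
        for c in self.channel:
            if c not in seen:
                seen.append(c)
        return seen


KNOWN_CHANNELS = ("470", "560", "415")


def deinterleave(session: PhotometrySession) -> dict:
    """Split an interleaved session into one :class:`ChannelTrace` per channel.

    Original timestamps are preserved, so a 78 Hz three-channel session yields
    ~26 Hz per-channel traces. Unknown channel flags raise a parse error
    naming the offending frame.
    """
    channels = np.asarray(session.channel)
    bad = [c for c in dict.fromkeys(channels) if str(c) not in KNOWN_CHANNELS]
    if bad:
        idx = int(np.argmax(np.isin(channels, bad)))
        raise ValueError(
            f"unknown channel flag {channels[idx]!r} at frame "
            f"{int(session.frame_index[idx])}"
        )
    out = {}
    for ch in session.channels:
        sel = channels == ch
        out[str(ch)] = ChannelTrace(
            session.timestamp_s[sel],
            session.fluorescence[sel],
            str(ch),
            [{"step": "deinterleave", "channel": str(ch)}],
        )
    return out


def lowpass_filter(
    trace: ChannelTrace, order: int = 4, cutoff_hz: float = 5.0
) -> ChannelTrace:
    """Zero-phase Butterworth lowpass smoothing (forward-backward filtfilt).

    DC gain is exactly 1, so constant traces pass through unchanged.
    """
    fs = trace.fs
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyq:.3g} Hz"
        )
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("non-finite samples in trace")
    b, a = sps.butter(order, cutoff_hz / nyq, btype="low")
    filtered = sps.filtfilt(b, a, trace.values)
    return trace._derive(filtered, "lowpass_filter", order=order, cutoff_hz=cutoff_hz)


def detrend_baseline(
    trace: ChannelTrace,
    frac: float = 2.0 / 3.0,
    it: int = 3,
    delta: float | None = None,
) -> ChannelTrace:
    """Subtract a LOWESS baseline to remove bleaching and slow drift.

    Defaults mirror the classic lowess smoother defaults (span f = 2/3,
    3 robustness iterations, interpolation gap delta = 1% of the time range).
    """
    n = len(trace.values)
    if n < 10:
        raise DegenerateTraceError(f"trace too short for detrending (n={n} < 10)")
    if delta is None:
        delta = 0.01 * float(trace.time_s[-1] - trace.time_s[0])
    baseline = _sm_lowess(
        trace.values,
        trace.time_s,
        frac=frac,
        it=it,
        delta=delta,
        return_sorted=False,
    )
    return trace._derive(
        trace.values - baseline, "detrend_baseline", frac=frac, it=it, delta=delta
    )


def robust_zscore(trace: ChannelTrace, mad_scale: float = MAD_SCALE) -> ChannelTrace:
    """Robust standardization ``z(F) = (F - median(F)) / MAD(F)``.

    MAD is the median absolute deviation scaled by ``mad_scale`` (default
    1.4826, the consistency constant for normal data). Constant traces have
    MAD = 0 and raise :class:`DegenerateTraceError`.
    """
    x = trace.values
    med = float(np.median(x))
    mad = mad_scale * float(np.median(np.abs(x - med)))
    if mad == 0.0:
        raise DegenerateTraceError("MAD is zero (constant trace); cannot standardize")
    return trace._derive((x - med) / mad, "robust_zscore", mad_scale=mad_scale)


def fit_reference_channel(
    z470: ChannelTrace,
    z415: ChannelTrace,
    huber_t: float = 1.345,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> tuple:
    """Fit the standardized reference (isosbestic) channel to the signal channel.

    Linear Huber M-estimation ``z470 ~ b0 + b1 * z415`` via iteratively
    reweighted least squares. Returns the fitted reference evaluated per
    sample and a diagnostics dict (slope, intercept, robust scale,
    iterations).
    """
    if len(z470.values) != len(z415.values):
        raise ValueError("signal and reference traces must have equal length")
    y = z470.values
    X = sm.add_constant(z415.values)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_t))
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs")
    b0, b1 = (float(p) for p in res.params)
    n_iter = len(res.fit_history.get("params", [])) if res.fit_history else -1
    if n_iter >= maxiter:
        hist = res.fit_history["params"]
        if len(hist) >= 2 and np.max(np.abs(hist[-1] - hist[-2])) > tol:
            raise RuntimeError(
                f"robust regression did not converge in {maxiter} iterations; "
                f"last estimate b0={b0:.6g}, b1={b1:.6g}"
            )
    fitted = z415._derive(b0 + b1 * z415.values, "fit_reference_channel",
                          intercept=b0, slope=b1)
    diagnostics = {
        "intercept": b0,
        "slope": b1,
        "robust_scale": float(res.scale),
        "iterations": n_iter,
    }
    return fitted, diagnostics


def compute_dff(z470: ChannelTrace, fitted415: ChannelTrace,
                diagnostics: dict | None = None) -> NormalizedTrace:
    """z(dF/F): standardized signal minus the fitted standardized reference."""
    if len(z470.values) != len(fitted415.values):
        raise ValueError("signal and fitted reference must have equal length")
    log = list(z470.processing_log) + [{"step": "compute_dff"}]
    return NormalizedTrace(
        time_s=z470.time_s,
        zdff=z470.values - fitted415.values,
        signal_channel=z470.channel,
        reference_channel=fitted415.channel,
        diagnostics=dict(diagnostics or {}),
        processing_log=log,
    )


def preprocess_session(
    session: PhotometrySession,
    signal_channel: str = "470",
    reference_channel: str = "415",
    filter_order: int = 4,
    cutoff_hz: float = 5.0,
    lowess_frac: float = 2.0 / 3.0,
    lowess_it: int = 3,
    mad_scale: float = MAD_SCALE,
) -> NormalizedTrace:
    """Run the full normalization chain on a raw session.

    deinterleave -> lowpass -> LOWESS detrend -> robust z-score (per channel)
    -> robust reference fit -> subtraction. The processing log records all six
    stages with their parameters.
    """
    traces = deinterleave(session)
    for ch in (signal_channel, reference_channel):
        if ch not in traces:
            raise ValueError(f"channel {ch!r} not present in session")

    def chain(tr: ChannelTrace) -> ChannelTrace:
        tr = lowpass_filter(tr, order=filter_order, cutoff_hz=cutoff_hz)
        tr = detrend_baseline(tr, frac=lowess_frac, it=lowess_it)
        return robust_zscore(tr, mad_scale=mad_scale)

    zsig = chain(traces[signal_channel])
    zref = chain(traces[reference_channel])

    # interleaved channels are sampled 1/fs_total apart; resample the
    # reference onto the signal timestamps so shared fast artifacts cancel
    zref = ChannelTrace(
        zsig.time_s,
        np.interp(zsig.time_s, zref.time_s, zref.values),
        zref.channel,
        zref.processing_log + [{"step": "align_to_signal_times"}],
    )

    fitted, diagnostics = fit_reference_channel(zsig, zref)
    zsig.processing_log.append({"step": "fit_reference_channel", **diagnostics})
    return compute_dff(zsig, fitted, diagnostics)
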