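"""Unit and property tests for the photometry normalization chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import photoloc as pl
from photoloc.photometry import ChannelTrace, DegenerateTraceError


def make_trace(values, fs=26.0, channel="470"):
    values = np.asarray(values, dtype=float)
    return ChannelTrace(np.arange(len(values)) / fs, values, channel)


class TestDeinterleave:
    def test_per_channel_rate_is_fs_total_over_n_channels(self, quiet_session):
        session, _ = quiet_session
        traces = pl.deinterleave(session)
        assert set(traces) == {"470", "560", "415"}
        for tr in traces.values():
            assert tr.fs == pytest.approx(26.0, rel=1e-6)
            # 60 s at 26 Hz effective rate
            assert len(tr.values) == pytest.approx(60 * 26, abs=1)

    def test_single_channel_session_passes_through(self):
        n = 100
        session = pl.PhotometrySession(
            frame_index=np.arange(n),
            timestamp_s=np.arange(n) / 26.0,
            channel=np.array(["470"] * n, dtype=object),
            fluorescence=np.linspace(1, 2, n),
            fs_total=26.0,
        )
        traces = pl.deinterleave(session)
        assert list(traces) == ["470"]
        np.testing.assert_array_equal(traces["470"].values, session.fluorescence)

    def test_unknown_flag_error_names_frame(self):
        session = pl.PhotometrySession(
            frame_index=np.arange(3),
            timestamp_s=np.array([0.0, 0.1, 0.2]),
            channel=np.array(["470", "999", "415"], dtype=object),
            fluorescence=np.ones(3),
            fs_total=30.0,
        )
        with pytest.raises(ValueError, match="999.*frame 1"):
            pl.deinterleave(session)


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        out = pl.lowpass_filter(make_trace(np.full(200, 3.7)))
        np.testing.assert_allclose(out.values, 3.7, atol=1e-9)

    @pytest.mark.parametrize(
        "freq_hz, check",
        [
            # expected attenuation from the squared Butterworth magnitude
            # response (zero-phase = forward + backward application):
            # |H|^2 = 1 / (1 + (f/5)^8)
            (0.5, lambda amp: amp > 0.99),
            (10.0, lambda amp: amp < 0.01),
        ],
    )
    def test_sinusoid_attenuation(self, freq_hz, check):
        fs = 26.0
        t = np.arange(int(60 * fs)) / fs
        tr = ChannelTrace(t, np.sin(2 * np.pi * freq_hz * t), "470")
        out = pl.lowpass_filter(tr)
        interior = slice(len(t) // 4, 3 * len(t) // 4)
        amp = np.max(np.abs(out.values[interior]))
        expected = 1.0 / (1.0 + (freq_hz / 5.0) ** 8)
        assert check(amp)
        assert amp == pytest.approx(expected, rel=0.05, abs=5e-3)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pl.lowpass_filter(make_trace(np.ones(50)), cutoff_hz=20.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        fx = pl.lowpass_filter(make_trace(x)).values
        fy = pl.lowpass_filter(make_trace(y)).values
        fxy = pl.lowpass_filter(make_trace(2.0 * x - 0.5 * y)).values
        np.testing.assert_allclose(fxy, 2.0 * fx - 0.5 * fy, atol=1e-9)


class TestDetrendBaseline:
    def test_exponential_bleach_removed(self, quiet_session):
        session, _ = quiet_session
        tr = pl.deinterleave(session)["470"]
        out = pl.detrend_baseline(tr)
        n = len(out.values)
        interior = out.values[n // 10 : -n // 10]
        assert np.max(np.abs(interior)) < 0.02 * tr.values[0]

    def test_zero_trace_stays_zero(self):
        out = pl.detrend_baseline(make_trace(np.zeros(100)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        t = np.arange(500) / 26.0
        ramp = 3.0 * t + 1.0
        out = pl.detrend_baseline(ChannelTrace(t, ramp, "470"))
        interior = out.values[50:-50]
        assert abs(interior.mean()) < 1e-6 * np.ptp(ramp)

    def test_short_trace_rejected(self):
        with pytest.raises(DegenerateTraceError):
            pl.detrend_baseline(make_trace(np.arange(5.0)))


class TestRobustZscore:
    def test_hand_computed_example(self):
        # median 3, raw MAD 1, scaled MAD 1.4826
        out = pl.robust_zscore(make_trace([1, 2, 3, 4, 5]))
        expected = [-1.3490, -0.6745, 0.0, 0.6745, 1.3490]
        np.testing.assert_allclose(out.values, expected, atol=1e-4)

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateTraceError, match="MAD"):
            pl.robust_zscore(make_trace(np.full(20, 2.0)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_median_zero_mad_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(101) * rng.uniform(0.1, 50) + rng.uniform(-100, 100)
        z = pl.robust_zscore(make_trace(x)).values
        assert abs(np.median(z)) < 1e-9
        assert abs(1.4826 * np.median(np.abs(z - np.median(z))) - 1.0) < 1e-9


class TestFitReferenceChannel:
    def test_self_fit_is_identity(self):
        rng = np.random.default_rng(1)
        z = pl.robust_zscore(make_trace(rng.standard_normal(500)))
        fitted, diag = pl.fit_reference_channel(z, z)
        assert diag["slope"] == pytest.approx(1.0, abs=1e-8)
        assert diag["intercept"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fitted.values, z.values, atol=1e-8)

    def test_independent_noise_gives_near_zero_slope(self):
        slopes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = pl.robust_zscore(make_trace(rng.standard_normal(10_000)))
            b = pl.robust_zscore(make_trace(rng.standard_normal(10_000)))
            _, diag = pl.fit_reference_channel(a, b)
            slopes.append(diag["slope"])
        assert np.max(np.abs(slopes)) < 0.05

    def test_huber_beats_ols_under_gross_outliers(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        e = rng.standard_normal(n) * 0.1
        gross = rng.random(n) < 0.10
        e[gross] += rng.choice([-1, 1], gross.sum()) * rng.uniform(5, 15, gross.sum())
        y = 0.8 * x + e
        _, diag = pl.fit_reference_channel(
            ChannelTrace(np.arange(n) / 26.0, y, "470"),
            ChannelTrace(np.arange(n) / 26.0, x, "415"),
        )
        # closed-form OLS slope on the same data
        ols = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert abs(diag["slope"] - 0.8) < abs(ols - 0.8)


class TestComputeDff:
    def test_subtraction_identities(self):
        rng = np.random.default_rng(0)
        z = pl.robust_zscore(make_trace(rng.standard_normal(200)))
        zero = ChannelTrace(z.time_s, np.zeros_like(z.values), "415")
        np.testing.assert_allclose(pl.compute_dff(z, z).zdff, 0.0)
        np.testing.assert_allclose(pl.compute_dff(z, zero).zdff, z.values)

    def test_length_mismatch_rejected(self):
        a = make_trace(np.arange(10.0))
        b = make_trace(np.arange(9.0))
        with pytest.raises(ValueError):
            pl.compute_dff(a, b)

    def test_motion_artifact_removed_from_dff(self, busy_session):
        session, gt = busy_session
        traces = pl.deinterleave(session)
        z470 = pl.robust_zscore(pl.detrend_baseline(pl.lowpass_filter(traces["470"])))
        zdff = pl.preprocess_session(session)
        g = gt.extras["motion_470"][: len(zdff.zdff)]
        assert abs(sstats.pearsonr(z470.values[: len(g)], g)[0]) > 0.5
        assert abs(sstats.pearsonr(zdff.zdff, g)[0]) < 0.1


class TestPreprocessSession:
    def test_degenerate_session_gives_flat_dff(self, quiet_session):
        session, _ = quiet_session
        zdff = pl.preprocess_session(session)
        assert np.max(np.abs(zdff.zdff)) < 0.1

    def test_transients_appear_as_local_maxima(self, busy_session):
        session, gt = busy_session
        zdff = pl.preprocess_session(session)
        for t0 in gt.transients["time_s"]:
            sel = (zdff.time_s >= t0 - 0.2) & (zdff.time_s <= t0 + 1.0)
            outside = (zdff.time_s >= t0 - 3.0) & (zdff.time_s < t0 - 0.5)
            assert zdff.zdff[sel].max() > zdff.zdff[outside].max() + 1.0

    def test_processing_log_records_six_stages(self, busy_session):
        session, _ = busy_session
        zdff = pl.preprocess_session(session)
        steps = [e["step"] for e in zdff.processing_log]
        assert steps == ["deinterleave", "lowpass_filter", "detrend_baseline",
                         "robust_zscore", "fit_reference_channel", "compute_dff"]

    def test_motion_rejection_across_amplitude_grid(self):
        """Squared artifact correlation drops >= 90% for all motion levels."""
        for amp in (0.05, 0.1, 0.2, 0.4):
            cfg = pl.PhotometrySimConfig(
                duration_s=60.0, seed=11, motion_amplitude=amp,
                motion_events_s=tuple(np.linspace(3, 57, 12)),
                transient_times_s=(10.0, 30.0, 50.0),
                transient_amplitude=0.05, noise_sd=0.002,
            )
            session, gt = pl.simulate_photometry_session(cfg)
            traces = pl.deinterleave(session)
            z470 = pl.robust_zscore(
                pl.detrend_baseline(pl.lowpass_filter(traces["470"])))
            zdff = pl.preprocess_session(session)
            g = gt.extras["motion_470"][: len(zdff.zdff)]
            r2_raw = sstats.pearsonr(z470.values[: len(g)], g)[0] ** 2
            r2_dff = sstats.pearsonr(zdff.zdff, g)[0] ** 2
            assert r2_dff <= 0.1 * r2_raw
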