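import numpy as np
import pytest

import photoloc as pl


@pytest.fixture
def quiet_session():
    """Noiseless, artifact-free, transient-free session (pure bleach)."""
    cfg = pl.PhotometrySimConfig(duration_s=60.0, seed=0, noise_sd=0.0,
                                 transient_times_s=(), motion_amplitude=0.0)
    session, gt = pl.simulate_photometry_session(cfg)
    return session, gt


@pytest.fixture
def busy_session():
    """Session with transients, motion artifacts and mild noise."""
    cfg = pl.PhotometrySimConfig(
        duration_s=60.0,
        seed=7,
        transient_times_s=(10.0, 20.0, 30.0, 40.0, 50.0),
        transient_amplitude=0.05,
        motion_amplitude=0.2,
        motion_events_s=(5.0, 15.0, 25.0, 35.0, 45.0),
        noise_sd=0.002,
    )
    session, gt = pl.simulate_photometry_session(cfg)
    return session, gt


@pytest.fixture
def labeled_track():
    """Hand-built track covering full and partial transitions."""
    labels = (["saline"] * 10 + ["center"] * 5 + ["cocaine"] * 10
              + ["center"] * 5 + ["saline"] * 10 + ["center"] * 5
              + ["saline"] * 10)
    time_s = np.arange(len(labels)) / 25.0
    return pl.BehaviorTrack(time_s, np.array(labels, dtype=object),
                            frame_rate=25.0)
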