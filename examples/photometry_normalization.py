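"""Normalize a dual-wavelength photometry session into z(dF/F).

Generates a synthetic 60 s recording (78 Hz total; interleaved 470/560/415
channels) with photobleaching, five calcium transients, motion artifacts and
noise, runs the full normalization chain, and reports how much of the motion
artifact survives in the output.
"""

import numpy as np
from scipy import stats

import photoloc as pl

cfg = pl.PhotometrySimConfig(
    duration_s=60.0,
    transient_times_s=(8.0, 19.0, 30.0, 41.0, 52.0),
    transient_amplitude=0.05,  # 5% dF/F transients
    motion_amplitude=0.2,
    motion_events_s=(5.0, 15.0, 25.0, 35.0, 45.0),
    noise_sd=0.002,
    seed=1,
)
session, truth = pl.simulate_photometry_session(cfg)
zdff = pl.preprocess_session(session)

# How correlated is the output with the known motion artifact, compared with
# the uncorrected (but standardized) 470 nm trace?
traces = pl.deinterleave(session)
z470 = pl.robust_zscore(pl.detrend_baseline(pl.lowpass_filter(traces["470"])))
g = truth.extras["motion_470"][: len(zdff.zdff)]
r_before = stats.pearsonr(z470.values[: len(g)], g)[0]
r_after = stats.pearsonr(zdff.zdff, g)[0]

print(f"samples per channel:        {len(zdff.zdff)} (~26 Hz effective)")
print(f"reference-fit slope:        {zdff.diagnostics['slope']:.3f}")
print(f"artifact corr, z470:        {r_before:+.3f}")
print(f"artifact corr, z(dF/F):     {r_after:+.3f}")
print(f"variance reduction:         {100 * (1 - r_after**2 / r_before**2):.1f}%")
print(f"peak z(dF/F):               {zdff.zdff.max():.1f}  (transients survive)")
# The motion artifact is shared between 470 and 415 nm, so subtracting the
# fitted isosbestic trace removes it while calcium transients (470-only)
# remain as large positive excursions.
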