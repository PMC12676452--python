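"""Peri-event matrices and the Coc/Sal AUC Ratio on a coupled simulation.

Couples a CPP trajectory with a photometry session whose transient
amplitudes are halved in the cocaine compartment, then shows (a) the
entry-locked peri-event average and (b) the per-second AUC discrimination
ratio between compartments.
"""

import photoloc as pl

track, _ = pl.simulate_behavior_track(
    pl.BehaviorSimConfig(duration_s=1200.0, mean_dwell_s=20.0, seed=21,
                         phase="posttest"))
session, truth = pl.simulate_place_modulated_session(
    track, {"cocaine": 0.5}, transient_rate_hz=0.5, base_amplitude=0.05,
    photometry_cfg=pl.PhotometrySimConfig(noise_sd=0.002, bleach_tau_s=3000.0),
    seed=22)
zdff = pl.preprocess_session(session)

events = [e for e in pl.detect_entries(track) if e.is_full_transition]
mat = pl.extract_perievent(zdff, events, window=(-5.0, 5.0))
pre_mask = mat.time_s < 0
post_mask = (mat.time_s > 0) & (mat.time_s < 2)
print(f"full-transition entries analyzed: {mat.data.shape[0]} "
      f"({mat.n_dropped} dropped at trace edges)")
print(f"mean z(dF/F) before entry: {mat.mean()[pre_mask].mean():+.3f}")
print(f"mean z(dF/F) after entry:  {mat.mean()[post_mask].mean():+.3f}")

res = pl.discrimination_ratio(zdff, track)
print(f"cocaine-side AUC/s: {res.auc_cocaine_per_s:+.3f} "
      f"over {res.occupancy_cocaine_s:.0f} s")
print(f"saline-side AUC/s:  {res.auc_saline_per_s:+.3f} "
      f"over {res.occupancy_saline_s:.0f} s")
print(f"Coc/Sal AUC Ratio:  {res.ratio:.3f}")
# With cocaine-compartment activity generated at half amplitude, the ratio
# falls below 1: the signal discriminates the two contexts.
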