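"""Score conditioned place preference from compartment-label trajectories.

Simulates a pre-test (unbiased exploration) and a post-test (cocaine-side
biased) trajectory in the three-chamber box, then computes the CPP score,
Paired - Unpaired Time, entry events, and stimulation bookkeeping windows.
"""

import photoloc as pl

pre_track, _ = pl.simulate_behavior_track(
    pl.BehaviorSimConfig(duration_s=1200.0, cocaine_bias=0.5, seed=10,
                         phase="pretest"))
post_track, _ = pl.simulate_behavior_track(
    pl.BehaviorSimConfig(duration_s=1200.0, cocaine_bias=0.8, seed=11,
                         phase="posttest"))

pre = pl.summarize_phase(pre_track)
post = pl.summarize_phase(post_track)

print(f"pre-test  cocaine side: {pre.time_cocaine_s:7.1f} s")
print(f"post-test cocaine side: {post.time_cocaine_s:7.1f} s")
print(f"CPP score:              {pl.cpp_score(pre, post):+7.1f} s")
print(f"paired-unpaired (post): {pl.paired_unpaired_time(post):+7.1f} s")

events = pl.detect_entries(post_track)
full = [e for e in events if e.is_full_transition]
print(f"side entries (post):    {len(events)}, "
      f"full transitions: {len(full)}")
# Only full transitions (opposite side -> center -> destination) are used
# for peri-event photometry; same-side returns and tracking glitches are
# excluded.

epochs = pl.stimulation_epochs(post_track)
total = sum(e - s for s, e, _ in epochs)
print(f"stimulation epochs:     {len(epochs)} covering {total:.0f} s "
      "(each capped at 300 s per entry)")
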