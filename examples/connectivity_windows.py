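"""From one segment to its time series of connectivity networks.

Shows the window bookkeeping: 1-s windows stepped by 0.5 s, then 30-s
smoothing advanced by 15 s, then rectification (negative correlations set
to zero).  At the full 25-min, 500-Hz geometry this yields 2999 raw and
98 smoothed networks.
"""

from seiznet import (
    CohortSpec, CouplingSchedule, generate_segment,
    bandpass_notch, prewhiten_ar1, sliding_correlation, smooth, rectify,
)

spec = CohortSpec(n_channels=8, fs=500.0, segment_length=1500.0, onset_offset=900.0)
schedule = CouplingSchedule.for_condition(spec, "bilateral")
seg, _ = generate_segment(spec, schedule, "bilateral", seed=7)

seg = prewhiten_ar1(bandpass_notch(seg, 1.0, 70.0, notch=60.0))
raw = sliding_correlation(seg, win=1.0, step=0.5)
smoothed = smooth(raw, span=30.0, stride=15.0)
nets = rectify(smoothed)

print(f"raw windows:      {len(raw)}")
print(f"smoothed windows: {len(smoothed)}")
pre = nets.matrices[nets.onset_relative_minutes < 0].mean()
post = nets.matrices[nets.onset_relative_minutes >= 0].mean()
print(f"mean edge weight pre-onset {pre:.3f}, post-onset {post:.3f}")
# Post-onset coupling gains raise pairwise correlations, so mean edge
# weight jumps after the (synthetic) seizure begins to spread.
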