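"""Bootstrap comparison of a metric between seizure types over time.

Builds a toy cohort with a pre-onset signature injected into the
bilateral class, computes per-segment modularity time courses, and runs
the segment-level bootstrap against a shuffled-label permutation null.
"""

import numpy as np

from seiznet import (
    CohortSpec, ScheduleParams, generate_cohort, RunConfig,
    segment_metrics, panel_from_series, compare_panels,
)

cfg = RunConfig(
    n_channels=8, fs=250.0, segment_length=300.0, onset_offset=180.0,
    band_high=40.0, notch=None, n_boot=2000, n_perm=2000, seed=2,
)
spec = CohortSpec(
    n_focal=8, n_bilateral=8, n_interictal=0,
    n_channels=8, fs=250.0, segment_length=300.0, onset_offset=180.0, seed=2,
)
series = []
for seg, _ in generate_cohort(spec, ScheduleParams(preictal_magnitude=0.5)):
    series.extend(segment_metrics(seg, cfg))

pa = panel_from_series(series, "bilateral", "modularity")
pb = panel_from_series(series, "focal", "modularity")
comp = compare_panels(pa, pb, metric="modularity", n_boot=2000, seed=3)

pre = comp.times_min < 0
print(f"pre-onset windows with p<0.05: {(comp.p[pre] < 0.05).sum()} / {pre.sum()}")
print(f"mean pre-onset difference (bilateral - focal): {comp.mean_diff[pre].mean():+.3f}")
print(f"significant intervals (min from onset): {comp.significant_intervals}")
if comp.d_min is not None:
    print(f"d_min = {comp.d_min:.2f}, 95% CI {comp.d_min_ci}")
# A positive pre-onset difference with small p recovers the injected
# signature: the bilateral class is more modular before onset.
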