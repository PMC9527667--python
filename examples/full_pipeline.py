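"""Run every stage end to end on a toy cohort and list the outputs.

Writes per-segment metric tables (CSV), per-comparison bootstrap results
(JSON), significant-interval and five-window ANOVA tables, and figure
files, all stamped with the config hash and seed.
"""

import json

from seiznet import RunConfig, run_pipeline

cfg = RunConfig(
    n_focal=3, n_bilateral=3, n_interictal=3, n_channels=8,
    fs=100.0, segment_length=150.0, onset_offset=90.0,
    band_high=40.0, notch=None, n_boot=500, n_perm=500,
    seed=4, outdir="scratch/example_run",
)
manifest = run_pipeline(cfg)
print(json.dumps(manifest, indent=1))
# Re-running with the same seed reproduces every table and JSON file
# byte for byte; see significant_intervals.csv for the per-metric
# bilateral-vs-focal windows with resampled p < 0.05.
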