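# Methods

## Pipeline overview

`seiznet` analyses conditioned 25-min epochs of multichannel
electrophysiology — 15 min before a seizure onset to 10 min after (or a
pseudo-onset for interictal epochs) — in four stages: preprocessing,
sliding-window connectivity, per-window graph statistics, and
time-resolved group comparison. Every stage is a pure function of its
inputs and the seed; fixed-seed reruns are byte-identical.

## Preprocessing

Channels are band-pass filtered 1–70 Hz (4th-order Butterworth) and notch
filtered at 60 Hz (IIR notch, quality factor 30), each applied
forward-backward so the passband gain is ~1 and phases — on which
windowed correlations depend — are untouched. Each channel is then
prewhitened with a first-order autoregressive model: φ is the lag-1
autocorrelation (Yule–Walker) of the mean-removed channel over the full
segment, and the channel is replaced by the innovation
x<sub>t</sub> − φ·x<sub>t−1</sub>. The first sample is dropped and the
last repeated so the segment keeps exactly 750 000 samples and the
downstream window counts stay exact. Prewhitening is per segment, not
global, so segments remain independent units for resampling. Zero-variance
channels pass through with φ = 0 and a logged warning. Re-referencing is
out of scope: inputs are assumed already common-referenced, and the
synthetic generator produces referenced signals.

## Connectivity geometry

Pearson correlation is computed in 1-s windows advanced by 0.5 s; only
fully contained windows are used, so a T-second segment yields
⌊(T − 1)/0.5⌋ + 1 windows (2999 at T = 1500). Smoothing averages 30-s
blocks of raw matrices advanced in 15-s strides, full blocks only:
⌊(2999 − 60)/30⌋ + 1 = 98 smoothed windows. This overlapping scheme is
the simple geometry that yields exactly 98 windows from the default
epoch, and the 15-s stride matches the 0.25-min granularity at which
significant intervals are reported. Negative correlations are then set
to zero (rectification), leaving weights in [0, 1]; a config switch
(`rectify_stage="raw"`) allows clipping before smoothing instead.
Diagonals are forced to zero — self-loops are meaningless for all seven
statistics. Each smoothed window is stamped with its block's first raw
window start; onset-relative time = start − 900 s, and a reported
significant interval runs from the first significant window start to the
last start + 0.25 min. Windows in which a channel has zero variance get
zero correlations for that channel and are counted in the log. An
optional region map averages channel-level correlations within region
pairs when nodes should be regions rather than electrodes; the default
is one node per channel.

## Graph statistics

All on symmetric non-negative matrices with zero diagonal:

* **Density** — Σ upper-triangular weights / [N(N−1)/2]; in [0, 1] for
  rectified correlations.
* **Clustering coefficient** — Onnela cube-root formula on raw weights:
  C<sub>i</sub> = Σ<sub>jh</sub> (A<sub>ij</sub>A<sub>ih</sub>A<sub>jh</sub>)^{1/3}
  / [k<sub>i</sub>(k<sub>i</sub>−1)] with binary degree k; nodes with
  k < 2 contribute 0; network value is the node mean. No max-weight
  rescaling: weights are already bounded by 1.
* **Characteristic path length** — edge length 1/w, Dijkstra all-pairs;
  mean over connected pairs, disconnected pairs excluded and counted; NaN
  (logged) if no pair connects.
* **Assortativity** — Pearson correlation of endpoint strengths with each
  undirected edge counted in both orientations (the symmetric weighted
  formula); NaN when endpoint strengths are equal (e.g. regular graphs).
* **Modularity** — Newman spectral method: recursive bisection on the
  leading eigenvector of the (generalized) modularity matrix with
  Kernighan–Lin-style node-moving refinement, stopping when no split
  increases Q. Q is evaluated with weighted degrees and 2m = total
  weight, resolution γ = 1 by default. Determinism: the eigenvector is
  oriented so its largest-magnitude entry is positive, entries within
  1e−12 of zero join the positive group, and the refinement sweeps nodes
  in index order breaking ties toward the lowest index. The method is a
  heuristic: the returned Q is guaranteed to equal the quality of the
  returned partition and to be ≥ 0, not to be the global optimum.
* **Spectral radius** — largest eigenvalue of A (symmetric eigensolver).
* **Synchronizability** — λ<sub>2</sub>/λ<sub>max</sub> of L = D − A,
  with λ<sub>2</sub> clipped at 0 against numerical negatives; 0 for
  disconnected graphs, 1 for complete graphs.

Undefined values propagate as NaN through metric tables rather than being
dropped, so window counts always match across metrics.

## Group statistics

For one metric, condition panels are segments × 98 windows. Per time
point:

* **Bootstrap.** Segments are resampled with replacement independently
  within each condition (default B = 10 000); the difference of
  per-condition means forms the difference distribution, summarized by
  its mean and percentile (2.5/97.5) CI. Percentile intervals are the
  simplest estimator consistent with a 95% CI.
* **Permutation null.** Pooled segments are reassigned to groups of the
  original sizes B times; the resulting mean-difference distribution is
  zero-centred by exchangeability.
* **p-values.** Two one-tailed tests are combined by doubling the smaller
  tail, then clamping to [1/B, 1] — so the smallest reportable p at
  B = 10 000 is 0.0001. The primary estimate refers the observed mean
  difference to the permutation null; a secondary estimate uses the
  fraction of the bootstrap difference distribution on the wrong side of
  zero. Both are reported; the null-based one drives significance at
  α = 0.05. The floor is applied after doubling: a distribution entirely
  on one side of zero reports exactly 1/B.
* **Effect sizes.** Cohen's d is computed between the bootstrapped
  per-condition *mean* distributions (pooled SD). Because these are
  distributions of means, d grows like √n — it measures separation of
  the group-mean estimates, not of individual segments; this is
  documented behaviour of the estimator, and the bootstrap-difference
  mean provides the complementary raw effect size. Within each maximal
  run of consecutive significant windows, d_min is the smallest |d|; its
  CI is the percentile interval of the per-iteration standardized
  differences at the arg-min window (the only distribution available at
  that locus). d_min is reported only when at least one window is
  significant.
* **No multiple-testing correction** is applied across the 98 windows;
  significance is per-window by design and flagged as such in every
  comparison JSON.
* **Windowed ANOVA.** Each metric series is averaged in five consecutive
  5-min windows (three preictal, one ictal, one postictal; half-open on
  the right so a window starting at onset is ictal). A mixed two-way
  ANOVA treats window as the within-segment factor and condition as the
  between-segment factor — a segment carries exactly one condition label,
  so condition cannot be a within-unit factor at the segment level.
  Fully degenerate (zero-variance) data reports F = 0, p = 1. Post hoc
  two-tailed paired t-tests compare all window pairs within each
  condition.

## Synthetic cohort generator

The generator emulates the *second-order structure* the pipeline
consumes, not seizure electrophysiology. Channels are partitioned into
hemisphere-confined communities (default 4 communities over 16 channels,
half per hemisphere). Channel i in community k is

x<sub>i</sub>(t) = [w<sub>k</sub>(t)·z<sub>k</sub>(t) + b(t)·g(t) + s·ε<sub>i</sub>(t)] / √(w<sub>k</sub>² + b² + s²),

where z<sub>k</sub> and g are unit-variance Gaussian latents band-limited
to 4–30 Hz (inside the 1–70 Hz analysis band, so preprocessing does not
remove the injected structure), ε<sub>i</sub> is white channel noise, and
the normalization keeps unit channel variance so gains map monotonically
onto expected correlations: within-community corr = (w² + b²)/(w² + b² + s²),
between = b²/(w² + b² + s²).

Condition schedules (all piecewise-linear with 15-s ramps):

* **interictal** — constant gains (w = 0.8, b = 0.4, s = 1, giving
  within/between correlations ≈ 0.44/0.09, plausible ECoG scales).
* **focal** — after onset the within gain of the onset community rises by
  1.2; no contralateral community is ever touched.
* **bilateral** — optionally, a pre-onset signature scales within gains
  by (1 + m) and the between gain by (1 − m) from segment start to onset
  (default m = 0.4), which raises modularity and lowers spectral radius;
  after onset the global between gain rises by 0.8 and, 30 s later,
  contralateral communities are recruited (within gain + 1.2) — raising
  density and clustering and shortening path lengths.

The magnitude m is a free simulation parameter: the source recordings
give no quantitative account of the pre-onset effect in raw-signal terms,
so m is chosen to be comfortably above the estimation noise floor, and
the recovery tests assert direction of effect, not magnitude. Sub-seeds
derive from (master seed, segment index), so cohorts are reproducible and
segments independent. Ground truth (communities, gain courses at 1 Hz,
onset community) is serialized as JSON beside each segment.

What the generator does **not** emulate — and hence what passing tests do
not establish about clinical data: seizure waveform morphology (spikes,
DC shifts, frequency evolution), patient-level clustering of segments,
electrode geometry and volume conduction, nonstationary noise, artifacts.
Passing recovery tests show the *pipeline* detects correlation-structure
signatures when present; they are not evidence about patients.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| fs | 500 Hz | sampling rate |
| epoch | 900 s pre + 600 s post onset | conditioned segment |
| band, notch | 1–70 Hz, 60 Hz | analysis band, powerline |
| win / step | 1 s / 0.5 s | raw correlation windows |
| span / stride | 30 s / 15 s | temporal smoothing |
| γ | 1 | modularity resolution |
| B | 10 000 | bootstrap and permutation iterations |
| α | 0.05 | per-window significance |
| cohort | 49 focal / 18 bilateral / 67 interictal | condition counts |

## Problem sizes used in the test suite

Unit tests run on seconds-long segments at 100–500 Hz. The acceptance
checks use: full 25-min/500-Hz geometry for the window-count identity; an
exhaustive sweep of all 3- and 4-node graphs with weights in {0, 0.3, 1}
plus 400 seeded 5/6-node samples for oracle agreement (a literally
exhaustive 6-node sweep would be ~14M graphs); 500 replicates at B = 1000
and 4 time points for type-I calibration; and 8-channel, full-length
49/18/67 cohorts at B = 5000 for signature recovery. These sizes are the
package's chosen desk-scale defaults; all of them are set in the tests
and can be raised.

## Known limitations

* The spectral modularity heuristic can return locally optimal
  partitions; only equation-consistency and non-negativity of Q are
  guaranteed.
* Cohen's d on bootstrapped means is sample-size dependent (see above)
  and not comparable across cohorts of different sizes.
* Per-window significance with no correction across 98 windows implies a
  ~5% per-window false-positive rate under the null; interval reports
  should be read accordingly.
* The mixed ANOVA uses the standard decomposition of its backend for
  unbalanced groups; heavily unbalanced designs (49/18/67) are intrinsic
  to the cohort and interpreted via the resampling analyses first.
* EDF files are read (via MNE) but not written; synthetic segments
  serialize to HDF5/CSV + JSON ground truth.
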