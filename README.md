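# seiznet

Time-resolved functional-connectivity network analysis of intracranial
(ECoG) recordings across seizure types.

Focal-onset seizures can stay confined to one hemisphere or spread
bilaterally, with very different clinical consequences. `seiznet`
implements a graph-theoretical pipeline for asking whether the two
propagation patterns are preceded and followed by measurable differences
in the brain's functional network: it turns multichannel recordings into
time series of weighted connectivity networks, summarizes each network
with seven graph statistics, and compares seizure types over time with a
segment-level bootstrap against shuffled-label permutation nulls. Because
clinical recordings of this kind are rarely shareable, the package also
ships a seeded synthetic-cohort generator with controllable,
community-structured coupling so the entire pipeline is testable end to
end without any patient data.

## Method

For each 25-min epoch (15 min before onset to 10 min after, at 500 Hz),
after 1–70 Hz band-pass, 60 Hz notch and per-channel AR(1) prewhitening:

1. **Connectivity.** Pairwise Pearson correlations in 1-s windows stepped
   by 0.5 s give a sequence of symmetric matrices *A*; 30-s blocks
   advanced by 15 s are averaged (2999 raw → 98 smoothed windows) and
   negative entries are set to zero, leaving edge weights in [0, 1].
2. **Graph statistics** per window: weighted density
   (Σ<sub>i<j</sub> A<sub>ij</sub> / [N(N−1)/2]), Onnela weighted
   clustering coefficient, characteristic path length (shortest paths
   with length 1/w), weighted assortativity (endpoint-strength
   correlation over edges), modularity *Q* with resolution γ = 1 found by
   Newman's spectral method (*Q* = (1/2m) Σ<sub>ij</sub> (A<sub>ij</sub> −
   γ k<sub>i</sub>k<sub>j</sub>/2m) δ(c<sub>i</sub>, c<sub>j</sub>) with
   weighted degrees), spectral radius λ<sub>max</sub>(A), and
   synchronizability λ<sub>2</sub>(L)/λ<sub>max</sub>(L) of the Laplacian
   L = D − A.
3. **Statistics.** Per metric and time point, segments are resampled with
   replacement within each condition (10 000 iterations) to form a
   difference distribution with percentile 95% CI; labels are shuffled
   10 000 times for a zero-centred null; the doubled one-tailed p is
   floored at 1/B (0.0001) and thresholded at 0.05; Cohen's *d* between
   the bootstrapped mean distributions is reported with *d*<sub>min</sub>
   (smallest |d| inside each significant run) and its percentile CI.
   Five consecutive 5-min window averages feed a mixed two-way ANOVA
   (condition × window) with post hoc paired t-tests.

## Worked example

```bash
python examples/graph_metrics_demo.py
```

```
two disconnected cliques:
  density            0.400
  clustering         1.000
  path length        1.000
  assortativity      nan
  modularity Q       0.500  partition=[0, 0, 0, 1, 1, 1]
  spectral radius    2.000
  synchronizability  0.000
```

Two unit-weight triangles with no link between them: 6 of the 15 possible
edges exist (density 0.4), every neighbourhood is a closed triangle
(clustering 1), the spectral partition recovers the two cliques exactly
(Q = 0.5), and a disconnected graph cannot synchronize (λ<sub>2</sub> = 0).
Assortativity is undefined (NaN) because all nodes have equal strength.

```bash
python examples/compare_seizure_types.py
```

```
pre-onset windows with p<0.05: 12 / 12
mean pre-onset difference (bilateral - focal): +0.345
significant intervals (min from onset): [(-3.0, 1.5)]
```

A toy cohort with a pre-onset signature injected into the bilateral class
(within-community gains up, between-community gain down): every pre-onset
window flags bilateral modularity as significantly higher than focal —
the pipeline recovers the injected direction of effect.

Other examples: `simulate_cohort.py` (ground-truthed cohort generation),
`connectivity_windows.py` (window bookkeeping: 2999 raw / 98 smoothed),
`full_pipeline.py` (all stages, serialized outputs). A thin CLI wraps the
pipeline: `seiznet run --seed 1 --outdir out/` (also `simulate`,
`analyze`; see `seiznet --help`).

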