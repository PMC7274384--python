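# Methods

This note records the model, the conventions adopted where the method
leaves genuine freedom, the synthetic-data generator's assumptions, and the
numerical choices, so results are interpretable and reproducible.

## Quantile-graph construction

A segment `X = {x(1..T)}` is discretised into `Q` quantile intervals.
Default `Q = round(2 T^{1/3})` (round half-up, minimum 2); `T = 1024`
gives `Q = 20`. The method is only weakly sensitive to `Q`, but the same
`Q` must be used across segments that are compared.

**Boundary convention.** Interior boundary `b_i` is the right-continuous
inverse-ECDF quantile at probability `i/Q`: the order statistic of rank
`floor(T i / Q) + 1` (0-based index `floor(T i / Q)` into the sorted
sample). `b_0` and `b_Q` are the sample min and max. Intervals are
half-open on the right, `[b_{i-1}, b_i)`, the last closed; a sample equal
to an interior boundary therefore falls in the upper interval. This exact
combination makes bin occupancy balanced: with distinct values each
interval holds between `floor(T/Q)` and `ceil(T/Q)` samples (exactly
`T/Q` when `Q` divides `T`). Taking the boundary at the `ceil(Ti/Q)`-th
order statistic instead would push each boundary sample upward and leave
the first interval one sample short.

Partitions are always refit per segment (quantile graphs are invariant to
monotone amplitude transformations, so per-segment fitting removes gain
differences between recordings). When a *reference* partition is reused on
another segment, out-of-range samples are clamped to the end bins with a
warning — no silent extrapolation.

**Counting.** `A_k[i][j]` counts lag-`k` transitions; the total is exactly
`T - k` and is asserted throughout. Rows of the normalised `W_k` with no
outgoing transitions are kept as zero rows and flagged unsupported rather
than filled uniformly: fabricating transitions would bias every downstream
metric. All metrics tolerate unsupported rows.

**Group aggregation.** The group-level matrix at lag `k` is the
element-wise median of the member segments' *count* matrices, normalised
afterwards. Median-then-normalise (rather than median of `W_k`) keeps the
aggregate interpretable as a typical count pattern and is robust to
outlying segments.

**Cross-lag consistency.** The lag-1 count matrix is the arc multiset of
an Eulerian path; higher-lag matrices are induced by the same underlying
index sequence. `consistency.find_consistent_sequence` decides whether a
family `{A_k}` is mutually consistent by enumerating Eulerian paths of the
lag-1 multigraph with pruning against the higher-lag count budgets (the
start node is forced by the degree imbalance when one exists). For the
embedded 20-sample worked example the search returns a generating sequence
in well under a second.

## Network metrics

All five metrics consume the Markov weights `W_k` (entries in `[0, 1]`).
With row-stochastic weights every node strength is at most 1, so the
symmetrised Laplacian spectrum is bounded by 2 and the Estrada index stays
`O(Q e^2)` — using raw counts instead would make `LEE` astronomically
large and numerically useless.

* **Clustering coefficient.** Per node
  `CC_i = [1/(s_i(d_i-1))] * sum_{j,h} ((w_ij + w_ih)/2) a_ij a_jh a_ih`,
  with `a` the unweighted arc indicator, `d_i` the number of distinct
  neighbours over the union of in/out arcs, `s_i` the out-strength.
  Self-loops are excluded; nodes with `d_i <= 1` or `s_i = 0` contribute 0.
  The weighted-clustering literature is ambiguous for digraphs; this
  directed reading (weights from the anchor node's outgoing arcs, closure
  over directed triangles) is the documented choice. On a symmetric
  unit-weight clique `CC = 1`; on triangle-free graphs `CC = 0`.
* **Mean jump length.** `MJL = (1/Q) tr(P W^T)`, `p_ij = |i - j|` — the
  expected quantile displacement per transition under uniform row choice.
  Bounds `0 <= MJL <= Q - 1`; `0` iff all supported mass is diagonal; a
  uniform matrix gives `(Q^2 - 1)/(3Q)` (6.65 at `Q = 20`), the
  independent-noise ceiling. A Monte-Carlo variant simulates an `S`-step
  random walk (restarting uniformly over supported rows at dead ends;
  restarts are not counted as jumps) and returns mean, standard error and
  `S`; on doubly stochastic matrices the two agree within Monte-Carlo
  error because the stationary law is uniform. Note `MJL` is deliberately
  *not* permutation-invariant: node indices are positions on the quantile
  axis.
* **Betweenness centrality.** Shortest paths counted unweighted
  (hop count) on the digraph of positive-weight arcs, self-loops ignored;
  per-node values normalised by `(Q-1)(Q-2)` and averaged. The hop-count
  rule is the simplest defensible choice given no edge-length convention;
  a `1/w` edge-length alternative would change only the path structure,
  not the pipeline.
* **Modularity.** `M(P) = sum_m [e_m/E - (d_m/2E)^2]` on the arithmetic-
  mean symmetrised graph with self-loops dropped. Partition search is
  greedy modularity maximisation (deterministic agglomeration), so `MO` is
  reproducible without a seed; the returned score is always recomputed
  from the returned assignment. An edgeless graph returns one module with
  `M = 0` by convention; the score itself is undefined at `E = 0`.
* **Laplacian Estrada index.** `LEE = sum_i exp(mu_i)` over the
  eigenvalues of `L = D - A` on the symmetrised loop-free graph;
  `LEE = n` for the edgeless graph, `1 + e^2` for a single unit edge.

## Discrimination pipeline

Curves `metric(k)`, `k = 1..25` by default, one per group, from the
median-aggregated matrices. The discriminating lag `k_max` maximises the
*worst-case* gap between the healthy and patient curve clusters
(`min` over cross pairs of `|curve_h(k) - curve_u(k)|`), ties resolved
toward the smallest lag; the worst-case gap (rather than the gap between
cluster means) guarantees that at `k_max` every healthy curve is separated
from every patient curve. The metric is then evaluated on each segment's
own `W_{k_max}` — aggregation is only used to pick the lag, never to
manufacture per-subject values.

Group separation is quantified by (i) the Mann–Whitney ROC area, oriented
as `max(AUC, 1 - AUC)` so it measures separability regardless of the
direction of the pathological shift, computed for the four cross-condition
pairs (A,C), (B,D), (A,D), (B,C) and averaged per channel; and (ii) a
two-level one-way ANOVA (healthy {A,B} vs patient {C,D}; equivalent to a
pooled t-test, `F = t^2`) with the 95% CI of the mean difference. No
multiple-testing correction is applied.

Classification uses one row per subject (a subject's eyes-open and
eyes-closed segments are averaged; the conditions used are recorded as
metadata), five features — each metric at its own `k_max` — a linear
SVM (`C = 1`) with features z-scored on each training fold, and stratified
10-fold cross-validation with a seeded shuffle. Accuracy, sensitivity,
specificity come from the pooled held-out confusion matrix; AUC from the
pooled decision scores. With 5 features and ~48 subjects a linear margin
is the honest default; the kernel is configurable.

## Frequency bands

Default scheme: 5-level db4 DWT at 128 Hz (periodised, perfectly
reconstructing), mapping dyadic levels to bands — delta = A5+D5 (0–4 Hz),
theta = D4 (4–8), alpha = D3 (8–16, approximating 8–13), beta = D2
(16–32, approximating 13–30), D1 returned as residual. The dyadic edges
only approximate the clinical alpha/beta cut-offs, so an exact zero-phase
Butterworth band-pass scheme (order 4, forward–backward) is provided for
any sampling rate; both are config options. Per-band quantile partitions
are refit on the band series.

The per-band group comparison evaluates the mean jump length per segment
at a **fixed** lag (default `k = 10`, mid-sweep) and runs the two-group
ANOVA. Selecting each band's own maximum-separation lag and then testing
at it on the same data inflates the false-positive rate on contrast-free
bands (observed empirically on null cohorts); the fixed-lag default keeps
the test calibrated, and `k=None` re-enables per-band selection for
exploratory use.

## Synthetic cohorts

The generator emulates the study shape — groups A/B (controls, eyes
open/closed) and C/D (patients), 24 subjects per group, 19 channels of the
10-20 system, `T = 1024` at 128 Hz — and the qualitative control-vs-patient
spectral contrast ("slowing": power shifts toward delta/theta with reduced
alpha). Each segment is a sum of per-band Gaussian noise (zero-phase
band-pass filtered white noise scaled to the group's band-power profile),
narrow-band rhythms (frequency- and amplitude-jittered sinusoids with a
slow stochastic envelope: an alpha rhythm, stronger with eyes closed and
on posterior channels, and a pathological ~2 Hz slow-wave rhythm in the
patient profile), plus white measurement noise. Per-subject log-normal
band-power jitter (sd 0.15) is shared across channels so subjects behave
as consistent traits. Everything is determined by
(seed, group, subject, channel).

The slow-wave rhythm matters for the band analysis specifically: quantile
graphs are invariant to amplitude scaling, so raising a group's delta
*power* alone is invisible once the delta band is isolated — it is the
different within-band temporal structure (rhythmic slow waves vs flat band
noise) that the per-band analysis detects.

**What passing tests show — and do not show.** The generator reproduces
group-level spectral structure only. It has no waveform morphology, no eye
or muscle artifacts (the emulated recordings were curated artifact-free),
no cross-channel coherence and no biophysics. Perfect synthetic
classification therefore demonstrates that the pipeline recovers a known
spectral contrast at the study's sample sizes, not that real EEG separates
this cleanly.

## Numerical choices and degenerate inputs

* Constant series raise a degenerate-partition error (no quantile
  partition exists); `Q > T` and `k >= T` are rejected.
* Supported rows of `W_k` sum to 1 within 1e-12 (asserted in tests).
* Median counts may be half-integers; normalisation handles them exactly.
* Ties in `k_max` selection go to the smallest lag; ties in sample-vs-
  boundary assignment go to the upper interval; Mann–Whitney ties get
  midrank credit.
* Zero-variance ANOVA inputs: equal means give `p = 1` by convention,
  unequal means `p = 0` with a point CI.
* All randomness (walks, CV shuffles, the generator) flows through
  explicit integer seeds; reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script run the study-shaped sweeps in
full — 1,200 graphs for a one-channel two-group sweep, 22,800 for the
19-channel sweep, 2,400 for a one-group four-band sweep — and use
24 subjects per group throughout; at `Q = 20` these complete in seconds.
The Monte-Carlo walk check uses 10^6 jumps. Smaller cohorts
(3–12 subjects, `T = 256`) are used only for structural tests where the
quantity checked is exact (counts, shapes, round trips).

## Known limitations

* Single-channel analysis only: no cross-channel (multivariate) graphs,
  no coherence features, no scalp-topography rendering.
* Regular sampling assumed; no continuous-time support.
* The clustering-coefficient digraph variant and the community-detection
  algorithm are documented choices among reasonable alternatives, not
  canonical definitions.
* The ANOVA assumes approximately normal within-group metric values; with
  24 subjects per group it is robust, but heavy-tailed metrics at extreme
  lags may warrant the ROC area instead.
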