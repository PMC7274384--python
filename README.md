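# quantgraph

Quantile-graph analysis of EEG time series: map a signal into a family of
lag-indexed weighted directed networks, summarise each network with five
topological metrics, and use them to discriminate healthy from pathological
recordings (e.g. Alzheimer-type "slowed" EEG) — including channel ranking,
frequency-band analysis and cross-validated classification.

## Who this is for

Researchers working with short, univariate biomedical time series
(EEG segments in particular) who want a nonlinear, distribution-free
characterisation of signal dynamics that does not assume stationarity,
high SNR, or a parametric spectral model.

## The method

A segment `X = {x(t)}` of length `T` is discretised into `Q` quantile
intervals (`Q = 2T^{1/3}` by default; `Q = 20` for the study's
`T = 1024`-sample, 128 Hz segments). Each interval is a node. For a lag
`k`, a directed arc `i -> j` is weighted by the number of times a sample in
quantile `i` is followed `k` steps later by a sample in quantile `j`:

    A_k[i, j] = #{ t : x(t) in q_i  and  x(t+k) in q_j },   sum A_k = T - k

Row-normalising `A_k` gives the Markov transition matrix `W_k`. Slowly
varying signals concentrate `W_k` near the diagonal; fast or uncorrelated
signals spread mass across it. Five metrics summarise each `W_k`:

| metric | meaning |
|--------|---------|
| `CC`   | weighted clustering coefficient (averaged over nodes) |
| `MJL`  | mean jump length `(1/Q) tr(P W_k^T)`, `p_ij = \|i-j\|` |
| `BC`   | normalised betweenness centrality (directed hops, averaged) |
| `MO`   | modularity of the best partition (greedy maximisation) |
| `LEE`  | Laplacian Estrada index `sum_i exp(mu_i)` of the symmetrised Laplacian |

The group pipeline aggregates each group's count matrices by an
element-wise **median** before normalising, sweeps `k = 1..25`, picks the
lag `k_max` where the healthy and patient curve clusters are farthest
apart, evaluates the metric per segment at `k_max`, and quantifies
separation by Mann–Whitney ROC areas, a two-level ANOVA with 95% CI, and a
stratified 10-fold cross-validated linear SVM on the five-metric feature
table. A wavelet (or zero-phase band-pass) decomposition re-runs the
analysis per clinical band (delta 1–4, theta 4–8, alpha 8–13,
beta 13–30 Hz).

A seeded synthetic cohort generator with the study shape (4 groups x 24
subjects x 19 channels x 1024 samples) and a controllable
control-vs-patient spectral contrast makes every stage testable without
any data download.

## Worked example

```python
import quantgraph as qg

# synthetic cohort: 24 controls (A) vs 24 patients (C), channel F7
spec = qg.two_group_spec(channels=("F7",), groups=("A", "C"), seed=1)
cohort = qg.generate_cohort(spec)

curves = qg.metric_curves(cohort, "F7", "MJL", k_cap=25)
sel = qg.select_kmax([curves["A"]], [curves["C"]])
print(f"k_max = {sel.k_max}, separation = {sel.separation:.3f}")

df = qg.per_segment_metrics(cohort, "F7", "MJL", sel.k_max)
by = {g: d["value"].to_numpy() for g, d in df.groupby("group")}
print(f"A_ROC = {qg.roc_auc(by['A'], by['C']):.4f}")
an = qg.group_anova(by["A"], by["C"])
print(f"ANOVA: F = {an.F:.1f}, p = {an.p:.2e}, "
      f"95% CI of mean difference = [{an.ci_low:.3f}, {an.ci_high:.3f}]")
```

prints

```
k_max = 6, separation = 3.853
A_ROC = 1.0000
ANOVA: F = 886.5, p = 1.05e-31, 95% CI of mean difference = [3.231, 3.699]
```

The alpha-dominant controls make larger quantile jumps at short lags than
the delta-dominant patients (group mean MJL 8.39 vs 4.93 at `k_max = 6`),
so the mean jump length separates the groups completely on this cohort:
ROC area 1.0 and a confidence interval for the healthy-minus-patient mean
difference far from zero.

The same stages are available from the shell:

```sh
quantgraph simulate --seed 1 --groups A,C --channels F7 --out cohort.tsv
quantgraph metrics cohort.tsv -c F7 -o curves.csv
quantgraph discriminate cohort.tsv -m MJL -o auc.csv
quantgraph run-all config.yaml
```

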