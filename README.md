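# scabc

Unsupervised clustering of single-cell ATAC-seq data and identification of
cluster-specific accessible peaks.

scATAC-seq measures chromatin accessibility one cell at a time, but each
cell yields only a few thousand distinct reads spread over hundreds of
thousands of potential regulatory regions, so the per-cell signal is
extremely sparse and the dropout pattern tracks sequencing depth rather
than biology. This package clusters cells directly on accessibility — no
reference epigenomes required — and then asks, peak by peak, which cluster
a region is specific to. It is aimed at anyone with a peak set called on
aggregated cells plus per-cell reads (or a precomputed cells × peaks count
matrix) who wants de novo cell groupings and the open-chromatin regions
that distinguish them.

## Method

**Clustering.** Each cell *i* receives a weight from its *sample depth*
h<sub>i</sub> (distinct reads in peak background regions),

$$w_i = \frac{1}{1+\exp\{-(h_i-c)/(c\lambda)\}},$$

with midpoint *c* = median depth and steepness λ = 0.1 by default, so
low-coverage cells pull less on the solution. Counts are rank-transformed
within each cell and cells are compared by d = 1 − Spearman correlation.
Weighted K-medoids minimizes

$$\sum_{k=1}^{K}\sum_{C(i)=k} w_i\, d(Y_i, Y_{i_k})$$

via the PAM algorithm (greedy BUILD seeding plus SWAP exchanges, with
restarts). Each cluster is summarized by a *landmark* — its summed counts
over the P = 2000 highest-count peaks — and every cell is re-assigned to
the landmark with the highest Spearman correlation over the union of
landmark peaks. The number of clusters is chosen by a gap statistic whose
reference sets permute each peak's counts across cells, preserving
per-peak sparsity while destroying cell structure.

**Cluster-specific peaks.** Counts follow a Poisson regression with the
sample depth as exposure,

$$y_{ri}\sim\mathrm{Poisson}(h_i q_{ri}),\qquad
\log q_{ri} = \beta_0 + \textstyle\sum_k x_{ik}\beta_{rk},\qquad
\beta_{rk}\sim\mathcal{N}(0,\sigma_k^2),$$

with the prior scale σ<sub>k</sub> estimated by DESeq2-style quantile
matching on the no-intercept maximum-likelihood effects (q = 0.05). A peak
is specific to cluster *k* when its shrunken (MAP) effect exceeds every
other cluster's: an intersection–union test whose p-value is the maximum
of the K−1 one-sided Wald p-values, thresholded at 10⁻⁶ (≈ Bonferroni at
family-wise error 0.05 for typical peak-set sizes).

## Worked example

```python
import numpy as np
from scabc import (SimulationSpec, simulate, cluster, ClusterConfig,
                   DesignInfo, call_specific_peaks)

spec = SimulationSpec(n_cells_per_cluster=(100, 100, 100), seed=7)
cm, truth = simulate(spec)
print(f"{cm.n_cells} cells x {cm.n_peaks} peaks, "
      f"{(cm.counts == 0).mean():.1%} zero entries")

model = cluster(cm, K="auto", cfg=ClusterConfig(seed=7))
print(f"gap statistic selected K = {model.K}")
sizes = np.bincount(model.assignment[model.assignment >= 0])
print(f"cluster sizes: {sizes.tolist()}")

design = DesignInfo.from_labels(model.assignment, cm.sample_depth)
res = call_specific_peaks(cm, design)
print(f"{(res.table.specific_cluster >= 0).sum()} cluster-specific peaks at p < 1e-6")
print("prior scales:", np.round(res.prior.sigma, 3))
```

prints

```
300 cells x 2400 peaks, 87.0% zero entries
gap statistic selected K = 3
cluster sizes: [99, 100, 101]
84 cluster-specific peaks at p < 1e-6
prior scales: [0.456 0.486 0.477]
```

The simulation plants three clusters of 100 cells with 200 peaks each at
4-fold elevated accessibility on top of 1800 shared peaks, with log-normal
depth heterogeneity. The gap statistic recovers K = 3, the cluster sizes
match the planted groups (the partition here differs from truth by a
single cell), and every one of the 84 peaks passing the 10⁻⁶ cutoff is a
genuinely planted specific peak — at this sparsity the cutoff trades
recall for a near-zero false-discovery rate. The prior scales ≈ 0.47
reflect the spread of the planted log-fold effects.

The same pipeline is available from the shell:

```bash
scabc simulate --seed 7 -o sim/
scabc run --matrix sim/ --seed 7 -o out/       # count -> QC -> cluster -> peaks
scabc cluster --matrix sim/ --k-range 1:6 -o out/   # individual stages
scabc peaks --matrix sim/ --assignments out/assignments.tsv -o out/
```

Outputs are TSV (assignments with nearest-landmark correlations, landmark
matrix, normalized similarity, gap curve, per-peak test table) plus BED
files of specific peaks per cluster, and a JSON manifest with input
checksums and the fully-resolved configuration.

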