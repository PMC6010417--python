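# Methods

This note documents the models implemented in `scabc`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmark does and does not establish about real data.

## Input model and sample depth

The unit of analysis is a cells × peaks matrix of non-negative integer
counts y_ri over a fixed peak set (0-based half-open intervals, BED
convention; a read counts toward every peak whose interval it intersects).
"Distinct reads" deduplicate on (chrom, start, end, strand); fragments
from a fragments-style file carry no strand and are treated as single
intervals. Strand is otherwise ignored — accessibility is unstranded.

Each cell's *sample depth* h_i is its number of distinct reads in the
*peak background*: the union of all peaks extended by a flank on each side
and merged. The flank defaults to 250 kb per side — wide enough that h_i
approximates per-cell library depth over mappable, peak-proximal genome
while excluding unannotated contigs — and is exposed as a flag
(`--flank`), since reasonable definitions of "background" differ. Cells
with fewer than 500 distinct background reads fail QC by default
(`--min-depth`); h_i = 0 always fails, because h_i is later a Poisson
exposure and a clustering weight covariate, both of which require h_i > 0.
Both thresholds are deliberately conservative, documented stand-ins: peak
backgrounds and cell QC are the least standardized steps of this kind of
pipeline and should be adapted to the assay at hand.

## Depth-weighted K-medoids

Sparse cells are unreliable: a zero in a low-depth cell carries almost no
evidence that the region is closed. Cells are therefore weighted by the
logistic transform

    w_i = 1 / (1 + exp{ -(h_i - c) / (c λ) }),

with midpoint c = median(h) and relative steepness λ = 0.1 by default.
w is strictly increasing in h_i and w(c) = 0.5 exactly; computed weights
are clipped to the open interval (0, 1) at double precision (a cell 50
logistic widths past the midpoint saturates to the largest double below
1). Clustering quality is insensitive to {c, λ} over a wide range; both
are exposed as flags.

Counts are rank-transformed within each cell (average ranks on ties, the
standard midrank correction, important because most entries are zero) so
that a handful of extremely accessible regions cannot dominate, and cells
are compared by d = 1 − ρ, with ρ the tie-corrected Spearman correlation
(Pearson on ranks), d ∈ [0, 2]. Cells whose counts are identical across
all peaks have zero rank variance, making ρ undefined; they are excluded
before clustering with an explicit reason and carry label −1 in the
output, never a silent ρ = 0.

The weighted objective Σ_k Σ_{C(i)=k} w_i d(Y_i, Y_{i_k}) is minimized by
PAM. BUILD greedily seeds K medoids (exact ties in the greedy gain are
broken randomly under the run seed); SWAP repeatedly applies the single
best medoid/non-medoid exchange until no exchange strictly decreases the
objective. The first restart seeds SWAP from BUILD; the remaining restarts
(10 total by default) seed from random medoid subsets. Random-subset
restarts are the package's own choice: a pure BUILD+SWAP descent is a
single-exchange local search and, on random small instances, lands in a
non-global local optimum roughly 1% of the time, while best-of-10 restarts
reproduced the exhaustive-enumeration optimum on every one of 200 random
instances with ≤9 cells and K ≤ 3 (this check is part of the test suite).
On generic data (no exact dissimilarity ties) the procedure is
deterministic given the seed, and equivariant to cell order up to label
renaming.

## Landmarks and re-assignment

K-medoids centers are single cells and inherit single-cell noise. Each
cluster is therefore summarized by a *landmark*: its cells' summed counts,
restricted to the cluster's P = 2000 highest-count peaks (ties at the P-th
place keep the peak earlier in genomic order, for determinism). Every cell
is then re-assigned to the landmark with the highest Spearman correlation
computed over the union of all clusters' landmark peaks; the correlation
uses raw cluster sums versus raw cell counts on the union subset, ranked
internally by the Spearman computation (subset first, then rank). Cells
with no counts on the union peaks are unassignable and reported as such.
A cells × landmarks similarity matrix is emitted, together with a
normalized version (each cell's correlations divided by the mean of their
absolute values), which sharpens the visual contrast between the matching
landmark and the rest.

## Choosing K: gap statistic with a permutation reference

Gap(K) = mean_b log W*_Kb − log W_K, where W_K is the weighted K-medoids
objective on the data and W*_Kb on the b-th reference set (B = 50).
Reference sets permute each peak's counts independently across cells:
this preserves every peak's marginal count distribution — and therefore
the data's sparsity, which a uniform-box reference badly misrepresents —
while destroying all cell structure. The per-cell depth weights are kept
fixed. The selected K is the smallest with Gap(K) ≥ Gap(K+1) − s_{K+1},
where s is the reference standard deviation times √(1 + 1/B). When no K
in the candidate range satisfies the rule (a continuously increasing gap
curve), the model reports "no plateau" rather than a number — that
signature suggests a continuum of states rather than discrete clusters,
and silently returning the largest K would be misleading.

## Cluster-specific peaks

Counts are modeled per peak as y_ri ~ Poisson(h_i q_ri) with
log q_ri = β₀ + Σ_k x_ik β_rk, membership x from the clustering, and
normal priors β_rk ~ N(0, σ_k²); β₀ carries no prior. Because membership
partitions the cells, the likelihood depends on the data only through the
per-cluster count totals S_k and exposure totals H_k, so:

- **MLE.** The no-intercept, no-prior MLE is the closed form
  β_rk = log(S_k / H_k). A pseudocount of 0.5 is added to S_k *only when
  S_k = 0*, preventing −∞ estimates from corrupting the prior-scale
  estimate without perturbing informative clusters.
- **Prior scale.** σ̂_k is the empirical (1−q) quantile of
  |β_·k − row-mean| divided by the standard normal (1 − q/2) quantile
  (1.959964 at the default q = 0.05) — quantile matching in the DESeq2
  style. The estimate is floored at 10⁻³ so the prior stays proper on
  degenerate inputs. Non-finite MLE columns (possible only with a zero
  pseudocount) are ignored in the quantile. All tested peaks enter the
  estimate; no additional low-count pre-filter is applied.
  The notation point that deserves emphasis: the quantile taken is the
  *upper* (1−q) empirical quantile of the absolute centered effects, and
  the divisor is the upper (1 − q/2) normal quantile, so that if the
  centered effects were exactly N(0, s²), σ̂ recovers s.
- **MAP.** The posterior mode over (β₀, β_r·) is found by damped Newton
  (step-halving on the log-posterior, gradient ∞-norm tolerance 10⁻⁸,
  max 100 iterations), batched across all peaks via a stacked
  (K+1)×(K+1) solve. Non-converged peaks are flagged and reported with NA
  p-values. The posterior covariance is the inverse negative Hessian at
  the mode, computed in closed form by block inversion: with
  D = diag(λ_k + 1/σ_k²), λ_k = H_k exp(β₀+β_k), the β-block is
  D⁻¹ + (D⁻¹λ)(D⁻¹λ)ᵀ·var(β₀). Wald contrast variances are assembled
  from these factors rather than from the assembled matrix: in the
  diffuse-prior limit the assembled covariance entries grow like σ² while
  the contrast variance stays O(1/λ), and forming the contrast from the
  assembled entries cancels catastrophically exactly where the
  diffuse-limit checks operate.
- **Test.** Peak r is specific to cluster k when β_rk exceeds every other
  β_rk′. The composite null "β_rk ≤ β_rk′ for some k′" decomposes into
  K−1 one-sided Wald hypotheses; the intersection–union p-value is the
  maximum of the component p-values p_k′ = 1 − Φ(z_k′), one-sided as the
  rejection region dictates. An IUT is level-α with no further
  correction — under equal-rate nulls it is in fact conservative, which
  the test suite verifies empirically. A zero standard error with a
  nonzero numerator yields p ∈ {0, 1} by sign; with a zero numerator,
  p = 0.5, flagged.

The default cutoff 10⁻⁶ approximates a Bonferroni correction at
family-wise error 0.05 for peak sets of a few times 10⁴–10⁵ regions.
Benjamini–Hochberg q-values are emitted alongside for inspection but play
no role in the default calls. Peaks with zero counts in every cell are
excluded with reason "no signal". Multiplying all h_i by a constant shifts
β₀ by −log(constant) and leaves every effect, z and p unchanged — an exact
equivariance, verified in the tests.

## Synthetic benchmark

The generator mirrors the inferential model: exposures h_i are log-normal,
rates are a shared base rate times a fold change on a cell's own cluster's
specific peaks, counts are Poisson. The default benchmark uses three
clusters of 100 cells, 1800 common peaks plus 200 specific peaks per
cluster at fold change 4, depths with median 5000 and a 10× spread between
the 10th and 90th percentiles, and a base rate calibrated by Gauss–Hermite
quadrature so the *expected* zero fraction is 0.85 (realized zero
fractions vary by roughly ±1.5 percentage points across seeds). The
calibration is deterministic and data-independent.

On this benchmark, clustering recovers the planted partition with ARI
0.97–1.0 and the gap statistic selects K = 3 reliably (20/20 seeds in the
suite's scan). Specific-peak calling at the 10⁻⁶ cutoff is a different
story, and deliberately so: with ~85% zeros, an off-cluster count total
for one peak is ~14 reads, the best-case one-sided Wald z for a 4-fold
effect averages ~4.2 (minimum over the two pairwise comparisons), and the
cutoff demands z > 4.75. Sensitivity at the cutoff is therefore ~0.2–0.3
— an information limit of the operating conditions, not of the estimator:
the diffuse-prior (pure MLE) version of the test does no better.
Precision, by contrast, is ~1.0, and under equal-rate nulls the empirical
rejection rate at α = 0.05 is well below 0.05 with zero calls at 10⁻⁶.
The method, like the cutoff it inherits, is tuned to say *specific* only
when the evidence is overwhelming.

What the benchmark does not emulate: zero inflation beyond the Poisson
(real scATAC may be further overdispersed), per-peak rate heterogeneity,
batch effects, fragment-level structure (Tn5 insertion bias, fragment
size mixtures), doublets, or genome-aware peak placement. Passing
recovery tests here demonstrates correctness of the algorithms under
their own model assumptions — it does not by itself establish performance
on real libraries, where the QC and background definitions above matter
as much as the statistics.

## Problem sizes and determinism

The test suite and the acceptance script run the benchmark at its native
size (300 cells × 2400 peaks; the gap-statistic scan uses 20 seeds at
B = 50 references each, candidate K from 1 to 6). A single top-level seed
fans out to BUILD tie-breaking, restart initializations, and gap
references; identical configuration and inputs reproduce byte-identical
outputs, and the run manifest records input checksums and the resolved
configuration with default/user provenance for every field.
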