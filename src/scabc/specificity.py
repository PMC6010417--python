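"""Cluster-specific peak calling via an empirical-Bayes Poisson model.

Counts for peak r in cell i are modeled as

    y_ri ~ Poisson(h_i * q_ri),     log q_ri = beta_0 + sum_k x_ik beta_rk,

with h_i the cell's sample depth (a known exposure), x_ik binary cluster
membership, and normal priors beta_rk ~ N(0, sigma_k^2). The prior scale is
estimated by quantile matching on the no-intercept maximum-likelihood
effects (the DESeq2 shrinkage recipe): sigma_k is the empirical (1-q)
quantile of |beta_mle_.k - rowmean(beta_mle)| divided by the normal
(1 - q/2) quantile, q = 0.05 by default.

A peak is called specific to cluster k when its shrunken effect exceeds
every other cluster's: the null "beta_rk <= beta_rk' for some k'" is an
intersection-union test whose p-value is the maximum of the K-1 one-sided
Wald p-values for the pairwise differences. The default cutoff 1e-6 is
roughly a Bonferroni correction at family-wise error 0.05 for the peak
counts typical of aggregate scATAC peak sets.

Because cluster membership partitions the cells, each peak's likelihood
depends on the data only through per-cluster count and exposure totals, so
all R peaks are fit simultaneously with a batched damped-Newton solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix_io import CountMatrix

DEFAULT_Q = 0.05
DEFAULT_CUTOFF = 1e-6
DEFAULT_PSEUDOCOUNT = 0.5
SIGMA_FLOOR = 1e-3


@dataclass
class DesignInfo:
    """Cluster membership design: binary N x K matrix and per-cell exposures."""

    x: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.x.ndim != 2 or not np.all(np.isin(self.x, (0.0, 1.0))):
            raise ValueError("x must be a binary matrix")
        if not np.allclose(self.x.sum(axis=1), 1.0):
            raise ValueError("each cell must belong to exactly one cluster")
        if self.h.shape != (self.x.shape[0],) or np.any(self.h <= 0):
            raise ValueError("h must be positive with one entry per cell")
        if np.any(self.x.sum(axis=0) == 0):
            raise ValueError("every cluster must contain at least one cell")

    @property
    def K(self) -> int:
        return self.x.shape[1]

    @property
    def cluster_exposure(self) -> np.ndarray:
        """H_k = sum of h_i over cells in cluster k."""
        return self.x.T @ self.h

    @classmethod
    def from_labels(cls, labels: Sequence[int], h: np.ndarray) -> "DesignInfo":
        labels = np.asarray(labels)
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative (drop unassigned cells first)")
        uniq = np.unique(labels)
        x = (labels[:, None] == uniq[None, :]).astype(float)
        return cls(x=x, h=np.asarray(h, dtype=float))


@dataclass
class PriorEstimate:
    sigma: np.ndarray       # per-cluster prior sd, floored at sigma_floor
    q: float
    beta_bar: np.ndarray    # per-peak mean of the MLE effects

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("prior sd must be positive")


@dataclass
class PeakGlmFit:
    """MAP fit of one peak's Poisson regression under the normal prior.

    ``cov`` is the inverse negative Hessian of the log-posterior at the
    optimum, ordered (beta0, beta_1..K). The private fields keep the
    Sherman-Morrison factors of the beta-block so Wald contrasts can be
    formed without the cancellation the assembled covariance suffers from
    when the prior is diffuse.
    """

    beta0: float
    beta: np.ndarray
    beta_mle: Optional[np.ndarray]
    cov: np.ndarray
    converged: bool
    iterations: int
    _d_inv: np.ndarray = field(default=None, repr=False)    # 1/(lam_k + 1/sigma_k^2)
    _u: np.ndarray = field(default=None, repr=False)        # d_inv * lam
    _cov00: float = field(default=0.0, repr=False)          # var(beta0)

    def contrast_var(self, k: int, kp: int) -> float:
        """Var(beta_k - beta_kp) from the posterior curvature."""
        du = self._u[k] - self._u[kp]
        return float(self._d_inv[k] + self._d_inv[kp] + du * du * self._cov00)


# ---------------------------------------------------------------------------
# MLE and prior


def fit_mle_no_intercept(counts_r: np.ndarray, design: DesignInfo,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Per-cluster Poisson MLE with offsets and no intercept: log(S_k / H_k).

    With membership a partition, the no-intercept MLE has the closed form
    beta_k = log(sum_{i in k} y_ri / sum_{i in k} h_i). The pseudocount is
    added to a cluster's count total only when that total is zero, keeping
    the estimate finite without perturbing informative clusters.
    """
    y = np.asarray(counts_r, dtype=float)
    S = design.x.T @ y
    H = design.cluster_exposure
    S = np.where(S == 0, pseudocount, S)
    with np.errstate(divide="ignore"):
        return np.log(S) - np.log(H)


def _mle_matrix(counts: np.ndarray, design: DesignInfo,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Closed-form no-intercept MLEs for all peaks at once (R x K)."""
    S = counts.T @ design.x            # R x K cluster count totals
    H = design.cluster_exposure
    S = np.where(S == 0, pseudocount, S)
    with np.errstate(divide="ignore"):
        return np.log(S) - np.log(H)[None, :]


def estimate_prior_sd(beta_mle: np.ndarray, q: float = DEFAULT_Q,
                      sigma_floor: float = SIGMA_FLOOR) -> PriorEstimate:
    """Quantile-matched empirical prior scale per cluster.

    sigma_k = (1-q) empirical quantile of |beta_mle_.k - rowmean| divided by
    the standard normal (1 - q/2) quantile. Infinite MLEs (possible with a
    zero pseudocount) are ignored; the estimate is floored so the prior
    stays proper on degenerate inputs.
    """
    beta_mle = np.asarray(beta_mle, dtype=float)
    if beta_mle.ndim != 2:
        raise ValueError("beta_mle must be R x K")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    beta_bar = beta_mle.mean(axis=1)
    centered = np.abs(beta_mle - beta_bar[:, None])
    z = norm.ppf(1.0 - q / 2.0)
    sigma = np.empty(beta_mle.shape[1])
    for k in range(beta_mle.shape[1]):
        col = centered[:, k]
        col = col[np.isfinite(col)]
        if len(col) < 2:
            raise ValueError(f"cluster {k}: fewer than 2 finite MLE effects")
        sigma[k] = np.quantile(col, 1.0 - q) / z
    return PriorEstimate(sigma=np.maximum(sigma, sigma_floor), q=q, beta_bar=beta_bar)


# ---------------------------------------------------------------------------
# MAP fitting


def _map_newton(S: np.ndarray, H: np.ndarray, sigma: np.ndarray,
                tol: float = 1e-8, max_iter: int = 100
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Damped Newton on the log-posterior for a batch of peaks.

    S is R x K cluster count totals, H length-K cluster exposures. Returns
    (beta0 (R,), beta (R,K), converged (R,), iterations (R,)). The intercept
    carries no prior; each beta_k has Gaussian precision 1/sigma_k^2.
    """
    R, K = S.shape
    prior_prec = 1.0 / sigma**2
    beta0 = np.log((S.sum(axis=1) + 0.5) / H.sum())
    beta = np.zeros((R, K))
    converged = np.zeros(R, dtype=bool)
    iterations = np.zeros(R, dtype=np.int64)

    def log_post(Ss: np.ndarray, b0: np.ndarray, b: np.ndarray) -> np.ndarray:
        eta = np.clip(b0[:, None] + b, -700, 700)
        lam = H[None, :] * np.exp(eta)
        return (Ss * eta - lam).sum(axis=1) - 0.5 * (b**2 * prior_prec[None, :]).sum(axis=1)

    active = np.arange(R)
    for it in range(1, max_iter + 1):
        b0a, ba = beta0[active], beta[active]
        eta = np.clip(b0a[:, None] + ba, -700, 700)
        lam = H[None, :] * np.exp(eta)
        g0 = (S[active] - lam).sum(axis=1)
        gk = S[active] - lam - ba * prior_prec[None, :]
        grad = np.concatenate([g0[:, None], gk], axis=1)
        done = np.max(np.abs(grad), axis=1) < tol
        converged[active[done]] = True
        iterations[active[done]] = it - 1
        active = active[~done]
        if len(active) == 0:
            break
        lam = lam[~done]
        grad = grad[~done]
        # negative Hessian: [[sum lam, lam^T], [lam, diag(lam + prior_prec)]]
        A = np.zeros((len(active), K + 1, K + 1))
        A[:, 0, 0] = lam.sum(axis=1)
        A[:, 0, 1:] = lam
        A[:, 1:, 0] = lam
        idx = np.arange(K)
        A[:, 1 + idx, 1 + idx] = lam + prior_prec[None, :]
        try:
            step = np.linalg.solve(A, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(a, g, rcond=None)[0] for a, g in zip(A, grad)])
        lp_old = log_post(S[active], beta0[active], beta[active])
        scale = np.ones(len(active))
        for _ in range(40):  # step-halving until the posterior does not decrease
            b0_new = beta0[active] + scale * step[:, 0]
            b_new = beta[active] + scale[:, None] * step[:, 1:]
            lp_new = log_post(S[active], b0_new, b_new)
            bad = lp_new < lp_old - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        beta0[active] = beta0[active] + scale * step[:, 0]
        beta[active] = beta[active] + scale[:, None] * step[:, 1:]
        iterations[active] = it
    return beta0, beta, converged, iterations


def _curvature_factors(beta0: np.ndarray, beta: np.ndarray, H: np.ndarray,
                       sigma: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sherman-Morrison pieces of the posterior covariance at the optimum.

    For negative Hessian A = [[L, lam^T], [lam, D]] with D = diag(lam + 1/sigma^2),
    the inverse has var(beta0) = 1/(L - lam^T D^-1 lam), beta-block
    D^-1 + (D^-1 lam)(D^-1 lam)^T var(beta0). Contrast variances assembled
    from these factors avoid the cancellation of the assembled matrix in the
    diffuse-prior limit.
    """
    eta = np.clip(beta0[:, None] + beta, -700, 700)
    lam = H[None, :] * np.exp(eta)
    prior_prec = 1.0 / sigma**2
    d_inv = 1.0 / (lam + prior_prec[None, :])
    u = d_inv * lam
    # L - lam^T D^-1 lam = sum_k lam_k * prior_prec_k / (lam_k + prior_prec_k)
    denom = (lam * prior_prec[None, :] * d_inv).sum(axis=1)
    cov00 = 1.0 / denom
    return d_inv, u, cov00


def _assemble_cov(d_inv: np.ndarray, u: np.ndarray, cov00: float) -> np.ndarray:
    K = len(d_inv)
    cov = np.empty((K + 1, K + 1))
    cov[0, 0] = cov00
    cov[0, 1:] = -u * cov00
    cov[1:, 0] = -u * cov00
    cov[1:, 1:] = np.diag(d_inv) + np.outer(u, u) * cov00
    return cov


def fit_map(counts_r: np.ndarray, design: DesignInfo, prior: PriorEstimate,
            tol: float = 1e-8, max_iter: int = 100,
            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PeakGlmFit:
    """MAP fit of one peak: Poisson likelihood with offset log h_i, normal
    prior on the cluster effects, flat prior on the intercept."""
    y = np.asarray(counts_r, dtype=float)
    S = (design.x.T @ y)[None, :]
    H = design.cluster_exposure
    beta0, beta, conv, iters = _map_newton(S, H, prior.sigma, tol=tol, max_iter=max_iter)
    d_inv, u, cov00 = _curvature_factors(beta0, beta, H, prior.sigma)
    return PeakGlmFit(
        beta0=float(beta0[0]), beta=beta[0],
        beta_mle=fit_mle_no_intercept(y, design, pseudocount=pseudocount),
        cov=_assemble_cov(d_inv[0], u[0], float(cov00[0])),
        converged=bool(conv[0]), iterations=int(iters[0]),
        _d_inv=d_inv[0], _u=u[0], _cov00=float(cov00[0]),
    )


# ---------------------------------------------------------------------------
# Intersection-union test


def iut_test(fit: PeakGlmFit, target_cluster: int) -> Tuple[np.ndarray, float]:
    """One-sided Wald IUT: is the target cluster's effect above every other?

    Returns the K-1 component z statistics (target minus each other
    cluster, in cluster order) and the IUT p-value, the maximum of the
    component one-sided p-values.
    """
    K = len(fit.beta)
    if K < 2:
        raise ValueError("IUT needs at least 2 clusters")
    if not fit.converged:
        return np.full(K - 1, np.nan), np.nan
    others = [k for k in range(K) if k != target_cluster]
    z = np.empty(K - 1)
    for j, kp in enumerate(others):
        num = fit.beta[target_cluster] - fit.beta[kp]
        se = np.sqrt(max(fit.contrast_var(target_cluster, kp), 0.0))
        if se == 0.0:
            z[j] = np.inf if num > 0 else (-np.inf if num < 0 else 0.0)
        else:
            z[j] = num / se
    p = float(np.max(norm.sf(z)))
    return z, p


# ---------------------------------------------------------------------------
# Full specificity pipeline


@dataclass
class SpecificityResult:
    """Per-peak shrunken effects and per-cluster IUT p-values.

    ``table`` has one row per peak: beta0, beta_<k>, p_<k>, q_<k>
    (Benjamini-Hochberg, informational only), best_cluster (smallest IUT
    p-value), specific_cluster (best cluster if its p-value beats the
    cutoff, else -1), tested flag and reason.
    """

    table: pd.DataFrame
    prior: PriorEstimate
    cutoff: float
    K: int

    def specific_peaks(self, cluster: Optional[int] = None) -> pd.DataFrame:
        df = self.table[self.table["specific_cluster"] >= 0]
        if cluster is not None:
            df = df[df["specific_cluster"] == cluster]
        return df

    def to_bed(self, cluster: int, peaks, path) -> None:
        """Write the cluster's specific peaks as BED with -10*log10(p) scores."""
        df = self.specific_peaks(cluster).merge(
            peaks.df[["chrom", "start", "end", "peak_id"]], on="peak_id"
        )
        p = df[f"p_{cluster}"].to_numpy()
        with np.errstate(divide="ignore"):
            score = np.minimum(-10.0 * np.log10(np.maximum(p, 1e-300)), 1000.0)
        out = df[["chrom", "start", "end", "peak_id"]].copy()
        out["score"] = np.round(score, 2)
        out.to_csv(path, sep="\t", header=False, index=False)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values with NaN passthrough."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    m = ok.sum()
    if m == 0:
        return q
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    q[ok] = vals
    return q


def call_specific_peaks(cm: CountMatrix, design: DesignInfo,
                        cutoff: float = DEFAULT_CUTOFF, q: float = DEFAULT_Q,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        tol: float = 1e-8, max_iter: int = 100,
                        peak_kind: Optional[str] = None) -> SpecificityResult:
    """Test every peak for specificity to each cluster.

    Peaks with zero counts in every cell are excluded (reason "no_signal").
    ``peak_kind`` restricts testing to peaks of that kind ("narrow"/"broad").
    All remaining peaks are fit in one batched Newton pass.
    """
    if design.x.shape[0] != cm.n_cells:
        raise ValueError("design does not match the count matrix")
    K = design.K
    if K < 2:
        raise ValueError("specificity testing needs at least 2 clusters")
    counts = cm.counts
    R = counts.shape[1]
    kinds = cm.peaks.df["kind"].to_numpy()
    tested = counts.sum(axis=0) > 0
    reason = np.where(tested, "", "no_signal")
    if peak_kind is not None:
        kind_ok = kinds == peak_kind
        reason = np.where(tested & ~kind_ok, "kind_filtered", reason)
        tested = tested & kind_ok

    beta_mle = _mle_matrix(counts[:, tested], design, pseudocount=pseudocount)
    prior = estimate_prior_sd(beta_mle, q=q)
    S = counts[:, tested].T @ design.x
    H = design.cluster_exposure
    beta0, beta, conv, iters = _map_newton(S, H, prior.sigma, tol=tol, max_iter=max_iter)
    d_inv, u, cov00 = _curvature_factors(beta0, beta, H, prior.sigma)

    # one-sided Wald p per (peak, target cluster): max over pairwise components
    n_t = tested.sum()
    p_mat = np.full((n_t, K), np.nan)
    for k in range(K):
        worst_p = np.zeros(n_t)
        for kp in range(K):
            if kp == k:
                continue
            num = beta[:, k] - beta[:, kp]
            du = u[:, k] - u[:, kp]
            var = d_inv[:, k] + d_inv[:, kp] + du * du * cov00
            se = np.sqrt(np.maximum(var, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, num / se,
                             np.where(num > 0, np.inf, np.where(num < 0, -np.inf, 0.0)))
            worst_p = np.maximum(worst_p, norm.sf(z))
        p_mat[:, k] = worst_p
    p_mat[~conv] = np.nan

    full = {
        "peak_id": cm.peaks.peak_ids,
        "kind": kinds,
        "tested": tested,
        "reason": reason,
        "converged": np.zeros(R, dtype=bool),
        "beta0": np.full(R, np.nan),
    }
    full["converged"][tested] = conv
    full["beta0"][tested] = beta0
    for k in range(K):
        col = np.full(R, np.nan)
        col[tested] = beta[:, k]
        full[f"beta_{k}"] = col
        colm = np.full(R, np.nan)
        colm[tested] = beta_mle[:, k]
        full[f"beta_mle_{k}"] = colm
        colp = np.full(R, np.nan)
        colp[tested] = p_mat[:, k]
        full[f"p_{k}"] = colp
    for k in range(K):
        full[f"q_{k}"] = _bh(full[f"p_{k}"])
    df = pd.DataFrame(full)
    pcols = df[[f"p_{k}" for k in range(K)]].to_numpy()
    best = _nanargmin_rows(pcols)
    df["best_cluster"] = best
    best_p = np.where(best >= 0, pcols[np.arange(R), np.maximum(best, 0)], np.nan)
    df["p_best"] = best_p
    df["specific_cluster"] = np.where(
        (best >= 0) & (best_p < cutoff), best, -1
    )
    return SpecificityResult(table=df, prior=prior, cutoff=cutoff, K=K)


def _nanargmin_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise nanargmin returning -1 for all-NaN rows."""
    out = np.full(a.shape[0], -1, dtype=np.int64)
    ok = ~np.isnan(a).all(axis=1)
    if ok.any():
        out[ok] = np.nanargmin(a[ok], axis=1)
    return out
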