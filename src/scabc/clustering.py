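"""Depth-weighted K-medoids clustering of rank-transformed peak counts.

Cells are weighted by a logistic transform of their sample depth h_i,

    w_i = 1 / (1 + exp{-(h_i - c) / (c * lambda)}),

so low-coverage cells, whose zero entries are least trustworthy, pull less
on the cluster medoids. Counts are rank-transformed within each cell and
cells are compared by d = 1 - Spearman rank correlation. The weighted
objective

    sum_k sum_{C(i)=k} w_i d(Y_i, Y_{i_k})

is minimized by the Partitioning Around Medoids (PAM) algorithm (BUILD +
SWAP). Each cluster is then summarized by a landmark -- its summed counts
over the P highest-count peaks -- and every cell is re-assigned to the
landmark with the highest Spearman correlation over the union of landmark
peaks. The number of clusters is chosen by a gap statistic whose reference
sets permute each peak's counts independently across cells, preserving
per-peak sparsity while destroying cell structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix_io import CountMatrix

DEFAULT_LAMBDA = 0.1
DEFAULT_LANDMARK_PEAKS = 2000
DEFAULT_RESTARTS = 10
DEFAULT_GAP_B = 50

_TIE_TOL = 0.0  # BUILD gain ties are broken randomly only on exact equality


class ClusteringError(RuntimeError):
    pass


@dataclass
class WeightConfig:
    """Logistic depth-weight parameters: midpoint ``c`` and steepness ``lam``.

    ``c=None`` means "use the median sample depth", the default midpoint.
    ``lam`` is the steepness of the logistic relative to ``c``.
    """

    c: Optional[float] = None
    lam: float = DEFAULT_LAMBDA

    def resolve_c(self, sample_depth: np.ndarray) -> float:
        c = float(np.median(sample_depth)) if self.c is None else float(self.c)
        if c <= 0:
            raise ValueError("weight midpoint c must be > 0")
        if self.lam <= 0:
            raise ValueError("weight steepness lambda must be > 0")
        return c


def compute_weights(sample_depth: np.ndarray, cfg: Optional[WeightConfig] = None) -> np.ndarray:
    """Logistic weights w_i = 1/(1 + exp{-(h_i - c)/(c*lam)}), in (0, 1)."""
    cfg = cfg or WeightConfig()
    h = np.asarray(sample_depth, dtype=float)
    if np.any(h <= 0):
        raise ValueError("sample depths must be positive")
    c = cfg.resolve_c(h)
    # clip the exponent to keep the weight in the open interval (0, 1)
    z = np.clip(-(h - c) / (c * cfg.lam), -700.0, 700.0)
    w = 1.0 / (1.0 + np.exp(z))
    return np.clip(w, np.nextafter(0, 1), np.nextafter(1, 0))


def rank_transform(counts: np.ndarray) -> np.ndarray:
    """Within-cell average ranks of peak counts; each row sums to R(R+1)/2."""
    counts = np.asarray(counts)
    if counts.shape[1] < 2:
        raise ValueError("rank transform needs at least 2 peaks")
    return rankdata(counts, axis=1)


def constant_cells(counts: np.ndarray) -> np.ndarray:
    """Cells whose counts are identical across all peaks (Spearman undefined)."""
    counts = np.asarray(counts)
    return counts.max(axis=1) == counts.min(axis=1)


def spearman_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - tie-corrected Spearman correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("Spearman dissimilarity undefined for a constant vector")
    rho = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (len(x) * sx * sy))
    return 1.0 - rho


def _normalized_ranks(ranks: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm, so R @ R.T is the Spearman matrix."""
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ClusteringError(
            "constant cell encountered in Spearman computation; "
            "filter with constant_cells() first"
        )
    return rc / norms

def spearman_dissimilarity_matrix(ranks: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman over rows of a rank matrix."""
    rn = _normalized_ranks(ranks)
    d = 1.0 - rn @ rn.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)  # guard float error outside [0, 2]


# ---------------------------------------------------------------------------
# PAM


def _pam_build(D: np.ndarray, w: np.ndarray, K: int, rng: np.random.Generator) -> Tuple[np.ndarray, bool]:
    """Weighted greedy BUILD seeding; returns (medoid indices, tie_seen)."""
    n = D.shape[0]
    tie_seen = False
    costs = w @ D  # cost of each point as sole medoid
    cand = np.flatnonzero(costs == costs.min())
    if len(cand) > 1:
        tie_seen = True
    medoids = [int(rng.choice(cand))]
    d_near = D[:, medoids[0]].copy()
    chosen = np.zeros(n, dtype=bool)
    chosen[medoids[0]] = True
    while len(medoids) < K:
        free = np.flatnonzero(~chosen)
        # objective if candidate j is added
        new_costs = w @ np.minimum(d_near[:, None], D[:, free])
        cand = np.flatnonzero(new_costs == new_costs.min())
        if len(cand) > 1:
            tie_seen = True
        j = int(free[rng.choice(cand)])
        medoids.append(j)
        chosen[j] = True
        d_near = np.minimum(d_near, D[:, j])
    return np.asarray(medoids), tie_seen


def _nearest_two(D: np.ndarray, medoids: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    dm = D[:, medoids]  # n x K
    if len(medoids) == 1:
        a1 = np.zeros(D.shape[0], dtype=np.int64)
        return dm[:, 0].copy(), a1, np.full(D.shape[0], np.inf)
    order = np.argsort(dm, axis=1, kind="stable")
    a1 = order[:, 0]
    rows = np.arange(D.shape[0])
    return dm[rows, a1], a1, dm[rows, order[:, 1]]


def _pam_swap(D: np.ndarray, w: np.ndarray, medoids: np.ndarray, max_iter: int = 200
              ) -> Tuple[np.ndarray, float]:
    """SWAP phase: exchange a medoid for a non-medoid while the weighted
    objective strictly decreases."""
    medoids = np.array(medoids, dtype=np.int64)
    n = D.shape[0]
    for _ in range(max_iter):
        d1, a1, d2 = _nearest_two(D, medoids)
        obj = float(w @ d1)
        is_med = np.zeros(n, dtype=bool)
        is_med[medoids] = True
        cand = np.flatnonzero(~is_med)
        if len(cand) == 0:
            return medoids, obj
        best = (0.0, -1, -1)  # (new objective - obj, medoid slot, candidate)
        for slot in range(len(medoids)):
            base = np.where(a1 == slot, d2, d1)
            new_obj = w @ np.minimum(base[:, None], D[:, cand])
            j = int(np.argmin(new_obj))
            delta = float(new_obj[j]) - obj
            if delta < best[0] - 1e-15:
                best = (delta, slot, int(cand[j]))
        if best[1] < 0 or best[0] >= -1e-12 * max(1.0, abs(obj)):
            return medoids, obj
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
    d1, _, _ = _nearest_two(D, medoids)
    return medoids, float(w @ d1)


def _pam(D: np.ndarray, w: np.ndarray, K: int, rng: np.random.Generator,
         n_restarts: int = DEFAULT_RESTARTS) -> Tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts weighted PAM on a precomputed dissimilarity matrix.

    The first restart seeds SWAP with the greedy BUILD solution (random
    tie-breaking when gains tie exactly); the remaining restarts seed with
    random medoid subsets, which lets SWAP escape the occasional BUILD-basin
    local optimum.
    """
    n = D.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} out of range for {n} cells")
    best_obj = np.inf
    best_med: Optional[np.ndarray] = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            seed_med, _ = _pam_build(D, w, K, rng)
        else:
            seed_med = rng.choice(n, size=K, replace=False)
        medoids, obj = _pam_swap(D, w, seed_med)
        if obj < best_obj - 1e-15:
            best_obj, best_med = obj, medoids
    assert best_med is not None
    assignment = np.argmin(D[:, best_med], axis=1)
    # present clusters in order of their medoid index for determinism
    order = np.argsort(best_med, kind="stable")
    relabel = np.empty(len(best_med), dtype=np.int64)
    relabel[order] = np.arange(len(best_med))
    return best_med[order], relabel[assignment], best_obj


@dataclass
class Landmarks:
    """Per-cluster pseudo-bulk profiles over the union of top-P peak sets."""

    matrix: np.ndarray                # K x U summed counts on union peaks
    peak_ids: List[List[str]]         # per-cluster top-P peak ids
    union_cols: np.ndarray            # column indices (into the CountMatrix) of the union
    union_peak_ids: List[str]


@dataclass
class ClusterModel:
    K: int
    weights: np.ndarray               # per retained cell, in (0, 1)
    medoid_cells: List[str]
    kmedoids_assignment: np.ndarray   # initial PAM labels (retained cells)
    assignment: np.ndarray            # final landmark-based labels, -1 = unassigned
    objective: float
    landmarks: Optional[Landmarks] = None
    similarity: Optional[np.ndarray] = None        # cells x K Spearman to landmarks
    norm_similarity: Optional[np.ndarray] = None   # similarity / mean |similarity| per cell
    gap: Optional["GapCurve"] = None
    cells: List[str] = field(default_factory=list)
    excluded_cells: List[str] = field(default_factory=list)


def weighted_kmedoids(rank_matrix: np.ndarray, K: int, weights: np.ndarray,
                      n_restarts: int = DEFAULT_RESTARTS, seed: int = 0) -> ClusterModel:
    """Weighted PAM under 1 - Spearman on a within-cell rank matrix."""
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("weights must lie strictly in (0, 1)")
    D = spearman_dissimilarity_matrix(rank_matrix)
    rng = np.random.default_rng(seed)
    medoids, labels, obj = _pam(D, w, K, rng, n_restarts)
    return ClusterModel(
        K=K, weights=w, medoid_cells=[str(m) for m in medoids],
        kmedoids_assignment=labels, assignment=labels.copy(), objective=obj,
        cells=[str(i) for i in range(rank_matrix.shape[0])],
    )


# ---------------------------------------------------------------------------
# Landmarks


def compute_landmarks(cm: CountMatrix, assignment: np.ndarray,
                      P: int = DEFAULT_LANDMARK_PEAKS) -> Landmarks:
    """Sum counts within each cluster and keep each cluster's top-P peaks.

    Boundary ties in the top-P selection keep the peak earlier in genomic
    order (the PeakSet is sorted by chrom, start), so the selection is
    deterministic. The landmark vectors are the cluster sums restricted to
    the union of all clusters' selected peaks.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    assignment = np.asarray(assignment)
    labels = np.unique(assignment[assignment >= 0])
    counts = cm.counts
    R = counts.shape[1]
    top = min(P, R)
    ids = np.asarray(cm.peaks.peak_ids)
    sums = np.stack([counts[assignment == k].sum(axis=0) for k in labels])
    selected: List[np.ndarray] = []
    for row in sums:
        order = np.lexsort((np.arange(R), -row))  # by count desc, then genomic order
        selected.append(np.sort(order[:top]))
    union = np.unique(np.concatenate(selected))
    return Landmarks(
        matrix=sums[:, union],
        peak_ids=[ids[s].tolist() for s in selected],
        union_cols=union,
        union_peak_ids=ids[union].tolist(),
    )


def assign_to_landmarks(cm: CountMatrix, landmarks: Landmarks
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each cell to the landmark with the highest Spearman correlation.

    Correlations are computed between raw cell counts and the raw landmark
    sums over the union of landmark peaks (rank-transformed internally).
    Returns (assignment, similarity, normalized similarity); cells with no
    counts on the union peaks get assignment -1 and NaN similarities. The
    normalized similarity divides each cell's correlations by the mean of
    their absolute values across landmarks, which sharpens the visual
    contrast between the matching landmark and the rest.
    """
    sub = cm.counts[:, landmarks.union_cols]
    lm = landmarks.matrix
    ok = sub.max(axis=1) > sub.min(axis=1)
    sim = np.full((sub.shape[0], lm.shape[0]), np.nan)
    if ok.any():
        rc = _normalized_ranks(rankdata(sub[ok], axis=1))
        rl = _normalized_ranks(rankdata(lm, axis=1))
        sim[ok] = rc @ rl.T
    assignment = np.full(sub.shape[0], -1, dtype=np.int64)
    norm_sim = np.full_like(sim, np.nan)
    if ok.any():
        assignment[ok] = np.argmax(sim[ok], axis=1)
        denom = np.abs(sim[ok]).mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm_sim[ok] = sim[ok] / denom
    return assignment, sim, norm_sim


# ---------------------------------------------------------------------------
# Gap statistic


@dataclass
class GapCurve:
    """Gap-statistic trace over candidate K and the selected K.

    ``chosen_K`` is None when the curve keeps increasing with no plateau,
    the signature of a continuum rather than discrete clusters.
    """

    table: pd.DataFrame  # columns: K, log_W, ref_log_W_mean, ref_log_W_sd, gap, se
    chosen_K: Optional[int]
    no_plateau: bool = False


def select_K(cm: CountMatrix, weights: np.ndarray, K_range: Sequence[int],
             B: int = DEFAULT_GAP_B, seed: int = 0,
             n_restarts: int = DEFAULT_RESTARTS) -> GapCurve:
    """Choose K by the gap statistic with per-peak permutation references.

    Gap(K) = mean_b log W*_Kb - log W_K, where W is the weighted K-medoids
    objective. Each reference set permutes every peak's counts independently
    across cells, preserving the per-peak count distribution (hence
    sparsity) while destroying any cell grouping. The chosen K is the
    smallest with Gap(K) >= Gap(K+1) - s_{K+1}, s the sd-based standard
    error over the B references.
    """
    if B < 2:
        raise ValueError("B must be >= 2 for an sd estimate")
    Ks = sorted(int(k) for k in K_range)
    if not Ks or Ks[0] < 1 or Ks[-1] >= cm.n_cells:
        raise ValueError("K_range must lie within [1, n_cells)")
    w = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    pam_seed_rng = np.random.default_rng(rng.integers(2**31))

    def objectives(counts: np.ndarray) -> np.ndarray:
        D = spearman_dissimilarity_matrix(rank_transform(counts))
        out = np.empty(len(Ks))
        for j, K in enumerate(Ks):
            _, _, obj = _pam(D, w, K, np.random.default_rng(pam_seed_rng.integers(2**31)),
                             n_restarts)
            out[j] = obj
        return out

    tiny = np.finfo(float).tiny
    log_W = np.log(np.maximum(objectives(cm.counts), tiny))
    ref_logs = np.empty((B, len(Ks)))
    counts = cm.counts
    for b in range(B):
        perm = np.empty_like(counts)
        for r in range(counts.shape[1]):
            perm[:, r] = counts[rng.permutation(counts.shape[0]), r]
        ref_logs[b] = np.log(np.maximum(objectives(perm), tiny))
    ref_mean = ref_logs.mean(axis=0)
    ref_sd = ref_logs.std(axis=0, ddof=1)
    gap = ref_mean - log_W
    se = ref_sd * np.sqrt(1.0 + 1.0 / B)
    chosen: Optional[int] = None
    if len(Ks) == 1:
        chosen = Ks[0]
    else:
        for j in range(len(Ks) - 1):
            if gap[j] >= gap[j + 1] - se[j + 1]:
                chosen = Ks[j]
                break
    table = pd.DataFrame({
        "K": Ks, "log_W": log_W, "ref_log_W_mean": ref_mean,
        "ref_log_W_sd": ref_sd, "gap": gap, "se": se,
    })
    return GapCurve(table=table, chosen_K=chosen, no_plateau=chosen is None)


# ---------------------------------------------------------------------------
# Full clustering pipeline


@dataclass
class ClusterConfig:
    weight: WeightConfig = field(default_factory=WeightConfig)
    landmark_P: int = DEFAULT_LANDMARK_PEAKS
    n_restarts: int = DEFAULT_RESTARTS
    K_range: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8)
    gap_B: int = DEFAULT_GAP_B
    seed: int = 0


def cluster(cm: CountMatrix, K: "int | str" = "auto",
            cfg: Optional[ClusterConfig] = None) -> ClusterModel:
    """Weights -> rank transform -> (gap-statistic K) -> weighted PAM ->
    landmarks -> landmark re-assignment.

    Cells with identical counts across all peaks are excluded up front
    (their Spearman correlation is undefined) and carry label -1 in the
    returned assignment, which is indexed like ``cm.cells``.
    """
    cfg = cfg or ClusterConfig()
    if cm.sample_depth is None:
        raise ValueError("CountMatrix needs sample_depth; run compute_sample_depth/qc first")
    const = constant_cells(cm.counts)
    retained = np.flatnonzero(~const)
    if len(retained) == 0:
        raise ClusteringError("no non-constant cells to cluster")
    sub = cm.subset_cells(retained)
    w = compute_weights(sub.sample_depth, cfg.weight)

    gap: Optional[GapCurve] = None
    if K == "auto":
        ks = [k for k in cfg.K_range if 1 <= k < sub.n_cells]
        gap = select_K(sub, w, ks, B=cfg.gap_B, seed=cfg.seed, n_restarts=cfg.n_restarts)
        if gap.chosen_K is None:
            raise ClusteringError(
                "gap statistic keeps increasing over the candidate range: "
                "no plateau, the data may form a continuum rather than discrete clusters"
            )
        K = gap.chosen_K
    K = int(K)
    if not 1 <= K <= sub.n_cells:
        raise ValueError(f"K={K} out of range for {sub.n_cells} cells")

    ranks = rank_transform(sub.counts)
    D = spearman_dissimilarity_matrix(ranks)
    rng = np.random.default_rng(cfg.seed)
    medoids, km_labels, obj = _pam(D, w, K, rng, cfg.n_restarts)
    lms = compute_landmarks(sub, km_labels, P=cfg.landmark_P)
    lm_assign, sim, norm_sim = assign_to_landmarks(sub, lms)

    assignment = np.full(cm.n_cells, -1, dtype=np.int64)
    assignment[retained] = lm_assign
    km_full = np.full(cm.n_cells, -1, dtype=np.int64)
    km_full[retained] = km_labels
    sim_full = np.full((cm.n_cells, K), np.nan)
    sim_full[retained] = sim
    norm_full = np.full((cm.n_cells, K), np.nan)
    norm_full[retained] = norm_sim
    return ClusterModel(
        K=K, weights=w, medoid_cells=[sub.cells[m] for m in medoids],
        kmedoids_assignment=km_full, assignment=assignment, objective=obj,
        landmarks=lms, similarity=sim_full, norm_similarity=norm_full, gap=gap,
        cells=list(cm.cells), excluded_cells=[cm.cells[i] for i in np.flatnonzero(const)],
    )
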