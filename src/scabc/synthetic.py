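"""Synthetic scATAC-like count matrices with known cluster structure.

The generator mirrors the inferential model: per-cell exposures h_i are
drawn log-normal (sequencing-depth heterogeneity), per-peak rates are a
common base rate multiplied by a fold change on peaks specific to the
cell's own cluster, and counts are Poisson,

    y_ri ~ Poisson(h_i * q_ri),
    q_ri = base_rate * fold_change^[peak r specific to cluster of cell i].

Sparsity arises from low h*q rather than zero inflation. When ``base_rate``
is left unset it is calibrated by quadrature so the expected fraction of
zero entries equals ``sparsity_target``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix_io import CountMatrix, PeakSet

#: default per-cell exposure distribution: log-normal with median 5000
#: distinct background reads and a 10x spread between the 10th and 90th
#: depth percentiles (sd_log = ln(10) / (2 * z_0.90))
DEFAULT_DEPTH_MEAN_LOG = math.log(5000.0)
DEFAULT_DEPTH_SD_LOG = math.log(10.0) / (2 * 1.2815515655446004)


@dataclass
class SimulationSpec:
    """Generating parameters for a clustered sparse count matrix.

    Defaults describe the standard recovery fixture: three equal clusters of
    100 cells, 1800 common peaks, 200 specific peaks per cluster at 4-fold
    elevation, 10x depth spread, and ~85% zero entries.
    """

    n_cells_per_cluster: Tuple[int, ...] = (100, 100, 100)
    n_common_peaks: int = 1800
    n_specific_peaks_per_cluster: int = 200
    base_rate: Optional[float] = None   # None: calibrate to sparsity_target
    fold_change: float = 4.0
    depth_mean_log: float = DEFAULT_DEPTH_MEAN_LOG
    depth_sd_log: float = DEFAULT_DEPTH_SD_LOG
    sparsity_target: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_cells_per_cluster):
            raise ValueError("every cluster needs at least one cell")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1 (1 gives the null regime)")
        if self.base_rate is not None and self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must be in (0, 1)")

    @property
    def K(self) -> int:
        return len(self.n_cells_per_cluster)

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_cluster)

    @property
    def n_peaks(self) -> int:
        return self.n_common_peaks + self.K * self.n_specific_peaks_per_cluster


@dataclass
class SyntheticTruth:
    labels: np.ndarray                    # per-cell true cluster
    specific_peaks: Dict[int, List[str]]  # cluster -> peak ids
    h: np.ndarray                         # per-cell exposure
    rate_matrix: np.ndarray               # R x K true rates q
    spec: SimulationSpec = None


def expected_zero_fraction(spec: SimulationSpec, base_rate: float,
                           n_nodes: int = 201) -> float:
    """Expected fraction of zero entries under the generative model.

    E[e^{-h q}] is integrated over the log-normal exposure by Gauss-Hermite
    quadrature, then averaged over the peak x cluster composition.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    h = np.exp(spec.depth_mean_log + spec.depth_sd_log * nodes)
    wts = weights / weights.sum()
    cell_frac = np.asarray(spec.n_cells_per_cluster) / spec.n_cells

    def p_zero(rate: float) -> float:
        return float(wts @ np.exp(-h * rate))

    R = spec.n_peaks
    f_common = spec.n_common_peaks / R
    f_specific = spec.n_specific_peaks_per_cluster / R
    zf = f_common * p_zero(base_rate)
    for k in range(spec.K):
        own = cell_frac[k]
        zf += f_specific * (own * p_zero(base_rate * spec.fold_change)
                            + (1 - own) * p_zero(base_rate))
    return zf


def calibrate_base_rate(spec: SimulationSpec) -> float:
    """Solve for the base rate matching the spec's expected zero fraction."""
    lo, hi = -30.0, 5.0  # log-rate bracket
    f = lambda lr: expected_zero_fraction(spec, math.exp(lr)) - spec.sparsity_target
    return math.exp(brentq(f, lo, hi, xtol=1e-12))


def _synthetic_peaks(spec: SimulationSpec) -> Tuple[PeakSet, Dict[int, List[str]]]:
    """Placeholder genomic coordinates so BED/MTX round-trips work."""
    R = spec.n_peaks
    width, gap = 500, 1500
    starts = np.arange(R) * (width + gap)
    ids = [f"peak_{i:05d}" for i in range(R)]
    df = pd.DataFrame({
        "chrom": "chrS", "start": starts, "end": starts + width,
        "peak_id": ids, "kind": "narrow",
    })
    specific: Dict[int, List[str]] = {}
    for k in range(spec.K):
        lo = spec.n_common_peaks + k * spec.n_specific_peaks_per_cluster
        hi = lo + spec.n_specific_peaks_per_cluster
        specific[k] = ids[lo:hi]
    return PeakSet(df), specific


def simulate(spec: SimulationSpec) -> Tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix and its generating truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    base = spec.base_rate if spec.base_rate is not None else calibrate_base_rate(spec)
    peaks, specific = _synthetic_peaks(spec)
    R, K = spec.n_peaks, spec.K

    rate = np.full((R, K), base)
    for k in range(K):
        lo = spec.n_common_peaks + k * spec.n_specific_peaks_per_cluster
        rate[lo:lo + spec.n_specific_peaks_per_cluster, k] = base * spec.fold_change

    labels = np.repeat(np.arange(K), spec.n_cells_per_cluster)
    h = rng.lognormal(spec.depth_mean_log, spec.depth_sd_log, size=spec.n_cells)
    mu = h[:, None] * rate[:, labels].T
    if float(np.exp(-mu).mean()) > 0.999:
        warnings.warn("expected zero fraction exceeds 99.9%: degenerate regime")
    counts = rng.poisson(mu)
    cells = [f"cell_{i:04d}" for i in range(spec.n_cells)]
    cm = CountMatrix(cells=cells, peaks=peaks, counts=counts, sample_depth=h)
    truth = SyntheticTruth(labels=labels, specific_peaks=specific, h=h,
                           rate_matrix=rate, spec=spec)
    return cm, truth


def default_recovery_fixture(seed: int = 0) -> Tuple[CountMatrix, SyntheticTruth]:
    """The standard 3-cluster recovery benchmark (300 cells, 2400 peaks)."""
    return simulate(SimulationSpec(seed=seed))
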