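import numpy as np
import pandas as pd
import pytest

from scabc import CountMatrix, PeakSet, default_recovery_fixture


def make_peaks(intervals, kind="unknown"):
    """Build a PeakSet from (chrom, start, end) tuples."""
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["peak_id"] = [f"p{i}" for i in range(len(df))]
    df["kind"] = kind
    return PeakSet(df)


def make_matrix(counts, depths=None, kind="unknown"):
    """CountMatrix with placeholder peak coordinates."""
    counts = np.asarray(counts)
    n, r = counts.shape
    peaks = make_peaks([("chr1", i * 1000, i * 1000 + 500) for i in range(r)], kind=kind)
    cells = [f"c{i}" for i in range(n)]
    if depths is None:
        depths = np.maximum(counts.sum(axis=1), 1).astype(float)
    return CountMatrix(cells=cells, peaks=peaks, counts=counts,
                       sample_depth=np.asarray(depths, dtype=float))


@pytest.fixture(scope="session")
def recovery_fixture():
    """The default 3-cluster synthetic benchmark (seed 1), shared per session."""
    return default_recovery_fixture(seed=1)


@pytest.fixture(scope="session")
def separable_matrix():
    """Two rank-separable groups of 15 cells each: clean clustering ground truth."""
    rng = np.random.default_rng(11)
    base_a = np.array([50, 40, 30, 5, 4, 3, 2, 1, 1, 1] * 3, dtype=float)
    base_b = base_a[::-1].copy()
    rows = [rng.poisson(base_a * 4) for _ in range(15)]
    rows += [rng.poisson(base_b * 4) for _ in range(15)]
    counts = np.array(rows)
    counts[:, 0] += 1  # no all-zero cells
    depths = rng.lognormal(6, 0.5, len(rows))
    labels = np.array([0] * 15 + [1] * 15)
    return make_matrix(counts, depths), labels
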