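"""Peak sets, per-cell read counting, sample depth, QC and matrix round-trips.

Coordinates are 0-based half-open (BED convention) throughout; a read
overlaps a peak iff their intervals have a non-empty intersection. "Distinct
reads" means deduplication on (chrom, start, end, strand); fragments from a
fragments-style file carry no strand and are treated as single intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

PEAK_KINDS = ("narrow", "broad", "unknown")

#: default half-width (bp) added to each peak when building the background
#: region used to measure per-cell sample depth
DEFAULT_BACKGROUND_FLANK = 250_000

#: default minimum number of distinct background reads for a cell to pass QC
DEFAULT_MIN_DEPTH = 500


class PeakParseError(ValueError):
    """A peak file line could not be parsed; carries the 1-based line number."""


class MatrixFormatError(ValueError):
    """Label/matrix dimension mismatch or malformed matrix input."""


@dataclass
class PeakSet:
    """Sorted genomic intervals defining the columns of a count matrix.

    ``df`` has columns ``chrom, start, end, peak_id, kind`` and is sorted by
    (chrom, start, end); ``overlaps_neighbor`` flags peaks that intersect
    another peak in the set (permitted, but flagged).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = ["chrom", "start", "end", "peak_id"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"PeakSet frame missing column {col!r}")
        if "kind" not in df.columns:
            df["kind"] = "unknown"
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"peak {df.loc[bad, 'peak_id']!r} has start >= end")
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak_id {dup!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        df["overlaps_neighbor"] = _flag_overlaps(df)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peak_ids(self) -> List[str]:
        return self.df["peak_id"].tolist()

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.df.loc[mask, ["chrom", "start", "end", "peak_id", "kind"]])

    def to_bed(self, path: Union[str, Path]) -> None:
        self.df[["chrom", "start", "end", "peak_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def trees(self) -> Dict[str, IntervalTree]:
        """Per-chromosome interval trees mapping intervals to row indices."""
        trees: Dict[str, IntervalTree] = {}
        for idx, row in enumerate(self.df.itertuples(index=False)):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, idx)
        return trees


def _flag_overlaps(df: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(df), dtype=bool)
    for _, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = grp.index.to_numpy()
        # sorted by start: peak i overlaps a later peak j iff start_j < end_i
        running_end = np.maximum.accumulate(ends)
        for j in range(1, len(idx)):
            if starts[j] < running_end[j - 1]:
                flags[idx[j]] = True
                # flag the earlier partner(s) too
                k = j - 1
                while k >= 0 and ends[k] > starts[j]:
                    flags[idx[k]] = True
                    k -= 1
    return flags


@dataclass
class QcReport:
    """Per-cell QC table: distinct reads in peaks / background, pass flag, reason."""

    df: pd.DataFrame  # columns: cell_id, in_peak_reads, background_reads, passed, reason

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Cells x peaks non-negative integer counts plus per-cell sample depth.

    ``sample_depth`` holds h_i, the number of distinct reads in peak
    backgrounds — the exposure used both for cell weighting in clustering and
    as the Poisson offset in the specificity model. It may be ``None`` while
    the matrix is under construction; all downstream analysis requires it.
    """

    cells: List[str]
    peaks: PeakSet
    counts: np.ndarray
    sample_depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x peaks array")
        if self.counts.shape != (len(self.cells), len(self.peaks)):
            raise MatrixFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.peaks)} peaks"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if self.sample_depth is not None:
            self.sample_depth = np.asarray(self.sample_depth, dtype=float)
            if self.sample_depth.shape != (len(self.cells),):
                raise MatrixFormatError("sample_depth length does not match cells")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            cells=[self.cells[i] for i in keep],
            peaks=self.peaks,
            counts=self.counts[keep],
            sample_depth=None if self.sample_depth is None else self.sample_depth[keep],
        )

    def subset_peaks(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return CountMatrix(
            cells=list(self.cells),
            peaks=self.peaks.subset(self.peaks.df.index.isin(cols)),
            counts=self.counts[:, cols],
            sample_depth=self.sample_depth,
        )


# ---------------------------------------------------------------------------
# Peak reading


def read_peaks(path: Union[str, Path], format: str = "bed") -> PeakSet:
    """Read a BED3+ or MACS2 narrowPeak file into a sorted, deduplicated PeakSet.

    Records identical in (chrom, start, end) are collapsed to one peak.
    ``kind`` is set to "narrow" for narrowPeak input and "unknown" for BED.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    kind = "narrow" if format == "narrowPeak" else "unknown"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise PeakParseError(f"line {lineno}: expected >=3 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PeakParseError(f"line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise PeakParseError(f"line {lineno}: end <= start ({start}, {end})")
            name = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") else None
            rows.append((chrom, start, end, name))
    if not rows:
        raise PeakParseError("peak file contains no records")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    df = df.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
    missing = df["peak_id"].isna() | df["peak_id"].duplicated(keep="first")
    fallback = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    df.loc[missing, "peak_id"] = fallback[missing]
    if df["peak_id"].duplicated().any():
        df["peak_id"] = fallback
    df["kind"] = kind
    return PeakSet(df[["chrom", "start", "end", "peak_id", "kind"]])


# ---------------------------------------------------------------------------
# Read sources

Read = Tuple[str, int, int, str]  # chrom, start, end, strand ('.' if unknown)
ReadSource = Union[str, Path, Mapping[str, Union[str, Path, Sequence[Read]]]]


def _load_reads(source: ReadSource) -> Dict[str, List[Read]]:
    """Normalize a read source into {cell_id: [(chrom, start, end, strand), ...]}.

    Accepted sources: a fragments-style TSV path (chrom, start, end,
    cell_id[, count]); a mapping cell_id -> BAM path; or a mapping
    cell_id -> in-memory read tuples (used heavily by the test-suite).
    """
    if isinstance(source, (str, Path)):
        return _load_fragments(Path(source))
    cells: Dict[str, List[Read]] = {}
    for cell_id, payload in source.items():
        if isinstance(payload, (str, Path)):
            cells[cell_id] = _load_bam(Path(payload))
        else:
            norm: List[Read] = []
            for r in payload:
                strand = str(r[3]) if len(r) > 3 and r[3] is not None else "."
                norm.append((str(r[0]), int(r[1]), int(r[2]), strand))
            cells[cell_id] = norm
    return cells


def _load_fragments(path: Path) -> Dict[str, List[Read]]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "cell_id"],
        dtype={"chrom": str, "cell_id": str},
    )
    if df["start"].isna().any() or df["end"].isna().any():
        raise MatrixFormatError(f"fragments file {path} has missing coordinates")
    cells: Dict[str, List[Read]] = {}
    for row in df.itertuples(index=False):
        cells.setdefault(row.cell_id, []).append((row.chrom, int(row.start), int(row.end), "."))
    return cells


def _load_bam(path: Path) -> List[Read]:
    import pysam

    reads: List[Read] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            end = aln.reference_end
            if end is None:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append((aln.reference_name, aln.reference_start, end, strand))
    return reads


def _dedup(reads: Iterable[Read]) -> List[Read]:
    return sorted(set(reads))


# ---------------------------------------------------------------------------
# Counting


def count_reads_in_peaks(
    reads: ReadSource,
    peaks: PeakSet,
    dedup: bool = True,
    skip_chroms: Sequence[str] = (),
) -> CountMatrix:
    """Count (distinct) reads of each cell overlapping each peak.

    A read overlapping several peaks increments each of them. Reads on
    chromosomes absent from the peak set are skipped with a warning (once per
    chromosome). The returned matrix has no sample depths yet; see
    :func:`compute_sample_depth`.
    """
    cell_reads = _load_reads(reads)
    trees = peaks.trees()
    known_chroms = set(trees)
    skip = set(skip_chroms)
    warned: set = set()
    cell_ids = list(cell_reads)
    counts = np.zeros((len(cell_ids), len(peaks)), dtype=np.int64)
    for i, cell_id in enumerate(cell_ids):
        rds = _dedup(cell_reads[cell_id]) if dedup else list(cell_reads[cell_id])
        for chrom, start, end, _ in rds:
            if chrom in skip:
                continue
            tree = trees.get(chrom)
            if tree is None:
                if chrom not in warned:
                    warnings.warn(f"chromosome {chrom!r} not present in peak set; skipping reads")
                    warned.add(chrom)
                continue
            for iv in tree.overlap(start, end):
                counts[i, iv.data] += 1
    return CountMatrix(cells=cell_ids, peaks=peaks, counts=counts)


def background_intervals(peaks: PeakSet, flank: int) -> Dict[str, np.ndarray]:
    """Union of peaks extended by ``flank`` bp on both sides, merged per chrom.

    Returns {chrom: array of shape (n, 2)} of disjoint sorted [start, end)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: Dict[str, np.ndarray] = {}
    for chrom, grp in peaks.df.groupby("chrom", sort=True):
        starts = np.maximum(grp["start"].to_numpy() - flank, 0)
        ends = grp["end"].to_numpy() + flank
        order = np.argsort(starts, kind="mergesort")
        merged: List[List[int]] = []
        for s, e in zip(starts[order], ends[order]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([int(s), int(e)])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def compute_sample_depth(
    reads: ReadSource,
    peaks: PeakSet,
    flank: int = DEFAULT_BACKGROUND_FLANK,
) -> pd.Series:
    """Per-cell sample depth h_i: distinct reads overlapping the peak background.

    The background is the union of all peaks extended by ``flank`` bp per
    side, merged. Returned as a Series indexed by cell_id.
    """
    cell_reads = _load_reads(reads)
    bg = background_intervals(peaks, flank)
    depths = {}
    for cell_id, rds in cell_reads.items():
        n = 0
        for chrom, start, end, _ in _dedup(rds):
            ivs = bg.get(chrom)
            if ivs is None:
                continue
            # disjoint sorted intervals: find first with interval_end > start
            j = int(np.searchsorted(ivs[:, 1], start, side="right"))
            if j < len(ivs) and ivs[j, 0] < end:
                n += 1
        depths[cell_id] = n
    return pd.Series(depths, name="sample_depth", dtype=float)


def attach_sample_depth(cm: CountMatrix, depths: pd.Series) -> CountMatrix:
    """Return a copy of ``cm`` with sample depths aligned to its cells."""
    missing = [c for c in cm.cells if c not in depths.index]
    if missing:
        raise MatrixFormatError(f"no sample depth for cells: {missing[:5]}")
    return CountMatrix(
        cells=list(cm.cells),
        peaks=cm.peaks,
        counts=cm.counts,
        sample_depth=depths.loc[cm.cells].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# QC


def qc_filter(cm: CountMatrix, min_depth: int = DEFAULT_MIN_DEPTH) -> Tuple[CountMatrix, QcReport]:
    """Drop cells whose sample depth is below ``min_depth``.

    Cells with zero sample depth always fail (the Poisson exposure must be
    positive). Raises if no cell survives.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if cm.sample_depth is None:
        raise ValueError("CountMatrix has no sample_depth; run compute_sample_depth first")
    in_peak = cm.counts.sum(axis=1)
    depth = cm.sample_depth
    passed = depth >= min_depth
    reasons = np.where(passed, "", f"sample_depth < {min_depth}")
    report = QcReport(
        pd.DataFrame(
            {
                "cell_id": cm.cells,
                "in_peak_reads": in_peak,
                "background_reads": depth,
                "passed": passed,
                "reason": reasons,
            }
        )
    )
    if not passed.any():
        raise ValueError("all cells removed by QC filter")
    return cm.subset_cells(passed), report


# ---------------------------------------------------------------------------
# Matrix round-trips


def write_matrix(cm: CountMatrix, outdir: Union[str, Path], format: str = "mtx_triplet") -> None:
    """Write a CountMatrix to a directory.

    ``mtx_triplet``: counts.mtx (cells x peaks, MatrixMarket integer) plus
    cells.tsv, peaks.tsv, depths.tsv sidecars. ``tsv``: counts.tsv dense with
    peak ids as header and cell ids as first column, same sidecars for peaks
    and depths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "mtx_triplet":
        mmwrite(str(outdir / "counts.mtx"), coo_matrix(cm.counts), field="integer")
        pd.Series(cm.cells, name="cell_id").to_csv(
            outdir / "cells.tsv", sep="\t", index=False
        )
    elif format == "tsv":
        pd.DataFrame(cm.counts, index=pd.Index(cm.cells, name="cell_id"),
                     columns=cm.peaks.peak_ids).to_csv(outdir / "counts.tsv", sep="\t")
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    cm.peaks.df[["chrom", "start", "end", "peak_id", "kind"]].to_csv(
        outdir / "peaks.tsv", sep="\t", index=False
    )
    if cm.sample_depth is not None:
        pd.DataFrame({"cell_id": cm.cells, "sample_depth": cm.sample_depth}).to_csv(
            outdir / "depths.tsv", sep="\t", index=False
        )


def read_matrix(indir: Union[str, Path], format: str = "mtx_triplet") -> CountMatrix:
    """Inverse of :func:`write_matrix`; round-trip is lossless."""
    indir = Path(indir)
    peaks_df = pd.read_csv(indir / "peaks.tsv", sep="\t", dtype={"chrom": str, "peak_id": str})
    peaks = PeakSet(peaks_df[["chrom", "start", "end", "peak_id", "kind"]])
    if format == "mtx_triplet":
        counts = np.asarray(mmread(str(indir / "counts.mtx")).todense())
        cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype=str)["cell_id"].tolist()
        if counts.shape[0] != len(cells):
            raise MatrixFormatError(
                f"counts.mtx has {counts.shape[0]} rows but cells.tsv lists {len(cells)} cells"
            )
        if counts.shape[1] != len(peaks):
            raise MatrixFormatError(
                f"counts.mtx has {counts.shape[1]} columns but peaks.tsv lists {len(peaks)} peaks"
            )
    elif format == "tsv":
        dense = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        cells = [str(c) for c in dense.index]
        if list(dense.columns) != peaks.peak_ids:
            raise MatrixFormatError("counts.tsv header does not match peaks.tsv peak ids")
        counts = dense.to_numpy()
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    depth_path = indir / "depths.tsv"
    sample_depth = None
    if depth_path.exists():
        ddf = pd.read_csv(depth_path, sep="\t", dtype={"cell_id": str})
        dmap = dict(zip(ddf["cell_id"], ddf["sample_depth"]))
        try:
            sample_depth = np.array([dmap[c] for c in cells], dtype=float)
        except KeyError as exc:
            raise MatrixFormatError(f"depths.tsv missing cell {exc.args[0]!r}") from exc
    return CountMatrix(cells=cells, peaks=peaks, counts=counts.astype(np.int64),
                       sample_depth=sample_depth)
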