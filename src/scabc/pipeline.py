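"""End-to-end run orchestration: count -> QC -> cluster -> specific peaks.

Every run writes its resolved configuration (with default/user provenance),
a JSON manifest with input checksums, and TSV outputs. Identical inputs and
configuration produce byte-identical outputs; nothing is read that is not
declared in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterConfig,
    ClusterModel,
    WeightConfig,
    cluster,
)
from .matrix_io import (
    CountMatrix,
    DEFAULT_BACKGROUND_FLANK,
    DEFAULT_MIN_DEPTH,
    attach_sample_depth,
    compute_sample_depth,
    count_reads_in_peaks,
    qc_filter,
    read_matrix,
    read_peaks,
    write_matrix,
)
from .specificity import DEFAULT_CUTOFF, DEFAULT_Q, DesignInfo, call_specific_peaks


@dataclass
class RunConfig:
    """All pipeline tunables, with provenance tracked per field.

    ``provenance`` maps field name -> "default" or "user"; it is serialized
    into every output directory so a run can be audited and reproduced.
    """

    # inputs (exactly one of matrix_dir or (peaks_path + reads))
    matrix_dir: Optional[str] = None
    peaks_path: Optional[str] = None
    peaks_format: str = "bed"
    fragments_path: Optional[str] = None
    bam_dir: Optional[str] = None
    # counting / QC
    flank: int = DEFAULT_BACKGROUND_FLANK
    min_depth: int = DEFAULT_MIN_DEPTH
    # clustering
    K: Union[int, str] = "auto"
    K_range: Sequence[int] = tuple(range(1, 9))
    weight_c: Optional[float] = None
    weight_lambda: float = 0.1
    landmark_P: int = 2000
    n_restarts: int = 10
    gap_B: int = 50
    # specificity
    cutoff: float = DEFAULT_CUTOFF
    q: float = DEFAULT_Q
    peak_kind: Optional[str] = None
    # misc
    seed: int = 0
    provenance: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_options(cls, **options) -> "RunConfig":
        """Build a config from possibly-None CLI options, recording provenance."""
        cfg = cls()
        prov = {}
        for f in dataclasses.fields(cls):
            if f.name == "provenance":
                continue
            val = options.get(f.name)
            if val is not None:
                setattr(cfg, f.name, val)
                prov[f.name] = "user"
            else:
                prov[f.name] = "default"
        cfg.provenance = prov
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["K_range"] = list(self.K_range)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_checksums(config: RunConfig) -> Dict[str, str]:
    sums: Dict[str, str] = {}
    candidates: List[Path] = []
    if config.matrix_dir:
        candidates += sorted(Path(config.matrix_dir).glob("*"))
    for p in (config.peaks_path, config.fragments_path):
        if p:
            candidates.append(Path(p))
    if config.bam_dir:
        candidates += sorted(Path(config.bam_dir).glob("*.bam"))
    for p in candidates:
        if p.is_file():
            sums[str(p)] = _sha256(p)
    return sums


def load_inputs(config: RunConfig) -> CountMatrix:
    """Resolve the configured input source into a CountMatrix with depths."""
    if config.matrix_dir:
        fmt = "mtx_triplet" if (Path(config.matrix_dir) / "counts.mtx").exists() else "tsv"
        cm = read_matrix(config.matrix_dir, format=fmt)
        if cm.sample_depth is None:
            raise ValueError(
                "matrix input lacks depths.tsv; provide per-cell sample depths "
                "(--matrix directory must contain depths.tsv)"
            )
        return cm
    if not config.peaks_path:
        raise ValueError("either --matrix or --peaks plus reads must be given")
    peaks = read_peaks(config.peaks_path, format=config.peaks_format)
    if config.fragments_path:
        source: Union[str, Dict[str, str]] = config.fragments_path
    elif config.bam_dir:
        source = {p.stem: str(p) for p in sorted(Path(config.bam_dir).glob("*.bam"))}
        if not source:
            raise ValueError(f"no BAM files found in {config.bam_dir}")
    else:
        raise ValueError("reads required: provide --fragments or --bam-dir")
    cm = count_reads_in_peaks(source, peaks)
    depths = compute_sample_depth(source, peaks, flank=config.flank)
    return attach_sample_depth(cm, depths)


def write_cluster_outputs(model: ClusterModel, outdir: Path) -> List[str]:
    written = []
    best_rho = np.full(len(model.cells), np.nan)
    if model.similarity is not None:
        ok = model.assignment >= 0
        best_rho[ok] = model.similarity[ok, model.assignment[ok]]
    assign = pd.DataFrame({
        "cell_id": model.cells,
        "cluster": pd.array([a + 1 if a >= 0 else pd.NA for a in model.assignment],
                            dtype="Int64"),
        "landmark_rho": np.round(best_rho, 10),
    })
    assign.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    written.append("assignments.tsv")
    if model.landmarks is not None:
        lm = pd.DataFrame(model.landmarks.matrix.T,
                          index=pd.Index(model.landmarks.union_peak_ids, name="peak_id"),
                          columns=[f"landmark_{k+1}" for k in range(model.K)])
        lm.to_csv(outdir / "landmarks.tsv", sep="\t")
        written.append("landmarks.tsv")
    if model.norm_similarity is not None:
        ns = pd.DataFrame(np.round(model.norm_similarity, 10),
                          index=pd.Index(model.cells, name="cell_id"),
                          columns=[f"landmark_{k+1}" for k in range(model.K)])
        ns.to_csv(outdir / "normalized_similarity.tsv", sep="\t")
        written.append("normalized_similarity.tsv")
    if model.gap is not None:
        model.gap.table.to_csv(outdir / "gap_curve.tsv", sep="\t", index=False)
        written.append("gap_curve.tsv")
    return written


def run_pipeline(config: RunConfig, outdir: Union[str, Path]) -> Path:
    """Execute the full pipeline into ``outdir``; returns the output path.

    On stage failure, partial outputs are kept and a FAILED marker naming
    the stage and error is written before the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    stage = "load"
    try:
        cm = load_inputs(config)
        stage = "qc"
        cm, qc = qc_filter(cm, min_depth=config.min_depth)
        qc.to_tsv(outdir / "qc_report.tsv")
        stage = "cluster"
        ccfg = ClusterConfig(
            weight=WeightConfig(c=config.weight_c, lam=config.weight_lambda),
            landmark_P=config.landmark_P, n_restarts=config.n_restarts,
            K_range=config.K_range, gap_B=config.gap_B, seed=config.seed,
        )
        model = cluster(cm, K=config.K, cfg=ccfg)
        written = ["config.yaml", "qc_report.tsv"] + write_cluster_outputs(model, outdir)
        stage = "specific-peaks"
        if model.K >= 2:
            assigned = model.assignment >= 0
            design = DesignInfo.from_labels(model.assignment[assigned],
                                            cm.sample_depth[assigned])
            res = call_specific_peaks(
                cm.subset_cells(assigned), design,
                cutoff=config.cutoff, q=config.q, peak_kind=config.peak_kind,
            )
            res.table.to_csv(outdir / "specific_peaks.tsv", sep="\t", index=False)
            written.append("specific_peaks.tsv")
            for k in range(model.K):
                bed = outdir / f"specific_peaks_cluster{k+1}.bed"
                res.to_bed(k, cm.peaks, bed)
                written.append(bed.name)
        stage = "manifest"
        manifest = {
            "package": "scabc",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "inputs": _input_checksums(config),
            "outputs": sorted(written),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return outdir
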