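"""End-to-end screening pipeline: metrics -> classification -> partition.

The stages are deliberately separable: ``compute_metrics`` produces the
per-contig table once (the expensive part: PAF aggregation and depth), and
``reclassify`` re-runs only the thresholding on a cached table, supporting
the two-round workflow where cutoffs are refined after inspecting the
ALCR/SDR scatter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

from . import classify as _classify
from . import depth as _depth
from . import io as _io
from .classify import Category, Classification, Cutoffs
from .core import (
    AlignmentBlock,
    ContigMetrics,
    RefClass,
    compute_alcr,
    compute_sdr,
    group_blocks,
    longest_alignment,
    union_aligned_length,
)
from .errors import ContractError, DepthReferenceError

SCATTER_COLUMNS = ["contig_id", "mito_ALCR", "mito_SDR", "chlo_ALCR", "chlo_SDR", "category"]


def compute_metrics(
    contigs: Sequence[_io.SeqRecord],
    blocks: Sequence[AlignmentBlock],
    contig_depths: dict[str, float],
    organelle_summary: _depth.OrganelleDepthSummary,
    alcr_mode: str = "union",
) -> list[ContigMetrics]:
    """Assemble per-contig ALCR/SDR metrics, in input contig order.

    A class absent from ``organelle_summary`` (no reference supplied) gets
    SDR 0, which can never clear a strict positive cutoff.
    """
    grouped = group_blocks(blocks)
    out: list[ContigMetrics] = []
    for rec in contigs:
        length = len(rec.seq)
        per_class = grouped.get(rec.id, {})
        union = {}
        longest = {}
        alcr = {}
        for rc in (RefClass.MITO, RefClass.CHLO):
            cls_blocks = per_class.get(rc, [])
            union[rc] = union_aligned_length(cls_blocks)
            longest[rc] = longest_alignment(cls_blocks)
            alcr[rc] = compute_alcr(length, cls_blocks, mode=alcr_mode)
        mean_depth = contig_depths.get(rec.id, 0.0)
        sdr = {}
        for rc in (RefClass.MITO, RefClass.CHLO):
            avg = organelle_summary.per_class.get(rc)
            sdr[rc] = compute_sdr(mean_depth, avg) if avg is not None else 0.0
        out.append(
            ContigMetrics(
                contig_id=rec.id,
                contig_length=length,
                union_len=union,
                longest=longest,
                alcr=alcr,
                mean_depth=mean_depth,
                sdr=sdr,
            )
        )
    return out


def metrics_stage(
    assembly: str | Path,
    paf: str | Path,
    mito_ref: str | Path | None = None,
    chlo_ref: str | Path | None = None,
    sam: str | Path | None = None,
    depth_table: str | Path | None = None,
    alcr_mode: str = "union",
    primary_only: bool = False,
) -> tuple[list[_io.SeqRecord], list[ContigMetrics], _depth.OrganelleDepthSummary]:
    """The expensive half of a run: read inputs and compute the metrics."""
    if mito_ref is None and chlo_ref is None:
        raise ContractError("at least one organelle reference FASTA is required")
    contigs = _io.read_fasta(assembly)
    db = _io.OrganelleDB.from_fastas(mito_ref, chlo_ref)
    blocks = _io.read_paf(paf, db, primary_only=primary_only)
    contig_depths, summary = _depth_evidence(sam, depth_table, contigs, db)
    metrics = compute_metrics(contigs, blocks, contig_depths, summary, alcr_mode)
    return contigs, metrics, summary


@dataclass
class RunResult:
    metrics: list[ContigMetrics]
    classifications: list[Classification]
    clean: list[_io.SeqRecord]
    organelle: list[_io.SeqRecord]
    outputs: dict[str, Path] = field(default_factory=dict)


def _depth_evidence(
    sam_path: str | Path | None,
    table_path: str | Path | None,
    contigs: Sequence[_io.SeqRecord],
    db: _io.OrganelleDB,
) -> tuple[dict[str, float], _depth.OrganelleDepthSummary]:
    """Contig mean depths and organelle class averages from SAM or TSV."""
    if (sam_path is None) == (table_path is None):
        raise ContractError("exactly one of SAM or depth-table evidence is required")
    if sam_path is not None:
        targets = list(contigs) + db.records
        profiles = _depth.depth_from_sam(sam_path, targets)
    else:
        profiles = _depth.depth_from_table(table_path)
    by_id = {p.seq_id: p for p in profiles}
    contig_depths = {
        rec.id: by_id[rec.id].mean if rec.id in by_id else 0.0 for rec in contigs
    }
    ref_profiles = [by_id[r.id] for r in db.records if r.id in by_id]
    if len(ref_profiles) < len(db.records):
        missing = [r.id for r in db.records if r.id not in by_id]
        raise ContractError(
            f"no depth evidence for organelle reference(s) {missing}"
        )
    summary = _depth.summarize_organelle_depth(ref_profiles, db.class_of)
    for rc, avg in summary.per_class.items():
        if not avg > 0:
            raise DepthReferenceError(
                f"average depth of the {rc.value} reference is {avg}; "
                "no reads support the organelle depth denominator"
            )
    return contig_depths, summary


def run_pipeline(
    assembly: str | Path,
    paf: str | Path,
    outdir: str | Path,
    mito_ref: str | Path | None = None,
    chlo_ref: str | Path | None = None,
    sam: str | Path | None = None,
    depth_table: str | Path | None = None,
    cutoffs: Cutoffs = Cutoffs(),
    alcr_mode: str = "union",
    primary_only: bool = False,
    quarantine_flagged: bool = False,
    baseline_min_len: int = 5000,
    seed: int | None = None,
) -> RunResult:
    """Full run: read inputs, compute metrics, classify, partition, write.

    Outputs in ``outdir``: ``metrics.tsv`` (metrics + category + rules),
    ``scatter.tsv`` (the plot's data), ``clean.fasta``, non-empty
    ``organelle_mito.fasta``/``organelle_chlo.fasta`` bins,
    ``baseline_comparison.tsv`` and a ``manifest.json`` recording versions,
    cutoffs and the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, metrics, summary = metrics_stage(
        assembly, paf, mito_ref, chlo_ref, sam, depth_table, alcr_mode, primary_only
    )
    result = _classify_and_write(
        contigs, metrics, cutoffs, outdir, quarantine_flagged, baseline_min_len
    )
    manifest = {
        "organsweep_version": _pkg_version("organsweep"),
        "inputs": {
            "assembly": str(assembly),
            "mito_ref": str(mito_ref) if mito_ref else None,
            "chlo_ref": str(chlo_ref) if chlo_ref else None,
            "paf": str(paf),
            "sam": str(sam) if sam else None,
            "depth_table": str(depth_table) if depth_table else None,
        },
        "cutoffs": cutoffs.__dict__,
        "alcr_mode": alcr_mode,
        "primary_only": primary_only,
        "quarantine_flagged": quarantine_flagged,
        "seed": seed,
        "organelle_reference_depth": {
            rc.value: summary.per_class[rc] for rc in sorted(summary.per_class)
        },
        "n_contigs": len(contigs),
        "n_clean": len(result.clean),
        "n_organelle": len(result.organelle),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    result.outputs["manifest"] = manifest_path
    return result


def _classify_and_write(
    contigs: Sequence[_io.SeqRecord] | None,
    metrics: Sequence[ContigMetrics],
    cutoffs: Cutoffs,
    outdir: Path,
    quarantine_flagged: bool,
    baseline_min_len: int,
) -> RunResult:
    classifications = _classify.classify_all(metrics, cutoffs)
    if contigs is not None:
        clean, organelle = _classify.partition_assembly(
            contigs, classifications, quarantine_flagged
        )
    else:
        clean, organelle = [], []
    outputs: dict[str, Path] = {}

    outputs["metrics"] = outdir / "metrics.tsv"
    _io.write_metrics_table(metrics, outputs["metrics"], classifications)

    frame = _io.metrics_frame(metrics, classifications)
    outputs["scatter"] = outdir / "scatter.tsv"
    frame[SCATTER_COLUMNS].to_csv(
        outputs["scatter"], sep="\t", index=False, float_format="%.6f"
    )

    outputs["baseline"] = outdir / "baseline_comparison.tsv"
    _classify.compare_baseline(metrics, classifications, baseline_min_len).to_csv(
        outputs["baseline"], sep="\t", index=False
    )

    if contigs is not None:
        if clean:
            outputs["clean"] = outdir / "clean.fasta"
            _io.write_fasta(clean, outputs["clean"])
        by_id = {c.contig_id: c for c in classifications}
        for cat, name in (
            (Category.ORGANELLE_MITO, "organelle_mito.fasta"),
            (Category.ORGANELLE_CHLO, "organelle_chlo.fasta"),
        ):
            bin_recs = [r for r in organelle if by_id[r.id].category is cat]
            if bin_recs:
                outputs[name] = outdir / name
                _io.write_fasta(bin_recs, outputs[name])

    return RunResult(list(metrics), classifications, clean, organelle, outputs)


def reclassify(
    metrics_tsv: str | Path,
    outdir: str | Path,
    cutoffs: Cutoffs = Cutoffs(),
    assembly: str | Path | None = None,
    quarantine_flagged: bool = False,
    baseline_min_len: int = 5000,
) -> RunResult:
    """Second-round thresholding on a cached metrics table.

    Identical to the classification stage of :func:`run_pipeline`; at equal
    cutoffs the written report is byte-identical (idempotent).  FASTA bins
    are only produced when the assembly is supplied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = _io.read_metrics_table(metrics_tsv)
    contigs = None
    if assembly is not None:
        contigs = _io.read_fasta(assembly)
        known = {m.contig_id for m in metrics}
        unknown = [r.id for r in contigs if r.id not in known]
        if unknown:
            raise ContractError(f"assembly contigs missing from metrics table: {unknown}")
    return _classify_and_write(
        contigs, metrics, cutoffs, outdir, quarantine_flagged, baseline_min_len
    )
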