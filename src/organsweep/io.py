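"""Readers and writers for the formats the pipeline touches.

FASTA parsing goes through Biopython with strict validation on top
(unique ids, non-empty IUPAC sequences); PAF is parsed directly since the
mandatory 12-column layout is fixed and no installed library reads it.
Plain-gzip transparency is provided for FASTA and PAF (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .core import AlignmentBlock, ContigMetrics, RefClass
from .errors import FormatError

_IUPAC = set("ACGTRYSWKMBDHVN")

#: column order of the metrics/report table, fixed for reproducibility
METRICS_COLUMNS = [
    "contig_id",
    "contig_length",
    "mito_union_len",
    "mito_longest",
    "mito_ALCR",
    "chlo_union_len",
    "chlo_longest",
    "chlo_ALCR",
    "mean_depth",
    "mito_SDR",
    "chlo_SDR",
    "category",
    "rules_fired",
]


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence; id is the first whitespace token of the header."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrganelleDB:
    """User-supplied organelle reference sequences with a class per record.

    Both classes may hold several sequences — plant mitochondrial genomes in
    particular often come as multiple fragments.
    """

    records: list[SeqRecord] = field(default_factory=list)
    class_of: dict[str, RefClass] = field(default_factory=dict)

    @classmethod
    def from_fastas(
        cls, mito_path: str | Path | None, chlo_path: str | Path | None
    ) -> "OrganelleDB":
        db = cls()
        for path, ref_class in ((mito_path, RefClass.MITO), (chlo_path, RefClass.CHLO)):
            if path is None:
                continue
            for rec in read_fasta(path):
                if rec.id in db.class_of:
                    raise FormatError(
                        f"reference id {rec.id!r} appears in both organelle classes"
                    )
                db.records.append(rec)
                db.class_of[rec.id] = ref_class
        return db

    def records_of(self, ref_class: RefClass) -> list[SeqRecord]:
        return [r for r in self.records if self.class_of[r.id] == ref_class]

    @property
    def classes(self) -> set[RefClass]:
        return set(self.class_of.values())


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into validated records.

    Ids are the first whitespace token; duplicates, empty sequences and
    non-IUPAC characters are format errors naming the offender.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rid = rec.id
            if not rid:
                raise FormatError(f"{path}: record with empty id")
            if rid in seen:
                raise FormatError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: record {rid!r} has empty sequence")
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"{path}: record {rid!r} contains non-IUPAC characters "
                    f"{sorted(bad)}"
                )
            records.append(SeqRecord(rid, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SeqRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; refuses an empty record list."""
    if not records:
        raise ValueError(f"refusing to write empty FASTA to {path}")
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                handle.write(rec.seq[i : i + line_width] + "\n")


def read_paf(
    path: str | Path, db: OrganelleDB, primary_only: bool = False
) -> list[AlignmentBlock]:
    """Parse minimap2 PAF lines into alignment blocks tagged with ref class.

    Only the 12 mandatory columns plus the optional ``tp:A:`` tag are
    interpreted.  Lines whose target is not in ``db`` raise — a silent drop
    would misassign classes downstream.  With ``primary_only`` secondary
    alignments (``tp:A:S``) are discarded; supplementary split hits
    (``tp:A:P`` on non-primary lines) are kept, the interval union absorbs
    any double counting.
    """
    blocks: list[AlignmentBlock] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF line has {len(cols)} columns, need >=12"
                )
            qname = cols[0]
            try:
                qlen, qstart, qend = int(cols[1]), int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            tname = cols[5]
            if qend <= qstart or qstart < 0 or qend > qlen:
                raise FormatError(
                    f"{path}:{lineno}: invalid query interval [{qstart}, {qend}) "
                    f"on {qname!r} (length {qlen})"
                )
            if tname not in db.class_of:
                raise FormatError(
                    f"{path}:{lineno}: alignment target {tname!r} is not in the "
                    "organelle reference database"
                )
            tp = None
            for tag in cols[12:]:
                if tag.startswith("tp:A:"):
                    tp = tag[5:]
                    break
            is_primary = tp != "S"
            if primary_only and not is_primary:
                continue
            blocks.append(
                AlignmentBlock(
                    contig_id=qname,
                    contig_start=qstart,
                    contig_end=qend,
                    ref_id=tname,
                    ref_class=db.class_of[tname],
                    is_primary=is_primary,
                )
            )
    return blocks


def metrics_frame(
    metrics: Sequence[ContigMetrics],
    classifications: "Sequence | None" = None,
) -> pd.DataFrame:
    """Assemble the per-contig metrics/report table (input contig order)."""
    by_id = {}
    if classifications is not None:
        by_id = {c.contig_id: c for c in classifications}
    rows = []
    for m in metrics:
        c = by_id.get(m.contig_id)
        rows.append(
            {
                "contig_id": m.contig_id,
                "contig_length": m.contig_length,
                "mito_union_len": m.union_len.get(RefClass.MITO, 0),
                "mito_longest": m.longest.get(RefClass.MITO, 0),
                "mito_ALCR": m.alcr.get(RefClass.MITO, 0.0),
                "chlo_union_len": m.union_len.get(RefClass.CHLO, 0),
                "chlo_longest": m.longest.get(RefClass.CHLO, 0),
                "chlo_ALCR": m.alcr.get(RefClass.CHLO, 0.0),
                "mean_depth": m.mean_depth,
                "mito_SDR": m.sdr.get(RefClass.MITO, 0.0),
                "chlo_SDR": m.sdr.get(RefClass.CHLO, 0.0),
                "category": c.category.value if c is not None else "",
                "rules_fired": ";".join(c.rules_fired) if c is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_table(
    metrics: Sequence[ContigMetrics],
    path: str | Path,
    classifications: "Sequence | None" = None,
) -> None:
    """Write the metrics/report TSV; floats carry six decimals."""
    frame = metrics_frame(metrics, classifications)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_metrics_table(path: str | Path) -> list[ContigMetrics]:
    """Re-read a metrics TSV into ContigMetrics (categories are recomputable)."""
    frame = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    missing = [c for c in METRICS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: metrics table missing columns {missing}")
    metrics = []
    for row in frame.itertuples(index=False):
        metrics.append(
            ContigMetrics(
                contig_id=row.contig_id,
                contig_length=int(row.contig_length),
                union_len={
                    RefClass.MITO: int(row.mito_union_len),
                    RefClass.CHLO: int(row.chlo_union_len),
                },
                longest={
                    RefClass.MITO: int(row.mito_longest),
                    RefClass.CHLO: int(row.chlo_longest),
                },
                alcr={
                    RefClass.MITO: float(row.mito_ALCR),
                    RefClass.CHLO: float(row.chlo_ALCR),
                },
                mean_depth=float(row.mean_depth),
                sdr={
                    RefClass.MITO: float(row.mito_SDR),
                    RefClass.CHLO: float(row.chlo_SDR),
                },
            )
        )
    return metrics


def records_by_id(records: Iterable[SeqRecord]) -> dict[str, SeqRecord]:
    return {r.id: r for r in records}
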