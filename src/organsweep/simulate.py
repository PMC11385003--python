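"""Synthetic assemblies with planted organelle contamination.

The generator emulates the situation the screening pipeline exists for: a
nuclear genome, much smaller circular organelle genomes present at elevated
per-cell copy number, an assembly whose contigs are verbatim windows of
those sources, nuclear contigs carrying horizontally transferred organelle
fragments (numts/nupts), and error-free paired short reads whose depth is
proportional to copy number.  Because contigs are exact substrings and reads
are error-free with known placement, ground-truth alignments (PAF) and a
truth SAM can be emitted directly from coordinates — no external aligner or
mapper runs, and every downstream metric has an exact expected value.

Reads are sampled target-by-target over the emission set
{assembly contigs + organelle reference sequences}: depth evidence must land
on exactly the coordinate systems the pipeline measures (SDR numerator =
contig depth, denominator = reference depth).  Each contig is sampled at the
copy-number depth of its source genome, so the configured depth law holds on
every target.  Reads that wrap a circular origin are written to the truth
SAM as two all-M segments sharing a read name, keeping per-base depth exact.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np

from .classify import Category, Cutoffs, classify_contig
from .core import ContigMetrics, RefClass
from .errors import ContractError
from .io import SeqRecord, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Source(str, enum.Enum):
    NUCLEAR = "nuclear"
    MITO = "mito"
    CHLO = "chlo"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SOURCE_CLASS = {Source.MITO: RefClass.MITO, Source.CHLO: RefClass.CHLO}


@dataclass(frozen=True)
class HgtInsert:
    """One organelle fragment to splice into the nuclear genome.

    ``offset`` is a position in the *original* (pre-insertion) nuclear
    coordinate system; inserts are applied in ascending offset order.
    """

    ref_class: RefClass
    length: int
    offset: int


@dataclass(frozen=True)
class ContigSpec:
    """One assembly contig: a window on a source genome (final coordinates)."""

    source: Source
    start: int
    end: int


@dataclass(frozen=True)
class HgtSpan:
    """Realized insert span, in final nuclear (or contig) coordinates."""

    ref_class: RefClass
    start: int
    end: int
    ref_id: str
    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``copy_ratio`` is the fold excess of organelle genome copies over the
    nuclear genome; organelle read depth is ``nuclear_depth x copy_ratio``.
    ``collapsed_repeat_depth`` multiplies the sampling depth of named
    contigs, emulating the depth inflation of collapsed tandem repeats that
    produces low-ALCR / high-SDR contigs in real assemblies.
    """

    seed: int
    nuclear_len: int = 500_000
    mito_len: int = 300_000
    chlo_len: int = 150_000
    copy_ratio: dict[RefClass, float] = field(
        default_factory=lambda: {RefClass.MITO: 20.0, RefClass.CHLO: 50.0}
    )
    nuclear_depth: float = 20.0
    read_len: int = 150
    frag_len: int = 350
    hgt_inserts: tuple[HgtInsert, ...] = ()
    contig_plan: tuple[ContigSpec, ...] = ()
    collapsed_repeat_depth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ContractError("seed is mandatory")
        for name in ("nuclear_len", "mito_len", "chlo_len", "read_len", "frag_len"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if self.frag_len < self.read_len:
            raise ContractError("frag_len must be >= read_len")
        for rc, ratio in self.copy_ratio.items():
            if ratio < 1:
                raise ContractError(f"copy ratio for {rc} must be >= 1, got {ratio}")
        offsets = [ins.offset for ins in self.hgt_inserts]
        if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
            raise ContractError("hgt_inserts must have strictly increasing offsets")
        for ins in self.hgt_inserts:
            if not 0 <= ins.offset <= self.nuclear_len:
                raise ContractError(f"insert offset {ins.offset} outside nuclear genome")


@dataclass
class Genomes:
    nuclear: SeqRecord
    mito: SeqRecord
    chlo: SeqRecord

    @property
    def circular_ids(self) -> set[str]:
        return {self.mito.id, self.chlo.id}

    def of_class(self, ref_class: RefClass) -> SeqRecord:
        return self.mito if ref_class is RefClass.MITO else self.chlo

    def of_source(self, source: Source) -> SeqRecord:
        if source is Source.NUCLEAR:
            return self.nuclear
        return self.of_class(_SOURCE_CLASS[source])


@dataclass
class TruthRecord:
    """Ground truth for one simulated contig."""

    contig_id: str
    source: Source
    source_start: int
    source_end: int
    hgt_spans: list[HgtSpan] = field(default_factory=list)
    expected_category: Category = Category.NUCLEAR


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_genomes(cfg: SimConfig) -> Genomes:
    """Uniform-random source genomes; organelle sequences are circular."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    return Genomes(
        nuclear=SeqRecord("nuclear", _random_seq(rng, cfg.nuclear_len)),
        mito=SeqRecord("mito_ref", _random_seq(rng, cfg.mito_len)),
        chlo=SeqRecord("chlo_ref", _random_seq(rng, cfg.chlo_len)),
    )


def plant_hgt(
    nuclear_seq: str,
    organelle: SeqRecord,
    ref_class: RefClass,
    insert_len: int,
    offset: int,
    rng: np.random.Generator,
) -> tuple[str, HgtSpan]:
    """Splice a random organelle substring into the nuclear sequence.

    Returns the modified sequence and the exact span of the insert in the
    *modified* coordinate system, with the source coordinates on the
    organelle reference.
    """
    if insert_len < 0 or insert_len > len(organelle.seq):
        raise ContractError(
            f"insert length {insert_len} exceeds organelle length {len(organelle.seq)}"
        )
    if not 0 <= offset <= len(nuclear_seq):
        raise ContractError(f"insert offset {offset} outside nuclear sequence")
    if insert_len == 0:
        return nuclear_seq, HgtSpan(ref_class, offset, offset, organelle.id, 0, 0)
    ref_start = int(rng.integers(0, len(organelle.seq) - insert_len + 1))
    fragment = organelle.seq[ref_start : ref_start + insert_len]
    modified = nuclear_seq[:offset] + fragment + nuclear_seq[offset:]
    return modified, HgtSpan(
        ref_class, offset, offset + insert_len, organelle.id, ref_start, ref_start + insert_len
    )


def apply_hgt_inserts(genomes: Genomes, cfg: SimConfig) -> tuple[Genomes, list[HgtSpan]]:
    """Apply all configured inserts in ascending offset order.

    Later offsets (given in original coordinates) are shifted by the length
    of every insert already placed, so spans come out in final coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    seq = genomes.nuclear.seq
    spans: list[HgtSpan] = []
    shift = 0
    for ins in cfg.hgt_inserts:
        organelle = genomes.of_class(ins.ref_class)
        seq, span = plant_hgt(
            seq, organelle, ins.ref_class, ins.length, ins.offset + shift, rng
        )
        spans.append(span)
        shift += ins.length
    return replace(genomes, nuclear=SeqRecord(genomes.nuclear.id, seq)), spans


def _truth_metrics(
    contig_id: str,
    contig_len: int,
    source: Source,
    spans: Sequence[HgtSpan],
    cfg: SimConfig,
    depth_multiplier: float,
) -> ContigMetrics:
    """Expected metrics of a contig from ground truth alone."""
    union = {RefClass.MITO: 0, RefClass.CHLO: 0}
    longest = {RefClass.MITO: 0, RefClass.CHLO: 0}
    if source is Source.NUCLEAR:
        for rc in union:
            lens = [s.length for s in spans if s.ref_class is rc]
            union[rc] = sum(lens)  # planted inserts never overlap
            longest[rc] = max(lens, default=0)
        rel_depth = depth_multiplier
    else:
        rc = _SOURCE_CLASS[source]
        union[rc] = longest[rc] = contig_len
        rel_depth = cfg.copy_ratio[rc] * depth_multiplier
    sdr = {rc: rel_depth / cfg.copy_ratio[rc] for rc in union}
    return ContigMetrics(
        contig_id=contig_id,
        contig_length=contig_len,
        union_len=union,
        longest=longest,
        alcr={rc: union[rc] / contig_len for rc in union},
        mean_depth=rel_depth * cfg.nuclear_depth,
        sdr=sdr,
    )


def make_contigs(
    genomes: Genomes,
    cfg: SimConfig,
    spans: Sequence[HgtSpan] = (),
    cutoffs: Cutoffs = Cutoffs(),
) -> tuple[list[SeqRecord], list[TruthRecord]]:
    """Cut contigs per the plan; truth records carry provenance and the
    category the default pipeline should assign (derived by running the
    classifier on the exact truth metrics)."""
    contigs: list[SeqRecord] = []
    truths: list[TruthRecord] = []
    for i, spec in enumerate(cfg.contig_plan, 1):
        src = genomes.of_source(spec.source)
        if not 0 <= spec.start < spec.end <= len(src.seq):
            raise ContractError(
                f"contig window [{spec.start}, {spec.end}) outside {spec.source} "
                f"(length {len(src.seq)})"
            )
        cid = f"contig_{i}"
        contigs.append(SeqRecord(cid, src.seq[spec.start : spec.end]))
        contig_spans = []
        if spec.source is Source.NUCLEAR:
            for span in spans:
                lo, hi = max(span.start, spec.start), min(span.end, spec.end)
                if hi <= lo:
                    continue
                contig_spans.append(
                    HgtSpan(
                        span.ref_class,
                        lo - spec.start,
                        hi - spec.start,
                        span.ref_id,
                        span.ref_start + (lo - span.start),
                        span.ref_end - (span.end - hi),
                    )
                )
        mult = cfg.collapsed_repeat_depth.get(cid, 1.0)
        expected = classify_contig(
            _truth_metrics(cid, spec.end - spec.start, spec.source, contig_spans, cfg, mult),
            cutoffs,
        ).category
        truths.append(
            TruthRecord(cid, spec.source, spec.start, spec.end, contig_spans, expected)
        )
    return contigs, truths


def truth_alignments(
    contigs: Sequence[SeqRecord],
    truths: Sequence[TruthRecord],
    genomes: Genomes,
    min_block: int = 100,
) -> list[str]:
    """Exact PAF lines for every organelle-derived region of each contig.

    Organelle-source contigs yield one full-length block against their
    reference; planted inserts on nuclear contigs yield one block per span
    of at least ``min_block`` bases.  No heuristic alignment is involved.
    """
    by_id = {t.contig_id: t for t in truths}
    lines: list[str] = []
    for rec in contigs:
        if rec.id not in by_id:
            raise ContractError(f"contig {rec.id!r} has unknown provenance")
        t = by_id[rec.id]
        qlen = len(rec.seq)
        if t.source in _SOURCE_CLASS:
            ref = genomes.of_class(_SOURCE_CLASS[t.source])
            lines.append(
                _paf_line(rec.id, qlen, 0, qlen, ref.id, len(ref.seq), t.source_start, t.source_end)
            )
        else:
            for span in t.hgt_spans:
                if span.length < min_block:
                    continue
                ref = genomes.of_class(span.ref_class)
                lines.append(
                    _paf_line(
                        rec.id, qlen, span.start, span.end,
                        ref.id, len(ref.seq), span.ref_start, span.ref_end,
                    )
                )
    return lines


def _paf_line(
    qname: str, qlen: int, qstart: int, qend: int,
    tname: str, tlen: int, tstart: int, tend: int,
) -> str:
    blen = qend - qstart
    return "\t".join(
        map(str, [qname, qlen, qstart, qend, "+", tname, tlen, tstart, tend, blen, blen, 60])
    ) + "\ttp:A:P"


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadPair:
    """One error-free fragment: qname, forward-mate and reverse-mate data.

    Sequences are stored reference-forward (as they appear in the SAM SEQ
    field); the FASTQ writer reverse-complements mate 2.
    """

    qname: str
    target_id: str
    pos1: int  # 0-based start of mate 1 on the target (modulo length)
    pos2: int
    seq1: str
    seq2: str


def depth_targets(
    contigs: Sequence[SeqRecord],
    truths: Sequence[TruthRecord],
    genomes: Genomes,
    cfg: SimConfig,
) -> list[tuple[SeqRecord, float, bool]]:
    """(sequence, sampling depth, circular) for contigs + organelle refs."""
    by_id = {t.contig_id: t for t in truths}
    targets: list[tuple[SeqRecord, float, bool]] = []
    for rec in contigs:
        t = by_id[rec.id]
        if t.source is Source.NUCLEAR:
            depth = cfg.nuclear_depth
        else:
            depth = cfg.nuclear_depth * cfg.copy_ratio[_SOURCE_CLASS[t.source]]
        depth *= cfg.collapsed_repeat_depth.get(rec.id, 1.0)
        targets.append((rec, depth, False))
    for rc in (RefClass.MITO, RefClass.CHLO):
        ref = genomes.of_class(rc)
        targets.append((ref, cfg.nuclear_depth * cfg.copy_ratio[rc], True))
    return targets


def simulate_read_pairs(
    target: SeqRecord, depth: float, circular: bool, cfg: SimConfig,
    rng: np.random.Generator,
) -> Iterator[ReadPair]:
    """Uniformly sampled error-free pairs at the requested mean depth.

    Circular targets are sampled over every origin-spanning position (the
    sequence is treated as doubled); linear targets constrain fragments to
    fit, which keeps the realized mean depth at exactly
    ``n_reads x read_len / length`` in both cases.
    """
    L = len(target.seq)
    rl, fl = cfg.read_len, cfg.frag_len
    if rl > L:
        raise ContractError(f"read length {rl} exceeds target {target.id!r} length {L}")
    n_pairs = int(round(depth * L / (2 * rl)))
    if n_pairs == 0:
        return
    if circular:
        starts = rng.integers(0, L, n_pairs)
        doubled = target.seq + target.seq[: fl]
    else:
        if fl > L:
            raise ContractError(f"fragment length {fl} exceeds target {target.id!r} length {L}")
        starts = rng.integers(0, L - fl + 1, n_pairs)
        doubled = target.seq
    for i, s in enumerate(starts):
        s = int(s)
        p2 = (s + fl - rl) % L if circular else s + fl - rl
        yield ReadPair(
            qname=f"{target.id}:{i}",
            target_id=target.id,
            pos1=s % L,
            pos2=p2,
            seq1=doubled[s : s + rl],
            seq2=doubled[s + fl - rl : s + fl],
        )


def _sam_segments(pos: int, seq: str, length: int) -> list[tuple[int, str]]:
    if pos + len(seq) <= length:
        return [(pos, seq)]
    head = length - pos
    return [(pos, seq[:head]), (0, seq[head:])]


def write_sam(
    path: str | Path,
    targets: Sequence[tuple[SeqRecord, float, bool]],
    cfg: SimConfig,
    rng: np.random.Generator,
    fastq1: IO[str] | None = None,
    fastq2: IO[str] | None = None,
) -> dict[str, int]:
    """Stream the truth SAM (and optionally paired FASTQ) for all targets.

    Returns the number of read pairs emitted per target.  Mates carry
    proper-pair flags (99/147); wrap-around segments on circular targets are
    emitted as extra all-M lines sharing the QNAME.
    """
    counts: dict[str, int] = {}
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec, _, _ in targets:
            out.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec.seq)}\n")
        for rec, depth, circular in targets:
            L = len(rec.seq)
            n = 0
            for pair in simulate_read_pairs(rec, depth, circular, cfg, rng):
                n += 1
                for flag, pos, seq, mpos, tlen in (
                    (99, pair.pos1, pair.seq1, pair.pos2, cfg.frag_len),
                    (147, pair.pos2, pair.seq2, pair.pos1, -cfg.frag_len),
                ):
                    for seg_pos, seg_seq in _sam_segments(pos, seq, L):
                        out.write(
                            f"{pair.qname}\t{flag}\t{rec.id}\t{seg_pos + 1}\t60\t"
                            f"{len(seg_seq)}M\t=\t{mpos + 1}\t{tlen}\t{seg_seq}\t*\n"
                        )
                if fastq1 is not None and fastq2 is not None:
                    fastq1.write(f"@{pair.qname}/1\n{pair.seq1}\n+\n{'I' * len(pair.seq1)}\n")
                    fastq2.write(f"@{pair.qname}/2\n{revcomp(pair.seq2)}\n+\n{'I' * len(pair.seq2)}\n")
            counts[rec.id] = n
    return counts


# ---------------------------------------------------------------------------
# scenario orchestration


@dataclass
class SimResult:
    cfg: SimConfig
    genomes: Genomes
    spans: list[HgtSpan]
    contigs: list[SeqRecord]
    truths: list[TruthRecord]
    paths: dict[str, Path]


def generate(cfg: SimConfig, outdir: str | Path, write_fastq: bool = False) -> SimResult:
    """Materialize a full scenario on disk.

    Writes ``assembly.fasta``, ``mito_ref.fasta``, ``chlo_ref.fasta``,
    ``alignments.paf``, ``reads.sam``, ``truth.tsv`` and (optionally)
    ``reads_1.fastq``/``reads_2.fastq`` into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, spans = apply_hgt_inserts(make_genomes(cfg), cfg)
    contigs, truths = make_contigs(genomes, cfg, spans)
    paths = {
        "assembly": outdir / "assembly.fasta",
        "mito_ref": outdir / "mito_ref.fasta",
        "chlo_ref": outdir / "chlo_ref.fasta",
        "paf": outdir / "alignments.paf",
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(contigs, paths["assembly"])
    write_fasta([genomes.mito], paths["mito_ref"])
    write_fasta([genomes.chlo], paths["chlo_ref"])
    paths["paf"].write_text(
        "".join(line + "\n" for line in truth_alignments(contigs, truths, genomes))
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    targets = depth_targets(contigs, truths, genomes, cfg)
    fq1 = fq2 = None
    try:
        if write_fastq:
            paths["fastq1"] = outdir / "reads_1.fastq"
            paths["fastq2"] = outdir / "reads_2.fastq"
            fq1 = open(paths["fastq1"], "w")
            fq2 = open(paths["fastq2"], "w")
        write_sam(paths["sam"], targets, cfg, rng, fq1, fq2)
    finally:
        for h in (fq1, fq2):
            if h is not None:
                h.close()
    with open(paths["truth"], "w") as out:
        out.write("contig_id\tsource\tsource_start\tsource_end\texpected_category\thgt_spans\n")
        for t in truths:
            spans_txt = ";".join(
                f"{s.ref_class.value}:{s.start}-{s.end}:{s.ref_id}:{s.ref_start}-{s.ref_end}"
                for s in t.hgt_spans
            )
            out.write(
                f"{t.contig_id}\t{t.source.value}\t{t.source_start}\t{t.source_end}\t"
                f"{t.expected_category.value}\t{spans_txt}\n"
            )
    return SimResult(cfg, genomes, spans, contigs, truths, paths)


def standard_scenario(seed: int) -> SimConfig:
    """The reference planted-contamination scenario.

    500 kb nuclear genome in five contigs, a 300 kb mitogenome split over
    two contigs, a 150 kb plastome as one contig; one 8 kb numt inside a
    208 kb nuclear contig and one 6 kb nupt inside a 106 kb contig; copy
    ratios 20x (mito) and 50x (chlo) over a 20x nuclear depth.
    """
    return SimConfig(
        seed=seed,
        nuclear_len=500_000,
        mito_len=300_000,
        chlo_len=150_000,
        copy_ratio={RefClass.MITO: 20.0, RefClass.CHLO: 50.0},
        nuclear_depth=20.0,
        read_len=150,
        frag_len=350,
        hgt_inserts=(
            HgtInsert(RefClass.MITO, 8_000, 100_000),
            HgtInsert(RefClass.CHLO, 6_000, 350_000),
        ),
        # final nuclear length 514 kb after both inserts
        contig_plan=(
            ContigSpec(Source.NUCLEAR, 0, 90_000),
            ContigSpec(Source.NUCLEAR, 90_000, 298_000),   # carries the 8 kb numt
            ContigSpec(Source.NUCLEAR, 298_000, 348_000),
            ContigSpec(Source.NUCLEAR, 348_000, 454_000),  # carries the 6 kb nupt
            ContigSpec(Source.NUCLEAR, 454_000, 514_000),
            ContigSpec(Source.MITO, 0, 150_000),
            ContigSpec(Source.MITO, 150_000, 300_000),
            ContigSpec(Source.CHLO, 0, 150_000),
        ),
    )
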