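"""Per-base coverage and mean depth for contigs and organelle references.

The SDR numerator is a contig's mean short-read depth; the denominator is
the length-weighted average depth over all sequences of an organelle class.
Depth evidence arrives either as a SAM file of read alignments (parsed with
pysam) or as a bedtools-genomecov-like 3-column per-base table.

Conventions follow samtools depth: CIGAR operations that consume the
reference and represent an aligned read (M/=/X) or a deletion (D) count a
base as covered; insertions, soft/hard clips and skips (N) do not.
Unmapped, secondary (0x100), supplementary (0x800) and duplicate-marked
(0x400) records are excluded.  No mapping-quality filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .core import RefClass
from .errors import ContractError, FormatError
from .io import SeqRecord

# CIGAR opcodes that consume the reference and count as coverage
_COVERING_OPS = {0, 7, 8, 2}  # M, =, X, D
_SKIP_OPS = {3}  # N consumes reference but is not coverage


@dataclass
class DepthProfile:
    """Per-base coverage over one sequence."""

    seq_id: str
    coverage: np.ndarray  # non-negative int counts, length == sequence length

    @property
    def length(self) -> int:
        return int(self.coverage.shape[0])

    @property
    def total(self) -> int:
        return int(self.coverage.sum())

    @property
    def mean(self) -> float:
        return self.total / self.length if self.length else 0.0


@dataclass
class OrganelleDepthSummary:
    """Average depth per organelle class and per reference sequence.

    The class average is length-weighted: total covered bases over total
    reference length.  An unweighted mean of per-sequence means would let
    tiny fragments of a multi-fragment mitogenome dominate the denominator.
    """

    per_class: dict[RefClass, float] = field(default_factory=dict)
    per_sequence: dict[str, float] = field(default_factory=dict)


def depth_from_sam(
    path: str | Path, targets: Sequence[SeqRecord]
) -> list[DepthProfile]:
    """Compute per-base depth over ``targets`` from a SAM file.

    Only records mapped to a listed target are counted; records on other
    references are ignored.  Coverage at position i is the number of kept
    reads whose aligned reference span (M/=/X and D operations) covers i.
    Uses a difference-array accumulation per CIGAR segment, so runtime is
    linear in the number of alignment segments, not in read length.
    """
    lengths = {t.id: len(t.seq) for t in targets}
    # diff arrays: cov = cumsum(diff[:-1])
    diffs = {tid: np.zeros(n + 1, dtype=np.int64) for tid, n in lengths.items()}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.references:
            raise FormatError(f"{path}: SAM file has no @SQ header lines")
        try:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                    continue
                tid = rec.reference_name
                if tid not in diffs:
                    continue
                n = lengths[tid]
                if rec.cigartuples is None:
                    raise FormatError(
                        f"{path}: mapped record {rec.query_name!r} lacks a CIGAR"
                    )
                pos = rec.reference_start
                diff = diffs[tid]
                for op, length in rec.cigartuples:
                    if op in _COVERING_OPS:
                        start = min(pos, n)
                        end = min(pos + length, n)
                        if end > start:
                            diff[start] += 1
                            diff[end] -= 1
                        pos += length
                    elif op in _SKIP_OPS:
                        pos += length
                    # I, S, H, P consume no reference
        except OSError as exc:
            # htslib refuses records whose CIGAR and SEQ lengths disagree
            raise FormatError(f"{path}: malformed SAM record ({exc})") from exc
    return [
        DepthProfile(t.id, np.cumsum(diffs[t.id][:-1])) for t in targets
    ]


def depth_from_table(path: str | Path) -> list[DepthProfile]:
    """Read per-base depth from a 3-column TSV: seq_id, 1-based pos, depth.

    Positions must be contiguous from 1 within each sequence; depths must be
    non-negative.  Sequence length is taken as the number of rows.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["seq_id", "pos", "depth"],
        dtype={"seq_id": str},
    )
    if frame.empty:
        raise FormatError(f"{path}: empty depth table")
    if (frame["depth"] < 0).any():
        bad = frame[frame["depth"] < 0].iloc[0]
        raise FormatError(
            f"{path}: negative depth {bad.depth} at {bad.seq_id}:{bad.pos}"
        )
    profiles = []
    for seq_id, grp in frame.groupby("seq_id", sort=False):
        pos = grp["pos"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            raise FormatError(
                f"{path}: positions for {seq_id!r} are not contiguous from 1"
            )
        profiles.append(DepthProfile(str(seq_id), grp["depth"].to_numpy(np.int64)))
    return profiles


def organelle_average_depth(profiles: Sequence[DepthProfile]) -> float:
    """Length-weighted mean depth over all sequences of one organelle class."""
    if not profiles:
        raise ContractError("organelle class has no depth profiles")
    total_len = sum(p.length for p in profiles)
    if total_len <= 0:
        raise ContractError("organelle class has zero total length")
    return sum(p.total for p in profiles) / total_len


def summarize_organelle_depth(
    profiles: Sequence[DepthProfile], class_of: dict[str, RefClass]
) -> OrganelleDepthSummary:
    """Group reference profiles by class and compute the weighted averages."""
    summary = OrganelleDepthSummary()
    by_class: dict[RefClass, list[DepthProfile]] = {}
    for p in profiles:
        if p.seq_id not in class_of:
            raise ContractError(f"profile {p.seq_id!r} has no organelle class")
        by_class.setdefault(class_of[p.seq_id], []).append(p)
        summary.per_sequence[p.seq_id] = p.mean
    for ref_class, ps in by_class.items():
        summary.per_class[ref_class] = organelle_average_depth(ps)
    return summary
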