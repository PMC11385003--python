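"""Core per-contig metrics: alignment length coverage ratio (ALCR) and
sequencing depth ratio (SDR).

ALCR is the fraction of a contig's bases that align to an organelle reference
set.  A contig copied out of an organelle genome aligns end to end (ALCR near
1), while a nuclear contig carrying a horizontally transferred organelle
fragment (numt/nupt) aligns only over that short insert and scores low.  The
default computation takes the *union* of the alignment intervals on the
contig, so double hits — e.g. a chloroplast inverted repeat matching one
contig region twice — cannot push the ratio above 1.  A ``raw-sum`` mode that
literally sums block lengths is kept for comparison.

SDR divides a contig's mean short-read depth by the average depth of the
organelle genome itself.  Organelle genomes are present at hundreds of copies
per cell, so true organelle contigs sit near SDR = 1 while nuclear contigs
fall near 1/copy-ratio; referencing the organelle (not nuclear) depth makes
the cutoff insensitive to the unknown, tissue-dependent copy number.

Coordinates are 0-based, half-open throughout (the PAF convention).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ContractError, DepthReferenceError


class RefClass(str, enum.Enum):
    """Organelle reference class of an alignment target."""

    MITO = "mito"
    CHLO = "chlo"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AlignmentBlock:
    """One contig-vs-organelle-reference match interval, on contig coordinates.

    ``contig_start``/``contig_end`` are 0-based half-open offsets on the
    *query* contig; ``ref_id`` names the organelle reference sequence hit and
    ``ref_class`` its class.  ``is_primary`` is False for minimap2 secondary
    alignments (``tp:A:S``); supplementary split hits stay primary.
    """

    contig_id: str
    contig_start: int
    contig_end: int
    ref_id: str
    ref_class: RefClass
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.contig_start < 0 or self.contig_end <= self.contig_start:
            raise ContractError(
                f"invalid interval [{self.contig_start}, {self.contig_end}) "
                f"on contig {self.contig_id!r}"
            )

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class ContigMetrics:
    """Per-contig, per-class coverage and depth metrics.

    The per-class dictionaries always carry both classes; a class without a
    supplied reference holds zeros so that strict ``>`` threshold comparisons
    can never fire for it.
    """

    contig_id: str
    contig_length: int
    union_len: dict[RefClass, int] = field(default_factory=dict)
    longest: dict[RefClass, int] = field(default_factory=dict)
    alcr: dict[RefClass, float] = field(default_factory=dict)
    mean_depth: float = 0.0
    sdr: dict[RefClass, float] = field(default_factory=dict)


def _check_homogeneous(blocks: Sequence[AlignmentBlock]) -> None:
    if not blocks:
        return
    cid = blocks[0].contig_id
    rc = blocks[0].ref_class
    for b in blocks:
        if b.contig_id != cid:
            raise ContractError(
                f"mixed contig ids in block set: {cid!r} vs {b.contig_id!r}"
            )
        if b.ref_class != rc:
            raise ContractError(
                f"mixed reference classes in block set: {rc} vs {b.ref_class}"
            )


def union_aligned_length(blocks: Sequence[AlignmentBlock]) -> int:
    """Number of distinct contig bases covered by at least one block.

    Blocks must all belong to one contig and one reference class; order is
    irrelevant.  Computed by sort-and-merge over half-open intervals.
    """
    _check_homogeneous(blocks)
    if not blocks:
        return 0
    ivals = sorted((b.contig_start, b.contig_end) for b in blocks)
    total = 0
    cur_start, cur_end = ivals[0]
    for start, end in ivals[1:]:
        if start > cur_end:  # half-open: touching intervals merge
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    total += cur_end - cur_start
    return total


def longest_alignment(blocks: Sequence[AlignmentBlock]) -> int:
    """Length of the single longest block; 0 for an empty set.

    This is the quantity traditional screens threshold on, kept for the
    baseline comparison.
    """
    _check_homogeneous(blocks)
    return max((b.length for b in blocks), default=0)


def raw_sum_aligned_length(blocks: Sequence[AlignmentBlock]) -> int:
    """Literal sum of block lengths, counting overlaps twice."""
    _check_homogeneous(blocks)
    return sum(b.length for b in blocks)


def compute_alcr(
    contig_length: int,
    blocks: Sequence[AlignmentBlock],
    mode: str = "union",
) -> float:
    """Alignment length coverage ratio of one contig against one class.

    Parameters
    ----------
    contig_length
        Total contig length in bases; must be positive.
    blocks
        Alignment blocks of one contig against one reference class.
    mode
        ``"union"`` (default) divides the interval union by the contig
        length, guaranteeing a ratio in [0, 1].  ``"raw-sum"`` divides the
        plain sum of block lengths, which can exceed 1 when blocks overlap.
    """
    if contig_length <= 0:
        raise ContractError(f"contig length must be positive, got {contig_length}")
    if mode == "union":
        aligned = union_aligned_length(blocks)
    elif mode == "raw-sum":
        aligned = raw_sum_aligned_length(blocks)
    else:
        raise ValueError(f"unknown ALCR mode {mode!r}")
    return aligned / contig_length


def compute_sdr(contig_mean_depth: float, organelle_avg_depth: float) -> float:
    """Sequencing depth ratio: contig mean depth over organelle average depth.

    Raises :class:`DepthReferenceError` when the organelle average depth is
    not positive (e.g. no reads mapped to the organelle references), since
    the ratio is then meaningless.
    """
    if not organelle_avg_depth > 0:
        raise DepthReferenceError(
            f"organelle average depth must be positive, got {organelle_avg_depth}"
        )
    if contig_mean_depth < 0 or math.isnan(contig_mean_depth):
        raise ContractError(f"invalid contig mean depth {contig_mean_depth}")
    return contig_mean_depth / organelle_avg_depth


def group_blocks(
    blocks: Iterable[AlignmentBlock],
) -> dict[str, dict[RefClass, list[AlignmentBlock]]]:
    """Index blocks by contig id, then by reference class."""
    out: dict[str, dict[RefClass, list[AlignmentBlock]]] = {}
    for b in blocks:
        out.setdefault(b.contig_id, {}).setdefault(b.ref_class, []).append(b)
    return out
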