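"""Threshold classification of contigs and assembly partitioning.

Decision order per contig (strict ``>`` at every cutoff, as the thresholds
are conventionally printed):

1. ``organelle_mito`` if mito ALCR > cutoff AND mito SDR > cutoff;
2. ``organelle_chlo`` analogously; when both classes pass, the class with
   the higher ALCR wins (an exact tie goes to chloroplast, recorded as a
   warning rule);
3. ``hgt_candidate`` when the best class's union aligned length exceeds
   ``hgt_min_aligned`` (default 5 kb) while its ALCR stays below
   ``hgt_max_alcr`` (default 10%) — the signature of a large organelle
   fragment horizontally transferred into a long nuclear contig;
4. ``ambiguous_high_sdr`` when some class shows low ALCR but
   above-cutoff SDR — mitochondrial/chloroplast cross-hits or repeat-driven
   depth inflation;
5. otherwise ``nuclear``.

HGT candidates and ambiguous contigs are *retained* in the clean assembly
by default: they are nuclear sequence carrying organelle-homologous
stretches, and removing them would delete real chromosome arms.  A
quarantine option moves them to a separate bin instead.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import ContigMetrics, RefClass
from .errors import ContractError
from .io import SeqRecord


class Category(str, enum.Enum):
    ORGANELLE_MITO = "organelle_mito"
    ORGANELLE_CHLO = "organelle_chlo"
    HGT_CANDIDATE = "hgt_candidate"
    AMBIGUOUS_HIGH_SDR = "ambiguous_high_sdr"
    NUCLEAR = "nuclear"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: categories removed from the clean assembly
ORGANELLE_CATEGORIES = {Category.ORGANELLE_MITO, Category.ORGANELLE_CHLO}

_CLASS_CATEGORY = {
    RefClass.MITO: Category.ORGANELLE_MITO,
    RefClass.CHLO: Category.ORGANELLE_CHLO,
}


@dataclass(frozen=True)
class Cutoffs:
    """Filtering thresholds; defaults are the tool's first-round settings."""

    mito_alcr: float = 0.5
    mito_sdr: float = 0.1
    chlo_alcr: float = 0.5
    chlo_sdr: float = 0.1
    hgt_min_aligned: int = 5000
    hgt_max_alcr: float = 0.10

    def __post_init__(self) -> None:
        for name in ("mito_alcr", "mito_sdr", "chlo_alcr", "chlo_sdr", "hgt_max_alcr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"cutoff {name}={v} outside [0, 1]")
        if self.hgt_min_aligned <= 0:
            raise ContractError("hgt_min_aligned must be positive")

    def alcr_cutoff(self, ref_class: RefClass) -> float:
        return self.mito_alcr if ref_class is RefClass.MITO else self.chlo_alcr

    def sdr_cutoff(self, ref_class: RefClass) -> float:
        return self.mito_sdr if ref_class is RefClass.MITO else self.chlo_sdr


@dataclass
class Classification:
    contig_id: str
    category: Category
    rules_fired: list[str] = field(default_factory=list)
    assigned_class_alcr: float = 0.0
    assigned_class_sdr: float = 0.0


def _check_finite(m: ContigMetrics) -> None:
    values = [m.mean_depth]
    for d in (m.alcr, m.sdr):
        values.extend(d.values())
    for v in values:
        if isinstance(v, float) and math.isnan(v):
            raise ContractError(f"NaN metric on contig {m.contig_id!r}")


def classify_contig(m: ContigMetrics, cutoffs: Cutoffs = Cutoffs()) -> Classification:
    """Apply the decision order above to one contig's metrics."""
    _check_finite(m)
    rules: list[str] = []

    passing = [
        rc
        for rc in (RefClass.MITO, RefClass.CHLO)
        if m.alcr.get(rc, 0.0) > cutoffs.alcr_cutoff(rc)
        and m.sdr.get(rc, 0.0) > cutoffs.sdr_cutoff(rc)
    ]
    if passing:
        if len(passing) == 1:
            winner = passing[0]
            rules.append(f"{winner.value}_alcr_sdr_pass")
        else:
            a_mito, a_chlo = m.alcr.get(RefClass.MITO, 0.0), m.alcr.get(RefClass.CHLO, 0.0)
            rules.append("mito_alcr_sdr_pass")
            rules.append("chlo_alcr_sdr_pass")
            if a_mito > a_chlo:
                winner = RefClass.MITO
                rules.append("both_classes_pass_resolved_by_higher_alcr")
            elif a_chlo > a_mito:
                winner = RefClass.CHLO
                rules.append("both_classes_pass_resolved_by_higher_alcr")
            else:
                winner = RefClass.CHLO
                rules.append("warning_both_classes_pass_alcr_tie_assigned_chlo")
        return Classification(
            m.contig_id,
            _CLASS_CATEGORY[winner],
            rules,
            assigned_class_alcr=m.alcr.get(winner, 0.0),
            assigned_class_sdr=m.sdr.get(winner, 0.0),
        )

    # best class by union aligned length (tie -> mito, deterministic)
    best = max(
        (RefClass.MITO, RefClass.CHLO), key=lambda rc: (m.union_len.get(rc, 0), rc is RefClass.MITO)
    )
    if (
        m.union_len.get(best, 0) > cutoffs.hgt_min_aligned
        and m.alcr.get(best, 0.0) < cutoffs.hgt_max_alcr
    ):
        rules.append(f"{best.value}_long_alignment_low_coverage")
        return Classification(
            m.contig_id,
            Category.HGT_CANDIDATE,
            rules,
            assigned_class_alcr=m.alcr.get(best, 0.0),
            assigned_class_sdr=m.sdr.get(best, 0.0),
        )

    ambiguous = [
        rc
        for rc in (RefClass.MITO, RefClass.CHLO)
        if m.alcr.get(rc, 0.0) <= cutoffs.alcr_cutoff(rc)
        and m.sdr.get(rc, 0.0) > cutoffs.sdr_cutoff(rc)
    ]
    if ambiguous:
        focus = max(ambiguous, key=lambda rc: m.sdr.get(rc, 0.0))
        rules.extend(f"{rc.value}_low_alcr_high_sdr" for rc in ambiguous)
        return Classification(
            m.contig_id,
            Category.AMBIGUOUS_HIGH_SDR,
            rules,
            assigned_class_alcr=m.alcr.get(focus, 0.0),
            assigned_class_sdr=m.sdr.get(focus, 0.0),
        )

    return Classification(
        m.contig_id,
        Category.NUCLEAR,
        rules,
        assigned_class_alcr=m.alcr.get(best, 0.0),
        assigned_class_sdr=m.sdr.get(best, 0.0),
    )


def classify_all(
    metrics: Sequence[ContigMetrics], cutoffs: Cutoffs = Cutoffs()
) -> list[Classification]:
    return [classify_contig(m, cutoffs) for m in metrics]


def partition_assembly(
    contigs: Sequence[SeqRecord],
    classifications: Sequence[Classification],
    quarantine_flagged: bool = False,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Split the assembly into (clean, organelle) bins, preserving order.

    With ``quarantine_flagged`` HGT candidates and ambiguous contigs move to
    the organelle bin as well; by default only the two organelle categories
    are removed.
    """
    by_id = {c.contig_id: c for c in classifications}
    removed = set(ORGANELLE_CATEGORIES)
    if quarantine_flagged:
        removed |= {Category.HGT_CANDIDATE, Category.AMBIGUOUS_HIGH_SDR}
    clean: list[SeqRecord] = []
    organelle: list[SeqRecord] = []
    for rec in contigs:
        if rec.id not in by_id:
            raise ContractError(f"contig {rec.id!r} has no classification")
        (organelle if by_id[rec.id].category in removed else clean).append(rec)
    return clean, organelle


def compare_baseline(
    metrics: Sequence[ContigMetrics],
    classifications: Sequence[Classification],
    min_len: int = 5000,
) -> pd.DataFrame:
    """Contrast the longest-alignment-only screen with the ALCR/SDR verdict.

    The baseline flags a contig as organelle whenever any single alignment
    exceeds ``min_len`` bases — the rule that misclassifies long nuclear
    contigs carrying large horizontally transferred organelle fragments.
    """
    by_id = {c.contig_id: c for c in classifications}
    rows = []
    for m in metrics:
        longest = max(m.longest.values(), default=0)
        cat = by_id[m.contig_id].category
        baseline = longest > min_len
        rows.append(
            {
                "contig_id": m.contig_id,
                "longest_alignment": longest,
                "baseline_organelle": baseline,
                "category": cat.value,
                "disagrees": baseline != (cat in ORGANELLE_CATEGORIES),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig_id", "longest_alignment", "baseline_organelle", "category", "disagrees"],
    )
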