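"""Shared helpers and independent oracles for the test suite."""

import re

import numpy as np

from organsweep.core import AlignmentBlock, RefClass

def blocks_from_intervals(intervals, contig_id="c1", ref_class=RefClass.MITO):
    """Build homogeneous alignment blocks from (start, end) pairs."""
    return [
        AlignmentBlock(contig_id, s, e, "refA", ref_class) for s, e in intervals
    ]


def boolean_union_oracle(intervals, length):
    """Independent per-base oracle: mark covered bases, count them."""
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    return int(covered.sum())


def write_sam_text(path, refs, records):
    """Write a SAM file: refs is {name: length}, records are
    (qname, flag, rname, pos1, cigar, seq) tuples."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\n")
        for name, length in refs.items():
            out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos1, cigar, seq in records:
            out.write(
                f"{qname}\t{flag}\t{rname}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def random_sam_fixture(rng, path, max_targets=2, max_target_len=2000, max_reads=200):
    """Random small SAM fixture; returns (refs dict, parsed records)."""
    refs = {}
    for i in range(int(rng.integers(1, max_targets + 1))):
        refs[f"t{i}"] = int(rng.integers(100, max_target_len + 1))
    names = list(refs)
    records = []
    for i in range(int(rng.integers(0, max_reads + 1))):
        rname = names[int(rng.integers(0, len(names)))]
        tlen = refs[rname]
        rlen = int(rng.integers(20, min(151, tlen + 1)))
        pos0 = int(rng.integers(0, tlen - rlen + 1))
        # occasionally a deletion or soft clip in the middle of the CIGAR
        style = int(rng.integers(0, 4))
        if style == 0 and rlen >= 40:
            a = rlen // 2
            d = int(rng.integers(1, 11))
            if pos0 + rlen + d <= tlen:
                cigar = f"{a}M{d}D{rlen - a}M"
            else:
                cigar = f"{rlen}M"
        elif style == 1 and rlen >= 40:
            s = int(rng.integers(5, 16))
            cigar = f"{s}S{rlen - s}M"
        else:
            cigar = f"{rlen}M"
        flag = 0
        r = rng.random()
        if r < 0.05:
            flag |= 0x100  # secondary
        elif r < 0.10:
            flag |= 0x400  # duplicate
        elif r < 0.15:
            flag |= 0x800  # supplementary
        records.append((f"r{i}", flag, rname, pos0 + 1, cigar, "A" * rlen))
    write_sam_text(path, refs, records)
    return refs, records


def pileup_oracle(refs, records):
    """Per-read per-base increment oracle over SAM record tuples."""
    import re

    cov = {name: np.zeros(length, dtype=int) for name, length in refs.items()}
    for _qname, flag, rname, pos1, cigar, _seq in records:
        if flag & (0x4 | 0x100 | 0x400 | 0x800):
            continue
        pos = pos1 - 1
        for count, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            count = int(count)
            if op in "M=XD":
                for i in range(pos, min(pos + count, refs[rname])):
                    cov[rname][i] += 1
                pos += count
            elif op == "N":
                pos += count
    return cov
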