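# Methods

## Problem and model

A draft assembly of a plant (or other eukaryote) genome mixes three kinds
of contigs: nuclear sequence, organelle genome sequence (mitochondrial or
plastid, present at high per-cell copy number), and nuclear sequence
carrying horizontally transferred organelle fragments (numts/nupts). The
screen classifies each contig from two observables:

- **ALCR** (alignment length coverage ratio): the fraction of the contig's
  bases covered by at least one alignment to the organelle references of a
  class. Formally, the size of the union of the query intervals of all
  alignment blocks, divided by contig length.
- **SDR** (sequencing depth ratio): the contig's mean short-read depth
  divided by the length-weighted average depth of the organelle references
  of that class.

Classification is a fixed decision list with strict `>` comparisons:
organelle if ALCR and SDR both exceed their cutoffs (defaults 0.5 and 0.1);
otherwise `hgt_candidate` if the union aligned length exceeds 5 kb while
ALCR stays below 10%; otherwise `ambiguous_high_sdr` if some class shows
ALCR at or below its cutoff but SDR above; otherwise nuclear. Only the two
organelle categories are removed from the clean assembly — HGT candidates
and ambiguous contigs are nuclear sequence and are retained (a quarantine
flag moves them out instead for cautious users).

### Assumptions

- Alignments faithfully report organelle homology; the screen does not
  re-align, it aggregates the PAF it is given.
- Short-read depth is proportional to copy number. SDR is referenced to
  the *organelle* depth, so no estimate of the (variable, tissue-dependent)
  organelle/nuclear copy ratio is needed; it only needs organelle depth to
  exceed the SDR cutoff times nuclear depth.
- Contigs are the classification unit; chimeric contigs (part nuclear,
  part organelle) will show intermediate ALCR and are surfaced through the
  HGT/ambiguous categories rather than resolved.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `mito_alcr`, `chlo_alcr` | 0.5 | per-class ALCR cutoff (fraction, strict >) |
| `mito_sdr`, `chlo_sdr` | 0.1 | per-class SDR cutoff (ratio, strict >) |
| `hgt_min_aligned` | 5000 bp | union aligned length above which a low-ALCR contig is an HGT candidate |
| `hgt_max_alcr` | 0.10 | ALCR below which the HGT rule may fire |
| `baseline min_len` | 5000 bp | longest-single-alignment cutoff of the comparison baseline |

The first-round cutoffs are deliberately permissive; the intended workflow
is to inspect the ALCR/SDR scatter (`scatter.tsv`) and re-threshold the
cached metrics table with `reclassify`, which is idempotent at unchanged
cutoffs and never re-reads alignments or reads.

## Design choices

- **Union vs raw sum.** Summing alignment block lengths (the literal
  formula) can exceed the contig length when blocks overlap on the contig —
  chloroplast inverted repeats routinely produce exactly that. The default
  therefore unions the intervals, keeping ALCR in [0, 1] and the cutoff
  interpretable; `--alcr-mode raw-sum` reproduces the literal sum for
  comparison. Coordinates are 0-based half-open (PAF convention) throughout.
- **Both classes passing.** When a contig clears both the mitochondrial
  and chloroplast rules, the class with the higher ALCR wins; an exact tie
  goes to chloroplast and a warning is recorded in `rules_fired`. The rule
  is explicit and overridable rather than inferred.
- **Depth conventions.** Following samtools-depth semantics: CIGAR M/=/X
  and D count a base as covered, I/S/H/N do not; unmapped, secondary,
  supplementary and duplicate-marked records are excluded; no
  mapping-quality filter. The organelle class average is length-weighted
  (total covered bases over total reference length) because plant
  mitogenomes often arrive as many fragments, and an unweighted mean of
  fragment means would let tiny fragments dominate the SDR denominator.
- **Secondary/supplementary PAF lines.** Only `tp:A:S` lines are treated
  as secondary (dropped under `--primary-only`); supplementary split hits
  are genuine homologous intervals and are kept — the union absorbs any
  double counting.
- **HGT rule on union length.** The >5 kb condition is applied to the
  union aligned length, not the longest block, consistent with the ALCR
  philosophy of aggregating all evidence.

## The synthetic-data generator

`organsweep.simulate` emulates the study conditions the screen is built
for: uniform-random source genomes (nuclear, plus circular mitochondrial
and plastid genomes), contigs cut as verbatim windows, organelle fragments
spliced into the nuclear genome at chosen offsets, and error-free paired
reads sampled uniformly at copy-number-proportional depth. The standard
scenario is a 500 kb nuclear genome in five contigs, a 300 kb mitogenome
in two contigs, a 150 kb plastome in one, one 8 kb numt inside a 208 kb
contig and one 6 kb nupt inside a 106 kb contig, copy ratios 20×/50× over
20× nuclear depth, 2×150 bp pairs with a 350 bp fragment. These sizes keep
a full simulation-plus-screen cycle under a minute on one CPU while
leaving every ratio (ALCR 0.038/0.057 for the inserts, SDR 1 vs 1/R) far
from the decision boundaries.

Reads are sampled target-by-target over the contigs *and* the organelle
references — the two coordinate systems the pipeline actually measures —
with each contig sampled at its source's depth. Placement is exact, so a
truth SAM (all-M CIGARs; origin-wrapping reads on circular targets split
into two records sharing a QNAME) and truth PAF are emitted directly from
coordinates, and no aligner or mapper runs anywhere in the test path. An
optional `align` subcommand wraps an external minimap2 binary for users
with real data.

What the generator does **not** emulate: sequencing errors, indels and
divergent (ancient, mutated) HGT inserts, repeat-driven mismapping, GC
bias, chimeric contigs, and organelle references that differ from the
organelle sequence in the assembly. Passing the recovery tests therefore
demonstrates that the metric arithmetic, thresholding and partitioning are
correct under the stated depth model — not that the screen is robust to
alignment noise on real data, where cutoff tuning via the two-round
workflow remains the user's responsibility. The collapsed-repeat knob
(`collapsed_repeat_depth`) inflates a contig's sampling depth to exercise
the `ambiguous_high_sdr` path, emulating the depth signature of collapsed
tandem repeats without modelling mismapping itself.

## Numerical notes

- Interval union is computed by sort-and-merge over half-open intervals;
  touching intervals (`end == next start`) merge without double counting.
- SAM depth uses a difference array per target (O(records + length)), so
  multi-million-record truth SAMs are processed in seconds; per-base
  equality against a naive per-read increment oracle is part of the test
  suite.
- SDR is undefined when the organelle reference receives no reads; that is
  an error (`DepthReferenceError`), not a silent zero, since every
  downstream decision would be meaningless.
- Metric tables round floats to six decimals; classification operates on
  the written values, so a reclassification round-trips bit-identically.
- All simulator randomness flows from one integer seed through named
  `SeedSequence` streams (genomes, inserts, reads), so outputs are
  byte-identical across runs and platforms.

## Known limitations

- No read-level verification of HGT junctions (e.g. spanning long reads);
  `hgt_candidate` is a reported category, not a validated call.
- Chimeric contig splitting is out of scope; the screen only labels whole
  contigs.
- The depth module intentionally ignores mapping quality; highly
  repetitive nuclear regions can therefore inherit organelle-like depth
  and surface as `ambiguous_high_sdr`.
- `-species` is accepted for command-line compatibility but is metadata
  only: chloroplast processing is active exactly when a chloroplast
  reference is supplied.
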