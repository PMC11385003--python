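# organsweep

Organelle-contamination screening for draft genome assemblies.

Plant (and many other eukaryote) cells carry mitochondrial and chloroplast
genomes at tens to hundreds of copies per cell. Long-read assemblers
therefore routinely emit contigs that are really organelle genome sequence,
and naive removal — "drop any contig with a long alignment to an organelle
reference" — also deletes genuine nuclear contigs that merely contain an
organelle fragment inserted by ancient horizontal transfer (a *numt* or
*nupt*). `organsweep` separates the two cases with two per-contig metrics
and partitions the assembly into a clean nuclear set and organelle bins.

## The two metrics

For each contig aligned (e.g. with minimap2) against per-class organelle
reference sequences:

**ALCR — alignment length coverage ratio**

```
ALCR(contig) = union of aligned contig intervals / total_length(contig)
```

A contig copied out of an organelle genome aligns end-to-end (ALCR ≈ 1);
a nuclear contig with an inserted fragment aligns only over that insert
(ALCR « 1). The default computation takes the *interval union* on the
contig, so duplicated hits (chloroplast inverted repeats) cannot push the
ratio above 1; a `raw-sum` mode that literally sums block lengths is
available for comparison.

**SDR — sequencing depth ratio**

```
SDR(contig) = mean short-read depth of contig / average depth of the organelle references
```

Because organelle genomes are highly multi-copy, true organelle contigs sit
near SDR = 1 while nuclear contigs sit near 1/copy-ratio. Referencing the
organelle depth (rather than the nuclear depth) makes the cutoff robust to
the unknown, tissue-dependent copy number.

A contig is binned as organelle when **ALCR > 0.5 and SDR > 0.1** (per
class, strict inequalities, both cutoffs adjustable). Contigs with more
than 5 kb of aligned sequence but ALCR below 10% are reported as
`hgt_candidate` and *kept* in the clean assembly; low-ALCR/high-SDR contigs
are reported as `ambiguous_high_sdr` (organelle cross-hits or collapsed
repeats) and also kept, unless `--quarantine-flagged` is set.

## Worked example

The package ships a simulator that generates a complete synthetic study:
a 500 kb nuclear genome in five contigs, a 300 kb mitogenome as two
contigs, a 150 kb plastome as one contig, one planted 8 kb numt and one
6 kb nupt, organelle copy ratios 20×/50× over 20× nuclear read depth, with
ground-truth PAF alignments and a truth SAM:

```
organsweep simulate -output demo/sim --seed 7
organsweep run -raw_genome demo/sim/assembly.fasta \
    -mito_ref demo/sim/mito_ref.fasta -chlo_ref demo/sim/chlo_ref.fasta \
    -alignment demo/sim/alignments.paf -depth_sam demo/sim/reads.sam \
    -output demo/out --seed 7
```

which prints `8 contigs in -> 5 clean + 3 organelle` and writes
`demo/out/scatter.tsv`:

```
contig_id  mito_ALCR  mito_SDR  chlo_ALCR  chlo_SDR  category
contig_1   0.000000   0.050000  0.000000   0.020000  nuclear
contig_2   0.038462   0.050001  0.000000   0.020000  hgt_candidate
contig_3   0.000000   0.049995  0.000000   0.019998  nuclear
contig_4   0.000000   0.050002  0.056604   0.020001  hgt_candidate
contig_5   0.000000   0.050000  0.000000   0.020000  nuclear
contig_6   1.000000   1.000000  0.000000   0.400000  organelle_mito
contig_7   1.000000   1.000000  0.000000   0.400000  organelle_mito
contig_8   0.000000   2.500000  1.000000   1.000000  organelle_chlo
```

The three organelle-source contigs show ALCR = 1 and SDR = 1 and are
removed to `organelle_mito.fasta` / `organelle_chlo.fasta`. The numt
contig (`contig_2`: 8 kb of mitochondrial sequence in 208 kb, ALCR 0.038)
and the nupt contig (`contig_4`) are flagged `hgt_candidate` and retained
in `clean.fasta`. Nuclear contigs sit at SDR = 1/20 (mito) and 1/50
(chlo), far below organelle depth. `baseline_comparison.tsv` shows what a
longest-alignment-only screen would have done: it flags `contig_2` and
`contig_4` (8 kb and 6 kb single alignments > 5 kb) as organelle —
deleting 314 kb of real nuclear sequence that the ALCR/SDR rule keeps.

Thresholds can be revised without re-aligning anything (the two-round
workflow): `organsweep reclassify -metrics demo/out/metrics.tsv
-mito_ALCR_cutoff 0.8 -output demo/round2`.

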