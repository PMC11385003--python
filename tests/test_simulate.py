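"""The synthetic-data generator: determinism, truth bookkeeping, depth law."""

import numpy as np
import pysam
import pytest

from organsweep.classify import Category
from organsweep.core import RefClass
from organsweep.depth import depth_from_sam
from organsweep.errors import ContractError
from organsweep.io import read_fasta
from organsweep.simulate import (
    ContigSpec,
    HgtInsert,
    SimConfig,
    Source,
    apply_hgt_inserts,
    depth_targets,
    generate,
    make_contigs,
    make_genomes,
    plant_hgt,
    revcomp,
    simulate_read_pairs,
    standard_scenario,
    truth_alignments,
    write_sam,
)

from .conftest import mini_config


def small_cfg(seed=3, **kw):
    defaults = dict(
        seed=seed,
        nuclear_len=20_000,
        mito_len=6_000,
        chlo_len=3_000,
        copy_ratio={RefClass.MITO: 10.0, RefClass.CHLO: 10.0},
        nuclear_depth=5.0,
        read_len=100,
        frag_len=250,
        contig_plan=(
            ContigSpec(Source.NUCLEAR, 0, 20_000),
            ContigSpec(Source.MITO, 0, 6_000),
            ContigSpec(Source.CHLO, 0, 3_000),
        ),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenomes:
    def test_deterministic_under_seed(self):
        a, b = make_genomes(small_cfg()), make_genomes(small_cfg())
        assert a.nuclear.seq == b.nuclear.seq
        assert a.mito.seq == b.mito.seq and a.chlo.seq == b.chlo.seq
        c = make_genomes(small_cfg(seed=4))
        assert c.nuclear.seq != a.nuclear.seq

    def test_lengths_honored(self):
        g = make_genomes(small_cfg())
        assert (len(g.nuclear.seq), len(g.mito.seq), len(g.chlo.seq)) == (
            20_000, 6_000, 3_000,
        )

    def test_base_composition_near_uniform(self):
        g = make_genomes(small_cfg(nuclear_len=100_000))
        counts = {b: g.nuclear.seq.count(b) for b in "ACGT"}
        for b, n in counts.items():
            assert abs(n / 100_000 - 0.25) < 0.02, (b, n)


class TestPlantHgt:
    def test_zero_length_insert_unchanged(self):
        g = make_genomes(small_cfg())
        rng = np.random.default_rng(0)
        seq, span = plant_hgt(g.nuclear.seq, g.mito, RefClass.MITO, 0, 100, rng)
        assert seq == g.nuclear.seq and span.length == 0

    def test_grows_by_insert_len_and_window_matches_source(self):
        g = make_genomes(small_cfg())
        rng = np.random.default_rng(0)
        seq, span = plant_hgt(g.nuclear.seq, g.mito, RefClass.MITO, 500, 1_000, rng)
        assert len(seq) == len(g.nuclear.seq) + 500
        assert seq[span.start : span.end] == g.mito.seq[span.ref_start : span.ref_end]
        assert seq[: span.start] == g.nuclear.seq[: 1_000]
        assert seq[span.end :] == g.nuclear.seq[1_000:]

    def test_insert_longer_than_organelle_rejected(self):
        g = make_genomes(small_cfg())
        with pytest.raises(ContractError):
            plant_hgt(g.nuclear.seq, g.chlo, RefClass.CHLO, 10_000, 0,
                      np.random.default_rng(0))

    def test_multiple_inserts_shift_downstream_coordinates(self):
        cfg = small_cfg(
            hgt_inserts=(
                HgtInsert(RefClass.MITO, 1_000, 2_000),
                HgtInsert(RefClass.CHLO, 500, 5_000),
            )
        )
        genomes, spans = apply_hgt_inserts(make_genomes(cfg), cfg)
        assert len(genomes.nuclear.seq) == 20_000 + 1_500
        assert (spans[0].start, spans[0].end) == (2_000, 3_000)
        # second offset shifted by the first 1 kb insert
        assert (spans[1].start, spans[1].end) == (6_000, 6_500)
        for span in spans:
            ref = genomes.of_class(span.ref_class)
            assert (
                genomes.nuclear.seq[span.start : span.end]
                == ref.seq[span.ref_start : span.ref_end]
            )


class TestMakeContigs:
    def test_whole_organelle_contig(self):
        cfg = small_cfg()
        genomes = make_genomes(cfg)
        contigs, truths = make_contigs(genomes, cfg)
        assert truths[1].source is Source.MITO
        assert truths[1].expected_category is Category.ORGANELLE_MITO
        assert contigs[1].seq == genomes.mito.seq

    def test_hgt_spans_shift_to_contig_space(self):
        cfg = mini_config()
        genomes, spans = apply_hgt_inserts(make_genomes(cfg), cfg)
        contigs, truths = make_contigs(genomes, cfg, spans)
        numt = truths[0]
        assert numt.expected_category is Category.HGT_CANDIDATE
        (span,) = numt.hgt_spans
        assert (span.start, span.end) == (5_000, 11_000)
        assert (
            contigs[0].seq[span.start : span.end]
            == genomes.mito.seq[span.ref_start : span.ref_end]
        )
        # windows that miss the insert carry no spans
        assert truths[1].hgt_spans == []
        assert truths[1].expected_category is Category.NUCLEAR

    def test_out_of_range_plan_rejected(self):
        cfg = small_cfg(contig_plan=(ContigSpec(Source.CHLO, 0, 99_999),))
        with pytest.raises(ContractError):
            make_contigs(make_genomes(cfg), cfg)

    def test_collapsed_repeat_contig_expected_ambiguous(self):
        cfg = small_cfg(collapsed_repeat_depth={"contig_1": 30.0})
        _, truths = make_contigs(make_genomes(cfg), cfg)
        assert truths[0].expected_category is Category.AMBIGUOUS_HIGH_SDR


class TestTruthAlignments:
    def test_blocks_per_provenance(self):
        cfg = mini_config()
        genomes, spans = apply_hgt_inserts(make_genomes(cfg), cfg)
        contigs, truths = make_contigs(genomes, cfg, spans)
        lines = [ln.split("\t") for ln in truth_alignments(contigs, truths, genomes)]
        by_query = {}
        for ln in lines:
            by_query.setdefault(ln[0], []).append(ln)
        # pure nuclear contig: no lines; numt contig: one 6 kb block
        assert "contig_2" not in by_query
        (numt_line,) = by_query["contig_1"]
        assert int(numt_line[3]) - int(numt_line[2]) == 6_000
        assert numt_line[5] == "mito_ref"
        # whole-organelle contig: a single full-length block
        (mito_line,) = by_query["contig_3"]
        assert (int(mito_line[2]), int(mito_line[3])) == (0, 20_000)

    def test_min_block_filters_short_spans(self):
        cfg = small_cfg(hgt_inserts=(HgtInsert(RefClass.MITO, 50, 1_000),))
        genomes, spans = apply_hgt_inserts(make_genomes(cfg), cfg)
        contigs, truths = make_contigs(genomes, cfg, spans)
        lines = truth_alignments(contigs, truths, genomes, min_block=100)
        assert all(ln.split("\t")[0] != "contig_1" for ln in lines)
        lines = truth_alignments(contigs, truths, genomes, min_block=10)
        assert any(ln.split("\t")[0] == "contig_1" for ln in lines)


class TestReads:
    def test_zero_depth_gives_no_reads(self):
        cfg = small_cfg()
        g = make_genomes(cfg)
        pairs = list(
            simulate_read_pairs(g.mito, 0.0, True, cfg, np.random.default_rng(0))
        )
        assert pairs == []

    def test_read_longer_than_target_rejected(self):
        cfg = small_cfg(read_len=5_000, frag_len=5_000)
        g = make_genomes(cfg)
        with pytest.raises(ContractError):
            list(simulate_read_pairs(g.chlo, 1.0, False, cfg, np.random.default_rng(0)))

    def test_pairs_match_target_including_circular_wrap(self):
        cfg = small_cfg()
        g = make_genomes(cfg)
        rng = np.random.default_rng(1)
        doubled = g.chlo.seq * 2
        wrapped = 0
        for pair in simulate_read_pairs(g.chlo, 20.0, True, cfg, rng):
            assert pair.seq1 == doubled[pair.pos1 : pair.pos1 + cfg.read_len]
            assert pair.seq2 == doubled[pair.pos2 : pair.pos2 + cfg.read_len]
            wrapped += pair.pos1 + cfg.read_len > len(g.chlo.seq)
        assert wrapped > 0  # origin-spanning fragments do occur

    def test_truth_sam_records_match_reference_substrings(self, mini_scenario):
        res = mini_scenario
        seqs = {r.id: r.seq for r in res.contigs}
        seqs[res.genomes.mito.id] = res.genomes.mito.seq
        seqs[res.genomes.chlo.id] = res.genomes.chlo.seq
        n = 0
        with pysam.AlignmentFile(str(res.paths["sam"]), "r") as sam:
            for rec in sam:
                ref = seqs[rec.reference_name]
                expected = ref[rec.reference_start : rec.reference_start + rec.query_length]
                assert rec.query_sequence == expected
                n += 1
                if n >= 2_000:
                    break
        assert n == 2_000

    def test_fastq_mates_are_reverse_complements_of_sam(self, mini_scenario):
        res = mini_scenario
        with open(res.paths["fastq2"]) as fq:
            head = [next(fq) for _ in range(8)]
        qname = head[0][1:].strip().removesuffix("/2")
        seq = head[1].strip()
        target_id = qname.rsplit(":", 1)[0]
        seqs = {r.id: r.seq for r in res.contigs}
        seqs[res.genomes.mito.id] = res.genomes.mito.seq
        seqs[res.genomes.chlo.id] = res.genomes.chlo.seq
        assert revcomp(seq) in (seqs[target_id] * 2)

    def test_depth_law(self, tmp_path):
        """Realized organelle/nuclear depth ratio tracks the copy ratio."""
        cfg = small_cfg(
            nuclear_len=50_000, mito_len=15_000,
            copy_ratio={RefClass.MITO: 10.0, RefClass.CHLO: 10.0},
            nuclear_depth=8.0,
            contig_plan=(
                ContigSpec(Source.NUCLEAR, 0, 50_000),
                ContigSpec(Source.MITO, 0, 15_000),
            ),
        )
        genomes = make_genomes(cfg)
        contigs, truths = make_contigs(genomes, cfg)
        targets = depth_targets(contigs, truths, genomes, cfg)
        sam = tmp_path / "r.sam"
        write_sam(sam, targets, cfg, np.random.default_rng(9))
        profiles = {p.seq_id: p for p in depth_from_sam(sam, [t[0] for t in targets])}
        nuclear_mean = profiles["contig_1"].mean
        mito_mean = profiles["contig_2"].mean
        assert nuclear_mean == pytest.approx(8.0, rel=0.05)
        assert mito_mean == pytest.approx(80.0, rel=0.05)
        assert mito_mean / nuclear_mean == pytest.approx(10.0, rel=0.10)


class TestGenerate:
    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        cfg = small_cfg()
        a = generate(cfg, tmp_path / "a", write_fastq=True)
        b = generate(cfg, tmp_path / "b", write_fastq=True)
        for key in a.paths:
            assert a.paths[key].read_bytes() == b.paths[key].read_bytes(), key

    def test_truth_table_matches_records(self, mini_scenario):
        res = mini_scenario
        lines = res.paths["truth"].read_text().splitlines()
        assert lines[0].startswith("contig_id\t")
        rows = [ln.split("\t") for ln in lines[1:]]
        assert [r[0] for r in rows] == [t.contig_id for t in res.truths]
        assert [r[4] for r in rows] == [t.expected_category.value for t in res.truths]

    def test_assembly_fasta_round_trips(self, mini_scenario):
        recs = read_fasta(mini_scenario.paths["assembly"])
        assert recs == mini_scenario.contigs


def test_standard_scenario_shape():
    cfg = standard_scenario(1)
    assert len(cfg.contig_plan) == 8
    assert sum(s.source is Source.NUCLEAR for s in cfg.contig_plan) == 5
    assert cfg.copy_ratio[RefClass.MITO] == 20.0
    assert cfg.copy_ratio[RefClass.CHLO] == 50.0
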