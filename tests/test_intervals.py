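"""Interval model, file round-trips, and oracle agreement for set operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texapt.intervals import (
    BedParseError,
    GenomeTable,
    GenomicInterval,
    SchemaError,
    TranscriptModel,
    intersect,
    read_bed,
    read_bed12,
    read_te_table,
    split_intersect,
    subtract,
    window_intersect,
    write_bed,
    write_bed12,
    write_te_table,
)
from conftest import make_copy, oracle_pairs, random_intervals


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_genome_table_validation(self, toy_genome):
        toy_genome.validate([GenomicInterval("chr1", 0, 10_000)])
        with pytest.raises(ValueError):
            toy_genome.validate([GenomicInterval("chr1", 0, 10_001)])
        with pytest.raises(ValueError):
            toy_genome.validate([GenomicInterval("chrX", 0, 10)])
        with pytest.raises(ValueError):
            GenomeTable([("chr1", 10), ("chr1", 20)])


class TestBedIO:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tx\t0\t+\n")
        (iv,) = read_bed(p)
        assert iv == GenomicInterval("chr1", 10, 20, "+", "x")

    def test_inverted_coordinates_name_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t5\nchr1\t20\t10\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_round_trip(self, tmp_path, rng):
        ivs = random_intervals(rng, 50, stranded=True)
        ivs = [GenomicInterval(i.chrom, i.start, i.end, i.strand, f"n{k}", float(k))
               for k, i in enumerate(ivs)]
        p = tmp_path / "rt.bed"
        write_bed(p, ivs)
        assert read_bed(p) == ivs

    def test_strand_required_flag(self, tmp_path):
        p = tmp_path / "n.bed"
        p.write_text("chr1\t1\t5\n")
        assert read_bed(p)[0].strand == "."
        with pytest.raises(BedParseError):
            read_bed(p, expect_strand=True)


class TestTETableIO:
    def test_row_mapping_and_rejection(self, tmp_path, caplog):
        p = tmp_path / "te.tsv"
        p.write_text(
            "#chrom\tstart\tend\tstrand\tclass\tfamily\tsubfamily\t"
            "repStart\trepEnd\tconsensusLength\n"
            "chr1\t100\t400\t+\tSINE\tMIR\tMIRb\t10\t262\t262\n"
            "chr1\t500\t600\t+\tSINE\tMIR\tMIRb\t50\t20\t262\n"  # repStart > repEnd
        )
        copies = read_te_table(p)
        assert len(copies) == 1
        assert (copies[0].rep_start, copies[0].rep_end) == (10, 262)
        assert copies[0].te_subfamily == "MIRb"

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "te.tsv"
        p.write_text("#chrom\tstart\tend\nchr1\t1\t2\n")
        with pytest.raises(SchemaError):
            read_te_table(p)

    def test_empty_file_and_round_trip(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_te_table(p) == []
        copies = [make_copy("chr1", 100, 400, rep_start=10, rep_end=262,
                            consensus_length=262)]
        write_te_table(p, copies)
        assert read_te_table(p) == copies


class TestIntersect:
    def test_single_bp_overlap_and_half_open_touching(self):
        q = [GenomicInterval("chr1", 10, 20)]
        assert intersect(q, [GenomicInterval("chr1", 19, 30)]) == [(0, 0)]
        assert intersect(q, [GenomicInterval("chr1", 20, 30)]) == []

    def test_min_overlap_threshold(self):
        q = [GenomicInterval("chr1", 10, 20)]
        s = [GenomicInterval("chr1", 15, 30)]
        assert intersect(q, s, min_overlap=5) == [(0, 0)]
        assert intersect(q, s, min_overlap=6) == []

    def test_strand_match(self):
        q = [GenomicInterval("chr1", 10, 20, "+")]
        s = [GenomicInterval("chr1", 10, 20, "-"), GenomicInterval("chr1", 10, 20, "+")]
        assert intersect(q, s, strand_match=True) == [(0, 1)]
        assert intersect(q, s) == [(0, 0), (0, 1)]

    def test_matches_oracle_on_random_instances(self, rng):
        q = random_intervals(rng, 200, stranded=True)
        s = random_intervals(rng, 200, stranded=True)
        for strand_match in (False, True):
            for mo in (1, 25):
                assert intersect(q, s, strand_match, mo) == oracle_pairs(
                    q, s, strand_match, mo
                )


class TestWindowIntersect:
    @pytest.mark.parametrize(
        "w,expected", [(300, [(0, 0)]), (100, []), (191, [(0, 0)]), (190, [])]
    )
    def test_gap_vs_window(self, w, expected):
        q = [GenomicInterval("chr1", 1000, 1010)]
        s = [GenomicInterval("chr1", 1200, 1210)]
        assert window_intersect(q, s, w) == expected

    def test_w_zero_is_intersect(self, rng):
        q = random_intervals(rng, 100)
        s = random_intervals(rng, 100)
        assert window_intersect(q, s, 0) == intersect(q, s)

    def test_clipping_at_chromosome_bounds(self, toy_genome):
        q = [GenomicInterval("chr1", 9_990, 10_000)]
        s = [GenomicInterval("chr1", 9_995, 10_000)]
        assert window_intersect(q, s, 500, genome=toy_genome) == [(0, 0)]


class TestSplitIntersect:
    @pytest.fixture
    def model(self):
        return TranscriptModel(
            interval=GenomicInterval("chr1", 100, 1000, "+", "t1|g1"),
            exons=((100, 200), (500, 600), (900, 1000)),
            transcript_id="t1", gene_id="g1",
        )

    def test_intron_only_overlap_yields_no_pair(self, model):
        probe = [GenomicInterval("chr1", 300, 400, "+")]
        assert split_intersect(probe, [model]) == []

    def test_one_bp_into_exon_yields_pair(self, model):
        probe = [GenomicInterval("chr1", 400, 501, "+")]
        assert split_intersect(probe, [model]) == [(0, 0)]

    def test_strand_mismatch_blocks(self, model):
        probe = [GenomicInterval("chr1", 150, 160, "-")]
        assert split_intersect(probe, [model]) == []
        assert split_intersect(probe, [model], strand_match=False) == [(0, 0)]

    def test_matches_exploded_exon_oracle(self, rng):
        models = []
        for k in range(30):
            start = int(rng.integers(0, 5000))
            exons = tuple(
                (start + off, start + off + 80) for off in (0, 300, 700)
            )
            models.append(
                TranscriptModel(
                    interval=GenomicInterval("chr1", start, start + 780,
                                             ("+", "-")[k % 2], f"t{k}|g{k}"),
                    exons=exons, transcript_id=f"t{k}", gene_id=f"g{k}",
                )
            )
        probes = random_intervals(rng, 150, chroms=("chr1",), max_pos=6000,
                                  max_len=120, stranded=True)
        expected = set()
        for ti, m in enumerate(models):
            pairs = oracle_pairs(probes, m.exon_intervals(), strand_match=True)
            expected.update((qi, ti) for qi, _ in pairs)
        assert split_intersect(probes, models) == sorted(expected)


class TestSubtract:
    def test_examples(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr1", 100, 110)
        hit = [GenomicInterval("chr1", 105, 120)]
        assert subtract([a, b], hit) == [a]
        assert subtract([a, b], []) == [a, b]

    def test_matches_oracle_complement(self, rng):
        q = random_intervals(rng, 150)
        s = random_intervals(rng, 150)
        hit = {qi for qi, _ in oracle_pairs(q, s)}
        assert subtract(q, s) == [iv for i, iv in enumerate(q) if i not in hit]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    start=st.integers(0, 1000),
    length=st.integers(1, 100),
    gap=st.integers(0, 50),
)
def test_touching_intervals_never_intersect(start, length, gap):
    """Half-open property: a gap of 0 (shared boundary) is never an overlap."""
    a = [GenomicInterval("chr1", start, start + length)]
    b = [GenomicInterval("chr1", start + length + gap, start + length + gap + 10)]
    assert intersect(a, b) == []
    assert intersect(b, a) == []


def test_bed12_round_trip(tmp_path):
    t = TranscriptModel(
        interval=GenomicInterval("chr1", 100, 1000, "-", "tx1|geneA"),
        exons=((100, 250), (600, 1000)),
        transcript_id="tx1", gene_id="geneA", tier="lncRNA_tier1",
    )
    p = tmp_path / "t.bed12"
    write_bed12(p, [t])
    (back,) = read_bed12(p, tier="lncRNA_tier1")
    assert back == t
    assert back.tss == 999
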