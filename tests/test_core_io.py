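"""Format round-trips, coordinate conventions and index correctness."""
import numpy as np
import pytest

from delscan import io as dio
from delscan.core import Annotation, GenomicInterval, Genotype
from delscan.consensus import ConsensusDeletion

from conftest import random_annotation


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
"""


class TestReadDeletionsVcf:
    def test_symbolic_record_uses_pos_end(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER +
                  "chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\tGT\t0/1\n")
        (call,) = dio.read_deletions_vcf(p, "manta")
        assert (call.interval.start, call.interval.end) == (1000, 1500)
        assert call.interval.length == 500
        assert call.genotype is Genotype.REF_DEL

    def test_explicit_record_padding_base(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER +
                  "chr1\t100\t.\tACGTA\tA\t.\tPASS\t.\tGT\t1/1\n")
        (call,) = dio.read_deletions_vcf(p, "manta")
        assert (call.interval.start, call.interval.end) == (100, 104)
        assert call.genotype is Genotype.DEL_DEL

    def test_non_del_records_skipped_with_tally(self, tmp_path):
        body = (
            "chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\tGT\t0/1\n"
            "chr1\t2000\t.\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=2500\tGT\t0/1\n"
            "chr1\t3000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=3700\tGT\t1/1\n"
        )
        counts = {}
        calls = dio.read_deletions_vcf(write(tmp_path, "a.vcf", VCF_HEADER + body),
                                       "manta", counts)
        assert len(calls) == 2
        assert counts == {"parsed": 2, "skipped_non_del": 1, "rejected": 0}

    def test_malformed_end_rejected(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER +
                  "chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=900\tGT\t0/1\n")
        counts = {}
        assert dio.read_deletions_vcf(p, "manta", counts) == []
        assert counts["rejected"] == 1

    def test_svlen_only_and_end_wins_over_svlen(self, tmp_path):
        body = (
            "chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-600\tGT\t0/1\n"
            "chr1\t5000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5800;SVLEN=-900\tGT\t0/1\n"
        )
        calls = dio.read_deletions_vcf(write(tmp_path, "a.vcf", VCF_HEADER + body), "m")
        assert calls[0].interval.end == 1600       # from |SVLEN|
        assert calls[1].interval.end == 5800       # END wins

    def test_missing_gt_is_missing_genotype(self, tmp_path):
        p = write(tmp_path, "a.vcf", VCF_HEADER +
                  "chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\tGT\t./.\n")
        (call,) = dio.read_deletions_vcf(p, "manta")
        assert call.genotype is Genotype.MISSING

    def test_unparseable_file_is_hard_error(self, tmp_path):
        p = write(tmp_path, "bad.vcf", "this is not a vcf\n")
        with pytest.raises(ValueError, match="cannot parse"):
            dio.read_deletions_vcf(p, "manta")

    def test_empty_caller_id_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            dio.read_deletions_vcf(tmp_path / "x.vcf", "")


GFF = """\
##gff-version 3
chr1\tsrc\tgene\t10\t100\t.\t+\t.\tID=gA;gene_biotype=protein_coding
chr1\tsrc\tmRNA\t10\t100\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\tsrc\texon\t10\t40\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr2\tsrc\tgene\t200\t400\t.\t-\t.\tID=gB;gene_biotype=protein_coding
chr2\tsrc\texon\t200\t300\t.\t-\t.\tID=gB.e1;Parent=gB
"""


class TestReadGff3:
    def test_coordinate_conversion_and_both_chroms(self, tmp_path):
        ann = dio.read_gff3(write(tmp_path, "a.gff3", GFF))
        assert ann.chromosomes == ["chr1", "chr2"]
        ga = next(g for g in ann if g.gene_id == "gA")
        assert (ga.span.start, ga.span.end) == (9, 100)
        assert (ga.exons[0].start, ga.exons[0].end) == (9, 40)

    def test_orphan_exon_is_hard_error(self, tmp_path):
        bad = GFF + "chr2\tsrc\texon\t350\t380\t.\t-\t.\tID=x;Parent=absent\n"
        with pytest.raises(ValueError, match="Parent"):
            dio.read_gff3(write(tmp_path, "a.gff3", bad))

    def test_exon_outside_gene_span_is_hard_error(self, tmp_path):
        bad = GFF + "chr2\tsrc\texon\t390\t500\t.\t-\t.\tID=y;Parent=gB\n"
        with pytest.raises(ValueError, match="outside"):
            dio.read_gff3(write(tmp_path, "a.gff3", bad))

    def test_gff3_roundtrip_via_writer(self, tmp_path):
        rng = np.random.default_rng(11)
        ann = random_annotation(rng, n_genes=20)
        dio.write_gff3(ann, tmp_path / "out.gff3")
        back = dio.read_gff3(tmp_path / "out.gff3")
        assert [(g.gene_id, g.span, g.exons, g.biotype, g.strand) for g in back] == [
            (g.gene_id, g.span, g.exons, g.biotype, g.strand) for g in ann
        ]


class TestConsensusVcfRoundTrip:
    def test_write_then_read_preserves_intervals_and_genotypes(self, tmp_path):
        calls = [
            ConsensusDeletion(GenomicInterval("chr1", 1000 * i, 1000 * i + 600),
                              f"s{i % 2}", Genotype.REF_DEL if i % 2 else Genotype.DEL_DEL,
                              0.8, ("a", "b"), ("manta", "lumpy"))
            for i in range(1, 6)
        ]
        dio.write_consensus_vcf(calls, tmp_path / "c.vcf")
        back = dio.read_deletions_vcf(tmp_path / "c.vcf", "consensus")
        kept = [(c.interval, c.sample_id, c.genotype) for c in back
                if c.genotype is not Genotype.MISSING]
        assert sorted(kept, key=lambda t: (t[0].start, t[1])) == sorted(
            [(c.interval, c.sample_id, c.genotype) for c in calls],
            key=lambda t: (t[0].start, t[1]),
        )


class TestBedGmtHits:
    def test_bed_roundtrip(self, tmp_path):
        ivs = [GenomicInterval("chr1", 999, 1500), GenomicInterval("chr2", 0, 5)]
        dio.write_bed(ivs, tmp_path / "a.bed")
        assert (tmp_path / "a.bed").read_text().splitlines()[0] == "chr1\t999\t1500"
        assert dio.read_bed(tmp_path / "a.bed") == ivs

    def test_gmt_membership_and_short_line_skip(self, tmp_path):
        p = write(tmp_path, "a.gmt", "pathA\tdesc\tg1\tg2\nshortline\nB\td\tg3\n")
        sets = dio.read_gmt(p)
        assert set(sets) == {"pathA", "B"}
        assert sets["pathA"].genes == frozenset({"g1", "g2"})

    def test_gmt_roundtrip(self, tmp_path):
        sets = [dio.GeneSet("s1", "d1", frozenset({"a", "b"})),
                dio.GeneSet("s2", "d2", frozenset({"c"}))]
        dio.write_gmt(sets, tmp_path / "x.gmt")
        back = dio.read_gmt(tmp_path / "x.gmt")
        assert {n: gs.genes for n, gs in back.items()} == {
            "s1": frozenset({"a", "b"}), "s2": frozenset({"c"})
        }

    def test_hits_roundtrip_and_bad_evalue(self, tmp_path):
        row = "m1\tchr1\t98.5\t120\t1\t0\t1\t120\t501\t620\t1e-50\t222.0\n"
        hits = dio.read_hits_tsv(write(tmp_path, "h.tsv", row))
        assert hits[0].marker_id == "m1" and hits[0].evalue == 1e-50
        dio.write_hits_tsv(hits, tmp_path / "h2.tsv")
        assert dio.read_hits_tsv(tmp_path / "h2.tsv") == hits
        bad = row.replace("1e-50", "notanumber")
        with pytest.raises(ValueError, match="evalue"):
            dio.read_hits_tsv(write(tmp_path, "bad.tsv", bad))


class TestAnnotationIndex:
    def test_index_queries_equal_linear_scan(self):
        rng = np.random.default_rng(5)
        ann = random_annotation(rng, n_genes=60)
        for _ in range(300):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, 900_000))
            iv = GenomicInterval(chrom, start, start + int(rng.integers(1, 30_000)))
            expected = sorted(
                (g for g in ann if g.span.overlaps(iv)),
                key=lambda g: (g.span.start, g.gene_id),
            )
            assert ann.overlapping(iv) == expected
            flank = int(rng.integers(0, 3000))
            expected_fl = sorted(
                (
                    g for g in ann
                    if g.span.chrom == chrom
                    and min(g.span.end + flank, iv.end) > max(g.span.start - flank, iv.start)
                ),
                key=lambda g: (g.span.start, g.gene_id),
            )
            assert ann.overlapping_flanked(iv, flank) == expected_fl

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
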