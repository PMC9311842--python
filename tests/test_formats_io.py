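"""I/O dialect: VCF field mapping, BED conventions, reports, round trips."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from transdx.formats_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DialectError,
    GenomicInterval,
    MeiRecord,
    SamplePanel,
    SourceDescriptor,
    TransductionRecord,
    TransSegment,
    read_bed,
    read_chrom_sizes,
    read_mei_vcf,
    write_mei_vcf,
    write_report,
)

MINI_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=SR,Number=1,Type=Integer,Description="x">
##INFO=<ID=ASSESS,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=SUBFAM,Number=1,Type=String,Description="x">
##INFO=<ID=MESOURCE,Number=1,Type=String,Description="x">
##INFO=<ID=METRANS,Number=1,Type=String,Description="x">
##INFO=<ID=XTRA,Number=1,Type=String,Description="pass-through">
##FILTER=<ID=rSD,Description="x">
##FILTER=<ID=lc,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body: str) -> Path:
    p = tmp_path / "mini.vcf"
    p.write_text(MINI_HEADER + body)
    return p


class TestReadMeiVcf:
    def test_field_mapping(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:L1>\t.\tPASS\t"
            "SR=6;ASSESS=5;SVLEN=6100;SUBFAM=L1HS\tGT\t0/1\t0/0\n",
        )
        (rec,) = read_mei_vcf(p)
        assert (rec.sr, rec.assess, rec.svlen) == (6, 5, 6100)
        assert rec.filter_flags == {"PASS"}
        assert rec.me_type == "L1" and rec.subfamily == "L1HS"
        assert list(rec.genotypes) == [HET, HOM_REF]
        assert not rec.is_transduction

    def test_multi_filter_split_and_missing_gt(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:SVA>\t.\trSD;lc\t"
            "SR=3;ASSESS=3;SVLEN=900;SUBFAM=SVA_E\tGT\t./.\t1/1\n",
        )
        (rec,) = read_mei_vcf(p)
        assert rec.filter_flags == {"rSD", "lc"}
        assert list(rec.genotypes) == [MISSING, HOM_ALT]

    def test_null_metrans_is_plain_record(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:L1>\t.\tPASS\t"
            "SR=6;ASSESS=5;SVLEN=6100;SUBFAM=L1HS;"
            "MESOURCE=chrX|1|2|+|L1HS|reference|50;METRANS=null\tGT\t0/1\t0/0\n",
        )
        (rec,) = read_mei_vcf(p)
        assert not rec.is_transduction
        assert not isinstance(rec, TransductionRecord)
        assert "MESOURCE" in rec.extra  # stray source preserved

    def test_metrans_present_yields_transduction(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:L1>\t.\tPASS\t"
            "SR=6;ASSESS=5;SVLEN=6100;SUBFAM=L1HS;"
            "MESOURCE=chrX|10|20|+|L1HS|reference|50;"
            "METRANS=chrX|20|70|+\tGT\t0/1\t0/0\n",
        )
        (rec,) = read_mei_vcf(p)
        assert isinstance(rec, TransductionRecord)
        assert rec.mesource.transduced_length == 50
        assert rec.metrans == TransSegment("chrX", 20, 70, "+")

    def test_unknown_info_passthrough(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:L1>\t.\tPASS\t"
            "SR=6;ASSESS=5;SVLEN=6100;SUBFAM=L1HS;XTRA=hello\tGT\t0/1\t0/0\n",
        )
        (rec,) = read_mei_vcf(p)
        assert rec.extra == {"XTRA": "hello"}

    @pytest.mark.parametrize(
        "alt,gts",
        [
            ("<INS:ME:L1>,<INS:ME:SVA>", "0/1\t0/0"),  # multi-allelic
            ("<INS:ME:L1>", "0\t0/0"),  # haploid
            ("<INS:ME:L1>", "0/1/1\t0/0"),  # triploid
        ],
    )
    def test_dialect_errors_name_line(self, tmp_path, alt, gts):
        p = _write_vcf(
            tmp_path,
            f"chr1\t100\tv1\tN\t{alt}\t.\tPASS\t"
            f"SR=6;ASSESS=5;SVLEN=100;SUBFAM=L1HS\tGT\t{gts}\n",
        )
        with pytest.raises(DialectError, match="line"):
            read_mei_vcf(p)

    def test_panel_sample_mismatch(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<INS:ME:L1>\t.\tPASS\t"
            "SR=6;ASSESS=5;SVLEN=100;SUBFAM=L1HS\tGT\t0/1\t0/0\n",
        )
        panel = SamplePanel(
            pd.DataFrame(
                {
                    "sample": ["A", "B", "C"],
                    "population": ["YRI"] * 3,
                    "super_population": ["AFR"] * 3,
                    "sex": ["F"] * 3,
                }
            )
        )
        with pytest.raises(DialectError, match="panel"):
            read_mei_vcf(p, panel)


def test_vcf_round_trip_is_byte_identical(bundle, panel, records, tmp_path):
    """read -> write reproduces the synthetic cohort's VCF byte for byte."""
    out = tmp_path / "roundtrip.vcf"
    sizes = read_chrom_sizes(bundle.chrom_sizes_tsv)
    write_mei_vcf(records, out, panel.samples, sizes)
    assert out.read_bytes() == Path(bundle.vcf).read_bytes()


def test_transduction_partition_of_read_records(records):
    """TransductionRecord iff METRANS non-null; plain records otherwise."""
    for r in records:
        assert r.is_transduction == isinstance(r, TransductionRecord)
        if r.is_transduction:
            assert r.metrans is not None


class TestBed:
    def test_six_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrX 11707247 11713279 L1HS + L1\n")
        (iv,) = read_bed(p)
        assert iv.length == 6032
        assert (iv.name, iv.strand, iv.me_type, iv.subfamily) == (
            "L1HS", "+", "L1", "L1HS",
        )

    def test_three_column_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        (iv,) = read_bed(p)
        assert (iv.name, iv.strand, iv.subfamily) == ("", ".", "")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_inverted_interval_errors_with_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t30\t30\n")
        with pytest.raises(DialectError, match="line 2"):
            read_bed(p)


class TestPanel:
    def test_duplicate_sample_rejected(self):
        df = pd.DataFrame(
            {
                "sample": ["A", "A"],
                "population": ["YRI", "YRI"],
                "super_population": ["AFR", "AFR"],
                "sex": ["F", "M"],
            }
        )
        with pytest.raises(DialectError, match="duplicate"):
            SamplePanel(df)

    def test_population_must_map_to_one_superpop(self):
        df = pd.DataFrame(
            {
                "sample": ["A", "B"],
                "population": ["YRI", "YRI"],
                "super_population": ["AFR", "EUR"],
                "sex": ["F", "M"],
            }
        )
        with pytest.raises(DialectError, match="multiple super-populations"):
            SamplePanel(df)

    def test_group_indexing(self, panel):
        assert len(panel.indices_for("ALL")) == len(panel)
        afr = panel.indices_for("AFR")
        yri = panel.indices_for("YRI")
        assert set(yri) <= set(afr)
        with pytest.raises(KeyError):
            panel.indices_for("NOPE")


class TestReports:
    def test_funnel_rows(self, tmp_path):
        p = tmp_path / "funnel.tsv"
        rows = [
            {"me_type": "L1", "n_total": 5, "n_removed_segdup": 1,
             "n_after_segdup": 4, "n_high": 3, "n_low": 1},
            {"me_type": "SVA", "n_total": 2, "n_removed_segdup": 0,
             "n_after_segdup": 2, "n_high": 1, "n_low": 1},
        ]
        write_report(rows, p, "funnel")
        lines = p.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t")[0] == "me_type"

    def test_empty_rows_header_only(self, tmp_path):
        p = tmp_path / "x.tsv"
        write_report([], p, "motifs")
        assert p.read_text().splitlines() == [
            "locus\telement\tsource_type\tpas\tuse\tdse"
        ]

    def test_missing_values_render_as_dot(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_report(
            [{"locus": "chr7:1-2", "element": "SVA_E", "source_type": "reference",
              "pas": "AAUAAA", "use": None, "dse": "GU-rich"}],
            p,
            "motifs",
        )
        assert p.read_text().splitlines()[1].split("\t")[4] == "."

    def test_unknown_schema(self, tmp_path):
        with pytest.raises(ValueError, match="unknown report schema"):
            write_report([], tmp_path / "x.tsv", "nope")


def test_descriptor_codecs_round_trip():
    src = SourceDescriptor("chrX", 11707247, 11713279, "+", "L1HS", "reference", 150)
    assert SourceDescriptor.decode(src.encode()) == src
    seg = TransSegment("chrX", 5, 10, "-")
    assert TransSegment.decode(seg.encode()) == seg
    with pytest.raises(DialectError):
        SourceDescriptor.decode("a|b")


def test_record_invariants():
    with pytest.raises(ValueError):
        MeiRecord("chr1", 0, "v", "L1", "L1HS", 10, 1, 1)
    with pytest.raises(ValueError):
        MeiRecord("chr1", 5, "v", "L1", "L1HS", -1, 1, 1)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
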