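"""Readers, writers and domain types for every file the pipeline touches.

The pipeline consumes mobile-element-insertion (MEI) call sets in a
restricted, documented VCF 4.2 dialect modelled on MELT output, plus
RepeatMasker-style element tracks and segmental-duplication tracks as BED,
a sample panel TSV, a chrom.sizes TSV and genome/flank FASTA. All
coordinate conventions are fixed here and nowhere else:

* VCF positions are 1-based (``pos`` is the insertion point);
* BED intervals are 0-based half-open ``[start, end)``.

Dialect INFO keys: ``SR`` (split-read count), ``ASSESS`` (breakpoint
evidence score), ``SVLEN`` (structural-variant length: TE plus transduced
segment for transduction calls), ``SUBFAM`` (element subfamily),
``MESOURCE`` (donor-locus descriptor) and ``METRANS`` (transduced-segment
descriptor). MELT does not publish an on-disk schema for the last two, so
this package defines a stand-in serialization::

    MESOURCE=chrom|start|end|strand|subfamily|source_type|transduced_length
    METRANS=chrom|start|end|strand          (or the literal ``null``)

FILTER values are drawn from {PASS, rSD, ac0, hDP, lc} and may be combined
with ``;``. Genotypes are unphased diploid biallelic; ``./.`` is missing.
Multi-allelic records and non-diploid calls are dialect errors, reported
with the offending line number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "NULL_MARKER",
    "MeiRecord",
    "TransductionRecord",
    "SourceDescriptor",
    "TransSegment",
    "GenomicInterval",
    "SamplePanel",
    "DialectError",
    "read_mei_vcf",
    "write_mei_vcf",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_fasta",
    "write_report",
    "REPORT_SCHEMAS",
]

# Genotype codes used throughout the package (np.int8 vectors).
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: Literal used by the caller dialect for "no transduced segment".
NULL_MARKER = "null"

ME_TYPES = ("L1", "SVA", "ALU")
FILTER_VOCAB = frozenset({"PASS", "rSD", "ac0", "hDP", "lc"})


class DialectError(ValueError):
    """A file violates the documented MEI dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceDescriptor:
    """Donor (progenitor) locus of a transduction, from the MESOURCE key.

    ``transduced_length`` is the length of the transduced segment measured
    at the source, *excluding* the TE body — whereas the offspring record's
    SVLEN includes the TE.
    """

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    source_type: str  # "reference" | "nonreference"
    transduced_length: int

    def __post_init__(self) -> None:
        if self.transduced_length < 0:
            raise ValueError("transduced_length must be >= 0")
        if self.source_type not in ("reference", "nonreference"):
            raise ValueError(f"bad source_type {self.source_type!r}")

    def encode(self) -> str:
        return "|".join(
            str(x)
            for x in (
                self.chrom,
                self.start,
                self.end,
                self.strand,
                self.subfamily,
                self.source_type,
                self.transduced_length,
            )
        )

    @classmethod
    def decode(cls, s: str) -> "SourceDescriptor":
        parts = s.split("|")
        if len(parts) != 7:
            raise DialectError(f"MESOURCE needs 7 '|'-fields, got {s!r}")
        c, st, en, strand, fam, typ, tl = parts
        return cls(c, int(st), int(en), strand, fam, typ, int(tl))


@dataclass(frozen=True)
class TransSegment:
    """Transduced-segment descriptor from the METRANS key."""

    chrom: str
    start: int
    end: int
    strand: str

    def encode(self) -> str:
        return f"{self.chrom}|{self.start}|{self.end}|{self.strand}"

    @classmethod
    def decode(cls, s: str) -> "TransSegment":
        parts = s.split("|")
        if len(parts) != 4:
            raise DialectError(f"METRANS needs 4 '|'-fields, got {s!r}")
        return cls(parts[0], int(parts[1]), int(parts[2]), parts[3])


@dataclass
class MeiRecord:
    """One polymorphic MEI call with QC fields and per-sample genotypes."""

    chrom: str
    pos: int  # 1-based insertion point
    variant_id: str
    me_type: str  # L1 | SVA | ALU
    subfamily: str  # or "UNDETERMINED"
    svlen: int | None
    assess: int | None
    sr: int | None
    filter_flags: frozenset[str] = frozenset()
    genotypes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for name in ("svlen", "sr", "assess"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        self.filter_flags = frozenset(self.filter_flags)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def is_transduction(self) -> bool:
        return False

    def genotype_counts(self) -> tuple[int, int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt, n_missing)."""
        g = self.genotypes
        return (
            int((g == HOM_REF).sum()),
            int((g == HET).sum()),
            int((g == HOM_ALT).sum()),
            int((g == MISSING).sum()),
        )


@dataclass
class TransductionRecord(MeiRecord):
    """MEI call annotated by MELT as carrying a 3' transduced segment."""

    mesource: SourceDescriptor = None  # type: ignore[assignment]
    metrans: TransSegment = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mesource is None or self.metrans is None:
            raise ValueError("TransductionRecord requires mesource and metrans")

    @property
    def is_transduction(self) -> bool:
        return True


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    me_type: str = ""
    subfamily: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class SamplePanel:
    """Sample -> population -> super-population mapping (panel TSV).

    The TSV has a header line ``sample\tpopulation\tsuper_population\tsex``.
    The population -> super-population mapping must be a function and
    sample ids must be unique.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["sample", "population", "super_population", "sex"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise DialectError(f"panel missing columns {missing}")
        if frame["sample"].duplicated().any():
            dup = frame.loc[frame["sample"].duplicated(), "sample"].iloc[0]
            raise DialectError(f"duplicate sample id {dup!r} in panel")
        pop2sup = frame.groupby("population")["super_population"].nunique()
        if (pop2sup > 1).any():
            bad = pop2sup[pop2sup > 1].index[0]
            raise DialectError(
                f"population {bad!r} maps to multiple super-populations"
            )
        self.frame = frame.reset_index(drop=True)
        self.samples: list[str] = list(frame["sample"])
        self._pop = dict(zip(frame["sample"], frame["population"]))
        self._sup = dict(zip(frame["sample"], frame["super_population"]))

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    @property
    def superpopulations(self) -> list[str]:
        return sorted(self.frame["super_population"].unique())

    def population_of(self, sample: str) -> str:
        return self._pop[sample]

    def superpopulation_of(self, sample: str) -> str:
        return self._sup[sample]

    def indices_for(self, group: str) -> np.ndarray:
        """Positional indices of samples in *group*.

        *group* is ``"ALL"``, a population code or a super-population code.
        """
        if group == "ALL":
            return np.arange(len(self.samples))
        mask = (self.frame["population"] == group) | (
            self.frame["super_population"] == group
        )
        if not mask.any():
            raise KeyError(f"unknown group code {group!r}")
        return np.flatnonzero(mask.to_numpy())

    @classmethod
    def read(cls, path: str | Path) -> "SamplePanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {
    (0, 0): HOM_REF,
    (0, 1): HET,
    (1, 0): HET,
    (1, 1): HOM_ALT,
    (None, None): MISSING,
}

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_DIALECT_INFO = ("SR", "ASSESS", "SVLEN", "SUBFAM", "MESOURCE", "METRANS")

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SR,Number=1,Type=Integer,Description="Total number of split reads at the insertion location">',
    '##INFO=<ID=ASSESS,Number=1,Type=Integer,Description="Breakpoint evidence score">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length (TE + transduced segment)">',
    '##INFO=<ID=SUBFAM,Number=1,Type=String,Description="Element subfamily or UNDETERMINED">',
    '##INFO=<ID=MESOURCE,Number=1,Type=String,Description="Transduction source locus: chrom|start|end|strand|subfamily|source_type|transduced_length">',
    '##INFO=<ID=METRANS,Number=1,Type=String,Description="Transduced segment: chrom|start|end|strand, or null">',
    '##FILTER=<ID=rSD,Description="Left/right breakpoint support differs by two standard deviations">',
    '##FILTER=<ID=ac0,Description="No genotype call had a non-zero allele count">',
    '##FILTER=<ID=hDP,Description="Insertion in a region of high local depth">',
    '##FILTER=<ID=lc,Description="Low complexity region">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _parse_me_type(alt: str, line_no: int) -> str:
    # symbolic ALT of the form <INS:ME:L1>
    if alt.startswith("<INS:ME:") and alt.endswith(">"):
        me = alt[len("<INS:ME:"):-1]
        if me in ME_TYPES:
            return me
    raise DialectError(f"line {line_no}: unsupported ALT {alt!r}")


def read_mei_vcf(
    path: str | Path, panel: SamplePanel | None = None
) -> list[MeiRecord]:
    """Read a MELT-dialect MEI VCF into :class:`MeiRecord` objects.

    Records whose METRANS key is present and not the ``null`` marker are
    returned as :class:`TransductionRecord`. Unknown INFO keys are kept in
    the record's ``extra`` pass-through map. Multi-allelic ALTs, non-diploid
    or half-called genotypes are hard dialect errors naming the offending
    line number.
    """
    records: list[MeiRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        n_header = len(str(vf.header).splitlines())
        vcf_samples = list(vf.header.samples)
        if panel is not None and vcf_samples != panel.samples:
            raise DialectError(
                "VCF sample columns do not match the panel "
                f"({len(vcf_samples)} vs {len(panel)} samples)"
            )
        for i, rec in enumerate(vf):
            line_no = n_header + i + 1
            if rec.alts is None or len(rec.alts) != 1:
                raise DialectError(
                    f"line {line_no}: dialect is biallelic, got ALT={rec.alts}"
                )
            me_type = _parse_me_type(rec.alts[0], line_no)
            info = dict(rec.info)
            gts = np.empty(len(vcf_samples), dtype=np.int8)
            for j, s in enumerate(vcf_samples):
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2:
                    raise DialectError(
                        f"line {line_no}: sample {s} has non-diploid GT {gt}"
                    )
                try:
                    gts[j] = _GT_MAP[tuple(gt)]
                except KeyError:
                    raise DialectError(
                        f"line {line_no}: sample {s} has malformed GT {gt}"
                    ) from None
            flags = frozenset(rec.filter.keys())
            extra = {
                k: _render_info_value(v)
                for k, v in info.items()
                if k not in _DIALECT_INFO
            }
            common = dict(
                chrom=rec.chrom,
                pos=rec.pos,
                variant_id=rec.id or ".",
                me_type=me_type,
                subfamily=str(info.get("SUBFAM", "UNDETERMINED")),
                svlen=_opt_int(info.get("SVLEN")),
                assess=_opt_int(info.get("ASSESS")),
                sr=_opt_int(info.get("SR")),
                filter_flags=flags,
                genotypes=gts,
                extra=extra,
            )
            metrans_raw = info.get("METRANS")
            if metrans_raw is not None and str(metrans_raw) != NULL_MARKER:
                mesource_raw = info.get("MESOURCE")
                if mesource_raw is None:
                    raise DialectError(
                        f"line {line_no}: METRANS without MESOURCE"
                    )
                records.append(
                    TransductionRecord(
                        **common,
                        mesource=SourceDescriptor.decode(str(mesource_raw)),
                        metrans=TransSegment.decode(str(metrans_raw)),
                    )
                )
            else:
                if "MESOURCE" in info:  # stray source on a null-METRANS line
                    extra["MESOURCE"] = str(info["MESOURCE"])
                records.append(MeiRecord(**common))
    return records


def _opt_int(v) -> int | None:
    return None if v is None else int(v)


def _render_info_value(v) -> str:
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    if v is True:
        return ""
    return str(v)


def _info_string(rec: MeiRecord) -> str:
    parts = []
    if rec.sr is not None:
        parts.append(f"SR={rec.sr}")
    if rec.assess is not None:
        parts.append(f"ASSESS={rec.assess}")
    if rec.svlen is not None:
        parts.append(f"SVLEN={rec.svlen}")
    parts.append(f"SUBFAM={rec.subfamily}")
    if isinstance(rec, TransductionRecord):
        parts.append(f"MESOURCE={rec.mesource.encode()}")
        parts.append(f"METRANS={rec.metrans.encode()}")
    for k in sorted(rec.extra):
        v = rec.extra[k]
        parts.append(k if v == "" else f"{k}={v}")
    return ";".join(parts) if parts else "."


def write_mei_vcf(
    records: Sequence[MeiRecord],
    path: str | Path,
    samples: Sequence[str],
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    """Serialize records in the documented dialect, deterministically.

    INFO keys are emitted in a fixed order (SR, ASSESS, SVLEN, SUBFAM,
    MESOURCE, METRANS, then pass-through keys sorted), so writing the same
    records twice yields byte-identical files.
    """
    chroms: list[str] = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    if chrom_sizes is not None:
        contig_lines = [
            f"##contig=<ID={c},length={chrom_sizes[c]}>" for c in chroms
        ]
    else:
        contig_lines = [f"##contig=<ID={c}>" for c in chroms]
    out = io.StringIO()
    for line in _VCF_HEADER_LINES[:1] + contig_lines + _VCF_HEADER_LINES[1:]:
        out.write(line + "\n")
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    for r in records:
        if len(r.genotypes) != len(samples):
            raise ValueError(
                f"{r.variant_id}: {len(r.genotypes)} genotypes for "
                f"{len(samples)} samples"
            )
        filt = (
            ";".join(sorted(r.filter_flags, key=_filter_sort_key))
            if r.filter_flags
            else "."
        )
        gts = "\t".join(_GT_STR[int(g)] for g in r.genotypes)
        out.write(
            f"{r.chrom}\t{r.pos}\t{r.variant_id}\tN\t<INS:ME:{r.me_type}>\t."
            f"\t{filt}\t{_info_string(r)}\tGT\t{gts}\n"
        )
    Path(path).write_text(out.getvalue())


def _filter_sort_key(flag: str) -> tuple[int, str]:
    # PASS first, then alphabetical — a stable, documented on-disk order
    return (0 if flag == "PASS" else 1, flag)


# ---------------------------------------------------------------------------
# BED / chrom.sizes / FASTA
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a whitespace-delimited BED(3+) file.

    Optional columns 4-7 are name, strand, me_type and subfamily
    (subfamily defaults to the name column). Intervals are 0-based
    half-open; ``start >= end`` is an error naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise DialectError(f"line {line_no}: need >= 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise DialectError(
                    f"line {line_no}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[4] if len(cols) > 4 else "."
            me_type = cols[5] if len(cols) > 5 else ""
            subfamily = cols[6] if len(cols) > 6 else name
            intervals.append(
                GenomicInterval(chrom, start, end, name, strand, me_type, subfamily)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.strand}"
                f"\t{iv.me_type}\t{iv.subfamily}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """chrom.sizes TSV (chrom\tlength) -> dict; lengths must be > 0."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    if (df["length"] <= 0).any():
        bad = df.loc[df["length"] <= 0, "chrom"].iloc[0]
        raise DialectError(f"non-positive length for {bad!r}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA, 60 columns per line."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# report TSVs
# ---------------------------------------------------------------------------

REPORT_SCHEMAS: dict[str, list[str]] = {
    "funnel": [
        "me_type",
        "n_total",
        "n_removed_segdup",
        "n_after_segdup",
        "n_high",
        "n_low",
    ],
    "popstats": ["variant_id", "group", "ac", "an", "af"],
    "hwe": [
        "variant_id",
        "n_hom_ref",
        "n_het",
        "n_hom_alt",
        "p_two_sided",
        "p_excess_het",
    ],
    "progenitors": [
        "source_chrom",
        "source_start",
        "source_end",
        "source_type",
        "subfamily",
        "n_offspring",
        "n_inter",
        "n_intra",
        "cumulative_share",
    ],
    "motifs": ["locus", "element", "source_type", "pas", "use", "dse"],
    "classified": ["variant_id", "chrom", "pos", "me_type", "label", "reasons"],
    "qc_drops": ["variant_id", "chrom", "pos", "me_type", "reason"],
    "density": ["chrom", "n_insertions", "length_bp", "per_mbp"],
}


def write_report(
    rows: Iterable[Mapping[str, object]], path: str | Path, schema: str
) -> None:
    """Write rows as a TSV with the named schema's fixed column order.

    Missing / None values render as ``'.'``; unknown schema names raise.
    """
    try:
        columns = REPORT_SCHEMAS[schema]
    except KeyError:
        raise ValueError(
            f"unknown report schema {schema!r}; "
            f"known: {sorted(REPORT_SCHEMAS)}"
        ) from None
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            vals = []
            for c in columns:
                v = row.get(c)
                vals.append("." if v is None or v == "" else str(v))
            fh.write("\t".join(vals) + "\n")
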