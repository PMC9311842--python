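"""3'-end polyadenylation-motif annotation of transduction donor loci.

A donor produces transductions when transcription reads through a weak
polyadenylation site into downstream sequence. Each donor's 3' end is
therefore scanned, in transcript orientation, for the three elements of a
canonical 3'-processing site:

* **PAS** — the polyadenylation signal hexamer (AAUAAA or AUUAAA on the
  transcript), sought 10-40 nt upstream of the cleavage site;
* **USE** — the upstream sequence element UGUAN (N = any base), sought
  40-100 nt upstream of the PAS;
* **DSE** — a GU-rich downstream element, sought 40-100 nt downstream of
  the PAS. "GU-rich" is operationalized as any 20-nt sliding subwindow
  with >= 60% G+T, both parameters configurable since no quantitative
  community definition exists.

The cleavage site is approximated by the annotated 3' terminus of the
element (for minus-strand donors the extracted sequence is
reverse-complemented so "upstream" always means toward the element body).
All scans are on the DNA strand of the transcript; hexamers are reported
in RNA rendering. Genomic ambiguity code N matches no motif letter and
counts as non-GT. Window offsets are measured from motif start and are
inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import GenomicInterval

__all__ = [
    "MotifConfig",
    "ThreePrimeAnnotation",
    "extract_3prime_context",
    "find_pas",
    "find_use",
    "find_dse",
    "annotate_sources",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConfig:
    pas_hexamers: tuple[str, ...] = ("AATAAA", "ATTAAA")  # DNA alphabet
    pas_window: tuple[int, int] = (10, 40)  # nt upstream of cleavage
    use_motif: str = "TGTAN"  # N = any base
    use_window: tuple[int, int] = (40, 100)  # nt upstream of PAS start
    dse_window: tuple[int, int] = (40, 100)  # nt downstream of PAS end
    dse_gt_fraction: float = 0.6
    dse_subwindow: int = 20

    def __post_init__(self) -> None:
        for w in (self.pas_window, self.use_window, self.dse_window):
            if not w[0] < w[1]:
                raise ValueError(f"window needs min < max, got {w}")
        if not 0 < self.dse_gt_fraction <= 1:
            raise ValueError("dse_gt_fraction must be in (0, 1]")


@dataclass
class ThreePrimeAnnotation:
    """Table-shaped 3'-end findings for one donor locus."""

    source: GenomicInterval
    pas: str | None  # RNA rendering, e.g. "AAUAAA"
    pas_offset: int | None  # nt upstream of cleavage (motif start)
    use: str | None  # RNA rendering of the matched USE
    dse: bool
    scanned_strand: str
    truncated: bool = False

    def to_row(self) -> dict[str, object]:
        """One row of the ``motifs`` report schema (1-based locus)."""
        src = self.source
        return {
            "locus": f"{src.chrom}:{src.start + 1}-{src.end}",
            "element": src.subfamily or src.name,
            "source_type": "reference" if src.me_type != "nonreference" else src.me_type,
            "pas": self.pas,
            "use": self.use,
            "dse": "GU-rich" if self.dse else "No",
        }


def _dna_to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def _seq_len(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    seq = genome[chrom][start:end]
    return str(seq).upper()


def extract_3prime_context(
    genome: Mapping[str, str],
    source: GenomicInterval,
    flank: int = 150,
) -> tuple[str, int, bool]:
    """Sequence around a donor's 3' terminus, in transcript orientation.

    Returns (seq, cleavage_idx, truncated): ``seq[:cleavage_idx]`` is the
    region upstream of the cleavage site reading 5'->3' on the transcript
    strand, ``seq[cleavage_idx:]`` the downstream flank. Plus-strand
    donors cleave at the annotated element end; minus-strand donors at
    the element start, with the window reverse-complemented. Windows are
    truncated (and flagged) at contig edges. *genome* is any mapping from
    chromosome name to sliceable sequence (dict of str, pyfaidx.Fasta).
    """
    if source.chrom not in _contig_names(genome):
        raise KeyError(f"chromosome {source.chrom!r} absent from FASTA")
    length = _seq_len(genome, source.chrom)
    cleave = source.end if source.strand != "-" else source.start
    s0, e0 = max(0, cleave - flank), min(length, cleave + flank)
    truncated = s0 > cleave - flank or e0 < cleave + flank
    window = _fetch(genome, source.chrom, s0, e0)
    if source.strand != "-":
        return window, cleave - s0, truncated
    return reverse_complement(window), e0 - cleave, truncated


def _contig_names(genome) -> Sequence[str]:
    return list(genome.keys())


def _matches(seq: str, pos: int, pattern: str) -> bool:
    """Pattern match at pos; 'N' in the pattern matches A/C/G/T only."""
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for p, s in zip(pattern, seq[pos : pos + len(pattern)]):
        if p == "N":
            if s not in "ACGT":
                return False
        elif s != p:
            return False
    return True


def find_pas(
    seq: str, cleavage_idx: int, cfg: MotifConfig = MotifConfig()
) -> tuple[str, int] | None:
    """Find the polyadenylation hexamer upstream of the cleavage site.

    Scans motif-start offsets from pas_window min to max (inclusive,
    ascending — the hit closest to the cleavage site wins; at equal
    offset the first hexamer in cfg order wins). Returns the matched DNA
    hexamer and its offset, or None.
    """
    lo, hi = cfg.pas_window
    for offset in range(lo, hi + 1):
        pos = cleavage_idx - offset
        for hexamer in cfg.pas_hexamers:
            if _matches(seq, pos, hexamer):
                return hexamer, offset
    return None


def find_use(
    seq: str, pas_start: int, cfg: MotifConfig = MotifConfig()
) -> tuple[str, int] | None:
    """Find the upstream sequence element (TGTAN) before the PAS.

    Motif-start offsets run use_window min..max (inclusive) upstream of
    the PAS start. Returns (matched DNA string, offset) or None.
    """
    lo, hi = cfg.use_window
    for offset in range(lo, hi + 1):
        pos = pas_start - offset
        if _matches(seq, pos, cfg.use_motif):
            return seq[pos : pos + len(cfg.use_motif)], offset
    return None


def find_dse(
    seq: str, pas_end: int, cfg: MotifConfig = MotifConfig()
) -> bool:
    """Is there a GU-rich element downstream of the PAS?

    The scanned region covers distances dse_window min..max nt downstream
    of the PAS end (the first base after the hexamer is at distance 1).
    True iff any dse_subwindow-length sliding window fully inside the
    region has a G+T fraction >= dse_gt_fraction. A region shorter than
    the subwindow (truncated contig) yields False.
    """
    lo, hi = cfg.dse_window
    region = seq[pas_end + lo - 1 : pas_end + hi]
    k = cfg.dse_subwindow
    if len(region) < k:
        return False
    gt = [1 if c in "GT" else 0 for c in region]
    window_sum = sum(gt[:k])
    best = window_sum
    for i in range(k, len(gt)):
        window_sum += gt[i] - gt[i - k]
        best = max(best, window_sum)
    return best / k >= cfg.dse_gt_fraction


def annotate_sources(
    genome: Mapping[str, str],
    sources: Sequence[GenomicInterval],
    cfg: MotifConfig = MotifConfig(),
    flank: int | None = None,
) -> list[ThreePrimeAnnotation]:
    """Annotate each donor locus with PAS / USE / DSE findings.

    One annotation per source. USE is only sought when a PAS was found (a
    processing site is anchored on its signal). DSE is anchored at the
    PAS end when one exists, else at the cleavage site. Absent motifs
    render as '-' in the report.
    """
    if flank is None:
        lo_needed = cfg.pas_window[1] + cfg.use_window[1] + len(cfg.use_motif)
        hi_needed = cfg.dse_window[1] + len(max(cfg.pas_hexamers, key=len))
        flank = max(lo_needed, hi_needed) + 10
    out: list[ThreePrimeAnnotation] = []
    for src in sources:
        seq, cleave, truncated = extract_3prime_context(genome, src, flank)
        pas_hit = find_pas(seq, cleave, cfg)
        if pas_hit is None:
            # no signal to anchor on: USE is not sought, but GU-richness
            # of the downstream flank is still reported, anchored at the
            # cleavage site
            dse = find_dse(seq, cleave, cfg)
            out.append(
                ThreePrimeAnnotation(
                    src, None, None, None, dse, src.strand, truncated
                )
            )
            continue
        hexamer, offset = pas_hit
        pas_start = cleave - offset
        pas_end = pas_start + len(hexamer)
        use_hit = find_use(seq, pas_start, cfg)
        dse = find_dse(seq, pas_end, cfg)
        out.append(
            ThreePrimeAnnotation(
                src,
                _dna_to_rna(hexamer),
                offset,
                _dna_to_rna(use_hit[0]) if use_hit else None,
                dse,
                src.strand,
                truncated,
            )
        )
    return out
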