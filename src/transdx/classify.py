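"""Two-tier validation of 3' transduction candidates.

Candidates (MEI calls whose METRANS descriptor is non-null) are first
removed if they overlap segmental-duplication loci, whose internal homology
confounds progenitor-offspring inference. Survivors are HIGH confidence
when all three clauses hold, else LOW with every failing clause recorded:

* read support: five or more supporting reads (the record's SR count);
* length consistency: the transduced-segment length reported at the source
  (MESOURCE, which excludes the TE body) must be strictly shorter than the
  offspring's SVLEN (which is TE + transduced segment) — the offspring is
  expected to exceed the source by roughly one TE length (~5 kb for L1,
  ~1 kb for SVA);
* active family: the donor subfamily belongs to a currently active human
  retroelement subfamily. Donors with an undetermined subfamily (MELT
  reports none for non-reference SVA sources) count as active by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .formats_io import GenomicInterval, TransductionRecord

__all__ = [
    "ClassifierConfig",
    "ClassifiedTransduction",
    "Funnel",
    "SegdupIndex",
    "overlaps_segdup",
    "length_consistent",
    "family_active",
    "classify",
    "classify_cohort",
]

HIGH, LOW, REMOVED_SEGDUP = "HIGH", "LOW", "REMOVED_SEGDUP"

SEGDUP_OVERLAP = "SEGDUP_OVERLAP"
LOW_SUPPORT = "LOW_SUPPORT"
LENGTH_INCONSISTENT = "LENGTH_INCONSISTENT"
INACTIVE_FAMILY = "INACTIVE_FAMILY"

#: Subfamilies treated as retrotranspositionally active in the recent human
#: genome. Configurable: authoritative lists vary between annotations.
DEFAULT_ACTIVE_SUBFAMILIES = frozenset(
    {"L1HS", "L1Ta", "L1ta1d", "L1T1d", "SVA_D", "SVA_E", "SVA_F"}
)

UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class ClassifierConfig:
    min_support_reads: int = 5
    active_subfamilies: frozenset[str] = DEFAULT_ACTIVE_SUBFAMILIES
    undetermined_is_active: bool = True
    segdup_mode: str = "point"  # "point" | "span"

    def __post_init__(self) -> None:
        if self.min_support_reads < 1:
            raise ValueError("min_support_reads must be >= 1")
        if not self.active_subfamilies:
            raise ValueError("active_subfamilies must be non-empty")
        if self.segdup_mode not in ("point", "span"):
            raise ValueError(f"bad segdup_mode {self.segdup_mode!r}")
        object.__setattr__(
            self,
            "active_subfamilies",
            frozenset(s.upper() for s in self.active_subfamilies),
        )


@dataclass
class ClassifiedTransduction:
    record: TransductionRecord
    label: str  # HIGH | LOW | REMOVED_SEGDUP
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.label == HIGH) != (not self.reasons):
            raise ValueError("HIGH iff no reasons")
        if (self.label == REMOVED_SEGDUP) != (self.reasons == [SEGDUP_OVERLAP]):
            if self.label == REMOVED_SEGDUP or SEGDUP_OVERLAP in self.reasons:
                raise ValueError("REMOVED_SEGDUP iff reasons == [SEGDUP_OVERLAP]")


@dataclass
class Funnel:
    """Per-ME-type classification funnel; n_total = removed + high + low."""

    n_total: int = 0
    n_removed_segdup: int = 0
    n_high: int = 0
    n_low: int = 0

    @property
    def n_after_segdup(self) -> int:
        return self.n_high + self.n_low


class SegdupIndex:
    """Per-chromosome interval index over segmental-duplication loci."""

    def __init__(self, segdups: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for iv in segdups:
            self._trees[iv.chrom].addi(iv.start, iv.end)

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """True iff [start0, end0) (0-based half-open) hits any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start0, end0))


def overlaps_segdup(
    record: TransductionRecord,
    segdups: SegdupIndex | Sequence[GenomicInterval],
    mode: str = "point",
) -> bool:
    """Does the offspring insertion hit a segmental duplication?

    A VCF insertion is anchored at the base *before* the inserted
    sequence, so the insertion junction sits at the 0-based gap
    coordinate equal to the 1-based POS. point mode: that junction lies
    inside a half-open interval [start, end) — an insertion at the
    interval's right edge is outside. span mode: the junction plus the
    structural-variant length, [pos, pos+svlen), intersects an interval.
    """
    index = segdups if isinstance(segdups, SegdupIndex) else SegdupIndex(segdups)
    j = record.pos  # 0-based junction coordinate
    if mode == "point":
        return index.overlaps(record.chrom, j, j + 1)
    if mode == "span":
        span = record.svlen if record.svlen else 1
        return index.overlaps(record.chrom, j, j + span)
    raise ValueError(f"bad mode {mode!r}")


def length_consistent(record: TransductionRecord) -> bool:
    """Source-side transduced length strictly shorter than offspring SVLEN."""
    if record.svlen is None:
        raise ValueError(f"{record.variant_id}: SVLEN required")
    return record.mesource.transduced_length < record.svlen


def family_active(
    record: TransductionRecord, cfg: ClassifierConfig = ClassifierConfig()
) -> bool:
    """Is the donor subfamily an active human retroelement subfamily?

    Case-insensitive membership in cfg.active_subfamilies; UNDETERMINED
    donors count as active when cfg.undetermined_is_active.
    """
    fam = record.mesource.subfamily.upper()
    if fam == UNDETERMINED or fam == "":
        return cfg.undetermined_is_active
    return fam in cfg.active_subfamilies


def classify(
    record: TransductionRecord,
    segdups: SegdupIndex | Sequence[GenomicInterval],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassifiedTransduction:
    """Classify one transduction candidate.

    Segdup overlap removes the record outright, regardless of other
    fields. Otherwise HIGH iff support, length consistency and family
    activity all hold; LOW records carry every failing clause.
    """
    if overlaps_segdup(record, segdups, cfg.segdup_mode):
        return ClassifiedTransduction(record, REMOVED_SEGDUP, [SEGDUP_OVERLAP])
    reasons: list[str] = []
    if record.sr is None or record.sr < cfg.min_support_reads:
        reasons.append(LOW_SUPPORT)
    if not length_consistent(record):
        reasons.append(LENGTH_INCONSISTENT)
    if not family_active(record, cfg):
        reasons.append(INACTIVE_FAMILY)
    return ClassifiedTransduction(record, HIGH if not reasons else LOW, reasons)


def classify_cohort(
    records: Sequence[TransductionRecord],
    segdups: SegdupIndex | Sequence[GenomicInterval],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[ClassifiedTransduction], dict[str, Funnel]]:
    """Classify every candidate; return per-ME-type funnel counts.

    The funnel satisfies the partition identity
    n_total = n_removed_segdup + n_high + n_low for every ME type.
    """
    index = segdups if isinstance(segdups, SegdupIndex) else SegdupIndex(segdups)
    classified: list[ClassifiedTransduction] = []
    funnel: dict[str, Funnel] = {}
    for rec in records:
        ct = classify(rec, index, cfg)
        classified.append(ct)
        f = funnel.setdefault(rec.me_type, Funnel())
        f.n_total += 1
        if ct.label == REMOVED_SEGDUP:
            f.n_removed_segdup += 1
        elif ct.label == HIGH:
            f.n_high += 1
        else:
            f.n_low += 1
    return classified, funnel
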