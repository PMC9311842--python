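"""QC filtering of polymorphic MEI calls and full-length source selection.

Call-set quality control mirrors the standard bcftools triage of MELT
output: keep calls with split-read support and breakpoint-evidence score
both at or above 3, FILTER tagged PASS or rSD, and none of the rejection
tags ac0 / hDP / lc. The rSD tag marks calls whose left/right breakpoint
support is unbalanced by two standard deviations; keeping them raises
transduction-discovery sensitivity.

Candidate donor elements are restricted to full-length copies, since 5'
truncation disrupts amplification and transduction potential: minimum
annotated spans default to 5900 bp for L1 and 1000 bp for SVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import GenomicInterval, MeiRecord

__all__ = ["QCThresholds", "passes_qc", "filter_cohort", "select_fulllength_sources"]

# Drop reasons, in evaluation order (first failing clause is reported).
LOW_SR = "LOW_SR"
LOW_ASSESS = "LOW_ASSESS"
NO_KEEP_FILTER = "NO_KEEP_FILTER"
REJECT_FILTER = "REJECT_FILTER"


@dataclass(frozen=True)
class QCThresholds:
    min_sr: int = 3
    min_assess: int = 3
    keep_filters: frozenset[str] = frozenset({"PASS", "rSD"})
    reject_filters: frozenset[str] = frozenset({"ac0", "hDP", "lc"})
    #: minimum annotated span for a full-length donor element, per ME type
    min_source_length: Mapping[str, int] = field(
        default_factory=lambda: {"L1": 5900, "SVA": 1000}
    )

    def __post_init__(self) -> None:
        if self.min_sr < 0 or self.min_assess < 0:
            raise ValueError("thresholds must be >= 0")
        object.__setattr__(self, "keep_filters", frozenset(self.keep_filters))
        object.__setattr__(self, "reject_filters", frozenset(self.reject_filters))
        if self.keep_filters & self.reject_filters:
            raise ValueError("keep_filters and reject_filters overlap")


def _failing_clause(record: MeiRecord, t: QCThresholds) -> str | None:
    if record.sr is None or record.assess is None:
        raise ValueError(
            f"{record.variant_id}: SR and ASSESS are required for QC"
        )
    if record.sr < t.min_sr:
        return LOW_SR
    if record.assess < t.min_assess:
        return LOW_ASSESS
    if not (record.filter_flags & t.keep_filters):
        return NO_KEEP_FILTER
    if record.filter_flags & t.reject_filters:
        return REJECT_FILTER
    return None


def passes_qc(record: MeiRecord, t: QCThresholds = QCThresholds()) -> bool:
    """True iff the record passes all four QC clauses.

    sr >= min_sr AND assess >= min_assess AND FILTER intersects the keep
    set AND FILTER avoids the reject set. A record carrying both a keep
    and a reject tag is dropped: the rejection clause is unconditional.
    """
    return _failing_clause(record, t) is None


def filter_cohort(
    records: Sequence[MeiRecord], t: QCThresholds = QCThresholds()
) -> tuple[list[MeiRecord], list[tuple[MeiRecord, str]]]:
    """Partition records into (kept, dropped_with_reason).

    Each dropped record is paired with the first failing clause name, in
    the documented evaluation order LOW_SR, LOW_ASSESS, NO_KEEP_FILTER,
    REJECT_FILTER.
    """
    kept: list[MeiRecord] = []
    dropped: list[tuple[MeiRecord, str]] = []
    for r in records:
        clause = _failing_clause(r, t)
        if clause is None:
            kept.append(r)
        else:
            dropped.append((r, clause))
    return kept, dropped


def select_fulllength_sources(
    intervals: Sequence[GenomicInterval], t: QCThresholds = QCThresholds()
) -> list[GenomicInterval]:
    """Keep annotated elements whose span reaches the full-length minimum.

    The test is on the annotated interval span (end - start), per ME type;
    input order is preserved. An interval whose me_type has no configured
    minimum is an error.
    """
    out: list[GenomicInterval] = []
    for iv in intervals:
        try:
            min_len = t.min_source_length[iv.me_type]
        except KeyError:
            raise KeyError(
                f"no full-length minimum configured for me_type "
                f"{iv.me_type!r} ({iv.chrom}:{iv.start}-{iv.end})"
            ) from None
        if iv.length >= min_len:
            out.append(iv)
    return out
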