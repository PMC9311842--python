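"""Progenitor-offspring mapping of classified 3' transductions.

Groups offspring insertions by their donor (source) locus, labels each
link inter- or intrachromosomal, and ranks donors by offspring yield —
"master elements" are the prolific donors at the top of the ranking.

Source identity for reference donors is the exact (chrom, start, end)
triple; non-reference donors (themselves polymorphic insertions) are
identified by their insertion point. No fuzzy coordinate merging is done
by default; a merge radius is available for call sets with jittered
source coordinates. Alternate-haplotype contigs are distinct chromosomes:
a link from chr6_GL000253v2_alt to chr6 is interchromosomal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .classify import HIGH, LOW, ClassifiedTransduction
from .formats_io import SourceDescriptor

__all__ = [
    "SourceKey",
    "ProgenitorSummary",
    "source_key",
    "link_type",
    "build_map",
    "rank_sources",
]

INTER, INTRA = "inter", "intra"


@dataclass(frozen=True, order=True)
class SourceKey:
    """Identity of a donor locus.

    Reference donors carry an interval (start, end); non-reference donors
    a point (start == insertion point, end is None).
    """

    chrom: str
    start: int
    end: int | None
    source_type: str
    subfamily: str


@dataclass
class ProgenitorSummary:
    key: SourceKey
    offspring: list[tuple[str, int, str]]  # (chrom, pos, inter|intra)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    @property
    def n_inter(self) -> int:
        return sum(1 for _, _, t in self.offspring if t == INTER)

    @property
    def n_intra(self) -> int:
        return sum(1 for _, _, t in self.offspring if t == INTRA)


def source_key(src: SourceDescriptor, merge_radius: int = 0) -> SourceKey:
    """Build the grouping key for a source descriptor.

    merge_radius > 0 snaps coordinates to a grid of that width, merging
    near-identical donor annotations; the default 0 keeps exact triples.
    """
    start, end = src.start, src.end
    if merge_radius > 0:
        start = start - start % merge_radius
        end = None if end is None else end - end % merge_radius
    if src.source_type == "nonreference":
        return SourceKey(src.chrom, start, None, src.source_type, src.subfamily)
    return SourceKey(src.chrom, start, end, src.source_type, src.subfamily)


def link_type(source: SourceKey | SourceDescriptor, offspring_chrom: str) -> str:
    """"intra" iff source and offspring chromosome names are equal.

    No normalization is applied: alt-haplotype contigs are their own
    chromosomes.
    """
    return INTRA if source.chrom == offspring_chrom else INTER


def build_map(
    classified: Sequence[ClassifiedTransduction],
    include: str = "HIGH",
    merge_radius: int = 0,
) -> list[ProgenitorSummary]:
    """Group offspring by donor locus.

    ``include`` is "HIGH" (default) or "HIGH+LOW"; segdup-removed records
    are never included. Offspring are sorted by (chrom, pos); summaries
    are returned sorted by key, so the result is permutation-invariant in
    the input.
    """
    if include == "HIGH":
        labels = {HIGH}
    elif include == "HIGH+LOW":
        labels = {HIGH, LOW}
    else:
        raise ValueError(f"include must be HIGH or HIGH+LOW, got {include!r}")
    groups: dict[SourceKey, list[tuple[str, int]]] = defaultdict(list)
    for ct in classified:
        if ct.label not in labels:
            continue
        rec = ct.record
        if not rec.is_transduction:
            raise ValueError(f"{rec.variant_id}: record lacks a source descriptor")
        groups[source_key(rec.mesource, merge_radius)].append((rec.chrom, rec.pos))
    out = []
    sort_key = lambda k: (  # noqa: E731
        k.chrom, k.start, -1 if k.end is None else k.end, k.source_type, k.subfamily,
    )
    for key in sorted(groups, key=sort_key):
        offspring = [
            (c, p, link_type(key, c)) for c, p in sorted(groups[key])
        ]
        out.append(ProgenitorSummary(key, offspring))
    return out


def rank_sources(
    summaries: Sequence[ProgenitorSummary], top_k: int | None = None
) -> list[tuple[ProgenitorSummary, float]]:
    """Rank donors by offspring count, with cumulative share of the total.

    Descending by n_offspring; ties broken by (chrom, start). The share
    accompanying each entry is the running fraction of all offspring
    produced by the donors ranked so far.
    """
    total = sum(s.n_offspring for s in summaries)
    ranked = sorted(
        summaries, key=lambda s: (-s.n_offspring, s.key.chrom, s.key.start)
    )
    if top_k is not None:
        ranked = ranked[:top_k]
    out: list[tuple[ProgenitorSummary, float]] = []
    running = 0
    for s in ranked:
        running += s.n_offspring
        out.append((s, running / total if total else 0.0))
    return out
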