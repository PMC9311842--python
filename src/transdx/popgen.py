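"""Population-genetic summaries of MEI call sets.

Stratified allele counts and frequencies, singleton detection, population
specificity, per-site heterozygote/homozygote ratios, an exact
Hardy-Weinberg equilibrium test, genomic insertion density and per-element
transduction rates.

Allele counting follows the bcftools fill-tags convention: a missing
diploid genotype contributes 0 to both AC and AN, so AN = 2 x (number of
non-missing genotypes in the group).

The HWE test is the exact conditional test: given the observed allele
counts, every admissible heterozygote count (same parity as the minor
allele count) is enumerated, and its probability under random mating is

    P(h) proportional_to 2**h * n! / (n_hom_minor! * h! * n_hom_major!)

with n genotypes and n_hom_minor = (n_minor - h) / 2. The two-sided
p-value sums all configurations no more probable than the observed one;
the excess-heterozygosity tail sums configurations with h >= observed.
Both are in (0, 1]; monomorphic sites give p = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .formats_io import HET, HOM_ALT, MISSING, MeiRecord, SamplePanel

__all__ = [
    "AlleleSummary",
    "HweResult",
    "allele_summary",
    "is_singleton",
    "group_presence",
    "superpop_presence",
    "het_hom_ratio",
    "hwe_exact",
    "density_per_mbp",
    "per_element_rate",
    "af_spectrum",
]


@dataclass(frozen=True)
class AlleleSummary:
    variant_id: str
    group: str  # "ALL", a population code or a super-population code
    ac: int
    an: int

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"need 0 <= ac <= an, got ac={self.ac}, an={self.an}")

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an else 0.0


@dataclass(frozen=True)
class HweResult:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    p_two_sided: float
    p_excess_het: float


def allele_summary(
    record: MeiRecord, panel: SamplePanel, group: str = "ALL"
) -> AlleleSummary:
    """Alternate allele count / number / frequency within a group."""
    idx = panel.indices_for(group)
    g = record.genotypes[idx]
    an = 2 * int((g != MISSING).sum())
    ac = 2 * int((g == HOM_ALT).sum()) + int((g == HET).sum())
    return AlleleSummary(record.variant_id, group, ac, an)


def is_singleton(record: MeiRecord, panel: SamplePanel) -> bool:
    """True iff exactly one alternate allele exists cohort-wide (AC = 1)."""
    return allele_summary(record, panel, "ALL").ac == 1


def group_presence(
    record: MeiRecord, panel: SamplePanel, level: str = "super_population"
) -> set[str]:
    """Group codes (population or super-population) where AC > 0.

    A variant is *group-specific* when the returned set has size 1.
    """
    codes = (
        panel.superpopulations
        if level == "super_population"
        else panel.populations
    )
    return {
        c for c in codes if allele_summary(record, panel, c).ac > 0
    }


def superpop_presence(record: MeiRecord, panel: SamplePanel) -> set[str]:
    return group_presence(record, panel, "super_population")


def het_hom_ratio(
    records: Sequence[MeiRecord],
    panel: SamplePanel | None = None,
    mode: str = "totals",
) -> dict[str, float]:
    """Heterozygous / alternate-homozygous ratio per ME type.

    ``totals`` (default) divides the summed het count across sites by the
    summed hom-alt count — the per-site tallies enter as totals, which
    stays defined when individual sites have no hom-alt carrier.
    ``mean_of_sites`` averages per-site ratios over sites with at least
    one hom-alt carrier. A zero denominator yields math.inf.
    """
    if mode not in ("totals", "mean_of_sites"):
        raise ValueError(f"bad mode {mode!r}")
    het: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        _, n_het, n_hom_alt, _ = r.genotype_counts()
        het.setdefault(r.me_type, []).append((n_het, n_hom_alt))
    out: dict[str, float] = {}
    for me_type, counts in het.items():
        if mode == "totals":
            num = sum(h for h, _ in counts)
            den = sum(a for _, a in counts)
            out[me_type] = num / den if den else math.inf
        else:
            ratios = [h / a for h, a in counts if a > 0]
            out[me_type] = float(np.mean(ratios)) if ratios else math.inf
    return out


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Exact Hardy-Weinberg test from genotype counts.

    Enumerates every heterozygote count with the parity of the minor
    allele count, conditional on the observed allele counts, and sums
    exact probabilities (computed via log-factorials and normalized by
    log-sum-exp, so counts in the thousands remain exact to machine
    precision).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype is required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:  # monomorphic: single admissible configuration
        return HweResult(n_hom_ref, n_het, n_hom_alt, 1.0, 1.0)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    log_w = (
        hs * math.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_minor - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln(n - hs - (n_minor - hs) / 2 + 1)
    )
    log_p = log_w - logsumexp(log_w)
    p = np.exp(log_p)
    i_obs = int(np.searchsorted(hs, n_het))
    if i_obs >= len(hs) or hs[i_obs] != n_het:
        raise ValueError(
            f"het count {n_het} inconsistent with allele count {n_minor}"
        )
    p_obs = p[i_obs]
    # probabilities equal up to rounding noise count as "as extreme"
    two_sided = float(p[p <= p_obs * (1 + 1e-10)].sum())
    excess = float(p[i_obs:].sum())
    return HweResult(
        n_hom_ref, n_het, n_hom_alt, min(two_sided, 1.0), min(excess, 1.0)
    )


def density_per_mbp(
    records: Sequence[MeiRecord], chrom_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Insertions per 1 Mbp for every chromosome in chrom_sizes.

    The denominator is the full assembly length (N runs included). A
    record on a chromosome absent from chrom_sizes is an error.
    """
    counts: dict[str, int] = {c: 0 for c in chrom_sizes}
    for r in records:
        if r.chrom not in counts:
            raise KeyError(f"no chromosome length for {r.chrom!r}")
        counts[r.chrom] += 1
    return {
        c: counts[c] / (chrom_sizes[c] / 1e6) for c in chrom_sizes
    }


def per_element_rate(
    n_high_conf: int, n_fulllength_elements: int, ndigits: int | None = 2
) -> float:
    """Transductions per full-length element, as a percentage.

    Rounded to two decimals (round-half-even) by default for report
    parity; pass ndigits=None for the raw value.
    """
    if n_fulllength_elements <= 0:
        raise ValueError("n_fulllength_elements must be > 0")
    rate = 100.0 * n_high_conf / n_fulllength_elements
    return rate if ndigits is None else round(rate, ndigits)


def af_spectrum(
    summaries: Sequence[AlleleSummary],
    bins: Sequence[tuple[float, float]],
) -> dict[str, dict[object, int]]:
    """Histogram of allele frequencies per group.

    ``bins`` must partition [0, 1] as contiguous (lo, hi] half-open
    intervals. Sites with an = 0 are skipped; called-but-absent sites
    (an > 0, ac = 0) land in a separate ``"monomorphic"`` bucket so that
    counts over bins + monomorphic equal the number of sites with an > 0.
    """
    bs = sorted(tuple(b) for b in bins)
    if not bs or bs[0][0] != 0.0 or bs[-1][1] != 1.0:
        raise ValueError("bins must cover [0, 1]")
    for (lo, hi), (lo2, _) in zip(bs, bs[1:]):
        if hi > lo2:
            raise ValueError(f"overlapping bins at {hi} > {lo2}")
        if hi < lo2:
            raise ValueError(f"gap between bins at ({hi}, {lo2})")
    if any(lo >= hi for lo, hi in bs):
        raise ValueError("each bin needs lo < hi")
    out: dict[str, dict[object, int]] = {}
    for s in summaries:
        if s.an == 0:
            continue
        hist = out.setdefault(
            s.group, {"monomorphic": 0, **{b: 0 for b in bs}}
        )
        if s.ac == 0:
            hist["monomorphic"] += 1
            continue
        af = s.af
        for lo, hi in bs:
            if lo < af <= hi:
                hist[(lo, hi)] += 1
                break
    return out
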