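# Methods

This note documents the models, rules and numerical choices behind
`transdx`, the assumptions they rest on, and what the synthetic-cohort
tests do and do not demonstrate about real data.

## Input dialect

The pipeline consumes a restricted VCF 4.2 dialect modelled on MELT MEI
output: biallelic symbolic insertions (`<INS:ME:L1|SVA|ALU>`), unphased
diploid genotypes, INFO keys `SR`, `ASSESS`, `SVLEN`, `SUBFAM`,
`MESOURCE`, `METRANS`, and FILTER values {PASS, rSD, ac0, hDP, lc}.
MELT's exact on-disk serialization of `MESOURCE`/`METRANS` is not
publicly documented, so this package defines a stand-in encoding
(`chrom|start|end|strand|subfamily|source_type|transduced_length` and
`chrom|start|end|strand` or the literal `null`) and treats it as the
normative dialect; anything that deviates (multi-allelic ALTs, haploid or
half-called genotypes) is a hard error naming the offending line, not a
silent coercion. VCF coordinates are 1-based, BED intervals 0-based
half-open; all conversions live in `formats_io`.

A record is a transduction candidate iff `METRANS` is present and not
`null`. A record with `METRANS=null` is an ordinary MEI call even if a
stray `MESOURCE` accompanies it (kept in the pass-through map).

## QC filter

A call is kept iff `SR >= min_sr` (default 3) AND `ASSESS >= min_assess`
(default 3) AND its FILTER set intersects the keep set ({PASS, rSD}) AND
avoids the reject set ({ac0, hDP, lc}). The three conditions usually
expressed as chained `bcftools view` calls collapse into this one
conjunction; in particular a record tagged both `PASS` and `lc` is
dropped, because the rejection clause is unconditional. rSD calls
(unbalanced left/right breakpoint support) are kept deliberately: they
raise transduction-discovery sensitivity. Drop reasons are reported as
the first failing clause in the fixed order LOW_SR, LOW_ASSESS,
NO_KEEP_FILTER, REJECT_FILTER.

Candidate donors are restricted to full-length elements by annotated
interval span — at least 5900 bp (L1) and 1000 bp (SVA) — not by a
fraction of consensus length. 5′-truncated copies cannot drive
transduction, so shorter annotations are excluded outright.

## Two-tier classification

Candidates whose insertion junction falls in a segmental duplication are
removed before any scoring: homology in these regions confounds the
discordant-read signature that progenitor inference rests on.

**Insertion-point geometry.** A VCF insertion is anchored at the base
*before* the inserted sequence, so the insertion junction sits at the
0-based gap coordinate numerically equal to the 1-based POS. Point mode
(default) tests that junction against half-open `[start, end)` segdup
intervals — an insertion at an interval's right edge is outside it. Span
mode instead intersects `[pos, pos + SVLEN)`, for users who want the
whole assembled insertion tested. Only the offspring locus is filtered;
the source locus is not consulted.

Surviving candidates are HIGH-confidence iff all three clauses hold:

* **Support:** the record's SR count is at least `min_support_reads`
  (default 5). The read-support field is taken to be SR; discordant-pair
  counts are not added.
* **Length consistency:** `MESOURCE` transduced length strictly less than
  `SVLEN`. MELT reports the offspring length as TE + transduced segment
  but the source-side length without the TE, so a genuine event's SVLEN
  exceeds the source length by roughly one TE (~5 kb L1, ~1 kb SVA).
  Ties fail: "shorter than" is strict.
* **Active family:** donor subfamily in the configured active set
  (default L1HS, L1Ta, L1ta1d, L1T1d, SVA_D, SVA_E, SVA_F;
  case-insensitive). Donors with an undetermined subfamily count as
  active by default because MELT reports no subfamily for non-reference
  SVA sources, and excluding them would silently discard that entire
  donor class. Both the set and the undetermined rule are configurable,
  since authoritative activity lists differ between annotations.

LOW records carry *every* failing clause, in evaluation order, to support
audit. The per-type funnel satisfies
`n_total = n_removed_segdup + n_high + n_low` by construction, and
grouping HIGH records by (source_type, subfamily) sums back to `n_high`.

## Population-genetic summaries

Allele counting follows bcftools fill-tags semantics: a missing genotype
contributes 0 to AC and AN, so AN = 2 × non-missing genotypes in the
group. Groups are the whole cohort, a population or a super-population; a
variant is group-specific when its presence set (groups with AC > 0) has
size 1, and a singleton when global AC = 1.

The het/hom-alt ratio is, by default, the ratio of summed per-site het
counts to summed per-site hom-alt counts ("totals" mode): a mean of
per-site ratios is undefined wherever a site has no hom-alt carrier. The
per-site mean over defined sites is available as `mean_of_sites`. A zero
denominator reports infinity.

The HWE exact test enumerates every heterozygote count with the parity of
the minor allele count, conditional on the allele counts, with exact
log-factorial probabilities normalized by log-sum-exp (counts in the
thousands stay accurate to ~1e-14 against a rational-arithmetic oracle).
The two-sided p sums configurations with probability ≤ observed (with a
1e-10 relative guard so exactly-tied configurations count as extreme);
the excess-het tail sums `h >= h_obs`. Monomorphic sites give p = 1. No
mid-p variant is applied.

Insertion density divides per-chromosome counts by the full assembly
length in Mbp, N runs included (assemblies' masked fractions are part of
the denominator on purpose — density is per assembled megabase, not per
accessible megabase). Per-element transduction rates are
`100 × n_high / n_fulllength`, rounded to two decimals half-even for
report parity; the raw value is available with `ndigits=None`.

AF spectra bin sites with AN > 0 into contiguous (lo, hi] bins
partitioning [0, 1]; called-but-absent sites (AC = 0) go to a separate
"monomorphic" bucket so bin totals plus that bucket equal the number of
called sites.

## Progenitor mapping

Reference donors are identified by their exact (chrom, start, end)
triple; non-reference donors (themselves polymorphic insertions) by their
insertion point. No fuzzy merging is applied by default — no principled
merge window exists — but a snap-to-grid `merge_radius` is available.
Chromosome names are compared verbatim: alternate-haplotype contigs are
distinct chromosomes, so a link from an alt contig to its parent
chromosome is interchromosomal. Ranking is by offspring count, ties
broken by (chrom, start); the cumulative share is the running fraction of
all included offspring.

## 3′-end motif scan

The cleavage site is approximated by the annotated 3′ terminus of the
donor element (for minus-strand donors the window is reverse-complemented
so scanning always reads in transcript orientation). Offsets are measured
from motif start and windows are inclusive at both ends:

* **PAS:** AATAAA then ATTAAA (DNA), start offsets 10–40 nt upstream of
  the cleavage site; the hit nearest the cleavage site wins, first
  hexamer in configuration order on ties. Reported in RNA rendering.
* **USE:** TGTAN (N = A/C/G/T), start offsets 40–100 nt upstream of the
  PAS start. Only sought when a PAS exists — the element is defined
  relative to the signal.
* **DSE:** "GU-rich" has no quantitative community definition, so it is
  operationalized as any 20-nt sliding window with ≥ 60 % G+T inside the
  region 40–100 nt downstream of the PAS end (both parameters exposed).
  When no PAS is found the DSE window anchors at the cleavage site
  instead, so downstream GU-richness is still reported for signal-less
  donors.

Whether the upstream/downstream windows anchor at the PAS start or end is
ambiguous in the literature; here USE anchors at the PAS start and DSE at
the PAS end. Genomic N matches no motif letter and counts as non-GT.
Truncated windows at contig edges are scanned as far as available and
flagged.

## Synthetic cohorts

The generator emulates the structure of a 26-population,
5-super-population human cohort at one tenth scale (320 samples; the
per-population sizes are the 1KGP panel scaled ÷10). Defaults:

| parameter | default | rationale |
|---|---|---|
| loci | 300 L1 + 130 SVA | ~1/24 of a cohort-scale call set; keeps the suite fast while every code path stays populated |
| allele frequencies | beta(0.3, 4), clipped to [1e-4, 1] | rare-variant-skewed, most mass below 1 %, as polymorphic MEI loci show |
| genotypes | i.i.d. HWE draws ((1−p)², 2pq, p²); `excess_het(ε)` adds ε to the het weight and renormalizes | unrelated-panel assumption; the excess-het mode models genotyping artifacts |
| missingness | 2 % | typical cohort-scale genotype missingness |
| QC failures | 15 % of loci, one clause each | exercises every drop reason |
| transduction candidates | 10 % of QC-passing loci; labels HIGH/LOW/REMOVED at 0.53/0.39/0.08 | label mix follows the observed funnel proportions |
| transduced lengths | log-uniform on [7, 997] bp | the observed min–max range; log-uniform puts most mass at short segments, matching the observed medians qualitatively |
| TE consensus lengths | 6019 bp (L1), 1316 bp (SVA) | consensus-scale maxima |
| SVLEN jitter | ±10 bp | assembly noise; never large enough to flip the strict length inequality for HIGH plants |

LOW plants violate exactly one chosen clause; REMOVED plants are placed
strictly inside an emitted segdup interval; HIGH plants satisfy all
clauses and avoid segdups. Donor-flank FASTA records plant all eight
PAS/USE/DSE presence combinations at fixed in-window offsets (PAS start
25 nt upstream of cleavage, USE 60 nt upstream of the PAS, GT run 50 nt
downstream), plus an out-of-window decoy hexamer 5 nt upstream of the
cleavage site on every donor; scan windows destined to be motif-free are
scrubbed, with planted motifs protected from the scrubber. Everything is
driven by one integer seed and the same seed yields a byte-identical
bundle.

**What passing closed-loop tests show — and don't.** Zero-mismatch
recovery of planted QC outcomes and classification labels shows the
implementation computes exactly the documented deterministic functions of
the record fields. It does not validate MELT's upstream calling, real
SR/ASSESS error distributions, relatedness, reference bias, or segdup
annotation quality; genotypes are i.i.d. with no linkage or population
divergence beyond the panel labels, so population-specificity statistics
on synthetic data exercise definitions, not realistic sharing patterns.

## Statistical test conditions

The HWE type-I error check plants 10,000 loci at af = 0.2 with 500
samples and requires the rejection rate at α = 0.01 to stay below nominal
plus three binomial standard errors (exact tests are conservative).
Allele-frequency recovery asserts the ±3-SE band covers ≥ 99 % of loci
over cohort-like frequencies *in the normal regime* (expected minor
allele count ≥ 10, a condition on the planted parameter), plus an
unconditional check at af = 0.2: AC is exactly binomial by construction,
and below ~10 expected copies the ±3-SE normal band under-covers for any
correct estimator, so asserting 99 % there would test the approximation,
not the code.

## Known limitations

* The MESOURCE/METRANS encoding is a documented stand-in, not MELT's.
* Whether read support should include discordant pairs in addition to SR
  is unresolved; SR alone is used.
* Segdup filtering consults only the offspring locus.
* The cleavage coordinate is the annotated element end; real cleavage
  sites scatter around it.
* No LD, phasing, relatedness or ancestry inference; no read-level
  simulation.
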