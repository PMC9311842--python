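# transdx

Post-processing, validation and population-genetic characterization of
**3′ DNA transductions** mediated by non-LTR retroelements (LINE-1 and SVA)
in human cohort-scale mobile-element-insertion (MEI) call sets.

When transcription of an active L1 or SVA reads through a weak
polyadenylation site, the downstream genomic sequence is co-mobilized to a
new locus — a 3′ transduction. MEI callers such as MELT emit candidate
transduction calls as VCF records carrying a source-locus descriptor
(`MESOURCE`) and a transduced-segment descriptor (`METRANS`), but those raw
candidates need substantial downstream curation before they can be
interpreted. `transdx` implements that curation as a tested, reusable
pipeline for anyone working with MELT-style MEI call sets:

1. **Call-set QC** — keep calls with split-read support `SR ≥ 3`,
   breakpoint-evidence score `ASSESS ≥ 3`, FILTER in {`PASS`, `rSD`} and
   none of {`ac0`, `hDP`, `lc`}; restrict candidate donors to full-length
   elements (≥ 5900 bp for L1, ≥ 1000 bp for SVA).
2. **Two-tier classification** — remove candidates whose insertion point
   falls in a segmental duplication, then call a candidate
   **high-confidence** iff all three clauses hold, and **low-confidence**
   otherwise (with every failing clause recorded):
   * read support ≥ 5;
   * `MESOURCE` transduced length < `SVLEN` (the offspring's SVLEN includes
     the TE body, so it must strictly exceed the source-side segment);
   * donor subfamily retrotranspositionally active (L1HS/L1Ta/…/SVA_E/SVA_F;
     undetermined donors count as active).
3. **Population genetics** — stratified allele counts/frequencies
   (AC = 2·hom_alt + het, AN = 2·non-missing, per population,
   super-population or cohort-wide), singletons (global AC = 1),
   population specificity, het/hom-alt ratios, exact Hardy–Weinberg tests,
   insertions per Mbp, and transductions per full-length element.
4. **Progenitor–offspring mapping** — group offspring by donor locus,
   label links inter/intrachromosomal, rank prolific "master elements"
   with cumulative offspring shares.
5. **3′-end motif annotation** — scan each donor's 3′ terminus, in
   transcript orientation, for the polyadenylation signal (AAUAAA/AUUAAA,
   10–40 nt upstream of the cleavage site), the upstream sequence element
   (UGUAN, 40–100 nt upstream of the PAS) and a GU-rich downstream element
   (40–100 nt downstream).
6. **Synthetic cohorts** — a seeded generator emits every input the
   pipeline consumes (MELT-dialect VCF, element/segdup BED, 26-population
   panel, chrom.sizes, donor-flank FASTA) with a planted truth table, so
   the whole pipeline is testable closed-loop.

The Hardy–Weinberg test is the exact conditional test: given `n` genotypes
and minor allele count `n_m`, each admissible heterozygote count `h`
(same parity as `n_m`) has probability

```
P(h) ∝ 2^h · n! / ( ((n_m − h)/2)! · h! · (n − h − (n_m − h)/2)! )
```

The two-sided p-value sums all configurations no more probable than the
observed one; the excess-heterozygosity tail (`h ≥ h_obs`) flags
genotyping artifacts.

## Worked example

Generate a seeded synthetic cohort (320 samples, 26 populations) and
classify its transduction candidates:

```console
$ transdx simulate --seed 7 --out-dir demo
wrote bundle to demo (430 loci)
$ transdx classify-td --vcf demo/cohort.vcf --segdup demo/segdups.bed \
      --out demo/classified.tsv --funnel demo/funnel.tsv
L1: 31 -> 30 -> 13 high + 17 low; SVA: 17 -> 16 -> 12 high + 4 low
$ cat demo/funnel.tsv
me_type	n_total	n_removed_segdup	n_after_segdup	n_high	n_low
L1	31	1	30	13	17
SVA	17	1	16	12	4
```

Reading: of 31 L1 candidates, 1 landed in a segmental duplication and was
removed; of the 30 survivors, 13 pass all three high-confidence clauses
and 17 fail at least one (`classified.tsv` lists which —
`LOW_SUPPORT`, `LENGTH_INCONSISTENT` or `INACTIVE_FAMILY`). The funnel
always satisfies `n_total = n_removed_segdup + n_high + n_low`.

Scan the bundled donor flanks for 3′-processing motifs:

```console
$ transdx motifscan --fasta demo/flanks.fasta \
      --sources demo/flank_sources.bed --out demo/motifs.tsv
annotated 8 sources
$ head -3 demo/motifs.tsv
locus	element	source_type	pas	use	dse
donor_0_pas1_use1_dse1:51-260	L1HS	reference	AAUAAA	UGUAG	GU-rich
donor_1_pas1_use1_dse0:51-260	L1HS	reference	AUUAAA	UGUAA	No
```

Each row reports the hexamer found (RNA rendering), the matched UGUAN
element ('.' when absent) and whether any 20-nt window 40–100 nt
downstream is ≥ 60 % G+T. `transdx run-all --config run.yaml` chains all
stages from one YAML file; `transdx --help` lists the remaining
subcommands (`filter-mei`, `popstats`, `progenitors`).

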