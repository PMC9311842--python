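"""Seeded synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes — a MELT-dialect MEI VCF, an
element track and a segmental-duplication track as BED, a sample panel, a
chrom.sizes table and donor-flank FASTA — together with a truth table
recording what was planted at each locus, so that every pipeline stage can
be tested closed-loop without any external data.

The default configuration emulates the structure of a 26-population /
5-super-population human cohort (panel sizes are the 1KGP population sizes
scaled by one tenth, 320 samples in total), with MEI loci at
Hardy-Weinberg-structured genotypes, rare-variant-skewed allele
frequencies, transduction candidates planted with controlled
source/offspring length relationships (transduced segments 7-997 bp on
top of consensus TE lengths of 6019 bp for L1 and 1316 bp for SVA), and
QC failures / classification outcomes planted one clause at a time.

Everything is driven by one integer seed: the same seed produces a
byte-identical file bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    HIGH,
    INACTIVE_FAMILY,
    LENGTH_INCONSISTENT,
    LOW,
    LOW_SUPPORT,
    REMOVED_SEGDUP,
    SEGDUP_OVERLAP,
    DEFAULT_ACTIVE_SUBFAMILIES,
    SegdupIndex,
)
from .formats_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenomicInterval,
    MeiRecord,
    SamplePanel,
    SourceDescriptor,
    TransductionRecord,
    TransSegment,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_mei_vcf,
)
from .motifs import reverse_complement

__all__ = [
    "SimConfig",
    "CohortBundle",
    "DEFAULT_POPULATIONS",
    "simulate_genotypes",
    "plant_transduction",
    "simulate_cohort",
    "simulate_flanks",
]

#: (population, super-population, n_samples): 1KGP panel scaled by 1/10.
DEFAULT_POPULATIONS: tuple[tuple[str, str, int], ...] = (
    ("ASW", "AFR", 7), ("YRI", "AFR", 18), ("LWK", "AFR", 10),
    ("GWD", "AFR", 18), ("MSL", "AFR", 10), ("ESN", "AFR", 15),
    ("ACB", "AFR", 12),
    ("MXL", "AMR", 10), ("PUR", "AMR", 14), ("CLM", "AMR", 13),
    ("PEL", "AMR", 12),
    ("CEU", "EUR", 18), ("TSI", "EUR", 11), ("FIN", "EUR", 10),
    ("GBR", "EUR", 9), ("IBS", "EUR", 16),
    ("GIH", "SAS", 10), ("PJL", "SAS", 15), ("BEB", "SAS", 13),
    ("STU", "SAS", 11), ("ITU", "SAS", 11),
    ("CHB", "EAS", 10), ("JPT", "EAS", 10), ("CHS", "EAS", 16),
    ("CDX", "EAS", 9), ("KHV", "EAS", 12),
)

DEFAULT_CHROM_SIZES: dict[str, int] = {
    "chr1": 8_000_000,
    "chr2": 6_000_000,
    "chr3": 5_000_000,
    "chrX": 4_000_000,
    "chrY": 1_000_000,
}

_ACTIVE_BY_TYPE = {
    "L1": ("L1HS", "L1Ta", "L1T1d"),
    "SVA": ("SVA_E", "SVA_F", "SVA_D"),
}
_INACTIVE_BY_TYPE = {"L1": ("L1PA4", "L1PA7"), "SVA": ("SVA_A", "SVA_B")}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    populations: tuple[tuple[str, str, int], ...] = DEFAULT_POPULATIONS
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )
    n_loci: Mapping[str, int] = field(
        default_factory=lambda: {"L1": 300, "SVA": 130}
    )
    #: allele-frequency law: ("beta", a, b) or ("point", p). The default
    #: beta(0.3, 4) concentrates mass below 1%, mirroring the rare-variant
    #: skew of polymorphic MEI loci.
    af_distribution: tuple = ("beta", 0.3, 4.0)
    hwe_mode: tuple = ("exact_hwe",)  # or ("excess_het", eps)
    missing_rate: float = 0.02
    qc_fail_fraction: float = 0.15
    #: fraction of QC-passing loci that carry a transduction candidate
    transduction_fraction: float = 0.10
    label_proportions: Mapping[str, float] = field(
        default_factory=lambda: {HIGH: 0.53, LOW: 0.39, REMOVED_SEGDUP: 0.08}
    )
    transduced_length_range: tuple[int, int] = (7, 997)
    te_consensus_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"L1": 6019, "SVA": 1316}
    )
    svlen_jitter: int = 10
    nonreference_source_fraction: float = 0.15
    n_elements: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"L1": (40, 15), "SVA": (25, 10)}
    )  # (full-length, truncated) per ME type
    n_segdups_per_chrom: int = 8
    segdup_length_range: tuple[int, int] = (20_000, 120_000)

    def __post_init__(self) -> None:
        if not 0 <= self.transduction_fraction <= 1:
            raise ValueError("transduction_fraction must be in [0, 1]")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction must be in [0, 1]")
        total = sum(self.label_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("label_proportions must sum to 1")
        lo, hi = self.transduced_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad transduced_length_range")

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.populations)


@dataclass
class CohortBundle:
    """Paths of an emitted synthetic bundle plus in-memory truth."""

    out_dir: Path
    vcf: Path
    elements_bed: Path
    segdups_bed: Path
    panel_tsv: Path
    chrom_sizes_tsv: Path
    flanks_fasta: Path
    flank_sources_bed: Path
    truth_tsv: Path
    flank_truth_tsv: Path
    truth: pd.DataFrame
    flank_truth: pd.DataFrame
    panel: SamplePanel


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    af: float,
    n_samples: int,
    hwe_mode: tuple = ("exact_hwe",),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw i.i.d. diploid genotypes at allele frequency *af*.

    ``("exact_hwe",)`` uses probabilities ((1-p)^2, 2p(1-p), p^2);
    ``("excess_het", eps)`` adds eps to the heterozygote weight and
    renormalizes, modelling the excess-heterozygosity signature of
    genotyping artifacts.
    """
    if not 0 <= af <= 1:
        raise ValueError("af must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    p, q = af, 1.0 - af
    w = np.array([q * q, 2 * p * q, p * p])
    if hwe_mode[0] == "excess_het":
        w[1] += hwe_mode[1]
        w = w / w.sum()
    elif hwe_mode[0] != "exact_hwe":
        raise ValueError(f"unknown hwe_mode {hwe_mode!r}")
    return rng.choice(
        np.array([HOM_REF, HET, HOM_ALT], dtype=np.int8), size=n_samples, p=w
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# transduction planting
# ---------------------------------------------------------------------------


def _loguniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def plant_transduction(
    source: GenomicInterval,
    label: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    segdups: Sequence[GenomicInterval],
    variant_id: str,
    reason: str | None = None,
    genotypes: np.ndarray | None = None,
    pos: int | None = None,
    chrom: str | None = None,
) -> tuple[TransductionRecord, dict]:
    """Plant one transduction candidate destined for *label*.

    HIGH plants satisfy all three classifier clauses (SR >= 5, source
    transduced length strictly below SVLEN, active subfamily) and avoid
    segdups. LOW plants violate exactly the requested *reason* clause
    (drawn uniformly when not given). REMOVED plants are positioned
    inside an emitted segdup interval. Returns the record and its truth
    row.
    """
    me_type = source.me_type
    consensus = cfg.te_consensus_lengths[me_type]
    lo, hi = cfg.transduced_length_range
    tlen = _loguniform_int(rng, lo, hi)
    sr = 5 + int(rng.poisson(3))
    jitter = int(rng.integers(-cfg.svlen_jitter, cfg.svlen_jitter + 1))
    svlen = consensus + tlen + jitter
    subfamily = source.subfamily
    if subfamily.upper() not in DEFAULT_ACTIVE_SUBFAMILIES:
        subfamily = str(rng.choice(_ACTIVE_BY_TYPE[me_type]))
    if label == LOW:
        if reason is None:
            reason = str(
                rng.choice([LOW_SUPPORT, LENGTH_INCONSISTENT, INACTIVE_FAMILY])
            )
        if reason == LOW_SUPPORT:
            sr = int(rng.integers(3, 5))  # still QC-passing, below support
        elif reason == LENGTH_INCONSISTENT:
            # tie or shorter offspring: strict inequality must fail
            svlen = tlen if rng.random() < 0.5 else max(0, tlen - int(rng.integers(1, 50)))
        elif reason == INACTIVE_FAMILY:
            subfamily = str(rng.choice(_INACTIVE_BY_TYPE[me_type]))
        else:
            raise ValueError(f"unknown LOW reason {reason!r}")
    elif label == REMOVED_SEGDUP:
        reason = SEGDUP_OVERLAP
        if not segdups:
            raise ValueError("REMOVED plant requires segdup intervals")
        sd = segdups[int(rng.integers(len(segdups)))]
        chrom = sd.chrom
        pos = int(rng.integers(sd.start + 1, sd.end))  # junction strictly inside
    elif label == HIGH:
        reason = None
    else:
        raise ValueError(f"unknown label {label!r}")
    if chrom is None or pos is None:
        raise ValueError("non-REMOVED plants need an insertion chrom/pos")
    nonref = rng.random() < cfg.nonreference_source_fraction
    if nonref:
        point = source.start
        mesource = SourceDescriptor(
            source.chrom, point, point, source.strand,
            "UNDETERMINED" if me_type == "SVA" else subfamily,
            "nonreference", tlen,
        )
        if label == LOW and reason == INACTIVE_FAMILY and me_type == "SVA":
            # UNDETERMINED counts as active; force a reference source so
            # the planted clause actually fails
            mesource = replace(
                mesource, subfamily=subfamily, source_type="nonreference"
            )
    else:
        mesource = SourceDescriptor(
            source.chrom, source.start, source.end, source.strand,
            subfamily, "reference", tlen,
        )
    if source.strand == "-":
        seg = TransSegment(source.chrom, max(0, source.start - tlen), source.start, "-")
    else:
        seg = TransSegment(source.chrom, source.end, source.end + tlen, "+")
    record = TransductionRecord(
        chrom=chrom,
        pos=pos,
        variant_id=variant_id,
        me_type=me_type,
        subfamily=subfamily,
        svlen=svlen,
        assess=3 + int(rng.poisson(3)),
        sr=sr,
        filter_flags=frozenset({"PASS"}),
        genotypes=genotypes if genotypes is not None else np.empty(0, np.int8),
        mesource=mesource,
        metrans=seg,
    )
    truth = {
        "variant_id": variant_id,
        "label": label,
        "reason": reason or "",
        "source_chrom": mesource.chrom,
        "source_start": mesource.start,
        "source_end": mesource.end,
        "source_type": mesource.source_type,
        "source_subfamily": mesource.subfamily,
        "transduced_length": tlen,
        "svlen": svlen,
    }
    return record, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def _build_panel(cfg: SimConfig, rng: np.random.Generator) -> SamplePanel:
    rows = []
    for pop, sup, n in cfg.populations:
        for i in range(n):
            rows.append(
                {
                    "sample": f"{pop}{i:03d}",
                    "population": pop,
                    "super_population": sup,
                    "sex": "M" if rng.random() < 0.5 else "F",
                }
            )
    return SamplePanel(pd.DataFrame(rows))


def _random_elements(
    cfg: SimConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    chroms = [c for c in cfg.chrom_sizes if c != "chrY"]
    out: list[GenomicInterval] = []
    specs = {
        "L1": {"full": (5900, 6019), "trunc": (500, 5899)},
        "SVA": {"full": (1000, 1316), "trunc": (300, 999)},
    }
    for me_type, (n_full, n_trunc) in cfg.n_elements.items():
        for kind, n in (("full", n_full), ("trunc", n_trunc)):
            lo, hi = specs[me_type][kind]
            for i in range(n):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, cfg.chrom_sizes[chrom] - length))
                fams = _ACTIVE_BY_TYPE[me_type] + _INACTIVE_BY_TYPE[me_type]
                fam = str(fams[int(rng.integers(len(fams)))])
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(
                    GenomicInterval(
                        chrom, start, start + length,
                        f"{fam}_{me_type}_{kind}_{i}", strand, me_type, fam,
                    )
                )
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def _random_segdups(
    cfg: SimConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    out = []
    lo, hi = cfg.segdup_length_range
    for chrom, size in cfg.chrom_sizes.items():
        for _ in range(cfg.n_segdups_per_chrom):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, size - length)))
            out.append(GenomicInterval(chrom, start, start + length, "segdup"))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def _draw_af(cfg: SimConfig, rng: np.random.Generator) -> float:
    dist = cfg.af_distribution
    if dist[0] == "beta":
        return float(np.clip(rng.beta(dist[1], dist[2]), 1e-4, 1.0))
    if dist[0] == "point":
        return float(dist[1])
    raise ValueError(f"unknown af_distribution {dist!r}")


def _free_position(
    cfg: SimConfig,
    rng: np.random.Generator,
    segdup_index: SegdupIndex,
) -> tuple[str, int]:
    chroms = list(cfg.chrom_sizes)
    # chrY kept sparse: most draws go to the larger contigs anyway
    weights = np.array([cfg.chrom_sizes[c] for c in chroms], float)
    weights /= weights.sum()
    while True:
        chrom = str(rng.choice(chroms, p=weights))
        pos = int(rng.integers(1, cfg.chrom_sizes[chrom]))
        if not segdup_index.overlaps(chrom, pos, pos + 1):
            return chrom, pos


_QC_CLAUSES = ("LOW_SR", "LOW_ASSESS", "NO_KEEP_FILTER", "REJECT_FILTER")


def simulate_cohort(cfg: SimConfig, out_dir: str | Path) -> CohortBundle:
    """Emit a complete synthetic input bundle plus its truth table.

    Same seed, same config => byte-identical files. The truth table has
    one row per emitted MEI locus with the planted allele frequency,
    genotype counts, QC outcome and (for candidates) the destined
    classification label and reason.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    panel = _build_panel(cfg, rng)
    elements = _random_elements(cfg, rng)
    segdups = _random_segdups(cfg, rng)
    segdup_index = SegdupIndex(segdups)
    fulllength = [
        iv
        for iv in elements
        if iv.length >= (5900 if iv.me_type == "L1" else 1000)
    ]
    active_full = {
        t: [
            iv
            for iv in fulllength
            if iv.me_type == t
            and iv.subfamily.upper() in DEFAULT_ACTIVE_SUBFAMILIES
        ]
        for t in cfg.n_loci
    }

    records: list[MeiRecord] = []
    truth_rows: list[dict] = []
    for me_type in sorted(cfg.n_loci):
        for i in range(cfg.n_loci[me_type]):
            vid = f"{me_type}_{i:05d}"
            af = _draw_af(cfg, rng)
            gts = simulate_genotypes(af, cfg.n_samples, cfg.hwe_mode, rng)
            if cfg.missing_rate > 0:
                miss = rng.random(cfg.n_samples) < cfg.missing_rate
                gts = gts.copy()
                gts[miss] = MISSING
            qc_fail = rng.random() < cfg.qc_fail_fraction
            sr = 3 + int(rng.poisson(4))
            assess = 3 + int(rng.poisson(3))
            flags = frozenset({"rSD"} if rng.random() < 0.1 else {"PASS"})
            qc_reason = ""
            if qc_fail:
                qc_reason = str(rng.choice(_QC_CLAUSES))
                if qc_reason == "LOW_SR":
                    sr = int(rng.integers(0, 3))
                elif qc_reason == "LOW_ASSESS":
                    assess = int(rng.integers(0, 3))
                elif qc_reason == "NO_KEEP_FILTER":
                    flags = frozenset({"hDP"})
                else:
                    flags = frozenset({"PASS", "lc"})
            base = {
                "variant_id": vid,
                "me_type": me_type,
                "af": af,
                "n_hom_ref": int((gts == HOM_REF).sum()),
                "n_het": int((gts == HET).sum()),
                "n_hom_alt": int((gts == HOM_ALT).sum()),
                "n_missing": int((gts == MISSING).sum()),
                "qc_pass": not qc_fail,
                "qc_reason": qc_reason,
            }
            is_candidate = (
                not qc_fail
                and active_full[me_type]
                and rng.random() < cfg.transduction_fraction
            )
            if is_candidate:
                labels = list(cfg.label_proportions)
                probs = np.array(
                    [cfg.label_proportions[l] for l in labels], float
                )
                label = str(rng.choice(labels, p=probs))
                pool = active_full[me_type]
                source = pool[int(rng.integers(len(pool)))]
                chrom, pos = _free_position(cfg, rng, segdup_index)
                rec, td_truth = plant_transduction(
                    source,
                    label,
                    cfg,
                    rng,
                    segdups=segdups,
                    variant_id=vid,
                    genotypes=gts,
                    chrom=chrom,
                    pos=pos,
                )
                records.append(rec)
                row = {**base, "is_transduction": True, **td_truth}
                row["chrom"], row["pos"] = rec.chrom, rec.pos
                truth_rows.append(row)
            else:
                chrom, pos = _free_position(cfg, rng, segdup_index)
                svlen = int(
                    rng.integers(
                        33, cfg.te_consensus_lengths[me_type] + 1
                    )
                )
                records.append(
                    MeiRecord(
                        chrom=chrom,
                        pos=pos,
                        variant_id=vid,
                        me_type=me_type,
                        subfamily=str(
                            rng.choice(_ACTIVE_BY_TYPE[me_type])
                        ),
                        svlen=svlen,
                        assess=assess,
                        sr=sr,
                        filter_flags=flags,
                        genotypes=gts,
                    )
                )
                truth_rows.append(
                    {
                        **base,
                        "chrom": chrom,
                        "pos": pos,
                        "is_transduction": False,
                        "label": "",
                        "reason": "",
                        "svlen": svlen,
                    }
                )
    # QC-failing transduction-shaped records never planted: candidates are
    # drawn from QC-passing loci so classification truth stays decoupled
    # from the QC stage.

    chrom_order = {c: i for i, c in enumerate(cfg.chrom_sizes)}
    order = sorted(
        range(len(records)),
        key=lambda i: (chrom_order[records[i].chrom], records[i].pos),
    )
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])

    flank_seqs, flank_truth = simulate_flanks(rng=rng)

    paths = {
        "vcf": out_dir / "cohort.vcf",
        "elements_bed": out_dir / "elements.bed",
        "segdups_bed": out_dir / "segdups.bed",
        "panel_tsv": out_dir / "panel.tsv",
        "chrom_sizes_tsv": out_dir / "chrom.sizes",
        "flanks_fasta": out_dir / "flanks.fasta",
        "flank_sources_bed": out_dir / "flank_sources.bed",
        "truth_tsv": out_dir / "truth.tsv",
        "flank_truth_tsv": out_dir / "flank_truth.tsv",
    }
    write_mei_vcf(records, paths["vcf"], panel.samples, cfg.chrom_sizes)
    write_bed(elements, paths["elements_bed"])
    write_bed(segdups, paths["segdups_bed"])
    panel.write(paths["panel_tsv"])
    write_chrom_sizes(cfg.chrom_sizes, paths["chrom_sizes_tsv"])
    write_fasta(flank_seqs, paths["flanks_fasta"])
    write_bed(
        (
            GenomicInterval(
                row["name"], row["element_start"], row["element_end"],
                row["name"], row["strand"], "L1", "L1HS",
            )
            for _, row in flank_truth.iterrows()
        ),
        paths["flank_sources_bed"],
    )
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    flank_truth.to_csv(paths["flank_truth_tsv"], sep="\t", index=False)
    return CohortBundle(
        out_dir=out_dir,
        truth=truth,
        flank_truth=flank_truth,
        panel=panel,
        **paths,
    )


# ---------------------------------------------------------------------------
# donor flanks with planted 3'-end motifs
# ---------------------------------------------------------------------------

_FLANK_LEN = 400
_CLEAVE = 260  # transcript-orientation cleavage index
_PAS_OFFSET = 25  # planted PAS start, nt upstream of cleavage
_USE_OFFSET = 60  # planted USE start, nt upstream of PAS start
_DSE_DISTANCE = 50  # planted GT-run start, nt downstream of PAS end


def default_flank_spec() -> list[dict]:
    """All 8 presence/absence combinations of {PAS, USE, DSE}.

    Two of the PAS-positive donors are placed on the minus strand; one
    uses the ATTAAA variant hexamer. Every donor also carries an
    out-of-window decoy hexamer 5 nt upstream of the cleavage site.
    """
    spec = []
    combos = [
        (p, u, d) for p in (True, False) for u in (True, False) for d in (True, False)
    ]
    for i, (p, u, d) in enumerate(combos):
        spec.append(
            {
                "name": f"donor_{i}_pas{int(p)}_use{int(u)}_dse{int(d)}",
                "pas": ("ATTAAA" if i == 1 else "AATAAA") if p else None,
                "use": u,
                "dse": d,
                "strand": "-" if i in (2, 3) else "+",
            }
        )
    return spec


def _mutate_matches(
    seq: list[str],
    patterns: Sequence[str],
    positions: Sequence[int],
    protected: set[int] = frozenset(),
) -> None:
    """Destroy any pattern match starting at the given positions.

    A match is broken by setting one of its bases to 'C' (no scanned
    pattern contains C). Bases at *protected* indices — planted motifs —
    are never touched; every unintended match overlaps a plant by at most
    part of its length, so a mutable base always exists.
    """
    from .motifs import _matches

    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for pos in positions:
            for pat in patterns:
                if _matches(s, pos, pat):
                    for i in range(pos, pos + len(pat)):
                        if i not in protected:
                            seq[i] = "C"
                            break
                    else:  # fully protected: planted on purpose
                        continue
                    changed = True
                    s = "".join(seq)


def _low_gt_region(rng: np.random.Generator, n: int, k: int, thr: float) -> str:
    """Random region guaranteed to have no k-window with GT fraction >= thr."""
    letters = np.array(list("ACGT"))
    probs = np.array([0.38, 0.38, 0.12, 0.12])
    while True:
        region = "".join(rng.choice(letters, size=n, p=probs))
        gt = [1 if c in "GT" else 0 for c in region]
        worst = max(
            (sum(gt[i : i + k]) for i in range(0, max(1, n - k + 1))),
            default=0,
        )
        if worst / k < thr:
            return region


def simulate_flanks(
    spec: Sequence[Mapping] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Donor flank sequences with planted PAS/USE/DSE combinations.

    Returns ({name: genomic sequence}, truth frame). Each record is one
    synthetic contig; the donor element occupies [50, 260) in transcript
    orientation (reverse-complemented on disk for minus-strand donors).
    Motifs destined to be absent are scrubbed from their scan windows;
    decoy hexamers sit outside the PAS window.
    """
    rng = np.random.default_rng() if rng is None else rng
    if spec is None:
        spec = default_flank_spec()
    letters = np.array(list("ACGT"))
    bg_probs = np.array([0.3, 0.3, 0.2, 0.2])
    seqs: dict[str, str] = {}
    rows = []
    for entry in spec:
        seq = list("".join(rng.choice(letters, size=_FLANK_LEN, p=bg_probs)))
        # scrub the PAS scan window (motif starts cleave-40..cleave-10)
        pas_positions = [ _CLEAVE - o for o in range(10, 41) ]
        _mutate_matches(seq, ["AATAAA", "ATTAAA"], pas_positions)
        pas_hex = entry["pas"]
        pas_start = _CLEAVE - _PAS_OFFSET
        pas_end = pas_start + 6
        # scrub the USE window relative to where a PAS would sit
        use_positions = [pas_start - o for o in range(40, 101)]
        _mutate_matches(seq, ["TGTAN"], use_positions)
        # DSE region: depress or plant GT content. The scan anchors at the
        # PAS end when one exists, else at the cleavage site.
        dse_anchor = pas_end if pas_hex else _CLEAVE
        dse_lo = dse_anchor + 40 - 1
        dse_hi = dse_anchor + 100
        region = _low_gt_region(rng, dse_hi - dse_lo, 20, 0.6)
        seq[dse_lo:dse_hi] = list(region)
        if entry["dse"]:
            gt_run = "".join(
                "G" if rng.random() < 0.5 else "T" for _ in range(20)
            )
            start = dse_anchor + _DSE_DISTANCE - 1
            seq[start : start + 20] = list(gt_run)
        if entry["use"]:
            use = "TGTA" + str(rng.choice(list("ACGT")))
            start = pas_start - _USE_OFFSET
            seq[start : start + 5] = list(use)
        if pas_hex:
            seq[pas_start:pas_end] = list(pas_hex)
        # out-of-window decoy hexamer, 5 nt upstream of cleavage
        seq[_CLEAVE - 5 : _CLEAVE + 1] = list("AATAAA")
        # planting can create fresh matches overlapping a plant edge;
        # re-scrub the scan windows around the protected plants
        protected = set(range(_CLEAVE - 5, _CLEAVE + 1))
        if pas_hex:
            protected |= set(range(pas_start, pas_end))
        if entry["use"]:
            protected |= set(range(pas_start - _USE_OFFSET, pas_start - _USE_OFFSET + 5))
        if entry["dse"]:
            dse_start = (pas_end if pas_hex else _CLEAVE) + _DSE_DISTANCE - 1
            protected |= set(range(dse_start, dse_start + 20))
        _mutate_matches(
            seq,
            ["AATAAA", "ATTAAA"],
            [p for p in pas_positions if not (pas_hex and p == pas_start)],
            protected,
        )
        _mutate_matches(
            seq,
            ["TGTAN"],
            [p for p in use_positions if not (entry["use"] and p == pas_start - _USE_OFFSET)],
            protected,
        )
        transcript = "".join(seq)
        if entry["strand"] == "-":
            genomic = reverse_complement(transcript)
            start, end = _FLANK_LEN - _CLEAVE, _FLANK_LEN - 50
        else:
            genomic = transcript
            start, end = 50, _CLEAVE
        seqs[entry["name"]] = genomic
        rows.append(
            {
                "name": entry["name"],
                "strand": entry["strand"],
                "element_start": start,
                "element_end": end,
                "pas_planted": pas_hex or "",
                "pas_offset": _PAS_OFFSET if pas_hex else "",
                "use_planted": bool(entry["use"]),
                "dse_planted": bool(entry["dse"]),
            }
        )
    return seqs, pd.DataFrame(rows)
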