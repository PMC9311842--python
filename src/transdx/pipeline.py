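"""End-to-end orchestration: QC -> classification -> popgen -> progenitors -> motifs.

One :class:`RunConfig` names every input; :func:`run_all` executes the
stages in order, logs one structured line per stage with its input/output
record counts (so the classification funnel can be audited from the log
alone), and writes the report TSVs. All stages are deterministic; any
randomness lives in the synthetic-cohort generator only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

from . import popgen
from .classify import HIGH, ClassifierConfig, classify_cohort
from .formats_io import (
    SamplePanel,
    read_bed,
    read_chrom_sizes,
    read_mei_vcf,
    write_report,
)
from .motifs import MotifConfig, annotate_sources
from .progenitors import build_map, rank_sources
from .qc import QCThresholds, filter_cohort, select_fulllength_sources

logger = logging.getLogger("transdx")

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    vcf: Path
    panel: Path
    chrom_sizes: Path
    out_dir: Path
    elements_bed: Path | None = None
    segdups_bed: Path | None = None
    fasta: Path | None = None
    #: explicit donor loci to motif-scan; falls back to the full-length
    #: subset of elements_bed when absent
    motif_sources_bed: Path | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    #: proceed without a segdup track (no REMOVED tier) instead of failing
    allow_missing_segdups: bool = False

    def __post_init__(self) -> None:
        for name in ("vcf", "panel", "chrom_sizes"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        self.out_dir = Path(self.out_dir)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_all(config: RunConfig) -> dict[str, object]:
    """Run the full pipeline; return report paths and the funnel."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    panel = SamplePanel.read(config.panel)
    sizes = read_chrom_sizes(config.chrom_sizes)
    records = _read(config, panel)
    logger.info("stage=read n_records=%d n_samples=%d", len(records), len(panel))

    kept, dropped = _qc(records, config)
    logger.info("stage=qc n_in=%d n_kept=%d n_dropped=%d", len(records), len(kept), len(dropped))
    paths["qc_drops"] = out / "qc_drops.tsv"
    write_report(
        (
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "me_type": r.me_type,
                "reason": reason,
            }
            for r, reason in dropped
        ),
        paths["qc_drops"],
        "qc_drops",
    )

    candidates = [r for r in kept if r.is_transduction]
    segdups = _read_segdups(config)
    classified, funnel = _classify(candidates, segdups, config)
    logger.info(
        "stage=classify n_candidates=%d funnel=%s",
        len(candidates),
        {t: (f.n_total, f.n_removed_segdup, f.n_high, f.n_low) for t, f in funnel.items()},
    )
    paths["funnel"] = out / "funnel.tsv"
    write_report(
        (
            {
                "me_type": t,
                "n_total": f.n_total,
                "n_removed_segdup": f.n_removed_segdup,
                "n_after_segdup": f.n_after_segdup,
                "n_high": f.n_high,
                "n_low": f.n_low,
            }
            for t, f in sorted(funnel.items())
        ),
        paths["funnel"],
        "funnel",
    )
    paths["classified"] = out / "classified.tsv"
    write_report(
        (
            {
                "variant_id": ct.record.variant_id,
                "chrom": ct.record.chrom,
                "pos": ct.record.pos,
                "me_type": ct.record.me_type,
                "label": ct.label,
                "reasons": ",".join(ct.reasons),
            }
            for ct in classified
        ),
        paths["classified"],
        "classified",
    )

    high = [ct.record for ct in classified if ct.label == HIGH]
    paths.update(_popstats(high, kept, panel, sizes, out))
    logger.info("stage=popstats n_high=%d n_sites=%d", len(high), len(kept))

    summaries = build_map(classified, include="HIGH")
    ranked = rank_sources(summaries)
    paths["progenitors"] = out / "progenitors.tsv"
    write_report(
        (
            {
                "source_chrom": s.key.chrom,
                "source_start": s.key.start,
                "source_end": s.key.end,
                "source_type": s.key.source_type,
                "subfamily": s.key.subfamily,
                "n_offspring": s.n_offspring,
                "n_inter": s.n_inter,
                "n_intra": s.n_intra,
                "cumulative_share": f"{share:.4f}",
            }
            for s, share in ranked
        ),
        paths["progenitors"],
        "progenitors",
    )
    logger.info("stage=progenitors n_sources=%d", len(summaries))

    if config.fasta is not None and (
        config.motif_sources_bed is not None or config.elements_bed is not None
    ):
        paths["motifs"] = out / "motifs.tsv"
        annotations = _motifs(config)
        write_report(
            (a.to_row() for a in annotations), paths["motifs"], "motifs"
        )
        logger.info("stage=motifs n_sources=%d", len(annotations))

    paths["funnel_counts"] = funnel
    return paths


@_stage("read")
def _read(config: RunConfig, panel: SamplePanel):
    return read_mei_vcf(config.vcf, panel)


@_stage("qc")
def _qc(records, config: RunConfig):
    return filter_cohort(records, config.qc)


def _read_segdups(config: RunConfig):
    if config.segdups_bed is None or not Path(config.segdups_bed).exists():
        if not config.allow_missing_segdups:
            raise PipelineError(
                "stage 'classify' failed: segdup track missing "
                "(set allow_missing_segdups to proceed without the REMOVED tier)"
            )
        logger.warning("no segdup track: classification has no REMOVED tier")
        return []
    return read_bed(config.segdups_bed)


@_stage("classify")
def _classify(candidates, segdups, config: RunConfig):
    return classify_cohort(candidates, segdups, config.classifier)


@_stage("popstats")
def _popstats(high, kept, panel, sizes, out: Path) -> dict[str, Path]:
    paths = {}
    groups = ["ALL"] + panel.superpopulations
    paths["popstats"] = out / "popstats.tsv"
    write_report(
        (
            {
                "variant_id": s.variant_id,
                "group": s.group,
                "ac": s.ac,
                "an": s.an,
                "af": f"{s.af:.6f}",
            }
            for r in high
            for s in (popgen.allele_summary(r, panel, g) for g in groups)
        ),
        paths["popstats"],
        "popstats",
    )
    paths["hwe"] = out / "hwe.tsv"
    rows = []
    for r in kept:
        n_rr, n_het, n_aa, _ = r.genotype_counts()
        h = popgen.hwe_exact(n_rr, n_het, n_aa)
        rows.append(
            {
                "variant_id": r.variant_id,
                "n_hom_ref": n_rr,
                "n_het": n_het,
                "n_hom_alt": n_aa,
                "p_two_sided": f"{h.p_two_sided:.6g}",
                "p_excess_het": f"{h.p_excess_het:.6g}",
            }
        )
    write_report(rows, paths["hwe"], "hwe")
    paths["density"] = out / "density.tsv"
    dens = popgen.density_per_mbp(kept, sizes)
    counts = {c: 0 for c in sizes}
    for r in kept:
        counts[r.chrom] += 1
    write_report(
        (
            {
                "chrom": c,
                "n_insertions": counts[c],
                "length_bp": sizes[c],
                "per_mbp": f"{dens[c]:.4f}",
            }
            for c in sizes
        ),
        paths["density"],
        "density",
    )
    return paths


@_stage("motifs")
def _motifs(config: RunConfig):
    if config.motif_sources_bed is not None:
        sources = read_bed(config.motif_sources_bed)
    else:
        elements = read_bed(config.elements_bed)
        sources = select_fulllength_sources(
            [iv for iv in elements if iv.me_type in config.qc.min_source_length],
            config.qc,
        )
    genome = Fasta(str(config.fasta))
    return annotate_sources(genome, sources, config.motif)
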