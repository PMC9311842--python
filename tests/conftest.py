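import numpy as np
import pytest

from transdx.formats_io import (
    GenomicInterval,
    MeiRecord,
    SamplePanel,
    SourceDescriptor,
    TransductionRecord,
    TransSegment,
    read_mei_vcf,
)
from transdx.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default seeded synthetic cohort, emitted once per session."""
    out = tmp_path_factory.mktemp("sim") / "bundle"
    return simulate_cohort(SimConfig(seed=11), out)


@pytest.fixture(scope="session")
def panel(bundle) -> SamplePanel:
    return SamplePanel.read(bundle.panel_tsv)


@pytest.fixture(scope="session")
def records(bundle, panel):
    return read_mei_vcf(bundle.vcf, panel)


def mk_record(
    sr=6,
    assess=5,
    flags=("PASS",),
    svlen=6100,
    me_type="L1",
    chrom="chr1",
    pos=1000,
    vid="v1",
    genotypes=(),
    subfamily="L1HS",
):
    return MeiRecord(
        chrom=chrom,
        pos=pos,
        variant_id=vid,
        me_type=me_type,
        subfamily=subfamily,
        svlen=svlen,
        assess=assess,
        sr=sr,
        filter_flags=frozenset(flags),
        genotypes=np.array(genotypes, dtype=np.int8),
    )


def mk_td(
    sr=6,
    svlen=6100,
    transduced_length=100,
    source_subfamily="L1HS",
    source_type="reference",
    source_chrom="chrX",
    chrom="chr1",
    pos=1000,
    me_type="L1",
    vid="td1",
    genotypes=(),
    assess=5,
    flags=("PASS",),
):
    src = SourceDescriptor(
        source_chrom, 11707247, 11713279, "+", source_subfamily,
        source_type, transduced_length,
    )
    seg = TransSegment(source_chrom, 11713279, 11713279 + transduced_length, "+")
    return TransductionRecord(
        chrom=chrom,
        pos=pos,
        variant_id=vid,
        me_type=me_type,
        subfamily=source_subfamily,
        svlen=svlen,
        assess=assess,
        sr=sr,
        filter_flags=frozenset(flags),
        genotypes=np.array(genotypes, dtype=np.int8),
        mesource=src,
        metrans=seg,
    )
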