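"""Allele summaries, HWE exact test, density, rates, spectra."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from conftest import mk_record
from transdx.formats_io import HET, HOM_ALT, HOM_REF, MISSING, SamplePanel
from transdx.popgen import (
    AlleleSummary,
    af_spectrum,
    allele_summary,
    density_per_mbp,
    group_presence,
    het_hom_ratio,
    hwe_exact,
    is_singleton,
    per_element_rate,
    superpop_presence,
)
from transdx.simulate import simulate_genotypes


def _panel(pops):
    rows = []
    for pop, sup, n in pops:
        for i in range(n):
            rows.append({"sample": f"{pop}{i}", "population": pop,
                         "super_population": sup, "sex": "F"})
    return SamplePanel(pd.DataFrame(rows))


PANEL4 = _panel([("YRI", "AFR", 2), ("CEU", "EUR", 2)])


class TestAlleleSummary:
    def test_basic_counts(self):
        rec = mk_record(genotypes=[HET, HOM_REF, HOM_REF, HOM_REF])
        s = allele_summary(rec, PANEL4, "ALL")
        assert (s.ac, s.an, s.af) == (1, 8, 0.125)

    def test_missing_excluded_from_an(self):
        rec = mk_record(genotypes=[HET, MISSING, HOM_REF, HOM_REF])
        assert allele_summary(rec, PANEL4, "ALL").an == 6

    def test_group_stratification_sums_to_global(self):
        rec = mk_record(genotypes=[HET, HOM_ALT, HOM_REF, HET])
        total = allele_summary(rec, PANEL4, "ALL")
        parts = [allele_summary(rec, PANEL4, g) for g in ("AFR", "EUR")]
        assert sum(p.ac for p in parts) == total.ac == 4
        assert sum(p.an for p in parts) == total.an

    def test_shared_transduction_af(self):
        """A het-only variant carried by 269 of 3202 samples has AF ~ 4.2%."""
        g = np.array([HET] * 269 + [HOM_REF] * (3202 - 269), dtype=np.int8)
        panel = _panel([("YRI", "AFR", 3202)])
        s = allele_summary(mk_record(genotypes=g), panel, "ALL")
        assert (s.ac, s.an) == (269, 6404)
        assert s.af == pytest.approx(0.0420, abs=5e-4)

    def test_unknown_group(self):
        with pytest.raises(KeyError):
            allele_summary(mk_record(genotypes=[HET] * 4), PANEL4, "XXX")

    def test_invariant_ac_le_an(self):
        with pytest.raises(ValueError):
            AlleleSummary("v", "ALL", 5, 4)


@pytest.mark.parametrize(
    "genotypes,expected",
    [
        ([HET, HOM_REF, HOM_REF, HOM_REF], True),  # single het carrier
        ([HOM_ALT, HOM_REF, HOM_REF, HOM_REF], False),  # one hom carrier: ac=2
        ([HOM_REF] * 4, False),  # ac=0
    ],
)
def test_singleton_definition(genotypes, expected):
    assert is_singleton(mk_record(genotypes=genotypes), PANEL4) is expected


class TestPresence:
    def test_specific_to_one_superpop(self):
        rec = mk_record(genotypes=[HET, HOM_ALT, HOM_REF, HOM_REF])
        assert superpop_presence(rec, PANEL4) == {"AFR"}

    def test_present_everywhere(self):
        rec = mk_record(genotypes=[HET] * 4)
        assert superpop_presence(rec, PANEL4) == {"AFR", "EUR"}
        assert group_presence(rec, PANEL4, "population") == {"YRI", "CEU"}

    def test_absent_everywhere(self):
        assert superpop_presence(mk_record(genotypes=[HOM_REF] * 4), PANEL4) == set()


class TestHetHomRatio:
    def test_ratio_of_totals(self):
        recs = [
            mk_record(genotypes=[HET] * 6 + [HOM_ALT], vid="a"),
            mk_record(genotypes=[HET] * 5 + [HOM_ALT], vid="b"),
        ]
        assert het_hom_ratio(recs)["L1"] == pytest.approx(11 / 2)

    def test_no_hom_alt_is_infinite(self):
        recs = [mk_record(genotypes=[HET, HOM_REF])]
        assert math.isinf(het_hom_ratio(recs)["L1"])

    def test_hwe_closed_form(self):
        """Under HWE at af=0.1 the ratio tends to 2pq/q^2 = 18."""
        rng = np.random.default_rng(5)
        recs = [
            mk_record(genotypes=simulate_genotypes(0.1, 4000, rng=rng), vid=str(i))
            for i in range(30)
        ]
        assert het_hom_ratio(recs)["L1"] == pytest.approx(18.0, rel=0.1)


def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent brute force: exact rational enumeration of the
    conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0, 1.0
    hs = list(range(n_minor % 2, n_minor + 1, 2))
    ws = [
        Fraction(
            2**h * math.factorial(n),
            math.factorial((n_minor - h) // 2)
            * math.factorial(h)
            * math.factorial(n - h - (n_minor - h) // 2),
        )
        for h in hs
    ]
    tot = sum(ws)
    ps = [w / tot for w in ws]
    p_obs = ps[hs.index(n_het)]
    return (
        float(sum(p for p in ps if p <= p_obs)),
        float(sum(ps[hs.index(n_het):])),
    )


class TestHweExact:
    def test_monomorphic(self):
        r = hwe_exact(25, 0, 0)
        assert r.p_two_sided == 1.0 and r.p_excess_het == 1.0

    def test_single_allele_forced_configuration(self):
        assert hwe_exact(99, 1, 0).p_two_sided == 1.0

    def test_against_oracle_example(self):
        r = hwe_exact(57, 33, 10)
        two, exc = _hwe_oracle(57, 33, 10)
        assert r.p_two_sided == pytest.approx(two, abs=1e-12)
        assert r.p_excess_het == pytest.approx(exc, abs=1e-12)

    def test_against_oracle_all_small_configs(self):
        """Exhaustive agreement with the rational-arithmetic oracle, n <= 25."""
        for n in range(1, 26):
            for nh in range(n + 1):
                for het in range(n - nh + 1):
                    naa = n - nh - het
                    r = hwe_exact(nh, het, naa)
                    two, exc = _hwe_oracle(nh, het, naa)
                    assert r.p_two_sided == pytest.approx(two, abs=1e-10)
                    assert r.p_excess_het == pytest.approx(exc, abs=1e-10)
                    assert 0 < r.p_two_sided <= 1

    def test_probabilities_are_normalized(self):
        # internal distribution sums to 1: p for the most probable
        # configuration equals 1 minus the mass of strictly less probable ones
        r = hwe_exact(500, 400, 100)
        assert 0 < r.p_two_sided <= 1 and 0 < r.p_excess_het <= 1

    def test_inconsistent_input(self):
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)


class TestDensity:
    def test_chry_rate(self):
        """Three MEIs on a 57,227,415 bp chromosome: 0.052 per Mbp."""
        recs = [mk_record(chrom="chrY", vid=str(i)) for i in range(3)]
        d = density_per_mbp(recs, {"chrY": 57_227_415})
        assert d["chrY"] == pytest.approx(0.0524, abs=5e-4)

    def test_unit_density_and_zero(self):
        recs = [mk_record(chrom="chr1")]
        d = density_per_mbp(recs, {"chr1": 1_000_000, "chr2": 2_000_000})
        assert d == {"chr1": 1.0, "chr2": 0.0}

    def test_missing_chromosome_errors(self):
        with pytest.raises(KeyError):
            density_per_mbp([mk_record(chrom="chrZ")], {"chr1": 100})


class TestPerElementRate:
    @pytest.mark.parametrize(
        "high,total,rate",
        [(268, 9847, 2.72), (162, 4066, 3.98), (0, 100, 0.0)],
    )
    def test_printed_rates(self, high, total, rate):
        assert per_element_rate(high, total) == rate

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            per_element_rate(1, 0)


class TestAfSpectrum:
    BINS = [(0.0, 0.01), (0.01, 0.05), (0.05, 1.0)]

    def test_rare_cutoff_and_monomorphic(self):
        summaries = [
            AlleleSummary("a", "ALL", 1, 200),  # af=0.005 -> rare bin
            AlleleSummary("b", "ALL", 0, 200),  # monomorphic bucket
            AlleleSummary("c", "ALL", 0, 0),  # uncalled: skipped
            AlleleSummary("d", "ALL", 100, 200),
        ]
        hist = af_spectrum(summaries, self.BINS)["ALL"]
        assert hist[(0.0, 0.01)] == 1
        assert hist["monomorphic"] == 1
        assert hist[(0.05, 1.0)] == 1
        assert sum(hist.values()) == 3  # every an>0 site counted once

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            af_spectrum([], [(0.0, 0.5), (0.4, 1.0)])
        with pytest.raises(ValueError):
            af_spectrum([], [(0.0, 0.5)])

    def test_uniform_afs_fill_bins_proportionally(self):
        rng = np.random.default_rng(3)
        summaries = [
            AlleleSummary(str(i), "ALL", int(a * 1000), 1000)
            for i, a in enumerate(rng.uniform(0.001, 0.999, 2000))
        ]
        hist = af_spectrum(summaries, self.BINS)["ALL"]
        n = sum(v for k, v in hist.items() if k != "monomorphic")
        assert hist[(0.05, 1.0)] / n == pytest.approx(0.95, abs=0.03)
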