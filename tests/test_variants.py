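"""Mutational spectrum, POLE rule, gene flags and VCF filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecsubtype import io as eio
from ecsubtype.variants import (
    _COLLAPSE, SPECTRUM_CLASSES, PoleRuleParams, SomaticVariant,
    SpectrumUndefinedError, SubstitutionSpectrum, VariantFilterParams,
    call_pole_signature, gene_flags, read_somatic_vcf, substitution_spectrum,
)


def snv(ref, alt, gene="GENE01", csq="missense", **kw):
    kw.setdefault("tumor_af", 0.3)
    kw.setdefault("normal_af", 0.0)
    return SomaticVariant(chrom="chr1", pos=1000, ref=ref, alt=alt, gene=gene,
                          consequence=csq, **kw)


class TestSpectrum:
    def test_hand_counted_rates(self):
        variants = (
            [snv("C", "A")] * 3 + [snv("G", "T")] + [snv("C", "G")]
            + [snv("T", "C")] * 5
        )
        sp = substitution_spectrum(variants)
        assert sp.n_snv == 10
        assert sp.ca_rate == pytest.approx(0.4)
        assert sp.cg_rate == pytest.approx(0.1)

    def test_pure_ca(self):
        sp = substitution_spectrum([snv("C", "A")] * 4)
        assert (sp.ca_rate, sp.cg_rate) == (1.0, 0.0)

    def test_indels_ignored_and_indel_only_is_undefined(self):
        indel = SomaticVariant(chrom="chr1", pos=5, ref="A", alt="AT",
                               gene="GENE01", consequence="frameshift",
                               tumor_af=0.3, normal_af=0.0)
        sp = substitution_spectrum([indel, snv("C", "A")])
        assert sp.n_snv == 1
        with pytest.raises(SpectrumUndefinedError):
            substitution_spectrum([indel])

    def test_strand_swap_invariance(self):
        fwd = [snv("C", "A"), snv("C", "G"), snv("T", "C"), snv("T", "G")]
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rev = [snv(comp[v.ref], comp[v.alt]) for v in fwd]
        a, b = substitution_spectrum(fwd), substitution_spectrum(rev)
        assert a.class_rates == b.class_rates

    @given(counts=st.lists(st.integers(0, 20), min_size=6, max_size=6)
           .filter(lambda c: sum(c) > 0))
    @settings(deadline=None, max_examples=50)
    def test_class_rates_partition_to_one(self, counts):
        variants = []
        for cls, k in zip(SPECTRUM_CLASSES, counts):
            ref, alt = next(pair for pair, c in _COLLAPSE.items() if c == cls)
            variants += [snv(ref, alt)] * k
        sp = substitution_spectrum(variants)
        assert sum(sp.class_rates.values()) == pytest.approx(1.0)
        assert sp.n_snv == sum(counts)


class TestPoleRule:
    @pytest.mark.parametrize("n,ca,cg,expected", [
        (501, 0.25, 0.01, True),   # all three criteria strictly satisfied
        (500, 0.25, 0.01, False),  # SNV count threshold is strict
        (501, 0.20, 0.01, False),  # C>A threshold is strict
        (501, 0.25, 0.03, False),  # C>G threshold is strict
    ])
    def test_strict_boundaries(self, n, ca, cg, expected):
        sp = SubstitutionSpectrum(n_snv=n, ca_rate=ca, cg_rate=cg)
        assert call_pole_signature(sp) is expected

    @given(n=st.integers(501, 10_000),
           ca=st.floats(0.2001, 0.9), cg=st.floats(0.0, 0.0299),
           dn=st.integers(0, 1000), dca=st.floats(0, 0.05), dcg=st.floats(0, 0.02))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_evidence(self, n, ca, cg, dn, dca, dcg):
        base = SubstitutionSpectrum(n_snv=n, ca_rate=ca, cg_rate=cg)
        if not call_pole_signature(base):
            return
        better = SubstitutionSpectrum(
            n_snv=n + dn, ca_rate=min(ca + dca, 1.0), cg_rate=max(cg - dcg, 0.0))
        assert call_pole_signature(better)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            PoleRuleParams(min_ca_rate=0.02, max_cg_rate=0.03)


class TestGeneFlags:
    def test_tp53_synonymous_is_silent(self):
        flags = gene_flags([snv("C", "T", gene="TP53", csq="synonymous")])
        assert not flags["tp53_nonsilent"]

    @pytest.mark.parametrize("csq", ["missense", "nonsense", "frameshift",
                                     "splice", "inframe_indel"])
    def test_tp53_nonsilent_classes(self, csq):
        flags = gene_flags([snv("C", "T", gene="TP53", csq=csq)])
        assert flags["tp53_nonsilent"]

    def test_pole_hotspot_and_domain_whitelist(self):
        hot = snv("C", "G", gene="POLE", aa_change="P286R")
        dom = snv("C", "T", gene="POLE", aa_change="A300T")
        outside = snv("C", "T", gene="POLE", aa_change="R600W")
        silent_dom = snv("C", "T", gene="POLE", csq="synonymous", aa_change="L300L")
        assert gene_flags([hot])["pole_pathogenic"]
        assert gene_flags([dom])["pole_pathogenic"]
        assert not gene_flags([outside])["pole_pathogenic"]
        assert not gene_flags([silent_dom])["pole_pathogenic"]

    def test_empty_variant_list(self):
        assert gene_flags([]) == {"pole_pathogenic": False, "tp53_nonsilent": False}


class TestVcfReading:
    def test_filter_contract(self, tmp_path):
        records = [
            snv("C", "A"),                            # kept
            snv("C", "T"),                            # dropped: non-PASS (below)
            snv("G", "T", normal_af=0.10),            # dropped: germline leak
            snv("T", "C", tumor_af=0.02),             # dropped: low tumor AF
            snv("C", "G", tumor_depth=10),            # dropped: shallow
        ]
        path = tmp_path / "s.vcf"
        eio.write_somatic_vcf(path, records,
                              filters=["PASS", "artifact", "PASS", "PASS", "PASS"])
        kept = read_somatic_vcf(path)
        assert len(kept) == 1
        assert (kept[0].ref, kept[0].alt) == ("C", "A")
        assert kept[0].gene == "GENE01" and kept[0].consequence == "missense"

    def test_configurable_thresholds(self, tmp_path):
        path = tmp_path / "s.vcf"
        eio.write_somatic_vcf(path, [snv("C", "A", tumor_af=0.03)])
        assert read_somatic_vcf(path) == []
        loose = VariantFilterParams(min_tumor_af=0.01)
        assert len(read_somatic_vcf(path, loose)) == 1

    def test_missing_normal_column_errors(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=60000000>\n'
            '##FORMAT=<ID=AF,Number=1,Type=Float,Description="af">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "chr1\t100\t.\tC\tA\t.\tPASS\t.\tAF:DP\t0.3:100\n"
        )
        path = tmp_path / "tumor_only.vcf"
        path.write_text(vcf_text)
        with pytest.raises(ValueError, match="NORMAL"):
            read_somatic_vcf(path)

    def test_roundtrip_preserves_annotations(self, tmp_path):
        v = snv("C", "G", gene="POLE", aa_change="P286R", tumor_depth=120)
        path = tmp_path / "p.vcf"
        eio.write_somatic_vcf(path, [v])
        (got,) = read_somatic_vcf(path)
        assert got.gene == "POLE" and got.aa_change == "P286R"
        assert got.tumor_af == pytest.approx(0.3, abs=1e-6)
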