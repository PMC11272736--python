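"""Synthetic cohort generator: determinism, planted signals, round-trips."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from conftest import subset_spec
from ecsubtype import io as eio
from ecsubtype.msi import call_msi, histograms_from_table
from ecsubtype.simulate import (
    CohortSpec, SamplePlan, SurvivalParams, default_fixture_spec, empty_bundle,
    generate_cn_training, generate_cohort, write_bundle,
)
from ecsubtype.qc import flag_msi_quality, QCMetrics
from ecsubtype.variants import call_pole_signature, read_somatic_vcf, substitution_spectrum


def dir_digest(d: Path) -> dict:
    return {p.relative_to(d).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.rglob("*")) if p.is_file()}


class TestSpecValidation:
    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(samples=()).validate()

    def test_contradictory_flags_name_the_sample(self):
        bad = CohortSpec(samples=(
            SamplePlan(sample_id="S001", pathogenic_pole=True, signature_pole=False),))
        with pytest.raises(ValueError, match="S001"):
            bad.validate()

    def test_nonpositive_hazard_multiplier_rejected(self):
        spec = CohortSpec(
            samples=(SamplePlan(sample_id="S001"),),
            survival=SurvivalParams(os_multipliers={
                "POLEmut": 0.0, "dMMR": 1.0, "p53abn": 1.0, "NSMP": 1.0}))
        with pytest.raises(ValueError, match="multiplier"):
            spec.validate()

    def test_duplicate_sample_ids_rejected(self):
        spec = CohortSpec(samples=(SamplePlan(sample_id="S1"),
                                   SamplePlan(sample_id="S1")))
        with pytest.raises(ValueError, match="duplicate"):
            spec.validate()


class TestDeterminism:
    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        spec = subset_spec(10)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_cohort(spec), d1)
        write_bundle(generate_cohort(spec), d2)
        assert dir_digest(d1) == dir_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_cohort(subset_spec(4, seed=1)), d1)
        write_bundle(generate_cohort(subset_spec(4, seed=2)), d2)
        assert dir_digest(d1) != dir_digest(d2)


class TestPlantedSignals:
    def test_pole_samples_inside_rule_region(self, small_bundle):
        truth = small_bundle.truth.set_index("sample")
        for sid, data in small_bundle.variants.items():
            spectrum = substitution_spectrum(data.passing())
            assert call_pole_signature(spectrum) == truth.loc[sid, "signature_pole"]
            if not truth.loc[sid, "signature_pole"]:
                # non-POLE samples sit outside the rule on the SNV-count criterion
                assert spectrum.n_snv <= 500

    def test_msi_scores_well_separated(self, small_bundle):
        truth = small_bundle.truth.set_index("sample")
        for sid, table in small_bundle.ms_loci.items():
            res = call_msi(histograms_from_table(table))
            if truth.loc[sid, "msi_h"]:
                assert res.aggregate_score >= 0.4
            else:
                assert res.aggregate_score <= 0.1

    def test_cluster4_samples_heavily_altered(self):
        seg, labels = generate_cn_training(n=20, frac_positive=0.5, seed=3)
        for sid, grp in seg.groupby("sample"):
            altered = ((grp["copy_number"] > 2.5) | (grp["copy_number"] < 1.5)).sum()
            if labels[sid]:
                assert altered >= 20
            else:
                assert altered == 0

    def test_degraded_sample_breaches_a_threshold(self, fixture_bundle):
        truth = fixture_bundle.truth.set_index("sample")
        qc = fixture_bundle.qc.set_index("sample")
        for sid, row in qc.iterrows():
            flags = flag_msi_quality(QCMetrics(
                sample_id=sid, pct_mapped=row["pct_mapped"],
                pct_on_target=row["pct_on_target"],
                pct_short_fragments=row["pct_short_fragments"],
                adapter_contamination=row["adapter_contamination"]))
            assert bool(flags) == bool(truth.loc[sid, "degraded_qc"])

    def test_training_label_balance_exact(self):
        _, labels = generate_cn_training(n=240, frac_positive=0.26, seed=17)
        assert labels.sum() == 62 and len(labels) == 240

    def test_fixture_plan_counts(self):
        spec = default_fixture_spec()
        truth = [p for p in spec.samples]
        assert len(truth) == 108
        assert sum(p.signature_pole for p in truth) == 9
        assert sum(p.pathogenic_pole for p in truth) == 6
        assert sum(p.msi_h for p in truth) == 53  # 51 planted + 2 POLE-signature
        assert sum(p.cn_cluster4 for p in truth) == 15
        assert sum(p.tp53_nonsilent for p in truth) == 11


class TestRoundTrip:
    def test_vcf_roundtrip_recovers_passing_records(self, small_bundle, tmp_path):
        sid, data = next(iter(small_bundle.variants.items()))
        path = tmp_path / f"{sid}.vcf"
        eio.write_somatic_vcf(path, data.records, filters=data.filters)
        got = read_somatic_vcf(path)
        want = data.passing()
        assert len(got) == len(want)
        got_keys = {(v.chrom, v.pos, v.ref, v.alt) for v in got}
        want_keys = {(v.chrom, v.pos, v.ref, v.alt) for v in want}
        assert got_keys == want_keys

    def test_written_cohort_tables_roundtrip(self, small_bundle, small_dir):
        seg = eio.read_seg_table(small_dir / "segments.tsv")
        assert set(seg["sample"]) == set(small_bundle.variants)
        clin = eio.read_clinical_table(small_dir / "clinical.tsv")
        assert len(clin) == 12
        loci = eio.read_locus_table(small_dir / "loci" / "S001.tsv")
        assert (loci.groupby("locus_id").size() > 0).all()

    def test_empty_cohort_writes_headers_only(self, tmp_path):
        write_bundle(empty_bundle(), tmp_path)
        assert list((tmp_path / "vcf").iterdir()) == []
        text = (tmp_path / "clinical.tsv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("sample")


class TestClinical:
    def test_survival_times_nonnegative_events_binary(self, fixture_bundle):
        clin = fixture_bundle.clinical
        assert (clin[["os_months", "pfs_months"]] >= 0).all().all()
        assert clin["os_event"].isin([0, 1]).all()
        assert clin["pfs_event"].isin([0, 1]).all()

    def test_high_risk_group_has_more_events(self, fixture_bundle):
        merged = fixture_bundle.clinical.merge(fixture_bundle.truth, on="sample")
        rates = merged.groupby("surrogate_truth")["os_event"].mean()
        assert rates["p53abn"] > rates["NSMP"]
        assert rates.get("POLEmut", 0.0) <= rates["NSMP"]
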