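"""Seeded synthetic tumor/normal cohorts with planted subtype truths.

No patient-level data accompany the study design this package implements, so
all testing and evaluation runs on simulated cohorts. Each sample carries a
planted truth (POLE-like spectrum, pathogenic POLE mutation, MSI-H shift,
CN-cluster-4 profile, non-silent TP53, degraded QC) and the generator emits
raw inputs — somatic VCF, microsatellite locus histograms, CN segments, QC
metrics, clinical outcomes — whose signals sit well inside or outside the
published decision boundaries, so a correct pipeline recovers every planted
label exactly. Survival times are exponential with per-subtype multiplicative
hazards and uniform administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .genes import BACKGROUND_GENES, CHROMS
from .variants import SomaticVariant

HISTOLOGIES = ("Endometrioid", "Mixed", "Serous", "Carcinosarcoma", "Clear cell")
HISTOLOGY_PROBS = (0.843, 0.055, 0.018, 0.046, 0.038)
FIGO_STAGES = ("I", "II", "III", "IV")
FIGO_PROBS = (0.814, 0.065, 0.102, 0.019)

#: substitution-class probabilities (C>A, C>G, C>T, T>A, T>C, T>G)
POLE_CLASS_PROBS = (0.32, 0.010, 0.30, 0.05, 0.22, 0.10)
BASELINE_CLASS_PROBS = (0.08, 0.09, 0.45, 0.07, 0.24, 0.07)
_CLASS_REPS = {  # (pyrimidine, purine) strand representations
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "C>T": (("C", "T"), ("G", "A")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>G": (("T", "G"), ("A", "C")),
}
_CLASS_ORDER = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class SamplePlan:
    """Planted per-sample truth flags."""

    sample_id: str
    signature_pole: bool = False
    pathogenic_pole: bool = False
    msi_h: bool = False
    cn_cluster4: bool = False
    tp53_nonsilent: bool = False
    degraded_qc: bool = False

    @property
    def surrogate_truth(self) -> str:
        if self.pathogenic_pole:
            return "POLEmut"
        if self.msi_h:
            return "dMMR"
        if self.tp53_nonsilent:
            return "p53abn"
        return "NSMP"


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential hazards per surrogate subtype (per month), with uniform
    administrative censoring on [0, censor_max_months].

    Multipliers default to the magnitudes of the published hazard ratios for
    the surrogate strata (p53abn OS 12.84, dMMR OS 1.44; PFS 9.58 / 2.07),
    with a near-zero POLE hazard so the excellent-prognosis group is
    essentially event-free.
    """

    os_baseline_hazard: float = 0.002
    pfs_baseline_hazard: float = 0.003
    os_multipliers: dict[str, float] = field(default_factory=lambda: {
        "POLEmut": 0.05, "dMMR": 1.44, "p53abn": 12.8, "NSMP": 1.0})
    pfs_multipliers: dict[str, float] = field(default_factory=lambda: {
        "POLEmut": 0.05, "dMMR": 2.07, "p53abn": 9.58, "NSMP": 1.0})
    censor_max_months: float = 140.0


@dataclass(frozen=True)
class CohortSpec:
    samples: tuple[SamplePlan, ...]
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0
    ms_loci_per_sample: int = 60
    ms_depth: int = 100
    pole_snv_range: tuple[int, int] = (600, 3000)
    background_snv_range: tuple[int, int] = (30, 300)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("cohort spec needs at least one sample")
        seen = set()
        for p in self.samples:
            if p.sample_id in seen:
                raise ValueError(f"duplicate sample id {p.sample_id}")
            seen.add(p.sample_id)
            if p.pathogenic_pole and not p.signature_pole:
                raise ValueError(
                    f"sample {p.sample_id}: pathogenic_pole requires signature_pole "
                    "in the planted fixture design")
        for mult in (*self.survival.os_multipliers.values(),
                     *self.survival.pfs_multipliers.values()):
            if mult <= 0:
                raise ValueError("hazard multipliers must be > 0")


@dataclass
class VcfSampleData:
    """Records destined for one sample's VCF, with per-record FILTER values."""

    records: list[SomaticVariant]
    filters: list[str]

    def passing(self) -> list[SomaticVariant]:
        """Records surviving the default read filter (PASS, AF/depth rules)."""
        out = []
        for v, f in zip(self.records, self.filters):
            if f == "PASS" and v.tumor_af >= 0.05 and v.normal_af <= 0.02 \
                    and v.tumor_depth >= 20:
                out.append(v)
        return out


@dataclass
class CohortBundle:
    variants: dict[str, VcfSampleData]
    ms_loci: dict[str, pd.DataFrame]
    cn_segments: pd.DataFrame
    qc: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame  # never consumed by classifiers; recovery testing only


# ---------------------------------------------------------------- variants

def _make_snv(rng, cls: str, gene: str, consequence: str) -> SomaticVariant:
    chrom = f"chr{int(rng.integers(1, 23))}"
    pos = int(rng.integers(1, CHROMS[chrom]))
    ref, alt = _CLASS_REPS[cls][int(rng.integers(2))]
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence,
        tumor_af=float(np.round(rng.uniform(0.1, 0.6), 4)), normal_af=0.0,
        tumor_depth=int(rng.integers(60, 200)),
    )


def _background_consequence(rng) -> str:
    return str(rng.choice(["missense", "synonymous", "other"], p=[0.45, 0.3, 0.25]))


def _sample_variants(plan: SamplePlan, spec: CohortSpec, rng) -> VcfSampleData:
    records: list[SomaticVariant] = []
    filters: list[str] = []

    if plan.signature_pole:
        lo, hi = spec.pole_snv_range
        probs = np.asarray(POLE_CLASS_PROBS)
        # resample until the realized spectrum sits safely inside the rule region
        while True:
            n = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(n, probs / probs.sum())
            ca, cg = counts[0] / n, counts[1] / n
            if n > 500 and ca > 0.25 and cg < 0.02:
                break
    else:
        lo, hi = spec.background_snv_range
        n = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(n, np.asarray(BASELINE_CLASS_PROBS))

    for cls, k in zip(_CLASS_ORDER, counts):
        for _ in range(int(k)):
            gene = str(rng.choice(BACKGROUND_GENES))
            records.append(_make_snv(rng, cls, gene, _background_consequence(rng)))
            filters.append("PASS")

    # a few passenger indels; the SNV criterion must not count these
    for _ in range(int(rng.integers(3, 12))):
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1, CHROMS[chrom]))
        if rng.random() < 0.5:
            ref, alt, csq = "A", "AT", "frameshift"
        else:
            ref, alt, csq = "CAAG", "C", "inframe_indel"
        records.append(SomaticVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=str(rng.choice(BACKGROUND_GENES)), consequence=csq,
            tumor_af=float(np.round(rng.uniform(0.1, 0.5), 4)), normal_af=0.0,
            tumor_depth=int(rng.integers(60, 200))))
        filters.append("PASS")

    if plan.pathogenic_pole:
        # exonuclease-domain hotspot P286R (c.857C>G)
        records.append(SomaticVariant(
            chrom="chr12", pos=40_050_857, ref="C", alt="G", gene="POLE",
            consequence="missense", tumor_af=0.38, normal_af=0.0,
            tumor_depth=120, aa_change="P286R"))
        filters.append("PASS")
    elif plan.signature_pole:
        # signature-only tumors may still carry an innocuous POLE variant
        records.append(SomaticVariant(
            chrom="chr12", pos=40_060_100, ref="G", alt="A", gene="POLE",
            consequence="synonymous", tumor_af=0.3, normal_af=0.0,
            tumor_depth=110, aa_change="L606L"))
        filters.append("PASS")

    if plan.tp53_nonsilent:
        records.append(SomaticVariant(
            chrom="chr17", pos=7_510_175, ref="G", alt="A", gene="TP53",
            consequence="missense", tumor_af=0.45, normal_af=0.0,
            tumor_depth=140, aa_change="R175H"))
        filters.append("PASS")
    elif rng.random() < 0.1:
        # silent TP53 passenger: must not trigger the p53abn arm
        records.append(SomaticVariant(
            chrom="chr17", pos=7_511_300, ref="C", alt="T", gene="TP53",
            consequence="synonymous", tumor_af=0.2, normal_af=0.0,
            tumor_depth=90, aa_change="P36P"))
        filters.append("PASS")

    # caller noise the read filter must reject: flagged, germline-leak, shallow
    noise = [
        (SomaticVariant("chr2", int(rng.integers(1, CHROMS["chr2"])), "C", "T",
                        str(rng.choice(BACKGROUND_GENES)), "missense",
                        0.3, 0.0, 100), "artifact"),
        (SomaticVariant("chr3", int(rng.integers(1, CHROMS["chr3"])), "G", "A",
                        str(rng.choice(BACKGROUND_GENES)), "missense",
                        0.48, 0.45, 100), "PASS"),
        (SomaticVariant("chr4", int(rng.integers(1, CHROMS["chr4"])), "T", "C",
                        str(rng.choice(BACKGROUND_GENES)), "missense",
                        0.3, 0.0, 10), "PASS"),
    ]
    for v, f in noise:
        records.append(v)
        filters.append(f)
    return VcfSampleData(records=records, filters=filters)


# ---------------------------------------------------------------- MSI loci

def _sample_ms_table(plan: SamplePlan, spec: CohortSpec, rng) -> pd.DataFrame:
    rows = []
    for j in range(spec.ms_loci_per_sample):
        locus = f"MS{j + 1:03d}"
        peak = int(rng.integers(10, 21))
        if plan.msi_h:
            lengths = list(range(peak - 4, peak + 2))
            normal_probs = [0.0, 0.0, 0.0, 0.1, 0.8, 0.1]
            tumor_probs = [0.05, 0.40, 0.05, 0.05, 0.40, 0.05]
        else:
            lengths = [peak - 1, peak, peak + 1]
            normal_probs = [0.1, 0.8, 0.1]
            tumor_probs = normal_probs
        normal = rng.multinomial(spec.ms_depth, normal_probs)
        tumor = rng.multinomial(spec.ms_depth, tumor_probs)
        for length, nc, tc in zip(lengths, normal, tumor):
            rows.append((locus, length, int(nc), int(tc)))
    return pd.DataFrame(rows, columns=eio.LOCUS_COLUMNS)


# ---------------------------------------------------------------- CN segments

def _sample_segments(plan: SamplePlan, rng) -> pd.DataFrame:
    """Non-overlapping full-coverage segments per autosome.

    Alterations are carved into disjoint 10 Mb cells; cluster-4 genomes get
    25-40 altered runs (gains 3-5 copies, losses 0.5-1.2), quiet genomes 0-3
    small ones, so the two classes are well separated in every count feature.
    """
    cell_size = 10_000_000
    cells_per_chrom = CHROMS["chr1"] // cell_size
    n_cells = 22 * cells_per_chrom
    n_alt = int(rng.integers(25, 41)) if plan.cn_cluster4 else 0
    chosen = rng.choice(n_cells, size=n_alt, replace=False)
    altered: dict[str, list[tuple[int, int, float]]] = {}
    for cell in np.sort(chosen):
        chrom = f"chr{int(cell // cells_per_chrom) + 1}"
        cell_start = int(cell % cells_per_chrom) * cell_size
        start = cell_start + int(rng.integers(0, 4_000_000))
        width = int(rng.integers(2_000_000, 6_000_001))
        end = min(start + width, cell_start + cell_size)
        if plan.cn_cluster4:
            cn = float(rng.uniform(3.0, 5.0)) if rng.random() < 0.6 \
                else float(rng.uniform(0.5, 1.2))
        else:
            cn = 3.0 if rng.random() < 0.5 else 1.0
        altered.setdefault(chrom, []).append((start, end, round(cn, 3)))
    def diploid_cn() -> float:
        # segment-level measurement jitter that never crosses the 1.5/2.5 cutoffs
        return float(np.clip(np.round(rng.normal(2.0, 0.08), 3), 1.6, 2.4))

    rows = []
    for i in range(1, 23):
        chrom = f"chr{i}"
        cursor = 0
        for start, end, cn in sorted(altered.get(chrom, [])):
            if start > cursor:
                rows.append((plan.sample_id, chrom, cursor, start, diploid_cn()))
            rows.append((plan.sample_id, chrom, start, end, cn))
            cursor = end
        if cursor < CHROMS[chrom]:
            rows.append((plan.sample_id, chrom, cursor, CHROMS[chrom], diploid_cn()))
    return pd.DataFrame(rows, columns=eio.SEG_COLUMNS)


# ---------------------------------------------------------------- QC, clinical

def _sample_qc(plan: SamplePlan, rng) -> dict:
    if plan.degraded_qc:
        return {
            "sample": plan.sample_id,
            "pct_mapped": round(float(rng.uniform(85.0, 91.5)), 2),
            "pct_on_target": round(float(rng.uniform(55.0, 65.5)), 2),
            "pct_short_fragments": round(float(rng.uniform(93.5, 97.0)), 2),
            "adapter_contamination": round(float(rng.uniform(6.5, 10.0)), 2),
            "sample_year": int(rng.integers(2008, 2011)),
        }
    return {
        "sample": plan.sample_id,
        "pct_mapped": round(float(rng.uniform(95.0, 99.0)), 2),
        "pct_on_target": round(float(rng.uniform(70.0, 85.0)), 2),
        "pct_short_fragments": round(float(rng.uniform(40.0, 70.0)), 2),
        "adapter_contamination": round(float(rng.uniform(0.2, 2.0)), 2),
        "sample_year": int(rng.integers(2011, 2017)),
    }


def _sample_clinical(plan: SamplePlan, spec: CohortSpec, rng) -> dict:
    sv = spec.survival
    label = plan.surrogate_truth
    row = {"sample": plan.sample_id,
           "histology": str(rng.choice(HISTOLOGIES, p=HISTOLOGY_PROBS)),
           "figo_stage": str(rng.choice(FIGO_STAGES, p=FIGO_PROBS))}
    for endpoint, base, mults in (
        ("os", sv.os_baseline_hazard, sv.os_multipliers),
        ("pfs", sv.pfs_baseline_hazard, sv.pfs_multipliers),
    ):
        lam = base * mults[label]
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(0.0, sv.censor_max_months)
        row[f"{endpoint}_months"] = round(float(min(t_event, t_censor)), 1)
        row[f"{endpoint}_event"] = int(t_event <= t_censor)
    return row


# ---------------------------------------------------------------- cohort

def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate the full per-sample raw data for a cohort spec.

    Deterministic for a fixed spec + seed: every sample draws from its own
    seeded substream, so cohorts are reproducible sample-by-sample.
    """
    spec.validate()
    variants: dict[str, VcfSampleData] = {}
    ms_loci: dict[str, pd.DataFrame] = {}
    seg_frames, qc_rows, clin_rows, truth_rows = [], [], [], []
    for i, plan in enumerate(spec.samples):
        rng = np.random.default_rng([spec.seed, i])
        variants[plan.sample_id] = _sample_variants(plan, spec, rng)
        ms_loci[plan.sample_id] = _sample_ms_table(plan, spec, rng)
        seg_frames.append(_sample_segments(plan, rng))
        qc_rows.append(_sample_qc(plan, rng))
        clin_rows.append(_sample_clinical(plan, spec, rng))
        truth_rows.append({
            "sample": plan.sample_id,
            "signature_pole": plan.signature_pole,
            "pathogenic_pole": plan.pathogenic_pole,
            "msi_h": plan.msi_h,
            "cn_cluster4": plan.cn_cluster4,
            "tp53_nonsilent": plan.tp53_nonsilent,
            "degraded_qc": plan.degraded_qc,
            "surrogate_truth": plan.surrogate_truth,
        })
    return CohortBundle(
        variants=variants,
        ms_loci=ms_loci,
        cn_segments=pd.concat(seg_frames, ignore_index=True),
        qc=pd.DataFrame(qc_rows, columns=eio.QC_COLUMNS),
        clinical=pd.DataFrame(clin_rows, columns=eio.CLINICAL_COLUMNS),
        truth=pd.DataFrame(truth_rows),
    )


def write_bundle(bundle: CohortBundle, directory) -> None:
    """Write the bundle as one VCF + locus TSV per sample plus cohort TSVs."""
    d = Path(directory)
    (d / "vcf").mkdir(parents=True, exist_ok=True)
    (d / "loci").mkdir(parents=True, exist_ok=True)
    for sid, data in bundle.variants.items():
        eio.write_somatic_vcf(d / "vcf" / f"{sid}.vcf", data.records,
                              filters=data.filters)
    for sid, table in bundle.ms_loci.items():
        eio.write_locus_table(d / "loci" / f"{sid}.tsv", table)
    eio.write_seg_table(d / "segments.tsv", bundle.cn_segments)
    eio.write_qc_table(d / "qc.tsv", bundle.qc)
    eio.write_clinical_table(d / "clinical.tsv", bundle.clinical)
    bundle.truth.to_csv(d / "truth.tsv", sep="\t", index=False)


def empty_bundle() -> CohortBundle:
    return CohortBundle(
        variants={}, ms_loci={},
        cn_segments=pd.DataFrame(columns=eio.SEG_COLUMNS),
        qc=pd.DataFrame(columns=eio.QC_COLUMNS),
        clinical=pd.DataFrame(columns=eio.CLINICAL_COLUMNS),
        truth=pd.DataFrame(columns=[
            "sample", "signature_pole", "pathogenic_pole", "msi_h",
            "cn_cluster4", "tp53_nonsilent", "degraded_qc", "surrogate_truth"]),
    )


# ---------------------------------------------------------------- fixtures

def default_fixture_spec(seed: int = 11) -> CohortSpec:
    """The packaged 108-sample cohort mirroring the published distribution.

    Plan: 9 POLE-signature tumors (6 also carrying a pathogenic POLE
    mutation; of the 3 signature-only, 2 MSI-H and 1 TP53-mutant), 51 further
    MSI-H, 15 CN-cluster-4, 10 further TP53-mutant, 23 with no specific
    profile. The cascades therefore yield 9/51/33/15 (TCGA-analogue) and
    6/53/38/11 (surrogate). Eight of the MSI-H tumors get FFPE-degraded QC
    metrics so the plausibility flags have work to do.
    """
    plans: list[SamplePlan] = []

    def add(**kw):
        plans.append(SamplePlan(sample_id=f"S{len(plans) + 1:03d}", **kw))

    for _ in range(6):
        add(signature_pole=True, pathogenic_pole=True)
    for _ in range(2):
        add(signature_pole=True, msi_h=True)
    add(signature_pole=True, tp53_nonsilent=True)
    for k in range(51):
        add(msi_h=True, degraded_qc=(k >= 43))  # last 8 MSI-H samples degraded
    for _ in range(15):
        add(cn_cluster4=True)
    for _ in range(10):
        add(tp53_nonsilent=True)
    for _ in range(23):
        add()
    return CohortSpec(samples=tuple(plans), seed=seed)


def cn_training_spec(n: int = 240, frac_positive: float = 0.26,
                     seed: int = 17) -> CohortSpec:
    """Training cohort for the cluster-4 model: n samples, planted positives.

    Positive count is round(n * frac_positive) — labels are assigned, not
    sampled, so the class balance is exact by construction.
    """
    n_pos = int(round(n * frac_positive))
    plans = tuple(
        SamplePlan(sample_id=f"T{i + 1:03d}", cn_cluster4=(i < n_pos))
        for i in range(n)
    )
    return CohortSpec(samples=plans, seed=seed)


def generate_cn_training(n: int = 240, frac_positive: float = 0.26,
                         seed: int = 17) -> tuple[pd.DataFrame, pd.Series]:
    """Segments + binary labels for cluster-4 training (no VCF/MSI overhead)."""
    spec = cn_training_spec(n, frac_positive, seed)
    spec.validate()
    frames = []
    labels = {}
    for i, plan in enumerate(spec.samples):
        rng = np.random.default_rng([spec.seed, i])
        frames.append(_sample_segments(plan, rng))
        labels[plan.sample_id] = int(plan.cn_cluster4)
    return pd.concat(frames, ignore_index=True), pd.Series(labels, name="cluster4")


def generate_cn_null(n: int = 240, frac_positive: float = 0.26,
                     seed: int = 29) -> tuple[pd.DataFrame, pd.Series]:
    """Null training cohort: labels independent of features by construction.

    Every genome is quiet (no planted cluster-4 effect) while labels keep the
    training class balance; any classifier evaluated on this cohort has no
    signal to learn, so its cross-validated accuracy should collapse to the
    majority rate.
    """
    n_pos = int(round(n * frac_positive))
    frames = []
    labels = {}
    for i in range(n):
        sid = f"N{i + 1:03d}"
        plan = SamplePlan(sample_id=sid, cn_cluster4=False)
        rng = np.random.default_rng([seed, i])
        frames.append(_sample_segments(plan, rng))
        labels[sid] = int(i < n_pos)
    return pd.concat(frames, ignore_index=True), pd.Series(labels, name="cluster4")
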