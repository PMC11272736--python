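"""Somatic variant parsing, mutational spectrum, POLE rule, gene flags.

The POLE ultramutator phenotype is called from the substitution spectrum of
filtered somatic SNVs: an ultramutated tumor (>500 SNVs) with a C>A-enriched
(>0.2) and C>G-depleted (<0.03) spectrum is labeled POLE. Inequalities are
strict, exactly as the rule is stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from cyvcf2 import VCF

CONSEQUENCES = (
    "missense", "nonsense", "frameshift", "splice",
    "inframe_indel", "synonymous", "other",
)
NON_SILENT = frozenset({"missense", "nonsense", "frameshift", "splice", "inframe_indel"})

#: POLE exonuclease-domain hotspot substitutions treated as (likely) pathogenic
POLE_HOTSPOTS = frozenset({"P286R", "V411L", "S297F", "A456P", "S459F"})
#: residues of the POLE exonuclease domain; any missense inside is whitelisted
POLE_EXO_DOMAIN = (268, 471)


class SpectrumUndefinedError(ValueError):
    """Raised when a substitution spectrum is requested for zero SNVs."""


@dataclass(frozen=True)
class SomaticVariant:
    """One filtered somatic call."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    tumor_af: float
    normal_af: float
    tumor_depth: int = 100
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for af in (self.tumor_af, self.normal_af):
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele fraction {af} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Pyrimidine-collapsed substitution-class fractions of somatic SNVs."""

    n_snv: int
    ca_rate: float
    cg_rate: float
    class_rates: dict[str, float] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class PoleRuleParams:
    """Thresholds of the spectrum-based POLE call (strict inequalities)."""

    min_snv: int = 500
    min_ca_rate: float = 0.2
    max_cg_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.min_snv <= 0 or self.min_ca_rate <= 0 or self.max_cg_rate <= 0:
            raise ValueError("POLE rule thresholds must be positive")
        if self.min_ca_rate <= self.max_cg_rate:
            raise ValueError("min_ca_rate must exceed max_cg_rate")


@dataclass(frozen=True)
class VariantFilterParams:
    """Paired-somatic filtering contract applied when reading a VCF.

    These reproduce conventional paired tumor/normal heuristics: PASS only,
    minimum tumor allele fraction, maximum normal allele fraction (germline
    leak guard) and minimum tumor depth. All configurable.
    """

    min_tumor_af: float = 0.05
    max_normal_af: float = 0.02
    min_tumor_depth: int = 20
    pass_only: bool = True


# pyrimidine-collapsed class of a single-base substitution
_COLLAPSE = {
    ("C", "A"): "C>A", ("G", "T"): "C>A",
    ("C", "G"): "C>G", ("G", "C"): "C>G",
    ("C", "T"): "C>T", ("G", "A"): "C>T",
    ("T", "A"): "T>A", ("A", "T"): "T>A",
    ("T", "C"): "T>C", ("A", "G"): "T>C",
    ("T", "G"): "T>G", ("A", "C"): "T>G",
}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-collapsed class (e.g. G→T collapses to C>A)."""
    try:
        return _COLLAPSE[(ref.upper(), alt.upper())]
    except KeyError:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}") from None


def read_somatic_vcf(
    path,
    filter_config: VariantFilterParams | None = None,
    *,
    gene_key: str = "GENE",
    consequence_key: str = "CSQCLASS",
    aa_key: str = "AACHANGE",
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[SomaticVariant]:
    """Read a paired tumor/normal VCF and return calls passing the filter.

    Expects per-sample FORMAT fields AF and DP and the gene/consequence INFO
    keys (defaults GENE, CSQCLASS). SNVs and indels are both retained.
    """
    params = filter_config or VariantFilterParams()
    path = str(path)
    vcf = VCF(path)
    try:
        samples = list(vcf.samples)
        if tumor_sample not in samples or normal_sample not in samples:
            raise ValueError(
                f"{path}: need tumor column '{tumor_sample}' and normal column "
                f"'{normal_sample}'; found {samples}"
            )
        t_idx = samples.index(tumor_sample)
        n_idx = samples.index(normal_sample)
        out: list[SomaticVariant] = []
        for i, rec in enumerate(vcf):
            try:
                if params.pass_only and rec.FILTER is not None:  # None == PASS
                    continue
                af = rec.format("AF")
                dp = rec.format("DP")
                if af is None or dp is None:
                    raise ValueError("missing AF/DP FORMAT fields")
                tumor_af = float(af[t_idx][0])
                normal_af = float(af[n_idx][0])
                tumor_depth = int(dp[t_idx][0])
                if tumor_af < params.min_tumor_af:
                    continue
                if normal_af > params.max_normal_af:
                    continue
                if tumor_depth < params.min_tumor_depth:
                    continue
                gene = rec.INFO.get(gene_key) or ""
                csq = rec.INFO.get(consequence_key) or "other"
                aa = rec.INFO.get(aa_key)
                out.append(SomaticVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                    gene=gene, consequence=csq,
                    tumor_af=tumor_af, normal_af=normal_af,
                    tumor_depth=tumor_depth, aa_change=aa,
                ))
            except (ValueError, TypeError, IndexError) as exc:
                raise ValueError(f"{path}: malformed record #{i + 1}: {exc}") from exc
        return out
    finally:
        vcf.close()


def substitution_spectrum(variants: Iterable[SomaticVariant]) -> SubstitutionSpectrum:
    """Compute SNV count and the six pyrimidine-collapsed class fractions.

    Raises :class:`SpectrumUndefinedError` when no SNVs are present; such a
    sample cannot be spectrum-classified and is routed to the non-POLE branch
    by the cascade.
    """
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    n = 0
    for v in variants:
        if not v.is_snv:
            continue
        counts[substitution_class(v.ref, v.alt)] += 1
        n += 1
    if n == 0:
        raise SpectrumUndefinedError("no somatic SNVs: spectrum undefined")
    rates = {k: c / n for k, c in counts.items()}
    return SubstitutionSpectrum(
        n_snv=n, ca_rate=rates["C>A"], cg_rate=rates["C>G"], class_rates=rates
    )


def call_pole_signature(
    spectrum: SubstitutionSpectrum, params: PoleRuleParams | None = None
) -> bool:
    """Spectrum-based POLE call: >min_snv SNVs, C>A rate > min, C>G rate < max."""
    p = params or PoleRuleParams()
    return (
        spectrum.n_snv > p.min_snv
        and spectrum.ca_rate > p.min_ca_rate
        and spectrum.cg_rate < p.max_cg_rate
    )


def _residue_number(aa_change: str) -> int | None:
    digits = "".join(ch for ch in aa_change if ch.isdigit())
    return int(digits) if digits else None


def pole_variant_is_pathogenic(v: SomaticVariant) -> bool:
    """Whitelist check for a POLE variant.

    Pathogenic iff the protein change is a known exonuclease-domain hotspot,
    or a missense mapping inside the exonuclease domain (residues 268-471).
    """
    if v.gene != "POLE" or v.aa_change is None:
        return False
    if v.aa_change in POLE_HOTSPOTS:
        return True
    if v.consequence == "missense":
        res = _residue_number(v.aa_change)
        if res is not None and POLE_EXO_DOMAIN[0] <= res <= POLE_EXO_DOMAIN[1]:
            return True
    return False


def gene_flags(variants: Sequence[SomaticVariant]) -> dict[str, bool]:
    """Driver-gene flags consumed by the surrogate-marker cascade.

    ``pole_pathogenic``: any POLE variant on the pathogenicity whitelist.
    ``tp53_nonsilent``: any TP53 variant with a non-silent consequence
    (missense, nonsense, frameshift, splice, in-frame indel).
    """
    pole = any(pole_variant_is_pathogenic(v) for v in variants)
    tp53 = any(v.gene == "TP53" and v.consequence in NON_SILENT for v in variants)
    return {"pole_pathogenic": pole, "tp53_nonsilent": tp53}
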