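"""Hierarchical molecular-subtype assignment and cohort summaries.

Two classification tracks are always computed per sample, independently:

* TCGA-analogue — precedence POLE → MSI → CN: spectrum-based POLE rule first,
  then MSI-H, then predicted CN cluster 4 (CN high), remainder CN low.
* Surrogate-marker — precedence POLEmut → dMMR → p53abn → NSMP: pathogenic
  POLE mutation first, then MSI-H (dMMR), then non-silent TP53 (p53abn),
  remainder NSMP.

The two tracks can legitimately diverge: a tumor with a POLE-like spectrum
but no whitelisted pathogenic POLE mutation is POLE on the first track yet
falls through to dMMR/p53abn/NSMP on the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .msi import MSI_H, MsiResult
from .variants import PoleRuleParams, SubstitutionSpectrum, call_pole_signature

TCGA_LABELS = ("POLE", "MSI", "CN_low", "CN_high")
SURROGATE_LABELS = ("POLEmut", "dMMR", "NSMP", "p53abn")
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class SampleEvidence:
    """Everything the cascades consume for one sample.

    ``spectrum`` is None when the sample had zero SNVs (spectrum undefined,
    treated as non-POLE on the signature rule); ``msi`` is None when no
    microsatellite locus was usable (MSI indeterminate).
    """

    sample_id: str
    spectrum: SubstitutionSpectrum | None
    msi: MsiResult | None
    cluster4_flag: bool
    cluster4_posterior: float
    pole_pathogenic: bool
    tp53_nonsilent: bool
    qc_flags: tuple[str, ...] = ()
    pole_rule: PoleRuleParams = field(default_factory=PoleRuleParams)


@dataclass
class SubtypeCall:
    sample_id: str
    tcga_label: str
    surrogate_label: str
    evidence: SampleEvidence
    reason: str = ""


@dataclass
class CohortSummary:
    counts: dict[str, dict[str, int]]
    percentages: dict[str, dict[str, float]]
    n_classified: dict[str, int]
    n_unclassifiable: dict[str, int]


def _pole_signature(ev: SampleEvidence) -> bool:
    if ev.spectrum is None:
        return False
    return call_pole_signature(ev.spectrum, ev.pole_rule)


def _msi_high(ev: SampleEvidence) -> bool | None:
    if ev.msi is None:
        return None
    return ev.msi.call == MSI_H


def classify_tcga_analogue(ev: SampleEvidence) -> str:
    """POLE → MSI → CN high / CN low, in that precedence."""
    if _pole_signature(ev):
        return "POLE"
    msi = _msi_high(ev)
    if msi is None:
        return UNCLASSIFIABLE  # MSI indeterminate: cannot resolve the MSI/CN stages
    if msi:
        return "MSI"
    return "CN_high" if ev.cluster4_flag else "CN_low"


def classify_surrogate(ev: SampleEvidence) -> str:
    """POLEmut → dMMR → p53abn → NSMP, in that precedence."""
    if ev.pole_pathogenic:
        return "POLEmut"
    msi = _msi_high(ev)
    if msi is None:
        return UNCLASSIFIABLE
    if msi:
        return "dMMR"
    return "p53abn" if ev.tp53_nonsilent else "NSMP"


def classify_sample(ev: SampleEvidence) -> SubtypeCall:
    tcga = classify_tcga_analogue(ev)
    surrogate = classify_surrogate(ev)
    reason = ""
    if UNCLASSIFIABLE in (tcga, surrogate):
        reason = "MSI indeterminate" + ("" if ev.spectrum else "; spectrum undefined")
    return SubtypeCall(ev.sample_id, tcga, surrogate, ev, reason)


def round_percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (printed-table convention)."""
    if total == 0:
        return float("nan")
    pct = Decimal(count * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(calls: list[SubtypeCall]) -> CohortSummary:
    """Per-track subtype counts and one-decimal percentages.

    Unclassifiable samples are excluded from denominators and reported
    separately.
    """
    if not calls:
        raise ValueError("no classified samples")
    counts: dict[str, dict[str, int]] = {}
    pct: dict[str, dict[str, float]] = {}
    n_cls: dict[str, int] = {}
    n_uncls: dict[str, int] = {}
    for track, labels, attr in (
        ("tcga", TCGA_LABELS, "tcga_label"),
        ("surrogate", SURROGATE_LABELS, "surrogate_label"),
    ):
        got = [getattr(c, attr) for c in calls]
        classified = [g for g in got if g != UNCLASSIFIABLE]
        n = len(classified)
        counts[track] = {lab: classified.count(lab) for lab in labels}
        pct[track] = {lab: round_percent(counts[track][lab], n) for lab in labels}
        n_cls[track] = n
        n_uncls[track] = len(got) - n
    return CohortSummary(counts=counts, percentages=pct,
                         n_classified=n_cls, n_unclassifiable=n_uncls)


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Per-sample output table (one row per sample, evidence columns included)."""
    rows = []
    for c in calls:
        ev = c.evidence
        rows.append({
            "sample": c.sample_id,
            "tcga_label": c.tcga_label,
            "surrogate_label": c.surrogate_label,
            "n_snv": ev.spectrum.n_snv if ev.spectrum else 0,
            "ca_rate": round(ev.spectrum.ca_rate, 6) if ev.spectrum else float("nan"),
            "cg_rate": round(ev.spectrum.cg_rate, 6) if ev.spectrum else float("nan"),
            "pole_signature": _pole_signature(ev),
            "pole_pathogenic": ev.pole_pathogenic,
            "tp53_nonsilent": ev.tp53_nonsilent,
            "msi_score": round(ev.msi.aggregate_score, 6) if ev.msi else float("nan"),
            "msi_call": ev.msi.call if ev.msi else "indeterminate",
            "cluster4_posterior": round(ev.cluster4_posterior, 6),
            "cluster4_flag": ev.cluster4_flag,
            "qc_flags": ";".join(ev.qc_flags),
            "msi_at_risk": bool(ev.qc_flags) and ev.msi is not None and ev.msi.call == MSI_H,
            "reason": c.reason,
        })
    return pd.DataFrame(rows)
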