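"""Sequencing-quality plausibility flags for MSI calls, and IHC concordance.

FFPE-degraded DNA inflates apparent microsatellite instability. Four QC
metrics were found to separate plausible from artifact-prone MSI calls:
fraction of mapped reads, fraction of on-target reads, fraction of short
fragments, and adapter contamination. Breaching any threshold raises a flag;
flags annotate MSI calls (an MSI-H call on a flagged sample is "at risk of
FFPE artifact") but never alter the cascade output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass



@dataclass(frozen=True)
class QCMetrics:
    sample_id: str
    pct_mapped: float | None = None
    pct_on_target: float | None = None
    pct_short_fragments: float | None = None
    adapter_contamination: float | None = None
    sample_year: int | None = None

    def __post_init__(self) -> None:
        for name in ("pct_mapped", "pct_on_target", "pct_short_fragments",
                     "adapter_contamination"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not 0 <= v <= 100:
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class QcThresholds:
    """Risk thresholds, strict inequalities exactly as published."""

    min_pct_mapped: float = 92.0          # flag if strictly below
    min_pct_on_target: float = 66.0       # flag if strictly below
    max_pct_short_fragments: float = 93.0  # flag if strictly above
    max_adapter_contamination: float = 6.34  # flag if strictly above


@dataclass(frozen=True)
class ConcordanceResult:
    """2x2 agreement between IHC MMR calls and WES MSI calls."""

    both_positive: int
    ihc_only: int
    wes_only: int
    both_negative: int

    @property
    def n(self) -> int:
        return self.both_positive + self.ihc_only + self.wes_only + self.both_negative

    @property
    def percent_agreement(self) -> float:
        return 100.0 * (self.both_positive + self.both_negative) / self.n

    @property
    def ihc_positive_rate(self) -> float:
        return 100.0 * (self.both_positive + self.ihc_only) / self.n

    @property
    def wes_positive_rate(self) -> float:
        return 100.0 * (self.both_positive + self.wes_only) / self.n


def flag_msi_quality(qc: QCMetrics, thresholds: QcThresholds | None = None) -> tuple[str, ...]:
    """Return one flag name per breached QC rule (OR-combined, strict).

    Missing metrics skip their rule with a warning.
    """
    t = thresholds or QcThresholds()
    flags: list[str] = []
    checks = [
        ("low_mapped", qc.pct_mapped, lambda v: v < t.min_pct_mapped),
        ("low_on_target", qc.pct_on_target, lambda v: v < t.min_pct_on_target),
        ("high_short_fragments", qc.pct_short_fragments,
         lambda v: v > t.max_pct_short_fragments),
        ("adapter_contamination", qc.adapter_contamination,
         lambda v: v > t.max_adapter_contamination),
    ]
    for name, value, breached in checks:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            warnings.warn(f"{qc.sample_id}: QC metric for rule '{name}' missing; rule skipped")
            continue
        if breached(value):
            flags.append(name)
    return tuple(flags)


def concordance(ihc_calls: dict[str, bool], wes_calls: dict[str, bool]) -> ConcordanceResult:
    """Cross-tabulate binary IHC (dMMR) vs WES (MSI-H) calls on one sample set."""
    if set(ihc_calls) != set(wes_calls):
        only_ihc = sorted(set(ihc_calls) - set(wes_calls))
        only_wes = sorted(set(wes_calls) - set(ihc_calls))
        raise ValueError(
            f"mismatched sample sets: IHC-only {only_ihc}, WES-only {only_wes}")
    a = b = c = d = 0
    for sid, ihc in ihc_calls.items():
        wes = wes_calls[sid]
        if ihc and wes:
            a += 1
        elif ihc and not wes:
            b += 1
        elif wes and not ihc:
            c += 1
        else:
            d += 1
    return ConcordanceResult(both_positive=a, ihc_only=b, wes_only=c, both_negative=d)


def nested_concordance_table(n: int, n_ihc_positive: int, n_wes_positive: int) -> ConcordanceResult:
    """Contingency table forced by marginals when WES-positives nest in IHC-positives.

    With every WES MSI-H sample also IHC-dMMR, the marginals determine the
    table completely: a = #WES+, b = #IHC+ - #WES+, c = 0, d = n - #IHC+.
    """
    if not 0 <= n_wes_positive <= n_ihc_positive <= n:
        raise ValueError("marginals violate the nested-calls assumption")
    return ConcordanceResult(
        both_positive=n_wes_positive,
        ihc_only=n_ihc_positive - n_wes_positive,
        wes_only=0,
        both_negative=n - n_ihc_positive,
    )
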