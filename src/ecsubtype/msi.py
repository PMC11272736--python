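"""Microsatellite instability scoring from tumor/normal repeat-length histograms.

Per locus, instability is scored as the total-variation distance between the
count-normalized tumor and normal repeat-length distributions,

    score = 1/2 * sum_k | f_T(k) - f_N(k) |,

which is 0 for identical distributions and 1 for disjoint supports. The
sample-level score is the unweighted mean over usable loci, and the sample is
called MSI-H when the aggregate reaches the operating threshold (default 0.3,
inclusive). This is an analogue of the MANTIS tumor/normal stepwise-difference
statistic, not a bit-exact port of that tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MSI_H = "MSI-H"
MSS = "MSS"

#: minimum read count per sample for a locus to be usable
MIN_LOCUS_DEPTH = 20


class MsiIndeterminateError(ValueError):
    """Raised when no locus is usable; the sample cannot be MSI-called."""


@dataclass(frozen=True)
class MsLocusHistogram:
    """Tumor and normal repeat-length read-count histograms for one locus."""

    locus_id: str
    repeat_lengths: tuple[int, ...]
    normal_counts: tuple[int, ...]
    tumor_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.repeat_lengths) == len(self.normal_counts) == len(self.tumor_counts)):
            raise ValueError(f"{self.locus_id}: histograms must share the length support")
        if any(c < 0 for c in self.normal_counts + self.tumor_counts):
            raise ValueError(f"{self.locus_id}: negative read count")

    @property
    def usable(self) -> bool:
        return (sum(self.normal_counts) >= MIN_LOCUS_DEPTH
                and sum(self.tumor_counts) >= MIN_LOCUS_DEPTH)


@dataclass(frozen=True)
class MsiResult:
    per_locus_scores: dict[str, float] = field(compare=False)
    aggregate_score: float = float("nan")
    call: str = MSS
    threshold: float = 0.3
    n_usable: int = 0
    n_unusable: int = 0


def locus_stepwise_difference(locus: MsLocusHistogram) -> float:
    """Total-variation distance between normalized tumor and normal histograms."""
    n = np.asarray(locus.normal_counts, dtype=float)
    t = np.asarray(locus.tumor_counts, dtype=float)
    if n.sum() == 0 or t.sum() == 0:
        raise ValueError(f"{locus.locus_id}: zero-depth histogram")
    return float(0.5 * np.abs(t / t.sum() - n / n.sum()).sum())


def call_msi(loci: list[MsLocusHistogram], threshold: float = 0.3) -> MsiResult:
    """Aggregate per-locus scores and call MSI-H / MSS.

    Loci with fewer than :data:`MIN_LOCUS_DEPTH` reads in either sample are
    excluded. Raises :class:`MsiIndeterminateError` when no locus is usable.
    """
    scores: dict[str, float] = {}
    n_unusable = 0
    for locus in loci:
        if not locus.usable:
            n_unusable += 1
            continue
        scores[locus.locus_id] = locus_stepwise_difference(locus)
    if not scores:
        raise MsiIndeterminateError("no usable microsatellite locus")
    aggregate = float(np.mean(list(scores.values())))
    call = MSI_H if aggregate >= threshold else MSS
    return MsiResult(
        per_locus_scores=scores, aggregate_score=aggregate, call=call,
        threshold=threshold, n_usable=len(scores), n_unusable=n_unusable,
    )


def histograms_from_table(table: pd.DataFrame) -> list[MsLocusHistogram]:
    """Build per-locus histograms from a long-format locus TSV table."""
    loci = []
    for locus_id, grp in table.groupby("locus_id", sort=True):
        grp = grp.sort_values("repeat_length")
        loci.append(MsLocusHistogram(
            locus_id=str(locus_id),
            repeat_lengths=tuple(int(x) for x in grp["repeat_length"]),
            normal_counts=tuple(int(x) for x in grp["normal_count"]),
            tumor_counts=tuple(int(x) for x in grp["tumor_count"]),
        ))
    return loci
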