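"""End-to-end orchestration: per-sample evidence → cascades → summaries → survival.

Per-sample failures (corrupt VCF, indeterminate MSI) are isolated: the sample
is reported unclassifiable with a reason and the rest of the cohort proceeds.
Every rule that fires is derivable from the evidence columns of the output
table, which is the auditability requirement of a clinically-framed pipeline.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as eio
from .cascade import (
    SampleEvidence, SubtypeCall, UNCLASSIFIABLE, calls_to_frame,
    classify_sample, summarize_cohort,
)
from .cn import Cluster4Model
from .config import PipelineConfig
from .msi import MsiIndeterminateError, call_msi, histograms_from_table
from .qc import QCMetrics, flag_msi_quality
from .survival import cox_ph, result_to_dict
from .variants import (
    SpectrumUndefinedError, gene_flags, read_somatic_vcf, substitution_spectrum,
)

log = logging.getLogger("ecsubtype")


def _qc_metrics_from_row(row: pd.Series) -> QCMetrics:
    def get(name):
        v = row.get(name)
        return None if v is None or pd.isna(v) else float(v)

    year = row.get("sample_year")
    return QCMetrics(
        sample_id=str(row["sample"]),
        pct_mapped=get("pct_mapped"),
        pct_on_target=get("pct_on_target"),
        pct_short_fragments=get("pct_short_fragments"),
        adapter_contamination=get("adapter_contamination"),
        sample_year=None if year is None or pd.isna(year) else int(year),
    )


def classify_cohort(
    cohort_dir,
    model: Cluster4Model,
    config: PipelineConfig | None = None,
) -> tuple[list[SubtypeCall], pd.DataFrame, dict]:
    """Classify every sample found in a written cohort directory.

    Expects the layout produced by :func:`ecsubtype.simulate.write_bundle`:
    ``vcf/<sample>.vcf``, ``loci/<sample>.tsv``, ``segments.tsv``, ``qc.tsv``.
    Returns (calls, per-sample table, cohort summary dict).
    """
    cfg = config or PipelineConfig()
    d = Path(cohort_dir)
    vcf_paths = sorted((d / "vcf").glob("*.vcf"))
    if not vcf_paths:
        raise FileNotFoundError(f"no VCFs under {d / 'vcf'}")
    seg = eio.read_seg_table(d / "segments.tsv")
    qc_table = None
    if (d / "qc.tsv").exists():
        qc_table = eio.read_qc_table(d / "qc.tsv").set_index("sample", drop=False)
    else:
        log.warning("no qc.tsv found; MSI plausibility flags will be absent")

    calls: list[SubtypeCall] = []
    for vcf_path in vcf_paths:
        sid = vcf_path.stem
        try:
            calls.append(_classify_one(sid, vcf_path, d, seg, qc_table, model, cfg))
        except Exception as exc:
            log.warning("sample %s failed: %s", sid, exc)
            ev = SampleEvidence(
                sample_id=sid, spectrum=None, msi=None, cluster4_flag=False,
                cluster4_posterior=float("nan"), pole_pathogenic=False,
                tp53_nonsilent=False, pole_rule=cfg.pole_rule)
            calls.append(SubtypeCall(sid, UNCLASSIFIABLE, UNCLASSIFIABLE, ev,
                                     reason=f"pipeline error: {exc}"))
    table = calls_to_frame(calls)
    summary = summarize_cohort(calls)
    summary_dict = {
        "n_samples": len(calls),
        "tcga": {"counts": summary.counts["tcga"],
                 "percent": summary.percentages["tcga"],
                 "n_classified": summary.n_classified["tcga"],
                 "n_unclassifiable": summary.n_unclassifiable["tcga"]},
        "surrogate": {"counts": summary.counts["surrogate"],
                      "percent": summary.percentages["surrogate"],
                      "n_classified": summary.n_classified["surrogate"],
                      "n_unclassifiable": summary.n_unclassifiable["surrogate"]},
    }
    return calls, table, summary_dict


def _classify_one(sid, vcf_path, d, seg, qc_table, model, cfg) -> SubtypeCall:
    variants = read_somatic_vcf(vcf_path, cfg.variant_filter)
    try:
        spectrum = substitution_spectrum(variants)
    except SpectrumUndefinedError:
        spectrum = None
        log.warning("sample %s: no SNVs, spectrum undefined", sid)
    flags = gene_flags(variants)

    loci_path = d / "loci" / f"{sid}.tsv"
    msi = None
    if loci_path.exists():
        try:
            msi = call_msi(histograms_from_table(eio.read_locus_table(loci_path)),
                           threshold=cfg.msi_threshold)
        except MsiIndeterminateError:
            log.warning("sample %s: MSI indeterminate", sid)
    else:
        log.warning("sample %s: no locus table", sid)

    sample_seg = seg[seg["sample"] == sid].drop(columns=["sample"])
    c4_flag, c4_post = model.predict_sample(sample_seg)

    qc_flags: tuple[str, ...] = ()
    if qc_table is not None and sid in qc_table.index:
        qc_flags = flag_msi_quality(_qc_metrics_from_row(qc_table.loc[sid]),
                                    cfg.qc_thresholds)

    ev = SampleEvidence(
        sample_id=sid, spectrum=spectrum, msi=msi,
        cluster4_flag=c4_flag, cluster4_posterior=c4_post,
        pole_pathogenic=flags["pole_pathogenic"],
        tp53_nonsilent=flags["tp53_nonsilent"],
        qc_flags=qc_flags, pole_rule=cfg.pole_rule,
    )
    call = classify_sample(ev)
    log.info("sample %s: n_snv=%s ca=%.3f cg=%.3f msi=%s c4=%.3f -> %s / %s",
             sid, spectrum.n_snv if spectrum else 0,
             spectrum.ca_rate if spectrum else float("nan"),
             spectrum.cg_rate if spectrum else float("nan"),
             msi.call if msi else "indeterminate", c4_post,
             call.tcga_label, call.surrogate_label)
    return call


def write_classification(table: pd.DataFrame, summary: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "subtype_calls.tsv", sep="\t", index=False)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1) + "\n")


def evaluate_survival(
    table: pd.DataFrame,
    clinical: pd.DataFrame,
    tcga_reference: str = "CN_low",
    surrogate_reference: str = "NSMP",
) -> dict:
    """Both tracks x both endpoints: log-rank p and per-subtype HR vs reference.

    Subjects with missing time or event status are dropped per endpoint;
    endpoints without any event are reported untestable.
    """
    merged = table.merge(clinical, on="sample", how="inner")
    out: dict = {}
    for track, label_col, ref in (
        ("tcga", "tcga_label", tcga_reference),
        ("surrogate", "surrogate_label", surrogate_reference),
    ):
        sub = merged[merged[label_col] != UNCLASSIFIABLE]
        out[track] = {}
        for endpoint in ("os", "pfs"):
            use = sub.dropna(subset=[f"{endpoint}_months", f"{endpoint}_event"])
            if use.empty or use[f"{endpoint}_event"].sum() == 0:
                out[track][endpoint] = {"untestable": "no events in endpoint"}
                continue
            try:
                res = cox_ph(use[f"{endpoint}_months"], use[f"{endpoint}_event"],
                             use[label_col], reference=ref,
                             endpoint=endpoint.upper())
                out[track][endpoint] = result_to_dict(res)
            except ValueError as exc:
                out[track][endpoint] = {"untestable": str(exc)}
    return out
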