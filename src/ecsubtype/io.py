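"""Readers and writers for the pipeline's on-disk formats.

Formats: per-sample VCF v4.2 (TUMOR/NORMAL columns, AF/DP FORMAT fields,
GENE/CSQCLASS/AACHANGE INFO tags), long-format microsatellite locus TSV,
cohort SEG-like TSV, QC TSV and clinical TSV. Everything is plain text and
round-trips losslessly through these functions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .genes import CHROMS
from .variants import SomaticVariant

LOCUS_COLUMNS = ["locus_id", "repeat_length", "normal_count", "tumor_count"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "copy_number"]
QC_COLUMNS = [
    "sample", "pct_mapped", "pct_on_target", "pct_short_fragments",
    "adapter_contamination", "sample_year",
]
CLINICAL_COLUMNS = [
    "sample", "os_months", "os_event", "pfs_months", "pfs_event",
    "histology", "figo_stage",
]


def _vcf_header(contigs: Mapping[str, int] | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in (contigs or CHROMS).items():
        header.contigs.add(name, length=length)
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Gene symbol")])
    header.add_meta(
        "INFO", items=[("ID", "CSQCLASS"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Consequence class")])
    header.add_meta(
        "INFO", items=[("ID", "AACHANGE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Protein change, e.g. P286R")])
    header.add_meta(
        "FORMAT", items=[("ID", "AF"), ("Number", "1"), ("Type", "Float"),
                         ("Description", "Alternate allele fraction")])
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                         ("Description", "Read depth")])
    header.filters.add("artifact", None, None, "Flagged by the somatic caller")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    return header


def write_somatic_vcf(
    path,
    variants: Iterable[SomaticVariant],
    *,
    filters: Sequence[str] | None = None,
    normal_depth: int = 80,
) -> None:
    """Write paired tumor/normal calls as uncompressed VCF v4.2.

    ``filters`` optionally gives a per-record FILTER value ("PASS" or
    "artifact"), parallel to ``variants``; defaults to all-PASS.
    """
    variants = list(variants)
    filt = list(filters) if filters is not None else ["PASS"] * len(variants)
    if len(filt) != len(variants):
        raise ValueError("filters must parallel variants")
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v, f in zip(variants, filt):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.filter.add(f)
            rec.info["GENE"] = v.gene
            rec.info["CSQCLASS"] = v.consequence
            if v.aa_change is not None:
                rec.info["AACHANGE"] = v.aa_change
            rec.samples["TUMOR"]["AF"] = v.tumor_af
            rec.samples["TUMOR"]["DP"] = v.tumor_depth
            rec.samples["NORMAL"]["AF"] = v.normal_af
            rec.samples["NORMAL"]["DP"] = normal_depth
            out.write(rec)


def write_locus_table(path, table: pd.DataFrame) -> None:
    table[LOCUS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_locus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: locus TSV missing columns {sorted(missing)}")
    return df[LOCUS_COLUMNS]


def write_seg_table(path, table: pd.DataFrame) -> None:
    table[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SEG TSV missing columns {sorted(missing)}")
    return df[SEG_COLUMNS]


def write_qc_table(path, table: pd.DataFrame) -> None:
    table[QC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_qc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: QC TSV needs a 'sample' column")
    return df


def write_clinical_table(path, table: pd.DataFrame) -> None:
    table[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "os_months", "os_event", "pfs_months", "pfs_event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical TSV missing columns {sorted(missing)}")
    return df
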