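"""Synthetic genome coordinates and gene model.

The pipeline only needs gene intervals for two purposes: counting which genes
are hit by copy-number alterations, and attaching gene symbols to simulated
variants. Real-data users plug in a BED file; the packaged model is a small
deterministic synthetic genome (22 autosomes of 60 Mb) carrying 40 background
genes plus POLE and TP53, which is all the cascades consume.
"""

from __future__ import annotations

import pandas as pd

# 22 autosomes, uniform length; chrX is carried in CN feature vectors but the
# synthetic genome places no genes or segments on it.
CHROM_LENGTH = 60_000_000
CHROMS: dict[str, int] = {f"chr{i}": CHROM_LENGTH for i in range(1, 23)}

#: chromosomes represented in per-chromosome CN features (1-22 plus X)
CN_FEATURE_CHROMS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


def synthetic_gene_model() -> pd.DataFrame:
    """Return the packaged gene→interval table.

    Columns: ``gene, chrom, start, end`` with 0-based half-open coordinates.
    40 background genes GENE01..GENE40 tile the autosomes; POLE sits on chr12
    and TP53 on chr17 (mirroring their real chromosomes, with synthetic
    coordinates).
    """
    rows = []
    for i in range(40):
        chrom = f"chr{(i % 22) + 1}"
        start = 5_000_000 + (i // 22) * 20_000_000
        rows.append((f"GENE{i + 1:02d}", chrom, start, start + 100_000))
    rows.append(("POLE", "chr12", 40_000_000, 40_150_000))
    rows.append(("TP53", "chr17", 7_500_000, 7_520_000))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return df.sort_values("gene", ignore_index=True)


def read_gene_model_bed(path) -> pd.DataFrame:
    """Read a 4-column BED (chrom, start, end, gene) into the model layout."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"],
        usecols=[0, 1, 2, 3],
    )
    if df["gene"].isna().any():
        raise ValueError(f"gene model BED {path} needs a name column")
    return df[["gene", "chrom", "start", "end"]].sort_values("gene", ignore_index=True)


#: background gene pool for simulated passenger variants — deliberately
#: excludes POLE and TP53 so driver flags are only ever planted explicitly
BACKGROUND_GENES: tuple[str, ...] = tuple(f"GENE{i:02d}" for i in range(1, 41))
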