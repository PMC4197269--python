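"""Readers and writers for the panel's small tabular formats.

Regions travel as BED3+name (0-based half-open), gene models as a TSV with
gene_id/chrom/strand/tss (0-based), expression as a genes x samples TSV with
an optional detection p-value sidecar, and sample metadata as a plain TSV
indexed by sample_id.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .methio import TargetRegion
from .integrate import GeneModel


def read_regions_bed(path: str | Path) -> list[TargetRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: row {lineno}: need chrom/start/end/name")
            regions.append(TargetRegion(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return regions


def write_regions_bed(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: gene TSV needs columns {sorted(required)}")
    return [
        GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss))
        for row in df.itertuples(index=False)
    ]


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression values (rows indexed by gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")
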