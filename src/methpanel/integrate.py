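"""TSS-window region-to-gene assignment and methylation-expression integration.

Each transcription start site defines a strand-aware regulatory window
(default 5 kb upstream to 1 kb downstream); targeted regions overlapping a
gene's window by at least one base are candidate regulators of that gene.
A candidate (region, gene) pair is kept when region methylation and gene
expression are strongly anti-correlated across samples (Spearman rho at or
below ``rho_max``) and the methylation change is substantial: at least one
case sample differs from the healthy control by ``fold_min``-fold or more
(pseudocount-stabilized ratio of ratios), with some sample's methylation
ratio reaching ``ratio_min``.  No p-value filtering is applied — the cohort
is too small for that — so the thresholds are the whole filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .methio import TargetRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what the window logic needs: TSS and strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")


@dataclass
class IntegrationParams:
    upstream_bp: int = 5000
    downstream_bp: int = 1000
    rho_max: float = -0.7
    fold_min: float = 2.0
    ratio_min: float = 0.3
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be >= 0")
        if not -1 <= self.rho_max < 0:
            raise ValueError("rho_max must be in [-1, 0)")
        if self.fold_min <= 1:
            raise ValueError("fold_min must be > 1")
        if not 0 < self.ratio_min < 1:
            raise ValueError("ratio_min must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class IntegrationHit:
    """A (region, gene) pair passing all three filter clauses."""

    region_id: str
    gene_id: str
    rho: float
    max_fold_change: float
    max_ratio: float


def tss_window(gene: GeneModel, params: IntegrationParams | None = None) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, half-open, clipped at 0.

    Plus strand: [tss - upstream, tss + downstream); minus strand mirrored.
    """
    if params is None:
        params = IntegrationParams()
    if gene.strand == "+":
        start, end = gene.tss - params.upstream_bp, gene.tss + params.downstream_bp
    else:
        start, end = gene.tss - params.downstream_bp, gene.tss + params.upstream_bp
    return max(start, 0), max(end, 0)


def assign_regions(
    regions: Sequence[TargetRegion],
    genes: Sequence[GeneModel],
    params: IntegrationParams | None = None,
) -> list[tuple[TargetRegion, GeneModel]]:
    """All (region, gene) pairs whose region overlaps the gene's TSS window.

    Overlap of a single base suffices; a region may pair with several genes
    and a gene with several regions.  Lookup uses a per-chromosome interval
    index over the windows.
    """
    if params is None:
        params = IntegrationParams()
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        start, end = tss_window(g, params)
        if end <= start:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(start, end, g)
    pairs: list[tuple[TargetRegion, GeneModel]] = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(r.start, r.end), key=lambda iv: iv.data.gene_id)
        pairs.extend((r, iv.data) for iv in hits)
    return pairs


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average-tie ranks).

    Raises ValueError on length mismatch, fewer than 3 pairs, or an all-tied
    vector (rank correlation undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("all-tied vector: Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def fold_change(a: float, b: float, pseudocount: float = 0.01) -> float:
    """Symmetric ratio-of-ratios fold change, pseudocount-stabilized (>= 1)."""
    a, b = a + pseudocount, b + pseudocount
    return max(a, b) / min(a, b)


def integration_filter(
    pairs: Sequence[tuple[str, str]],
    region_meth: pd.DataFrame,
    expression: pd.DataFrame,
    control_sample: str,
    params: IntegrationParams | None = None,
    include_control_in_correlation: bool = True,
) -> list[IntegrationHit]:
    """Apply the anti-correlation / fold-change / minimum-ratio filter.

    Parameters
    ----------
    pairs
        Candidate (region_id, gene_id) pairs, e.g. from :func:`assign_regions`.
    region_meth
        Region x sample mean methylation ratios.
    expression
        Gene x sample expression values (same sample columns).
    control_sample
        The healthy control column; used as the fold-change reference and, by
        default, included in the correlation (the full-cohort profile set).

    A pair is kept iff rho <= rho_max AND max over case samples of
    fold(m_case, m_control) >= fold_min AND max over all samples (control
    included) of the methylation ratio >= ratio_min.  Pairs whose rank
    correlation is undefined (an all-tied vector) are skipped with a log
    entry.  Hits are sorted by rho ascending.
    """
    if params is None:
        params = IntegrationParams()
    samples = [s for s in region_meth.columns if s in expression.columns]
    if control_sample not in samples:
        raise ValueError(f"control sample {control_sample!r} missing from inputs")
    cases = [s for s in samples if s != control_sample]
    corr_samples = samples if include_control_in_correlation else cases
    if len(corr_samples) < 3:
        raise ValueError("need >= 3 samples with both measurements")

    hits: list[IntegrationHit] = []
    for rid, gid in pairs:
        m = region_meth.loc[rid, samples].astype(float)
        e = expression.loc[gid, samples].astype(float)
        mask = m.notna() & e.notna()
        if control_sample not in m[mask].index or mask.sum() < 3:
            continue
        mc = float(m[control_sample])
        case_ok = [s for s in cases if mask[s]]
        try:
            rho = spearman_rho(
                m[[s for s in corr_samples if mask[s]]].to_numpy(),
                e[[s for s in corr_samples if mask[s]]].to_numpy(),
            )
        except ValueError:
            logger.info("pair (%s, %s) skipped: undefined rank correlation", rid, gid)
            continue
        max_fold = max(fold_change(float(m[s]), mc, params.pseudocount) for s in case_ok)
        max_ratio = float(m[mask].max())
        if rho <= params.rho_max and max_fold >= params.fold_min and max_ratio >= params.ratio_min:
            hits.append(IntegrationHit(rid, gid, rho, max_fold, max_ratio))
    hits.sort(key=lambda h: (h.rho, h.region_id, h.gene_id))
    return hits


def hits_to_frame(hits: Sequence[IntegrationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [h.region_id for h in hits],
            "gene_id": [h.gene_id for h in hits],
            "rho": [h.rho for h in hits],
            "max_fold": [h.max_fold_change for h in hits],
            "max_ratio": [h.max_ratio for h in hits],
        }
    )
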