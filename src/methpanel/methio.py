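"""Reading per-CpG methylation counts and building filtered CpG x sample matrices.

The atomic input is a Bismark-style coverage file: one row per CpG with the
chromosome, 1-based inclusive start/end, percent methylation, methylated read
count and unmethylated read count.  Internally every coordinate is 0-based
half-open; conversion happens only at the I/O boundary.

Missing methylation ratios (zero coverage, or a site filtered out) are a
first-class state represented as NaN in the ratio matrix, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


class CpGSite(NamedTuple):
    """A single CpG position (0-based)."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class MethylationCall:
    """Methylated/unmethylated read counts at one CpG for one sample."""

    site: CpGSite
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(f"negative counts at {self.site}")
        if self.site.pos < 0:
            raise ValueError(f"negative position {self.site}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def methylation_ratio(call: MethylationCall) -> float | None:
    """Methylated fraction n_meth / coverage, or None when coverage is zero."""
    cov = call.coverage
    if cov == 0:
        return None
    return call.n_meth / cov


@dataclass(frozen=True)
class TargetRegion:
    """A targeted amplicon/capture region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty region {self.region_id}: [{self.start}, {self.end})")


@dataclass
class MatrixFilterParams:
    """Site-retention filters applied when assembling the methylation matrix.

    Defaults mirror the standard whole-cohort filter: autosomal CpGs with
    coverage of at least 10 in every sample.
    """

    min_coverage: int = 10
    autosomes_only: bool = True
    require_complete: bool = True
    autosome_names: Sequence[str] = DEFAULT_AUTOSOMES

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class MethylationMatrix:
    """Filtered CpG x sample methylation ratios with a coverage sidecar.

    ``ratio`` and ``coverage`` share an index of (chrom, pos) tuples sorted by
    chromosome then position, and identical sample columns.  A ratio is defined
    (non-NaN) exactly where coverage > 0.
    """

    ratio: pd.DataFrame
    coverage: pd.DataFrame
    n_retained: int = field(default=0)

    @property
    def sites(self) -> list[CpGSite]:
        return [CpGSite(c, p) for c, p in self.ratio.index]

    @property
    def samples(self) -> list[str]:
        return list(self.ratio.columns)

    @property
    def is_empty(self) -> bool:
        return self.ratio.shape[0] == 0


def read_coverage_file(path: str | Path) -> list[MethylationCall]:
    """Parse a Bismark-coverage TSV into methylation calls.

    Columns: chrom, start (1-based), end, percent methylation, count
    methylated, count unmethylated.  Positions are converted to 0-based.
    Malformed rows raise with the offending row number; a percent column that
    disagrees with the counts by more than 0.1 is logged, not fatal.
    Duplicate positions within one file have their counts summed (warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    merged: dict[CpGSite, list[int]] = {}
    dup_warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: row {lineno}: expected 6 columns, got {len(parts)}")
            chrom, start_s, _end_s, pct_s, meth_s, unmeth_s = parts
            try:
                start = int(start_s)
                pct = float(pct_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: malformed numeric field ({exc})") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: row {lineno}: negative counts")
            if not chrom:
                raise ValueError(f"{path}: row {lineno}: empty chromosome")
            cov = n_meth + n_unmeth
            if cov > 0 and abs(pct - 100.0 * n_meth / cov) > 0.1:
                logger.warning(
                    "%s: row %d: percent column %.3f disagrees with counts (%d/%d)",
                    path, lineno, pct, n_meth, cov,
                )
            site = CpGSite(chrom, start - 1)
            if site in merged:
                if not dup_warned:
                    logger.warning("%s: duplicate position %s:%d, summing counts", path, *site)
                    dup_warned = True
                merged[site][0] += n_meth
                merged[site][1] += n_unmeth
            else:
                merged[site] = [n_meth, n_unmeth]
    return [MethylationCall(site, m, u) for site, (m, u) in merged.items()]


def write_coverage_file(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """Write calls as Bismark-coverage TSV (1-based inclusive positions)."""
    rows = sorted(calls, key=lambda c: (c.site.chrom, c.site.pos))
    with open(path, "w") as fh:
        for c in rows:
            cov = c.coverage
            pct = 100.0 * c.n_meth / cov if cov > 0 else 0.0
            start = c.site.pos + 1
            fh.write(f"{c.site.chrom}\t{start}\t{start}\t{pct:.6g}\t{c.n_meth}\t{c.n_unmeth}\n")


def build_matrix(
    calls_per_sample: Mapping[str, Sequence[MethylationCall]],
    params: MatrixFilterParams | None = None,
) -> MethylationMatrix:
    """Assemble the filtered CpG x sample ratio matrix.

    A site is retained iff it lies on an allowed chromosome (when
    ``autosomes_only``) and has coverage >= ``min_coverage`` in every sample
    (when ``require_complete``; otherwise in at least one sample).  Zero
    retained sites yield an empty matrix (``is_empty``), not an exception.
    """
    if params is None:
        params = MatrixFilterParams()
    if len(calls_per_sample) < 2:
        raise ValueError("need at least 2 samples to build a matrix")
    samples = list(calls_per_sample)
    meth = {}
    cov = {}
    for s in samples:
        by_site_m = {}
        by_site_c = {}
        for call in calls_per_sample[s]:
            by_site_m[call.site] = by_site_m.get(call.site, 0) + call.n_meth
            by_site_c[call.site] = by_site_c.get(call.site, 0) + call.coverage
        meth[s] = pd.Series(by_site_m, dtype=float)
        cov[s] = pd.Series(by_site_c, dtype=float)
    meth_df = pd.DataFrame(meth).fillna(0.0)
    cov_df = pd.DataFrame(cov).reindex(meth_df.index).fillna(0.0)

    keep = pd.Series(True, index=cov_df.index)
    if params.autosomes_only:
        allowed = set(params.autosome_names)
        keep &= pd.Series([site[0] in allowed for site in cov_df.index], index=cov_df.index)
    passing = cov_df >= params.min_coverage
    if params.require_complete:
        keep &= passing.all(axis=1)
    else:
        keep &= passing.any(axis=1)

    cov_df = cov_df.loc[keep]
    meth_df = meth_df.loc[keep]
    order = sorted(range(len(cov_df)), key=lambda i: cov_df.index[i])
    cov_df = cov_df.iloc[order]
    meth_df = meth_df.iloc[order]

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = meth_df / cov_df
    ratio = ratio.where(cov_df > 0)
    n = int(ratio.shape[0])
    if n == 0:
        logger.info("build_matrix: zero sites retained under %s", params)
    return MethylationMatrix(ratio=ratio, coverage=cov_df.astype(int), n_retained=n)


def region_mean_methylation(
    matrix: MethylationMatrix, region: TargetRegion, sample: str
) -> float | None:
    """Unweighted mean ratio over the region's CpGs for one sample.

    Uses sites with region.start <= pos < region.end on region.chrom; returns
    None when the region contains no CpG with a defined ratio for the sample.
    """
    if matrix.is_empty:
        return None
    idx = matrix.ratio.index
    mask = [(c == region.chrom and region.start <= p < region.end) for c, p in idx]
    vals = matrix.ratio.loc[mask, sample].dropna()
    if vals.empty:
        return None
    return float(vals.mean())


def region_mean_matrix(
    matrix: MethylationMatrix, regions: Sequence[TargetRegion]
) -> tuple[pd.DataFrame, pd.Series]:
    """Region x sample mean-methylation table plus per-region defined-CpG counts.

    The CpG count reported for a region is the number of retained matrix sites
    falling inside it (sites whose ratio is defined for at least one sample).
    """
    cols = matrix.samples
    out = pd.DataFrame(np.nan, index=[r.region_id for r in regions], columns=cols)
    counts = pd.Series(0, index=out.index, dtype=int)
    if matrix.is_empty:
        return out, counts
    idx = pd.DataFrame(
        {"chrom": [c for c, _ in matrix.ratio.index], "pos": [p for _, p in matrix.ratio.index]}
    )
    for r in regions:
        mask = ((idx["chrom"] == r.chrom) & (idx["pos"] >= r.start) & (idx["pos"] < r.end)).values
        counts[r.region_id] = int(mask.sum())
        if mask.any():
            out.loc[r.region_id] = matrix.ratio.iloc[mask].mean(axis=0, skipna=True)
    return out, counts


def cross_platform_correlation(
    matrix_a: MethylationMatrix, matrix_b: MethylationMatrix, min_coverage: int = 10
) -> tuple[float, int]:
    """Pearson r of ratios over sites covered >= min_coverage on both platforms.

    Both matrices must be single-sample views or share one column; values are
    paired site-by-site over the intersection.  Fewer than 3 shared sites is an
    error naming the count.
    """
    a_ok = matrix_a.coverage.iloc[:, 0] >= min_coverage
    b_ok = matrix_b.coverage.iloc[:, 0] >= min_coverage
    shared = matrix_a.ratio.index[a_ok].intersection(matrix_b.ratio.index[b_ok])
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} shared sites pass coverage {min_coverage}; need >= 3")
    x = matrix_a.ratio.loc[shared].iloc[:, 0].to_numpy(float)
    y = matrix_b.ratio.loc[shared].iloc[:, 0].to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n


def write_matrix(matrix: MethylationMatrix, ratio_path: str | Path, coverage_path: str | Path) -> None:
    """Persist ratio and coverage tables as TSV with 'chrom:pos' row ids."""
    ids = [f"{c}:{p}" for c, p in matrix.ratio.index]
    r = matrix.ratio.copy()
    r.index = ids
    r.to_csv(ratio_path, sep="\t", index_label="site", na_rep="NA")
    cv = matrix.coverage.copy()
    cv.index = ids
    cv.to_csv(coverage_path, sep="\t", index_label="site")


def read_matrix(ratio_path: str | Path, coverage_path: str | Path) -> MethylationMatrix:
    """Inverse of :func:`write_matrix`."""

    def _load(p):
        df = pd.read_csv(p, sep="\t", index_col=0, na_values=["NA"])
        split = [s.rsplit(":", 1) for s in df.index]
        df.index = pd.Index([(c, int(pos)) for c, pos in split])
        return df

    ratio = _load(ratio_path)
    cov = _load(coverage_path).astype(int)
    return MethylationMatrix(ratio=ratio, coverage=cov, n_retained=int(ratio.shape[0]))
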