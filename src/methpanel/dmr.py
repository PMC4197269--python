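"""Subgroup-unique differentially methylated region (DMR) extraction.

A targeted region is called uniquely differentially methylated in a subgroup
when every subgroup sample shifts from the healthy control by at least
``delta_subgroup_min`` in a common direction while every other case sample
stays within ``delta_others_max`` of the control.  Calling operates on
region-level mean methylation (the amplicon average), not individual CpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methio import TargetRegion

logger = logging.getLogger(__name__)

HYPO = "hypo"
HYPER = "hyper"


@dataclass
class DmrParams:
    """Thresholds for the all-of-subgroup / none-of-the-others criterion."""

    delta_subgroup_min: float = 0.2
    delta_others_max: float = 0.1
    min_cpgs_per_region: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.delta_subgroup_min <= 1:
            raise ValueError("delta_subgroup_min must be in (0, 1]")
        if not 0 <= self.delta_others_max < 1:
            raise ValueError("delta_others_max must be in [0, 1)")
        if self.delta_others_max >= self.delta_subgroup_min:
            raise ValueError("delta_others_max must be < delta_subgroup_min")
        if self.min_cpgs_per_region < 1:
            raise ValueError("min_cpgs_per_region must be >= 1")


@dataclass
class DMRRecord:
    """One region called subgroup-unique, with direction and effect sizes."""

    region: TargetRegion
    subgroup: str
    direction: str  # HYPO when subgroup mean < control
    subgroup_mean: float
    control_value: float
    max_other_delta: float


def call_unique_dmrs(
    region_means: pd.DataFrame,
    groups: Mapping[str, str],
    control_sample: str,
    subgroup_label: str,
    params: DmrParams | None = None,
    regions: Sequence[TargetRegion] | None = None,
    cpg_counts: Mapping[str, int] | None = None,
) -> list[DMRRecord]:
    """Extract regions uniquely differentially methylated in ``subgroup_label``.

    Parameters
    ----------
    region_means
        Region x sample mean methylation (NaN = undefined).
    groups
        sample id -> group label for every case sample.
    control_sample
        Column holding the pooled healthy control.
    regions
        Optional region coordinates, keyed into the output records; regions
        absent from this list get placeholder coordinates.
    cpg_counts
        Defined-CpG count per region for the ``min_cpgs_per_region`` clause;
        regions missing from the mapping are treated as passing.

    A region is reported iff (a) every subgroup sample deviates from the
    control by >= delta_subgroup_min, all in the same direction, (b) every
    other case sample deviates by < delta_others_max, and (c) the region has
    at least min_cpgs_per_region defined CpGs.  Regions with a missing control
    value are skipped with a log entry.
    """
    if params is None:
        params = DmrParams()
    if control_sample not in region_means.columns:
        raise ValueError(f"control sample {control_sample!r} not in region means")
    sub = [s for s, g in groups.items() if g == subgroup_label and s != control_sample]
    if not sub:
        raise ValueError(f"unknown or empty subgroup label {subgroup_label!r}")
    others = [
        s for s in region_means.columns
        if s != control_sample and s not in sub and s in groups
    ]
    region_lookup = {r.region_id: r for r in regions} if regions else {}

    out: list[DMRRecord] = []
    for rid, row in region_means.iterrows():
        ctl = row[control_sample]
        if pd.isna(ctl):
            logger.info("region %s skipped: missing control value", rid)
            continue
        if cpg_counts is not None and cpg_counts.get(rid, params.min_cpgs_per_region) < params.min_cpgs_per_region:
            continue
        sub_vals = row[sub].astype(float)
        oth_vals = row[others].astype(float)
        if sub_vals.isna().any() or oth_vals.isna().any():
            continue
        deltas = sub_vals - ctl
        if (deltas.abs() < params.delta_subgroup_min).any():
            continue
        signs = np.sign(deltas.to_numpy())
        if not (signs == signs[0]).all():
            continue
        if ((oth_vals - ctl).abs() >= params.delta_others_max).any():
            continue
        region = region_lookup.get(rid, TargetRegion("?", 0, 1, str(rid)))
        sub_mean = float(sub_vals.mean())
        out.append(
            DMRRecord(
                region=region,
                subgroup=subgroup_label,
                direction=HYPO if sub_mean < ctl else HYPER,
                subgroup_mean=sub_mean,
                control_value=float(ctl),
                max_other_delta=float((oth_vals - ctl).abs().max()) if others else 0.0,
            )
        )
    return out


def hypomethylation_fraction(dmrs: Sequence[DMRRecord]) -> tuple[int, int, float | None]:
    """(#hypomethylated, total, fraction); fraction is None for an empty list."""
    total = len(dmrs)
    n_hypo = sum(1 for d in dmrs if d.direction == HYPO)
    if total == 0:
        return 0, 0, None
    return n_hypo, total, n_hypo / total


def dmrs_to_frame(dmrs: Sequence[DMRRecord]) -> pd.DataFrame:
    """Tabular view (one row per DMR) used by the TSV/BED exports."""
    return pd.DataFrame(
        {
            "region_id": [d.region.region_id for d in dmrs],
            "chrom": [d.region.chrom for d in dmrs],
            "start": [d.region.start for d in dmrs],
            "end": [d.region.end for d in dmrs],
            "subgroup": [d.subgroup for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "subgroup_mean": [d.subgroup_mean for d in dmrs],
            "control_value": [d.control_value for d in dmrs],
            "max_other_delta": [d.max_other_delta for d in dmrs],
        }
    )


def write_dmr_bed(dmrs: Sequence[DMRRecord], path) -> None:
    """BED6 with '<region_id>|<direction>' in the name field."""
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.region.chrom, d.region.start)):
            r = d.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}|{d.direction}\t0\t.\n")
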