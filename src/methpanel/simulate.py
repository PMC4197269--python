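"""Synthetic targeted-bisulfite cohort generator with planted ground truth.

Emulates a small AML-style targeted panel: a handful of molecular subgroups of
two patients each plus a pooled healthy control, a few hundred targeted
regions spread over chr1-chr22 and chrX, per-CpG coverage drawn from a
negative binomial around 83x, and region methylation baselines drawn from
class-specific Beta distributions (CpG island / shore / open sea).

Two kinds of signal are planted and recorded as ground truth:

* subgroup-unique DMRs — a chosen subgroup's samples are shifted by a fixed
  methylation delta (hypomethylated in a configurable fraction of cases,
  default 69%), every other sample stays at baseline;
* methylation-coupled genes — regions given continuous per-patient latent
  methylation heterogeneity whose paired gene's log10 expression decreases
  linearly in methylation, scaled by a coupling strength.

Coverage-level binomial counting noise sits on top of everything, so the
downstream matrix, DMR and integration code sees realistic inputs.  The same
seed always yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .methio import CpGSite, MethylationCall, TargetRegion, write_coverage_file
from .integrate import GeneModel

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMS = AUTOSOMES + ("chrX",)
REGION_CLASSES = ("island", "shore", "open_sea")


@dataclass
class SimConfig:
    """Cohort design and signal parameters.

    Defaults describe the study conditions the package is tested under:
    7 case subgroups x 2 samples + 1 pooled control (15 samples), 500 targeted
    regions of 3-10 CpGs, mean coverage 83x, a 0.4 methylation effect planted
    in subgroup G1 with a 69% hypomethylation fraction, and 30 genes coupled
    to regional methylation with strength 0.9.
    """

    n_case_groups: int = 7
    samples_per_group: int = 2
    n_controls: int = 1
    n_regions: int = 500
    cpgs_per_region: tuple[int, int] = (3, 10)
    coverage_mean: float = 83.0
    coverage_dispersion: float = 20.0
    baseline_beta_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"island": (1.0, 9.0), "shore": (3.0, 3.0), "open_sea": (9.0, 1.0)}
    )
    n_planted_dmrs: int = 50
    dmr_effect: float = 0.4
    hypo_fraction: float = 0.69
    n_planted_pairs: int = 30
    coupling_strength: float = 0.9
    expression_noise_sd: float = 0.15
    seed: int = 0

    # inter-patient latent methylation heterogeneity at coupled regions
    pair_level_sd: float = 0.20
    pair_mean_range: tuple[float, float] = (0.2, 0.6)
    # expression model: log10 e = baseline - slope * coupling * methylation + noise
    expression_baseline: float = 2.5
    expression_slope: float = 2.0
    # panel layout
    region_spacing: int = 8000
    cpg_spacing: int = 50
    max_redraws: int = 5000

    def __post_init__(self) -> None:
        for name in ("n_case_groups", "samples_per_group", "n_controls", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.cpgs_per_region
        if not 0 < lo <= hi:
            raise ValueError("cpgs_per_region must be a positive (low, high) range")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        if not 0 <= self.dmr_effect <= 1:
            raise ValueError("dmr_effect must be in [0, 1]")
        if not 0 <= self.hypo_fraction <= 1:
            raise ValueError("hypo_fraction must be in [0, 1]")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.n_planted_dmrs + self.n_planted_pairs > self.n_regions:
            raise ValueError("more planted regions than regions")
        if set(self.baseline_beta_params) != set(REGION_CLASSES):
            raise ValueError(f"baseline_beta_params must cover {REGION_CLASSES}")


@dataclass
class SimTruth:
    """Planted signals: what a perfect analysis should recover."""

    planted_dmrs: list[dict]   # region_id, subgroup, direction, delta (signed)
    planted_pairs: list[dict]  # region_id, gene_id, sign (-1 anti, 0 uncoupled)

    def dmr_region_ids(self) -> set[str]:
        return {d["region_id"] for d in self.planted_dmrs}

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(p["region_id"], p["gene_id"]) for p in self.planted_pairs}


@dataclass
class Cohort:
    """In-memory cohort bundle; `write_cohort` persists it as plain text."""

    config: SimConfig
    calls: dict[str, list[MethylationCall]]
    regions: list[TargetRegion]
    genes: list[GeneModel]
    expression: pd.DataFrame
    detection_p: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimTruth
    latent_levels: pd.DataFrame  # region x sample true methylation (pre-noise)

    @property
    def samples(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def control_sample(self) -> str:
        return self.metadata.index[self.metadata["group"] == "control"][0]


def _sample_names(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    groups: dict[str, str] = {}
    k = 1
    for g in range(1, cfg.n_case_groups + 1):
        for _ in range(cfg.samples_per_group):
            name = f"AML_{k}"
            names.append(name)
            groups[name] = f"G{g}"
            k += 1
    for c in range(1, cfg.n_controls + 1):
        name = "CD34_pool" if cfg.n_controls == 1 else f"CD34_pool_{c}"
        names.append(name)
        groups[name] = "control"
    return names, groups


def _draw_representable_baseline(
    rng: np.random.Generator, a: float, b: float, effect: float, hypo: bool, max_redraws: int
) -> float:
    """Baseline level at which the full signed effect stays inside [0.02, 0.98]."""
    for _ in range(max_redraws):
        p = rng.beta(a, b)
        if hypo and p - effect >= 0.02:
            return p
        if not hypo and p + effect <= 0.98:
            return p
    raise RuntimeError(
        f"could not draw a baseline supporting a {'hypo' if hypo else 'hyper'} "
        f"shift of {effect} from Beta({a}, {b}) in {max_redraws} tries"
    )


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort.

    Separate RNG streams (fixed offsets from the master seed) drive layout,
    methylation and expression, so the draws of one component are unaffected
    by changes to another.
    """
    cfg = config if config is not None else SimConfig()
    rng_layout = np.random.default_rng(cfg.seed)
    rng_meth = np.random.default_rng(cfg.seed + 1)
    rng_expr = np.random.default_rng(cfg.seed + 2)

    samples, group_of = _sample_names(cfg)
    subgroup = "G1"
    sub_samples = [s for s, g in group_of.items() if g == subgroup]

    # ---- panel layout -----------------------------------------------------
    regions: list[TargetRegion] = []
    region_class: dict[str, str] = {}
    cpg_positions: dict[str, list[int]] = {}
    per_chrom_count = {c: 0 for c in CHROMS}
    for i in range(cfg.n_regions):
        chrom = CHROMS[i % len(CHROMS)]
        slot = per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        n_cpg = int(rng_layout.integers(cfg.cpgs_per_region[0], cfg.cpgs_per_region[1] + 1))
        start = 10_000 + slot * cfg.region_spacing
        end = start + (n_cpg - 1) * cfg.cpg_spacing + 2
        rid = f"R{i + 1:04d}"
        regions.append(TargetRegion(chrom, start, end, rid))
        region_class[rid] = REGION_CLASSES[int(rng_layout.integers(0, 3))]
        cpg_positions[rid] = [start + j * cfg.cpg_spacing for j in range(n_cpg)]

    autosomal = [r.region_id for r in regions if r.chrom != "chrX"]
    picked = rng_layout.choice(
        len(autosomal), size=cfg.n_planted_dmrs + cfg.n_planted_pairs, replace=False
    )
    dmr_ids = [autosomal[i] for i in picked[: cfg.n_planted_dmrs]]
    pair_ids = [autosomal[i] for i in picked[cfg.n_planted_dmrs:]]

    # one gene per region, TSS just inside the region so its window covers it
    genes: list[GeneModel] = []
    gene_of_region: dict[str, str] = {}
    for i, r in enumerate(regions):
        strand = "+" if i % 2 == 0 else "-"
        gid = f"G{i + 1:04d}"
        genes.append(GeneModel(gid, r.chrom, strand, r.start + 100))
        gene_of_region[r.region_id] = gid

    # ---- latent methylation levels ---------------------------------------
    truth_dmrs: list[dict] = []
    levels = pd.DataFrame(0.0, index=[r.region_id for r in regions], columns=samples)
    plant_dmrs = cfg.dmr_effect > 0
    for r in regions:
        rid = r.region_id
        a, b = cfg.baseline_beta_params[region_class[rid]]
        if rid in pair_ids:
            mu = rng_meth.uniform(*cfg.pair_mean_range)
            levels.loc[rid] = np.clip(
                rng_meth.normal(mu, cfg.pair_level_sd, len(samples)), 0.02, 0.98
            )
        elif plant_dmrs and rid in dmr_ids:
            hypo = bool(rng_meth.random() < cfg.hypo_fraction)
            base = _draw_representable_baseline(
                rng_meth, a, b, cfg.dmr_effect, hypo, cfg.max_redraws
            )
            delta = -cfg.dmr_effect if hypo else cfg.dmr_effect
            levels.loc[rid] = base
            levels.loc[rid, sub_samples] = base + delta
            truth_dmrs.append(
                {
                    "region_id": rid,
                    "subgroup": subgroup,
                    "direction": "hypo" if hypo else "hyper",
                    "delta": delta,
                }
            )
        else:
            levels.loc[rid] = rng_meth.beta(a, b)

    truth_pairs = [
        {
            "region_id": rid,
            "gene_id": gene_of_region[rid],
            "sign": -1 if cfg.coupling_strength > 0 else 0,
        }
        for rid in pair_ids
    ]

    # ---- per-CpG counts ---------------------------------------------------
    theta = cfg.coverage_dispersion
    p_nb = theta / (theta + cfg.coverage_mean)
    calls: dict[str, list[MethylationCall]] = {s: [] for s in samples}
    for r in regions:
        rid = r.region_id
        for pos in cpg_positions[rid]:
            site = CpGSite(r.chrom, pos)
            cov = rng_meth.negative_binomial(theta, p_nb, len(samples))
            meth = rng_meth.binomial(cov, levels.loc[rid].to_numpy())
            for s, c, m in zip(samples, cov, meth):
                calls[s].append(MethylationCall(site, int(m), int(c - m)))

    # ---- expression -------------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    log_e = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    coupled_genes = {p["gene_id"]: p["region_id"] for p in truth_pairs}
    for g in genes:
        if g.gene_id in coupled_genes:
            m = levels.loc[coupled_genes[g.gene_id]].to_numpy()
            log_e.loc[g.gene_id] = (
                cfg.expression_baseline
                - cfg.expression_slope * cfg.coupling_strength * m
                + rng_expr.normal(0.0, cfg.expression_noise_sd, len(samples))
            )
        else:
            a_g = rng_expr.uniform(1.0, 3.0)
            log_e.loc[g.gene_id] = a_g + rng_expr.normal(0.0, 0.3, len(samples))
    expression = (10.0 ** log_e).round(6)

    detection = pd.DataFrame(
        rng_expr.uniform(0.0, 0.04, size=(len(gene_ids), len(samples))),
        index=gene_ids, columns=samples,
    )
    uncoupled = [g for g in gene_ids if g not in coupled_genes]
    n_undetected = max(1, len(uncoupled) // 20)
    for gi in rng_expr.choice(len(uncoupled), size=n_undetected, replace=False):
        s = samples[int(rng_expr.integers(0, len(samples)))]
        detection.loc[uncoupled[int(gi)], s] = float(rng_expr.uniform(0.06, 0.5))
    detection = detection.round(6)

    metadata = pd.DataFrame(
        {
            "group": [group_of[s] for s in samples],
            "material": ["BM" if i % 2 == 0 else "PB" for i in range(len(samples))],
            "is_control": [int(group_of[s] == "control") for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )

    return Cohort(
        config=cfg,
        calls=calls,
        regions=regions,
        genes=genes,
        expression=expression,
        detection_p=detection,
        metadata=metadata,
        truth=SimTruth(planted_dmrs=truth_dmrs, planted_pairs=truth_pairs),
        latent_levels=levels,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Persist the cohort as plain-text files re-readable by the I/O layer."""
    out = Path(out_dir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    for s, calls in cohort.calls.items():
        write_coverage_file(calls, out / "meth" / f"{s}.cov.tsv")
    mio.write_regions_bed(cohort.regions, out / "regions.bed")
    mio.write_genes_tsv(cohort.genes, out / "genes.tsv")
    mio.write_expression_tsv(cohort.expression, out / "expression.tsv")
    mio.write_expression_tsv(cohort.detection_p, out / "detection_p.tsv")
    mio.write_metadata_tsv(cohort.metadata, out / "metadata.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(cohort.truth), fh, indent=2, sort_keys=True)
        fh.write("\n")


def generate_survival(
    metadata: pd.DataFrame,
    relapse_rate_ratio: float,
    seed: int,
    horizon_days: float = 1825.0,
    median_relapse_days: float = 540.0,
    median_os_days: float = 900.0,
    high_category: str = "up",
) -> pd.DataFrame:
    """Attach exponential OS/RFS outcomes to a categorized cohort.

    The ``high_category`` expression class has its relapse hazard multiplied by
    ``relapse_rate_ratio``; everyone is administratively censored at
    ``horizon_days``.  Relapse and death-without-relapse are mutually
    exclusive competing events on the RFS axis.
    """
    if relapse_rate_ratio <= 0:
        raise ValueError("relapse_rate_ratio must be positive")
    if "expression_category" not in metadata.columns:
        raise ValueError("metadata needs an 'expression_category' column")
    rng = np.random.default_rng(seed)
    n = len(metadata)
    lam_rel = np.log(2) / median_relapse_days
    lam_dth = np.log(2) / median_os_days
    high = (metadata["expression_category"] == high_category).to_numpy()
    rates = np.where(high, lam_rel * relapse_rate_ratio, lam_rel)
    t_rel = rng.exponential(1.0 / rates, n)
    t_dth = rng.exponential(1.0 / lam_dth, n)

    out = metadata.copy()
    out["os_time"] = np.minimum(t_dth, horizon_days)
    out["os_event"] = (t_dth <= horizon_days).astype(int)
    rfs = np.minimum(np.minimum(t_rel, t_dth), horizon_days)
    out["rfs_time"] = rfs
    out["relapse_event"] = ((t_rel < t_dth) & (t_rel <= horizon_days)).astype(int)
    out["death_event"] = ((t_dth <= t_rel) & (t_dth <= horizon_days)).astype(int)
    if horizon_days == 0:
        out[["os_event", "relapse_event", "death_event"]] = 0
    return out
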