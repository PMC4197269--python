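"""Generate the study cohort: 14 AML-like cases in 7 molecular subgroups plus
a pooled healthy control, 500 targeted regions at ~83x coverage, with 50
subgroup-unique DMRs (69% hypomethylated) planted in subgroup G1 and 30
methylation-coupled genes.

Full cohort files go to scratch/cohort/ (large, regenerable); a small design
summary goes to results/cohort_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from methpanel.simulate import SimConfig, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, ROOT / "scratch" / "cohort")

    coverages = np.concatenate(
        [[c.coverage for c in calls] for calls in cohort.calls.values()]
    )
    dirs = [d["direction"] for d in cohort.truth.planted_dmrs]
    summary = {
        "seed": SEED,
        "samples": len(cohort.samples),
        "case_groups": cfg.n_case_groups,
        "regions": len(cohort.regions),
        "cpg_calls": int(coverages.size),
        "mean_coverage": round(float(coverages.mean()), 2),
        "coverage_range_p1_p99": [
            round(float(np.percentile(coverages, 1)), 1),
            round(float(np.percentile(coverages, 99)), 1),
        ],
        "planted_dmrs": len(cohort.truth.planted_dmrs),
        "planted_hypo_fraction": round(dirs.count("hypo") / len(dirs), 3),
        "planted_pairs": len(cohort.truth.planted_pairs),
    }
    out = ROOT / "results" / "cohort_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(f"cohort written to scratch/cohort ({summary['samples']} samples, "
          f"{summary['regions']} regions, mean coverage {summary['mean_coverage']}x)")
    print(f"planted: {summary['planted_dmrs']} DMRs "
          f"({100 * summary['planted_hypo_fraction']:.0f}% hypomethylated), "
          f"{summary['planted_pairs']} coupled genes")


if __name__ == "__main__":
    main()
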