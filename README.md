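# methpanel

Analysis toolkit for **targeted bisulfite sequencing** of small clinical
cohorts — the kind of design where a dozen leukemia patients and one pooled
healthy CD34+ control are sequenced over a capture panel of regulatory
regions at ~80× coverage, and the questions are: which samples cluster
together, which regions are uniquely differentially methylated in a
molecular subgroup, and which of those methylation changes plausibly drive
gene expression.

It is organised as an analysis project: the library under `src/methpanel/`
carries every computation, the numbered scripts under `analysis/` run the
study end to end on a synthetic cohort with planted ground truth, and the
test suite checks each operation against independent brute-force oracles.

## What it computes

- **Methylation matrices** (`methio`): Bismark-coverage TSV in, filtered
  CpG × sample ratio matrix out. A CpG is kept iff it is autosomal and
  covered ≥ 10× in *every* sample; methylation ratio is
  `n_meth / (n_meth + n_unmeth)`, undefined (never 0) without coverage.
  Region-level methylation is the unweighted CpG average per amplicon.
- **Clustering** (`clustering`): samples clustered with correlation distance
  `d(i,j) = 1 − r(x_i, x_j)` and Ward linkage (Ward.D2); cluster stability
  by feature bootstrap — a node's support is the fraction of resampled trees
  containing the same leaf set. Expression side: detection-p filter
  (p ≤ 0.05 in all samples) and quantile normalization.
- **Subgroup-unique DMRs** (`dmr`): region reported iff every subgroup
  sample shifts ≥ 0.2 from the control with one sign while every other case
  stays within 0.1; direction `hypo`/`hyper`, hypomethylation fraction
  summarized over the call set.
- **Methylation–expression integration** (`integrate`): strand-aware TSS
  windows (−5 kb … +1 kb), region–gene pairs by ≥ 1 bp overlap, kept when
  Spearman ρ ≤ −0.7 **and** methylation changes ≥ 2-fold vs control
  (pseudocount 0.01) **and** some sample reaches ratio ≥ 0.3.
- **Cohort statistics** (`cohortstats`): over/under-expresser categories
  (conjunctive > 2-fold and > 10-fold vs the healthy mean), Fisher's exact,
  Mann–Whitney (exact for small tie-free samples), Kaplan–Meier, two-sided
  log-rank, and Aalen–Johansen cumulative incidence of relapse with death
  as competing risk.
- **Synthetic cohorts** (`simulate`): 15-sample panel (7 subgroups × 2 + 1
  control), negative-binomial coverage around 83×, class-specific Beta
  baselines, planted subgroup DMRs (69% hypomethylated, effect 0.4) and
  methylation-coupled genes, exponential survival with a configurable
  relapse-hazard ratio — with the planted truth returned for recovery
  scoring. Same seed ⇒ byte-identical files.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/03_call_dmrs.py
python analysis/04_integrate_expression.py
```

prints (seed 1, the repository default):

```
cohort written to scratch/cohort (15 samples, 500 regions, mean coverage 83.04x)
planted: 50 DMRs (74% hypomethylated), 30 coupled genes
48 subgroup-unique DMRs; 36 hypomethylated (75%)
recovery of planted truth: 48/50 (sensitivity 0.96), 0 false discoveries
500 candidate region-gene pairs -> 28 hits (28 unique genes)
planted-pair recovery: 28/30 (93%); 0 hits outside the planted truth
```

That is the whole story in three lines per step: the DMR caller finds 96% of
the planted subgroup-unique regions with no false calls, the hypomethylation
fraction of the call set tracks the planted 69%/31% direction mix, and the
TSS-window anti-correlation filter recovers 93% of the genes whose
expression was coupled to regional methylation — with zero spurious pairs.
`analysis/02_cluster_samples.py` shows the planted two-patient subgroup as a
sibling pair with bootstrap support 1.00 in the methylation tree, and
`analysis/05_cohort_statistics.py` runs the downstream categorical and
survival statistics (e.g. the 0/6-vs-26/46 risk-group table gives Fisher
p = 0.02).

A `methpanel` CLI wraps the same operations for file-based use
(`methpanel simulate|matrix|cluster|dmr|integrate|stats …`; see `--help`).

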