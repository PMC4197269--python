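# Methods

`methpanel` implements a targeted bisulfite-sequencing analysis chain for a
small leukemia-style cohort — per-CpG methylation matrices, sample
clustering, subgroup-unique DMR extraction, TSS-window methylation–expression
integration, and cohort statistics — together with a synthetic cohort
generator that plants the signals the chain is supposed to find. This note
records the models, the parameters that matter, and the design choices made
where more than one reasonable convention exists.

## Methylation matrices

A Bismark-style coverage file gives, per CpG, methylated and unmethylated
read counts; the methylation ratio is `n_meth / (n_meth + n_unmeth)`, and a
zero-coverage site has an *undefined* ratio — missingness is a first-class
state (NaN in the matrix), never encoded as 0. Internal coordinates are
0-based half-open; conversion from the 1-based coverage dialect and to/from
BED happens only at I/O boundaries. Duplicate positions within one file are
summed with a warning; a percent column disagreeing with the counts by more
than 0.1 is logged but not fatal.

The cohort matrix retains exactly the CpGs that lie on the configured
autosomes (`chr1`–`chr22` by default, so sex-chromosome and mitochondrial
calls drop out) and reach the minimum coverage (default 10×) in **every**
sample. Region-level methylation is the unweighted mean of the defined CpG
ratios inside a region — the amplicon average — and is undefined for a
region with no defined CpG.

## Clustering

Sample distance is `1 − Pearson r` between complete feature profiles
(features with any missing value are dropped first, consistent with the
available-in-all-samples matrix filter). Trees are built by Ward
agglomeration in the Ward.D2 convention — the Lance–Williams squared-distance
update applied to the precomputed distance matrix, which is what
`scipy.cluster.hierarchy.linkage(method="ward")` computes on a condensed
input; an independent O(n³) Lance–Williams implementation in the test suite
cross-checks both merge sets and heights. Tie-breaking follows scipy's
nearest-neighbor chain; ties are measure-zero for continuous profiles.

Cluster stability is an **ordinary feature bootstrap**: features resampled
with replacement, tree rebuilt, and a node's support is the fraction of
bootstrap trees containing the same leaf set (bootstrap probability).
Multiscale bootstrap with approximately-unbiased corrections is deliberately
not reproduced: plain BP answers the qualitative question (does the planted
pair hold together?) without the extra machinery, and the divergence is
documented here. Default 1000 replicates; the bundled analyses use 200,
which is ample for a 15-sample tree.

Expression preprocessing: genes are kept when their detection p-value is
≤ α (inclusive, default 0.05) in every sample, then quantile-normalized —
each column's sorted values are replaced by cross-column rank means, tied
entries receiving the value interpolated at their average rank. Microarray
background subtraction is out of scope.

## Subgroup-unique DMRs

The uniqueness criterion is threshold-based and operates on region means:
a region is called for subgroup S iff

1. every S sample deviates from the pooled healthy control by
   ≥ `delta_subgroup_min` (default 0.2), all deviations sharing one sign;
2. every non-S, non-control case deviates by < `delta_others_max`
   (default 0.1);
3. the region has ≥ `min_cpgs_per_region` (default 3) defined CpGs.

Direction is `hypo` when the subgroup mean is below the control. The
thresholds are configurable because no single canonical pair exists; the
defaults separate a planted 0.4 effect from ~0.02–0.04 counting noise with a
wide margin in both directions. Calling is region-level (the validation unit
is the amplicon), not a sliding-window de-novo scan, and no per-region
significance test is attached. With several controls the control value is
their mean.

## Methylation–expression integration

Each TSS defines a strand-aware window from 5 kb upstream to 1 kb downstream
(mirrored on the minus strand, clipped at 0); regions overlapping a window
by ≥ 1 bp are candidate (region, gene) pairs — many-to-many by design. A
pair becomes a hit iff, across the cohort profiles:

* Spearman ρ(methylation, expression) ≤ `rho_max` (default −0.7);
* some case sample's region methylation differs from the control by
  ≥ `fold_min`-fold (default 2) in either direction, computed as
  `max(a+ε, b+ε)/min(a+ε, b+ε)` with pseudocount ε = 0.01 so that
  near-zero ratios neither blow up nor silently pass;
* some sample (control included) has methylation ratio ≥ `ratio_min`
  (default 0.3).

The healthy control is included in the correlation by default (15 profiles);
a flag excludes it. No p-value filter or multiple-testing correction is
applied — at this sample size the thresholds *are* the filter. Expression
enters as provided: Spearman is rank-invariant, so a log transform would
change nothing.

## Cohort statistics

* **Expression categories**: a patient is an over-/under-expresser when the
  ratio to the healthy-donor mean exceeds both the fold threshold (2) and
  the order-of-magnitude threshold (10) — read conjunctively, so 10× is the
  effective cutoff; both remain configurable since a disjunctive reading is
  defensible.
* **Fisher's exact**: two-sided by summation of hypergeometric probabilities
  ≤ that of the observed table (scipy); the worked risk-group table
  (0/6 vs 26/46) gives p = 0.0226, printing as 0.02.
* **Mann–Whitney**: exact enumeration when min(n, m) ≤ 8 and the pooled data
  are tie-free (exact null enumeration is undefined under ties); otherwise
  the normal approximation with tie correction and **no** continuity
  correction, so identical samples return p = 1 exactly.
* **Survival**: Kaplan–Meier product-limit curves and the two-sided log-rank
  test (lifelines). Relapse is summarized twice: log-rank on relapse with
  death censored, and the Aalen–Johansen cumulative incidence with
  death-without-relapse as a competing risk — the two answer different
  questions and are reported side by side; Gray's test is not implemented.
  Cox regression is out of scope.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions everything else is validated under.

**Design.** 7 molecular subgroups × 2 patients + 1 pooled healthy control
(15 samples); 500 targeted regions of 3–10 CpGs (50 bp spacing) laid out
round-robin over chr1–chr22 and chrX, so autosome filtering is exercised;
one gene per region with alternating strand and a TSS 100 bp inside the
region, so every region is its own gene's promoter-window candidate.

**Counts.** Per-CpG coverage ~ negative binomial with mean 83 and size 20,
giving a central 46–131-style spread; only the mean and range of real
panels are typically reported, so the NB size is a stand-in exposed in the
config. Methylated counts ~ Binomial(coverage, level).

**Baselines.** Each region draws one class — CpG island, shore, open sea —
and a baseline level from Beta(1, 9), Beta(3, 3) or Beta(9, 1) respectively,
mimicking the bimodal-with-middle mix of a promoter-weighted panel.

**Planted DMRs** (default 50, all in subgroup G1): direction is hypo with
probability 0.69; the subgroup's level is the baseline shifted by the full
effect (default 0.4). Baselines are redrawn (bounded retries) until the full
effect fits inside [0.02, 0.98]: a clamped shift would plant a DMR whose
recorded truth overstates its realized effect, corrupting recovery metrics.

**Planted coupled pairs** (default 30, disjoint from the DMR regions): these
regions receive *continuous per-patient heterogeneity* — latent levels
clipped-Normal around a region mean drawn from U(0.2, 0.6) with SD 0.20 —
and the paired gene's log10 expression is
`2.5 − 2.0 · coupling · level + N(0, 0.15)`. The heterogeneity is essential:
with counting noise alone (~2% SD) the integration filter's fold-change
clause is unsatisfiable, since no case would ever differ 2-fold from the
control. Inter-patient variation of this size at regulatory regions is the
realistic regime the filter was designed for. The SD/mean-range values were
fixed once by a pre-build Monte Carlo of the three filter clauses (joint
recovery ≈ 0.92 at coupling 0.9).

Uncoupled genes get an independent gene-level mean (log10 ~ U(1, 3)) with
0.3 SD per-sample noise; detection p-values are < 0.05 everywhere except a
5% subset of uncoupled genes given one undetected sample.

**Streams and determinism.** Layout, methylation and expression use separate
`default_rng(seed + k)` streams, so adding a component never perturbs the
others; a fixed seed yields byte-identical files.

**Survival.** `generate_survival` attaches exponential event times: relapse
hazard ln2/540 days (multiplied by the configured rate ratio for the
high-expression category), death hazard ln2/900 days, administrative
censoring at 5 years. Relapse and death-without-relapse are mutually
exclusive first-event flags, feeding both the log-rank and the
competing-risk estimators. A zero horizon censors everything at 0.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level artifacts (bisulfite conversion
error, M-bias, mapping bias), strand structure, linkage between neighboring
CpGs within a region beyond the shared level, copy-number or purity effects,
a subgroup-wide *expression* program (only per-gene coupling is planted, so
expression clustering of the synthetic cohort is a null), and any real
genome annotation.

## Problem sizes and numerical choices

The bundled analyses and the acceptance script run the default cohort
(15 samples, 500 regions, ≈ 3 300 CpG calls per sample) with 200 bootstrap
replicates — sizes at which every planted-signal metric is stable across
seeds while a full run stays in the tens of seconds. The null-calibration
study uses 2 000 replicates per statistic; its log-rank replicates use 100
patients per arm because the chi-square approximation of the log-rank test
is mildly liberal at 50/arm (empirical type-I 0.056 vs 0.049 at 100/arm,
measured by a 20 000-replicate pre-study) and the study's purpose is to
verify the implementations at nominal operating conditions, not to probe
small-sample behavior.

Degenerate inputs are explicit everywhere: empty matrices signal emptiness
rather than raising mid-pipeline, an all-tied vector makes Spearman
undefined (the pair is skipped and logged), a DMR region with a missing
control value is skipped and logged, the hypomethylation fraction of an
empty DMR list is missing rather than 0, and a log-rank with no events at
all raises.

## Known limitations

Bootstrap probabilities are not AU p-values and are biased low for clades
near the resolution limit. The DMR criterion is a deterministic threshold
rule, not an inferential test; its false-discovery behavior under strong
inter-patient heterogeneity (beyond the planted-pair regions) is untested.
The Mann–Whitney exact path refuses ties rather than enumerating the
conditional null. The integration filter assumes one shared sample namespace
between methylation and expression and performs complete-case analysis per
pair.
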