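# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator
emulates, and the numerical edge-case decisions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quality control and normalization

A cell is excluded when **any** criterion fails: mapped reads < 500,000,
mitochondrial mapping percentage > 10, or detected genes < 3,000. The
inequalities are strict as printed, so boundary cells (exactly 500,000
reads, exactly 10%, exactly 3,000 genes) pass; the reading of the
exclusion conjunction as an OR of violations is deliberate — requiring all
three failures simultaneously would retain cells that clearly failed one
check. The detected-genes metric comes from the per-cell statistics table
(genes at ≥ 1 RPKM upstream) and is never recomputed from counts, since
the pipeline does not see gene lengths.

CPM is count / library total × 10⁶, per cell; the level scale for PCA,
clustering and the level test is log2(CPM + 1). Variable genes satisfy
CV ≥ 1 — coefficient of variation with the sample (n−1) standard
deviation, on the CPM scale — and mean CPM > 1. The CV threshold is
inclusive (≥): where the operational description says ≥ and a narrative
description says >, the operational form wins; the cut is a parameter
either way. "Mean expression log2(CPM) > 0" is read as mean CPM > 1
(log of the mean, not mean of the logs), matching the narrative "average
expression > 1 count per million".

## PCA, top-loading genes, hierarchical clustering

PCA is gene-centered and unscaled, over cells, on log2(CPM+1) of the
variable genes; raw CPM would be magnitude-dominated and scaling to unit
variance would up-weight noise genes, so centering-only is the default
with scaling available upstream of the call. Loadings are reported as the
Pearson correlation between each gene's expression vector and each
component's score vector, which keeps them in [−1, 1] and comparable
across components. Component signs are fixed (largest-|entry| of each
score vector positive); all downstream selections are sign-invariant
anyway.

Each gene is scored by the maximum |loading| over the first 3 components
(the aggregation across components is genuinely open; `max` is the
default, with `l2` and per-component `union` as alternatives) and the top
100 genes are kept, ties broken lexicographically for determinism. Cells
are then clustered by complete linkage on d = 1 − Pearson r computed over
those 100 genes only. A cell constant across the panel has no defined
correlation and raises an error naming the cell.

Cluster-group concordance is summarized as purity: the mean over cells of
the majority-group share of each cluster (1.0 = clusters and age groups
coincide).

## Dual differential expression

Per gene, with two cell groups:

* **frequency**: Fisher's exact test (two-sided, sum of same-margin table
  probabilities ≤ the observed one) on detected/not-detected × group,
  where detected means CPM > 0 (threshold configurable). A χ² variant
  (no continuity correction) is available; see calibration below.
* **level**: two-sided Wilcoxon rank-sum on log2(CPM+1) among detecting
  cells only, so the two components measure complementary signal —
  how often the gene is on versus how strongly it is expressed when on.
  An all-cells mode exists behind a flag. Exact enumeration is used when
  both groups have ≤ 8 values and no ties; otherwise the tie-corrected
  normal approximation without continuity correction (identical samples
  then give exactly p = 1). A gene with fewer than two detecting cells,
  or none in one group, gets p_level = 1 and the frequency test carries
  the signal.
* **combination**: Fisher's method. X = −2(ln p_level + ln p_freq) is
  χ² with 4 df; the upper tail has closed form e^(−X/2)(1 + X/2). Zero
  p-values are clamped to 1e−300. Combining (p, 1) yields p(1 − ln p) ≥ p.
* **multiplicity**: Benjamini–Hochberg step-up across all tested genes;
  significance threshold 0.05 for comparisons of ≤ 100 cells and 0.005
  above 100, following the large-sample rule.

**Calibration.** The exact Fisher component is conservative on discrete
2×2 tables, so the combined null rejection rate at α = 0.05 sits near
0.02–0.03 rather than 0.05; this is a property of exact conditional
tests, not a defect. The χ² variant is the calibrated one: on
exchangeable two-group simulations (2,000 genes, 50 cells/group, uniform
detection 0.5) its combined rejection rate is 0.045–0.055. Both variants
are exposed; the exact test is the default for per-gene inference (no
minimum-count requirements), the χ² variant for calibration-sensitive
uses.

`fold_regulation` is the difference of group means of log2(CPM+1) over
all cells, i.e. a log2 fold that blends frequency and conditional level.

## GSEA

Ranking metric: log2((x̄_A + c)/(x̄_B + c)) on group-mean CPM with
pseudo-mean c = 1 to guard empty means; ties break on gene id. The
weighted KS running sum increments at set members by |metric|^w
normalized by the summed member weights (w = 1 default, the cited tool's
default; w = 0 gives the unweighted statistic) and decrements at
non-members by 1/(N − N_hits); ES is the signed extremum. The null is
**gene-set permutation** — random same-size sets from the ranked
universe — exactly as the study configured it (1,000 permutations);
NES = ES / mean(|null ES| of the same sign), and
p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
null}), so p ≥ 1/(n_perm + 1). The permutation null is evaluated in a
vectorized form that uses only member positions (the walk is linear
between hits, so extrema occur adjacent to hits); a test verifies it
against direct running-sum recomputation. A set covering the whole
universe has no miss step; its walk is measured against the uniform
expectation and is near zero, and permutation analysis rejects it.

## Single-cell qPCR

ΔCt = Ct_reference − Ct_assay per cell (reference assay Kit), so larger
ΔCt means higher expression; cells without reference expression are
excluded and listed with the reason. Detection is a valid Ct below the
limit of detection (default 40 cycles, configurable — the platform's
fail flags and empty exports both map to missing at read time).
Frequencies compare by χ² (continuity correction off by default),
levels among positive cells by a two-tailed two-sample t-test (an assay
with < 2 positive cells in a group is flagged untestable rather than
given a p), and co-expression by a two-sample KS test on the per-cell
count of detected panel assays. Per-assay tests carry no multiplicity
correction beyond the α rules, mirroring the figure-level analyses; a BH
flag is available.

## Clonal analytics

Inclusion: any lineage ≥ 0.1% at any analysed time point (the boundary is
inclusive; both "> 0.1%" and "at least 0.1%" appear in the source
descriptions, and the inclusive reading is parameterized). The threefold
rule uses L = max(B, T) by default — whether lymphoid output should be
the max or the sum of B and T is not specified anywhere; `sum` is an
option. A clone's label must hold at both weeks 10 and 16; discordant
weeks yield Ba. Platelet-restricted requires platelet ≥ 0.1% at some
analysed week and myeloid, B and T each below 0.01% (the detection floor
is not printed anywhere; 0.01% with override) at every analysed week; the
flag is only set together with the Pl label.

The limiting-dilution estimator assumes single-hit Poisson engraftment:
with k of n recipients positive at `dose` cells each, the negative
fraction estimates e^(−f·dose), so f = −ln((n − k)/n)/dose. k = n has no
finite estimate and raises. Point estimate only — no confidence
interval, matching the original analysis.

## Synthetic-data generator

The generator produces data with the statistical structure the analyses
assume — nothing more. Three modalities:

**Counts.** Gene × cell counts are Bernoulli(detection) ×
negative-binomial(mean, dispersion α; var = μ + αμ²; α = 0 is Poisson),
with per-gene base means log-normal (natural-log mean 3.0, sd 2.0 — a
realistic several-decade abundance span) and per-cell library size
factors from 50,000–200,000. Background-gene detection is
expression-linked: a logistic in log2 mean (slope 0.75 log2 units,
range 0.02–0.98), so abundant genes are rarely missed and rare genes
mostly drop out — the shared detection profile that real single-cell
data show and that correlation-based clustering relies on. The platelet
program (default 50 of 2,000 genes) is mostly silent at baseline
(detection 0.15 in both groups) and induced in the old group: detection
+ freq_effect (default 0.75, i.e. old cells detect program genes at
0.9) and negative-binomial mean × a per-gene log-normal fold with
median level_effect (default 4) and log-sd 0.5 — real programs shift
heterogeneously, and that heterogeneity is what makes the old cells'
shared program profile visible to Pearson distance. A `uniform`
detection mode applies one probability to every gene, for degenerate
checks and exchangeable-null calibration. The per-gene truth table
records programmed status, detection probabilities and means.

What the generator does **not** emulate: transcriptome-wide gene-gene
correlation, batch effects, cell-cycle structure, or depth-dependent
per-cell dropout. Consequently a passing clustering test shows that the
recipe separates groups whose difference is a coherently shifted gene
program over a realistic abundance/dropout landscape — not that it would
survive confounded real data. Under weak shifts (freq_effect ≲ 0.4) the
groups are not separable by this recipe in independence-generated data,
although the differential-expression and GSEA stages still detect the
program easily; the end-to-end separation property is therefore asserted
at the defaults (strong shift), which emulate the broadly induced
platelet program of aged HSCs.

**Ct matrices.** Per assay and group, a detection probability and a mean
ΔCt; reference Ct is Gaussian (mean 15, sd 0.5), detected assay Ct =
Ct_ref − ΔCt + N(0, 0.5), undetected entries missing, reference detected
at 0.95. Defaults give three platelet/myeloid assays with old-vs-young
frequency shifts of 0.1–0.3 and ΔCt shifts of 0.5–2 cycles at 150
cells/group.

**Clone tables.** A planted mixture of the four archetypes (defaults
40/30/20/10% Pl / Pl-My / Ba / Ly) with per-lineage mean profiles chosen
so each archetype satisfies its rule with margin, log-normal output
noise (sd 0.3, "moderate"), two time points (10, 16 weeks), and 10%
non-engrafting clones below the inclusion threshold everywhere. The
composition is exact-count (rounded expectation, shuffled), not
multinomial, so recovery checks measure classification error rather than
sampling noise of the mixture itself.

All generators are deterministic functions of their seed (numpy
`default_rng`).

## Problem sizes and determinism

Default study-scale sizes are used throughout the tests and the
acceptance script: 2,000 genes × 100 cells/group for transcriptome
stages, 3 seeds × 50 cells/group for null calibration, 1,000
permutations for GSEA (200-replicate uniformity checks at 200
permutations on a 500-gene universe), 150 cells/group for qPCR, 200
clones for the clonal mixture. Every stochastic step takes an explicit
seed; the CLI stamps each output with the seed and a configuration hash,
and rerunning with the same seed reproduces outputs byte-for-byte.

## Known limitations

* Exact-test conservatism makes the default dual test under-reject on
  null data (see Calibration above); effect-size recovery is unaffected.
* The Wilcoxon normal approximation (no continuity correction) can
  deviate from the exact tail by up to ~0.04 at n = 8/8 in the small-p
  region; the exact branch covers those sizes in practice.
* Purity as a concordance measure is optimistic for many small clusters;
  it is only used at the 2-cluster cut.
* The NES normalization assumes enough same-sign null scores; with
  pathological metrics (all-zero) the ES falls back to unweighted steps.
* No covariates, batch correction, doublet handling, or multi-group
  designs — the pipeline mirrors a two-group study design.
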