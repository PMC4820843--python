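# hscbias

Analytics for the platelet bias of aged haematopoietic stem cells (HSCs).

Ageing expands a platelet-primed, Vwf⁺ HSC subset: aged HSCs express
platelet-lineage genes in more cells and at higher levels, and single-HSC
transplants from old mice are dominated by platelet-biased — often
platelet-restricted — clones. `hscbias` is a tested, reusable
implementation of the computational pipeline behind that kind of study,
covering five analysis modalities plus a seeded synthetic-data generator
that emulates each one, so the whole pipeline runs end-to-end with no
external data.

## What it computes

**Single-cell RNA-seq QC and clustering** (`qc`, `cluster`). Cells are
excluded when mapped reads < 500,000, mitochondrial mapping > 10%, or
detected genes < 3,000 (strict inequalities; boundary cells pass). Counts
are CPM-normalized (value = count / library × 10⁶); variable genes satisfy
CV = s/x̄ ≥ 1 (sample sd) and mean CPM > 1. Gene-centered PCA of
log2(CPM+1) yields loadings as Pearson correlations between each gene and
each component score; the 100 genes with the highest |loading| over the
first 3 components feed complete-linkage clustering under the distance
d = 1 − r (Pearson, over those genes).

**Dual differential expression** (`diffexp`). Per gene, two complementary
tests between groups: a Wilcoxon rank-sum test on log2(CPM+1) among
detecting cells (*level*) and a Fisher exact test on the 2×2
detected/not-detected × group table (*frequency*; χ² optional). The
p-values combine by Fisher's method — X = −2(ln p_level + ln p_freq) is
χ²₄, with upper tail e^(−X/2)(1 + X/2) — then Benjamini–Hochberg across
genes. Significance: q < 0.05 for ≤ 100 cells per comparison, q < 0.005
above.

**Permutation GSEA** (`gsea`). Genes ranked by log2((x̄_A + c)/(x̄_B + c))
of group-mean CPM (pseudo-mean c = 1); the weighted Kolmogorov–Smirnov
running sum gives ES ∈ [−1, 1]; 1,000 random same-size gene sets from the
ranked universe give a signed-null NES = ES / mean|ES_null, same sign| and
an add-one permutation p (never 0).

**Single-cell qPCR** (`qpcr`). ΔCt = Ct_Kit − Ct_assay per cell (larger =
more expressed); Kit-negative cells are excluded. Detection frequencies
compare by χ², levels among positive cells by two-tailed t-test, and
panel co-expression breadth (detected panel genes per cell) by a
two-sample KS test.

**Clonal transplantation analytics** (`clonal`). Clones with ≥ 0.1%
contribution to some lineage at some time point are classified by the
threefold rule at weeks 10 and 16 (P = platelet, M = myeloid,
L = max(B, T)): Pl if P ≥ 3M and P ≥ 3L; else Pl/My if min(P, M) ≥ 3L;
else Ly if L ≥ 3M and L ≥ 3P; else Ba — the label must hold at both
weeks. Platelet-restricted clones show platelet output with no other
lineage above 0.01%. Subtype frequencies compare by Fisher's exact test,
reconstitution levels by Mann–Whitney, and repopulation frequency comes
from the single-hit Poisson limiting-dilution estimator
f = −ln((n − k)/n) / dose.

## Worked example

```bash
python examples/clonal_bias.py
```

```
clones: 200 simulated, 180 pass the 0.1% filter
subtype counts: {'Pl': 72, 'Pl/My': 53, 'Ba': 37, 'Ly': 18}
classification accuracy vs planted archetypes: 99.4%
platelet-restricted clones (no detectable My/B/T output): 0

repopulation frequency, young: 16.0% per cell
repopulation frequency, old:   30.1% per cell
With platelet output included in the readout, aged HSCs repopulate
at least as frequently as young ones (30% vs 16%).
```

The simulated mixture plants 40/30/20/10% Pl / Pl-My / Ba / Ly clones with
log-normal output noise; the threefold classifier recovers the planted
labels almost perfectly, and the limiting-dilution estimates reproduce the
young/old repopulation frequencies from the published recipient counts
(11/20 and 21/27 positive at 5 cells per recipient). The other example
scripts (`transcriptome_clustering.py`, `differential_expression.py`,
`gsea_enrichment.py`, `qpcr_delta_ct.py`) walk the remaining modalities
the same way.

A thin CLI wraps the same functions (`hscbias simulate|qc|cluster|diffexp|
gsea|qpcr|clonal|run`); `hscbias run --seed 7 --out-dir out/` executes the
whole transcriptome pipeline on synthetic or user data and is byte-for-byte
reproducible per seed.

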