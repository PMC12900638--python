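# Methods

`episcope` re-implements, as a reusable and fully tested pipeline, a
procedure for separating **exposure-associated** from **genotype-associated**
differential DNA methylation in single-cell immune methylomes, and for
linking genotype-associated methylation to disease GWAS signals and gene
expression.  Because the kind of data this procedure targets is
access-controlled, every stage is exercised against a synthetic-data
generator with planted ground truth; the generator is first-class, tested
code, not a fixture.

## The hypomethylation score

Single-cell bisulfite data are sparse: each cell covers only a few percent
of the genome, with a handful of reads per 5-kb bin.  Rather than a raw
methylation fraction, each (cell, bin) entry is scored by the binomial upper
tail

```
hyposcore(m, c, p) = P(X > m),  X ~ Binomial(c, p),
```

where `m` and `c` are the bin's methylated and total read counts and `p` is
the cell's *expected* methylation probability.  A score near 1 means the bin
has far fewer methylated reads than the cell's genome-wide methylation
predicts — evidence of focal hypomethylation.  The matrix is binarized at
hyposcore ≥ 0.95 (inclusive) for clustering.

Two numerical points:

* `p` is computed as Σmᵢ / Σcᵢ over the cell's retained bins.  (A published
  formulation prints `p = Σ mᵢcᵢ`, which is dimensionally not a
  probability; the ratio matches the stated meaning, "the expected
  probability of methylation for this cell".)
* The binomial tail is evaluated through the regularised incomplete beta
  function (scipy's survival function), which is computed in log space and
  stays accurate for large `c`; tests verify equivalence with a term-by-term
  summation oracle to 1e-12 for `c ≤ 50` and the exact complement identity
  `hyposcore + BinomialCDF = 1`.

Cell QC uses three strict thresholds (mapping rate > 50%, ≥ 500,001 final mC
reads, global mCG > 0.5).  Sex and mitochondrial chromosomes are excluded;
bins overlapping the artifact blacklist by ≥ 1 bp are removed
(bedtools-intersect any-overlap semantics).  Bins covered by fewer than 5
cells are dropped, then bins whose nonzero-cell count has |z| > 2 across
bins; a zero-variance z is defined as 0 (nothing removed) to avoid a
division by zero.  "Covered" means cov > 0 in the bin.

## Clustering and annotation

PCA (top 32 PCs by default) on the binarized matrix, a kNN graph, and Leiden
community detection with a fixed seed.  Resolution is a knob (default 1.0);
the end-to-end run uses 0.25 because its simulated world plants major cell
types, not fine subtypes.  An externally corrected PC matrix (e.g. from a
batch-integration tool) can be passed in to bypass the internal PCA.  Within
the B and NK lineages, the cluster with higher mean global mCG is labelled
naive and the lower memory (B) or active (NK); ties break deterministically
on cluster id.  Cluster-composition bias is tested per (cluster, group) with
two-sided Fisher's exact tests (BH-corrected) and with an uncorrected
Pearson chi-square on the full contingency table.  DMGs between two clusters
use a two-sided Student's t on per-cell gene-body mCG with BH FDR, reported
at FDR < 0.01 and |ΔmCG| > 0.05; a covariate mode replaces the t-test with
OLS on the cluster indicator plus age, sex and ancestry (categoricals
dummy-encoded).  The t-test is a deliberate simplification of the cited
package's internal statistic, which is unpublished; the thresholds are the
documented ones.

## The eDMR cascade

The primary caller is a simplified site-level re-implementation behind a
pluggable interface (any BED-like candidate table can be injected).  Per
CpG, the statistic is the root-mean-square deviation of group methylation
fractions from the pooled fraction; its null is built by permuting the
sample→group assignment.  Null statistics are **pooled across sites and
permutations**: with a few hundred permutations a per-site p-value cannot
fall below ~1/200, which would make BH at thousands of sites impossible.
Significant sites within 250 bp (configurable) merge into regions; singleton
CpGs are allowed, matching the observation that most exposure DMRs are
single CpG sites.

Region levels are Σmc/Σcov per sample inside [start, end); zero coverage is
a missing value, never zero, and missing levels are excluded pairwise from
tests, never imputed.  The filters:

* **internal control** (longitudinal designs): retain iff the minimum
  two-sided Student's t p-value over all group pairs is < 0.05;
* **external control**: with exactly three control cohorts, retain iff the
  exposure group differs from each control (p < 0.05) *and* no two control
  cohorts differ (p > 0.05).  All six tests are recorded.  The second clause
  is the batch guard: a shift confined to one control cohort fails the
  control-consistency tests no matter how strongly the exposure differs.
* **label-shuffle validation**: the cascade is re-run under permuted group
  labels (sizes preserved, permuting within the exposure experiment) and
  the observed retained count is compared with the shuffled distribution.
  The summary statistic — observed count versus the shuffled 95th
  percentile — is our operationalisation; the source procedure states only
  that real calls should be "substantially more significant".
* **covariate filter**: regions whose levels associate with age, sex or
  ancestry (OLS coefficient p < 0.05, configurable) are excluded; an
  ancestry mode residualizes levels on age and sex and reports
  ancestry-associated regions (BH < 0.05).

Effect sizes are Cohen's d with Bessel-corrected pooled SD, reported for all
three group pairs; zero pooled SD gives a missing value, never ±inf.
Equal-variance Student's t is the default everywhere (Welch via flag).

A consequence worth knowing when reading sensitivity numbers: the
control-consistency rule rejects a *true* region whenever any
control–control pair is spuriously significant, so sensitivity saturates
near 0.95 (correlated tests), not 1.0.

## Genotypes and meQTL mapping

SNPs with MAF < 0.05 (strict) or any blacklist overlap are removed; MAF is
min(f, 1−f) over non-missing dosages.  LD pruning follows plink's
`--indep-pairwise 200 50 0.1` semantics (long-range-LD regions excluded
first; within each 200-SNP window the later-indexed SNP of any pair with
r² > 0.1 is dropped; slide by 50).  Genotype PCA centers and unit-scales
dosages (zero-variance SNPs dropped, missing mean-imputed) and fixes score
signs by making each component's largest-magnitude loading positive.

meQTL mapping is OLS of region level on dosage plus covariates (age, sex,
five genotype PCs, exposure indicators).  The scan residualizes phenotype
and dosage on the covariates once (Frisch–Waugh) — numerically identical to
the full design including the residual degrees of freedom — and computes
beta, SE and a two-sided t p-value per pair.  Cis means |SNP − region
midpoint| ≤ 1 Mb (midpoint anchoring; start/end available); trans is the
exact complement (different chromosome or beyond the window), and BH FDR is
applied within each scan separately, significant at FDR < 0.01 per run (the
per-cell-type convention).  Missing dosages are mean-imputed for regression
only.  The per-region permutation pass permutes the residualized phenotype
K times (default 1,000, ≥ 100 enforced), takes min nominal p as the
statistic, and reports p = (1 + #{perm ≤ obs})/(K + 1) ∈ [1/(K+1), 1] — the
multiplicity-correct empirical p for the region's best SNP.

## Colocalization and SMR

Per SNP and trait, the Wakefield log approximate Bayes factor is
`0.5·[log(1−r) + r·z²]` with `r = W/(W+V)`, prior SD 0.2 for quantitative
and 0.15 for case-control traits (the cited method's defaults).  When only
p/MAF/n are available, |z| is recovered from the two-sided p and V is
approximated by 1/(2·n·maf·(1−maf)); this path is valid for colocalization
(sign-free) but not for the SMR effect ratio.  Hypothesis evidence is
accumulated by log-sum-exp over single-causal configurations with priors
p1 = p2 = 1e−4, p12 = 1e−5; H3 (two distinct causal variants) uses the
pair-sum identity Σᵢ≠ⱼ = Σ₁·Σ₂ − Σ₁₂ in log space, verified against a
brute-force double loop to 1e−8.  Posteriors always sum to 1; PP4 > 0.50 is
the significance call.

SMR sets region methylation as exposure and gene expression as outcome.
The instrument is the top meQTL SNP below 5e−8 (the cited tool's default;
configurable); `T_SMR = z_x²z_y²/(z_x²+z_y²)` is chi-square(1) under the
null, and `b_SMR = β_eQTL/β_meQTL` is the Wald ratio.  Significance is
Bonferroni at 0.05/n over tested pairs, with pairs inside the HLA region
(chr6:28,477,797–33,448,354) flagged and excluded from the family.  The
HEIDI heterogeneity test is deliberately not implemented: with exposure and
outcome statistics drawn from different populations it is uninformative.
SNP-set overlap between meQTL and GWAS hits uses an uncorrected chi-square
over the per-region tested-SNP universe (our documented choice of universe),
BH across pairs.

## Enrichment and modality concordance

Region-set enrichment in annotation tracks is a two-sided Fisher's exact
test on any-overlap membership, BH across feature sets.  The background is
the candidate-region set entering the cascade (not the whole genome); a
genome-shuffle background can be supplied instead.  Methylation–accessibility
concordance is the Pearson (or Spearman) correlation between per-bin
hyposcore pseudobulk and Tn5 insertion counts, per cell type and pooled,
with bins missing in either modality dropped pairwise; the hypo-eDMR/gained-
peak overlap is the fraction of hypo-eDMRs with any-overlap against the
externally produced peak BED.

## The synthetic world

The default design mirrors a longitudinal exposure study: one exposure
cohort and three external control cohorts (two pre-exposure baselines plus
commercial healthy donors), ten donors each; three immune cell types with
global mCG baselines 0.85/0.78/0.70 and cell-type-specific hypomethylation
at 30% of regions; a 5-Mb two-chromosome toy genome tiled into 5-kb regions
with 3 CpG sites each.

* **Counts.**  Per site, coverage is zero-inflated negative binomial (mean
  20, dispersion 2, detection probability 0.3 — chosen so a cell observes
  roughly a third of sites, emulating the sparsity of single-cell bisulfite
  data; no per-site depth distribution is published, only qualitative
  genome-coverage figures).  Methylated counts are Binomial(cov, π) with π
  the cell-type baseline plus region, exposure, genotype and covariate
  shifts, clipped to [0, 1] with a logged warning.
* **Exposure effects.**  Planted deltas of ±0.3 (68% hypomethylated,
  matching the reported hypo/hyper ratio of ~0.68).
* **Genotypes.**  Hardy–Weinberg dosages at MAF ~ U(0.05, 0.5); optional
  two-subpopulation allele-frequency divergence and copied-with-noise LD
  blocks exist purely to exercise PCA and pruning.
* **Summary statistics.**  Single-causal-variant model: marginal z-scores
  have mean r(j, causal)·z_causal and noise ~ N(0, R) drawn via Cholesky —
  the correlated-noise form is essential; independent noise would let a
  neighbour outrank the causal SNP in one trait only and spuriously favour
  two-distinct-causal configurations.  R is exponential-decay by SNP index
  for standalone loci and the empirical dosage correlation for loci tied to
  the simulated genotypes.
* **Region-level world.**  The cascade is additionally exercised on a
  direct region-level simulator (levels = baseline + effects + N(0, 0.05))
  with 2,000 regions, 200 planted eDMRs of delta 0.2 and 10 samples per
  cohort, plus optional control-cohort batch shifts and age slopes.

What a green test does *not* establish: the generator draws independent
sites (no within-region correlation beyond the shared π), has no bisulfite
conversion error, no read-level structure, no imputation uncertainty and no
realistic LD beyond block copies/decay — so the tests validate the
statistical machinery, not robustness to those artifacts.

## Determinism and degenerate inputs

Every stochastic step derives its generator from the user seed via
`SeedSequence` with crc32-hashed string keys, so results are independent of
`PYTHONHASHSEED` and reproducible across processes.  Degenerate cases are
defined, not crashed on: zero-coverage cells are excluded (p undefined),
zero-variance t-tests yield missing p (record dropped with reason),
single-SNP loci make H3 impossible (PP3 = 0), zero pooled SD gives missing
d, empty SNP intersections/margins are skipped and logged.

## Known limitations

* The primary DMR caller is a deliberate simplification of the cited
  external tool (site-level RMS + permutation rather than its HMM-style
  machinery); the pluggable interface accepts externally produced DMRs.
* The permutation pass implements direct permutations only; the
  beta-approximation accelerator of the cited QTL tool is not implemented.
* Per-sample aggregation is used for external-control t-tests when donors
  contribute multiple samples; per-donor aggregation is a caller decision
  (aggregate before calling).
* The chi-square overlap test inherits the asymptotic approximation; at
  small counts it deviates from the permutation null (tests document this).
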