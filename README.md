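# episcope

Separating **exposure-associated** from **genotype-associated** differential
DNA methylation in single-cell immune methylomes.

The epigenome of immune cells carries marks from both nature (genetic
variation acting through methylation quantitative trait loci, meQTLs) and
nurture (pathogen and chemical exposures).  `episcope` implements, as a
reusable library plus CLI, the computational machinery needed to tell the
two apart in single-nucleus bisulfite data:

* **Hyposcore matrices** — per cell and 5-kb bin, the binomial upper-tail
  probability `P(X > m | c, p)` of seeing more methylated reads than
  observed given the cell's expected methylation probability
  `p = Σm/Σc`; binarized at ≥ 0.95.  Cell QC, blacklist/sex-chromosome
  exclusion and bin filtering included.
* **Clustering & annotation** — PCA + Leiden on the binarized matrix;
  naive/memory (B) and naive/active (NK) splits by global mCG; cluster
  composition statistics (Fisher exact, chi-square) and differentially
  methylated genes (t-test or covariate-adjusted OLS, FDR < 0.01,
  |ΔmCG| > 0.05).
* **The eDMR cascade** — a site-level permutation DMR caller (pluggable),
  per-sample region levels, the minimum-pairwise-p internal-control filter,
  the external-control consistency rule (exposure differs from all three
  control cohorts, no two control cohorts differ), label-shuffle
  validation, Cohen's d effect sizes and age/sex/ancestry covariate
  filtering.
* **Genotypes & meQTLs** — MAF/blacklist SNP filtering, plink-style LD
  pruning (200/50/0.1), genotype PCA, and cis (±1 Mb) / trans OLS scans
  with covariate adjustment, BH FDR < 0.01 and a permutation-based
  empirical p per region.
* **GWAS integration** — Wakefield approximate-Bayes-factor colocalization
  (PP0–PP4, significant at PP4 > 0.50) and summary-based Mendelian
  randomization of methylation on expression
  (`T_SMR = z_x²z_y²/(z_x²+z_y²)`, Bonferroni 0.05/n, HLA region excluded).
* **Enrichment & concordance** — Fisher enrichment of region sets in
  annotation BEDs over a candidate background; hyposcore–Tn5-insertion
  correlation per cell type; hypo-eDMR × gained-ATAC-peak overlap.

Real data of this kind are access-controlled, so the package ships a
first-class synthetic-data generator (`episcope.simulate`) that emits
ALLC-style per-cell counts, genotypes, covariates and GWAS/eQTL summary
statistics with planted, machine-readable ground truth — every stage is
testable end to end without any download.

## Worked example

Recover planted exposure DMRs through the external-control cascade, then
colocalize a shared-causal locus:

```python
from episcope import simulate, dmr, coloc

# 2,000 regions, 200 planted eDMRs (delta 0.2, level sd 0.05),
# one exposure cohort + three control cohorts, 10 samples each
levels, samples, truth = simulate.simulate_region_levels(
    n_regions=2000, n_true=200, delta=0.2, level_sd=0.05, seed=20)
groups = samples.set_index("sample")["cohort"].to_dict()
res = dmr.filter_external_control(
    levels, groups, "exposure", ("hiv_pre", "flu_pre", "commercial"))
called = res["retained"]
tp = (called & truth["is_edmr"].to_numpy()).sum()
print(f"retained {called.sum()} of 2000 regions; "
      f"{tp}/200 planted eDMRs recovered, "
      f"{called.sum() - tp} false positives")

g1, g2 = simulate.simulate_locus_stats(n_snps=50, shared=True, seed=0)
cc = coloc.coloc_abf(g1, g2)
print(f"shared-causal locus: PP4 = {cc.pp4:.3f}, PP3 = {cc.pp3:.3f}")
```

prints

```
retained 191 of 2000 regions; 181/200 planted eDMRs recovered, 10 false positives
shared-causal locus: PP4 = 1.000, PP3 = 0.000
```

Sensitivity is 181/200 = 0.905 with an observed false-discovery proportion
of 10/191 ≈ 0.05.  Sensitivity saturates near 0.95 by construction: the
control-consistency rule drops a true region whenever any control–control
pair is spuriously significant.  The colocalization call (PP4 ≈ 1) reflects
a locus where both traits share one causal variant; a distinct-causal locus
(`shared=False`) flips the mass to PP3.

The same flow is available from the shell:

```bash
episcope simulate --out sim/ --seed 1
episcope matrix --allc-dir sim/allc --metadata sim/cell_metadata.tsv \
    --genome chr1:2500000,chr2:2500000 --out matrix/
episcope edmr --levels levels.tsv --groups groups.tsv --mode external \
    --exposure exposure --controls hiv_pre,flu_pre,commercial \
    --shuffle 200 --seed 1 --out edmr.tsv
episcope run --seed 1          # full chain on the default simulation
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on the default simulated
dataset — simulation, QC, matrix construction, clustering, the eDMR
cascade, cis meQTL mapping with permutation passes, colocalization, SMR and
enrichment — logging the stage summaries it computes along the way and
writing its JSON result to `--out`.

See `docs/methods.md` for the statistical model behind each stage, the
synthetic world's assumptions, and known limitations.
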