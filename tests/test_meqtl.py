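"""Genotype QC, LD pruning, genotype PCA and meQTL mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcope import meqtl, simulate
from episcope.meqtl import GenotypeMatrix


def _gt(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_snps = dosage.shape
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(n_snps)],
            "chrom": chrom if chrom is not None else ["chr1"] * n_snps,
            "pos": pos if pos is not None else (np.arange(n_snps) + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n_samples)], snps=snps, dosage=dosage)


class TestFilterSnps:
    def test_maf_from_dosages(self):
        gt = _gt(np.array([[0, 0, 2], [0, 0, 2], [1, 0, 2], [1, 0, 1], [2, 0, 2]]))
        assert gt.maf[0] == pytest.approx(0.4)  # f = 0.4 -> kept
        out = meqtl.filter_snps(gt)
        # rs1 monomorphic (MAF 0) removed; rs2 f = 0.9 folds to MAF 0.1, kept
        assert list(out.snps["snp"]) == ["rs0", "rs2"]

    def test_maf_folding(self):
        # f and 1-f give the same MAF (allele-flip invariance)
        g1 = _gt(np.array([[0], [0], [1], [1], [2]], dtype=float))
        g2 = _gt(2.0 - np.array([[0], [0], [1], [1], [2]], dtype=float))
        assert g1.maf[0] == pytest.approx(g2.maf[0])

    def test_boundary_inclusive(self):
        # MAF exactly 0.05 is kept ("below 0.05" excluded)
        dos = np.zeros((20, 1))
        dos[0, 0] = 2
        gt = _gt(dos)
        assert gt.maf[0] == pytest.approx(0.05)
        assert len(meqtl.filter_snps(gt).snps) == 1

    def test_blacklist_removes_regardless_of_maf(self):
        gt = _gt(np.array([[0], [1], [1], [2]], dtype=float))
        blk = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150]})
        assert len(meqtl.filter_snps(gt, blacklist=blk).snps) == 0

    def test_all_missing_removed(self):
        gt = _gt(np.full((5, 1), np.nan))
        assert len(meqtl.filter_snps(gt).snps) == 0


class TestLdPrune:
    def test_duplicated_snp_one_survivor(self, rng):
        col = rng.binomial(2, 0.4, size=200).astype(float)
        other = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
        gt = _gt(np.column_stack([col, col, other]))
        surv = meqtl.ld_prune(gt)
        assert ("rs0" in surv) != ("rs1" in surv)  # exactly one of the pair
        assert "rs0" in surv  # the later-indexed copy is dropped

    def test_independent_snps_mostly_survive(self, rng):
        X = rng.binomial(2, 0.3, size=(500, 300)).astype(float)
        gt = _gt(X)
        surv = meqtl.ld_prune(gt)
        assert len(surv) / 300 > 0.95

    def test_no_surviving_pair_above_threshold(self):
        cfg = simulate.SimConfig(
            cohort_design={"exposure": 150, "hiv_pre": 150},
            n_snps=300,
            ld_block_size=5,
            seed=3,
        )
        gt = simulate.simulate_genotypes(cfg)
        surv = meqtl.ld_prune(gt, window=200, step=50, r2_threshold=0.1)
        pruned = gt.subset_snps(gt.snps["snp"].isin(surv).to_numpy())
        order = np.lexsort((pruned.snps["pos"], pruned.snps["chrom"]))
        for chrom in pruned.snps["chrom"].unique():
            idx = order[pruned.snps["chrom"].to_numpy()[order] == chrom]
            X = pruned.dosage[:, idx]
            for start in range(0, len(idx), 50):
                sub = X[:, start : start + 200]
                if sub.shape[1] < 2:
                    continue
                r2 = np.corrcoef(sub, rowvar=False) ** 2
                np.fill_diagonal(r2, 0.0)
                assert np.nanmax(r2) <= 0.1 + 1e-9

    def test_long_ld_excluded_first(self, rng):
        X = rng.binomial(2, 0.4, size=(100, 4)).astype(float)
        gt = _gt(X)
        long_ld = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [250]})
        surv = meqtl.ld_prune(gt, long_ld=long_ld)
        assert set(surv) <= {"rs2", "rs3"}

    def test_window_smaller_than_step_rejected(self, rng):
        gt = _gt(rng.binomial(2, 0.4, size=(50, 5)).astype(float))
        with pytest.raises(ValueError):
            meqtl.ld_prune(gt, window=10, step=20)


class TestGenotypePca:
    def test_scores_orthogonal(self, rng):
        gt = _gt(rng.binomial(2, 0.3, size=(80, 60)).astype(float))
        pcs = meqtl.genotype_pca(gt, n_pcs=4)
        r = np.corrcoef(pcs["PC1"], pcs["PC2"])[0, 1]
        assert abs(r) < 1e-10

    def test_separates_subpopulations(self):
        cfg = simulate.SimConfig(
            cohort_design={"exposure": 60, "hiv_pre": 60},
            n_snps=400,
            n_subpops=2,
            subpop_divergence=0.3,
            frac_divergent_snps=0.5,
            seed=6,
        )
        gt = simulate.simulate_genotypes(cfg)
        surv = meqtl.ld_prune(gt)
        pruned = gt.subset_snps(gt.snps["snp"].isin(surv).to_numpy())
        pcs = meqtl.genotype_pca(pruned, n_pcs=2)
        pops = np.arange(len(gt.samples)) % 2
        g0, g1 = pcs["PC1"][pops == 0], pcs["PC1"][pops == 1]
        within_sd = np.sqrt((g0.var() + g1.var()) / 2)
        assert abs(g0.mean() - g1.mean()) > 3 * within_sd

    def test_duplicating_samples_preserves_directions(self, rng):
        X = rng.binomial(2, 0.3, size=(60, 40)).astype(float)
        pcs1 = meqtl.genotype_pca(_gt(X), n_pcs=2)
        gt2 = GenotypeMatrix(
            samples=[f"s{i}" for i in range(120)],
            snps=_gt(X).snps,
            dosage=np.vstack([X, X]),
        )
        pcs2 = meqtl.genotype_pca(gt2, n_pcs=2)
        # same direction up to scale: correlation of PC1 scores ~ +-1
        r = np.corrcoef(pcs1["PC1"], pcs2["PC1"][:60])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_npcs_truncated_to_rank(self, rng):
        gt = _gt(rng.binomial(2, 0.4, size=(5, 3)).astype(float))
        pcs = meqtl.genotype_pca(gt, n_pcs=10)
        assert pcs.shape[1] <= 3


def _meqtl_world(n=100, beta=0.1, noise=0.02, maf=0.3, n_regions=1, seed=0, n_snps=1):
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
    gt = _gt(dosage)
    levels = pd.DataFrame(
        {
            gt.samples[i]: 0.5 + beta * dosage[i, 0] + rng.normal(0, noise)
            for i in range(n)
        },
        index=["region_00000"],
    )
    regions = pd.DataFrame(
        {"region_id": ["region_00000"], "chrom": ["chr1"], "start": [0], "end": [200]}
    )
    return regions, levels, gt


class TestCisScan:
    def test_beta_matches_statsmodels_oracle(self, rng):
        n = 60
        dosage = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        gt = _gt(dosage)
        age = rng.uniform(20, 60, n)
        sex = rng.choice(["F", "M"], n)
        y = 0.4 + 0.08 * dosage[:, 0] + 0.002 * age + rng.normal(0, 0.05, n)
        levels = pd.DataFrame([y], index=["r0"], columns=gt.samples)
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"], "start": [0], "end": [400]})
        covs = pd.DataFrame({"age": age, "sex": sex}, index=gt.samples)
        out = meqtl.map_cis_meqtl(regions, levels, gt, covs)

        import statsmodels.api as sm

        sexm = (sex == "M").astype(float)
        for j in range(3):
            X = sm.add_constant(np.column_stack([dosage[:, j], age, sexm]))
            fit = sm.OLS(y, X).fit()
            row = out[out["snp_id"] == f"rs{j}"].iloc[0]
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert row["se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert row["p_nominal"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_planted_effect_recovered(self):
        regions, levels, gt = _meqtl_world(seed=1)
        out = meqtl.map_cis_meqtl(regions, levels, gt)
        assert out["beta"].iloc[0] == pytest.approx(0.1, abs=0.02)
        assert out["significant"].iloc[0]

    def test_permuted_genotype_null_uniform(self, rng):
        pvals = []
        for rep in range(400):
            regions, levels, gt = _meqtl_world(n=50, beta=0.0, seed=rep)
            out = meqtl.map_cis_meqtl(regions, levels, gt)
            pvals.append(out["p_nominal"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_confounded_association_removed_by_covariate(self, rng):
        n = 100
        pc1 = rng.normal(size=n)
        dosage = np.clip(np.round(1 + 0.8 * pc1 + rng.normal(0, 0.3, n)), 0, 2)
        gt = _gt(dosage[:, None])
        y = 0.5 + 0.05 * pc1 + rng.normal(0, 0.01, n)
        levels = pd.DataFrame([y], index=["r0"], columns=gt.samples)
        regions = pd.DataFrame({"region_id": ["r0"], "chrom": ["chr1"], "start": [0], "end": [200]})
        naive = meqtl.map_cis_meqtl(regions, levels, gt)
        covs = pd.DataFrame({"PC1": pc1}, index=gt.samples)
        adjusted = meqtl.map_cis_meqtl(regions, levels, gt, covs)
        assert naive["p_nominal"].iloc[0] < 1e-6
        assert adjusted["p_nominal"].iloc[0] > 0.01

    def test_missing_levels_handled_pairwise(self, rng):
        regions, levels, gt = _meqtl_world(n=40, seed=2)
        levels.iloc[0, :5] = np.nan
        out = meqtl.map_cis_meqtl(regions, levels, gt)
        assert np.isfinite(out["beta"].iloc[0])
        assert out["beta"].iloc[0] == pytest.approx(0.1, abs=0.03)


class TestTransScan:
    def test_partition_exhaustive_and_disjoint(self, rng):
        dosage = rng.binomial(2, 0.3, size=(40, 6)).astype(float)
        gt = _gt(dosage, chrom=["chr1"] * 3 + ["chr2"] * 3, pos=[100, 500_000, 2_000_000] * 2)
        levels = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(2, 40)),
            index=["a", "b"],
            columns=gt.samples,
        )
        regions = pd.DataFrame(
            {
                "region_id": ["a", "b"],
                "chrom": ["chr1", "chr2"],
                "start": [0, 0],
                "end": [5000, 5000],
            }
        )
        cis = meqtl.map_cis_meqtl(regions, levels, gt)
        trans = meqtl.map_trans_meqtl(regions, levels, gt)
        cis_pairs = set(zip(cis["snp_id"], cis["region_id"]))
        trans_pairs = set(zip(trans["snp_id"], trans["region_id"]))
        assert cis_pairs.isdisjoint(trans_pairs)
        assert len(cis_pairs) + len(trans_pairs) == 12
        assert (trans["distance"].abs() > 1_000_000).all() or trans["distance"].isna().any()

    def test_planted_trans_effect_detected(self, rng):
        n = 100
        dosage = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        gt = _gt(dosage, chrom=["chr1"] * 5, pos=[100, 200, 300, 400, 500])
        y = 0.5 + 0.15 * dosage[:, 2] + rng.normal(0, 0.05, n)
        levels = pd.DataFrame([y], index=["far"], columns=gt.samples)
        regions = pd.DataFrame(
            {"region_id": ["far"], "chrom": ["chr2"], "start": [0], "end": [5000]}
        )
        out = meqtl.map_trans_meqtl(regions, levels, gt)
        hit = out[out["snp_id"] == "rs2"].iloc[0]
        assert hit["fdr"] < 0.05
        assert np.isnan(hit["distance"])  # cross-chromosome


class TestPermutationPass:
    def test_bounds_and_determinism(self, rng):
        regions, levels, gt = _meqtl_world(n=60, beta=0.0, seed=3, n_snps=10)
        r1 = meqtl.permutation_pass(levels.iloc[0], gt, n_permutations=200, seed=5)
        r2 = meqtl.permutation_pass(levels.iloc[0], gt, n_permutations=200, seed=5)
        assert r1 == r2
        assert 1 / 201 <= r1["p_empirical"] <= 1.0

    def test_single_snp_consistent_with_nominal(self):
        regions, levels, gt = _meqtl_world(n=80, beta=0.03, noise=0.05, seed=4)
        res = meqtl.permutation_pass(levels.iloc[0], gt, n_permutations=2000, seed=0)
        p_nom = meqtl.map_cis_meqtl(regions, levels, gt)["p_nominal"].iloc[0]
        se = np.sqrt(p_nom * (1 - p_nom) / 2000)
        assert abs(res["p_empirical"] - p_nom) < max(4 * se, 0.02)

    def test_correlated_snps_multiplicity_corrected(self):
        # 30 copies of one SNP: min nominal p is inflated, empirical p is not
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.4, size=100).astype(float)
        dosage = np.column_stack([base + rng.normal(0, 0.01, 100) for _ in range(30)])
        gt = _gt(dosage)
        emp = []
        for rep in range(40):
            y = rng.uniform(0.4, 0.6, 100)
            lev = pd.Series(y, index=gt.samples)
            emp.append(meqtl.permutation_pass(lev, gt, n_permutations=100, seed=rep)["p_empirical"])
        assert stats.kstest(emp, "uniform").pvalue > 0.001

    def test_too_few_permutations_rejected(self):
        regions, levels, gt = _meqtl_world(seed=7)
        with pytest.raises(ValueError):
            meqtl.permutation_pass(levels.iloc[0], gt, n_permutations=50)
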