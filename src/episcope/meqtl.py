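"""Genotype QC, LD pruning, genotype PCA and cis/trans meQTL mapping.

The association model is ordinary least squares of a region's per-sample
methylation level on SNP dosage plus covariates (age, sex, genotype PCs,
exposure), testing the dosage coefficient.  Covariates enter the design
matrix directly; the scan residualizes both phenotype and dosage on the
covariates once (Frisch-Waugh), which is numerically identical to the full
regression including the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, logger, overlaps_any

CIS_WINDOW = 1_000_000
MEQTL_FDR = 0.01


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix ({0,1,2}; NaN = missing) with SNP metadata."""

    samples: list
    snps: pd.DataFrame  # snp, chrom, pos (1-based), ref, alt
    dosage: np.ndarray  # (n_samples, n_snps) float

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError("dosage shape must be (n_samples, n_snps)")

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP: min(f, 1-f), f = mean(dosage)/2
        over non-missing donors.  All-missing SNPs get NaN."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNPs
            f = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return replace(
            self, snps=self.snps.iloc[idx].reset_index(drop=True), dosage=self.dosage[:, idx]
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage.T, index=self.snps["snp"], columns=self.samples)


def filter_snps(
    genotypes: GenotypeMatrix,
    blacklist: pd.DataFrame | None = None,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= min_maf (below-threshold excluded) and no
    blacklist overlap; all-missing SNPs are dropped."""
    maf = genotypes.maf
    keep = np.isfinite(maf) & (maf >= min_maf)
    if blacklist is not None and len(blacklist):
        iv = pd.DataFrame(
            {
                "chrom": genotypes.snps["chrom"],
                "start": genotypes.snps["pos"] - 1,
                "end": genotypes.snps["pos"],
            }
        )
        keep &= ~overlaps_any(iv, blacklist)
    return genotypes.subset_snps(keep)


def _fill_mean(X: np.ndarray) -> np.ndarray:
    X = np.array(X, dtype=float)
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
    return X


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 200,
    step: int = 50,
    r2_threshold: float = 0.1,
    long_ld: pd.DataFrame | None = None,
) -> list[str]:
    """Greedy windowed LD pruning (plink --indep-pairwise semantics).

    Long-range-LD regions are excluded first.  Within each ``window``-SNP
    window (slid by ``step``), for any remaining pair with r^2 >
    ``r2_threshold`` the later-indexed SNP is dropped.  Returns surviving
    SNP ids in genomic order.
    """
    if window < step:
        raise ValueError("window must be >= step")
    snps = genotypes.snps
    keep0 = np.ones(len(snps), dtype=bool)
    if long_ld is not None and len(long_ld):
        iv = pd.DataFrame({"chrom": snps["chrom"], "start": snps["pos"] - 1, "end": snps["pos"]})
        keep0 &= ~overlaps_any(iv, long_ld)
    gt = genotypes.subset_snps(keep0)
    X = _fill_mean(gt.dosage)

    order = np.lexsort((gt.snps["pos"].to_numpy(), gt.snps["chrom"].to_numpy()))
    removed = np.zeros(len(gt.snps), dtype=bool)
    for chrom in gt.snps["chrom"].unique():
        cidx = order[gt.snps["chrom"].to_numpy()[order] == chrom]
        n = len(cidx)
        start = 0
        while start < n:
            widx = cidx[start : start + window]
            active = widx[~removed[widx]]
            if len(active) > 1:
                sub = X[:, active]
                sd = sub.std(axis=0)
                sub = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
                r2 = (sub.T @ sub / len(sub)) ** 2
                for a in range(len(active)):
                    if removed[active[a]]:
                        continue
                    hits = np.nonzero(r2[a, a + 1 :] > r2_threshold)[0]
                    for b in hits + a + 1:
                        removed[active[b]] = True
            if start + window >= n:
                break
            start += step
    surv = gt.snps["snp"].to_numpy()[~removed]
    return list(surv)


def genotype_pca(genotypes: GenotypeMatrix, n_pcs: int = 5) -> pd.DataFrame:
    """PCA of the (centered, unit-scaled) dosage matrix by SVD.

    Zero-variance SNPs are dropped; missing dosages mean-imputed.  Score
    signs are fixed by making the largest-magnitude loading of each
    component positive.  Returns a samples x PC1..PCn frame.
    """
    X = _fill_mean(genotypes.dosage)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    rank = min(X.shape)
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds rank %d; truncated", n_pcs, rank)
        n_pcs = rank
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    scores = (U * S) * flip
    return pd.DataFrame(
        scores[:, :n_pcs],
        index=pd.Index(genotypes.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )


def design_matrix(covariates: pd.DataFrame | None, samples) -> np.ndarray:
    """Intercept + covariates, categoricals dummy-encoded (first level
    dropped); constant columns dropped with a warning."""
    n = len(samples)
    if covariates is None:
        return np.ones((n, 1))
    cov = covariates.loc[samples]
    num = pd.get_dummies(cov, drop_first=True, dtype=float)
    X = [np.ones(n)]
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("constant covariate %s dropped", col)
            continue
        X.append(v)
    C = np.column_stack(X)
    # drop collinear columns via QR pivoting on the rank check
    q, r = np.linalg.qr(C)
    keep = np.abs(np.diag(r)) > 1e-10
    if not keep.all():
        logger.warning("collinear covariate columns dropped")
        C = C[:, keep]
    return C


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def _pair_stats(RX, RY, dof):
    """beta/se/p for simple regressions of every RY column on every RX column.

    RX: (n, n_x) residualized dosages; RY: (n, n_y) residualized levels.
    Returns (beta, se, p) arrays of shape (n_x, n_y)."""
    rxx = np.einsum("ij,ij->j", RX, RX)
    ryy = np.einsum("ij,ij->j", RY, RY)
    cross = RX.T @ RY
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / rxx[:, None]
        rss = ryy[None, :] - beta * cross
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / rxx[:, None])
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, p


def _aligned(regions, levels, genotypes, covariates):
    samples = [s for s in levels.columns if s in set(genotypes.samples)]
    if covariates is not None:
        samples = [s for s in samples if s in covariates.index]
    if len(samples) < 3:
        raise ValueError("fewer than 3 samples shared across levels/genotypes/covariates")
    gpos = {s: i for i, s in enumerate(genotypes.samples)}
    X = _fill_mean(genotypes.dosage[[gpos[s] for s in samples], :])
    Y = levels[samples].to_numpy(dtype=float).T  # (n_samples, n_regions)
    C = design_matrix(covariates, samples)
    return samples, X, Y, C


def _distance_table(regions: pd.DataFrame, snps: pd.DataFrame):
    """Signed bp distance SNP -> region midpoint; +inf across chromosomes."""
    mid = ((regions["start"] + regions["end"]) // 2).to_numpy()
    same = snps["chrom"].to_numpy()[:, None] == regions["chrom"].to_numpy()[None, :]
    dist = snps["pos"].to_numpy()[:, None] - mid[None, :]
    return np.where(same, dist, np.inf)


def _scan(regions, levels, genotypes, covariates, pair_mask, mode):
    samples, X, Y, C = _aligned(regions, levels, genotypes, covariates)
    n, k = C.shape
    dof = n - k - 1
    if dof < 1:
        raise ValueError("not enough samples for the covariate design")
    nan_regions = np.isnan(Y).any(axis=0)
    RX = _residualize(X, C)
    RY = _residualize(np.where(np.isnan(Y), 0.0, Y), C)
    beta, se, p = _pair_stats(RX, RY, dof)

    dist = _distance_table(regions, genotypes.snps)
    si, ri = np.nonzero(pair_mask)
    rows = pd.DataFrame(
        {
            "snp_id": genotypes.snps["snp"].to_numpy()[si],
            "region_id": regions["region_id"].to_numpy()[ri],
            "distance": [d if np.isfinite(d) else np.nan for d in dist[si, ri]],
            "beta": beta[si, ri],
            "se": se[si, ri],
            "p_nominal": p[si, ri],
            "mode": mode,
        }
    )

    # regions with missing levels: redo their pairs sample-masked
    if nan_regions.any():
        for r in np.nonzero(nan_regions)[0]:
            ok = ~np.isnan(Y[:, r])
            if ok.sum() < k + 2:
                rows.loc[rows["region_id"] == regions["region_id"].iloc[r], ["beta", "se", "p_nominal"]] = np.nan
                continue
            Cm = C[ok]
            dofm = ok.sum() - np.linalg.matrix_rank(Cm) - 1
            RXm = _residualize(X[ok], Cm)
            RYm = _residualize(Y[ok][:, [r]], Cm)
            bm, sm, pm = _pair_stats(RXm, RYm, max(dofm, 1))
            sel = rows.index[rows["region_id"] == regions["region_id"].iloc[r]]
            snp_rows = rows.loc[sel, "snp_id"].map(
                {s: i for i, s in enumerate(genotypes.snps["snp"])}
            ).to_numpy()
            rows.loc[sel, "beta"] = bm[snp_rows, 0]
            rows.loc[sel, "se"] = sm[snp_rows, 0]
            rows.loc[sel, "p_nominal"] = pm[snp_rows, 0]

    rows["fdr"] = bh_fdr(rows["p_nominal"])
    rows["significant"] = rows["fdr"] < MEQTL_FDR
    return rows


def map_cis_meqtl(
    regions: pd.DataFrame,
    levels: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Test every SNP-region pair within ``window`` bp of the region midpoint.

    ``regions`` needs region_id/chrom/start/end; ``levels`` is regions x
    samples.  Returns one row per pair with beta, se, nominal p, BH FDR
    across all cis pairs and a significance flag at FDR < 0.01.
    """
    regions = regions.reset_index(drop=True)
    dist = _distance_table(regions, genotypes.snps)
    mask = np.abs(dist) <= window
    return _scan(regions, levels, genotypes, covariates, mask, "cis")


def map_trans_meqtl(
    regions: pd.DataFrame,
    levels: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Complement of the cis scan: different chromosome or beyond the window.
    BH FDR is applied across trans pairs only."""
    regions = regions.reset_index(drop=True)
    dist = _distance_table(regions, genotypes.snps)
    mask = ~(np.abs(dist) <= window)
    return _scan(regions, levels, genotypes, covariates, mask, "trans")


def permutation_pass(
    region_levels: pd.Series,
    cis_genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical p-value for a region's best cis association.

    The observed statistic is the minimum nominal p over the region's cis
    SNPs; the null permutes the residualized phenotype ``K`` times and
    records each permutation's minimum p.  p_empirical = (1 + #{perm <=
    observed}) / (K + 1), bounded in [1/(K+1), 1].
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if len(cis_genotypes.snps) == 0:
        return {"p_empirical": np.nan, "min_p_nominal": np.nan, "best_snp": None}
    samples = [s for s in region_levels.index if s in set(cis_genotypes.samples)]
    gpos = {s: i for i, s in enumerate(cis_genotypes.samples)}
    X = _fill_mean(cis_genotypes.dosage[[gpos[s] for s in samples], :])
    y = region_levels[samples].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    X, y = X[ok], y[ok]
    C = design_matrix(covariates, list(np.asarray(samples)[ok]))
    n, k = C.shape
    dof = n - k - 1
    RX = _residualize(X, C)
    ry = _residualize(y[:, None], C)[:, 0]

    rng = np.random.default_rng(int(seed) % (2**31))
    perms = np.column_stack([ry] + [rng.permutation(ry) for _ in range(n_permutations)])
    # max |t| over SNPs <-> min p; compute t^2 for all (snp, perm)
    rxx = np.einsum("ij,ij->j", RX, RX)
    ryy = float(ry @ ry)
    cross = RX.T @ perms
    with np.errstate(divide="ignore", invalid="ignore"):
        b = cross / rxx[:, None]
        rss = np.maximum(ryy - b * cross, 0.0)
        t2 = np.where(rss > 0, b * cross * dof / rss, np.inf)
    best = t2.max(axis=0)
    obs, null = best[0], best[1:]
    p_emp = (1.0 + np.sum(null >= obs)) / (n_permutations + 1.0)
    best_snp = cis_genotypes.snps["snp"].iloc[int(t2[:, 0].argmax())]
    min_p = float(2 * stats.t.sf(np.sqrt(obs), dof)) if np.isfinite(obs) else 0.0
    return {"p_empirical": float(p_emp), "min_p_nominal": min_p, "best_snp": best_snp}
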