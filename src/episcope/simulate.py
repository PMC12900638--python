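"""Synthetic single-cell methylomes, genotypes and QTL summary statistics.

Everything downstream of raw data access is exercised against this module:
it emits per-cell binomial cytosine counts over genomic bins with planted
cell types, exposure effects, additive genotype effects and covariate
confounding; Hardy-Weinberg genotype dosages with optional population
structure and LD blocks; and GWAS/eQTL summary statistics under a
single-causal-variant model with LD decay.  Every generator is deterministic
given the config seed, and the planted truth is returned (and written)
alongside the data so tests never re-derive it.

The default study design mirrors a longitudinal exposure cohort with one
exposure group and three external control cohorts (two pre-exposure
baselines plus commercial healthy donors), ten donors each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import logger, spawn_rng
from .meqtl import GenotypeMatrix

DEFAULT_COHORTS = {"exposure": 10, "hiv_pre": 10, "flu_pre": 10, "commercial": 10}


@dataclass
class SimConfig:
    """Stated world for the simulators.

    Counts and effect sizes default to the design the downstream tests
    exercise: 3 immune cell types with distinct global mCG baselines, a 5-Mb
    two-chromosome toy genome tiled into 5-kb regions, binomial counts with
    negative-binomial per-site depth, and ten donors per cohort.
    """

    # cohort design: cohort name -> number of donors; one exposure cohort
    cohort_design: dict = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    exposure_cohort: str = "exposure"
    cells_per_donor_per_celltype: int = 8
    n_celltypes: int = 3
    # genome
    genome: tuple = (("chr1", 2_500_000), ("chr2", 2_500_000))
    bin_size: int = 5000
    sites_per_region: int = 3
    # planted exposure effects (methylation-fraction delta)
    n_edmr_true: int = 50
    edmr_effect: float = 0.3
    hypo_fraction: float = 0.68  # fraction of planted eDMRs hypomethylated in exposure
    # genotypes and planted genotype effects
    n_snps: int = 400
    maf_range: tuple = (0.05, 0.5)
    n_gdmr_true: int = 8
    gdmr_effect_per_allele: float = 0.12
    n_subpops: int = 1
    subpop_divergence: float = 0.0
    frac_divergent_snps: float = 0.5
    ld_block_size: int = 1
    # covariate model: methylation effects of age/sex/ancestry at planted regions
    covariate_model: dict = field(
        default_factory=lambda: {
            "age_effect": 0.0,
            "n_age_regions": 0,
            "sex_effect": 0.0,
            "n_sex_regions": 0,
            "ancestry_effect": 0.0,
            "n_ancestry_regions": 0,
        }
    )
    # cell-type structure
    celltype_baselines: tuple = (0.85, 0.78, 0.70)
    frac_celltype_regions: float = 0.3
    celltype_effect: float = 0.3
    # depth model: per-site negative-binomial coverage with zero inflation
    depth_model: dict = field(
        default_factory=lambda: {"mean": 20.0, "dispersion": 2.0, "detect_prob": 0.3}
    )
    qc_fail_fraction: float = 0.05
    # summary statistics
    snps_per_locus: int = 50
    ld_decay: float = 0.9
    causal_z: float = 10.0
    gwas_n: int = 50_000
    eqtl_n: int = 30_000
    seed: int = 0

    @property
    def regions(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.genome:
            starts = np.arange(0, int(length), self.bin_size)
            for s in starts:
                e = min(s + self.bin_size, int(length))
                rows.append((f"{chrom}:{s}-{e}", chrom, s, e))
        return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])

    @property
    def n_regions(self) -> int:
        return sum(-(-int(L) // self.bin_size) for _, L in self.genome)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.cohort_design.values()) < 1 or self.cells_per_donor_per_celltype < 1:
            raise ValueError("counts must be positive")
        if self.exposure_cohort not in self.cohort_design:
            raise ValueError("exposure cohort missing from cohort_design")
        if self.n_celltypes != len(self.celltype_baselines):
            raise ValueError("one baseline per cell type required")
        if not all(0 <= b <= 1 for b in self.celltype_baselines):
            raise ValueError("baselines must lie in [0, 1]")
        for b in self.celltype_baselines:
            if not 0 <= b - self.edmr_effect <= 1 and not 0 <= b + self.edmr_effect <= 1:
                logger.warning("edmr_effect pushes expected methylation outside [0, 1]; clipping")


@dataclass
class TruthTable:
    """Planted ground truth emitted next to every simulated dataset."""

    edmr: pd.DataFrame       # region_id, delta (exposure-vs-control), direction
    gdmr: pd.DataFrame       # region_id, causal_snp, effect_per_allele
    coloc: pd.DataFrame      # region_id, shared (bool), gwas_causal, meqtl_causal
    smr_pairs: pd.DataFrame  # region_id, gene_id, causal_snp, true_b

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.edmr.to_csv(d / "truth_edmr.tsv", sep="\t", index=False)
        self.gdmr.to_csv(d / "truth_gdmr.tsv", sep="\t", index=False)
        self.coloc.to_csv(d / "truth_coloc.tsv", sep="\t", index=False)
        self.smr_pairs.to_csv(d / "truth_smr.tsv", sep="\t", index=False)


def _donor_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cohort, n in config.cohort_design.items():
        for k in range(n):
            rows.append((f"{cohort}_d{k:02d}", cohort))
    donors = pd.DataFrame(rows, columns=["donor", "cohort"])
    donors["exposure_group"] = np.where(
        donors["cohort"] == config.exposure_cohort, "exposed", "control"
    )
    donors["age"] = rng.integers(20, 61, size=len(donors))
    donors["sex"] = rng.choice(["F", "M"], size=len(donors))
    if config.n_subpops > 1:
        pops = [f"POP{i}" for i in range(config.n_subpops)]
        donors["ancestry"] = [pops[i % config.n_subpops] for i in range(len(donors))]
    else:
        donors["ancestry"] = rng.choice(["AFR", "EUR"], size=len(donors))
    return donors


def simulate_genotypes(config: SimConfig, donors: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg dosages {0,1,2} per donor x SNP.

    Optional features: `n_subpops` > 1 with `subpop_divergence` splits allele
    frequencies between ancestry groups on a fraction of SNPs (for PCA
    tests); `ld_block_size` > 1 tiles SNPs into blocks copied from the block
    head with 2% flip noise (for pruning tests).
    """
    config.validate()
    rng = spawn_rng(config.seed, "genotypes")
    if donors is None:
        donors = _donor_table(config, spawn_rng(config.seed, "donors"))
    n_donors = len(donors)

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    chroms = np.array([c for c, _ in config.genome])
    lengths = np.array([L for _, L in config.genome])
    snp_chrom_idx = rng.integers(0, len(chroms), size=config.n_snps)
    pos = np.array([rng.integers(1, lengths[i] + 1) for i in snp_chrom_idx])
    order = np.lexsort((pos, snp_chrom_idx))
    snp_chrom_idx, pos = snp_chrom_idx[order], pos[order]
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i:05d}" for i in range(config.n_snps)],
            "chrom": chroms[snp_chrom_idx],
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )

    freq = np.tile(maf, (n_donors, 1))
    if config.n_subpops > 1 and config.subpop_divergence > 0:
        divergent = rng.random(config.n_snps) < config.frac_divergent_snps
        pops = donors["ancestry"].astype("category").cat.codes.to_numpy()
        shift = config.subpop_divergence / 2.0
        for p in np.unique(pops):
            sign = 1.0 if p % 2 == 0 else -1.0
            freq[np.ix_(pops == p, divergent)] = np.clip(
                maf[divergent] + sign * shift, 0.01, 0.99
            )
    dosage = rng.binomial(2, freq).astype(float)

    if config.ld_block_size > 1:
        for start in range(0, config.n_snps, config.ld_block_size):
            head = dosage[:, start]
            for j in range(start + 1, min(start + config.ld_block_size, config.n_snps)):
                flip = rng.random(n_donors) < 0.02
                dosage[:, j] = np.where(flip, rng.binomial(2, freq[:, j]), head)

    return GenotypeMatrix(samples=list(donors["donor"]), snps=snps, dosage=dosage)


def simulate_methylomes(
    config: SimConfig, genotypes: GenotypeMatrix | None = None
) -> tuple[pd.DataFrame, TruthTable, pd.DataFrame]:
    """Per-cell ALLC-style counts with planted structure.

    For each cell and CpG site, total count ``c`` is drawn from a
    zero-inflated negative-binomial depth model and the methylated count
    ``m ~ Binomial(c, pi)``, where ``pi`` is the cell-type baseline shifted
    by region effects, planted exposure deltas, additive genotype effects and
    covariate confounding, clipped to [0, 1] (clipping is logged).

    Returns (site counts long table, truth, cell metadata).
    """
    config.validate()
    rng = spawn_rng(config.seed, "methylomes")
    donors = _donor_table(config, spawn_rng(config.seed, "donors"))
    if genotypes is None:
        genotypes = simulate_genotypes(config, donors)
    regions = config.regions
    n_regions = len(regions)

    # --- choose planted regions (disjoint sets) ---
    perm = rng.permutation(n_regions)
    n_cov = config.covariate_model
    cursor = 0

    def take(n):
        nonlocal cursor
        sel = perm[cursor : cursor + n]
        cursor += n
        return sel

    edmr_idx = take(config.n_edmr_true)
    gdmr_idx = take(config.n_gdmr_true)
    age_idx = take(int(n_cov.get("n_age_regions", 0)))
    sex_idx = take(int(n_cov.get("n_sex_regions", 0)))
    anc_idx = take(int(n_cov.get("n_ancestry_regions", 0)))
    ct_idx = take(int(config.frac_celltype_regions * n_regions))

    # eDMR deltas: hypo (negative in exposure) for hypo_fraction of regions
    hypo = rng.random(len(edmr_idx)) < config.hypo_fraction
    edmr_delta = np.where(hypo, -config.edmr_effect, config.edmr_effect)
    truth_edmr = pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy()[edmr_idx],
            "delta": edmr_delta,
            "direction": np.where(hypo, "hypo", "hyper"),
        }
    )

    # gDMRs: causal SNP on the same chromosome, preferring |pos-mid| <= 1 Mb
    causal_snps, keep_gdmr = [], []
    for ridx in gdmr_idx:
        chrom = regions["chrom"].iloc[ridx]
        mid = (regions["start"].iloc[ridx] + regions["end"].iloc[ridx]) // 2
        cand = genotypes.snps.index[
            (genotypes.snps["chrom"] == chrom)
            & ((genotypes.snps["pos"] - mid).abs() <= 1_000_000)
        ]
        if len(cand) == 0:
            continue
        causal_snps.append(genotypes.snps.loc[rng.choice(cand), "snp"])
        keep_gdmr.append(ridx)
    gdmr_idx = np.array(keep_gdmr, dtype=int)
    truth_gdmr = pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy()[gdmr_idx],
            "causal_snp": causal_snps,
            "effect_per_allele": config.gdmr_effect_per_allele,
        }
    )

    # --- per-region and per-cell-type effects ---
    region_offset = rng.normal(0, 0.03, size=n_regions)
    ct_effect = np.zeros((config.n_celltypes, n_regions))
    if len(ct_idx):
        which_ct = rng.integers(0, config.n_celltypes, size=len(ct_idx))
        ct_effect[which_ct, ct_idx] = -config.celltype_effect

    # --- cells ---
    cells = []
    for drow in donors.itertuples(index=False):
        for ct in range(config.n_celltypes):
            for k in range(config.cells_per_donor_per_celltype):
                cells.append((f"{drow.donor}_ct{ct}_c{k:02d}", drow.donor, ct))
    cell_df = pd.DataFrame(cells, columns=["cell_id", "donor", "celltype_true"])
    cell_df = cell_df.merge(donors, on="donor")
    n_cells = len(cell_df)

    donor_pos = {d: i for i, d in enumerate(donors["donor"])}
    dosage_by_cell = genotypes.dosage[[donor_pos[d] for d in cell_df["donor"]], :]
    snp_pos = {s: j for j, s in enumerate(genotypes.snps["snp"])}

    # --- expected methylation pi per (cell, region) ---
    pi = np.empty((n_cells, n_regions))
    baselines = np.asarray(config.celltype_baselines)
    pi[:] = region_offset[None, :]
    pi += baselines[cell_df["celltype_true"].to_numpy()][:, None]
    pi += ct_effect[cell_df["celltype_true"].to_numpy(), :]
    pi += rng.normal(0, 0.02, size=n_cells)[:, None]  # per-cell global shift

    exposed = (cell_df["exposure_group"] == "exposed").to_numpy()
    pi[np.ix_(exposed, edmr_idx)] += edmr_delta[None, :]

    for ridx, snp in zip(gdmr_idx, causal_snps):
        pi[:, ridx] += config.gdmr_effect_per_allele * dosage_by_cell[:, snp_pos[snp]]

    age_c = (cell_df["age"].to_numpy() - cell_df["age"].mean()).astype(float)
    male = (cell_df["sex"] == "M").to_numpy().astype(float)
    anc = (cell_df["ancestry"] == cell_df["ancestry"].iloc[0]).to_numpy().astype(float)
    if len(age_idx):
        pi[:, age_idx] += n_cov["age_effect"] * age_c[:, None]
    if len(sex_idx):
        pi[:, sex_idx] += n_cov["sex_effect"] * male[:, None]
    if len(anc_idx):
        pi[:, anc_idx] += n_cov["ancestry_effect"] * anc[:, None]

    clipped = ((pi < 0) | (pi > 1)).mean()
    if clipped > 0:
        logger.warning("%.2f%% of expected methylation values clipped to [0, 1]", 100 * clipped)
    pi = np.clip(pi, 0.0, 1.0)

    # --- draw counts per site ---
    S = config.sites_per_region
    depth = config.depth_model
    mean, disp, detect = depth["mean"], depth["dispersion"], depth["detect_prob"]
    if mean <= 0 or disp <= 0 or not 0 < detect <= 1:
        raise ValueError("depth model requires positive mean/dispersion and detect_prob in (0, 1]")
    nb_p = disp / (disp + mean)

    pi_sites = np.repeat(pi, S, axis=1)  # (cells, regions * S)
    cov = rng.negative_binomial(disp, nb_p, size=pi_sites.shape)
    cov *= rng.random(pi_sites.shape) < detect
    mc = rng.binomial(cov, pi_sites)

    # site coordinates: evenly spaced inside each region (1-based)
    width = regions["end"].to_numpy() - regions["start"].to_numpy()
    offs = ((np.arange(S) + 0.5) / S)
    site_pos = (regions["start"].to_numpy()[:, None] + offs[None, :] * width[:, None]).astype(int) + 1
    site_chrom = np.repeat(regions["chrom"].to_numpy(), S)
    site_pos = site_pos.ravel()

    ci, sj = np.nonzero(cov)
    counts = pd.DataFrame(
        {
            "cell_id": cell_df["cell_id"].to_numpy()[ci],
            "chrom": site_chrom[sj],
            "pos": site_pos[sj],
            "strand": "+",
            "context": "CGN",
            "mc": mc[ci, sj],
            "cov": cov[ci, sj],
        }
    )

    # --- cell metadata incl. QC metrics; a small fraction planted to fail QC ---
    tot_cov = cov.sum(axis=1)
    tot_mc = mc.sum(axis=1)
    qc_rng = spawn_rng(config.seed, "qc")
    cell_df["global_mcg"] = np.where(tot_cov > 0, tot_mc / np.maximum(tot_cov, 1), np.nan)
    cell_df["mapping_rate"] = qc_rng.uniform(0.55, 0.95, size=n_cells)
    cell_df["final_mc_reads"] = qc_rng.integers(600_000, 2_000_000, size=n_cells)
    fail = qc_rng.random(n_cells) < config.qc_fail_fraction
    cell_df.loc[fail, "mapping_rate"] = qc_rng.uniform(0.2, 0.5, size=int(fail.sum()))

    # coloc/SMR truth: every gDMR region is a coloc locus; alternate shared/distinct
    shared = np.arange(len(gdmr_idx)) % 2 == 0
    truth_coloc = pd.DataFrame(
        {
            "region_id": truth_gdmr["region_id"],
            "shared": shared,
            "meqtl_causal": truth_gdmr["causal_snp"],
            "gwas_causal": truth_gdmr["causal_snp"],
        }
    )
    truth_smr = pd.DataFrame(
        {
            "region_id": truth_gdmr["region_id"],
            "gene_id": "gene_" + truth_gdmr["region_id"],
            "causal_snp": truth_gdmr["causal_snp"],
            "true_b": 1.5,
        }
    )
    truth = TruthTable(edmr=truth_edmr, gdmr=truth_gdmr, coloc=truth_coloc, smr_pairs=truth_smr)
    return counts, truth, cell_df


def _ld_matrix(n_snps: int, decay: float) -> np.ndarray:
    idx = np.arange(n_snps)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def simulate_locus_stats(
    n_snps: int = 50,
    ld_decay: float = 0.9,
    z_causal_1: float = 10.0,
    z_causal_2: float = 10.0,
    shared: bool = True,
    n1: int = 50_000,
    n2: int = 30_000,
    seed: int = 0,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    locus: str = "locus",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two traits' summary statistics at one locus under a single-causal-
    variant model with exponential LD decay by SNP index.

    Marginal z-scores follow the standard single-causal model: mean
    r(j, causal) * z_causal with noise ~ N(0, R) (correlated across SNPs in
    LD, drawn via Cholesky), and beta/se follow from a unit-variance trait
    (se = 1/sqrt(n)).  With ``shared=False`` the two causal SNPs are placed
    at opposite ends of the locus so their LD is negligible.
    """
    if n_snps < 2:
        raise ValueError("a locus needs at least 2 SNPs")
    rng = spawn_rng(seed, "locus", locus)
    R = _ld_matrix(n_snps, ld_decay)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
    c1 = n_snps // 4
    c2 = c1 if shared else (3 * n_snps) // 4
    maf = rng.uniform(0.1, 0.5, size=n_snps)

    def trait(z_causal, causal, n, key):
        trng = spawn_rng(seed, "trait", locus, key)
        z = R[:, causal] * z_causal + L @ trng.standard_normal(n_snps)
        se = np.full(n_snps, 1.0 / np.sqrt(n))
        beta = z * se
        from scipy import stats as sps

        return pd.DataFrame(
            {
                "snp": [f"{locus}_rs{j:03d}" for j in range(n_snps)],
                "chrom": chrom,
                "pos": start_pos + 100 * np.arange(n_snps),
                "a1": "A",
                "a2": "G",
                "beta": beta,
                "se": se,
                "p": 2 * sps.norm.sf(np.abs(z)),
                "maf": maf,
                "n": n,
            }
        )

    return trait(z_causal_1, c1, n1, 1), trait(z_causal_2, c2, n2, 2)


def simulate_summary_stats(
    config: SimConfig, truth: TruthTable, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS and eQTL summary statistics over the genotyped SNPs around each
    coloc locus.

    LD between SNPs is taken from the sample correlation of the simulated
    dosages, so the GWAS signal is coherent with the meQTL scan the pipeline
    runs on the same genotypes: shared-causal loci put the GWAS causal at the
    planted meQTL SNP, distinct-causal loci at the SNP least correlated with
    it.  The eQTL trait is always driven by the planted SNP (the SMR chain).
    """
    if truth.coloc.empty:
        raise ValueError("no coloc loci in the truth table (need >= 1 gDMR)")
    regions = config.regions.set_index("region_id")
    D = genotypes.dosage
    sd = D.std(axis=0)
    from scipy import stats as sps

    gwas_rows, eqtl_rows = [], []
    for k, row in enumerate(truth.coloc.itertuples(index=False)):
        reg = regions.loc[row.region_id]
        mid = (reg["start"] + reg["end"]) // 2
        in_cis = (
            (genotypes.snps["chrom"] == reg["chrom"])
            & ((genotypes.snps["pos"] - mid).abs() <= 1_000_000)
            & (sd > 0)
        )
        j_all = np.nonzero(in_cis.to_numpy())[0]
        if len(j_all) < 2:
            continue
        snp_ids = genotypes.snps["snp"].to_numpy()[j_all]
        causal_j = np.nonzero(snp_ids == row.meqtl_causal)[0]
        if len(causal_j) == 0:
            continue
        causal_j = causal_j[0]
        X = D[:, j_all]
        R = np.corrcoef(X, rowvar=False)
        L = np.linalg.cholesky(R + 1e-6 * np.eye(len(j_all)))
        if not row.shared:
            gwas_causal_j = int(np.argmin(np.abs(R[:, causal_j])))
        else:
            gwas_causal_j = causal_j
        rng = spawn_rng(config.seed, "sumstats", k)
        for rows_out, causal, n, key in (
            (gwas_rows, gwas_causal_j, config.gwas_n, "gwas"),
            (eqtl_rows, causal_j, config.eqtl_n, "eqtl"),
        ):
            trng = spawn_rng(config.seed, "sumstats", k, key)
            z = R[:, causal] * config.causal_z + L @ trng.standard_normal(len(j_all))
            se = np.full(len(j_all), 1.0 / np.sqrt(n))
            frame = pd.DataFrame(
                {
                    "snp": snp_ids,
                    "chrom": reg["chrom"],
                    "pos": genotypes.snps["pos"].to_numpy()[j_all],
                    "a1": "A",
                    "a2": "G",
                    "beta": z * se,
                    "se": se,
                    "p": 2 * sps.norm.sf(np.abs(z)),
                    "maf": genotypes.maf[j_all],
                    "n": n,
                    "region_id": row.region_id,
                }
            )
            if key == "eqtl":
                frame["gene_id"] = "gene_" + row.region_id
            rows_out.append(frame)
    if not gwas_rows:
        raise ValueError("no coloc locus had >= 2 usable cis SNPs")
    return pd.concat(gwas_rows, ignore_index=True), pd.concat(eqtl_rows, ignore_index=True)


def simulate_region_levels(
    n_regions: int = 2000,
    n_true: int = 200,
    delta: float = 0.2,
    level_sd: float = 0.05,
    samples_per_cohort: int = 10,
    cohorts: tuple = ("exposure", "hiv_pre", "flu_pre", "commercial"),
    exposure_cohort: str = "exposure",
    hypo_fraction: float = 0.68,
    baseline_range: tuple = (0.3, 0.7),
    n_batch_regions: int = 0,
    batch_shift: float = 0.0,
    batch_cohort: str = "hiv_pre",
    n_age_regions: int = 0,
    age_effect: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Region-level methylation fractions per sample: the eDMR cascade world.

    Each region's per-sample level is a Gaussian around a region baseline
    (sd ``level_sd``), with ``n_true`` regions shifted by ±``delta`` in the
    exposure cohort.  Optional plants: a batch shift in one control cohort
    (to exercise the control-consistency rule) and an age slope (to exercise
    the covariate filter).  Returns (levels regions x samples, samples
    metadata, truth per region).
    """
    rng = spawn_rng(seed, "levels")
    samples = []
    for cohort in cohorts:
        for k in range(samples_per_cohort):
            samples.append((f"{cohort}_s{k:02d}", cohort))
    samp = pd.DataFrame(samples, columns=["sample", "cohort"])
    samp["exposure_group"] = np.where(samp["cohort"] == exposure_cohort, "exposed", "control")
    samp["age"] = rng.integers(20, 61, size=len(samp))
    samp["sex"] = rng.choice(["F", "M"], size=len(samp))
    samp["ancestry"] = rng.choice(["AFR", "EUR"], size=len(samp))

    region_ids = [f"region_{i:05d}" for i in range(n_regions)]
    perm = rng.permutation(n_regions)
    true_idx = perm[:n_true]
    batch_idx = perm[n_true : n_true + n_batch_regions]
    age_idx = perm[n_true + n_batch_regions : n_true + n_batch_regions + n_age_regions]

    base = rng.uniform(*baseline_range, size=n_regions)
    levels = base[:, None] + rng.normal(0, level_sd, size=(n_regions, len(samp)))

    hypo = rng.random(n_true) < hypo_fraction
    deltas = np.where(hypo, -delta, delta)
    exposed = (samp["exposure_group"] == "exposed").to_numpy()
    levels[np.ix_(true_idx, exposed)] += deltas[:, None]

    if len(batch_idx):
        in_batch = (samp["cohort"] == batch_cohort).to_numpy()
        levels[np.ix_(batch_idx, in_batch)] += batch_shift
        # batch regions also carry the exposure shift so only the
        # control-consistency rule can reject them
        levels[np.ix_(batch_idx, exposed)] += delta
    if len(age_idx):
        age_c = (samp["age"] - samp["age"].mean()).to_numpy()
        levels[np.ix_(age_idx, np.ones(len(samp), dtype=bool))] += age_effect * age_c[None, :]

    levels = np.clip(levels, 0.0, 1.0)
    truth = pd.DataFrame({"region_id": region_ids})
    truth["is_edmr"] = np.isin(np.arange(n_regions), true_idx)
    truth["delta"] = 0.0
    truth.loc[true_idx, "delta"] = deltas
    truth["is_batch"] = np.isin(np.arange(n_regions), batch_idx)
    truth["is_age"] = np.isin(np.arange(n_regions), age_idx)

    levels_df = pd.DataFrame(levels, index=pd.Index(region_ids, name="region_id"), columns=samp["sample"])
    return levels_df, samp, truth
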