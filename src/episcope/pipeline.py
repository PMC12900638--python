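"""End-to-end orchestration on a simulated dataset.

``run_pipeline`` chains every stage — simulate -> QC -> bin matrix ->
clustering -> eDMR cascade -> meQTL -> colocalization -> SMR -> enrichment —
and reports summary metrics against the planted truth.  It exists for smoke
testing, the CLI and the acceptance script; each stage is equally usable on
its own.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import clustering, coloc, dmr, enrichment, meqtl, methylome, simulate
from ._utils import overlaps_any, spawn_rng
from .smr import smr_scan


def make_blacklist(config: simulate.SimConfig, truth: simulate.TruthTable, n_intervals: int = 5) -> pd.DataFrame:
    """A synthetic artifact blacklist: a few bins with no planted effects."""
    regions = config.regions
    planted = set(truth.edmr["region_id"]) | set(truth.gdmr["region_id"])
    free = regions[~regions["region_id"].isin(planted)]
    rng = spawn_rng(config.seed, "blacklist")
    pick = free.iloc[rng.choice(len(free), size=min(n_intervals, len(free)), replace=False)]
    return pick[["chrom", "start", "end"]].reset_index(drop=True)


def pseudobulk_counts(counts: pd.DataFrame, cell_to_sample: pd.Series) -> pd.DataFrame:
    """Aggregate per-cell site counts to per-sample (donor) pseudobulk."""
    df = counts.copy()
    df["sample"] = df["cell_id"].map(cell_to_sample)
    return (
        df.dropna(subset=["sample"])
        .groupby(["sample", "chrom", "pos"], as_index=False)[["mc", "cov"]]
        .sum()
    )


def donor_bin_levels(
    pseudobulk: pd.DataFrame, genome, bin_size: int, blacklist: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor methylation level of every retained bin (regions, levels)."""
    bm = methylome.build_bin_matrix(
        pseudobulk.rename(columns={"sample": "cell_id"}), genome, bin_size, blacklist
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(bm.cov > 0, bm.mc / np.maximum(bm.cov, 1), np.nan)
    regions = bm.bins.copy()
    regions.insert(
        0,
        "region_id",
        regions["chrom"].astype(str)
        + ":"
        + regions["start"].astype(str)
        + "-"
        + regions["end"].astype(str),
    )
    levels = pd.DataFrame(
        lev.T, index=pd.Index(regions["region_id"], name="region_id"), columns=bm.cells
    )
    return regions, levels


def run_pipeline(config: simulate.SimConfig | None = None, seed: int | None = None) -> dict:
    """Run every stage on one simulated dataset; returns summary metrics."""
    if config is None:
        config = simulate.SimConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))

    # ------------------------------------------------ simulate
    genotypes = simulate.simulate_genotypes(config)
    counts, truth, cell_meta = simulate.simulate_methylomes(config, genotypes)
    gwas_stats, eqtl_stats = simulate.simulate_summary_stats(config, truth, genotypes)
    blacklist = make_blacklist(config, truth)

    # ------------------------------------------------ QC + matrix
    passing = methylome.filter_cells(cell_meta)
    bm = methylome.build_bin_matrix(
        counts[counts["cell_id"].isin(passing)], config.genome, config.bin_size, blacklist, cells=passing
    )
    bm = methylome.filter_bins(bm)

    # ------------------------------------------------ clustering
    # coarse resolution: the smoke world plants major cell types, not subtypes
    clusters = clustering.cluster_cells(
        bm, n_pcs=min(32, bm.n_cells - 2), resolution=0.25, seed=config.seed
    )
    meta_idx = cell_meta.set_index("cell_id").loc[passing]
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(meta_idx["celltype_true"], clusters.to_numpy())

    # ------------------------------------------------ eDMR cascade
    pb = pseudobulk_counts(
        counts[counts["cell_id"].isin(passing)], cell_meta.set_index("cell_id")["donor"]
    )
    donor_meta = cell_meta.drop_duplicates("donor").set_index("donor")
    donor_cohort = donor_meta["cohort"].to_dict()
    candidates = dmr.call_primary_dmrs(
        pb, donor_cohort, fdr=0.05, n_permutations=100, seed=config.seed
    )
    levels = dmr.add_methylation_level(candidates, pb)
    controls = tuple(c for c in config.cohort_design if c != config.exposure_cohort)
    cascade = dmr.filter_external_control(
        levels, donor_cohort, config.exposure_cohort, controls
    )
    retained = candidates[cascade["retained"].to_numpy()]

    truth_regions = config.regions.set_index("region_id")
    true_edmr_iv = truth_regions.loc[truth.edmr["region_id"], ["chrom", "start", "end"]]
    if len(retained):
        hit = overlaps_any(retained, true_edmr_iv.reset_index(drop=True))
    else:
        hit = np.zeros(0, dtype=bool)
    detected_true = overlaps_any(true_edmr_iv.reset_index(drop=True), retained) if len(retained) else np.zeros(len(true_edmr_iv), dtype=bool)
    sensitivity = float(detected_true.mean()) if len(true_edmr_iv) else float("nan")
    false_rate = float((~hit).mean()) if len(retained) else 0.0

    # ------------------------------------------------ meQTL
    gt = meqtl.filter_snps(genotypes, blacklist)
    pcs = meqtl.genotype_pca(gt, n_pcs=5)
    covars = donor_meta[["age", "sex", "exposure_group"]].join(pcs)
    regions_all, bin_levels = donor_bin_levels(pb, config.genome, config.bin_size, blacklist)
    cis = meqtl.map_cis_meqtl(regions_all, bin_levels, gt, covars)
    cis_sig = cis[cis["significant"]]

    # permutation pass on the planted gDMR regions
    p_emp = {}
    region_pos = regions_all.set_index("region_id")
    for rid in truth.gdmr["region_id"]:
        if rid not in region_pos.index or rid not in bin_levels.index:
            continue
        mid = (region_pos.loc[rid, "start"] + region_pos.loc[rid, "end"]) // 2
        in_cis = (gt.snps["chrom"] == region_pos.loc[rid, "chrom"]) & (
            (gt.snps["pos"] - mid).abs() <= meqtl.CIS_WINDOW
        )
        res = meqtl.permutation_pass(
            bin_levels.loc[rid], gt.subset_snps(in_cis.to_numpy()), covars,
            n_permutations=200, seed=config.seed,
        )
        p_emp[rid] = res["p_empirical"]

    gdmr_detected = truth.gdmr["region_id"].isin(cis_sig["region_id"]).mean() if len(truth.gdmr) else float("nan")

    # ------------------------------------------------ coloc + SMR
    coloc_rows = []
    for row in truth.coloc.itertuples(index=False):
        mstats = cis[cis["region_id"] == row.region_id][["snp_id", "beta", "se"]].rename(
            columns={"snp_id": "snp"}
        )
        gstats = gwas_stats[gwas_stats["region_id"] == row.region_id]
        res = coloc.coloc_abf(mstats.dropna(), gstats, region_id=row.region_id, trait_id="gwas")
        if res is not None:
            d = res.as_dict()
            d["shared_truth"] = row.shared
            coloc_rows.append(d)
    coloc_df = pd.DataFrame(coloc_rows)

    smr_pairs = []
    snp_coords = gt.snps.set_index("snp")[["chrom", "pos"]]
    for row in truth.smr_pairs.itertuples(index=False):
        mstats = cis[cis["region_id"] == row.region_id][["snp_id", "beta", "se"]].rename(
            columns={"snp_id": "snp"}
        ).join(snp_coords, on="snp")
        estats = eqtl_stats[eqtl_stats["gene_id"] == row.gene_id]
        smr_pairs.append((row.region_id, row.gene_id, mstats.dropna(), estats))
    smr_df = smr_scan(smr_pairs)

    # ------------------------------------------------ enrichment / concordance
    rng = spawn_rng(config.seed, "atac")
    hypo_bins = bm.hyposcore.mean(axis=0)
    insertions = 5.0 + 20.0 * hypo_bins + rng.normal(0, 0.5, size=len(hypo_bins))
    conc = enrichment.mc_atac_correlation(
        pd.DataFrame({"all": hypo_bins}, index=regions_all["region_id"][: len(hypo_bins)]),
        pd.DataFrame({"all": insertions}, index=regions_all["region_id"][: len(hypo_bins)]),
    )
    # feature track = the true eDMR bins; retained eDMRs should be enriched
    # against the full tested-bin background.  Retained regions carry
    # site-level coordinates, so they are mapped onto background bins by
    # any-overlap to satisfy query-subset-of-background.
    if len(retained):
        q_bins = regions_all[overlaps_any(regions_all, retained)]
        enr = enrichment.fisher_enrichment(
            q_bins[["chrom", "start", "end"]],
            {"true_edmr_bins": true_edmr_iv.reset_index(drop=True)},
            regions_all[["chrom", "start", "end"]],
        )
    else:
        enr = pd.DataFrame()

    return {
        "config": config,
        "truth": truth,
        "n_cells_pass_qc": len(passing),
        "n_bins": bm.n_bins,
        "clustering_ari": float(ari),
        "n_candidate_dmrs": int(len(candidates)),
        "n_retained_edmrs": int(len(retained)),
        "edmr_sensitivity": sensitivity,
        "edmr_false_rate": false_rate,
        "n_cis_pairs": int(len(cis)),
        "n_cis_significant": int(len(cis_sig)),
        "gdmr_detection_rate": float(gdmr_detected),
        "p_empirical": p_emp,
        "coloc": coloc_df,
        "smr": smr_df,
        "concordance": conc,
        "enrichment": enr,
        "candidates": candidates,
        "retained": retained,
        "cis": cis,
    }
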