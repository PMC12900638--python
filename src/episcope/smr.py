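"""Summary-based Mendelian randomization linking region methylation to gene
expression.

Exposure = a DMR's methylation, outcome = a gene's expression.  The
instrument is the region's top meQTL SNP (below an instrument p threshold);
the SMR statistic combines the instrument's meQTL and eQTL z-scores

    T_SMR = z_x^2 z_y^2 / (z_x^2 + z_y^2)  ~  chi-square(1) under H0,

and the Wald ratio b_SMR = beta_eQTL / beta_meQTL estimates the expression
change per unit methylation.  Pairs inside the HLA region are flagged and
excluded from the Bonferroni family; the HEIDI heterogeneity test is
deliberately not implemented (population mismatch makes it uninformative
here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import logger

INSTRUMENT_P = 5e-8
HLA_REGION = ("chr6", 28_477_797, 33_448_354)  # 1-based inclusive


def smr_statistic(z_x, z_y):
    """T_SMR = z_x^2 z_y^2 / (z_x^2 + z_y^2); 0 when either z is 0."""
    z_x = np.asarray(z_x, dtype=float)
    z_y = np.asarray(z_y, dtype=float)
    num = z_x**2 * z_y**2
    den = z_x**2 + z_y**2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    return float(t) if t.ndim == 0 else t


def in_hla(chrom, pos) -> bool:
    c, lo, hi = HLA_REGION
    return str(chrom) == c and lo <= int(pos) <= hi


def smr_test(
    meqtl_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    instrument_p_threshold: float = INSTRUMENT_P,
) -> dict | None:
    """SMR test for one (region, gene) pair.

    Both frames carry snp, beta, se (and chrom/pos for the HLA flag).  The
    instrument is the shared SNP with the smallest meQTL p below the
    threshold; None if no instrument qualifies or beta_meQTL = 0.
    """
    merged = meqtl_stats.merge(eqtl_stats, on="snp", suffixes=("_x", "_y"))
    if merged.empty:
        return None
    zx_all = merged["beta_x"] / merged["se_x"]
    p_x = 2 * stats.norm.sf(np.abs(zx_all))
    ok = p_x < instrument_p_threshold
    if not ok.any():
        return None
    best = int(np.argmin(np.where(ok, p_x, np.inf)))
    row = merged.iloc[best]
    if row["beta_x"] == 0:
        logger.warning("instrument with zero meQTL beta; pair skipped")
        return None
    z_x = row["beta_x"] / row["se_x"]
    z_y = row["beta_y"] / row["se_y"]
    t = smr_statistic(z_x, z_y)
    chrom = row.get("chrom_x", row.get("chrom", ""))
    pos = row.get("pos_x", row.get("pos", 0))
    return {
        "instrument_snp": row["snp"],
        "b_smr": float(row["beta_y"] / row["beta_x"]),
        "se_smr": float(abs(row["beta_y"] / row["beta_x"]))
        * float(np.sqrt(1.0 / z_x**2 + 1.0 / z_y**2))
        if z_x != 0 and z_y != 0
        else np.nan,
        "t_smr": t,
        "p_smr": float(stats.chi2.sf(t, df=1)),
        "in_hla": in_hla(chrom, pos),
    }


def smr_scan(
    pairs: list,
    instrument_p_threshold: float = INSTRUMENT_P,
    alpha: float = 0.05,
    exclude_hla: bool = True,
) -> pd.DataFrame:
    """SMR over (region_id, gene_id, meqtl_stats, eqtl_stats) tuples.

    The Bonferroni family is the set of tested pairs outside the HLA region
    (alpha = 0.05 / n); HLA pairs are reported but flagged and never counted
    significant when ``exclude_hla``.
    """
    rows = []
    for region_id, gene_id, mstats, estats in pairs:
        res = smr_test(mstats, estats, instrument_p_threshold)
        if res is None:
            continue
        res["region_id"] = region_id
        res["gene_id"] = gene_id
        rows.append(res)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    family = ~out["in_hla"] if exclude_hla else pd.Series(True, index=out.index)
    n_tests = int(family.sum())
    out["n_tests"] = n_tests
    out["passes_bonferroni"] = family & (out["p_smr"] < alpha / max(n_tests, 1))
    return out
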