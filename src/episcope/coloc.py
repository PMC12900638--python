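"""Bayesian colocalization of two association signals at a locus.

Implements the approximate-Bayes-factor (ABF) framework: each SNP's evidence
of association with a trait is a Wakefield log-ABF computed from its effect
estimate and standard error under a normal effect prior; the five mutually
exclusive hypotheses (H0 no association, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared causal variant) accumulate evidence
by log-sum-exp over single-causal-variant configurations, weighted by the
per-SNP priors p1, p2 and p12.  The decision rule downstream is PP4 > 0.50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from ._utils import bh_fdr, logger

PRIOR_SD_QUANT = 0.2  # effect-size prior sd for quantitative traits
PRIOR_SD_CC = 0.15  # for case-control (log-odds scale)
PP4_THRESHOLD = 0.50


def wakefield_labf(beta, se, prior_sd: float = PRIOR_SD_QUANT):
    """Wakefield log approximate Bayes factor for one association.

    With z = beta/se, V = se^2, W = prior_sd^2 and r = W/(W+V):
        lABF = 0.5 * (log(1 - r) + r * z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


def z_from_p(p):
    """|z| recovered from a two-sided p-value (sign unavailable)."""
    return np.sqrt(stats.chi2.isf(np.asarray(p, dtype=float), df=1))


def _labf_column(df: pd.DataFrame, prior_sd: float) -> np.ndarray:
    """lABF per SNP from beta/se when present, else from p (+maf, n) with
    V approximated by 1/(2 n maf (1-maf)) for a unit-variance trait."""
    if "beta" in df and "se" in df and df["se"].notna().all():
        return wakefield_labf(df["beta"].to_numpy(), df["se"].to_numpy(), prior_sd)
    if not {"p", "maf", "n"} <= set(df.columns):
        raise ValueError("need beta/se or p/maf/n columns")
    z = z_from_p(df["p"].to_numpy())
    V = 1.0 / (2.0 * df["n"].to_numpy() * df["maf"].to_numpy() * (1.0 - df["maf"].to_numpy()))
    r = prior_sd**2 / (prior_sd**2 + V)
    return 0.5 * (np.log1p(-r) + r * z * z)


@dataclass
class ColocResult:
    region_id: str
    trait_id: str
    n_snps: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    priors: tuple = (1e-4, 1e-4, 1e-5)

    @property
    def significant(self) -> bool:
        return self.pp4 > PP4_THRESHOLD

    def as_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "trait_id": self.trait_id,
            "n_snps": self.n_snps,
            "pp0": self.pp0,
            "pp1": self.pp1,
            "pp2": self.pp2,
            "pp3": self.pp3,
            "pp4": self.pp4,
            "significant": self.significant,
        }


def coloc_abf(
    stats_trait1: pd.DataFrame,
    stats_trait2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = PRIOR_SD_QUANT,
    prior_sd2: float = PRIOR_SD_QUANT,
    region_id: str = "",
    trait_id: str = "",
) -> ColocResult | None:
    """Colocalization posteriors for two traits sharing a SNP panel.

    Input frames carry at least snp + (beta, se) or (p, maf, n); the SNP
    intersection (by id) is analysed.  Returns None (logged) on an empty
    intersection.  Posteriors always sum to 1.
    """
    merged = stats_trait1.merge(stats_trait2, on="snp", suffixes=("_1", "_2"))
    if merged.empty:
        logger.warning("coloc %s/%s: no shared SNPs", region_id, trait_id)
        return None
    l1 = _labf_column(
        merged.rename(columns={"beta_1": "beta", "se_1": "se", "p_1": "p", "maf_1": "maf", "n_1": "n"}),
        prior_sd1,
    )
    l2 = _labf_column(
        merged.rename(columns={"beta_2": "beta", "se_2": "se", "p_2": "p", "maf_2": "maf", "n_2": "n"}),
        prior_sd2,
    )
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered distinct pairs: exp(s1)*exp(s2) - exp(s12), in log space
    both = s1 + s2
    if s12 < both:
        s_pairs = both + np.log1p(-np.exp(s12 - both))
    else:
        s_pairs = -np.inf  # single SNP (or numerically exhausted): H3 impossible
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + s_pairs,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(
        region_id=region_id,
        trait_id=trait_id,
        n_snps=len(merged),
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        priors=(p1, p2, p12),
    )


def coloc_scan(
    meqtl_stats: pd.DataFrame,
    gwas_stats: pd.DataFrame,
    region_col: str = "region_id",
    trait_col: str = "trait_id",
    **kwargs,
) -> pd.DataFrame:
    """Run coloc_abf for every (region, trait) locus pair sharing SNPs.

    Both inputs are long frames with a region/trait column; loci pair on
    ``region_col`` when the GWAS frame carries it, else all-vs-all.
    """
    results = []
    traits = gwas_stats.groupby(trait_col) if trait_col in gwas_stats else [("trait", gwas_stats)]
    for trait, tstats in traits:
        for region, rstats in meqtl_stats.groupby(region_col):
            sub = tstats
            if region_col in tstats.columns:
                sub = tstats[tstats[region_col] == region]
                if sub.empty:
                    continue
            res = coloc_abf(rstats, sub, region_id=str(region), trait_id=str(trait), **kwargs)
            if res is not None:
                results.append(res.as_dict())
    return pd.DataFrame(results)


def overlap_chisq(set1, set2, universe) -> dict:
    """Chi-square independence test of two SNP-set memberships over a
    universe.  Degenerate margins -> NaN statistic (skipped)."""
    universe = list(universe)
    s1, s2 = set(set1), set(set2)
    if not s1 <= set(universe) or not s2 <= set(universe):
        raise ValueError("both sets must be subsets of the universe")
    in1 = np.array([u in s1 for u in universe])
    in2 = np.array([u in s2 for u in universe])
    table = np.array(
        [
            [int((in1 & in2).sum()), int((in1 & ~in2).sum())],
            [int((~in1 & in2).sum()), int((~in1 & ~in2).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in overlap test; skipped")
        return {"statistic": np.nan, "p": np.nan, "table": table}
    res = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "table": table}


def overlap_chisq_batch(pairs: dict, universe_by_pair: dict) -> pd.DataFrame:
    """overlap_chisq per (region, trait) pair with BH correction across pairs.

    ``pairs`` maps pair-key -> (meqtl snp set, gwas snp set)."""
    rows = []
    for key, (a, b) in pairs.items():
        res = overlap_chisq(a, b, universe_by_pair[key])
        rows.append({"pair": key, "statistic": res["statistic"], "p": res["p"]})
    out = pd.DataFrame(rows)
    out["bh_q"] = bh_fdr(out["p"])
    return out
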