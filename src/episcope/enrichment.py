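"""Fisher-exact enrichment of region sets in genomic annotations and
methylation-accessibility concordance metrics.

Interval intersection is any-overlap (>= 1 bp, bedtools-intersect default)
throughout.  The enrichment background defaults to the candidate-region set
the cascade tested, not the whole genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, logger, overlaps_any


def fisher_enrichment(
    query: pd.DataFrame, feature_sets: dict, background: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided Fisher enrichment of ``query`` regions (subset of
    ``background``) in each feature BED, BH-corrected across feature sets.

    2x2 table: [query n feature, query \\ feature; nonquery n feature,
    nonquery \\ feature], membership by any-overlap.  Degenerate margins
    (e.g. query == background) are skipped with a reason.
    """
    if len(background) == 0:
        raise ValueError("empty background")
    bg = background.reset_index(drop=True)
    key = bg["chrom"].astype(str) + ":" + bg["start"].astype(str) + "-" + bg["end"].astype(str)
    qkey = set(
        query["chrom"].astype(str) + ":" + query["start"].astype(str) + "-" + query["end"].astype(str)
    )
    in_query = key.isin(qkey).to_numpy()
    rows = []
    for name, feat in feature_sets.items():
        hit = overlaps_any(bg, feat)
        a = int((in_query & hit).sum())
        b = int((in_query & ~hit).sum())
        c = int((~in_query & hit).sum())
        d = int((~in_query & ~hit).sum())
        if min(a + b, c + d, a + c, b + d) == 0:
            logger.warning("feature %s: degenerate margin, skipped", name)
            rows.append((name, a, b, c, d, np.nan, np.nan, "skipped"))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "enriched" if odds > 1 else ("depleted" if odds < 1 else "none")
        rows.append((name, a, b, c, d, odds, p, direction))
    out = pd.DataFrame(
        rows, columns=["feature_set", "a", "b", "c", "d", "odds_ratio", "p", "direction"]
    )
    out["bh_q"] = bh_fdr(out["p"])
    return out


def mc_atac_correlation(
    hyposcore_by_bin: pd.DataFrame,
    insertions_by_bin: pd.DataFrame,
    method: str = "pearson",
    min_bins: int = 10,
) -> pd.DataFrame:
    """Correlation between per-bin hyposcore pseudobulk and Tn5 insertion
    counts, per cell type (shared columns) and pooled across cell types.

    Both frames are bins x cell types on a shared bin index; bins missing in
    either modality are excluded pairwise.  Zero variance -> NaN coefficient.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    shared_bins = hyposcore_by_bin.index.intersection(insertions_by_bin.index)
    celltypes = [c for c in hyposcore_by_bin.columns if c in insertions_by_bin.columns]
    rows = []

    def corr(x, y):
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_bins:
            return np.nan, int(ok.sum())
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            return np.nan, int(ok.sum())
        if method == "pearson":
            return float(stats.pearsonr(x, y).statistic), int(ok.sum())
        return float(stats.spearmanr(x, y).statistic), int(ok.sum())

    pooled_x, pooled_y = [], []
    for ct in celltypes:
        x = hyposcore_by_bin.loc[shared_bins, ct].to_numpy(dtype=float)
        y = insertions_by_bin.loc[shared_bins, ct].to_numpy(dtype=float)
        r, n = corr(x, y)
        rows.append({"cell_type": ct, "correlation": r, "n_bins": n})
        pooled_x.append(x)
        pooled_y.append(y)
    if celltypes:
        r, n = corr(np.concatenate(pooled_x), np.concatenate(pooled_y))
        rows.append({"cell_type": "pooled", "correlation": r, "n_bins": n})
    return pd.DataFrame(rows)


def edmr_peak_overlap(hypo_edmrs: pd.DataFrame, gained_peaks: pd.DataFrame) -> float:
    """Fraction of hypomethylated eDMRs with any-overlap against gained ATAC
    peaks.  Empty eDMR set -> NaN."""
    if len(hypo_edmrs) == 0:
        return float("nan")
    if len(gained_peaks) == 0:
        return 0.0
    return float(overlaps_any(hypo_edmrs, gained_peaks).mean())
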