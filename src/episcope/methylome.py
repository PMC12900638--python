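"""Cell-level QC, 5-kb binning, hypomethylation scoring and bin filtering.

The central object is the cell-by-bin :class:`BinMatrix`.  Each entry holds a
*hyposcore*: the upper-tail binomial probability of seeing **more** than the
observed number of methylated reads in a bin, given the bin's total coverage
``c`` and the cell's expected methylation probability ``p``,

    hyposcore(m, c, p) = 1 - BinomialCDF(m; c, p) = P(X > m).

A score near 1 means the bin carries far fewer methylated reads than the
cell's genome-wide methylation level predicts, i.e. the bin is hypomethylated
in that cell.  The matrix is binarized at hyposcore >= 0.95 for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import AUTOSOME_EXCLUDE, logger, overlaps_any

# QC thresholds; all strict inequalities.
QC_MIN_MAPPING_RATE = 0.5
QC_MIN_MC_READS = 500_000
QC_MIN_GLOBAL_MCG = 0.5

BINARIZE_CUTOFF = 0.95


def filter_cells(metrics: pd.DataFrame) -> list[str]:
    """Return ids of cells passing all three QC thresholds (strict).

    ``metrics`` needs columns ``cell_id``, ``mapping_rate``, ``final_mc_reads``
    and ``global_mcg``.  Cells with any missing metric are rejected (and
    logged), never passed by default.
    """
    required = ["mapping_rate", "final_mc_reads", "global_mcg"]
    passing = []
    for row in metrics.itertuples(index=False):
        vals = [getattr(row, c) for c in required]
        if any(pd.isna(v) for v in vals):
            logger.warning("cell %s rejected: missing QC metric", row.cell_id)
            continue
        if (
            row.mapping_rate > QC_MIN_MAPPING_RATE
            and row.final_mc_reads > QC_MIN_MC_READS
            and row.global_mcg > QC_MIN_GLOBAL_MCG
        ):
            passing.append(row.cell_id)
    return passing


def compute_cell_p(mc, cov) -> float:
    """Expected methylation probability for one cell: sum(mc) / sum(cov).

    Raises ValueError on zero total coverage (the cell carries no
    information and must be excluded upstream).
    """
    total = float(np.sum(cov))
    if total <= 0:
        raise ValueError("zero total coverage: p undefined, exclude cell")
    p = float(np.sum(mc)) / total
    if not 0.0 <= p <= 1.0:
        raise ValueError("methylated counts exceed coverage")
    return p


def hyposcore(m, c, p):
    """P(X > m) for X ~ Binomial(c, p); the hypomethylation score.

    Vectorised over numpy-broadcastable inputs.  ``m`` must not exceed ``c``.
    scipy's survival function evaluates the regularised incomplete beta in
    log space, which keeps the tail accurate for large ``c``.
    """
    m = np.asarray(m)
    c = np.asarray(c)
    if np.any(m > c) or np.any(m < 0) or np.any(c < 0):
        raise ValueError("require 0 <= m <= c")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    out = stats.binom.sf(m, c, p)
    return float(out) if out.ndim == 0 else out


@dataclass
class BinMatrix:
    """Cells x genomic-bins hyposcore matrix with its binarized companion.

    Attributes
    ----------
    cells : list of cell ids (row order).
    bins : DataFrame with chrom/start/end (0-based half-open), column order.
    mc, cov : int arrays (n_cells, n_bins) of summed counts per bin.
    hyposcore : float array in [0, 1]; 0 where a cell has no coverage in a bin.
    binarized : uint8 array, 1 iff hyposcore >= 0.95.
    per_cell_p : expected methylation probability per cell over retained bins.
    """

    cells: list
    bins: pd.DataFrame
    mc: np.ndarray
    cov: np.ndarray
    hyposcore: np.ndarray = field(default=None)
    binarized: np.ndarray = field(default=None)
    per_cell_p: np.ndarray = field(default=None)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def recompute_scores(self) -> "BinMatrix":
        """(Re)derive per_cell_p, hyposcore and binarized from mc/cov."""
        tot_mc = self.mc.sum(axis=1)
        tot_cov = self.cov.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot_cov > 0, tot_mc / np.maximum(tot_cov, 1), np.nan)
        score = np.zeros(self.mc.shape, dtype=float)
        covered = self.cov > 0
        if covered.any():
            rows = np.nonzero(covered.any(axis=1))[0]
            for i in rows:
                j = covered[i]
                score[i, j] = stats.binom.sf(self.mc[i, j], self.cov[i, j], p[i])
        self.per_cell_p = p
        self.hyposcore = score
        self.binarized = (score >= BINARIZE_CUTOFF).astype(np.uint8)
        return self

    def subset_bins(self, mask: np.ndarray) -> "BinMatrix":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            bins=self.bins.loc[mask].reset_index(drop=True),
            mc=self.mc[:, mask],
            cov=self.cov[:, mask],
            hyposcore=None if self.hyposcore is None else self.hyposcore[:, mask],
            binarized=None if self.binarized is None else self.binarized[:, mask],
        )


def make_bins(genome, bin_size: int = 5000, blacklist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tile autosomes into fixed-width bins; drop sex/mito chromosomes and any
    bin overlapping the blacklist by >= 1 bp."""
    if not genome:
        raise ValueError("empty genome")
    rows = []
    for chrom, length in genome:
        if chrom in AUTOSOME_EXCLUDE:
            continue
        starts = np.arange(0, int(length), int(bin_size))
        ends = np.minimum(starts + int(bin_size), int(length))
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        raise ValueError("no autosomal chromosomes in genome")
    bins = pd.concat(rows, ignore_index=True)
    if blacklist is not None and len(blacklist):
        bins = bins.loc[~overlaps_any(bins, blacklist)].reset_index(drop=True)
    return bins


def build_bin_matrix(
    counts: pd.DataFrame,
    genome,
    bin_size: int = 5000,
    blacklist: pd.DataFrame | None = None,
    cells: list | None = None,
) -> BinMatrix:
    """Aggregate per-site counts into a cell-by-bin matrix and score it.

    ``counts`` is ALLC-like: cell_id, chrom, pos (1-based), mc, cov.  Sites on
    excluded chromosomes or inside blacklisted bins simply fall outside the
    retained bins and are dropped.
    """
    bins = make_bins(genome, bin_size, blacklist)
    if cells is None:
        cells = sorted(counts["cell_id"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}

    # map each site to its tiling bin, then keep only retained bins
    key = bins["chrom"].astype(str) + ":" + (bins["start"] // bin_size).astype(str)
    bin_index = {k: j for j, k in enumerate(key)}

    sub = counts[counts["cell_id"].isin(cell_index)]
    site_key = sub["chrom"].astype(str) + ":" + ((sub["pos"].astype(int) - 1) // bin_size).astype(str)
    j = site_key.map(bin_index)
    keep = j.notna()
    sub = sub.loc[keep]
    j = j[keep].astype(int).to_numpy()
    i = sub["cell_id"].map(cell_index).to_numpy()

    mc = np.zeros((len(cells), len(bins)), dtype=np.int64)
    cov = np.zeros_like(mc)
    np.add.at(mc, (i, j), sub["mc"].astype(int).to_numpy())
    np.add.at(cov, (i, j), sub["cov"].astype(int).to_numpy())

    return BinMatrix(cells=list(cells), bins=bins, mc=mc, cov=cov).recompute_scores()


def filter_bins(matrix: BinMatrix, min_cells: int = 5, z_cut: float = 2.0) -> BinMatrix:
    """Drop sparsely covered and extreme-coverage bins.

    First remove bins covered (cov > 0) by fewer than ``min_cells`` cells;
    then z-score the nonzero-cell counts across the remaining bins and remove
    bins with |z| > ``z_cut``.  With zero variance across bins z is defined
    as 0 everywhere (nothing removed); with < 2 bins the z step is skipped.
    """
    ncells = (matrix.cov > 0).sum(axis=0)
    m = matrix.subset_bins(ncells >= min_cells)
    ncells = (m.cov > 0).sum(axis=0)
    if m.n_bins < 2:
        logger.warning("fewer than 2 bins after coverage filter; z filter skipped")
        return m.recompute_scores()
    sd = ncells.std()
    z = np.zeros(m.n_bins) if sd == 0 else (ncells - ncells.mean()) / sd
    return m.subset_bins(np.abs(z) <= z_cut).recompute_scores()
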