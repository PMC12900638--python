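"""Differential-methylation calling and the exposure-DMR filter cascade.

The primary caller works at single-CpG resolution on pseudobulk counts: the
per-site statistic is the root-mean-square deviation of group methylation
fractions from the pooled fraction, its null is built by permuting the
sample-to-group assignment, and significant sites within ``max_gap`` bp are
merged into regions (singleton-CpG regions are allowed and common).  The
caller is pluggable: any BED-like candidate table can be fed to the
downstream cascade instead.

The cascade then works on per-sample region methylation levels:

* internal-control mode - retain a region iff the minimum two-sided
  Student's t p-value over all group pairs is < 0.05;
* external-control mode - retain iff the exposure group differs from each of
  the three control cohorts (p < 0.05) while no two control cohorts differ
  (p > 0.05), which guards against single-cohort batch artifacts;
* label-shuffle validation - re-run the cascade under permuted group labels
  and compare the observed retained count to the shuffled distribution;
* covariate filtering - drop regions whose levels associate with age, sex or
  ancestry; ancestry mode reports ancestry-linked regions after residualizing
  out sex and age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, logger, spawn_rng


# ---------------------------------------------------------------- primary caller


def site_rms_statistic(mc_by_group: np.ndarray, cov_by_group: np.ndarray) -> np.ndarray:
    """Per-site RMS deviation of group methylation fractions from the pooled
    fraction.  Arrays are (n_groups, n_sites); groups with zero coverage at a
    site are excluded from that site's mean."""
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cov_by_group > 0, mc_by_group / np.maximum(cov_by_group, 1), np.nan)
    pooled = mc_by_group.sum(axis=0) / np.maximum(cov_by_group.sum(axis=0), 1)
    dev = (frac - pooled[None, :]) ** 2
    return np.sqrt(np.nanmean(dev, axis=0))


def call_primary_dmrs(
    counts: pd.DataFrame,
    sample_groups: dict,
    fdr: float = 0.05,
    max_gap: int = 250,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-level permutation DMR caller on per-sample pseudobulk counts.

    ``counts`` is long-form: sample, chrom, pos (1-based), mc, cov.  The
    permutation null pools statistics across sites and label permutations,
    which gives p-value resolution fine enough for BH at thousands of sites.
    Returns merged regions as a BED-like frame (start 0-based half-open)
    with n_sites per region.
    """
    samples = sorted(set(counts["sample"]) & set(sample_groups))
    groups = sorted({sample_groups[s] for s in samples})
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    wide_mc = counts.pivot_table(index=["chrom", "pos"], columns="sample", values="mc", aggfunc="sum", fill_value=0)
    wide_cov = counts.pivot_table(index=["chrom", "pos"], columns="sample", values="cov", aggfunc="sum", fill_value=0)
    wide_mc, wide_cov = wide_mc[samples], wide_cov[samples]
    covered = wide_cov.sum(axis=1) > 0
    wide_mc, wide_cov = wide_mc.loc[covered], wide_cov.loc[covered]
    MC = wide_mc.to_numpy(dtype=float).T  # (n_samples, n_sites)
    COV = wide_cov.to_numpy(dtype=float).T

    glabels = np.array([sample_groups[s] for s in samples])

    def group_stack(order):
        mcg = np.stack([MC[order][glabels == g].sum(axis=0) for g in groups])
        covg = np.stack([COV[order][glabels == g].sum(axis=0) for g in groups])
        return mcg, covg

    ident = np.arange(len(samples))
    obs = site_rms_statistic(*group_stack(ident))

    rng = spawn_rng(seed, "primary-dmr")
    null = np.concatenate(
        [site_rms_statistic(*group_stack(rng.permutation(ident))) for _ in range(n_permutations)]
    )
    null = np.sort(null[np.isfinite(null)])
    # pooled-null p: fraction of null statistics >= observed
    ge = len(null) - np.searchsorted(null, obs, side="left")
    pvals = (1.0 + ge) / (1.0 + len(null))

    sites = wide_mc.index.to_frame(index=False)
    sites["statistic"] = obs
    sites["p"] = pvals
    sites["fdr"] = bh_fdr(pvals)
    sig = sites[sites["fdr"] < fdr].sort_values(["chrom", "pos"])

    regions = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            regions.append((chrom, int(pos[a]) - 1, int(pos[b]), int(b - a + 1)))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_sites"])
    out.insert(0, "region_id", [f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])])
    return out


def add_methylation_level(regions: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample methylation level of each region: sum(mc)/sum(cov) over
    sites inside [start, end).  Zero coverage -> NaN, never 0.

    ``counts``: sample, chrom, pos (1-based), mc, cov.  Returns a regions x
    samples frame indexed by region_id.
    """
    samples = sorted(counts["sample"].unique())
    out = pd.DataFrame(
        np.nan, index=pd.Index(regions["region_id"], name="region_id"), columns=samples
    )
    by_chrom = {c: sub for c, sub in counts.groupby("chrom")}
    for row in regions.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        inside = sub[(sub["pos"] - 1 >= row.start) & (sub["pos"] - 1 < row.end)]
        if not len(inside):
            continue
        agg = inside.groupby("sample")[["mc", "cov"]].sum()
        agg = agg[agg["cov"] > 0]
        out.loc[row.region_id, agg.index] = agg["mc"] / agg["cov"]
    return out


# ---------------------------------------------------------------- level t-tests


def _group_arrays(levels: pd.DataFrame, sample_groups: dict):
    groups = {}
    for s in levels.columns:
        g = sample_groups.get(s)
        if g is not None:
            groups.setdefault(g, []).append(s)
    return {g: levels[cols].to_numpy(dtype=float) for g, cols in groups.items()}


def _pairwise_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Row-wise two-sided t-test p-values between two (n_regions, n_i)
    arrays, NaN levels dropped pairwise.  Degenerate rows (either group < 2
    defined values, or zero pooled variance) give NaN."""
    import warnings

    with warnings.catch_warnings():
        # near-constant rows raise precision-loss warnings; their p-values
        # come out NaN/1 and are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    p[(n1 < 2) | (n2 < 2)] = np.nan
    return p


def filter_internal_control(
    levels: pd.DataFrame, sample_groups: dict, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Retain regions whose minimum pairwise-group t-test p-value is < alpha.

    Returns a frame indexed by region_id with one p-value column per group
    pair, ``min_p`` and the boolean ``retained``.  Regions where every pair
    is degenerate are dropped (retained = False, min_p = NaN).
    """
    arrs = _group_arrays(levels, sample_groups)
    names = sorted(arrs)
    if len(names) < 2:
        raise ValueError("need at least two groups with samples")
    out = pd.DataFrame(index=levels.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[f"p_{names[i]}_vs_{names[j]}"] = _pairwise_t(arrs[names[i]], arrs[names[j]], equal_var)
    out["min_p"] = out.min(axis=1, skipna=True)
    out["retained"] = out["min_p"] < alpha
    return out


def filter_external_control(
    levels: pd.DataFrame,
    sample_groups: dict,
    exposure_group: str,
    control_cohorts: tuple,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Control-consistency cascade for externally controlled exposures.

    Requires exactly three control cohorts.  A region is retained iff the
    exposure group differs from *each* control cohort (p < alpha) and no two
    control cohorts differ from each other (p > alpha).  All six t-tests are
    returned on the record.
    """
    if len(control_cohorts) != 3:
        raise ValueError("exactly three control cohorts are required")
    arrs = _group_arrays(levels, sample_groups)
    missing = [g for g in (exposure_group, *control_cohorts) if g not in arrs]
    if missing:
        raise ValueError(f"missing cohorts in levels: {missing}")
    out = pd.DataFrame(index=levels.index)
    exp_p = []
    for c in control_cohorts:
        p = _pairwise_t(arrs[exposure_group], arrs[c], equal_var)
        out[f"p_exposure_vs_{c}"] = p
        exp_p.append(p)
    ctl_p = []
    for i in range(3):
        for j in range(i + 1, 3):
            p = _pairwise_t(arrs[control_cohorts[i]], arrs[control_cohorts[j]], equal_var)
            out[f"p_{control_cohorts[i]}_vs_{control_cohorts[j]}"] = p
            ctl_p.append(p)
    exp_p, ctl_p = np.stack(exp_p), np.stack(ctl_p)
    ok = ~np.isnan(exp_p).any(axis=0) & ~np.isnan(ctl_p).any(axis=0)
    out["retained"] = ok & (exp_p < alpha).all(axis=0) & (ctl_p > alpha).all(axis=0)
    return out


def group_direction(levels: pd.DataFrame, sample_groups: dict) -> pd.DataFrame:
    """Hypo/hyper status per group: group mean level below/above the
    across-group mean of group means."""
    arrs = _group_arrays(levels, sample_groups)
    means = pd.DataFrame({g: np.nanmean(a, axis=1) for g, a in arrs.items()}, index=levels.index)
    center = means.mean(axis=1)
    status = means.lt(center, axis=0).replace({True: "hypo", False: "hyper"})
    return status.add_prefix("status_")


@dataclass
class ShuffleResult:
    observed_count: int
    shuffled_counts: np.ndarray
    percentile: float  # fraction of shuffles with count < observed

    @property
    def exceeds_95th(self) -> bool:
        return self.observed_count > np.percentile(self.shuffled_counts, 95)

    @property
    def within_central_95(self) -> bool:
        lo, hi = np.percentile(self.shuffled_counts, [2.5, 97.5])
        return lo <= self.observed_count <= hi


def shuffle_validate(
    levels: pd.DataFrame,
    sample_groups: dict,
    cascade,
    n_iterations: int = 200,
    seed: int = 0,
) -> ShuffleResult:
    """Compare the observed retained-region count against label shuffles.

    ``cascade`` is a callable (levels, sample_groups) -> record frame with a
    boolean ``retained`` column (e.g. a partial of filter_external_control).
    Group sizes are preserved: labels are permuted over the same sample set,
    within the exposure experiment at hand.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    samples = [s for s in levels.columns if s in sample_groups]
    labels = [sample_groups[s] for s in samples]
    observed = int(cascade(levels, sample_groups)["retained"].sum())
    rng = spawn_rng(seed, "shuffle")
    counts = np.empty(n_iterations, dtype=int)
    for it in range(n_iterations):
        perm = rng.permutation(labels)
        shuffled = dict(zip(samples, perm))
        counts[it] = int(cascade(levels, shuffled)["retained"].sum())
    pct = float(np.mean(counts < observed))
    return ShuffleResult(observed_count=observed, shuffled_counts=counts, percentile=pct)


# ---------------------------------------------------------------- effect sizes


def cohens_d(levels_g1, levels_g2) -> float:
    """Cohen's d with Bessel-corrected pooled standard deviation.

    d = (mean1 - mean2) / s_pooled,
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    Zero pooled sd -> NaN (undefined, never infinite).
    """
    x = np.asarray(levels_g1, dtype=float)
    y = np.asarray(levels_g2, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per group")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def pairwise_cohens_d(levels: pd.DataFrame, sample_groups: dict) -> pd.DataFrame:
    """The three (or k-choose-2) pairwise d values per region."""
    arrs = _group_arrays(levels, sample_groups)
    names = sorted(arrs)
    out = pd.DataFrame(index=levels.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrs[names[i]], arrs[names[j]]
            col = []
            for r in range(len(levels)):
                try:
                    col.append(cohens_d(a[r], b[r]))
                except ValueError:
                    col.append(np.nan)
            out[f"d_{names[i]}_vs_{names[j]}"] = col
    return out


# ---------------------------------------------------------------- covariates


def _covariate_design(metadata: pd.DataFrame, samples, columns=("age", "sex", "ancestry")):
    sub = metadata.loc[list(samples), list(columns)]
    num = pd.get_dummies(sub, drop_first=True, dtype=float)
    keep, names = [], []
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("constant covariate %s skipped", col)
            continue
        keep.append(v)
        names.append(col)
    return np.column_stack([np.ones(len(sub))] + keep), names


def covariate_association(
    levels: pd.DataFrame, metadata: pd.DataFrame, columns=("age", "sex", "ancestry")
) -> pd.DataFrame:
    """OLS of each region's levels on the covariates; per-covariate two-sided
    t p-values for the coefficients.  Metadata is indexed by sample id."""
    samples = [s for s in levels.columns if s in metadata.index]
    X, names = _covariate_design(metadata, samples)
    Y = levels[samples].to_numpy(dtype=float).T  # samples x regions
    n, k = X.shape
    dof = n - k
    if dof < 1:
        raise ValueError("not enough samples for the covariate design")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T

    out = pd.DataFrame(index=levels.index)
    complete = ~np.isnan(Y).any(axis=0)
    B = H @ np.where(np.isnan(Y), 0.0, Y)
    resid = Y - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pmat = 2 * stats.t.sf(np.abs(tstat), dof)
    for i, name in enumerate(names):
        col = pmat[i + 1]
        col = np.where(complete, col, np.nan)
        out[f"p_{name}"] = col

    # regions with missing samples: refit with the available rows
    for r in np.nonzero(~complete)[0]:
        y = Y[:, r]
        ok = ~np.isnan(y)
        if ok.sum() < k + 1:
            continue
        Xm = X[ok]
        bm, *_ = np.linalg.lstsq(Xm, y[ok], rcond=None)
        rm = y[ok] - Xm @ bm
        dofm = ok.sum() - k
        s2 = rm @ rm / dofm
        cov = np.linalg.pinv(Xm.T @ Xm) * s2
        tm = bm / np.sqrt(np.diag(cov))
        pm = 2 * stats.t.sf(np.abs(tm), dofm)
        for i, name in enumerate(names):
            out.iloc[r, out.columns.get_loc(f"p_{name}")] = pm[i + 1]
    return out


def filter_covariates(
    levels: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Exclude regions significantly associated with age, sex or ancestry.

    Returns the covariate p-value table with a boolean ``retained`` column:
    False iff any covariate coefficient has p < alpha.
    """
    assoc = covariate_association(levels, metadata)
    pcols = [c for c in assoc.columns if c.startswith("p_")]
    any_sig = (assoc[pcols] < alpha).any(axis=1)
    assoc["retained"] = ~any_sig
    return assoc


def ancestry_edmrs(
    levels: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Ancestry-associated regions after regressing out sex and age.

    Levels are residualized on age + sex, the residuals are tested for an
    ancestry association (OLS coefficient t-test, BH-corrected), and
    significant regions are flagged per ancestry contrast.
    """
    samples = [s for s in levels.columns if s in metadata.index]
    X, _ = _covariate_design(metadata, samples, columns=("age", "sex"))
    Y = levels[samples].to_numpy(dtype=float).T
    Y0 = np.where(np.isnan(Y), np.nanmean(Y, axis=0, keepdims=True), Y)
    Q, _ = np.linalg.qr(X)
    R = Y0 - Q @ (Q.T @ Y0)
    resid = pd.DataFrame(R.T, index=levels.index, columns=samples)
    assoc = covariate_association(resid, metadata, columns=("ancestry",))
    pcols = [c for c in assoc.columns if c.startswith("p_")]
    for c in pcols:
        assoc[c.replace("p_", "q_")] = bh_fdr(assoc[c])
    qcols = [c for c in assoc.columns if c.startswith("q_")]
    assoc["ancestry_associated"] = (assoc[qcols] < alpha).any(axis=1)
    return assoc
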