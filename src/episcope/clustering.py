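"""PCA + Leiden clustering of the binarized bin matrix, cell annotation by
global mCG, cluster-composition statistics and DMG identification."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_fdr, logger

DMG_FDR = 0.01
DMG_MIN_DELTA = 0.05


def cluster_cells(
    matrix,
    n_pcs: int = 32,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
    pcs: np.ndarray | None = None,
) -> pd.Series:
    """Cluster cells: PCA on the binarized matrix, kNN graph on the top PCs,
    Leiden community detection.  Deterministic given the seed.

    ``pcs`` accepts an externally corrected PC matrix (e.g. harmony output),
    bypassing the internal PCA.  Returns a cluster-id Series indexed by cell.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    if pcs is None:
        X = np.asarray(matrix.binarized, dtype=float)
        n_pcs_eff = min(n_pcs, min(X.shape) - 1)
        if n_pcs_eff < n_pcs:
            logger.warning("n_pcs reduced from %d to %d (matrix rank)", n_pcs, n_pcs_eff)
        pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=int(seed) % (2**31))
        pcs = pca.fit_transform(X - X.mean(axis=0))
    k = min(n_neighbors, len(pcs) - 1)
    adj = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = igraph.Graph(n=len(pcs), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed) % (2**31),
    )
    return pd.Series(part.membership, index=pd.Index(matrix.cells, name="cell_id"), name="cluster_id")


def annotate_by_global_mcg(
    clusters: pd.Series, global_mcg: pd.Series, facs_label: pd.Series
) -> pd.DataFrame:
    """Split B and NK lineages into naive vs memory/active by global mCG.

    Within each lineage, the cluster with the higher mean global mCG is the
    naive state; the lower is B-mem (B lineage) or NK-active (NK lineage).
    With more than two clusters, the highest-mCG cluster is naive and the
    rest take the lower label.  Ties break deterministically on cluster id
    (and are logged).  Other lineages keep their FACS label.
    """
    lineage_low = {"B": "B-mem", "NK": "NK-active"}
    df = pd.DataFrame(
        {"cluster_id": clusters, "global_mcg": global_mcg, "facs_label": facs_label}
    )
    df["final_label"] = df["facs_label"]
    for lineage, low_label in lineage_low.items():
        sub = df[df["facs_label"] == lineage]
        if sub.empty:
            continue
        means = sub.groupby("cluster_id")["global_mcg"].mean()
        if len(means) < 2:
            continue  # single cluster: lineage label retained
        ordered = means.sort_values(ascending=False, kind="mergesort")
        if len(means) > 1 and ordered.iloc[0] == ordered.iloc[1]:
            logger.warning("mCG tie in %s lineage; breaking by cluster id", lineage)
            ordered = means.loc[sorted(means.index)].sort_values(ascending=False, kind="mergesort")
        naive_cluster = ordered.index[0]
        lab = np.where(sub["cluster_id"] == naive_cluster, f"{lineage}-naive", low_label)
        df.loc[sub.index, "final_label"] = lab
    return df


def composition_fisher(annotation: pd.DataFrame, group_col: str = "group", cluster_col: str = "cluster_id") -> pd.DataFrame:
    """Per (cluster, group) 2x2 Fisher's exact enrichment of group cells in
    the cluster, BH-corrected across all tests.

    Table: [[in-cluster & in-group, in-cluster & out-group],
            [out-cluster & in-group, out-cluster & out-group]].
    Tests with an empty margin are skipped (recorded with NaN p).
    """
    groups = annotation[group_col].unique()
    clusters = annotation[cluster_col].unique()
    if len(groups) < 2 or len(clusters) < 2:
        raise ValueError("need >= 2 groups and >= 2 clusters")
    rows = []
    for cl in clusters:
        in_cl = annotation[cluster_col] == cl
        for g in groups:
            in_g = annotation[group_col] == g
            a = int((in_cl & in_g).sum())
            b = int((in_cl & ~in_g).sum())
            c = int((~in_cl & in_g).sum())
            d = int((~in_cl & ~in_g).sum())
            if min(a + b, c + d, a + c, b + d) == 0:
                logger.warning("cluster %s group %s: empty margin, test skipped", cl, g)
                rows.append((cl, g, a, b, c, d, np.nan, np.nan))
                continue
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((cl, g, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["cluster_id", "group", "a", "b", "c", "d", "odds_ratio", "p_value"]
    )
    out["fdr"] = bh_fdr(out["p_value"])
    return out


def composition_chisq(annotation: pd.DataFrame, group_col: str = "group", cluster_col: str = "cluster_id"):
    """Pearson chi-square (uncorrected) on the groups x clusters table."""
    table = pd.crosstab(annotation[group_col], annotation[cluster_col]).to_numpy()
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def identify_dmg(
    gene_mcg: pd.DataFrame,
    clusters: pd.Series,
    cluster_a,
    cluster_b,
    covariates: pd.DataFrame | None = None,
    min_cells: int = 3,
    fdr_threshold: float = DMG_FDR,
    min_delta: float = DMG_MIN_DELTA,
) -> pd.DataFrame:
    """Differentially methylated genes between two clusters.

    ``gene_mcg`` is genes x cells of gene-body mCG fractions (sum mc / sum
    cov per cell; NaN where uncovered).  Default test: two-sided Student's t
    on per-cell gene mCG.  With ``covariates`` (cells x age/sex/ethnicity),
    OLS of mCG on the cluster indicator plus covariates tests the indicator
    coefficient instead.  Genes covered in < ``min_cells`` cells in either
    cluster are skipped.  Reported genes satisfy FDR < 0.01 and
    |delta mCG| > 0.05.
    """
    cells_a = clusters.index[clusters == cluster_a]
    cells_b = clusters.index[clusters == cluster_b]
    A = gene_mcg[cells_a].to_numpy(dtype=float)
    B = gene_mcg[cells_b].to_numpy(dtype=float)
    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    testable = (na >= min_cells) & (nb >= min_cells)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gene rows
        delta = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    p = np.full(len(gene_mcg), np.nan)
    if covariates is None:
        res = stats.ttest_ind(A[testable], B[testable], axis=1, nan_policy="omit")
        p[testable] = res.pvalue
    else:
        cells = list(cells_a) + list(cells_b)
        indicator = np.array([1.0] * len(cells_a) + [0.0] * len(cells_b))
        cov = pd.get_dummies(covariates.loc[cells], drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(cells)), indicator, cov.to_numpy()])
        Y = gene_mcg[cells].to_numpy(dtype=float).T
        for gi in np.nonzero(testable)[0]:
            y = Y[:, gi]
            ok = ~np.isnan(y)
            dof = ok.sum() - X.shape[1]
            if dof < 1:
                continue
            b, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
            r = y[ok] - X[ok] @ b
            s2 = (r @ r) / dof
            covb = np.linalg.pinv(X[ok].T @ X[ok]) * s2
            se = np.sqrt(covb[1, 1])
            if se > 0:
                p[gi] = 2 * stats.t.sf(abs(b[1]) / se, dof)

    out = pd.DataFrame(
        {
            "gene_id": gene_mcg.index,
            "delta_mcg": delta,
            "p_value": p,
            "direction": np.where(delta > 0, "hyper", "hypo"),
        }
    )
    out["fdr"] = bh_fdr(out["p_value"])
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["delta_mcg"].abs() > min_delta)
    return out
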