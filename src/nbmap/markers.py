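"""Marker-gene statistics and differential expression for single-cell data.

The tf-idf marker statistic scores how specifically a gene marks a cluster:
``tfidf = tf * ln(1 / global_rate)`` where ``tf`` is the fraction of the
cluster's cells expressing the gene (count > 0) and ``global_rate`` the
fraction of all cells expressing it.  A cutoff ``t`` therefore admits a gene
exactly when ``global_rate < exp(-t / tf)``.  Significance comes from an
upper-tail hypergeometric test (drawing the cluster's cells from all cells,
successes being globally expressing cells) with Benjamini–Hochberg
correction.

Also provided: the stringent cell-type marker filter (tf-idf > 1 plus a
<=20% ceiling on expression in any other single cluster, with an extrinsic
negative-control cluster included), tumor-marker merging across two
datasets, Wilcoxon rank-sum DE with a 25% detection prefilter, and NB DE
with genewise (unshrunk) overdispersion for copy-number comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._nbglm import profile_ml_alpha, ql_f_test

__all__ = [
    "tfidf_score",
    "tfidf_markers",
    "stringent_cell_type_markers",
    "merge_tumor_markers",
    "ranksum_de",
    "nb_de_genewise",
    "hypergeometric_enrichment",
]


def tfidf_score(tf, global_rate):
    """tf-idf of a gene: in-cluster expressing fraction times ln(1/global rate).

    Zero when the gene is expressed globally in every cell (ln 1 = 0) or in
    none.  A cutoff ``t`` admits a gene exactly when
    ``global_rate < exp(-t / tf)``.
    """
    tf = np.asarray(tf, dtype=float)
    global_rate = np.asarray(global_rate, dtype=float)
    with np.errstate(divide="ignore"):
        idf = np.where(global_rate > 0, -np.log(global_rate), 0.0)
    return np.where(global_rate > 0, tf * idf, 0.0)


def _binary_matrix(adata) -> sp.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = sp.csr_matrix(X)
    return (X > 0).astype(np.int64)


def tfidf_markers(
    adata,
    clusters: pd.Series | np.ndarray,
    tfidf_cutoff: float = 1.0,
    p_cutoff: float = 0.01,
    return_all: bool = False,
) -> pd.DataFrame:
    """tf-idf marker table per gene × cluster with hypergeometric p-values.

    Returns rows with ``tfidf`` strictly above the cutoff and BH-adjusted p
    strictly below ``p_cutoff`` (or all rows with ``return_all``).
    """
    clusters = pd.Series(np.asarray(clusters), index=adata.obs_names).astype(
        getattr(clusters, "dtype", object)
    )
    if isinstance(clusters.dtype, pd.CategoricalDtype):
        counts_per = clusters.value_counts()
        empty = counts_per.index[counts_per == 0].tolist()
        if empty:
            raise ValueError(f"empty clusters: {empty}")
    B = _binary_matrix(adata)
    n_cells = adata.n_obs
    global_k = np.asarray(B.sum(axis=0)).ravel()  # expressing cells per gene
    global_rate = global_k / n_cells

    frames = []
    for cl, idx in clusters.groupby(clusters, observed=True).groups.items():
        rows = adata.obs_names.get_indexer(idx)
        if len(rows) == 0:
            raise ValueError(f"cluster '{cl}' is empty")
        k_in = np.asarray(B[rows].sum(axis=0)).ravel()
        tf = k_in / len(rows)
        tfidf = tfidf_score(tf, global_rate)
        p = hypergeom.sf(k_in - 1, n_cells, global_k, len(rows))
        frames.append(
            pd.DataFrame(
                {
                    "gene": adata.var_names,
                    "cluster": cl,
                    "tf": tf,
                    "global_rate": global_rate,
                    "tfidf": tfidf,
                    "p_raw": p,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    if return_all:
        return out
    return out[(out["tfidf"] > tfidf_cutoff) & (out["p_adj"] < p_cutoff)].reset_index(
        drop=True
    )


def expressing_fraction(adata, clusters) -> pd.DataFrame:
    """Fraction of cells expressing each gene (rows) per cluster (columns)."""
    clusters = pd.Series(np.asarray(clusters), index=adata.obs_names)
    B = _binary_matrix(adata)
    cols = {}
    for cl, idx in clusters.groupby(clusters, observed=True).groups.items():
        rows = adata.obs_names.get_indexer(idx)
        cols[cl] = np.asarray(B[rows].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=adata.var_names)


def stringent_cell_type_markers(
    adata,
    clusters,
    tfidf_cutoff: float = 1.0,
    p_cutoff: float = 0.01,
    other_max_fraction: float = 0.2,
    control_cluster: str = "podocyte",
) -> dict[str, list[str]]:
    """Most-specific markers per cluster with an extrinsic negative control.

    Keeps genes passing the tf-idf cutoff whose expressing fraction does not
    strictly exceed ``other_max_fraction`` in any other single cluster.  The
    control cluster (an unrelated extrinsic population) participates as a
    competitor like any other cluster; its absence is tolerated with a
    warning.
    """
    clusters = pd.Series(np.asarray(clusters), index=adata.obs_names)
    if control_cluster not in set(clusters):
        warnings.warn(
            f"negative-control cluster '{control_cluster}' not present; proceeding",
            stacklevel=2,
        )
    markers = tfidf_markers(adata, clusters, tfidf_cutoff, p_cutoff)
    frac = expressing_fraction(adata, clusters)
    out: dict[str, list[str]] = {}
    for cl in frac.columns:
        if cl == control_cluster:
            continue
        cand = markers.loc[markers["cluster"] == cl, "gene"]
        others = [c for c in frac.columns if c != cl]
        keep = [g for g in cand if not (frac.loc[g, others] > other_max_fraction).any()]
        out[cl] = keep
    return out


def merge_tumor_markers(
    list_a: pd.DataFrame,
    list_b: pd.DataFrame,
    tfidf_cutoff: float = 0.85,
    leukocyte_fraction: pd.Series | None = None,
    leukocyte_max: float = 0.25,
) -> pd.DataFrame:
    """Merge tumor-marker lists from two datasets by average tf-idf.

    A gene present in both lists contributes the mean of its two tf-idf
    values; a gene in only one list contributes its single value.  Genes are
    kept when the average strictly exceeds ``tfidf_cutoff`` and, if a
    leukocyte expressing fraction is supplied, when that fraction does not
    strictly exceed ``leukocyte_max``.
    """
    a = list_a.set_index("gene")["tfidf"]
    b = list_b.set_index("gene")["tfidf"]
    merged = pd.concat([a.rename("a"), b.rename("b")], axis=1)
    merged["avg_tfidf"] = merged[["a", "b"]].mean(axis=1, skipna=True)
    merged = merged[merged["avg_tfidf"] > tfidf_cutoff]
    if leukocyte_fraction is not None:
        lf = merged.index.map(lambda g: leukocyte_fraction.get(g, 0.0))
        merged = merged[~(np.asarray(lf) > leukocyte_max)]
    out = merged.reset_index()[["gene", "avg_tfidf"]]
    return out.sort_values("avg_tfidf", ascending=False).reset_index(drop=True)


def _log2fc_of_means(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    # Seurat-style fold change of de-logged normalized means with pseudocount 1
    return np.log2(norm_a + 1.0) - np.log2(norm_b + 1.0)


def ranksum_de(
    adata,
    group_a,
    group_b,
    min_detect: float = 0.25,
    p_cutoff: float = 0.01,
    return_all: bool = False,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE on log-normalized expression.

    Genes must be detected (count > 0) in at least ``min_detect`` of the
    cells of at least one group to be tested; constant genes get p = 1.
    ``log2fc`` compares de-logged normalized group means (pseudocount 1).
    """
    idx_a = adata.obs_names.get_indexer(pd.Index(group_a))
    idx_b = adata.obs_names.get_indexer(pd.Index(group_b))
    if (idx_a < 0).any() or (idx_b < 0).any():
        raise ValueError("group contains unknown cells")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each group needs at least 3 cells")

    X = sp.csr_matrix(adata.X, dtype=float)
    B = _binary_matrix(adata)
    det_a = np.asarray(B[idx_a].mean(axis=0)).ravel()
    det_b = np.asarray(B[idx_b].mean(axis=0)).ravel()
    testable = np.maximum(det_a, det_b) >= min_detect

    Xa = X[idx_a].toarray()
    Xb = X[idx_b].toarray()
    genes = np.asarray(adata.var_names)
    rows = []
    for gi in np.flatnonzero(testable):
        a, b = Xa[:, gi], Xb[:, gi]
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "gene": genes[gi],
                "log2fc": float(
                    _log2fc_of_means(np.expm1(a).mean(), np.expm1(b).mean())
                ),
                "statistic": stat,
                "p_raw": p,
                "detected_a": det_a[gi],
                "detected_b": det_b[gi],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "log2fc", "statistic", "p_raw", "detected_a", "detected_b"],
    )
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    if return_all:
        return out
    return out[out["p_adj"] < p_cutoff].reset_index(drop=True)


def nb_de_genewise(
    adata,
    group_a,
    group_b,
    g1_only: bool = False,
    min_cells: int = 10,
) -> pd.DataFrame:
    """NB DE with genewise maximum-likelihood overdispersion (no shrinkage).

    Fits, per gene, an NB GLM of raw counts on a group indicator with a
    log-library-size offset; the overdispersion is estimated independently
    for each gene by profile maximum likelihood (deliberately no information
    sharing between genes — appropriate when both groups are large enough to
    estimate genewise dispersion robustly), and the group effect is assessed
    with a quasi-likelihood F test.  With ``g1_only`` the comparison is
    restricted to G0/G1 cells (S and G2-M scores <= 0) to avoid confounding
    with proliferation.

    Constant-zero genes are reported with status ``all_zero`` and excluded
    from testing; tested genes have status ``ok``.
    """
    obs = adata.obs
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if g1_only:
        for col in ("s_score", "g2m_score"):
            if col not in obs:
                raise ValueError(f"g1_only requires obs['{col}']")
        g1 = set(obs.index[(obs["s_score"] <= 0) & (obs["g2m_score"] <= 0)])
        group_a = [c for c in group_a if c in g1]
        group_b = [c for c in group_b if c in g1]
    if len(group_a) < min_cells or len(group_b) < min_cells:
        raise ValueError(
            f"groups need >= {min_cells} cells each to estimate genewise "
            "overdispersion; use the fixed-dispersion bulk model for smaller groups"
        )
    idx_a = adata.obs_names.get_indexer(pd.Index(group_a))
    idx_b = adata.obs_names.get_indexer(pd.Index(group_b))
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = sp.csr_matrix(counts)
    sub = counts[np.concatenate([idx_a, idx_b])].toarray()
    group = np.r_[np.ones(len(idx_a)), np.zeros(len(idx_b))]
    libsize = sub.sum(axis=1)
    if np.any(libsize == 0):
        raise ValueError("cells with zero counts present")
    offset = np.log(libsize)
    X_full = np.column_stack([np.ones_like(group), group])
    X_red = X_full[:, :1]

    genes = np.asarray(adata.var_names)
    rows = []
    for gi in range(sub.shape[1]):
        y = sub[:, gi]
        if y.sum() == 0:
            rows.append({"gene": genes[gi], "status": "all_zero", "log2fc": np.nan,
                         "statistic": np.nan, "p_raw": np.nan, "dispersion": np.nan,
                         "detected_a": 0.0, "detected_b": 0.0})
            continue
        alpha = profile_ml_alpha(y, X_full, offset=offset)
        res = ql_f_test(y, X_full, X_red, alpha, offset=offset)
        rows.append(
            {
                "gene": genes[gi],
                "status": "ok",
                "log2fc": float(res["params"][1] / np.log(2)),
                "statistic": res["f_stat"],
                "p_raw": res["p_value"],
                "dispersion": alpha,
                "detected_a": float((y[: len(idx_a)] > 0).mean()),
                "detected_b": float((y[len(idx_a):] > 0).mean()),
            }
        )
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
    return out


def hypergeometric_enrichment(hit_list, marker_set, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of >= the observed overlap.

    ``hit_list`` and ``marker_set`` must be subsets of ``universe``; returns
    (overlap size, p-value).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hits = set(hit_list)
    markers = set(marker_set)
    if not hits <= universe or not markers <= universe:
        raise ValueError("hit list and marker set must be subsets of the universe")
    overlap = len(hits & markers)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(markers), len(hits)))
    return overlap, p
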