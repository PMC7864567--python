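"""Cell-level quality control, cluster-level failure rule, and normalization.

Three platform presets mirror the filtering rules of droplet reference data,
droplet tumor data and plate-based tumor data:

=============  ====  =========  ========  =======  ============  =======
preset         mito  min genes  min UMIs  doublet  cluster rule  cycling
=============  ====  =========  ========  =======  ============  =======
``adrenal``    0.30  300        1000      0.2      >50% fail     yes
``tumor10x``   0.20  300        1000      —        —             no
``tumorplate`` 0.20  200        500       —        —             no
=============  ====  =========  ========  =======  ============  =======

All thresholds are strict: a mitochondrial fraction of exactly 0.30 passes,
exactly 300 genes passes, a cell-cycle score of exactly 0 is kept.  The
cluster rule marks every cell of a high-resolution cluster as failing when
the cluster's individually-failing fraction strictly exceeds 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "PRESETS",
    "flag_cells",
    "apply_cluster_rule",
    "filter_cell_cycle",
    "normalize_log",
    "run_qc",
    "cluster_cells",
]


@dataclass(frozen=True)
class QCThresholds:
    max_mito_fraction: float
    min_genes: int
    min_umis: int
    max_doublet_score: float | None = None
    cluster_fail_fraction: float | None = None
    exclude_cycling: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.min_genes < 0 or self.min_umis < 0:
            raise ValueError("min_genes and min_umis must be >= 0")
        if self.cluster_fail_fraction is not None and not (
            0.0 <= self.cluster_fail_fraction <= 1.0
        ):
            raise ValueError("cluster_fail_fraction must lie in [0, 1]")


PRESETS: dict[str, QCThresholds] = {
    "adrenal": QCThresholds(0.30, 300, 1000, max_doublet_score=0.2,
                            cluster_fail_fraction=0.5, exclude_cycling=True),
    "tumor10x": QCThresholds(0.20, 300, 1000),
    "tumorplate": QCThresholds(0.20, 200, 500),
}


def _ensure_detection_columns(adata: ad.AnnData) -> None:
    X = adata.X
    if "n_genes_detected" not in adata.obs:
        adata.obs["n_genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    if "n_umis" not in adata.obs:
        adata.obs["n_umis"] = np.asarray(X.sum(axis=1)).ravel()


def _add_reason(adata: ad.AnnData, mask: np.ndarray, reason: str) -> None:
    reasons = adata.obs["qc_fail_reasons"].to_numpy(dtype=object)
    for i in np.flatnonzero(mask):
        cur = reasons[i]
        parts = set(cur.split(";")) if cur else set()
        parts.add(reason)
        reasons[i] = ";".join(sorted(parts))
    adata.obs["qc_fail_reasons"] = reasons
    adata.obs["qc_pass"] = adata.obs["qc_fail_reasons"] == ""


def flag_cells(adata: ad.AnnData, thresholds: QCThresholds) -> ad.AnnData:
    """Label each cell pass/fail against the per-cell thresholds.

    Failing reasons accumulate in ``obs['qc_fail_reasons']`` (semicolon
    separated, sorted); ``obs['qc_pass']`` holds the verdict.  Idempotent.
    """
    adata = adata.copy()
    _ensure_detection_columns(adata)
    if "mito_fraction" not in adata.obs:
        raise ValueError("obs['mito_fraction'] is required")
    if "qc_fail_reasons" not in adata.obs:
        adata.obs["qc_fail_reasons"] = ""
        adata.obs["qc_pass"] = True
    # drop stale per-cell reasons so the operation is idempotent
    cleaned = [
        ";".join(p for p in r.split(";") if p in ("cluster", "cycling")) if r else ""
        for r in adata.obs["qc_fail_reasons"]
    ]
    adata.obs["qc_fail_reasons"] = cleaned

    _add_reason(adata, adata.obs["mito_fraction"].to_numpy() > thresholds.max_mito_fraction, "mito")
    _add_reason(adata, adata.obs["n_genes_detected"].to_numpy() < thresholds.min_genes, "genes")
    _add_reason(adata, adata.obs["n_umis"].to_numpy() < thresholds.min_umis, "umis")
    if thresholds.max_doublet_score is not None:
        if "doublet_score" not in adata.obs or adata.obs["doublet_score"].isna().any():
            bad = (
                adata.obs.index[adata.obs["doublet_score"].isna()].tolist()
                if "doublet_score" in adata.obs
                else list(adata.obs.index)
            )
            raise ValueError(f"doublet_score missing for cells: {bad[:5]}")
        _add_reason(
            adata,
            adata.obs["doublet_score"].to_numpy() > thresholds.max_doublet_score,
            "doublet",
        )
    _add_reason(adata, np.zeros(adata.n_obs, dtype=bool), "")  # refresh qc_pass
    return adata


def apply_cluster_rule(adata: ad.AnnData, thresholds: QCThresholds) -> ad.AnnData:
    """Fail every cell of a cluster whose individual-failure fraction strictly
    exceeds ``cluster_fail_fraction``.

    Requires high-resolution cluster labels in ``obs['cluster']`` and prior
    :func:`flag_cells` flags.  Per-cell reasons other than the cluster rule
    itself count toward the fraction.
    """
    if thresholds.cluster_fail_fraction is None:
        return adata.copy()
    adata = adata.copy()
    if "cluster" not in adata.obs or adata.obs["cluster"].isna().any():
        raise ValueError("all cells need a cluster label for the cluster-level rule")
    if "qc_fail_reasons" not in adata.obs:
        raise ValueError("run flag_cells first")
    individual_fail = np.array(
        [bool(set(r.split(";")) - {"", "cluster"}) for r in adata.obs["qc_fail_reasons"]]
    )
    frac = pd.Series(individual_fail, index=adata.obs.index).groupby(
        adata.obs["cluster"], observed=True
    ).mean()
    bad_clusters = frac.index[frac > thresholds.cluster_fail_fraction]
    mask = adata.obs["cluster"].isin(bad_clusters).to_numpy()
    _add_reason(adata, mask, "cluster")
    return adata


def filter_cell_cycle(adata: ad.AnnData) -> ad.AnnData:
    """Flag cycling cells: S or G2-M score strictly greater than 0 fails."""
    adata = adata.copy()
    for col in ("s_score", "g2m_score"):
        if col not in adata.obs or adata.obs[col].isna().any():
            raise ValueError(f"obs['{col}'] missing or incomplete")
    if "qc_fail_reasons" not in adata.obs:
        adata.obs["qc_fail_reasons"] = ""
        adata.obs["qc_pass"] = True
    mask = (adata.obs["s_score"].to_numpy() > 0) | (adata.obs["g2m_score"].to_numpy() > 0)
    _add_reason(adata, mask, "cycling")
    return adata


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Depth-normalize to 10,000 counts per cell and log-transform.

    ``value = ln(1 + 10000 * count / cell_total)``.  Raw counts are kept in
    ``layers['counts']``.  Cells with zero total counts are rejected.
    """
    adata = adata.copy()
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        zero = adata.obs.index[totals == 0].tolist()
        raise ValueError(f"cells with zero counts cannot be normalized: {zero[:5]}")
    adata.layers["counts"] = adata.X.copy()
    scaled = sp.diags(1e4 / totals) @ X
    scaled.data = np.log1p(scaled.data)
    adata.X = scaled
    return adata


def run_qc(
    adata: ad.AnnData,
    preset: str | QCThresholds = "adrenal",
    subset: bool = True,
    normalize: bool = True,
) -> ad.AnnData:
    """Compose the full QC: per-cell flags, cluster rule, cycling filter.

    With ``subset`` the failing cells are removed; with ``normalize`` the
    survivors are depth-normalized and log-transformed.
    """
    thresholds = PRESETS[preset] if isinstance(preset, str) else preset
    adata = flag_cells(adata, thresholds)
    if thresholds.cluster_fail_fraction is not None and "cluster" in adata.obs:
        adata = apply_cluster_rule(adata, thresholds)
    if thresholds.exclude_cycling:
        adata = filter_cell_cycle(adata)
    if subset:
        adata = adata[adata.obs["qc_pass"]].copy()
    if normalize:
        adata = normalize_log(adata)
    return adata


def cluster_cells(adata: ad.AnnData, resolution: float = 10.0, seed: int = 0,
                  n_pcs: int = 30) -> ad.AnnData:
    """High-resolution graph clustering (plumbing, delegated to scanpy).

    Log-normalizes a working copy, runs PCA → kNN graph → Leiden at the given
    resolution, and writes the labels into ``obs['cluster']`` of a copy of
    the input.  Very high resolutions deliberately over-partition the data so
    the cluster-level QC rule can act on small homogeneous groups.
    """
    import scanpy as sc

    work = adata.copy()
    sc.pp.normalize_total(work, target_sum=1e4)
    sc.pp.log1p(work)
    n_pcs = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
    sc.pp.pca(work, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(work, n_pcs=n_pcs, random_state=seed)
    sc.tl.leiden(
        work, resolution=resolution, random_state=seed, key_added="cluster",
        flavor="igraph", n_iterations=2, directed=False,
    )
    out = adata.copy()
    out.obs["cluster"] = work.obs["cluster"].to_numpy()
    return out
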