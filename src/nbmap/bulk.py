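"""Fetal cell-type signal in bulk RNA-seq cohorts.

A gene counts as "present" in a bulk sample when its log2(TPM) exceeds the
peak (KDE mode) of the pooled log2(TPM) distribution across all genes and
samples.  On top of that presence rule the module offers per-marker-set
presence fractions (optionally stratified by risk group), the two-rule
age/MYCN/stage risk stratification, the extra-adrenal site filter, a
fixed-dispersion NB GLM for risk-dependent expression, and the ranking of
fetal-cancer transcripts by expression outside the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.stats.multitest import multipletests

from ._nbglm import ql_f_test

__all__ = [
    "BulkCohort",
    "presence_threshold",
    "marker_presence_fraction",
    "stratify_risk_seqc",
    "filter_extra_adrenal",
    "nb_glm_fixed_dispersion",
    "fetal_cancer_transcripts",
    "EXTRA_ADRENAL_STOP_WORDS",
]

EXTRA_ADRENAL_STOP_WORDS = (
    "kidney",
    "adrenal",
    "abdominal",
    "abdomen",
    "unknown",
    "retroperitoneum",
    "other",
)


@dataclass
class BulkCohort:
    """Sample-by-gene TPM with clinical covariates (and optional raw counts).

    ``tpm`` rows are samples and must each sum to ~10^6; ``covariates`` is
    keyed 1:1 to samples (columns such as age_months, mycn_status, stage,
    risk, site_description); ``tissue`` labels normal-tissue panels.
    """

    tpm: pd.DataFrame
    covariates: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    tissue: pd.Series | None = None

    def __post_init__(self) -> None:
        sums = self.tpm.sum(axis=1)
        nonzero = sums[sums > 0]
        if len(nonzero) and not np.allclose(nonzero, 1e6, rtol=1e-3):
            raise ValueError("TPM rows must sum to 1e6")
        if self.covariates is not None and not self.covariates.index.equals(
            self.tpm.index
        ):
            raise ValueError("covariates must be keyed 1:1 to samples")


def _tpm_of(cohort) -> pd.DataFrame:
    return cohort.tpm if isinstance(cohort, BulkCohort) else pd.DataFrame(cohort)


def presence_threshold(cohort) -> float:
    """Peak of the pooled log2(TPM) distribution over strictly positive values.

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth) evaluated
    on a fine grid; a degenerate point mass returns its log2 value directly.
    Requires at least 100 positive entries.
    """
    tpm = _tpm_of(cohort)
    vals = tpm.to_numpy().ravel()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("all TPM entries are zero")
    if pos.size < 100:
        raise ValueError("need at least 100 positive TPM entries")
    logv = np.log2(pos)
    if np.ptp(logv) == 0:
        return float(logv[0])
    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min(), logv.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


def marker_presence_fraction(
    cohort,
    marker_sets: dict[str, list[str]],
    strata: pd.Series | None = None,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene presence fractions for each marker set, plus set summaries.

    ``present`` means log2(TPM) strictly above the threshold.  Returns a
    per-gene table (marker set, gene, stratum, fraction, status) and a
    summary with the median and interquartile range of the per-gene
    fractions within each set × stratum; marker genes absent from the cohort
    are recorded as missing and excluded from summaries.
    """
    tpm = _tpm_of(cohort)
    if threshold is None:
        threshold = presence_threshold(cohort)
    present = tpm > 2.0**threshold

    if strata is None:
        strata_groups = {"all": tpm.index}
    else:
        strata = pd.Series(strata).reindex(tpm.index)
        strata_groups = {
            str(k): idx for k, idx in strata.groupby(strata, observed=True).groups.items()
        }

    rows = []
    for set_name, genes in marker_sets.items():
        for g in genes:
            if g not in tpm.columns:
                rows.append({"marker_set": set_name, "gene": g, "stratum": "all",
                             "fraction_present": np.nan, "status": "missing"})
                continue
            for stratum, samples in strata_groups.items():
                rows.append(
                    {
                        "marker_set": set_name,
                        "gene": g,
                        "stratum": stratum,
                        "fraction_present": float(present.loc[samples, g].mean()),
                        "status": "ok",
                    }
                )
    per_gene = pd.DataFrame(
        rows, columns=["marker_set", "gene", "stratum", "fraction_present", "status"]
    )
    ok = per_gene[per_gene["status"] == "ok"]
    summary = (
        ok.groupby(["marker_set", "stratum"])["fraction_present"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n_genes="count",
        )
        .reset_index()
    )
    return per_gene, summary


def stratify_risk_seqc(cohort) -> pd.DataFrame:
    """Two-rule risk stratification from age, MYCN status and stage.

    low: age at diagnosis < 18 months and MYCN-negative, excluding stage 4S.
    high: age > 18 months and MYCN-positive, excluding stage 4S.
    Everything else (including exactly 18 months, stage 4S, or missing
    covariates) is unclassified, with the reason recorded.
    """
    cov = cohort.covariates if isinstance(cohort, BulkCohort) else cohort
    out = []
    for sample, row in cov.iterrows():
        age = row.get("age_months")
        mycn = row.get("mycn_status")
        stage = str(row.get("stage", ""))
        if pd.isna(age) or pd.isna(mycn) or mycn not in ("pos", "neg"):
            out.append((sample, "unclassified", "missing_covariate"))
            continue
        if stage.upper() == "4S":
            out.append((sample, "unclassified", "stage_4S"))
            continue
        if age < 18 and mycn == "neg":
            out.append((sample, "low", ""))
        elif age > 18 and mycn == "pos":
            out.append((sample, "high", ""))
        else:
            out.append((sample, "unclassified", "no_rule"))
    return pd.DataFrame(out, columns=["sample", "risk", "reason"]).set_index("sample")


def filter_extra_adrenal(cohort) -> pd.Index:
    """Samples whose site description marks an extra-adrenal tumor.

    Retains samples with a non-empty description containing none of the
    seven stop-words (case-insensitive substring match): kidney, adrenal,
    abdominal, abdomen, unknown, retroperitoneum, other.
    """
    cov = cohort.covariates if isinstance(cohort, BulkCohort) else cohort
    desc = cov["site_description"]
    keep = []
    for sample, d in desc.items():
        if pd.isna(d) or str(d).strip() == "":
            continue
        low = str(d).lower()
        if any(w in low for w in EXTRA_ADRENAL_STOP_WORDS):
            continue
        keep.append(sample)
    return pd.Index(keep)


def _design_matrices(covariates: pd.DataFrame, test_var: str):
    parts, names = [], []
    parts.append(np.ones(len(covariates)))
    names.append("(intercept)")
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(dtype=float))
            names.append(col)
        else:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:  # first level is the baseline
                parts.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
    X = np.column_stack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        kept = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    test_cols = [j for j, n in enumerate(names) if n == test_var or n.startswith(f"{test_var}[")]
    if not test_cols:
        raise ValueError(f"test variable '{test_var}' not in the design")
    keep_cols = [j for j in range(X.shape[1]) if j not in test_cols]
    return X, X[:, keep_cols], names, test_cols


def nb_glm_fixed_dispersion(
    cohort,
    covariates: pd.DataFrame | None = None,
    sqrt_dispersion: float = 0.4,
    test_var: str = "risk",
    log2fc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB regression at fixed overdispersion with a QL F test.

    The overdispersion is fixed at ``sqrt_dispersion**2`` (default 0.4 on the
    square-root scale), the device used when genuine biological replicates
    are unavailable.  The model includes a log-library-size offset and all
    covariate columns (categoricals are dummy-coded); the ``test_var``
    coefficient(s) are tested by a quasi-likelihood F test and BH-adjusted.
    The ``significant`` flag applies the reporting rule |log2FC| > 1 and
    FDR < 0.05.

    Raw counts are required: a cohort with only TPM refuses to run, as TPM
    values are not valid NB observations.
    """
    if isinstance(cohort, BulkCohort):
        counts = cohort.counts
        covariates = cohort.covariates[["age_months", "mycn_status", "risk"]] \
            if covariates is None and cohort.covariates is not None else covariates
    else:
        counts = cohort
    if counts is None:
        raise ValueError(
            "raw counts are required for the NB model; TPM alone cannot be used"
        )
    if covariates is None:
        raise ValueError("covariates are required")
    covariates = covariates.loc[counts.index]
    X_full, X_red, names, test_cols = _design_matrices(covariates, test_var)
    alpha = float(sqrt_dispersion) ** 2
    libsize = counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(libsize == 0):
        raise ValueError("samples with zero total counts present")
    offset = np.log(libsize)

    rows = []
    Y = counts.to_numpy()
    for gi, gene in enumerate(counts.columns):
        y = Y[:, gi]
        if y.sum() == 0:
            rows.append({"gene": gene, "status": "all_zero", "log2fc": np.nan,
                         "statistic": np.nan, "p_raw": np.nan})
            continue
        res = ql_f_test(y, X_full, X_red, alpha, offset=offset)
        # single-column test variables report a signed log2 fold change
        lfc = res["params"][test_cols[0]] / np.log(2) if len(test_cols) == 1 else np.nan
        rows.append({"gene": gene, "status": "ok", "log2fc": float(lfc),
                     "contrast": names[test_cols[0]] if len(test_cols) == 1 else test_var,
                     "statistic": res["f_stat"], "p_raw": res["p_value"]})
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
    out["significant"] = (
        ok & (out["log2fc"].abs() > log2fc_cutoff) & (out["p_adj"] < fdr_cutoff)
    )
    return out


def fetal_cancer_transcripts(
    cancer_markers: dict[str, pd.DataFrame],
    medulla_fraction: pd.Series,
    normal_panel: BulkCohort,
    brain_label: str = "brain",
    min_cancer_fraction: float = 0.5,
    max_other_fraction: float = 0.2,
    min_medulla_fraction: float = 0.1,
    top_k: int = 25,
) -> pd.DataFrame:
    """Rank shared cancer/fetal transcripts by expression outside the brain.

    ``cancer_markers`` maps each tumor dataset to a table with columns
    ``gene``, ``cancer_fraction`` (fraction of cancer cells expressing) and
    ``max_other_fraction`` (highest expressing fraction in any other single
    cluster of that dataset).  Within each dataset, genes expressed in fewer
    than 50% of cancer cells or in more than 20% of any other cluster are
    removed; the per-dataset lists are intersected; genes expressed in fewer
    than 10% of adrenal medullary cells are removed; the survivors are sorted
    by increasing mean log2(TPM + 1) over the panel's non-brain tissues.
    """
    if len(cancer_markers) < 2:
        raise ValueError("marker stats for both tumor datasets are required")
    surviving = None
    for name, df in cancer_markers.items():
        keep = set(
            df.loc[
                (df["cancer_fraction"] >= min_cancer_fraction)
                & ~(df["max_other_fraction"] > max_other_fraction),
                "gene",
            ]
        )
        surviving = keep if surviving is None else (surviving & keep)
    genes = sorted(
        g for g in surviving if medulla_fraction.get(g, 0.0) >= min_medulla_fraction
    )
    if not genes:
        return pd.DataFrame(columns=["gene", "mean_log2_tpm_outside_brain"])

    if normal_panel.tissue is None:
        raise ValueError("normal panel needs tissue labels")
    non_brain = normal_panel.tissue.index[normal_panel.tissue != brain_label]
    tpm = normal_panel.tpm.loc[non_brain]
    present = [g for g in genes if g in tpm.columns]
    means = np.log2(tpm[present] + 1.0).mean(axis=0)
    out = (
        pd.DataFrame({"gene": present, "mean_log2_tpm_outside_brain": means.to_numpy()})
        .sort_values(["mean_log2_tpm_outside_brain", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out.head(top_k)
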