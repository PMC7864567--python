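"""Logistic-regression similarity scoring of query cells against a reference.

One elastic-net-penalized logistic model is trained per reference cell type
(one-vs-rest, mixing parameter alpha = 0.99 by default) on log-normalized
expression.  Query cells are scored on the raw logit scale with no softmax
across classes, so a cell that resembles none of the reference types scores
negative for every class; a logit of 0 carries no information.  Per-cluster
summaries are arithmetic means of member-cell logits.

Regularization strength is chosen per class by K-fold cross-validated
deviance with a one-standard-error rule (the strongest penalty whose mean
deviance is within one SE of the minimum), glmnet-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = ["ReferenceModel", "SimilarityScores", "train_reference_model",
           "score_cells", "kmeans_split_scores"]


@dataclass
class ReferenceModel:
    """Per-cell-type elastic-net logistic coefficients over a shared gene list."""

    class_labels: list[str]
    gene_list: list[str]
    coefficients: np.ndarray  # (n_classes, n_genes)
    intercepts: np.ndarray  # (n_classes,)
    alpha: float
    lambdas: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.coefficients.shape != (len(self.class_labels), len(self.gene_list)):
            raise ValueError("coefficient matrix shape mismatch")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        rows = []
        for ci, cls in enumerate(self.class_labels):
            rows.append({"gene": "(intercept)", "class": cls,
                         "coefficient": self.intercepts[ci],
                         "alpha": self.alpha,
                         "lambda": self.lambdas[ci] if len(self.lambdas) else np.nan})
            for gi, g in enumerate(self.gene_list):
                rows.append({"gene": g, "class": cls,
                             "coefficient": self.coefficients[ci, gi],
                             "alpha": self.alpha,
                             "lambda": self.lambdas[ci] if len(self.lambdas) else np.nan})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceModel":
        df = pd.read_csv(path, sep="\t")
        classes = list(pd.unique(df["class"]))
        genes = [g for g in pd.unique(df["gene"]) if g != "(intercept)"]
        coef = np.zeros((len(classes), len(genes)))
        inter = np.zeros(len(classes))
        lambdas = np.zeros(len(classes))
        gidx = {g: i for i, g in enumerate(genes)}
        for ci, c in enumerate(classes):
            sub = df[df["class"] == c]
            lambdas[ci] = sub["lambda"].iloc[0]
            for rec in sub.itertuples(index=False):
                if rec.gene == "(intercept)":
                    inter[ci] = rec.coefficient
                else:
                    coef[ci, gidx[rec.gene]] = rec.coefficient
        return cls(classes, genes, coef, inter, float(df["alpha"].iloc[0]), lambdas)


@dataclass
class SimilarityScores:
    """Raw per-cell logits (cells × classes) and optional cluster means."""

    cell_logits: pd.DataFrame
    cluster_mean_logits: pd.DataFrame | None = None

    def with_cluster_means(self, clusters: pd.Series | dict) -> "SimilarityScores":
        clusters = pd.Series(clusters).reindex(self.cell_logits.index)
        if clusters.isna().any():
            raise ValueError("every scored cell needs a cluster label")
        means = self.cell_logits.groupby(clusters, observed=True).mean()
        return SimilarityScores(self.cell_logits, means)


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    # glmnet-style: lambda_max is the smallest penalty that zeroes all
    # coefficients, computed on standardized features
    n = len(y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    resid = y - y.mean()
    lam_max = np.max(np.abs(((X - mu) / sd).T @ resid)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def _path_fit(X, y, alpha, lambdas, seed) -> list[tuple[np.ndarray, float]]:
    """Elastic-net logistic fits along a decreasing lambda path.

    Features are standardized before penalization (the glmnet convention,
    which also conditions the saga solver well) and coefficients are mapped
    back to the original scale.  Fits are warm-started from the previous,
    stronger penalty.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LogisticRegression(
        l1_ratio=alpha, C=1.0, solver="saga",
        max_iter=1500, tol=3e-4, random_state=seed, warm_start=True,
    )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in lambdas:
            clf.C = 1.0 / (len(y) * lam)
            clf.fit(Xs, y)
            coef = clf.coef_.ravel() / sd
            intercept = float(clf.intercept_[0] - np.dot(clf.coef_.ravel(), mu / sd))
            out.append((coef.copy(), intercept))
    return out


def _fit_binary(X, y, alpha, lam, seed) -> tuple[np.ndarray, float]:
    return _path_fit(X, y, alpha, [lam], seed)[0]


def train_reference_model(
    reference,
    labels: pd.Series | np.ndarray,
    alpha: float = 0.99,
    n_lambda: int = 8,
    n_folds: int = 3,
    min_cells: int = 10,
    lambda_: float | None = None,
    seed: int = 0,
) -> ReferenceModel:
    """Train one-vs-rest elastic-net logistic models on a labeled reference.

    Parameters
    ----------
    reference
        AnnData (cells × genes) holding log-normalized expression in ``.X``,
        or a (matrix, gene_names) pair.
    labels
        Cell-type label per reference cell (>= 2 classes, each with at least
        ``min_cells`` cells).
    alpha
        Elastic-net mixing parameter (1 = lasso); default 0.99.
    lambda_
        Fixed regularization strength; when None, chosen per class by
        ``n_folds``-fold CV deviance with the one-SE rule over an
        ``n_lambda``-point path.
    """
    if hasattr(reference, "X"):
        X = _as_dense(reference.X)
        genes = list(reference.var_names)
    else:
        X, genes = reference
        X = _as_dense(X)
        genes = list(genes)
    labels = np.asarray(pd.Series(labels).astype(str))
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        n_c = int((labels == c).sum())
        if n_c < min_cells:
            raise ValueError(f"class '{c}' has only {n_c} cells (minimum {min_cells})")

    coef = np.zeros((len(classes), len(genes)))
    inter = np.zeros(len(classes))
    lambdas = np.zeros(len(classes))
    for ci, c in enumerate(classes):
        y = (labels == c).astype(int)
        if lambda_ is not None:
            lam = float(lambda_)
        else:
            path = _lambda_path(X, y, alpha, n_lambda)
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            losses = np.zeros((n_lambda, n_folds))
            for fi, (tr, va) in enumerate(cv.split(X, y)):
                fits = _path_fit(X[tr], y[tr], alpha, path, seed)
                for li, (w, b) in enumerate(fits):
                    p = 1.0 / (1.0 + np.exp(-np.clip(X[va] @ w + b, -500, 500)))
                    losses[li, fi] = log_loss(y[va], p, labels=[0, 1])
            mean = losses.mean(axis=1)
            se = losses.std(axis=1, ddof=1) / np.sqrt(n_folds)
            best = int(np.argmin(mean))
            within = np.flatnonzero(mean <= mean[best] + se[best])
            lam = float(path[within.min()])  # strongest penalty within one SE
        w, b = _fit_binary(X, y, alpha, lam, seed)
        coef[ci] = w
        inter[ci] = b
        lambdas[ci] = lam
    return ReferenceModel(classes, genes, coef, inter, alpha, lambdas)


def score_cells(model: ReferenceModel, query) -> SimilarityScores:
    """Score query cells on the raw logit scale for every reference class.

    Query genes are aligned to the model's gene list; genes absent from the
    query contribute zero.  No normalization is applied across classes.
    """
    if hasattr(query, "X"):
        X = _as_dense(query.X)
        genes = list(query.var_names)
        cells = list(query.obs_names)
    else:
        X, genes, cells = query
        X = _as_dense(X)
    gidx = {g: i for i, g in enumerate(genes)}
    shared = [g for g in model.gene_list if g in gidx]
    if not shared:
        raise ValueError("query shares no genes with the model gene list")
    aligned = np.zeros((X.shape[0], len(model.gene_list)))
    for mi, g in enumerate(model.gene_list):
        if g in gidx:
            aligned[:, mi] = X[:, gidx[g]]
    logits = aligned @ model.coefficients.T + model.intercepts
    return SimilarityScores(
        pd.DataFrame(logits, index=cells, columns=model.class_labels)
    )


def kmeans_split_scores(scores, k: int = 2, seed: int = 0) -> pd.Series:
    """Split a 1-D score vector by k-means; for k=2 label groups low/high.

    The group with the smaller mean is labeled ``low``.  Deterministic via a
    seeded multi-start; all-identical inputs are rejected as degenerate.
    """
    from sklearn.cluster import KMeans

    s = pd.Series(scores, dtype=float)
    vals = s.to_numpy().reshape(-1, 1)
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct values for a k={k} split")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(vals)
    order = np.argsort([vals[km.labels_ == j].mean() for j in range(k)])
    if k == 2:
        names = {order[0]: "low", order[1]: "high"}
    else:
        names = {j: f"group{rank}" for rank, j in enumerate(order)}
    return pd.Series([names[l] for l in km.labels_], index=s.index)
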