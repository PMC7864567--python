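"""Genotyping single cells from allelic imbalance in copy-number-altered regions.

Tumor copy-number changes distort the maternal/paternal mRNA allele ratio away
from 1:1 inside the affected segment.  Given clonal copy-number segments and
per-cell allele counts at heterozygous SNPs, this module (i) phases SNPs onto a
shared "major" haplotype per segment using pooled counts, (ii) computes, per
cell, a posterior probability of carrying the tumor genome versus a diploid
genome from per-segment binomial likelihoods, and (iii) aggregates calls to a
per-cluster tumor/not-tumor verdict.

The likelihood model: within segment ``s`` with allele-specific copy numbers
``(major_cn, minor_cn)``, the expected fraction of reads from the major
haplotype is ``f_s = major_cn / (major_cn + minor_cn)`` (1 when the minor
haplotype is lost), clipped into ``[error_rate, 1 - error_rate]`` to absorb
base-call/mapping error.  A cell with ``k_s`` major-haplotype reads of ``n_s``
total in segment ``s`` contributes ``Binomial(k_s; n_s, f_s)`` to the tumor
likelihood and ``Binomial(k_s; n_s, 0.5)`` to the diploid likelihood; segments
are combined by product.  A cell with no informative reads keeps the prior
(posterior 0.5 under the default flat prior, i.e. logit 0 = no information).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "CopyNumberSegment",
    "phase_snps",
    "compute_posterior",
    "classify_clusters",
]


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval with clonal allele-specific copy number.

    Coordinates are 0-based half-open (BED convention).  If
    ``expected_major_fraction`` is not given it is derived from the copy
    numbers: ``major_cn / (major_cn + minor_cn)``, or 1.0 on complete loss of
    the minor haplotype.
    """

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    expected_major_fraction: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn must be >= minor_cn")
        if self.expected_major_fraction is None:
            if self.minor_cn == 0:
                f = 1.0
            else:
                f = self.major_cn / (self.major_cn + self.minor_cn)
            object.__setattr__(self, "expected_major_fraction", f)
        f = self.expected_major_fraction
        if not (0.5 <= f <= 1.0):
            raise ValueError(
                f"expected_major_fraction must lie in [0.5, 1], got {f}"
            )

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def _segment_of(chrom: str, pos: int, segments: list[CopyNumberSegment]) -> str | None:
    for seg in segments:
        if seg.contains(chrom, pos):
            return seg.segment_id
    return None


def phase_snps(
    counts: pd.DataFrame,
    segments: list[CopyNumberSegment],
    het_snps: pd.DataFrame,
    min_pooled_depth: int = 1,
) -> pd.DataFrame:
    """Assign each heterozygous SNP's alleles to the major/minor haplotype.

    SNPs inside the same copy-number aberration are phased jointly by a simple
    pooled-count estimator: within an imbalanced segment the major haplotype is
    over-represented in the mRNA pool, so for each SNP the allele with the
    larger total count across all cells is assigned to the major haplotype.

    Parameters
    ----------
    counts
        Allele count table with columns ``cell, chrom, pos, ref_count,
        alt_count`` (one row per cell × SNP).
    segments
        Imbalanced copy-number segments; every SNP must fall in at most one.
    het_snps
        Heterozygous SNP table with columns ``chrom, pos`` (optionally
        ``ref, alt``).
    min_pooled_depth
        SNPs with pooled depth below this are dropped.

    Returns
    -------
    DataFrame with columns ``chrom, pos, segment_id, major_is_alt,
    phase_confidence, tie`` — ``phase_confidence`` is the pooled major-allele
    fraction; exact 50/50 ties are broken toward the reference allele and
    flagged.
    """
    pooled = (
        counts.groupby(["chrom", "pos"], sort=False)[["ref_count", "alt_count"]]
        .sum()
        .reset_index()
    )
    pooled = het_snps[["chrom", "pos"]].merge(pooled, on=["chrom", "pos"], how="left")
    pooled[["ref_count", "alt_count"]] = pooled[["ref_count", "alt_count"]].fillna(0)

    rows = []
    for rec in pooled.itertuples(index=False):
        seg_id = _segment_of(rec.chrom, rec.pos, segments)
        if seg_id is None:
            warnings.warn(
                f"SNP {rec.chrom}:{rec.pos} lies outside all segments; skipped",
                stacklevel=2,
            )
            continue
        depth = rec.ref_count + rec.alt_count
        if depth < max(min_pooled_depth, 1):
            continue
        tie = rec.ref_count == rec.alt_count
        major_is_alt = rec.alt_count > rec.ref_count
        confidence = max(rec.ref_count, rec.alt_count) / depth
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "segment_id": seg_id,
                "major_is_alt": bool(major_is_alt),
                "phase_confidence": float(confidence),
                "tie": bool(tie),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "segment_id", "major_is_alt", "phase_confidence", "tie"],
    )


def compute_posterior(
    counts: pd.DataFrame,
    phased: pd.DataFrame,
    segments: list[CopyNumberSegment],
    error_rate: float = 0.01,
    prior_tumor: float = 0.5,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Posterior probability of the tumor genotype for each cell.

    Parameters
    ----------
    counts
        Allele count table (``cell, chrom, pos, ref_count, alt_count``).
    phased
        Output of :func:`phase_snps`.
    segments
        The imbalanced segments (keyed by segment_id).
    error_rate
        Sequencing/mapping error; the tumor major-haplotype fraction is
        clipped into ``[error_rate, 1 - error_rate]``.  Must lie in (0, 0.5).
    prior_tumor
        Prior probability of the tumor genotype, in (0, 1).
    cells
        Optional full cell universe; cells absent from ``counts`` are reported
        with posterior equal to the prior and call ``uninformative``.

    Returns
    -------
    DataFrame indexed by cell with columns ``k_major, n_total,
    posterior_tumor, logit, call`` where call is one of ``definitive_tumor``
    (posterior > 0.99), ``definitive_normal`` (posterior < 0.01) or
    ``uninformative``.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    if not (0.0 < prior_tumor < 1.0):
        raise ValueError("prior_tumor must lie in (0, 1)")

    seg_frac = {s.segment_id: s.expected_major_fraction for s in segments}
    merged = counts.merge(phased, on=["chrom", "pos"], how="inner")
    merged["n"] = merged["ref_count"] + merged["alt_count"]
    merged["k_major"] = np.where(
        merged["major_is_alt"], merged["alt_count"], merged["ref_count"]
    )
    per_seg = (
        merged.groupby(["cell", "segment_id"], sort=False)[["k_major", "n"]]
        .sum()
        .reset_index()
    )
    per_seg["f_tumor"] = (
        per_seg["segment_id"].map(seg_frac).clip(error_rate, 1.0 - error_rate)
    )
    per_seg["ll_tumor"] = binom.logpmf(per_seg["k_major"], per_seg["n"], per_seg["f_tumor"])
    per_seg["ll_normal"] = binom.logpmf(per_seg["k_major"], per_seg["n"], 0.5)

    agg = per_seg.groupby("cell").agg(
        k_major=("k_major", "sum"),
        n_total=("n", "sum"),
        ll_tumor=("ll_tumor", "sum"),
        ll_normal=("ll_normal", "sum"),
    )
    log_prior_odds = np.log(prior_tumor) - np.log1p(-prior_tumor)
    log_odds = log_prior_odds + agg["ll_tumor"] - agg["ll_normal"]
    posterior = 1.0 / (1.0 + np.exp(-log_odds))

    out = pd.DataFrame(
        {
            "k_major": agg["k_major"].astype(int),
            "n_total": agg["n_total"].astype(int),
            "posterior_tumor": posterior,
            "logit": log_odds,
        }
    )
    if cells is not None:
        missing = pd.Index(cells).difference(out.index)
        if len(missing):
            filler = pd.DataFrame(
                {
                    "k_major": 0,
                    "n_total": 0,
                    "posterior_tumor": prior_tumor,
                    "logit": log_prior_odds,
                },
                index=missing,
            )
            out = pd.concat([out, filler])
        out = out.reindex(pd.Index(cells))
    out["call"] = np.select(
        [out["posterior_tumor"] > 0.99, out["posterior_tumor"] < 0.01],
        ["definitive_tumor", "definitive_normal"],
        default="uninformative",
    )
    out.index.name = "cell"
    return out


def classify_clusters(
    posteriors: pd.DataFrame, clusters: pd.Series | dict
) -> pd.DataFrame:
    """Per-cluster tumor verdict from per-cell definitive calls.

    A cluster is called tumor iff it holds strictly more definitively tumor
    cells (posterior > 0.99) than definitively normal cells (posterior <
    0.01).  Also reports the cluster-average posterior.
    """
    clusters = pd.Series(clusters)
    missing = posteriors.index.difference(clusters.index)
    if len(missing):
        raise ValueError(f"cells without cluster labels: {list(missing[:5])}")
    df = posteriors.copy()
    df["cluster"] = clusters.reindex(df.index)
    out = df.groupby("cluster").apply(
        lambda g: pd.Series(
            {
                "n_cells": len(g),
                "n_definitive_tumor": int((g["call"] == "definitive_tumor").sum()),
                "n_definitive_normal": int((g["call"] == "definitive_normal").sum()),
                "mean_posterior": float(g["posterior_tumor"].mean()),
            }
        ),
        include_groups=False,
    )
    out["verdict"] = np.where(
        out["n_definitive_tumor"] > out["n_definitive_normal"], "tumor", "not_tumor"
    )
    for c in ("n_cells", "n_definitive_tumor", "n_definitive_normal"):
        out[c] = out[c].astype(int)
    return out
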