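"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study's data-generating processes: cell-type-structured
negative-binomial single-cell counts (SCP / bridge / chromaffin /
sympathoblast / leukocyte / mesenchyme, plus an optional tumor population),
binomial mRNA allele counts under copy-number-driven allelic imbalance,
risk-structured bulk TPM cohorts with clinical covariates, and a toy genome
annotation with strictly ordered transcription start sites.

Counts use the mean–dispersion NB parameterization (variance = mu + phi*mu^2)
with phi the square of the sqrt-scale ``nb_dispersion``; per-cell depth is
Poisson around ``mean_umis``.  All generators are bit-deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotyping import CopyNumberSegment

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CELL_TYPE_NAMES",
    "simulate_reference_counts",
    "simulate_allele_counts",
    "simulate_bulk_cohort",
    "simulate_genome_annotation",
]

CELL_TYPE_NAMES = (
    "SCP",
    "bridge",
    "chromaffin",
    "sympathoblast",
    "leukocyte",
    "mesenchyme",
)

_SITE_DESCRIPTIONS = (
    "Adrenal gland, NOS",
    "Kidney, NOS",
    "Abdominal mass",
    "Abdomen, NOS",
    "Retroperitoneum",
    "Unknown primary site",
    "Other ill-defined sites",
    "Thoracic sympathetic chain",
    "Posterior mediastinum",
    "Pelvis, NOS",
    "Cervical sympathetic ganglion",
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults describe a desk-scale study.

    ``nb_dispersion`` is on the square-root scale (the NB overdispersion used
    in draws is its square).  ``marker_log2fc`` is the planted elevation of
    each type's marker genes, in log2 units.
    """

    seed: int = 0
    n_cell_types: int = 4
    cells_per_type: int = 200
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.4
    mean_umis: float = 5000.0
    tumor_fraction: float = 0.0
    snps_per_segment: int = 30
    mean_allele_depth: float = 20.0
    allele_error: float = 0.01
    n_bulk_samples: int = 100
    qc_violation_fraction: float = 0.05

    def validate(self) -> None:
        positive_ints = (
            "n_cell_types",
            "cells_per_type",
            "n_genes",
            "markers_per_type",
            "snps_per_segment",
        )
        for name in positive_ints:
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"SimConfig.{name} must be a positive integer")
        for name in ("mean_umis", "mean_allele_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        for name in ("tumor_fraction", "allele_error", "qc_violation_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"SimConfig.{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("SimConfig.nb_dispersion must be >= 0")
        if self.marker_log2fc < 0:
            raise ValueError("SimConfig.marker_log2fc must be >= 0")
        if self.n_bulk_samples < 2:
            raise ValueError("SimConfig.n_bulk_samples must be >= 2")
        if self.n_cell_types > len(CELL_TYPE_NAMES):
            raise ValueError(
                f"SimConfig.n_cell_types must be <= {len(CELL_TYPE_NAMES)}"
            )
        if self.markers_per_type * (self.n_cell_types + 1) > self.n_genes:
            raise ValueError(
                "SimConfig.n_genes too small for the requested marker blocks"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Book-keeping of everything the generators planted."""

    cell_type_of: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    tumor_status_of: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    haplotype_of: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    de_genes: dict = field(default_factory=dict)
    marker_genes: dict = field(default_factory=dict)
    risk_genes: dict = field(default_factory=dict)
    region_genes: list = field(default_factory=list)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with variance mu + phi*mu^2 (Poisson when phi == 0)."""
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    # gamma-Poisson mixture keeps mu exact for non-integer r
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_reference_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Cell-type-structured NB count matrix with per-cell QC metadata.

    Each type's ``markers_per_type`` marker genes are elevated by
    ``marker_log2fc`` over a shared baseline expression profile.  When
    ``tumor_fraction`` > 0, an extra tumor population (with its own marker
    block) is appended so that tumor cells make up that fraction of the
    dataset.  A ``qc_violation_fraction`` of cells gets a planted QC violation
    (high mito fraction, low depth, high doublet score, or a positive
    cell-cycle score).

    Returns an AnnData (cells × genes, sparse counts in ``.X``, per-cell
    metadata in ``.obs``) and the ground truth.
    """
    config.validate()
    rng = _rng(config, 0)
    phi = config.nb_dispersion**2

    type_names = list(CELL_TYPE_NAMES[: config.n_cell_types])
    n_normal = config.n_cell_types * config.cells_per_type
    n_tumor = 0
    if config.tumor_fraction > 0:
        n_tumor = int(round(config.tumor_fraction / (1 - config.tumor_fraction) * n_normal)) \
            if config.tumor_fraction < 1 else config.cells_per_type
        n_tumor = max(n_tumor, 1)
    populations = type_names + (["tumor"] if n_tumor else [])
    cells_per_pop = [config.cells_per_type] * config.n_cell_types + ([n_tumor] if n_tumor else [])
    n_cells = sum(cells_per_pop)

    genes = np.array([f"gene_{i:05d}" for i in range(config.n_genes)])
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)

    truth = GroundTruth()
    marker_blocks: dict[str, np.ndarray] = {}
    m = config.markers_per_type
    for i, pop in enumerate(populations):
        idx = np.arange(i * m, (i + 1) * m)
        marker_blocks[pop] = idx
        truth.marker_genes[pop] = list(genes[idx])
        for g in genes[idx]:
            truth.de_genes[g] = {"population": pop, "log2fc": config.marker_log2fc}

    # Marker genes are moderately expressed in their own type (~2 counts per
    # cell at mean depth) and near-silent elsewhere, as real cell-type
    # markers are: the off-type baseline is the in-type level divided by
    # 2**marker_log2fc, so the planted elevation is exactly marker_log2fc.
    all_marker_idx = np.arange(len(populations) * m)
    nonmarker_total = baseline[len(populations) * m :].sum()
    w_marker = 2.0 * 2.0**-config.marker_log2fc * nonmarker_total / config.mean_umis
    baseline[all_marker_idx] = w_marker * rng.lognormal(0.0, 0.3, size=len(all_marker_idx))

    profiles = {}
    for pop in populations:
        w = baseline.copy()
        w[marker_blocks[pop]] *= 2.0**config.marker_log2fc
        profiles[pop] = w / w.sum()

    cell_type = np.repeat(populations, cells_per_pop)
    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_cells)])

    # planted QC violations
    n_viol = int(round(config.qc_violation_fraction * n_cells))
    viol_cells = rng.choice(n_cells, size=n_viol, replace=False)
    viol_kind = rng.choice(["mito", "depth", "doublet", "cycling"], size=n_viol)
    kind_of = dict(zip(viol_cells, viol_kind))

    depth = rng.poisson(config.mean_umis, size=n_cells).astype(float)
    for c, k in kind_of.items():
        if k == "depth":
            depth[c] = rng.integers(50, 500)
    depth = np.maximum(depth, 1.0)

    blocks = []
    start = 0
    for pop, n_pop in zip(populations, cells_per_pop):
        mu = depth[start : start + n_pop, None] * profiles[pop][None, :]
        blocks.append(_nb_draw(rng, mu, phi))
        start += n_pop
    counts = np.vstack(blocks)

    mito = rng.beta(2.0, 20.0, size=n_cells)
    doublet = rng.beta(1.0, 30.0, size=n_cells)
    s_score = rng.uniform(-1.0, -0.01, size=n_cells)
    g2m_score = rng.uniform(-1.0, -0.01, size=n_cells)
    for c, k in kind_of.items():
        if k == "mito":
            mito[c] = rng.uniform(0.31, 0.6)
        elif k == "doublet":
            doublet[c] = rng.uniform(0.21, 0.6)
        elif k == "cycling":
            if rng.random() < 0.5:
                s_score[c] = rng.uniform(0.01, 1.0)
            else:
                g2m_score[c] = rng.uniform(0.01, 1.0)

    obs = pd.DataFrame(
        {
            "cell_type_true": cell_type,
            "tumor_status_true": np.where(cell_type == "tumor", "tumor", "normal"),
            "mito_fraction": mito,
            "n_genes_detected": (counts > 0).sum(axis=1),
            "n_umis": counts.sum(axis=1),
            "doublet_score": doublet,
            "s_score": s_score,
            "g2m_score": g2m_score,
            "sample": np.where(np.arange(n_cells) % 2 == 0, "sample_A", "sample_B"),
        },
        index=cell_ids,
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=genes)
    )
    truth.cell_type_of = pd.Series(cell_type, index=cell_ids)
    truth.tumor_status_of = pd.Series(obs["tumor_status_true"].to_numpy(), index=cell_ids)
    return adata, truth


def simulate_allele_counts(
    config: SimConfig,
    segments: list[CopyNumberSegment],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Per-cell, per-SNP mRNA allele counts under allelic imbalance.

    For each cell and segment, total depth is Poisson(``mean_allele_depth``)
    split uniformly across the segment's SNPs.  Major-haplotype reads are
    binomial with probability equal to the segment's expected major fraction
    clipped by ``allele_error`` for tumor cells, and 0.5 for normal cells.
    The planted per-SNP haplotype assignment (whether the alt allele is the
    major-haplotype allele) is written into ``truth.haplotype_of`` in place.

    Returns a table with columns ``cell, chrom, pos, ref_count, alt_count``
    (rows with zero depth omitted).
    """
    config.validate()
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and not (a.end <= b.start or b.end <= a.start):
            raise ValueError(f"segments overlap: {a.segment_id}, {b.segment_id}")
    cells = truth.tumor_status_of.index
    if len(cells) == 0:
        raise ValueError("GroundTruth.tumor_status_of covers no cells")
    rng = _rng(config, 1)

    snp_rows = []
    hap = {}
    for seg in segments:
        pos = np.sort(
            rng.choice(np.arange(seg.start, seg.end), size=config.snps_per_segment, replace=False)
        )
        major_is_alt = rng.random(config.snps_per_segment) < 0.5
        for p, mia in zip(pos, major_is_alt):
            snp_rows.append((seg.chrom, int(p), seg.segment_id, bool(mia),
                             float(np.clip(seg.expected_major_fraction,
                                           config.allele_error, 1 - config.allele_error))))
            hap[f"{seg.chrom}:{p}"] = bool(mia)
    truth.haplotype_of = pd.Series(hap, dtype=bool)

    is_tumor = (truth.tumor_status_of == "tumor").to_numpy()
    rows = []
    for ci, cell in enumerate(cells):
        for seg_i, seg in enumerate(segments):
            total = rng.poisson(config.mean_allele_depth)
            if total == 0:
                continue
            per_snp = rng.multinomial(total, np.full(config.snps_per_segment, 1.0 / config.snps_per_segment))
            seg_snps = [r for r in snp_rows if r[2] == seg.segment_id]
            for (chrom, p, _sid, mia, p_major), n in zip(seg_snps, per_snp):
                if n == 0:
                    continue
                prob = p_major if is_tumor[ci] else 0.5
                k_major = rng.binomial(n, prob)
                alt = k_major if mia else n - k_major
                rows.append((cell, chrom, p, int(n - alt), int(alt)))
    return pd.DataFrame(rows, columns=["cell", "chrom", "pos", "ref_count", "alt_count"])


def simulate_bulk_cohort(config: SimConfig):
    """Risk-structured bulk cohort: NB counts, TPM, clinical covariates.

    Half the samples are low-risk, half high-risk.  5% of genes (rounded up,
    at least one) are planted risk-dependent with log2 fold change
    ``marker_log2fc`` in high-risk samples.  Covariates follow the clinical
    structure of neuroblastoma cohorts: low-risk samples are mostly young
    (age < 18 months), MYCN-negative, stage 1/2/4S; high-risk samples older,
    often MYCN-amplified, stage 3/4.  Site descriptions are drawn from a
    fixed vocabulary including adrenal and extra-adrenal strings.
    """
    from .bulk import BulkCohort  # deferred: bulk imports nothing from here

    config.validate()
    rng = _rng(config, 2)
    n = config.n_bulk_samples
    genes = np.array([f"gene_{i:05d}" for i in range(config.n_genes)])
    samples = np.array([f"bulk_{i:04d}" for i in range(n)])

    risk = np.where(np.arange(n) < n // 2, "low", "high")
    age = np.where(
        risk == "low",
        rng.uniform(1.0, 17.0, size=n),
        rng.uniform(19.0, 120.0, size=n),
    )
    mycn = np.where(
        risk == "high",
        np.where(rng.random(n) < 0.4, "pos", "neg"),
        np.where(rng.random(n) < 0.02, "pos", "neg"),
    )
    stage = np.where(
        risk == "low",
        rng.choice(["1", "2", "4S"], size=n, p=[0.5, 0.3, 0.2]),
        rng.choice(["3", "4"], size=n, p=[0.3, 0.7]),
    )
    site = rng.choice(_SITE_DESCRIPTIONS, size=n)

    n_risk_genes = max(1, int(np.ceil(0.05 * config.n_genes)))
    risk_idx = np.arange(n_risk_genes)
    truth = GroundTruth()
    truth.risk_genes = {genes[i]: config.marker_log2fc for i in risk_idx}

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    mu = np.tile(base, (n, 1))
    mu[risk == "high"] = mu[risk == "high"] * np.where(
        np.isin(np.arange(config.n_genes), risk_idx), 2.0**config.marker_log2fc, 1.0
    )
    counts = _nb_draw(rng, mu, config.nb_dispersion**2).astype(np.int64)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    tpm = counts / totals * 1e6

    covariates = pd.DataFrame(
        {
            "age_months": age,
            "mycn_status": mycn,
            "stage": stage,
            "risk": risk,
            "site_description": site,
        },
        index=samples,
    )
    cohort = BulkCohort(
        tpm=pd.DataFrame(tpm, index=samples, columns=genes),
        covariates=covariates,
        counts=pd.DataFrame(counts, index=samples, columns=genes),
    )
    return cohort, truth


def simulate_genome_annotation(
    config: SimConfig,
    n_chroms: int = 1,
    chrom_length: int = 10_000_000,
    planted_region: tuple[str, int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene annotation on 1–2 synthetic chromosomes (0-based TSS, bp).

    Genes are split evenly across chromosomes with strictly increasing,
    distinct TSS coordinates per chromosome.  If ``planted_region``
    (chrom, start, end) is given, genes inside it are flagged in the
    ``in_region`` column (e.g. a planted sympathoblast-high region).

    Returns the annotation table (gene, chrom, tss, in_region) and a dict of
    chromosome lengths.
    """
    config.validate()
    if n_chroms not in (1, 2):
        raise ValueError("n_chroms must be 1 or 2")
    rng = _rng(config, 3)
    genes = np.array([f"gene_{i:05d}" for i in range(config.n_genes)])
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: int(chrom_length) for c in chroms}

    per = np.array_split(np.arange(config.n_genes), n_chroms)
    frames = []
    for c, idx in zip(chroms, per):
        tss = np.sort(rng.choice(chrom_length, size=len(idx), replace=False))
        frames.append(pd.DataFrame({"gene": genes[idx], "chrom": c, "tss": tss}))
    annotation = pd.concat(frames, ignore_index=True)

    annotation["in_region"] = False
    if planted_region is not None:
        chrom, start, end = planted_region
        mask = (
            (annotation["chrom"] == chrom)
            & (annotation["tss"] >= start)
            & (annotation["tss"] < end)
        )
        annotation.loc[mask, "in_region"] = True
    return annotation, chrom_lengths
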