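"""End-to-end analysis on synthetic data: simulate → QC → cluster →
genotype → similarity → markers → bulk signal → region test.

One :class:`~nbmap.simulate.SimConfig` plus a seed drives the whole run;
all outputs are serialized as plain text and the run is bit-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .bulk import marker_presence_fraction, presence_threshold, stratify_risk_seqc
from .genotyping import CopyNumberSegment, classify_clusters, compute_posterior, phase_snps
from .markers import tfidf_markers
from .qc import cluster_cells, run_qc
from .similarity import score_cells, train_reference_model
from .simulate import (
    SimConfig,
    simulate_allele_counts,
    simulate_bulk_cohort,
    simulate_genome_annotation,
    simulate_reference_counts,
)
from .smoothing import mean_normalized_expression, region_difference_test, smooth_expression_track

__all__ = ["run_pipeline"]


def run_pipeline(config: SimConfig, outdir, seed: int | None = None) -> dict:
    """Run the full synthetic-data pipeline and serialize every output.

    Returns a summary dict (also written to ``summary.json``) with the key
    quantities: QC survivor counts, per-cluster genotype verdicts, top
    similarity assignments, marker counts, the bulk presence threshold, and
    the region-test p-value.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, seed=seed)
    seed = config.seed

    # --- reference (normal) and query (tumor-bearing) single-cell data
    ref_config = config
    query_config = replace(config, seed=seed + 1, tumor_fraction=max(config.tumor_fraction, 0.5))
    reference, ref_truth = simulate_reference_counts(ref_config)
    query, query_truth = simulate_reference_counts(query_config)
    io.write_cellmatrix(reference, outdir / "reference")
    io.write_cellmatrix(query, outdir / "query")

    # --- QC: cluster-level rule needs high-resolution clusters
    reference = cluster_cells(reference, resolution=10.0, seed=seed)
    ref_qc = run_qc(reference, "adrenal")
    query_qc = run_qc(query, "tumor10x")
    io.write_table(
        run_qc(reference, "adrenal", subset=False, normalize=False).obs[
            ["qc_pass", "qc_fail_reasons"]
        ],
        outdir / "reference_qc_report.tsv",
        index=True,
    )

    # --- analysis clusters on the query
    query_qc = cluster_cells(query_qc, resolution=1.0, seed=seed)

    # --- genotyping on the query from allelic imbalance
    segments = [
        CopyNumberSegment("chr1", 0, 5_000_000, 1, 0),
        CopyNumberSegment("chr1", 6_000_000, 10_000_000, 2, 1),
    ]
    io.write_segments_bed(segments, outdir / "segments.bed")
    allele_counts = simulate_allele_counts(query_config, segments, query_truth)
    allele_counts = allele_counts[allele_counts["cell"].isin(query_qc.obs_names)]
    io.write_table(allele_counts, outdir / "allele_counts.tsv")
    het_snps = allele_counts[["chrom", "pos"]].drop_duplicates()
    phased = phase_snps(allele_counts, segments, het_snps)
    posteriors = compute_posterior(
        allele_counts, phased, segments, cells=list(query_qc.obs_names)
    )
    verdicts = classify_clusters(posteriors, query_qc.obs["cluster"])
    io.write_table(posteriors, outdir / "genotype_cells.tsv", index=True)
    io.write_table(verdicts, outdir / "genotype_clusters.tsv", index=True)

    # --- similarity: train on reference truth labels, score the query
    model = train_reference_model(
        ref_qc, ref_qc.obs["cell_type_true"], alpha=0.99, seed=seed
    )
    model.to_tsv(outdir / "reference_model.tsv")
    scores = score_cells(model, query_qc).with_cluster_means(query_qc.obs["cluster"])
    io.write_table(scores.cell_logits, outdir / "similarity_cells.tsv", index=True)
    io.write_table(scores.cluster_mean_logits, outdir / "similarity_clusters.tsv", index=True)

    # --- markers of the reference cell types
    marker_table = tfidf_markers(ref_qc, ref_qc.obs["cell_type_true"])
    io.write_table(marker_table, outdir / "reference_markers.tsv")
    marker_sets = {
        cl: list(sub["gene"]) for cl, sub in marker_table.groupby("cluster", observed=True)
    }

    # --- bulk cohort signal
    cohort, bulk_truth = simulate_bulk_cohort(replace(config, seed=seed + 2))
    io.write_table(cohort.tpm, outdir / "bulk_tpm.tsv", index=True)
    io.write_table(cohort.covariates, outdir / "bulk_covariates.tsv", index=True)
    threshold = presence_threshold(cohort)
    risk = stratify_risk_seqc(cohort)
    per_gene, summary = marker_presence_fraction(
        cohort, marker_sets, strata=risk["risk"], threshold=threshold
    )
    io.write_table(per_gene, outdir / "bulk_marker_presence.tsv")
    io.write_table(summary, outdir / "bulk_marker_presence_summary.tsv")

    # --- genomic smoothing + permutation test on a planted region
    annotation, chrom_lengths = simulate_genome_annotation(
        config, planted_region=("chr1", 2_000_000, 4_000_000)
    )
    io.write_table(annotation, outdir / "annotation.tsv")
    type_a = ref_qc.obs_names[ref_qc.obs["cell_type_true"] == "sympathoblast"]
    type_b = ref_qc.obs_names[ref_qc.obs["cell_type_true"] == "chromaffin"]
    w_a = mean_normalized_expression(ref_qc, type_a)
    w_b = mean_normalized_expression(ref_qc, type_b)
    track_a = smooth_expression_track(annotation, w_a, chrom_lengths=chrom_lengths,
                                      cell_type="sympathoblast")
    track_b = smooth_expression_track(annotation, w_b, chrom_lengths=chrom_lengths,
                                      cell_type="chromaffin")
    track_a.to_bedgraph(outdir / "track_sympathoblast.bedgraph")
    track_b.to_bedgraph(outdir / "track_chromaffin.bedgraph")
    test = region_difference_test(
        track_a, track_b, ("chr1", 2_000_000, 4_000_000), n_permutations=1000, seed=seed
    )

    summary_out = {
        "seed": seed,
        "n_reference_cells_input": int(reference.n_obs),
        "n_reference_cells_pass_qc": int(ref_qc.n_obs),
        "n_query_cells_input": int(query.n_obs),
        "n_query_cells_pass_qc": int(query_qc.n_obs),
        "n_tumor_clusters": int((verdicts["verdict"] == "tumor").sum()),
        "n_clusters": int(len(verdicts)),
        "presence_threshold_log2tpm": float(threshold),
        "n_markers": int(len(marker_table)),
        "region_test_observed_diff": test.observed_diff,
        "region_test_p": test.p,
        "cluster_top_similarity": {
            str(cl): str(scores.cluster_mean_logits.loc[cl].idxmax())
            for cl in scores.cluster_mean_logits.index
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_out, fh, indent=2, sort_keys=True)
    return summary_out
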