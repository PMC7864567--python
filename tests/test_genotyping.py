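"""Allelic-imbalance genotyping: phasing, Bayes posterior, cluster verdicts."""

import math

import numpy as np
import pandas as pd
import pytest

from nbmap.genotyping import (
    CopyNumberSegment,
    classify_clusters,
    compute_posterior,
    phase_snps,
)

LOSS = CopyNumberSegment("chr1", 0, 1_000_000, 1, 0)  # expected major fraction 1
GAIN = CopyNumberSegment("chr2", 0, 1_000_000, 2, 1)  # expected major fraction 2/3


def _counts(rows):
    return pd.DataFrame(rows, columns=["cell", "chrom", "pos", "ref_count", "alt_count"])


def _phased(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "segment_id", "major_is_alt", "phase_confidence", "tie"]
    )


class TestSegments:
    def test_major_fraction_derived_from_copy_numbers(self):
        assert LOSS.expected_major_fraction == 1.0
        assert GAIN.expected_major_fraction == pytest.approx(2 / 3)

    def test_balanced_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            CopyNumberSegment("chr1", 0, 10, 2, 1, expected_major_fraction=0.4)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="start"):
            CopyNumberSegment("chr1", 5, 5, 1, 0)


class TestPhasing:
    def test_majority_allele_assigned_to_major_haplotype(self):
        counts = _counts([("a", "chr1", 100, 10, 90)])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        out = phase_snps(counts, [LOSS], snps)
        assert bool(out["major_is_alt"].iloc[0]) is True
        assert out["phase_confidence"].iloc[0] == pytest.approx(0.9)

    def test_tie_breaks_to_reference_and_is_flagged(self):
        counts = _counts([("a", "chr1", 100, 50, 50)])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        out = phase_snps(counts, [LOSS], snps)
        assert bool(out["major_is_alt"].iloc[0]) is False
        assert bool(out["tie"].iloc[0]) is True
        assert out["phase_confidence"].iloc[0] == pytest.approx(0.5)

    def test_snp_outside_segments_skipped_with_warning(self):
        counts = _counts([("a", "chr9", 100, 5, 5)])
        snps = pd.DataFrame({"chrom": ["chr9"], "pos": [100]})
        with pytest.warns(UserWarning, match="outside"):
            out = phase_snps(counts, [LOSS], snps)
        assert len(out) == 0

    def test_phasing_recovers_planted_haplotypes_from_simulation(self):
        from nbmap.simulate import GroundTruth, SimConfig, simulate_allele_counts

        cfg = SimConfig(seed=21, snps_per_segment=30, mean_allele_depth=25.0)
        cells = [f"c{i}" for i in range(100)]
        truth = GroundTruth()
        truth.tumor_status_of = pd.Series(
            ["tumor"] * 80 + ["normal"] * 20, index=cells
        )
        counts = simulate_allele_counts(cfg, [LOSS], truth)
        snps = counts[["chrom", "pos"]].drop_duplicates()
        out = phase_snps(counts, [LOSS], snps)
        key = out["chrom"] + ":" + out["pos"].astype(str)
        agree = (
            out["major_is_alt"].to_numpy() == truth.haplotype_of.reindex(key).to_numpy()
        ).mean()
        assert agree >= 0.95


class TestPosterior:
    def test_no_reads_means_no_information(self):
        counts = _counts([("a", "chr1", 100, 3, 7)])
        phased = _phased([("chr1", 100, LOSS.segment_id, True, 1.0, False)])
        out = compute_posterior(counts, phased, [LOSS], cells=["a", "empty"])
        assert out.loc["empty", "posterior_tumor"] == pytest.approx(0.5)
        assert out.loc["empty", "logit"] == pytest.approx(0.0)
        assert out.loc["empty", "call"] == "uninformative"

    def test_closed_form_loss_segment_all_major(self):
        # k = 10 of 10 on a loss segment (p = 0.99 after error clipping)
        counts = _counts([("a", "chr1", 100, 0, 10)])
        phased = _phased([("chr1", 100, LOSS.segment_id, True, 1.0, False)])
        out = compute_posterior(counts, phased, [LOSS], error_rate=0.01)
        expected = 0.99**10 / (0.99**10 + 0.5**10)
        assert out.loc["a", "posterior_tumor"] == pytest.approx(expected, abs=1e-12)
        assert out.loc["a", "call"] == "definitive_tumor"

    def test_closed_form_loss_segment_half_major(self):
        counts = _counts([("a", "chr1", 100, 5, 5)])
        phased = _phased([("chr1", 100, LOSS.segment_id, True, 1.0, False)])
        out = compute_posterior(counts, phased, [LOSS], error_rate=0.01)
        expected = (0.99**5 * 0.01**5) / (0.99**5 * 0.01**5 + 0.5**10)
        assert out.loc["a", "posterior_tumor"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(9.7e-8, rel=0.02)
        assert out.loc["a", "call"] == "definitive_normal"

    def test_posterior_monotone_in_major_count(self):
        posts = []
        phased = _phased([("chr2", 50, GAIN.segment_id, True, 1.0, False)])
        for k in range(21):
            counts = _counts([("a", "chr2", 50, 20 - k, k)])
            out = compute_posterior(counts, phased, [GAIN])
            posts.append(out.loc["a", "posterior_tumor"])
        assert (np.diff(posts) > 0).all()

    def test_ref_alt_swap_invariance(self):
        counts = _counts([("a", "chr1", 100, 2, 8), ("a", "chr2", 50, 6, 4)])
        phased = _phased(
            [
                ("chr1", 100, LOSS.segment_id, True, 0.9, False),
                ("chr2", 50, GAIN.segment_id, False, 0.7, False),
            ]
        )
        swapped_counts = counts.rename(
            columns={"ref_count": "alt_count", "alt_count": "ref_count"}
        )
        swapped_phased = phased.assign(major_is_alt=~phased["major_is_alt"])
        a = compute_posterior(counts, phased, [LOSS, GAIN])
        b = compute_posterior(swapped_counts, swapped_phased, [LOSS, GAIN])
        assert a["posterior_tumor"].equals(b["posterior_tumor"])

    def test_multi_segment_product_matches_brute_force(self):
        phased = _phased(
            [
                ("chr1", 100, LOSS.segment_id, True, 1.0, False),
                ("chr2", 50, GAIN.segment_id, True, 1.0, False),
            ]
        )
        k1, n1, k2, n2 = 7, 9, 5, 8
        counts = _counts(
            [("a", "chr1", 100, n1 - k1, k1), ("a", "chr2", 50, n2 - k2, k2)]
        )
        out = compute_posterior(counts, phased, [LOSS, GAIN], error_rate=0.01)

        def binom_pmf(k, n, p):
            return math.comb(n, k) * p**k * (1 - p) ** (n - k)

        lt = binom_pmf(k1, n1, 0.99) * binom_pmf(k2, n2, 2 / 3)
        ln = binom_pmf(k1, n1, 0.5) * binom_pmf(k2, n2, 0.5)
        assert out.loc["a", "posterior_tumor"] == pytest.approx(
            lt / (lt + ln), abs=1e-12
        )

    def test_invalid_error_rate_rejected(self):
        counts = _counts([("a", "chr1", 100, 1, 1)])
        with pytest.raises(ValueError, match="error_rate"):
            compute_posterior(counts, _phased([]), [LOSS], error_rate=0.7)


class TestClusterVerdicts:
    def _posteriors(self, spec):
        rows = []
        for cluster, (n_tumor, n_normal, n_unsure) in spec.items():
            for i in range(n_tumor):
                rows.append((f"{cluster}_t{i}", cluster, 0.999, "definitive_tumor"))
            for i in range(n_normal):
                rows.append((f"{cluster}_n{i}", cluster, 0.001, "definitive_normal"))
            for i in range(n_unsure):
                rows.append((f"{cluster}_u{i}", cluster, 0.5, "uninformative"))
        df = pd.DataFrame(rows, columns=["cell", "cluster", "posterior_tumor", "call"])
        post = df.set_index("cell")[["posterior_tumor", "call"]]
        post["k_major"] = 0
        post["n_total"] = 0
        return post, df.set_index("cell")["cluster"]

    def test_majority_tumor_cluster_called_tumor(self):
        post, clusters = self._posteriors({"A": (30, 5, 0)})
        out = classify_clusters(post, clusters)
        assert out.loc["A", "verdict"] == "tumor"

    def test_empty_counts_not_tumor(self):
        post, clusters = self._posteriors({"A": (0, 0, 4)})
        out = classify_clusters(post, clusters)
        assert out.loc["A", "verdict"] == "not_tumor"

    def test_tie_not_tumor(self):
        post, clusters = self._posteriors({"A": (7, 7, 2)})
        out = classify_clusters(post, clusters)
        assert out.loc["A", "verdict"] == "not_tumor"

    def test_missing_cluster_label_rejected(self):
        post, clusters = self._posteriors({"A": (1, 1, 0)})
        with pytest.raises(ValueError, match="without cluster"):
            classify_clusters(post, clusters.iloc[:-1])
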