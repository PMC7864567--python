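"""tf-idf markers, marker merging, rank-sum and genewise NB DE, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_adata
from nbmap.markers import (
    hypergeometric_enrichment,
    merge_tumor_markers,
    nb_de_genewise,
    ranksum_de,
    stringent_cell_type_markers,
    tfidf_markers,
    tfidf_score,
)


def _clustered_adata(blocks):
    """blocks: list of (cluster, count rows)."""
    counts = np.vstack([b for _, b in blocks])
    labels = np.concatenate(
        [[name] * len(b) for name, b in blocks]
    )
    adata = make_adata(counts)
    adata.obs["cluster"] = labels
    return adata


class TestTfidf:
    def test_ubiquitous_gene_is_never_a_marker(self):
        counts = np.ones((20, 5), dtype=int)
        adata = make_adata(counts)
        adata.obs["cluster"] = ["A"] * 10 + ["B"] * 10
        out = tfidf_markers(adata, adata.obs["cluster"], return_all=True)
        assert (out["tfidf"] == 0).all()
        assert len(tfidf_markers(adata, adata.obs["cluster"])) == 0

    def test_boundary_value_excluded_under_strict_cutoff(self):
        # tf = 1 and global_rate = e^-1 sit exactly at tfidf = 1
        assert tfidf_score(1.0, math.exp(-1)) == pytest.approx(1.0)
        n = 20
        k_global = round(n * math.exp(-1))  # 7 of 20 ~ not exact; use direct check
        assert tfidf_score(1.0, math.exp(-1)) <= 1.0

    def test_toy_matrix_matches_direct_summation_oracle(self, rng):
        counts = rng.integers(0, 2, size=(30, 20))
        adata = make_adata(counts + rng.integers(0, 3, size=(30, 20)) * counts)
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        adata.obs["cluster"] = labels
        out = tfidf_markers(adata, labels, return_all=True).set_index(["gene", "cluster"])
        N = 30
        B = (counts > 0) | (adata.X.toarray() > 0)
        for gi, gene in enumerate(adata.var_names):
            K = int(B[:, gi].sum())
            for cl in "ABC":
                rows = labels == cl
                n = int(rows.sum())
                k = int(B[rows, gi].sum())
                tf = k / n
                gr = K / N
                expected_tfidf = tf * (math.log(1 / gr) if gr > 0 else 0.0)
                # direct hypergeometric upper tail by enumeration
                p = sum(
                    math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                    for j in range(k, min(K, n) + 1)
                )
                row = out.loc[(gene, cl)]
                assert row["tfidf"] == pytest.approx(expected_tfidf, abs=1e-12)
                assert row["p_raw"] == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_empty_cluster_rejected(self):
        adata = make_adata(np.ones((4, 3), dtype=int))
        labels = pd.Series(["A", "A", "B", "B"], index=adata.obs_names)
        labels = labels.astype(pd.CategoricalDtype(["A", "B", "C"]))
        with pytest.raises(ValueError, match="empty"):
            tfidf_markers(adata, labels)


class TestStringentMarkers:
    def _adata(self):
        # gene 0: perfect A marker; gene 1: A marker but 25% of B expresses it;
        # gene 2: housekeeping
        a = np.zeros((20, 3), dtype=int)
        a[:, 0] = 5
        a[:, 1] = 5
        a[:, 2] = 1
        b = np.zeros((20, 3), dtype=int)
        b[:5, 1] = 3  # 25% of B
        b[:, 2] = 1
        pod = np.zeros((20, 3), dtype=int)
        pod[:, 2] = 1
        counts = np.vstack([a, b, pod])
        adata = make_adata(counts)
        adata.obs["cluster"] = ["A"] * 20 + ["B"] * 20 + ["podocyte"] * 20
        return adata

    def test_cross_expressed_gene_excluded_and_specific_gene_kept(self):
        adata = self._adata()
        out = stringent_cell_type_markers(adata, adata.obs["cluster"])
        assert "g0" in out["A"]
        assert "g1" not in out["A"]

    def test_missing_control_cluster_warns(self):
        adata = self._adata()
        labels = adata.obs["cluster"].replace("podocyte", "B")
        with pytest.warns(UserWarning, match="podocyte"):
            stringent_cell_type_markers(adata, labels)


class TestMergeTumorMarkers:
    list_a = pd.DataFrame({"gene": ["g1", "g2", "g3"], "tfidf": [1.0, 0.9, 0.86]})
    list_b = pd.DataFrame({"gene": ["g1", "g2"], "tfidf": [0.8, 0.7]})

    def test_average_rule_and_cutoff(self):
        out = merge_tumor_markers(self.list_a, self.list_b)
        kept = dict(zip(out["gene"], out["avg_tfidf"]))
        assert kept["g1"] == pytest.approx(0.9)  # (1.0 + 0.8)/2 > 0.85
        assert "g2" not in kept  # 0.8 <= 0.85
        assert kept["g3"] == pytest.approx(0.86)  # single-list gene keeps own value

    def test_leukocyte_filter_is_strict(self):
        lf = pd.Series({"g1": 0.30, "g3": 0.25})
        out = merge_tumor_markers(self.list_a, self.list_b, leukocyte_fraction=lf)
        assert list(out["gene"]) == ["g3"]  # exactly 25% is kept, 30% removed


class TestRanksumDE:
    def _adata(self, counts):
        from nbmap.qc import normalize_log

        return normalize_log(make_adata(counts))

    def test_low_detection_gene_excluded_before_testing(self, rng):
        counts = rng.poisson(5, size=(20, 10))
        counts[:, 0] = 0
        counts[0, 0] = 1  # detected in 10% of group A only
        counts[10, 0] = 1
        counts[:, 1] += 1
        adata = self._adata(counts)
        out = ranksum_de(adata, adata.obs_names[:10], adata.obs_names[10:],
                         return_all=True)
        assert "g0" not in set(out["gene"])

    def test_null_comparison_yields_no_discoveries(self, rng):
        counts = rng.poisson(5, size=(60, 100)) + 1
        adata = self._adata(counts)
        out = ranksum_de(adata, adata.obs_names[:30], adata.obs_names[30:])
        assert len(out) == 0

    def test_statistic_matches_manual_rank_sum(self):
        a_vals = np.array([12, 15, 9, 20, 31])
        b_vals = np.array([1, 2, 3, 4, 5])
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = np.r_[a_vals, b_vals]
        counts[:, 1] = 100  # equalizes library size differences partly
        adata = self._adata(counts)
        out = ranksum_de(adata, adata.obs_names[:5], adata.obs_names[5:],
                         return_all=True)
        x = adata.X.toarray()[:, 0]
        u_manual = sum(
            (xa > xb) + 0.5 * (xa == xb) for xa in x[:5] for xb in x[5:]
        )
        row = out.set_index("gene").loc["g0"]
        assert row["statistic"] == pytest.approx(u_manual)

    def test_disjoint_groups_required(self, rng):
        adata = self._adata(rng.poisson(5, size=(10, 4)) + 1)
        with pytest.raises(ValueError, match="disjoint"):
            ranksum_de(adata, adata.obs_names[:5], adata.obs_names[4:])


class TestGenewiseNB:
    def test_constant_zero_gene_reported_with_status(self, rng):
        counts = rng.poisson(5, size=(40, 5)) + 1
        counts[:, 2] = 0
        adata = make_adata(counts)
        out = nb_de_genewise(adata, adata.obs_names[:20], adata.obs_names[20:])
        assert out.set_index("gene").loc["g2", "status"] == "all_zero"
        assert np.isnan(out.set_index("gene").loc["g2", "p_adj"])

    def test_small_groups_advised_to_fixed_dispersion(self, rng):
        counts = rng.poisson(5, size=(10, 3)) + 1
        adata = make_adata(counts)
        with pytest.raises(ValueError, match="fixed-dispersion"):
            nb_de_genewise(adata, adata.obs_names[:5], adata.obs_names[5:])

    def test_g1_only_restricts_to_noncycling_cells(self, rng):
        counts = rng.poisson(5, size=(50, 3)) + 1
        adata = make_adata(counts)
        adata.obs["s_score"] = np.r_[np.full(25, 0.5), np.full(25, -0.5)]
        adata.obs["g2m_score"] = -1.0
        with pytest.raises(ValueError, match="cells each"):
            # only 25 G1 cells remain, all in group B
            nb_de_genewise(adata, adata.obs_names[:25], adata.obs_names[25:],
                           g1_only=True)

    def test_planted_effect_recovered(self, rng):
        phi = 0.16
        r = 1 / phi
        base = rng.lognormal(np.log(3), 0.5, 60)
        mu = np.tile(base, (120, 1))
        mu[:60, :5] *= 4.0  # log2FC 2 in 5 of 60 genes: mild composition shift
        counts = rng.poisson(rng.gamma(r, mu / r))
        adata = make_adata(counts)
        out = nb_de_genewise(adata, adata.obs_names[:60], adata.obs_names[60:])
        planted = out.set_index("gene").loc[[f"g{i}" for i in range(5)]]
        assert (planted["p_adj"] < 0.05).all()
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.4)


class TestEnrichment:
    def test_certain_overlap_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        overlap, p = hypergeometric_enrichment(universe, universe[:4], universe)
        assert overlap == 4
        assert p == pytest.approx(1.0)

    def test_small_case_matches_combinatorial_value(self):
        universe = [f"g{i}" for i in range(20)]
        hits = universe[:10]
        markers = universe[:4]
        overlap, p = hypergeometric_enrichment(hits, markers, universe)
        assert overlap == 4
        assert p == pytest.approx(math.comb(10, 4) / math.comb(20, 4), rel=1e-12)

    def test_zero_overlap_matches_enumeration(self):
        universe = [f"g{i}" for i in range(8)]
        hits = universe[:3]
        markers = universe[5:]
        overlap, p = hypergeometric_enrichment(hits, markers, universe)
        total = 0.0
        for j in range(0, 4):
            total += math.comb(3, j) * math.comb(5, 3 - j) / math.comb(8, 3)
        assert overlap == 0
        assert p == pytest.approx(1.0)  # P(X >= 0) is certain

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment([], [], [])
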