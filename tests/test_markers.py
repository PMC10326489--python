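"""Pairwise DE, rank/p combination semantics and marker selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import gbmdecon as gd


def _log_matrix(arr, genes=None):
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return gd.ExpressionMatrix(
        pd.DataFrame(arr, index=genes,
                     columns=[f"c{j}" for j in range(arr.shape[1])]),
        scale="log")


class TestPairwiseDE:
    def test_maximal_separation(self):
        arr = np.array([[5.0, 5, 5, 0, 0, 0],
                        [1.0, 1, 1, 1, 1, 1]])
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=mat.obs_ids)
        tab = gd.pairwise_de(mat, labels).table("A", "B")
        assert tab.loc["g0", "lfc"] == pytest.approx(5.0)
        assert tab.loc["g0", "p_t"] < 0.05
        assert tab.loc["g0", "p_w"] < 0.05

    def test_constant_gene_degenerate_rule(self):
        arr = np.array([[2.0, 2, 2, 2, 2, 2]])
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=mat.obs_ids)
        tab = gd.pairwise_de(mat, labels).table("A", "B")
        assert tab.loc["g0", "p_t"] == 1.0
        assert tab.loc["g0", "p_w"] == 1.0
        assert tab.loc["g0", "lfc"] == 0.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(30)
        arr = rng.normal(5.0, 1.0, size=(1000, 60))
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=mat.obs_ids)
        tab = gd.pairwise_de(mat, labels).table("A", "B")
        assert scipy.stats.kstest(tab["p_t"], "uniform").pvalue > 0.01
        assert scipy.stats.kstest(tab["p_w"], "uniform").pvalue > 0.01

    def test_lfc_antisymmetric(self):
        rng = np.random.default_rng(31)
        arr = rng.normal(size=(50, 20))
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=mat.obs_ids)
        de = gd.pairwise_de(mat, labels)
        assert np.allclose(de.table("A", "B")["lfc"],
                           -de.table("B", "A")["lfc"])

    def test_small_cluster_errors(self):
        arr = np.zeros((5, 5))
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 2 + ["B"] * 3, index=mat.obs_ids)
        with pytest.raises(ValueError, match="A"):
            gd.pairwise_de(mat, labels)


class TestCombinePairwise:
    def _manual_de(self):
        """Three clusters, four genes, hand-set p-values and lfc."""
        genes = pd.Index(["g0", "g1", "g2", "g3"])
        tables = {}
        data = {
            ("A", "B"): {"lfc": [3.0, 1.0, -1.0, 0.5],
                         "p_t": [1e-5, 1e-3, 0.9, 0.02],
                         "p_w": [1e-4, 1e-3, 0.8, 0.05]},
            ("A", "C"): {"lfc": [2.0, 0.2, 2.0, -0.1],
                         "p_t": [1e-2, 0.5, 1e-6, 0.7],
                         "p_w": [1e-2, 0.4, 1e-5, 0.6]},
        }
        for key, cols in data.items():
            tables[key] = pd.DataFrame(cols, index=genes)
        return gd.PairwiseDEResult(tables, ["A", "B", "C"], genes)

    def test_rule_arithmetic(self):
        stats = gd.combine_pairwise(self._manual_de(), "A")
        # g0: rank 1 in both tests vs B; rank 2 vs C -> rank_any 1
        assert stats.loc["g0", "rank_any"] == 1.0
        # p_all: max over partners, then max across tests
        assert stats.loc["g0", "p_all"] == pytest.approx(1e-2)
        assert stats.loc["g0", "min_lfc"] == pytest.approx(2.0)
        # g2 is down vs B -> negative min_lfc
        assert stats.loc["g2", "min_lfc"] == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(32)
        arr = rng.normal(size=(80, 36))
        mat = _log_matrix(arr)
        labels = pd.Series(["A"] * 12 + ["B"] * 12 + ["C"] * 12,
                           index=mat.obs_ids)
        de = gd.pairwise_de(mat, labels)
        stats = gd.combine_pairwise(de, "B")
        # brute force from the pairwise tables
        for gene in ["g0", "g17", "g79"]:
            per_test_rank, per_test_pall = [], []
            for test in ("p_t", "p_w"):
                ranks, ps = [], []
                for partner in ("A", "C"):
                    tab = de.table("B", partner)
                    r = scipy.stats.rankdata(tab[test])[
                        list(tab.index).index(gene)]
                    ranks.append(r)
                    ps.append(tab.loc[gene, test])
                per_test_rank.append(min(ranks))
                per_test_pall.append(max(ps))
            assert stats.loc[gene, "rank_any"] == max(per_test_rank)
            assert stats.loc[gene, "p_all"] == pytest.approx(
                max(per_test_pall))
            assert stats.loc[gene, "min_lfc"] == pytest.approx(
                min(de.table("B", p).loc[gene, "lfc"] for p in ("A", "C")))

    def test_focal_absent_errors(self):
        with pytest.raises(ValueError, match="absent"):
            gd.combine_pairwise(self._manual_de(), "Z")


class TestDeriveMarkerSet:
    def test_planted_markers_recovered(self, default_sim, default_norm):
        _, _, truth = default_sim
        de = gd.pairwise_de(default_norm, truth.cell_labels)
        stats = {c: gd.combine_pairwise(de, c) for c in de.clusters}
        derived = gd.derive_marker_set(stats).as_dict()
        planted = truth.markers.as_dict()
        recovery = np.mean([
            len(set(planted[t]) & set(derived.get(t, []))) / len(planted[t])
            for t in planted])
        assert recovery >= 0.9

    def test_n_top_one_returns_single_marker_per_cluster(self):
        stats = {
            "A": pd.DataFrame({"rank_any": [1.0, 2.0], "p_all": [0.01, 0.02],
                               "min_lfc": [1.0, 1.0]}, index=["g0", "g1"]),
            "B": pd.DataFrame({"rank_any": [1.0, 2.0], "p_all": [0.01, 0.02],
                               "min_lfc": [1.0, 1.0]}, index=["g2", "g3"]),
        }
        mk = gd.derive_marker_set(stats, gd.MarkerParams(n_top=1))
        assert mk.as_dict() == {"A": ["g0"], "B": ["g2"]}

    def test_require_unique_assigns_to_best_rank(self):
        stats = {
            "A": pd.DataFrame({"rank_any": [1.0], "p_all": [0.01],
                               "min_lfc": [1.0]}, index=["shared"]),
            "B": pd.DataFrame({"rank_any": [3.0, 1.0], "p_all": [0.05, 0.01],
                               "min_lfc": [1.0, 1.0]},
                              index=["shared", "own"]),
        }
        mk = gd.derive_marker_set(stats, gd.MarkerParams(n_top=5))
        d = mk.as_dict()
        assert "shared" in d["A"] and "shared" not in d["B"]

    def test_no_gene_under_two_cell_types(self, default_sim, default_norm):
        _, _, truth = default_sim
        de = gd.pairwise_de(default_norm, truth.cell_labels)
        stats = {c: gd.combine_pairwise(de, c) for c in de.clusters}
        mk = gd.derive_marker_set(stats)
        assert not mk.entries["gene"].duplicated().any()

    def test_negative_lfc_excluded(self):
        stats = {
            "A": pd.DataFrame({"rank_any": [1.0, 2.0], "p_all": [0.01, 0.01],
                               "min_lfc": [-0.5, 1.0]}, index=["down", "up"]),
            "B": pd.DataFrame({"rank_any": [1.0], "p_all": [0.01],
                               "min_lfc": [1.0]}, index=["other"]),
        }
        mk = gd.derive_marker_set(stats, gd.MarkerParams(n_top=5))
        assert mk.as_dict()["A"] == ["up"]

    def test_empty_cluster_errors(self):
        stats = {"A": pd.DataFrame({"rank_any": [1.0], "p_all": [0.5],
                                    "min_lfc": [-1.0]}, index=["g0"])}
        with pytest.raises(ValueError, match="A"):
            gd.derive_marker_set(stats)

    def test_selected_markers_are_specific(self, default_sim, default_norm):
        """min_lfc > 0 implies each marker's own-type mean exceeds its
        mean in every other type; assert post hoc on the expression."""
        _, _, truth = default_sim
        de = gd.pairwise_de(default_norm, truth.cell_labels)
        stats = {c: gd.combine_pairwise(de, c) for c in de.clusters}
        mk = gd.derive_marker_set(stats, gd.MarkerParams(n_top=5))
        values = default_norm.values
        labels = truth.cell_labels
        for _, row in mk.entries.iterrows():
            own = values.loc[row["gene"], (labels == row["cell_type"]).values]
            for other in labels.unique():
                if other == row["cell_type"]:
                    continue
                rest = values.loc[row["gene"], (labels == other).values]
                assert own.mean() > rest.mean()

    def test_determinism(self, default_sim, default_norm):
        _, _, truth = default_sim
        de = gd.pairwise_de(default_norm, truth.cell_labels)
        stats = {c: gd.combine_pairwise(de, c) for c in de.clusters}
        m1 = gd.derive_marker_set(stats)
        m2 = gd.derive_marker_set(stats)
        pd.testing.assert_frame_equal(m1.entries, m2.entries)


class TestFilterTumorIntrinsic:
    def _markers(self):
        return gd.MarkerTable(pd.DataFrame({
            "gene": ["A", "B", "C", "CD3E", "B"],
            "cell_type": ["MES", "MES", "MES", "T-cells", "T-cells"],
        }))

    def test_set_difference_on_targeted_types(self):
        out = gd.filter_tumor_intrinsic(self._markers(), {"B"}, {"MES"})
        assert out.genes_for("MES") == ["A", "C"]

    def test_disjoint_excluded_set_is_identity(self):
        out = gd.filter_tumor_intrinsic(self._markers(), {"ZZZ"}, {"MES"})
        pd.testing.assert_frame_equal(out.entries, self._markers().entries)

    def test_non_targeted_types_untouched(self):
        out = gd.filter_tumor_intrinsic(self._markers(), {"B", "CD3E"},
                                        {"MES"})
        assert out.genes_for("T-cells") == ["CD3E", "B"]

    def test_emptied_type_errors(self):
        with pytest.raises(ValueError, match="MES"):
            gd.filter_tumor_intrinsic(self._markers(), {"A", "B", "C"},
                                      {"MES"})

    def test_unknown_applies_to_errors(self):
        with pytest.raises(ValueError, match="applies_to"):
            gd.filter_tumor_intrinsic(self._markers(), {"A"}, {"NPC"})
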