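"""Tissue-sharing categories, specificity source, breadth, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutlink import (directionality_consistency, enumerate_sharing_categories,
                     gene_set_clustering, genus_summary, jaccard_index,
                     regulatory_breadth, sharing_categories,
                     specificity_source, weighted_effect_correlation)

TISSUES = ("ileum", "sigmoid", "transverse")


def _pairs(rows):
    return pd.DataFrame(rows, columns=["gene", "genus", "tissue", "beta",
                                       "se", "significant"])


class TestSharing:
    def test_seven_categories_enumerated(self):
        assert len(enumerate_sharing_categories(TISSUES)) == 7

    def test_all_three_tissues_is_full_category(self):
        df = _pairs([("g1", "m1", t, 0.1, 0.01, True) for t in TISSUES])
        labels, counts = sharing_categories(df, TISSUES)
        assert labels["category"].iloc[0] == "ileum+sigmoid+transverse"
        assert counts["ileum+sigmoid+transverse"] == 1

    def test_counts_partition_significant_keys(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(20):
            for t in TISSUES:
                rows.append((f"g{g}", "m1", t, 0.1, 0.01,
                             bool(rng.random() < 0.5)))
        df = _pairs(rows)
        labels, counts = sharing_categories(df, TISSUES)
        n_keys = df[df["significant"]].groupby(["gene", "genus"]).ngroups
        assert counts.sum() == n_keys == len(labels)


class TestSpecificitySource:
    def test_egene_only_in_focal_tissue_is_eqtl_specific(self):
        labels = pd.DataFrame({"gene": ["g1"], "genus": ["m1"],
                               "category": ["transverse"]})
        egenes = {"transverse": {"g1"}, "sigmoid": set(), "ileum": set()}
        out = specificity_source(labels, egenes, TISSUES)
        row = out[out["tissue"] == "transverse"].iloc[0]
        assert row["eqtl_specific"] == 1 and row["regulation_specific"] == 0

    def test_shared_egene_is_regulation_specific(self):
        labels = pd.DataFrame({"gene": ["g1"], "genus": ["m1"],
                               "category": ["ileum"]})
        egenes = {t: {"g1"} for t in TISSUES}
        out = specificity_source(labels, egenes, TISSUES)
        row = out[out["tissue"] == "ileum"].iloc[0]
        assert row["regulation_specific"] == 1 and row["eqtl_specific"] == 0

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        labels = pd.DataFrame({
            "gene": genes, "genus": "m1",
            "category": rng.choice(list(TISSUES), 30)})
        egenes = {t: set(rng.choice(genes, 10, replace=False)) for t in TISSUES}
        out = specificity_source(labels, egenes, TISSUES)
        for _, row in out.iterrows():
            assert (row["eqtl_specific"] + row["regulation_specific"]
                    + row["unclassifiable"]) == row["n_specific"]

    def test_injected_regulation_specific_pairs_recovered(self):
        """Genes that are eGenes everywhere but regulate the microbiome in
        one tissue only must land in the regulation-specific subgroup."""
        rows = []
        for g in range(40):
            rows.append((f"g{g}", "m1", "ileum", 0.2, 0.02, True))
        df = _pairs(rows)
        labels, _ = sharing_categories(df, TISSUES)
        egenes = {t: {f"g{g}" for g in range(40)} for t in TISSUES}
        out = specificity_source(labels, egenes, TISSUES)
        row = out[out["tissue"] == "ileum"].iloc[0]
        assert row["regulation_specific"] / row["n_specific"] >= 0.9


class TestConsistency:
    def test_all_same_sign(self):
        rows = [("g1", "m1", "ileum", 0.1, 0.01, True),
                ("g1", "m1", "sigmoid", 0.2, 0.01, True)]
        out = directionality_consistency(_pairs(rows), TISSUES)
        row = out[(out["tissue_1"] == "ileum") & (out["tissue_2"] == "sigmoid")]
        assert row["consistency"].iloc[0] == 1.0

    def test_half_flipped(self):
        rows = []
        for i, sign in enumerate([1, 1, -1, -1]):
            rows.append((f"g{i}", "m1", "ileum", 0.1, 0.01, True))
            rows.append((f"g{i}", "m1", "sigmoid", sign * 0.1, 0.01, True))
        out = directionality_consistency(_pairs(rows), TISSUES)
        row = out[(out["tissue_1"] == "ileum") & (out["tissue_2"] == "sigmoid")]
        assert row["consistency"].iloc[0] == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_sign_count(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        betas = {}
        for g in range(15):
            for t in ("ileum", "sigmoid"):
                b = rng.normal()
                rows.append((f"g{g}", "m1", t, b, 0.01, True))
                betas[(f"g{g}", t)] = b
        out = directionality_consistency(_pairs(rows), TISSUES)
        expected = np.mean([
            np.sign(betas[(f"g{g}", "ileum")]) ==
            np.sign(betas[(f"g{g}", "sigmoid")]) for g in range(15)])
        row = out[(out["tissue_1"] == "ileum") & (out["tissue_2"] == "sigmoid")]
        assert row["consistency"].iloc[0] == pytest.approx(expected)


class TestWeightedCorrelation:
    def test_identical_vectors(self):
        b = np.array([0.1, -0.2, 0.3, 0.05])
        se = np.full(4, 0.02)
        r, slope, p = weighted_effect_correlation(b, b, se, se)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_negated_vector(self):
        b = np.array([0.1, -0.2, 0.3, 0.05])
        se = np.full(4, 0.02)
        r, slope, _ = weighted_effect_correlation(b, -b, se, se)
        assert r == pytest.approx(-1.0)

    def test_equal_weights_match_pearson_oracle(self, rng):
        b1 = rng.normal(0, 1, 50)
        b2 = rng.normal(0.5 * b1, 0.5)
        se = np.full(50, 0.03)
        r, _, p = weighted_effect_correlation(b1, b2, se, se)
        from scipy import stats
        lr = stats.pearsonr(b1, b2)
        assert r == pytest.approx(lr.statistic)
        assert p == pytest.approx(lr.pvalue, rel=1e-6)

    def test_below_three_points_missing(self):
        r, slope, p = weighted_effect_correlation([1, 2], [1, 2],
                                                  [0.1, 0.1], [0.1, 0.1])
        assert np.isnan(r) and np.isnan(slope) and np.isnan(p)


class TestBreadth:
    @pytest.mark.parametrize("n_genera,expected", [
        (11, "broadly"), (9, "specifically"), (10, "specifically")])
    def test_threshold_rule(self, n_genera, expected):
        rows = [("g1", f"m{i}", "ileum", 0.1, 0.01, True)
                for i in range(n_genera)]
        out = regulatory_breadth(_pairs(rows))
        assert out["class"].iloc[0] == expected
        assert out["n_genera"].iloc[0] == n_genera


class TestClustering:
    def _indicator(self, rng, n_genes=12, n_genera=8):
        mat = rng.integers(0, 2, size=(n_genes, n_genera))
        mat[0] = mat[1] = [1, 1, 0, 0, 1, 0, 1, 0]  # forced duplicates
        return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"m{j}" for j in range(n_genera)])

    def test_duplicated_rows_co_cluster(self, rng):
        clusters = gene_set_clustering(self._indicator(rng), k=3)
        assert clusters["g0"] == clusters["g1"]

    def test_exactly_k_clusters(self, rng):
        clusters = gene_set_clustering(self._indicator(rng), k=4)
        assert clusters.nunique() == 4

    def test_row_permutation_invariance(self, rng):
        ind = self._indicator(rng)
        base = gene_set_clustering(ind, k=3)
        perm = ind.sample(frac=1.0, random_state=7)
        out = gene_set_clustering(perm, k=3)
        assert (out.sort_index() == base.sort_index()).all()

    def test_k_exceeding_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_set_clustering(self._indicator(rng), k=13)


class TestJaccard:
    def test_identical(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard_index({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard_index({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_both_empty(self):
        assert jaccard_index(set(), set()) == 0.0

    @given(a=st.sets(st.integers(0, 20)), b=st.sets(st.integers(0, 20)))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_symmetric(self, a, b):
        j = jaccard_index(a, b)
        assert 0 <= j <= 1
        assert j == jaccard_index(b, a)


class TestGenusSummary:
    @pytest.mark.parametrize("pairs,genera,expected", [
        (6088, 116, 52), (5810, 116, 50), (2398, 116, 21), (10, 5, 2)])
    def test_rounded_mean(self, pairs, genera, expected):
        assert genus_summary(pairs, genera) == expected

    def test_zero_genera_rejected(self):
        with pytest.raises(ValueError):
            genus_summary(10, 0)
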