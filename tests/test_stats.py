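import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isomirkit.io import ExpressionMatrix
from isomirkit.stats import (ArmRatioRow, arm_ratio, canberra, classify_ratio,
                             cluster_samples, concordance, pairwise_ttests,
                             pearson, student_t_pvalue)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson([1, 2, 5], [1, 2, 5]) == 1.0

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_definition_formula(self):
        u, v = np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 10.0])
        cov = np.mean((u - u.mean()) * (v - v.mean()))
        expected = cov / (u.std() * v.std())
        assert pearson(u, v) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))


class TestConcordance:
    def test_fixture_within_tissue_averages(self, table2):
        report = concordance(table2)
        assert report.rounded() == {"BF": 0.98, "F": 0.95, "GF": 0.98,
                                    "GL": 0.95, "O": 0.97,
                                    "cross_tissue": 0.66}

    def test_every_tissue_meets_the_replicate_standard(self, table2):
        report = concordance(table2)
        assert all(report.in_band.values())

    def test_without_exclusion_everything_correlates(self, table2):
        """The abnormally abundant read drives every r toward one."""
        report = concordance(table2, exclusions=())
        assert all(round(v, 2) >= 0.99 for v in report.within_tissue.values())

    def test_scale_invariance_on_proportional_columns(self):
        table = pd.DataFrame({
            "locus": ["L"] * 4,
            "sequence": ["ACGTACGTACGTACGTAC", "TTGTACGTACGTACGTAC",
                         "GGGTACGTACGTACGTAC", "CCCTACGTACGTACGTAC"],
            "X1": [1.0, 2.0, 3.0, 4.0],
            "X2": [10.0, 20.0, 30.0, 40.0]})
        report = concordance(ExpressionMatrix(table), exclusions=())
        assert report.within_tissue["X"] == pytest.approx(1.0)

    def test_unknown_exclusion_warns(self, table2):
        with pytest.warns(UserWarning, match="not found"):
            concordance(table2, exclusions=("HE999999",))

    def test_excluding_proportional_sequence_keeps_ordering(self, table2):
        """Dropping a read whose profile is proportional across libraries
        must not reorder within-tissue correlations."""
        dedup = table2.dedup()
        probe = "A" * 10 + "CGTACGTACG"
        scaled = dedup.sum(axis=0) * 0.01
        table = table2.table.copy()
        table.loc[len(table)] = ["Lx", probe, "AXX", *scaled.tolist()]
        augmented = ExpressionMatrix(table)
        base = concordance(table2, exclusions=())
        dropped = concordance(augmented, exclusions=(probe,))
        order_base = sorted(base.within_tissue, key=base.within_tissue.get)
        order_drop = sorted(dropped.within_tissue,
                            key=dropped.within_tissue.get)
        assert order_base == order_drop


class TestPairwiseTTests:
    def test_identical_groups_give_p_one(self):
        assert student_t_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_unequal_groups_degenerate(self):
        assert student_t_pvalue([2, 2, 2], [3, 3, 3]) == 0.0
        assert student_t_pvalue([2, 2, 2], [2, 2, 2]) == 1.0

    def test_matches_closed_form_pooled_t(self):
        """Textbook pooled-variance t with df=4 on real expression values."""
        a = np.array([356.2, 210.4, 280.2])
        b = np.array([540.3, 700.2, 723.5])
        sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * sps.t.sf(abs(t), df=4)
        assert student_t_pvalue(a, b) == pytest.approx(expected, abs=1e-9)
        assert expected < 0.05

    def test_mir398_read_separates_eight_of_ten_pairs(self, table2):
        report = pairwise_ttests(table2, alpha=0.05)
        seq = table2.sequence_of("HE860366")
        assert int(report.n_significant[seq]) == 8

    def test_significance_counts_bounded(self, table2):
        report = pairwise_ttests(table2)
        assert report.pvalues.shape[1] == 10
        assert report.n_significant.between(0, 10).all()


class TestCanberra:
    def test_identity(self):
        assert canberra([1, 2, 0], [1, 2, 0]) == 0.0

    def test_disjoint_support(self):
        assert canberra([1, 0], [0, 1]) == pytest.approx(2.0)

    def test_hand_computed_terms(self):
        assert canberra([1, 3], [3, 1]) == pytest.approx(1.0)

    def test_metric_axioms_on_random_triples(self, rng):
        """Symmetry, identity and triangle inequality, 1000 triples."""
        for _ in range(1000):
            u, v, w = rng.random((3, 6)) * rng.integers(1, 100)
            duv, dvw, duw = canberra(u, v), canberra(v, w), canberra(u, w)
            assert duv >= 0
            assert duv == pytest.approx(canberra(v, u))
            assert canberra(u, u) == 0.0
            assert duw <= duv + dvw + 1e-9


def brute_force_complete_linkage(points, metric):
    """Exhaustive agglomeration for small n: returns merge partitions."""
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(metric(points[i], points[j]) for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append(a | b)
    return merges


class TestClustering:
    def test_identical_columns_merge_at_height_zero(self):
        table = pd.DataFrame({
            "locus": ["L"] * 2,
            "sequence": ["ACGTACGTACGTACGTAC", "TTGTACGTACGTACGTAC"],
            "X1": [1.0, 2.0], "X2": [1.0, 2.0], "Y1": [9.0, 1.0]})
        dend = cluster_samples(ExpressionMatrix(table), mode="all_reads",
                               average_replicates=False)
        assert dend.linkage_matrix[0, 2] == 0.0
        assert frozenset({"X1", "X2"}) in dend.clades()

    def test_topology_matches_brute_force_linkage(self, rng):
        """3-leaf toy against exhaustive enumeration of complete-linkage
        merges under hand-computable Canberra distances."""
        values = rng.random((6, 3)) * 10
        table = pd.DataFrame({
            "locus": ["L"] * 6,
            "sequence": [f"ACGTACGTACGTACGT{s}"
                         for s in ("AA", "AC", "AG", "AT", "CA", "CC")]})
        for j, col in enumerate(["P1", "Q1", "R1"]):
            table[col] = values[:, j]
        dend = cluster_samples(ExpressionMatrix(table),
                               average_replicates=False)
        cols = [values[:, j] for j in range(3)]
        merges = brute_force_complete_linkage(cols, canberra)
        labels = ["P1", "Q1", "R1"]
        expected = {frozenset(labels[i] for i in m) for m in merges}
        assert set(dend.clades()) == expected

    def test_fixture_replicates_cluster_together(self, table2):
        """Replicate-level dominant-only tree: each tissue's three
        replicates form one clade."""
        dend = cluster_samples(table2, mode="dominant_only",
                               average_replicates=False)
        clades = set(dend.clades())
        for tissue in ("BF", "F", "GF", "GL", "O"):
            assert frozenset(f"{tissue}{i}" for i in (1, 2, 3)) in clades

    def test_single_column_rejected(self):
        table = pd.DataFrame({"locus": ["L"], "sequence": ["ACGTACGTACGTACGTAC"],
                              "X1": [1.0]})
        with pytest.raises(ValueError, match="2 columns"):
            cluster_samples(ExpressionMatrix(table), average_replicates=False)


class TestArmRatio:
    def test_locus_3_16_O_is_inverted(self, table2):
        row = arm_ratio(table2, "3_16", "HE860348", "HE860347")
        assert round(row.tissue_mean["O"], 1) == 0.4
        assert row.tissue_class["O"] == "inverted"

    def test_locus_3_16_GF_GL_pooled_is_low(self, table2):
        row = arm_ratio(table2, "3_16", "HE860348", "HE860347")
        pooled = row.group_mean([l for l in table2.libraries
                                 if l.startswith(("GF", "GL"))])
        assert round(pooled, 1) == 5.7
        assert classify_ratio(pooled) == "low"

    def test_equal_abundance_is_boundary_low(self):
        table = pd.DataFrame({
            "locus": ["L"] * 2,
            "sequence": ["ACGTACGTACGTACGTAC", "TTGTACGTACGTACGTAC"],
            "accession": ["M1", "S1"],
            "A1": [5.0, 5.0], "A2": [7.0, 7.0], "A3": [2.0, 2.0]})
        row = arm_ratio(ExpressionMatrix(table), "L", "M1", "S1")
        assert row.tissue_mean["A"] == pytest.approx(1.0)
        assert row.tissue_class["A"] == "low"

    def test_zero_star_replicates_excluded(self):
        table = pd.DataFrame({
            "locus": ["L"] * 2,
            "sequence": ["ACGTACGTACGTACGTAC", "TTGTACGTACGTACGTAC"],
            "accession": ["M1", "S1"],
            "A1": [5.0, 0.0], "A2": [6.0, 2.0]})
        row = arm_ratio(ExpressionMatrix(table), "L", "M1", "S1")
        assert row.per_replicate["A1"] is None
        assert row.tissue_mean["A"] == pytest.approx(3.0)

    @pytest.mark.parametrize("ratio,label", [
        (250.0, "high"), (100.0, "high"), (50.0, "intermediate"),
        (10.0, "intermediate"), (5.0, "low"), (1.0, "low"),
        (0.4, "inverted"), (0.0, "inverted")])
    def test_ratio_bins(self, ratio, label):
        assert classify_ratio(ratio) == label
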