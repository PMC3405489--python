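import numpy as np
import pandas as pd
import pytest

from isomirkit.catalog import (annotate_isomir, build_catalog, dominance_table,
                               five_prime_composition, normalize_counts,
                               sample_invariant_dominants)
from isomirkit.io import ExpressionMatrix, LocusModel
from isomirkit.simulate import make_genome, plant_precursor


class TestNormalizeCounts:
    def test_zero_count_is_zero(self):
        assert normalize_counts(0, 700_000) == 0.0

    def test_hand_arithmetic(self):
        assert normalize_counts(7, 700_000) == pytest.approx(10.0)

    def test_single_read_in_real_library_total(self):
        # one read against the largest fixture library denominator
        assert normalize_counts(1, 797_297) == pytest.approx(1.2542, abs=1e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="BF9"):
            normalize_counts(5, 0, library_id="BF9")

    def test_linearity_under_common_scaling(self):
        assert normalize_counts(7 * 13, 700_000 * 13) == \
            normalize_counts(7, 700_000)


@pytest.fixture(scope="module")
def hairpin():
    genome = make_genome(400, 21)
    _, locus = plant_precursor(genome, 40, "TTGCACGTACGTACGTACGTAC", 22)
    return locus


class TestAnnotateIsomir:
    def test_mature_reference_is_origin(self, hairpin):
        ann = annotate_isomir(hairpin.mature_ref, hairpin)
        assert (ann.arm, ann.offset5, ann.offset3) == ("mature", 0, 0)

    def test_star_three_prime_extension(self, hairpin):
        ext = hairpin.precursor_seq[
            hairpin.star_start:hairpin.star_start + len(hairpin.star_ref) + 1]
        ann = annotate_isomir(ext, hairpin)
        assert (ann.arm, ann.offset5, ann.offset3) == ("star", 0, 1)

    def test_agrees_with_brute_force_placement(self, hairpin):
        """Exhaustive oracle over every precursor substring near the arms."""
        prec = hairpin.precursor_seq
        refs = {"mature": hairpin.mature_interval, "star": hairpin.star_interval}
        for arm, (r0, r1) in refs.items():
            for o5 in (-2, -1, 0, 1, 2):
                for o3 in (-2, -1, 0, 1, 2):
                    s, e = r0 + o5, r1 + o3
                    if s < 0 or e > len(prec) or e - s < 12:
                        continue
                    seq = prec[s:e]
                    if prec.count(seq) != 1:
                        continue  # ambiguous placements aside
                    ann = annotate_isomir(seq, hairpin)
                    assert (ann.arm, ann.offset5, ann.offset3) == (arm, o5, o3)

    def test_unplaceable_sequence_is_unaligned(self, hairpin):
        ann = annotate_isomir("TTTTTTTTTTTTTTTTTT", hairpin)
        assert ann.arm == "unaligned"

    def test_five_prime_variant_shifts_offset_by_one(self):
        """Two co-expressed variants differing by one 5'-terminal T."""
        longer = "TTTGCCAACCCCGCCCATTCCAA"
        shorter = "TTGCCAACCCCGCCCATTCCAA"
        prec = make_genome(20, 7) + longer + make_genome(60, 8)
        locus = LocusModel("1_26", precursor_seq=prec, mature_ref=shorter,
                           mature_start=21)
        a = annotate_isomir(longer, locus)
        b = annotate_isomir(shorter, locus)
        assert a.arm == b.arm == "mature"
        assert a.offset3 == b.offset3
        assert b.offset5 - a.offset5 == 1


class TestBuildCatalog:
    def test_fixture_catalog_shape(self, table2):
        matrix, records = build_catalog(table2)
        assert len(matrix.loci) == 26
        assert len(matrix.libraries) == 15
        assert len(records) == len(matrix.table)

    def test_simulated_catalog_recovers_truth_annotations(
            self, small_experiment):
        """Every generated isomiR is present with exact arm/offset calls."""
        libs = [r.library for r in small_experiment["cascades"].values()]
        assigns = {lib_id: r.locus_assignments
                   for lib_id, r in small_experiment["cascades"].items()}
        matrix, records = build_catalog(libs, small_experiment["loci"], assigns)
        by_key = {(r.locus_id, r.sequence): r for r in records}
        for lib_id, sim in small_experiment["sims"].items():
            truth = sim.truth_table
            for _, row in truth[truth["count"] > 0].iterrows():
                rec = by_key[(row["locus"], row["sequence"])]
                assert (rec.arm, rec.offset5, rec.offset3) == \
                    (row["arm"], row["offset5"], row["offset3"])

    def test_simulated_rpm_equals_truth_rpm(self, small_experiment):
        libs = [r.library for r in small_experiment["cascades"].values()]
        assigns = {lib_id: r.locus_assignments
                   for lib_id, r in small_experiment["cascades"].items()}
        matrix, _ = build_catalog(libs, small_experiment["loci"], assigns)
        for lib_id, sim in small_experiment["sims"].items():
            total = sim.truth.genome_matched_total
            sub = matrix.dedup()[lib_id]
            for seq, count in sim.truth.reads.items():
                assert sub[seq] == pytest.approx(count / total * 1e6,
                                                 rel=1e-12)


class TestDominance:
    def test_locus_1_25_ranking_in_first_library(self, table2):
        report = dominance_table(table2)
        ranked = report.per_library[("1_25", "BF1")]
        assert ranked[0] == (table2.sequence_of("HE860304"),
                             pytest.approx(1135.1))
        # second-most-frequent read (its accession is not unique in the
        # packaged table, so match by sequence)
        assert ranked[1] == ("GGGTGAGAGGTTGCCGGAAAGA", pytest.approx(32.6))

    def test_locus_3_16_star_dominates_O_replicates(self, table2):
        report = dominance_table(table2)
        star = table2.sequence_of("HE860347")
        for lib in ("O1", "O2", "O3"):
            assert report.dominant("3_16", lib) == star

    def test_single_variant_locus_has_no_second(self):
        table = pd.DataFrame({
            "locus": ["L"], "sequence": ["ACGTACGTACGTACGTAC"],
            "A1": [5.0], "A2": [4.0], "A3": [6.0]})
        report = dominance_table(ExpressionMatrix(table))
        assert report.dominant("L", "A1") == "ACGTACGTACGTACGTAC"
        assert report.second("L", "A1") is None

    def test_dominance_is_a_sorted_permutation(self, table2):
        report = dominance_table(table2)
        for (locus, lib), ranked in report.per_library.items():
            rpms = [v for _, v in ranked]
            assert rpms == sorted(rpms, reverse=True)
            expected = table2.per_locus(locus)[lib]
            assert set(s for s, _ in ranked) == \
                set(expected[expected > 0].index)

    def test_forced_dominance_switch_excluded_from_invariants(self):
        rows = []
        for locus, flip in (("L1", False), ("L2", True)):
            dom = dict(locus=locus, sequence=f"AAACGTACGTACGTACG{'A' if locus=='L1' else 'C'}",
                       A1=100.0, A2=100.0, B1=100.0 if not flip else 1.0,
                       B2=100.0 if not flip else 1.0)
            other = dict(locus=locus, sequence=f"GGGCGTACGTACGTACG{'A' if locus=='L1' else 'C'}",
                         A1=10.0, A2=10.0, B1=10.0, B2=10.0)
            rows += [dom, other]
        matrix = ExpressionMatrix(pd.DataFrame(rows))
        report = dominance_table(matrix)
        invariants = sample_invariant_dominants(report)
        assert report.invariant["L1"] and not report.invariant["L2"]
        assert invariants == {"AAACGTACGTACGTACGA"}

    def test_all_invariant_degenerate_case_yields_one_read_per_locus(self):
        rows = [dict(locus=f"L{i}", sequence="ACGT" * 4 + "AC" + "AT"[i % 2],
                     A1=50.0, B1=50.0) for i in range(2)]
        matrix = ExpressionMatrix(pd.DataFrame(rows))
        report = dominance_table(matrix)
        assert len(sample_invariant_dominants(report)) == 2


class TestFivePrimeComposition:
    def test_all_t_locus_is_one(self):
        table = pd.DataFrame({
            "locus": ["L", "L"],
            "sequence": ["TACGTACGTACGTACGTA", "TTACGTACGTACGTACGT"],
            "A1": [3.0, 1.0]})
        comp = five_prime_composition(ExpressionMatrix(table))
        assert comp["fraction_t"].iloc[0] == 1.0

    def test_hand_built_three_to_one_split(self):
        table = pd.DataFrame({
            "locus": ["L", "L"],
            "sequence": ["TACGTACGTACGTACGTA", "AACGTACGTACGTACGTA"],
            "A1": [3.0, 1.0]})
        comp = five_prime_composition(ExpressionMatrix(table))
        assert comp["fraction_t"].iloc[0] == pytest.approx(0.75)

    def test_fixture_dominant_of_1_25_starts_with_t(self, table2):
        comp = five_prime_composition(table2)
        row = comp[(comp["locus"] == "1_25") & (comp["library"] == "BF1")]
        assert bool(row["dominant_starts_t"].iloc[0])

    def test_zero_abundance_reported_missing(self):
        table = pd.DataFrame({
            "locus": ["L"], "sequence": ["TACGTACGTACGTACGTA"],
            "A1": [0.0], "A2": [1.0]})
        comp = five_prime_composition(ExpressionMatrix(table))
        assert np.isnan(comp.loc[comp["library"] == "A1",
                                 "fraction_t"].iloc[0])
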