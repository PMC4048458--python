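"""Length summaries, concordance, overlap rules, scorecards and Fisher tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genedist.compare import (
    AssociationRegion,
    ContingencyTable2x2,
    TopSNP,
    boundary_concordance,
    candidate_inclusion,
    candidate_miss_table,
    concordant_loci_table,
    extension_length_summary,
    fisher_exact_one_tailed,
    genes_containing_position,
    genes_overlapping_region,
    locus_scorecard,
)
from genedist.extend import GeneUnit
from genedist.genes import GeneRecord
from genedist.synthetic import make_fixture


def unit(chrom, left, right, name, method="srr", body=None):
    body = body or (left, right)
    g = GeneRecord(chrom, body[0], body[1], name)
    return GeneUnit(gene=g, left=left, right=right, method=method)


def ext_unit(name, ext_left, ext_right, method="srr"):
    g = GeneRecord("chr1", 1_000_000, 1_010_000, name)
    return GeneUnit(gene=g, left=g.start - ext_left, right=g.end + ext_right,
                    method=method)


class TestLengthSummary:
    def test_small_sample_median_and_iqr(self):
        units = [ext_unit("A", 10_000, 20_000), ext_unit("B", 30_000, 40_000)]
        s = extension_length_summary(units)
        assert s.median == pytest.approx(25.0)
        assert (s.iqr_low, s.iqr_high) == (pytest.approx(17.5), pytest.approx(32.5))
        assert s.n_extensions == 4

    def test_degenerate_iqr_when_all_equal(self):
        units = [ext_unit("A", 30_000, 30_000), ext_unit("B", 30_000, 30_000)]
        s = extension_length_summary(units)
        assert s.iqr_high - s.iqr_low == 0
        assert s.fraction_below[10.0] == 0.0 and s.fraction_above[10.0] == 1.0

    def test_empty_and_mixed_method_rejected(self):
        with pytest.raises(ValueError):
            extension_length_summary([])
        with pytest.raises(ValueError, match="mix"):
            extension_length_summary([ext_unit("A", 1, 1), ext_unit("B", 1, 1, "fixed")])


class TestConcordance:
    def test_identical_sets(self):
        a = [ext_unit("A", 10_000, 10_000), ext_unit("B", 5_000, 5_000)]
        c = boundary_concordance(a, a, tolerance=10_000)
        assert c.fraction_per_extension == 1.0 and c.fraction_per_gene == 1.0

    def test_all_shifted_beyond_tolerance(self):
        a = [ext_unit("A", 10_000, 10_000)]
        b = [ext_unit("A", 30_000, 30_000)]
        c = boundary_concordance(a, b, tolerance=10_000)
        assert c.fraction_per_extension == 0.0 and c.fraction_per_gene == 0.0

    def test_one_side_concordant_per_gene_zero(self):
        a = [ext_unit("A", 10_000, 10_000), ext_unit("B", 10_000, 10_000)]
        b = [ext_unit("A", 10_000, 40_000), ext_unit("B", 12_000, 35_000)]
        c = boundary_concordance(a, b, tolerance=10_000)
        assert c.fraction_per_extension == 0.5
        assert c.fraction_per_gene == 0.0

    def test_unmatched_genes_excluded(self, caplog):
        a = [ext_unit("A", 1, 1), ext_unit("ONLY_A", 1, 1)]
        b = [ext_unit("A", 1, 1)]
        with caplog.at_level("WARNING"):
            c = boundary_concordance(a, b)
        assert c.n_genes == 1


class TestOverlapRules:
    region = AssociationRegion("L1", "chr1", 100, 200)

    def test_partial_overlap_counts(self):
        assert genes_overlapping_region([unit("chr1", 50, 150, "G")], self.region) == ["G"]

    def test_touching_boundary_excluded(self):
        assert genes_overlapping_region([unit("chr1", 0, 100, "G")], self.region) == []

    def test_wrong_chromosome_and_empty(self):
        assert genes_overlapping_region([unit("chr2", 100, 200, "G")], self.region) == []

    def test_containment_half_open(self):
        units = [unit("chr1", 50_000, 250_000, "G")]
        assert genes_containing_position(units, TopSNP("rs1", "chr1", 100_000)) == ["G"]
        assert genes_containing_position(units, TopSNP("rs2", "chr1", 250_000)) == []

    def test_overlapping_units_both_returned(self):
        units = [unit("chr1", 0, 300, "A"), unit("chr1", 100, 400, "B")]
        snp = TopSNP("rs1", "chr1", 150)
        assert genes_containing_position(units, snp) == ["A", "B"]

    @given(pos=st.integers(0, 500), left=st.integers(0, 300), width=st.integers(1, 300),
           rstart=st.integers(0, 400), rwidth=st.integers(1, 200))
    @settings(derandomize=True, max_examples=200)
    def test_containment_implies_region_overlap(self, pos, left, width, rstart, rwidth):
        """A unit containing a position overlaps any region containing it."""
        u = unit("chr1", left, left + width, "G")
        region = AssociationRegion("L", "chr1", rstart, rstart + rwidth)
        snp = TopSNP("rs", "chr1", pos)
        if u.contains(pos) and region.start <= pos < region.end:
            assert genes_overlapping_region([u], region) == ["G"]


class TestScorecard:
    def test_exact_match_and_extras(self):
        region = AssociationRegion("L", "chr1", 0, 1000, expert_genes=("A", "B"))
        exact = [unit("chr1", 10, 20, "A"), unit("chr1", 30, 40, "B")]
        noisy = exact + [unit("chr1", 50, 60, "C", "fixed"), unit("chr1", 70, 80, "D", "fixed")]
        card = locus_scorecard({"srr": exact, "fixed": noisy}, [region])
        row = card.iloc[0]
        assert row["srr_extra"] == 0 and row["srr_missing"] == 0
        assert row["fixed_extra"] == 2 and row["fixed_missing"] == 0

    def test_missing_counted(self):
        region = AssociationRegion("L", "chr1", 0, 1000, expert_genes=("A", "B"))
        card = locus_scorecard({"srr": [unit("chr1", 10, 20, "A")]}, [region])
        assert card.iloc[0]["srr_missing"] == 1

    def test_printed_rows_fixture_totals(self):
        fx = make_fixture("wtccc-loci")
        card = locus_scorecard(fx.defs, fx.regions)
        total = card[card["locus"] == "Total"].iloc[0]
        assert total["expert"] == 107
        assert total["srr_extra"] == 7
        assert total["fixed_extra"] == 26
        assert total["srr_missing"] == 0 and total["fixed_missing"] == 0
        t = concordant_loci_table(card)
        assert (t.a, t.b, t.c, t.d) == (17, 1, 6, 12)


class TestCandidateInclusion:
    def test_miss_pattern_and_shared_exclusion(self):
        fx = make_fixture("rbc-candidates")
        inc = candidate_inclusion(fx.defs, fx.snps)
        assert len(inc) == 43
        assert int((~inc["srr_hit"]).sum()) == 4
        assert int((~inc["fixed_hit"]).sum()) == 10
        t = candidate_miss_table(inc)
        assert (t.a, t.b, t.c, t.d) == (1, 39, 7, 33)
        t_all = candidate_miss_table(inc, exclude_shared=False)
        assert (t_all.a, t_all.c) == (4, 10)


def enumerate_tail(a, b, c, d, direction):
    """Brute-force hypergeometric tail: enumerate every table with the
    observed margins and sum the probabilities of those at least as extreme."""
    r1, c1, n = a + b, a + c, a + b + c + d
    total = math.comb(n, r1)
    acc = 0
    for k in range(0, min(r1, c1) + 1):
        if r1 - k > n - c1:
            continue
        if (direction == "row1_lower" and k <= a) or (direction == "row1_higher" and k >= a):
            acc += math.comb(c1, k) * math.comb(n - c1, r1 - k)
    return acc / total


class TestFisher:
    def test_concordant_loci_value(self):
        p = fisher_exact_one_tailed(ContingencyTable2x2(17, 1, 6, 12), "row1_higher")
        assert p == pytest.approx(1.4831e-4, rel=1e-3)
        assert f"{p:.5f}" == "0.00015"

    def test_candidate_miss_value(self):
        p = fisher_exact_one_tailed(ContingencyTable2x2(1, 39, 7, 33), "row1_lower")
        assert p == pytest.approx(0.02838, rel=1e-3)
        assert f"{p:.3f}" == "0.028"

    def test_single_draw(self):
        assert fisher_exact_one_tailed(ContingencyTable2x2(0, 1, 1, 0), "row1_lower") == 0.5

    def test_degenerate_margins_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_one_tailed(ContingencyTable2x2(0, 0, 3, 4), "row1_lower") == 1.0

    def test_opposite_extreme_gives_one(self):
        # observed cell at the maximum -> P(X <= a) covers the whole support
        assert fisher_exact_one_tailed(ContingencyTable2x2(3, 0, 0, 3), "row1_lower") == 1.0

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            fisher_exact_one_tailed(ContingencyTable2x2(1, 1, 1, 1), "two_sided")

    def test_matches_enumeration_for_all_small_tables(self):
        """Exact agreement with full fixed-margin enumeration, total <= 12."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = ContingencyTable2x2(a, b, c, d)
                        r1, c1 = a + b, a + c
                        if r1 in (0, n) or c1 in (0, n):
                            continue  # degenerate: tested separately
                        for direction in ("row1_lower", "row1_higher"):
                            assert fisher_exact_one_tailed(t, direction) == pytest.approx(
                                enumerate_tail(a, b, c, d, direction), rel=1e-12
                            )

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact

        for (a, b, c, d), direction, alt in [
            ((17, 1, 6, 12), "row1_higher", "greater"),
            ((1, 39, 7, 33), "row1_lower", "less"),
            ((5, 2, 3, 8), "row1_higher", "greater"),
        ]:
            ours = fisher_exact_one_tailed(ContingencyTable2x2(a, b, c, d), direction)
            theirs = fisher_exact([[a, b], [c, d]], alternative=alt).pvalue
            assert ours == pytest.approx(theirs, rel=1e-10)

    @given(a=st.integers(0, 8), b=st.integers(0, 8), c=st.integers(0, 8), d=st.integers(0, 8))
    @settings(derandomize=True, max_examples=200)
    def test_row_swap_symmetry_and_range(self, a, b, c, d):
        """Swapping rows flips the tested tail; p is always in (0, 1]."""
        if a + b + c + d == 0 or (a + b) in (0, a + b + c + d) or (a + c) in (0, a + b + c + d):
            return
        p1 = fisher_exact_one_tailed(ContingencyTable2x2(a, b, c, d), "row1_lower")
        p2 = fisher_exact_one_tailed(ContingencyTable2x2(c, d, a, b), "row1_higher")
        assert 0 < p1 <= 1
        assert p1 == pytest.approx(p2, rel=1e-12)
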