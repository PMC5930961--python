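"""Directional tallies, bias ratios, and their cross-checks.

The independent oracle here is a deliberately naive column-by-column
enumerator that re-derives every tally from first principles (translate,
compare, count), kept free of any package counting code.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coldbias import (
    AMINO_ACIDS,
    aa_bias_ratio,
    aa_gc_regression,
    aa_substitution_matrix,
    bias_ratio,
    equal_gc_property_bias,
    gc_group_correlation,
    mean_gc_by_aa,
    per_codon_bias,
    property_bias,
    property_gc_correlation,
    tally_gc_substitutions,
)
from coldbias.codon_core import STANDARD_CODE, translate_codon
from coldbias.ortholog_pairing import CodonAlignment, ProteinAlignment
from coldbias.properties import default_property_table
from coldbias.substitution_asymmetry import (
    AASubstitutionMatrix,
    BiasResult,
    SubstitutionTally,
    property_bias_from_matrix,
)
from conftest import random_codon_alignment

MW = default_property_table("molecular_weight")


# ---------------------------------------------------------------- oracle
def oracle_recount(columns):
    """First-principles recount of every statistic over codon columns."""
    out = {
        "s1_syn": 0, "s2_syn": 0, "s1_nonsyn": 0, "s2_nonsyn": 0,
        "aa_counts": {}, "mw_smaller": 0, "mw_larger": 0,
        "eqgc_smaller": 0, "eqgc_larger": 0,
        "codon_num": {}, "codon_den": {},
    }
    for ca, cb in columns:
        if ca is None or cb is None:
            continue
        aa_a, aa_b = STANDARD_CODE.table[ca], STANDARD_CODE.table[cb]
        if aa_a == "*" or aa_b == "*":
            continue
        if ca == cb:
            continue
        syn = aa_a == aa_b
        key = "syn" if syn else "nonsyn"
        for i in range(3):
            if ca[i] == cb[i]:
                continue
            if ca[i] in "GC" and cb[i] in "AT":
                out[f"s1_{key}"] += 1
            if ca[i] in "AT" and cb[i] in "GC":
                out[f"s2_{key}"] += 1
        if (ca[2] in "GC") != (cb[2] in "GC"):
            out["codon_num"][(ca, key)] = out["codon_num"].get((ca, key), 0) + 1
            out["codon_den"][(cb, key)] = out["codon_den"].get((cb, key), 0) + 1
        if not syn:
            out["aa_counts"][(aa_a, aa_b)] = out["aa_counts"].get((aa_a, aa_b), 0) + 1
            if MW[aa_a] < MW[aa_b]:
                out["mw_smaller"] += 1
            elif MW[aa_a] > MW[aa_b]:
                out["mw_larger"] += 1
            gc_a = sum(ch in "GC" for ch in ca)
            gc_b = sum(ch in "GC" for ch in cb)
            if gc_a == gc_b:
                if MW[aa_a] < MW[aa_b]:
                    out["eqgc_smaller"] += 1
                elif MW[aa_a] > MW[aa_b]:
                    out["eqgc_larger"] += 1
    return out


def assert_matches_oracle(aln):
    expected = oracle_recount(aln.columns)
    for class_label, key in (("synonymous", "syn"), ("nonsynonymous", "nonsyn")):
        tally = tally_gc_substitutions(aln, class_label)
        assert tally.s1 == expected[f"s1_{key}"]
        assert tally.s2 == expected[f"s2_{key}"]
        per_codon = per_codon_bias([aln], class_label)
        for codon, result in per_codon.items():
            assert result.numerator_count == expected["codon_num"].get((codon, key), 0)
            assert result.denominator_count == expected["codon_den"].get((codon, key), 0)
    matrix = aa_substitution_matrix([aln])
    for cell, n in expected["aa_counts"].items():
        assert matrix.counts[cell] == n
    assert matrix.total_changes() == sum(expected["aa_counts"].values())
    mw_result = property_bias([aln], MW)
    assert (mw_result.numerator_count, mw_result.denominator_count) == (
        expected["mw_smaller"], expected["mw_larger"])
    eq_result = equal_gc_property_bias([aln], MW)
    assert (eq_result.numerator_count, eq_result.denominator_count) == (
        expected["eqgc_smaller"], expected["eqgc_larger"])


class TestTallyGCSubstitutions:
    def test_hand_counted_example(self):
        aln = CodonAlignment("a", "b", [("GGC", "GGT"), ("AAA", "AAG")])
        tally = tally_gc_substitutions(aln, "synonymous")
        assert (tally.s1, tally.s2) == (1, 1)

    def test_within_class_change_counts_neither(self):
        aln = CodonAlignment("a", "b", [("GGA", "GGT")])
        tally = tally_gc_substitutions(aln, "synonymous")
        assert (tally.s1, tally.s2) == (0, 0)
        assert tally.n_sites_scanned == 1

    def test_identical_sequences(self):
        aln = CodonAlignment("a", "b", [("GGA", "GGA")] * 5)
        tally = tally_gc_substitutions(aln, "synonymous")
        assert (tally.s1, tally.s2, tally.n_sites_scanned) == (0, 0, 0)

    def test_stop_columns_and_gaps_skipped(self):
        aln = CodonAlignment("a", "b", [("TGA", "GGA"), (None, "GGA"), ("GGC", "GGT")])
        tally = tally_gc_substitutions(aln, "synonymous")
        assert (tally.s1, tally.s2) == (1, 0)

    def test_strict_mode_drops_multi_hit_codons(self):
        aln = CodonAlignment("a", "b", [("TTA", "CTG"), ("GGC", "GGT")])
        default = tally_gc_substitutions(aln, "synonymous")
        strict = tally_gc_substitutions(aln, "synonymous", multi_hit="strict")
        # TTA/CTG differs at positions 1 and 3, both focal-AT vs reference-GC
        assert (default.s1, default.s2) == (1, 2)
        assert (strict.s1, strict.s2) == (1, 0)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        assert_matches_oracle(random_codon_alignment(rng, n_codons=10, allow_gaps=True))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_role_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_codon_alignment(rng, n_codons=12)
        swapped = aln.swapped()
        for class_label in ("synonymous", "nonsynonymous"):
            t1 = tally_gc_substitutions(aln, class_label)
            t2 = tally_gc_substitutions(swapped, class_label)
            assert (t1.s1, t1.s2) == (t2.s2, t2.s1)
        m1 = aa_substitution_matrix([aln])
        m2 = aa_substitution_matrix([swapped])
        assert m2.counts == m1.transposed().counts


class TestBiasRatio:
    @pytest.mark.parametrize(
        "s1,s2,ratio,chi2",
        [(10, 5, 2.0, None), (5, 5, 1.0, 0.0), (60, 40, 1.5, 4.0), (10, 0, None, 10.0)],
    )
    def test_arithmetic(self, s1, s2, ratio, chi2):
        result = bias_ratio(SubstitutionTally(s1=s1, s2=s2))
        assert result.ratio == (pytest.approx(ratio) if ratio is not None else None)
        if chi2 is not None:
            assert result.chi2 == pytest.approx(chi2)

    def test_zero_substitution_flag(self):
        result = bias_ratio(SubstitutionTally(s1=0, s2=0))
        assert result.ratio is None and result.zero_substitutions

    def test_low_count_flag(self):
        assert BiasResult(3, 9).low_count
        assert not BiasResult(3, 10).low_count


class TestAAMatrix:
    def test_cells_are_380(self):
        assert len(AASubstitutionMatrix().counts) == 380

    def test_counts_and_conserved(self):
        aln = ProteinAlignment("a", "b", "GGAA", "AAGG", score=0)
        matrix = aa_substitution_matrix([aln])
        assert matrix.counts[("G", "A")] == 2
        assert matrix.counts[("A", "G")] == 2
        assert matrix.conserved == 0

    def test_identity_alignment_all_zero(self):
        aln = ProteinAlignment("a", "b", "MKLV", "MKLV", score=0)
        matrix = aa_substitution_matrix([aln])
        assert matrix.total_changes() == 0 and matrix.conserved == 4

    def test_aa_bias_transpose_inverts_ratio(self):
        matrix = AASubstitutionMatrix()
        matrix.counts[("G", "A")] = 12
        matrix.counts[("A", "G")] = 6
        assert aa_bias_ratio(matrix, "G").ratio == pytest.approx(2.0)
        assert aa_bias_ratio(matrix.transposed(), "G").ratio == pytest.approx(0.5)


class TestPropertyBias:
    def test_symmetric_columns(self):
        aln = ProteinAlignment("a", "b", "GA", "AG", score=0)
        assert property_bias([aln], MW).ratio == pytest.approx(1.0)

    def test_mw_ordering_example(self):
        aln = ProteinAlignment("a", "b", "GGW", "WFG", score=0)
        result = property_bias([aln], MW)
        assert (result.numerator_count, result.denominator_count) == (2, 1)

    def test_leu_ile_tie_excluded(self):
        aln = ProteinAlignment("a", "b", "L", "I", score=0)
        result = property_bias([aln], MW)
        assert (result.numerator_count, result.denominator_count) == (0, 0)

    def test_matrix_route_agrees(self, rng):
        aln = random_codon_alignment(rng, n_codons=200)
        direct = property_bias([aln], MW)
        via_matrix = property_bias_from_matrix(aa_substitution_matrix([aln]), MW)
        assert (direct.numerator_count, direct.denominator_count) == (
            via_matrix.numerator_count, via_matrix.denominator_count)


class TestEqualGCPropertyBias:
    def test_unequal_gc_excluded(self):
        aln = CodonAlignment("a", "b", [("GCA", "ACA")])  # Ala(2) vs Thr(1)
        result = equal_gc_property_bias([aln], MW)
        assert (result.numerator_count, result.denominator_count) == (0, 0)

    def test_equal_gc_included(self):
        # GAT (Asp, gc=1) vs CAT (His, gc=1): MW(D)=133.10 < MW(H)=155.16
        aln = CodonAlignment("a", "b", [("GAT", "CAT")])
        result = equal_gc_property_bias([aln], MW)
        assert (result.numerator_count, result.denominator_count) == (1, 0)

    def test_synonymous_columns_excluded(self):
        aln = CodonAlignment("a", "b", [("GGA", "GGT")])
        result = equal_gc_property_bias([aln], MW)
        assert result.zero_substitutions


class TestCorrelationsAndRegression:
    def test_gc_group_monotone_ratios(self):
        per_codon = {
            "ATA": BiasResult(1, 10), "GAT": BiasResult(5, 10),
            "GCT": BiasResult(10, 10), "GCG": BiasResult(20, 10),
        }
        result = gc_group_correlation(per_codon)
        assert result.statistic == pytest.approx(1.0)

    def test_too_few_points_missing(self):
        assert gc_group_correlation({"GGA": BiasResult(1, 2)}).missing

    def test_regression_perfectly_linear(self):
        mean_gc = mean_gc_by_aa()
        per_aa = {aa: BiasResult(int(1000 * (1 + 2 * mean_gc[aa])), 1000)
                  for aa in AMINO_ACIDS}
        result = aa_gc_regression(per_aa)
        assert result.r_squared == pytest.approx(1.0, abs=1e-6)
        assert result.test.df == 18  # 20 amino acids

    def test_mw_gc_correlation_constant(self):
        """Genetic-code constant: free-AA mass vs mean codon GC, r = -0.36."""
        result = property_gc_correlation(MW)
        assert result.statistic == pytest.approx(-0.36, abs=0.005)
        assert result.p_value == pytest.approx(0.12, abs=0.005)

    def test_property_equal_to_gc_gives_one(self):
        mean_gc = mean_gc_by_aa()
        from coldbias.properties import PropertyTable
        table = PropertyTable("self", dict(mean_gc))
        assert property_gc_correlation(table).statistic == pytest.approx(1.0)
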