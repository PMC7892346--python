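"""Odds-ratio conventions, the exact Fisher test against an enumeration
oracle, allele-specificity verdicts, full-retention confirmation, rescue."""

import math
from itertools import product

import pytest
from hypothesis import given, strategies as st

from missplice.allele import (
    INCONCLUSIVE,
    REFERENCE_SPECIFIC,
    VARIANT_SPECIFIC,
    RescueCandidate,
    confirm_full_intron_retention,
    cryptic_allele_test,
    fisher_exact,
    odds_ratio,
    rescue_variants,
    skip_allele_test,
)
from missplice.evidence import AlleleObservation, ReadObservation

from conftest import make_variant


def enumerate_fisher(table):
    """Oracle: exhaustive hypergeometric enumeration with exact fractions.

    Probabilities are rational (binomial-coefficient ratios), so the
    two-sided probability-mass sum is computed with integer arithmetic and
    only converted to float at the end.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def weight(x):  # numerator of P(X=x) at common denominator C(n, c1)
        return math.comb(r1, x) * math.comb(n - r1, c1 - x)

    w_obs = weight(a)
    denom = math.comb(n, c1)
    total = sum(
        weight(x)
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if weight(x) <= w_obs
    )
    return total / denom


class TestOddsRatio:
    def test_plain_arithmetic(self):
        assert odds_ratio([[8, 2], [4, 6]]) == pytest.approx(6.0)

    def test_zero_denominator_is_infinite(self):
        assert odds_ratio([[9, 0], [45, 55]]) == math.inf

    def test_zero_numerator_is_zero(self):
        assert odds_ratio([[0, 9], [45, 55]]) == 0

    def test_doubly_degenerate_is_undefined(self):
        assert odds_ratio([[0, 0], [3, 4]]) is None

    @given(
        a=st.integers(1, 12), b=st.integers(1, 12),
        c=st.integers(1, 12), d=st.integers(1, 12),
    )
    def test_verdict_invariant_under_double_swap(self, a, b, c, d):
        """Swapping both rows and both columns preserves the OR (hence any
        >1 / <1 verdict)."""
        or1 = odds_ratio([[a, b], [c, d]])
        or2 = odds_ratio([[d, c], [b, a]])
        assert or1 == pytest.approx(or2)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[1, 0], [0, 1]], 1.0),
        ],
    )
    def test_symmetric_tables(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected)

    def test_nine_zero_table_matches_enumeration(self):
        table = [[0, 9], [10, 2]]
        assert fisher_exact(table) == pytest.approx(enumerate_fisher(table), abs=1e-12)

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher

        for table in ([[3, 7], [9, 2]], [[1, 11], [8, 4]], [[0, 5], [6, 1]]):
            assert fisher_exact(table) == pytest.approx(
                scipy_fisher(table).pvalue, rel=1e-9
            )

    def test_all_zero_table_raises(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_agrees_with_enumeration_on_small_margin_sweep(self):
        for a, b, c, d in product(range(0, 7), repeat=4):
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert abs(fisher_exact(table) - enumerate_fisher(table)) < 1e-9


def reads_with_alleles(alleles, qual=40, pos=100):
    return [
        ReadObservation(
            sample_id="S1", gene_id="g", read_id=f"r{i}", kind="unspliced_span",
            span=(pos - 20, pos + 20), allele_at=AlleleObservation(pos, b, qual),
        )
        for i, b in enumerate(alleles)
    ]


class TestCrypticAlleleTest:
    def test_all_mutant_reads_give_infinite_or(self):
        v = make_variant(100, ref="C", alt="T", dna_ref_count=10, dna_alt_count=10)
        res = cryptic_allele_test(v, reads_with_alleles("T" * 9))
        assert res.odds_ratio == math.inf
        assert res.verdict == VARIANT_SPECIFIC

    def test_two_informative_reads_inconclusive(self):
        v = make_variant(100, ref="C", alt="T")
        res = cryptic_allele_test(v, reads_with_alleles("TT"))
        assert res.verdict == INCONCLUSIVE

    def test_balanced_table_not_variant_specific(self):
        v = make_variant(100, ref="C", alt="T", dna_ref_count=10, dna_alt_count=10)
        res = cryptic_allele_test(v, reads_with_alleles("TTTTTCCCCC"))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.verdict == INCONCLUSIVE


class TestSkipAlleleTest:
    def test_underrepresented_mutant_is_reference_specific(self):
        v = make_variant(100, ref="C", alt="G", dna_ref_count=12, dna_alt_count=10)
        res = skip_allele_test(v, (30, 2))
        assert res.odds_ratio == pytest.approx((12 * 2) / (10 * 30))
        assert res.verdict == REFERENCE_SPECIFIC

    def test_balanced_not_reference_specific(self):
        v = make_variant(100, ref="C", alt="G", dna_ref_count=10, dna_alt_count=10)
        res = skip_allele_test(v, (10, 10))
        assert res.verdict == INCONCLUSIVE

    def test_zero_rna_coverage_inconclusive(self):
        v = make_variant(100, ref="C", alt="G")
        assert skip_allele_test(v, (0, 0)).verdict == INCONCLUSIVE


class TestConfirmFullIntronRetention:
    def test_intronic_83pct_alt_confirmed(self):
        v = make_variant(100, ref="C", alt="T", dna_ref_count=10, dna_alt_count=10)
        ok, why, _ = confirm_full_intron_retention(v, "proximal_intronic", reads_with_alleles("TTTTTC"))
        assert ok and why == "allele_confirmed"

    def test_intronic_two_alt_reads_unconfirmed(self):
        v = make_variant(100, ref="C", alt="T")
        ok, why, _ = confirm_full_intron_retention(v, "proximal_intronic", reads_with_alleles("TT"))
        assert not ok and why == "alt_reads_below_minimum"

    def test_intronic_exactly_80pct_not_above_threshold(self):
        v = make_variant(100, ref="C", alt="T", dna_ref_count=10, dna_alt_count=10)
        ok, why, _ = confirm_full_intron_retention(v, "proximal_intronic", reads_with_alleles("TTTTC"))
        assert not ok and why == "alt_fraction_below_80pct"

    def test_exonic_branch_returns_fisher_p(self):
        v = make_variant(100, ref="C", alt="T")
        ok, why, p = confirm_full_intron_retention(
            v, "exonic", reads_with_alleles("TTTTTTTTT"), spliced_counts=(20, 18)
        )
        assert why == "fisher_pending_fdr"
        expected = enumerate_fisher([[20, 18], [0, 9]])
        assert p == pytest.approx(expected, abs=1e-9)


class TestRescueVariants:
    def _cand(self, alleles, reason="distance", dist=60):
        v = make_variant(100, ref="C", alt="T")
        return RescueCandidate(
            variant=v, reason_code=reason,
            abnormal_reads=reads_with_alleles(alleles), distance_to_cryptic=dist,
        )

    def test_full_alt_support_within_100bp_rescued(self):
        assert rescue_variants([self._cand("TTTT")]) != []

    def test_67pct_alt_not_rescued(self):
        assert rescue_variants([self._cand("TTTTCC")]) == []

    def test_two_reads_not_rescued(self):
        assert rescue_variants([self._cand("TT")]) == []

    def test_beyond_rescue_window_not_rescued(self):
        assert rescue_variants([self._cand("TTTT", dist=150)]) == []

    def test_coverage_excluded_ignores_distance(self):
        assert rescue_variants([self._cand("TTTT", reason="coverage", dist=None)]) != []
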