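"""Ratio eligibility, background construction, z-test, FDR and filters."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from missplice.detection import (
    BackgroundDistribution,
    CohortCounts,
    DetectionConfig,
    bh_fdr,
    build_background,
    candidate_window,
    confounder_filter,
    event_ratio,
)
from missplice.detection import test_event as ratio_z_test
from missplice.gene_models import LocationCall

from conftest import make_variant


def manual_bh(p):
    """Independent step-up oracle: q_i = min over k>=rank(i) of p(k)*m/k."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestEventRatio:
    def test_simple_ratio(self):
        assert event_ratio(5, 45) == pytest.approx(0.10)

    def test_below_minimum_abnormal_reads_ineligible(self):
        assert event_ratio(2, 50) is None

    def test_boundary_three_three_eligible(self):
        assert event_ratio(3, 3) == pytest.approx(0.5)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            event_ratio(-1, 5)


class TestBuildBackground:
    def _cohort(self, n, normal=10, abnormal=0, prefix="s"):
        ids = [f"{prefix}{i}" for i in range(n)]
        loci = [("g", "intron", 0)]
        return CohortCounts(
            ids, loci,
            np.full((n, 1), normal), np.full((n, 1), abnormal),
        )

    def test_600_and_610_samples_testable(self):
        bg = build_background(("g", "intron", 0), self._cohort(600), self._cohort(610, prefix="t"))
        assert bg.testable()

    def test_501_and_400_untestable(self):
        bg = build_background(("g", "intron", 0), self._cohort(501), self._cohort(400, prefix="t"))
        assert not bg.testable()

    def test_samples_below_three_normal_reads_excluded(self):
        normal = self._cohort(600)
        cancer = self._cohort(600, prefix="t")
        cancer.normal_counts[:50, 0] = 2
        bg = build_background(("g", "intron", 0), normal, cancer)
        assert bg.n_cancer == 550

    def test_flagged_cancer_samples_excluded(self):
        normal = self._cohort(600)
        cancer = self._cohort(600, prefix="t")
        bg = build_background(("g", "intron", 0), normal, cancer, {"t0", "t1", "t2"})
        assert bg.n_cancer == 597


class TestTestEvent:
    def _bg(self, normal, cancer):
        return BackgroundDistribution(("g",), np.asarray(normal, float), np.asarray(cancer, float))

    def test_ratio_at_mean_gives_half_p(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.02, 0.01, size=600).clip(0, 1)
        res = ratio_z_test(float(vals.mean()), self._bg(vals, vals))
        assert res.z_normal == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5)

    def test_z3_right_tail_matches_independent_cdf(self):
        # frozen from the complementary-error-function form of the normal tail
        vals = np.concatenate([np.full(300, 0.01), np.full(300, 0.03)])  # mean .02 sd .01
        res = ratio_z_test(0.05, self._bg(vals, vals))
        assert res.z_normal == pytest.approx(3.0)
        expected = 0.5 * math.erfc(3.0 / math.sqrt(2))  # 0.0013498...
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.00135, abs=1e-5)

    def test_zero_sd_background_untestable(self):
        res = ratio_z_test(0.1, self._bg(np.zeros(600), np.zeros(600)))
        assert not res.testable and res.reason == "zero_background_sd"

    def test_top1_uses_empirical_percentile(self):
        vals = np.linspace(0, 0.099, 600)
        res = ratio_z_test(0.2, self._bg(vals, vals))
        assert res.top1_normal and res.top1_cancer
        res2 = ratio_z_test(0.05, self._bg(vals, vals))
        assert not res2.top1_normal

    def test_ineligible_ratio_propagates(self):
        res = ratio_z_test(None, self._bg(np.ones(600), np.ones(600)))
        assert res.reason == "ineligible_counts"


class TestBhFdr:
    def test_hand_applied_example(self):
        q = bh_fdr([0.01, 0.02, 0.9])
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.5])[0] == pytest.approx(0.5)

    def test_all_equal_ps_unchanged(self):
        q = bh_fdr([0.2] * 7)
        assert np.allclose(q, 0.2)

    def test_matches_manual_step_up_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), manual_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_q_values_invariant_to_input_order(self, p):
        perm = p[::-1]
        q1 = sorted(bh_fdr(p))
        q2 = sorted(bh_fdr(perm))
        assert np.allclose(q1, q2)


class TestConfounderFilter:
    def test_lone_deep_intronic_passes(self):
        v = make_variant(500)
        ok, reason = confounder_filter(v, [(v, False)])
        assert ok and reason is None

    def test_non_silent_in_gene_fails(self):
        v = make_variant(500)
        other = make_variant(900, sample="S1")
        ok, reason = confounder_filter(v, [(v, False), (other, True)])
        assert not ok and reason == "non_silent_in_gene"

    def test_nearby_variant_fails(self):
        v = make_variant(500)
        other = make_variant(510)
        ok, reason = confounder_filter(v, [(v, False), (other, False)])
        assert not ok and reason == "nearby_variant"

    def test_sv_breakpoint_fails(self):
        v = make_variant(500)
        ok, reason = confounder_filter(v, [(v, False)], sv_exon_breakpoint=True)
        assert not ok and reason == "sv_breakpoint_in_gene"


class TestCandidateWindow:
    def _loc(self, category, dist):
        return LocationCall(category=category, distance_bp=dist, side="donor")

    def test_proximal_within_30bp_eligible(self):
        assert candidate_window(self._loc("proximal_intronic", 7))

    def test_deep_intronic_near_cryptic_site_eligible(self, plus_transcript):
        from missplice.events import type_event
        from test_evidence import jread

        reads = [jread([(200, 250)], rid=f"r{i}") for i in range(3)]
        ev = type_event(reads, plus_transcript)
        loc = self._loc("deep_intronic", 62)
        assert candidate_window(loc, ev, variant_pos=262)  # 12 bp from cryptic acceptor
        assert not candidate_window(loc, ev, variant_pos=281)  # 31 bp away

    def test_deep_intronic_in_bp_window_eligible(self):
        loc = self._loc("deep_intronic", 200)
        assert candidate_window(loc, None, bp_positions=[1000], variant_pos=998)  # -2 of BP
        assert candidate_window(loc, None, bp_positions=[1000], variant_pos=1003)  # +3 of BP
        assert not candidate_window(loc, None, bp_positions=[1000], variant_pos=1004)
        assert not candidate_window(loc, None, bp_positions=[1000], variant_pos=994)  # -6

    def test_deep_intronic_far_from_everything_ineligible(self):
        loc = self._loc("deep_intronic", 200)
        assert not candidate_window(loc, None, variant_pos=5000)
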