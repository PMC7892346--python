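"""Permutation enrichment, PTC scanning, NMD classification, expression
effects and burden summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from missplice.downstream import (
    aberrant_exons,
    compare_effect_groups,
    expression_effect,
    fisher_exact_rxc,
    gene_burden_summary,
    nmd_classify,
    permutation_enrichment,
    ptc_scan,
)
from missplice.events import EventForm, SpliceEventCall
from missplice.gene_models import GenomeSequence, TranscriptModel


class TestPermutationEnrichment:
    def test_four_snv_worked_example_exact(self):
        """Universe of 4 with 1 hit, draw 2, observe the hit: 3 of the 6
        subsets contain it, so p = 1/2 exactly."""
        universe = ["a", "b", "c", "hit"]
        res = permutation_enrichment(["a", "hit"], universe, lambda x: x == "hit", exact=True)
        assert res.p_value == pytest.approx(0.5)
        assert res.n_permutations == 6

    def test_zero_observed_count_gives_p_one(self):
        universe = list(range(20))
        res = permutation_enrichment([0, 1], universe, lambda x: x > 100, n=500, seed=0)
        assert res.observed_count == 0
        assert res.p_value == 1.0

    def test_same_seed_reproduces_p(self):
        universe = list(range(200))
        obs = list(range(30))
        p1 = permutation_enrichment(obs, universe, lambda x: x < 50, n=2000, seed=9).p_value
        p2 = permutation_enrichment(obs, universe, lambda x: x < 50, n=2000, seed=9).p_value
        assert p1 == p2

    def test_strong_enrichment_small_p(self):
        universe = list(range(400))
        obs = list(range(30))  # all hits under the predicate below
        res = permutation_enrichment(obs, universe, lambda x: x < 40, n=2000, seed=1)
        assert res.p_value <= 1 / 2000 * 5

    def test_duplicate_sequences_counted_once(self):
        universe = [("s1", True), ("s1", True), ("s2", True), ("s3", False), ("s4", False)]
        res = permutation_enrichment(
            universe[:3],
            universe,
            lambda x: x[1],
            exact=True,
            sequence_key=lambda x: x[0],
        )
        assert res.observed_count == 2  # s1 twice counts once

    def test_observed_larger_than_universe_raises(self):
        with pytest.raises(ValueError):
            permutation_enrichment([1, 2], [1], lambda x: True)


def make_toy_transcript(n_exons=10, exon_len=90, intron_len=200, utr5=30, utr3=60):
    exons = []
    pos = 100
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    cds_start = exons[0][0] + utr5
    cds_end = exons[-1][1] - utr3
    return TranscriptModel(
        transcript_id="toy", gene_id="toy", chrom="chrToy", strand="+",
        exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
    )


class TestNmdClassify:
    def test_first_250nt_insensitive(self):
        assert nmd_classify(120, last_junction_cds_position=2000) == "insensitive"

    def test_within_55_of_last_junction_insensitive(self):
        assert nmd_classify(1960, last_junction_cds_position=2000) == "insensitive"

    def test_mid_cds_sensitive(self):
        assert nmd_classify(600, last_junction_cds_position=1100) == "sensitive"

    def test_no_junction_insensitive(self):
        assert nmd_classify(600, last_junction_cds_position=None) == "insensitive"

    def test_brute_force_over_toy_ten_exon_transcript(self):
        """Exhaustive agreement with a first-principles rule at every PTC
        position of a 10-exon toy transcript (90 nt exons, 30 nt 5'UTR)."""
        t = make_toy_transcript()
        # CDS nt coordinates of exon-exon junctions, built from exon lengths
        exon_lens = [e - s for s, e in t.exons]
        junctions_tx = list(itertools.accumulate(exon_lens))[:-1]
        cds_off = 30  # 5' UTR
        last_junction_cds = junctions_tx[-1] - cds_off
        cds_len = sum(exon_lens) - 30 - 60
        for ptc in range(1, cds_len + 1):
            expected = (
                "insensitive"
                if (ptc <= 250 or ptc >= last_junction_cds - 55)
                else "sensitive"
            )
            assert nmd_classify(ptc, last_junction_cds_position=last_junction_cds) == expected


def build_coding_genome(t: TranscriptModel, intron_fill="C", insert=None):
    """Sequence where the spliced CDS is an open reading frame of CAA codons
    ending in TAA; introns are stop-free filler unless ``insert`` places a
    sequence at a genomic position."""
    length = t.span[1] + 200
    seq = [intron_fill] * length
    # exonic content: UTR5 'A', CDS 'CAA' repeats, stop TAA, UTR3 'A'
    tx_positions = [p for s, e in t.exons_genomic for p in range(s, e)]
    cds_positions = [p for p in tx_positions if t.cds_start <= p < t.cds_end]
    for p in tx_positions:
        seq[p] = "A"
    body = "CAA" * ((len(cds_positions) - 3) // 3) + "TAA"
    for p, b in zip(cds_positions, body):
        seq[p] = b
    if insert:
        pos, s = insert
        seq[pos : pos + len(s)] = list(s)
    return GenomeSequence({t.chrom: "".join(seq)})


@pytest.fixture(scope="module")
def transcript():
    return make_toy_transcript(n_exons=4, exon_len=120, intron_len=150)


class TestPtcScan:

    def _event(self, locus, form):
        return SpliceEventCall(
            gene_id="toy", sample_id="S", locus=locus, event_type=form.event_type,
            forms=[form], abnormal_count=form.count,
        )

    def test_frame_preserving_stop_free_insertion_has_no_ptc(self, transcript):
        # retained intron of length 150 (=0 mod 3) filled with 'CAC' repeats
        t = make_toy_transcript(n_exons=4, exon_len=120, intron_len=150)
        genome = build_coding_genome(t, intron_fill="X")
        lo, hi = t.introns[1]
        fill = "CAC" * 50
        g = build_coding_genome(t)
        g = build_coding_genome(t, insert=(lo, fill))
        form = EventForm(kind="retention", event_type="full_intron_retention", count=5)
        call = ptc_scan(self._event(("intron", 1), form), t, g)
        assert call.ptc_cds_position is None
        assert call.nmd_class == "none"

    def test_pseudoexon_with_in_frame_stop(self):
        t = make_toy_transcript(n_exons=4, exon_len=150, intron_len=150)
        lo, hi = t.introns[1]
        pe = (lo + 40, lo + 40 + 30)  # 30 nt: frame-preserving
        g = build_coding_genome(t, insert=(pe[0], "CAGCAGCAGTAACAGCAGCAGCAGCAGCAG"))
        form = EventForm(
            kind="pseudoexon", event_type="pseudoexon_activation", count=5,
            cryptic_acceptor=pe[0], cryptic_donor=pe[1], pseudoexon=pe,
        )
        call = ptc_scan(self._event(("intron", 1), form), t, g)
        # upstream CDS: (150-30) + 150 = 270 nt; TAA begins at pseudoexon
        # offset 9, so its first base is CDS nt 280 (1-based)
        assert call.ptc_cds_position == 270 + 9 + 1
        # last junction of the aberrant transcript at CDS nt 450; 280 is past
        # 250 and more than 55 nt upstream of 450 -> degraded
        assert call.nmd_class == "sensitive"

    def test_highest_count_form_is_analysed(self, transcript):
        t = transcript
        lo, hi = t.introns[1]
        g = build_coding_genome(t, insert=(lo + 20, "TAAATAAATAA"))
        big = EventForm(kind="retention", event_type="full_intron_retention", count=12)
        small = EventForm(
            kind="cryptic_acceptor", event_type="partial_intron_retention", count=5,
            cryptic_acceptor=hi - 30,
        )
        event = SpliceEventCall(
            gene_id="toy", sample_id="S", locus=("intron", 1),
            event_type="full_intron_retention", forms=[big, small], abnormal_count=17,
        )
        call = ptc_scan(event, t, g)
        assert call.form_used == "retention"

    def test_utr_only_event_returns_none_class(self):
        # CDS starts in exon 1, so retaining intron 0 only alters the 5' UTR
        base = make_toy_transcript(n_exons=4, exon_len=120, intron_len=150)
        t = TranscriptModel(
            transcript_id="toy", gene_id="toy", chrom="chrToy", strand="+",
            exons=base.exons, cds_start=base.exons[1][0] + 9, cds_end=base.cds_end,
        )
        g = build_coding_genome(t)
        form = EventForm(kind="retention", event_type="full_intron_retention", count=4)
        call = ptc_scan(self._event(("intron", 0), form), t, g)
        assert call.nmd_class == "none"

    def test_noncoding_transcript_returns_none(self):
        t = TranscriptModel(
            transcript_id="nc", gene_id="nc", chrom="chrToy", strand="+",
            exons=((0, 100), (200, 300)),
        )
        g = GenomeSequence({"chrToy": "A" * 400})
        form = EventForm(kind="retention", event_type="full_intron_retention", count=4)
        call = ptc_scan(self._event(("intron", 0), form), t, g)
        assert call.nmd_class == "none"


class TestAberrantExons:
    def test_full_retention_merges_exons(self, plus_transcript):
        form = EventForm(kind="retention", event_type="full_intron_retention", count=3)
        exons = aberrant_exons(plus_transcript, ("intron", 0), form)
        assert exons == [(100, 400), (500, 600)]

    def test_partial_retention_extends_exon(self, plus_transcript):
        form = EventForm(
            kind="cryptic_acceptor", event_type="partial_intron_retention", count=3,
            cryptic_acceptor=250,
        )
        exons = aberrant_exons(plus_transcript, ("intron", 0), form)
        assert exons == [(100, 200), (250, 400), (500, 600)]

    def test_full_skip_removes_exon(self, plus_transcript):
        form = EventForm(
            kind="full_skip", event_type="full_exon_skipping", count=3, skipped_exons=(1,)
        )
        exons = aberrant_exons(plus_transcript, ("skip", (200, 500)), form)
        assert exons == [(100, 200), (500, 600)]

    def test_pseudoexon_inserts_exon(self, plus_transcript):
        form = EventForm(
            kind="pseudoexon", event_type="pseudoexon_activation", count=3,
            cryptic_acceptor=240, cryptic_donor=263, pseudoexon=(240, 263),
        )
        exons = aberrant_exons(plus_transcript, ("intron", 0), form)
        assert exons == [(100, 200), (240, 263), (300, 400), (500, 600)]


class TestExpressionAndBurden:
    def test_log2_ratio_against_five_controls(self):
        expr = pd.DataFrame(
            {f"s{i}": [10.0] for i in range(5)} | {"mut": [5.0]}, index=["g1"]
        )
        types = {s: "T" for s in expr.columns}
        eff = expression_effect("g1", "T", "mut", expr, types)
        assert eff == (pytest.approx(-1.0), 5)

    def test_four_controls_returns_none(self):
        expr = pd.DataFrame({f"s{i}": [10.0] for i in range(4)} | {"mut": [5.0]}, index=["g1"])
        types = {s: "T" for s in expr.columns}
        assert expression_effect("g1", "T", "mut", expr, types) is None

    def test_identical_groups_rank_sum_p_near_one(self):
        a = [0.1, -0.2, 0.05, 0.0, -0.1]
        assert compare_effect_groups(a, a) > 0.9

    def test_burden_proportions_and_threshold(self):
        mis = pd.DataFrame({"gene": ["A", "A"], "sample": ["s1", "s2"]})
        trunc = pd.DataFrame({"gene": ["A"] * 8, "sample": [f"t{i}" for i in range(8)]})
        out = gene_burden_summary(mis, trunc)
        row = out.set_index("gene").loc["A"]
        assert row.missplicing_fraction == pytest.approx(0.2)
        assert bool(row.above_threshold)

    def test_gene_with_no_mutant_samples_excluded(self):
        mis = pd.DataFrame(columns=["gene", "sample"])
        trunc = pd.DataFrame({"gene": ["B"], "sample": ["t"]})
        out = gene_burden_summary(mis, trunc)
        assert list(out.gene) == ["B"]


class TestFisherRxc:
    def test_matches_2x2_fisher(self):
        from missplice.allele import fisher_exact

        for table in ([[3, 7], [9, 2]], [[0, 5], [6, 1]]):
            assert fisher_exact_rxc(table) == pytest.approx(fisher_exact(table), abs=1e-9)

    def test_2x3_p_in_unit_interval(self):
        p = fisher_exact_rxc([[4, 1, 3], [2, 5, 2]])
        assert 0 < p <= 1
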