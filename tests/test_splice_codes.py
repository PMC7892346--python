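"""Splice-site strength models, U2 duplex energies, branchpoints, motifs."""

import itertools
import math

import numpy as np
import pytest

from missplice.gene_models import GenomeSequence
from missplice.splice_codes import (
    ACCEPTOR_LEN,
    DONOR_LEN,
    U2_MOTIF,
    U2_PERFECT_COMPLEMENT,
    MotifSet,
    SpliceStrengthModel,
    annotate_branchpoint,
    load_motif_set,
    motif_scan,
    pyrimidine_fraction,
    score_splice_site,
    strength_delta,
    u2_binding_energy,
)

from conftest import make_variant


class TestStrengthModel:
    def test_uniform_model_scores_zero_everywhere(self):
        m = SpliceStrengthModel.uniform("donor")
        for w in ("CAGGTAAGT", "AAAAAAAAA", "GTCATGCAT"):
            assert score_splice_site(w, m) == pytest.approx(0.0)

    def test_consensus_argmax_is_maximal(self):
        windows = ["CAGGTAAGT", "AAGGTAAGT", "CAGGTGAGT", "CAGGTAAGA"] * 5
        m = SpliceStrengthModel.train("donor", windows)
        consensus = "".join("ACGT"[int(np.argmax(row))] for row in m.probs)
        best = score_splice_site(consensus, m)
        rng = np.random.default_rng(3)
        for _ in range(200):
            w = "".join(rng.choice(list("ACGT"), size=DONOR_LEN))
            assert score_splice_site(w, m) <= best + 1e-12

    def test_hand_computed_add_one_smoothing(self):
        # 4 training 9-mers; position 0 counts: C=3, A=1
        windows = ["CAGGTAAGT", "CAGGTAAGT", "CAGGTAAGT", "AAGGTAAGT"]
        m = SpliceStrengthModel.train("donor", windows)
        # query differs from the training consensus only at position 0 ('A')
        score = score_splice_site("AAGGTAAGT", m)
        expected = math.log2((1 + 1) / 8 / 0.25) + 8 * math.log2((3 + 1 + 1) / 8 / 0.25)
        assert score == pytest.approx(expected)

    def test_wrong_length_and_non_acgt_raise(self):
        m = SpliceStrengthModel.uniform("acceptor")
        with pytest.raises(ValueError):
            score_splice_site("ACGT", m)
        with pytest.raises(ValueError):
            score_splice_site("N" * ACCEPTOR_LEN, m)

    def test_table_round_trip(self):
        m = SpliceStrengthModel.train("donor", ["CAGGTAAGT", "AAGGTCAGT"])
        m2 = SpliceStrengthModel.from_table(m.to_table(), "donor")
        for w in ("CAGGTAAGT", "TTTTTTTTT"):
            assert score_splice_site(w, m2) == pytest.approx(score_splice_site(w, m), abs=1e-4)

    def test_single_base_change_is_local(self):
        """A one-base change moves the score by exactly the difference of the
        two position terms (positional independence of the default model)."""
        m = SpliceStrengthModel.train("donor", ["CAGGTAAGT", "AAGGTCAGT", "CTGGTAAGC"])
        w1, w2 = "CAGGTAAGT", "CAGGTAAGA"
        diff = score_splice_site(w2, m) - score_splice_site(w1, m)
        i = 8
        expected = math.log2(m.probs[i, 0] / 0.25) - math.log2(m.probs[i, 3] / 0.25)
        assert diff == pytest.approx(expected)


@pytest.fixture(scope="module")
def donor_setup():
    seq = list("A" * 400)
    seq[197:206] = "CAGGTAAGT"  # donor window -3..+6 anchored at boundary 200
    genome = GenomeSequence({"chrT": "".join(seq)})
    model = SpliceStrengthModel.train(
        "donor", ["CAGGTAAGT", "AAGGTAAGT", "CAGGTGAGT", "CAGGCAAGT"]
    )
    return genome, model


class TestStrengthDelta:
    def test_consensus_breaking_plus5_change_is_negative(self, donor_setup):
        genome, model = donor_setup
        v = make_variant(204, ref="G", alt="A")  # +5 G->A breaks the invariant G
        wt, mut, delta = strength_delta(v, 200, genome, model, chrom="chrT", strand="+")
        assert delta < 0

    def test_toward_consensus_change_is_positive(self, donor_setup):
        genome, model = donor_setup
        seq = "A" * 197 + "CAGGCAAGT" + "A" * 194
        weak = GenomeSequence({"chrT": seq})  # +2 C instead of T
        v = make_variant(201, ref="C", alt="T")
        wt, mut, delta = strength_delta(v, 200, weak, model, chrom="chrT", strand="+")
        assert delta > 0

    def test_variant_outside_window_raises(self, donor_setup):
        genome, model = donor_setup
        v = make_variant(300, ref="A", alt="G")
        with pytest.raises(ValueError):
            strength_delta(v, 200, genome, model, chrom="chrT", strand="+")


class TestU2BindingEnergy:
    def test_perfect_complement_is_global_minimum(self):
        """Exhaustive over all 4^8 windows: the perfect reverse complement of
        the U2 motif attains the unique minimum energy."""
        best = u2_binding_energy(U2_PERFECT_COMPLEMENT)
        for w in map("".join, itertools.product("ACGT", repeat=8)):
            e = u2_binding_energy(w)
            if w == U2_PERFECT_COMPLEMENT:
                continue
            assert e > best

    def test_every_single_mutation_raises_energy(self):
        base = u2_binding_energy(U2_PERFECT_COMPLEMENT)
        count = 0
        for i in range(8):
            for b in "ACGT":
                if b == U2_PERFECT_COMPLEMENT[i]:
                    continue
                w = U2_PERFECT_COMPLEMENT[:i] + b + U2_PERFECT_COMPLEMENT[i + 1 :]
                assert u2_binding_energy(w) > base
                count += 1
        assert count == 24

    def test_t_u_spelling_equivalent(self):
        assert u2_binding_energy("UACUACAC") == u2_binding_energy("TACTACAC")

    def test_zero_complementary_window_is_pure_penalty(self):
        # vs motif reversed AUGAUGUG, each base chosen to pair nothing
        w = "CCACCACA"
        assert u2_binding_energy(w) == pytest.approx(8.0)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            u2_binding_energy("ACGTACG")


class TestAnnotateBranchpoint:
    def test_nearest_bp_relative_position(self):
        # acceptor at 1000 (+): variant 32 bp upstream at 968, BP 30 bp at 970
        hit = annotate_branchpoint(968, [970], acceptor_boundary=1000)
        assert hit == (970, -2, True)

    def test_variant_downstream_of_bp(self):
        hit = annotate_branchpoint(972, [970], acceptor_boundary=1000)
        assert hit == (970, 2, True)

    def test_equidistant_bps_choose_lower_coordinate(self):
        hit = annotate_branchpoint(970, [965, 975], acceptor_boundary=1000)
        assert hit[0] == 965

    def test_outside_15_to_60_range_returns_none(self):
        assert annotate_branchpoint(990, [970], acceptor_boundary=1000) is None  # 10 bp
        assert annotate_branchpoint(930, [970], acceptor_boundary=1000) is None  # 70 bp


@pytest.fixture(scope="module")
def motif_genome():
    #      0123456789012345
    seq = "AAAAACCGTACGGAAAAAAA" + "T" * 80
    return GenomeSequence({"chrT": seq})


class TestMotifScan:

    def test_gain_of_silencer_on_mutant_allele(self, motif_genome):
        ms = MotifSet(name="s", hexamers=frozenset({"CGTTCG"}), role="silencer")
        v = make_variant(9, ref="A", alt="T")  # CCGTACGG -> CCGTTCGG
        wt, mut, once = motif_scan(v, motif_genome, ms, chrom="chrT")
        assert wt == set() and mut == {"CGTTCG"} and once

    def test_multiple_matching_hexamers_counted_once(self, motif_genome):
        ms = MotifSet(name="e", hexamers=frozenset({"AAAAAA"}), role="enhancer")
        v = make_variant(70, ref="T", alt="A")
        seq = "A" * 100
        g = GenomeSequence({"chrT": seq[:70] + "T" + seq[71:]})
        wt, mut, once = motif_scan(v, g, ms, chrom="chrT")
        assert mut == {"AAAAAA"}  # six frames, one distinct hexamer
        assert once

    def test_matchless_alleles_empty(self, motif_genome):
        ms = MotifSet(name="e", hexamers=frozenset({"GGGGGG"}), role="enhancer")
        v = make_variant(9, ref="A", alt="T")
        wt, mut, _ = motif_scan(v, motif_genome, ms, chrom="chrT")
        assert wt == set() == mut

    def test_truncated_flank_raises(self, motif_genome):
        ms = MotifSet(name="e", hexamers=frozenset({"GGGGGG"}), role="enhancer")
        v = make_variant(2, ref="A", alt="T")
        with pytest.raises(ValueError, match="truncated"):
            motif_scan(v, motif_genome, ms, chrom="chrT")

    def test_load_motif_set_text(self):
        ms = load_motif_set("ACGTAC\nuuuuuu\n", "m", "enhancer")
        assert ms.hexamers == frozenset({"ACGTAC", "TTTTTT"})


def test_pyrimidine_fraction_of_ppt():
    seq = "A" * 180 + "T" * 17 + "CAG" + "A" * 100  # PPT all T upstream of acceptor at 200
    g = GenomeSequence({"chrT": seq})
    assert pyrimidine_fraction(g, "chrT", "+", 200) == pytest.approx(1.0)
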