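"""Synthetic genomes, cohorts and mutations with known ground truth.

The generator emulates the data a paired WGS/RNA-seq mis-splicing study
consumes, at the junction-evidence level rather than base-level sequencing:

* multi-exon genes with consensus-bearing donor (MAG|GTRAGT-like) and
  acceptor (PPT + YAG|) splice sites, a branchpoint adenosine in a
  U2-complementary context 18-40 bp upstream of each acceptor, and a CDS
  spanning several exons;
* cassettes planted in the middle introns — a decoy pseudoexon (silent in
  the wild type) with its own acceptor/donor context, enhancer/silencer
  hexamer sites, and a cryptic acceptor near the branchpoint — so that every
  mutation class of the ground-truth taxonomy is injectable;
* background cohorts (defaults: 600 normal + 600 cancer samples, satisfying
  the >500-sample minimum) whose per-locus abnormal-read ratios follow a
  Beta(1, 99) law (mean 1%) with Poisson(mean 40) spliced-read coverage;
* mutation carriers whose target locus splices abnormally at an injected
  ratio (default Uniform(0.15, 0.6)) with the abnormal reads carrying the
  variant allele at a configurable fidelity (default 1.0).

Background cohorts are emitted as per-sample count tables (a lossless
summary for ratio statistics); per-read evidence is emitted for mutation
carriers, where allele-level information matters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import CohortCounts
from .evidence import AlleleObservation, ReadObservation, write_evidence_table
from .gene_models import GenomeSequence, TranscriptModel, VariantRecord
from .splice_codes import BranchpointAnnotation, MotifSet

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SimulatedStudy",
    "MutationTruth",
    "MUTATION_CLASSES",
    "MAJOR_CLASSES",
    "generate_genome",
    "inject_mutation",
    "simulate_cohort",
    "simulate_study",
]

MUTATION_CLASSES = (
    "donor_disrupt",
    "ss_dinucleotide",
    "acceptor_disrupt",
    "ppt_disrupt",
    "bp_disrupt",
    "cryptic_donor_gain",
    "cryptic_donor_gain_gc",
    "cryptic_acceptor_gain",
    "cryptic_ppt_gain",
    "enhancer_gain",
    "silencer_loss",
    "neutral",
)

#: the five classes exercised in parameter-recovery runs: loss of the donor
#: site, the polypyrimidine tract and the branchpoint, and gain of cryptic
#: donor / acceptor sites
MAJOR_CLASSES = (
    "donor_disrupt",
    "ppt_disrupt",
    "bp_disrupt",
    "cryptic_donor_gain",
    "cryptic_acceptor_gain",
)

_STOP_ALL_FRAMES = "TAAATAAATAA"  # stop codon in every reading frame

# position probability laws for authentic splice sites (approximate mammalian
# consensus; the +1/+2 GT and -2/-1 AG dinucleotides are invariant)
_DONOR_LAW = {  # intronic +3..+6
    3: ("AGCT", (0.60, 0.35, 0.02, 0.03)),
    4: ("ACGT", (0.70, 0.08, 0.10, 0.12)),
    5: ("GACT", (0.82, 0.06, 0.05, 0.07)),
    6: ("TACG", (0.50, 0.17, 0.16, 0.17)),
}
_PPT_LAW = ("CTAG", (0.35, 0.45, 0.10, 0.10))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort (see module docstring)."""

    n_genes: int = 50
    n_exons: int = 5
    n_normal_samples: int = 600
    n_cancer_samples: int = 600
    bg_alpha: float = 1.0
    bg_beta: float = 99.0
    coverage_mean: float = 40.0
    coverage_floor: int = 0  # minimum spliced-read coverage at mutated loci
    effect_low: float = 0.15
    effect_high: float = 0.6
    allele_fidelity: float = 1.0
    frac_flagged: float = 0.05  # cancer samples with non-silent lesions per gene
    dna_depth_mean: float = 60.0
    dna_vaf: float = 0.45
    nmd_expression_factor: float = 0.5
    n_passenger_deep: int = 200
    n_motifs: int = 60
    qualities: tuple[int, ...] = (41, 37, 33, 27, 17)
    quality_probs: tuple[float, ...] = (0.55, 0.20, 0.12, 0.08, 0.05)


@dataclass
class IntronFeatures:
    """Planted feature coordinates inside one intron (genomic, plus strand)."""

    interval: tuple[int, int]
    donor_flank: tuple[int, int]  # +3..+6 genomic span
    bp_pos: int
    bp_window: tuple[int, int]  # genomic span of the -5..+3 context
    ppt: tuple[int, int]  # depths 3..20
    has_cassette: bool = False
    pe: tuple[int, int] | None = None  # decoy pseudoexon interval
    pe_acceptor_plus1: int | None = None  # weak exonic +1 base of the decoy acceptor
    pe_donor_minus1: int | None = None  # weak -1 base of the decoy donor
    pe_donor_gc: tuple[int, int] | None = None  # GC dinucleotide of a second decoy donor
    silencer_site: tuple[int, int] | None = None
    enhancer_site: tuple[int, int] | None = None  # 1-mismatch enhancer; middle base restores
    enhancer_fix: tuple[int, str, str] | None = None  # (pos, ref, alt) restoring the motif
    bp_cryptic_acceptor: int | None = None  # boundary of the cryptic acceptor near the BP
    filler: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneFeatures:
    gene_id: str
    chrom: str
    transcript: TranscriptModel
    introns: list[IntronFeatures]


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    genes: dict[str, GeneFeatures]
    branchpoints: dict[str, list[BranchpointAnnotation]]
    enhancers: MotifSet
    silencers: MotifSet

    def to_fasta(self) -> str:
        out = []
        for name, seq in self.sequences.items():
            out.append(f">{name}")
            out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    def to_gtf(self) -> str:
        lines = []
        for t in self.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            lo, hi = t.span
            lines.append(
                f"{t.chrom}\tsim\ttranscript\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t{attrs}"
            )
            for s, e in t.exons_genomic:
                lines.append(f"{t.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}")
            if t.cds_start is not None:
                lines.append(
                    f"{t.chrom}\tsim\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t{t.strand}\t0\t{attrs}"
                )
        return "\n".join(lines) + "\n"

    def branchpoint_table(self) -> str:
        rows = ["chrom\tpos\tsource\tgene_id"]
        for gene, bps in self.branchpoints.items():
            chrom = self.genes[gene].chrom
            rows.extend(f"{chrom}\t{b.pos + 1}\t{b.source}\t{gene}" for b in bps)
        return "\n".join(rows) + "\n"


@dataclass
class MutationTruth:
    """Ground-truth record for one injected mutation."""

    variant_id: str
    mutation_class: str
    gene_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    intended_event: str | None
    intended_ratio: float
    allele_fidelity: float
    target_intron: int | None
    cryptic_donor: int | None = None
    cryptic_acceptor: int | None = None
    pseudoexon: tuple[int, int] | None = None
    skip_junction: tuple[int, int] | None = None
    ptc_expected: bool | None = None
    nmd_expected: str | None = None
    variant_transcribed: bool = True


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, bases: str, probs: Sequence[float]) -> str:
    return bases[rng.choice(len(bases), p=np.asarray(probs) / np.sum(probs))]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


_NONSTOP_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    assert n_nt % 3 == 0
    return "".join(rng.choice(_NONSTOP_CODONS, size=n_nt // 3))


def _build_intron(
    rng: np.random.Generator, with_cassette: bool, enhancer: str, silencer: str
) -> tuple[str, dict]:
    """Intron sequence (relative coordinates) plus a feature dict."""
    feats: dict = {}
    head = "GT" + "".join(_draw(rng, *_DONOR_LAW[p]) for p in (3, 4, 5, 6))
    head += "C" + _STOP_ALL_FRAMES  # stops near the donor: retained in full retention
    feats["donor_flank_rel"] = (2, 6)  # +3..+6 (0-based rel offsets 2..5)

    parts = [head]
    cursor = len(head)

    if with_cassette:
        gap = _random_seq(rng, 22)
        parts.append(gap)
        cursor += len(gap)
        ppt_decoy = "TTACTTTGCT" + "AG"  # decoy PPT keeps two purines for the cryptic-PPT-gain class
        parts.append(ppt_decoy)
        cursor += len(ppt_decoy)
        pe_lo = cursor
        enh_weak = enhancer[:3] + ("A" if enhancer[3] != "A" else "C") + enhancer[4:]
        body = (
            "A"  # weak exonic +1 of the decoy acceptor (G restores consensus)
            + "GCT"
            + _STOP_ALL_FRAMES
            + silencer
            + _random_seq(rng, 14)
            + enh_weak
            + _random_seq(rng, 14)
        )
        body += _random_seq(rng, 100 - len(body) - 3) + "CAA"  # weak -1 'A' before the decoy donor
        assert len(body) == 100
        parts.append(body)
        cursor += len(body)
        pe_hi = cursor
        feats["pe_rel"] = (pe_lo, pe_hi)
        feats["pe_acceptor_plus1_rel"] = pe_lo
        feats["pe_donor_minus1_rel"] = pe_hi - 1
        feats["silencer_rel"] = (pe_lo + 15, pe_lo + 21)
        feats["enh_rel"] = (pe_lo + 35, pe_lo + 41)
        feats["enh_fix_rel"] = (pe_lo + 38, enh_weak[3], enhancer[3])
        tail = "GTAAGT"  # pre-existing strong GT after the decoy donor
        parts.append(tail)
        cursor += len(tail)
        # a second decoy donor context with GC (GC->GT conversion class)
        gc_gap = _random_seq(rng, 8)
        gc_site = "GCAAGT"
        parts.append(gc_gap + gc_site)
        feats["pe_donor_gc_rel"] = (cursor + len(gc_gap), cursor + len(gc_gap) + 2)
        cursor += len(gc_gap) + len(gc_site)
        filler_len = int(rng.integers(25, 45))
    else:
        filler_len = int(rng.integers(60, 140))

    filler = _random_seq(rng, filler_len)
    feats["filler_rel"] = (cursor, cursor + filler_len)
    parts.append(filler)
    cursor += filler_len

    # acceptor-proximal block, built right-to-left from fixed depths
    d_bp = int(rng.choice([24, 25, 27, 28, 30]))  # keeps the retained segment frameshifting
    # depths (1-based from the last intron base): AG at 1-2, PPT at 3-20,
    # BP context spans depths d_bp+5 .. d_bp-3, cryptic AG at d_bp+12..d_bp+11
    block_len = d_bp + 14
    block = list(_random_seq(rng, block_len))

    def set_depth(depth: int, base: str) -> None:
        block[block_len - depth] = base

    set_depth(2, "A")
    set_depth(1, "G")
    set_depth(3, "C")  # acceptor intronic +3 consensus pyrimidine
    for depth in range(4, 21):
        set_depth(depth, _draw(rng, *_PPT_LAW))
    context = "TACTA" + "A" + "CAC"  # perfect U2 complement around the BP adenosine
    for i, base in enumerate(context):
        set_depth(d_bp + 5 - i, base)
    set_depth(d_bp + 12, "A")
    set_depth(d_bp + 11, "G")
    parts.append("".join(block))
    total = cursor + block_len
    feats["d_bp"] = d_bp
    feats["length"] = total
    return "".join(parts), feats


def generate_genome(config: SimulationConfig, seed: int) -> SyntheticGenome:
    """Deterministically generate the synthetic genome, gene models, motif
    sets and branchpoint annotation for one study."""
    rng = np.random.default_rng(seed)

    # disjoint synthetic enhancer/silencer hexamer sets
    all_hex = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    hexamers = rng.permutation(["".join(p) for p in itertools.product(all_hex, all_hex)])
    enh = frozenset(hexamers[: config.n_motifs])
    sil = frozenset(hexamers[config.n_motifs : 2 * config.n_motifs])
    enhancers = MotifSet(name="synthetic_enhancers", hexamers=enh, role="enhancer")
    silencers = MotifSet(name="synthetic_silencers", hexamers=sil, role="silencer")
    enh_list = sorted(enh)
    sil_list = sorted(sil)

    cds_chunks = (270, 150, 150, 150, 120)[: config.n_exons]
    sequences: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    genes: dict[str, GeneFeatures] = {}
    branchpoints: dict[str, list[BranchpointAnnotation]] = {}

    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        chrom = f"chr_{gene_id}"
        pad = 120
        utr5, utr3 = 60, 80

        exon_seqs = []
        for e, chunk in enumerate(cds_chunks):
            cds = _random_cds(rng, chunk)
            if e < len(cds_chunks) - 1:
                cds = cds[:-3] + "CAG"  # codon-aligned consensus MAG donor flank
            if e > 0:
                cds = "GCT" + cds[3:]  # exonic acceptor flank starting with G
            if e == 0:
                cds = "ATG" + cds[3:]
                exon_seqs.append(_random_seq(rng, utr5 - 3) + "CAT" + cds)
            elif e == len(cds_chunks) - 1:
                exon_seqs.append(cds + "TAA" + _random_seq(rng, utr3))
            else:
                exon_seqs.append(cds)

        enh_hex = enh_list[g % len(enh_list)]
        sil_hex = sil_list[g % len(sil_list)]
        intron_data = []
        for k in range(config.n_exons - 1):
            with_cassette = k in (1, 2)
            intron_data.append(_build_intron(rng, with_cassette, enh_hex, sil_hex))

        seq_parts = [_random_seq(rng, pad)]
        pos = pad
        exon_ivs, intron_feats = [], []
        for e, ex in enumerate(exon_seqs):
            exon_ivs.append((pos, pos + len(ex)))
            seq_parts.append(ex)
            pos += len(ex)
            if e < len(intron_data):
                iseq, f = intron_data[e]
                ilo, ihi = pos, pos + len(iseq)
                seq_parts.append(iseq)
                pos = ihi
                d_bp = f["d_bp"]
                bp_pos = ihi - d_bp
                feats = IntronFeatures(
                    interval=(ilo, ihi),
                    donor_flank=(ilo + f["donor_flank_rel"][0], ilo + f["donor_flank_rel"][1]),
                    bp_pos=bp_pos,
                    bp_window=(bp_pos - 5, bp_pos + 4),
                    ppt=(ihi - 20, ihi - 3),
                    has_cassette="pe_rel" in f,
                    filler=[(ilo + f["filler_rel"][0], ilo + f["filler_rel"][1])],
                    bp_cryptic_acceptor=bp_pos - 10,
                )
                if feats.has_cassette:
                    feats.pe = (ilo + f["pe_rel"][0], ilo + f["pe_rel"][1])
                    feats.pe_acceptor_plus1 = ilo + f["pe_acceptor_plus1_rel"]
                    feats.pe_donor_minus1 = ilo + f["pe_donor_minus1_rel"]
                    feats.pe_donor_gc = (ilo + f["pe_donor_gc_rel"][0], ilo + f["pe_donor_gc_rel"][1])
                    feats.silencer_site = (ilo + f["silencer_rel"][0], ilo + f["silencer_rel"][1])
                    feats.enhancer_site = (ilo + f["enh_rel"][0], ilo + f["enh_rel"][1])
                    fp, ref, alt = f["enh_fix_rel"]
                    feats.enhancer_fix = (ilo + fp, ref, alt)
                intron_feats.append(feats)
        seq_parts.append(_random_seq(rng, pad))
        sequence = "".join(seq_parts)

        cds_start = exon_ivs[0][0] + utr5
        cds_end = exon_ivs[-1][0] + cds_chunks[-1] + 3  # includes the TAA stop
        t = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            chrom=chrom,
            strand="+",
            exons=tuple(exon_ivs),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        sequences[chrom] = sequence
        transcripts.append(t)
        genes[gene_id] = GeneFeatures(gene_id=gene_id, chrom=chrom, transcript=t, introns=intron_feats)
        branchpoints[gene_id] = [
            BranchpointAnnotation(chrom=chrom, pos=f.bp_pos, source="known") for f in intron_feats
        ]

    return SyntheticGenome(
        genome=GenomeSequence(sequences),
        sequences=sequences,
        transcripts=transcripts,
        genes=genes,
        branchpoints=branchpoints,
        enhancers=enhancers,
        silencers=silencers,
    )


# ---------------------------------------------------------------------------
# mutation injection
# ---------------------------------------------------------------------------


def _hexamer_frames(seq11: str) -> set[str]:
    return {seq11[i : i + 6] for i in range(6)}


def inject_mutation(
    sg: SyntheticGenome,
    mutation_class: str,
    rng: np.random.Generator,
    config: SimulationConfig = SimulationConfig(),
    exclude_genes: Iterable[str] = (),
) -> MutationTruth | None:
    """Plant one mutation of the requested class at a feasible locus.

    Each class corresponds to one single-base edit with a defined intended
    splicing outcome; infeasible draws (no qualifying site after a bounded
    search) return ``None`` with a log message.  Sample assignment and read
    simulation happen later in :func:`simulate_cohort`.
    """
    if mutation_class not in MUTATION_CLASSES:
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    excluded = set(exclude_genes)
    candidates = [g for g in sorted(sg.genes) if g not in excluded]
    if not candidates:
        log.warning("no genes left for class %s", mutation_class)
        return None
    gene_id = candidates[int(rng.integers(len(candidates)))]
    gf = sg.genes[gene_id]
    seq = sg.sequences[gf.chrom]
    ratio = float(rng.uniform(config.effect_low, config.effect_high))

    def base(p: int) -> str:
        return seq[p]

    def truth(**kw) -> MutationTruth:
        defaults = dict(
            variant_id="",
            mutation_class=mutation_class,
            gene_id=gene_id,
            sample_id="",
            chrom=gf.chrom,
            intended_ratio=ratio,
            allele_fidelity=config.allele_fidelity,
        )
        defaults.update(kw)
        return MutationTruth(**defaults)

    cassette_introns = [k for k, f in enumerate(gf.introns) if f.has_cassette]

    if mutation_class in ("donor_disrupt", "ss_dinucleotide"):
        k = int(rng.choice(cassette_introns))
        f = gf.introns[k]
        ilo, ihi = f.interval
        if mutation_class == "ss_dinucleotide":
            pos = ilo + int(rng.integers(0, 2))
            alt = {"G": "A", "T": "C"}[base(pos)]
        else:
            # pick a +3..+6 position carrying the consensus mode and break it
            laws = {p: _DONOR_LAW[p] for p in (3, 4, 5, 6)}
            options = []
            for p, (bases, probs) in laws.items():
                gpos = ilo + p - 1
                if base(gpos) == bases[int(np.argmax(probs))]:
                    options.append((gpos, bases[int(np.argmin(probs))]))
            if not options:
                return None
            pos, alt = options[int(rng.integers(len(options)))]
        return truth(
            pos=pos,
            ref=base(pos),
            alt=alt,
            intended_event="full_intron_retention",
            target_intron=k,
            ptc_expected=True,
            nmd_expected="sensitive" if k in (0, 1, 2) else "insensitive",
        )

    if mutation_class in ("acceptor_disrupt", "ppt_disrupt"):
        k = int(rng.choice(cassette_introns))
        f = gf.introns[k]
        ilo, ihi = f.interval
        if mutation_class == "acceptor_disrupt":
            pos = ihi - 3  # intronic +3 from the acceptor
            alt = "G" if base(pos) != "G" else "A"
        else:
            depths = [d for d in range(4, 21) if base(ihi - d) in "CT"]
            if not depths:
                return None
            d = int(rng.choice(depths))
            pos = ihi - d
            alt = "A" if base(pos) == "T" else "G"
        skipped_exon = k + 1
        exs = gf.transcript.exons_genomic
        skip_junction = (exs[k][1], exs[k + 2][0])
        return truth(
            pos=pos,
            ref=base(pos),
            alt=alt,
            intended_event="full_exon_skipping",
            target_intron=k,
            skip_junction=skip_junction,
            ptc_expected=False,  # internal CDS chunks are frame-preserving and stop-free
            nmd_expected=None,
        )

    if mutation_class == "bp_disrupt":
        k = int(rng.choice(cassette_introns))
        f = gf.introns[k]
        # break a U2-complementary base in the -5..+3 context (BP excluded)
        offsets = [o for o in range(-5, 4) if o != 0]
        o = int(rng.choice(offsets))
        pos = f.bp_pos + o
        ref = base(pos)
        # choose an alt that neither Watson-Crick- nor wobble-pairs the motif
        window_index = o + 5 if o < 0 else o + 4  # position within the 8-mer
        motif_rev = "GUGUAGUA"[::-1]
        m = motif_rev[window_index]
        non_pairing = [b for b in "ACGT" if b != ref and (b, m) not in
                       {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("T", "G")}]
        if not non_pairing:
            return None
        alt = non_pairing[int(rng.integers(len(non_pairing)))]
        return truth(
            pos=pos,
            ref=ref,
            alt=alt,
            intended_event="partial_intron_retention",
            target_intron=k,
            cryptic_acceptor=f.bp_cryptic_acceptor,
            ptc_expected=True,
            nmd_expected="sensitive" if k in (0, 1, 2) else "insensitive",
        )

    if mutation_class in (
        "cryptic_donor_gain",
        "cryptic_donor_gain_gc",
        "cryptic_acceptor_gain",
        "cryptic_ppt_gain",
        "enhancer_gain",
        "silencer_loss",
    ):
        k = int(rng.choice(cassette_introns))
        f = gf.introns[k]
        ilo, ihi = f.interval
        pe_lo, pe_hi = f.pe
        common = dict(target_intron=k, ptc_expected=True, nmd_expected="sensitive")
        if mutation_class == "cryptic_donor_gain":
            pos = f.pe_donor_minus1
            return truth(
                pos=pos, ref=base(pos), alt="G",
                intended_event="pseudoexon_activation",
                cryptic_donor=pe_hi, cryptic_acceptor=pe_lo, pseudoexon=(pe_lo, pe_hi),
                **common,
            )
        if mutation_class == "cryptic_donor_gain_gc":
            gc_lo, gc_hi = f.pe_donor_gc
            pos = gc_lo + 1  # the C of GC; C->T creates GT
            return truth(
                pos=pos, ref=base(pos), alt="T",
                intended_event="pseudoexon_activation",
                cryptic_donor=gc_lo, cryptic_acceptor=pe_lo, pseudoexon=(pe_lo, gc_lo),
                variant_transcribed=False,
                **common,
            )
        if mutation_class == "cryptic_acceptor_gain":
            pos = f.pe_acceptor_plus1
            return truth(
                pos=pos, ref=base(pos), alt="G",
                intended_event="partial_intron_retention",
                cryptic_acceptor=pe_lo,
                **common,
            )
        if mutation_class == "cryptic_ppt_gain":
            # purine in the decoy PPT (depths 4..14 upstream of the decoy AG)
            depths = [d for d in range(3, 13) if base(pe_lo - 2 - d) in "AG"]
            if not depths:
                return None
            d = int(rng.choice(depths))
            pos = pe_lo - 2 - d
            return truth(
                pos=pos, ref=base(pos), alt="T",
                intended_event="partial_intron_retention",
                cryptic_acceptor=pe_lo,
                variant_transcribed=False,
                **common,
            )
        if mutation_class == "enhancer_gain":
            pos, ref, alt = f.enhancer_fix
            wt11 = seq[pos - 5 : pos + 6]
            mut11 = wt11[:5] + alt + wt11[6:]
            if _hexamer_frames(wt11) & sg.enhancers.hexamers:
                return None
            if not _hexamer_frames(mut11) & sg.enhancers.hexamers:
                return None
            return truth(
                pos=pos, ref=ref, alt=alt,
                intended_event="pseudoexon_activation",
                cryptic_donor=pe_hi, cryptic_acceptor=pe_lo, pseudoexon=(pe_lo, pe_hi),
                **common,
            )
        # silencer_loss: break the planted silencer hexamer
        s_lo, s_hi = f.silencer_site
        for _ in range(12):
            off = int(rng.integers(6))
            pos = s_lo + off
            ref = base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            mut11 = seq[pos - 5 : pos] + alt + seq[pos + 1 : pos + 6]
            if not _hexamer_frames(mut11) & sg.silencers.hexamers:
                return truth(
                    pos=pos, ref=ref, alt=alt,
                    intended_event="pseudoexon_activation",
                    cryptic_donor=pe_hi, cryptic_acceptor=pe_lo, pseudoexon=(pe_lo, pe_hi),
                    **common,
                )
        log.warning("silencer_loss: no motif-destroying edit found in %s", gene_id)
        return None

    if mutation_class == "neutral":
        for _ in range(30):
            k = int(rng.integers(len(gf.introns)))
            f = gf.introns[k]
            if not f.filler:
                continue
            flo, fhi = f.filler[0]
            if fhi - flo < 14:
                continue
            pos = int(rng.integers(flo + 6, fhi - 6))
            ilo, ihi = f.interval
            if min(pos - ilo + 1, ihi - pos) <= 30:
                continue  # keep neutral edits deep and window-ineligible
            ref = base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return truth(
                pos=pos, ref=ref, alt=alt,
                intended_event=None, intended_ratio=0.0,
                target_intron=k, ptc_expected=False,
            )
        return None

    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def locus_list(sg: SyntheticGenome) -> list[tuple]:
    """Global locus keys: every intron plus every internal-exon skip."""
    loci: list[tuple] = []
    for gene_id in sorted(sg.genes):
        t = sg.genes[gene_id].transcript
        for k in range(len(t.introns)):
            loci.append((gene_id, "intron", k))
        exs = t.exons_genomic
        for e in range(1, len(exs) - 1):
            loci.append((gene_id, "skip", exs[e - 1][1], exs[e + 1][0]))
    return loci


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    seed: int
    genome: SyntheticGenome
    truths: list[MutationTruth]
    variants: list[VariantRecord]
    evidence: dict[tuple[str, str], list[ReadObservation]]  # (sample, gene) -> reads
    normal_counts: CohortCounts
    cancer_counts: CohortCounts
    gene_flags: dict[str, set[str]]  # non-silent lesion flags per gene
    expression: pd.DataFrame
    sample_types: dict[str, str]
    novel_junction_fraction: dict[str, float]
    splicing_factor_flagged: set[str]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truths])

    def evidence_tsv(self) -> str:
        reads = [r for obs in self.evidence.values() for r in obs]
        return write_evidence_table(reads)

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos + 1 for v in self.variants],  # 1-based in I/O
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "sample": [v.sample_id for v in self.variants],
                "t_ref_count": [v.dna_ref_count for v in self.variants],
                "t_alt_count": [v.dna_alt_count for v in self.variants],
                "callers": [v.caller_count for v in self.variants],
            }
        )

    def to_vcf(self) -> str:
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample">',
            '##INFO=<ID=TRC,Number=1,Type=Integer,Description="Tumour DNA ref count">',
            '##INFO=<ID=TAC,Number=1,Type=Integer,Description="Tumour DNA alt count">',
            '##INFO=<ID=CALLERS,Number=1,Type=Integer,Description="Supporting caller count">',
        ]
        for chrom, length in sorted((c, len(s)) for c, s in self.genome.sequences.items()):
            lines.append(f"##contig=<ID={chrom},length={length}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        for i, v in enumerate(self.variants):
            info = f"SAMPLE={v.sample_id};TRC={v.dna_ref_count};TAC={v.dna_alt_count};CALLERS={v.caller_count}"
            lines.append(f"{v.chrom}\t{v.pos + 1}\tvar{i + 1}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}")
        return "\n".join(lines) + "\n"


def _quality(rng: np.random.Generator, config: SimulationConfig) -> int:
    return int(rng.choice(config.qualities, p=config.quality_probs))


def _carrier_reads(
    sg: SyntheticGenome,
    truth: MutationTruth,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[list[ReadObservation], dict[tuple, tuple[int, int]]]:
    """Per-read evidence of a mutation carrier at its gene, plus the
    resulting per-locus (normal, abnormal) counts."""
    gf = sg.genes[truth.gene_id]
    t = gf.transcript
    reads: list[ReadObservation] = []
    counts: dict[tuple, tuple[int, int]] = {}
    rid = itertools.count(1)

    def new_id() -> str:
        return f"{truth.sample_id}.{truth.gene_id}.r{next(rid)}"

    def allele_obs(transcribed: bool) -> AlleleObservation | None:
        if not transcribed:
            return None
        is_alt = rng.random() < truth.allele_fidelity
        return AlleleObservation(
            pos=truth.pos,
            base=truth.alt if is_alt else truth.ref,
            base_quality=_quality(rng, config),
        )

    introns = [(min(iv), max(iv)) for iv in t.introns]
    event_intron = truth.target_intron

    # coverage at every intron junction; the event locus gets the floor
    totals = {}
    for k in range(len(introns)):
        tot = int(rng.poisson(config.coverage_mean))
        if k == event_intron:
            tot = max(tot, config.coverage_floor)
        totals[k] = tot

    ab_counts: dict[tuple, int] = {}
    ev = truth.intended_event
    if ev is not None and event_intron is not None:
        tot = totals[event_intron]
        ab = int(rng.binomial(tot, truth.intended_ratio))
        ilo, ihi = introns[event_intron]
        if ev == "full_intron_retention":
            for _ in range(ab):
                span = (ilo - 20, min(ihi + 20, ilo + 60))
                reads.append(
                    ReadObservation(
                        sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                        kind="unspliced_span", span=span, allele_at=allele_obs(True),
                    )
                )
            ab_counts[("intron", event_intron)] = ab
            totals[event_intron] = tot - ab
        elif ev == "full_exon_skipping":
            l, r = truth.skip_junction
            for _ in range(ab):
                reads.append(
                    ReadObservation(
                        sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                        kind="junction", junctions=((l, r),), allele_at=None,
                    )
                )
            ab_counts[("skip", l, r)] = ab
            # inclusion reads of the two flanking introns drop accordingly
            keep = tot - ab
            k2 = event_intron + 1
            split = int(rng.binomial(keep, 0.5))
            totals[event_intron] = split
            if k2 in totals:
                totals[k2] = keep - split
        elif ev == "partial_intron_retention":
            a = truth.cryptic_acceptor
            junction = (ilo, a)
            for _ in range(ab):
                reads.append(
                    ReadObservation(
                        sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                        kind="junction", junctions=(junction,),
                        allele_at=allele_obs(truth.variant_transcribed),
                    )
                )
            ab_counts[("intron", event_intron)] = ab
            totals[event_intron] = tot - ab
        elif ev == "pseudoexon_activation":
            pe_lo, pe_hi = truth.pseudoexon
            juncs = ((ilo, pe_lo), (pe_hi, ihi))
            for _ in range(ab):
                reads.append(
                    ReadObservation(
                        sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                        kind="junction", junctions=juncs,
                        allele_at=allele_obs(truth.variant_transcribed),
                    )
                )
            ab_counts[("intron", event_intron)] = ab
            totals[event_intron] = tot - ab

    # background-level abnormal noise at every intron (retention-like spans)
    for k, (lo, hi) in enumerate(introns):
        noise = int(rng.binomial(totals[k], rng.beta(config.bg_alpha, config.bg_beta)))
        for _ in range(noise):
            reads.append(
                ReadObservation(
                    sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                    kind="unspliced_span", span=(lo - 15, lo + 15),
                )
            )
        if noise:
            ab_counts[("intron", k)] = ab_counts.get(("intron", k), 0) + noise

    # normally spliced reads at every annotated junction
    for k, (lo, hi) in enumerate(introns):
        for _ in range(totals[k]):
            reads.append(
                ReadObservation(
                    sample_id=truth.sample_id, gene_id=truth.gene_id, read_id=new_id(),
                    kind="junction", junctions=((lo, hi),),
                )
            )

    for k in range(len(introns)):
        counts[("intron", k)] = (totals[k], ab_counts.get(("intron", k), 0))
    exs = t.exons_genomic
    for e in range(1, len(exs) - 1):
        key = ("skip", exs[e - 1][1], exs[e + 1][0])
        flank_normal = totals.get(e - 1, 0) + totals.get(e, 0)
        counts[key] = (flank_normal, ab_counts.get(key, 0))
    return reads, counts


def simulate_cohort(
    sg: SyntheticGenome,
    truths: Sequence[MutationTruth],
    config: SimulationConfig,
    seed: int,
) -> SimulatedStudy:
    """Draw the normal and cancer cohorts, assign carriers, and emit evidence.

    Background counts per (sample, locus): total spliced coverage is
    Poisson(mean 40; doubled for two-junction skip loci), the abnormal
    fraction Beta(1, 99), abnormal reads Binomial(total, fraction).  Carrier
    samples get their counts replaced by the aggregate of their simulated
    per-read evidence so both views stay consistent.
    """
    rng = np.random.default_rng(seed)
    loci = locus_list(sg)
    n_loci = len(loci)
    normal_ids = [f"N{i + 1:04d}" for i in range(config.n_normal_samples)]
    cancer_ids = [f"T{i + 1:04d}" for i in range(config.n_cancer_samples)]

    def draw_counts(n_samples: int) -> tuple[np.ndarray, np.ndarray]:
        lam = np.array([config.coverage_mean * (2 if l[1] == "skip" else 1) for l in loci])
        total = rng.poisson(lam, size=(n_samples, n_loci))
        rho = rng.beta(config.bg_alpha, config.bg_beta, size=(n_samples, n_loci))
        ab = rng.binomial(total, rho)
        return total - ab, ab

    nn, na = draw_counts(config.n_normal_samples)
    cn, ca = draw_counts(config.n_cancer_samples)

    # carriers: distinct cancer samples, assigned deterministically under rng
    truths = [replace(t) for t in truths]
    carrier_idx = rng.choice(config.n_cancer_samples, size=len(truths), replace=False)
    locus_index = {l: i for i, l in enumerate(loci)}
    evidence: dict[tuple[str, str], list[ReadObservation]] = {}
    variants: list[VariantRecord] = []
    for i, (t_row, si) in enumerate(zip(truths, carrier_idx)):
        t_row.sample_id = cancer_ids[int(si)]
        t_row.variant_id = f"var{i + 1:04d}"
        reads, counts = _carrier_reads(sg, t_row, rng, config)
        evidence[(t_row.sample_id, t_row.gene_id)] = reads
        for local, (n, a) in counts.items():
            gl = (t_row.gene_id, *local)
            cn[si, locus_index[gl]] = n
            ca[si, locus_index[gl]] = a
        depth = max(6, int(rng.poisson(config.dna_depth_mean)))
        alt_count = int(rng.binomial(depth, config.dna_vaf))
        variants.append(
            VariantRecord(
                chrom=t_row.chrom, pos=t_row.pos, ref_allele=t_row.ref, alt_allele=t_row.alt,
                kind="SNV", sample_id=t_row.sample_id,
                dna_ref_count=depth - alt_count, dna_alt_count=alt_count, caller_count=2,
            )
        )

    # passenger deep intronic SNVs (no splicing effect): the enrichment universe
    gene_ids = sorted(sg.genes)
    for j in range(config.n_passenger_deep):
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gf = sg.genes[gene_id]
        k = int(rng.integers(len(gf.introns)))
        f = gf.introns[k]
        flo, fhi = f.filler[0]
        if fhi - flo < 14:
            continue
        pos = int(rng.integers(flo + 6, fhi - 6))
        ilo, ihi = f.interval
        if min(pos - ilo + 1, ihi - pos) <= 20:
            continue
        ref = sg.sequences[gf.chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sample = cancer_ids[int(rng.integers(config.n_cancer_samples))]
        depth = max(6, int(rng.poisson(config.dna_depth_mean)))
        alt_count = int(rng.binomial(depth, config.dna_vaf))
        variants.append(
            VariantRecord(
                chrom=gf.chrom, pos=pos, ref_allele=ref, alt_allele=alt, kind="SNV",
                sample_id=sample, dna_ref_count=depth - alt_count, dna_alt_count=alt_count,
                caller_count=2,
            )
        )

    # per-gene non-silent lesion flags over non-carrier cancer samples
    carrier_samples = {t.sample_id for t in truths}
    gene_flags: dict[str, set[str]] = {}
    for gene_id in gene_ids:
        n_flag = int(rng.binomial(config.n_cancer_samples, config.frac_flagged))
        picks = rng.choice(config.n_cancer_samples, size=n_flag, replace=False)
        gene_flags[gene_id] = {cancer_ids[int(p)] for p in picks} - carrier_samples

    # expression: genes x cancer samples, log-normal baseline per gene
    base = rng.lognormal(mean=3.0, sigma=0.25, size=len(gene_ids))
    expr = np.outer(base, np.exp(rng.normal(0, 0.2, size=config.n_cancer_samples)))
    expression = pd.DataFrame(expr, index=gene_ids, columns=cancer_ids)
    for t_row in truths:
        if t_row.nmd_expected == "sensitive":
            expression.loc[t_row.gene_id, t_row.sample_id] *= config.nmd_expression_factor

    types = ["adeno", "squamous", "lymphoid", "glioma"]
    sample_types = {s: types[i % len(types)] for i, s in enumerate(cancer_ids)}
    novel_frac = {s: float(rng.normal(0.05, 0.01)) for s in cancer_ids}
    factor_flagged = set()

    return SimulatedStudy(
        config=config,
        seed=seed,
        genome=sg,
        truths=list(truths),
        variants=variants,
        evidence=evidence,
        normal_counts=CohortCounts(normal_ids, loci, nn, na),
        cancer_counts=CohortCounts(cancer_ids, loci, cn, ca),
        gene_flags=gene_flags,
        expression=expression,
        sample_types=sample_types,
        novel_junction_fraction=novel_frac,
        splicing_factor_flagged=factor_flagged,
    )


def simulate_study(
    config: SimulationConfig,
    class_counts: dict[str, int],
    seed: int,
) -> SimulatedStudy:
    """Generate a genome, inject the requested mutation classes (one gene per
    mutation), and simulate the cohorts — the end-to-end entry point."""
    sg = generate_genome(config, seed)
    rng = np.random.default_rng(seed + 1)
    truths: list[MutationTruth] = []
    used: set[str] = set()
    for cls in sorted(class_counts):
        for _ in range(class_counts[cls]):
            t = None
            for _attempt in range(12):  # bounded feasibility search over loci
                t = inject_mutation(sg, cls, rng, config, exclude_genes=used)
                if t is not None:
                    break
            if t is None:
                log.warning("class %s: no feasible site after bounded search; skipped", cls)
                continue
            used.add(t.gene_id)
            truths.append(t)
    return simulate_cohort(sg, truths, config, seed + 2)


def donor_feature_sample(
    sg: SyntheticGenome,
    donor_model,
    acceptor_model,
    n: int,
    seed: int,
    mode: str = "disrupt",
) -> np.ndarray:
    """Feature matrix (n x 2) for donor-intronic SNVs at +3..+6 positions.

    ``mode="disrupt"`` samples consensus-breaking edits (the mis-splicing
    training cloud); ``mode="random"`` samples arbitrary substitutions at the
    same positions (the comparator the prediction models are benchmarked
    against)."""
    from .prediction import make_features

    if mode not in ("disrupt", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    genes = sorted(sg.genes)
    out = []
    while len(out) < n:
        gene = genes[int(rng.integers(len(genes)))]
        gf = sg.genes[gene]
        k = int(rng.integers(len(gf.introns)))
        ilo = gf.introns[k].interval[0]
        p = int(rng.integers(3, 7))
        pos = ilo + p - 1
        ref = sg.sequences[gf.chrom][pos]
        bases, probs = _DONOR_LAW[p]
        if mode == "disrupt":
            if ref != bases[int(np.argmax(probs))]:
                continue
            alt = bases[int(np.argmin(probs))]
        else:
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
        v = VariantRecord(
            chrom=gf.chrom, pos=pos, ref_allele=ref, alt_allele=alt, kind="SNV", sample_id="S"
        )
        fv = make_features(v, gf.transcript, sg.genome, donor_model, acceptor_model)
        out.append([fv.f1, fv.f2])
    return np.asarray(out)
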