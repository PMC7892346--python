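"""Quantitative splice-code models: donor/acceptor strength, polypyrimidine
tract content, branchpoint U2-duplex energy, and enhancer/silencer hexamers.

The default splice-site strength scorer is a smoothed position log-odds
model trained on a supplied set of authentic junction windows (donor: 3
exonic + 6 intronic bases; acceptor: 20 intronic + 3 exonic).  Externally
derived model tables (e.g. maximum-entropy score tables exported as
per-position probabilities) load through the same interface, so the scorer
is pluggable.  Scores are in log2-odds units against a uniform background;
higher means stronger.

U2 duplex energies use a bundled nearest-neighbour-style stack table over
Watson-Crick and G.U pairs with a fixed per-position mismatch penalty; the
values are documented stand-ins and only the sign and ordering of ddG are
meaningful.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gene_models import GenomeSequence, TranscriptModel, VariantRecord, revcomp

__all__ = [
    "SpliceStrengthModel",
    "MotifSet",
    "BranchpointAnnotation",
    "score_splice_site",
    "strength_delta",
    "donor_window",
    "acceptor_window",
    "u2_binding_energy",
    "u2_delta",
    "branchpoint_window",
    "annotate_branchpoint",
    "motif_scan",
    "load_motif_set",
    "pyrimidine_fraction",
    "U2_MOTIF",
    "U2_PERFECT_COMPLEMENT",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DONOR_EXONIC, DONOR_INTRONIC = 3, 6  # -3..-1 | +1..+6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # -20..-1 | +1..+3
DONOR_LEN = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC


@dataclass
class SpliceStrengthModel:
    """Per-position probability model of a splice-site window."""

    side: str  # donor | acceptor
    probs: np.ndarray  # (window length, 4), rows sum to 1
    provenance: str = "trained"

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be donor or acceptor, got {self.side!r}")
        self.probs = np.asarray(self.probs, dtype=float)
        expected = DONOR_LEN if self.side == "donor" else ACCEPTOR_LEN
        if self.probs.shape != (expected, 4):
            raise ValueError(f"{self.side} model needs shape ({expected}, 4)")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def uniform(cls, side: str) -> "SpliceStrengthModel":
        n = DONOR_LEN if side == "donor" else ACCEPTOR_LEN
        return cls(side=side, probs=np.full((n, 4), 0.25), provenance="uniform")

    @classmethod
    def train(cls, side: str, windows: Iterable[str]) -> "SpliceStrengthModel":
        """Fit per-position probabilities from authentic junction windows with
        add-one smoothing: p = (count + 1) / (n + 4)."""
        n_pos = DONOR_LEN if side == "donor" else ACCEPTOR_LEN
        counts = np.zeros((n_pos, 4))
        n = 0
        for w in windows:
            w = w.upper().replace("U", "T")
            if len(w) != n_pos or any(b not in _BASE_INDEX for b in w):
                raise ValueError(f"training window {w!r}: need {n_pos}-mer over ACGT")
            for i, b in enumerate(w):
                counts[i, _BASE_INDEX[b]] += 1
            n += 1
        if n == 0:
            raise ValueError("no training windows")
        return cls(side=side, probs=(counts + 1) / (n + 4), provenance=f"trained(n={n})")

    @classmethod
    def from_table(cls, source, side: str) -> "SpliceStrengthModel":
        """Load an externally supplied model table: TSV with header
        ``pos A C G T`` and one probability row per window position."""
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, str) and "\n" in source:
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
        rows = [l.split("\t") for l in text.strip().splitlines()]
        if rows[0] != ["pos", "A", "C", "G", "T"]:
            raise ValueError("model table: expected header 'pos\\tA\\tC\\tG\\tT'")
        probs = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(side=side, probs=probs, provenance="external_table")

    def to_table(self) -> str:
        buf = io.StringIO()
        buf.write("pos\tA\tC\tG\tT\n")
        for i, row in enumerate(self.probs):
            buf.write(f"{i}\t" + "\t".join(f"{p:.6g}" for p in row) + "\n")
        return buf.getvalue()

    def score(self, window: str) -> float:
        return score_splice_site(window, self)


def score_splice_site(window_seq: str, model: SpliceStrengthModel) -> float:
    """Log2-odds score of a window against uniform background."""
    w = window_seq.upper().replace("U", "T")
    if len(w) != model.length:
        raise ValueError(f"window length {len(w)} != model length {model.length}")
    total = 0.0
    for i, b in enumerate(w):
        j = _BASE_INDEX.get(b)
        if j is None:
            raise ValueError(f"non-ACGT base {b!r} in window")
        total += math.log2(model.probs[i, j] / 0.25)
    return total


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def donor_window(genome: GenomeSequence, chrom: str, strand: str, boundary: int) -> tuple[str, int, int]:
    """9-mer donor window (3 exonic + 6 intronic) on the transcript sense.

    ``boundary`` is the genomic exon|intron boundary as produced by
    :meth:`TranscriptModel.donor_boundary` (first intron base for '+',
    half-open intron end for '-').  Returns ``(sequence, g_start, g_end)``
    with the genomic interval covered.
    """
    if strand == "+":
        s, e = boundary - DONOR_EXONIC, boundary + DONOR_INTRONIC
        return genome.fetch(chrom, s, e), s, e
    s, e = boundary - DONOR_INTRONIC, boundary + DONOR_EXONIC
    return revcomp(genome.fetch(chrom, s, e)), s, e


def acceptor_window(genome: GenomeSequence, chrom: str, strand: str, boundary: int) -> tuple[str, int, int]:
    """23-mer acceptor window (20 intronic + 3 exonic) on the transcript
    sense; ``boundary`` as from :meth:`TranscriptModel.acceptor_boundary`."""
    if strand == "+":
        s, e = boundary - ACCEPTOR_INTRONIC, boundary + ACCEPTOR_EXONIC
        return genome.fetch(chrom, s, e), s, e
    s, e = boundary - ACCEPTOR_EXONIC, boundary + ACCEPTOR_INTRONIC
    return revcomp(genome.fetch(chrom, s, e)), s, e


def _mutate_window(window: str, g_start: int, g_end: int, strand: str, variant: VariantRecord) -> str:
    if not g_start <= variant.pos < g_end:
        raise ValueError(f"variant at {variant.pos} outside window {g_start}-{g_end}")
    i = variant.pos - g_start if strand == "+" else g_end - 1 - variant.pos
    alt = variant.alt_allele if strand == "+" else revcomp(variant.alt_allele)
    ref = variant.ref_allele if strand == "+" else revcomp(variant.ref_allele)
    if window[i] != ref:
        raise ValueError(
            f"reference mismatch at {variant.pos}: window has {window[i]!r}, variant ref {ref!r}"
        )
    return window[:i] + alt + window[i + 1 :]


def strength_delta(
    variant: VariantRecord,
    site_boundary: int,
    genome: GenomeSequence,
    model: SpliceStrengthModel,
    *,
    chrom: str,
    strand: str = "+",
    reference_boundary: int | None = None,
) -> tuple[float, float, float]:
    """Mutant-vs-wild-type strength difference at a splice site.

    ``site_boundary`` anchors the model window at an authentic or cryptic
    site; the variant must fall inside the window.  Returns
    ``(score_wt, score_mut, delta)``; with ``reference_boundary`` set (the
    matched authentic site of a cryptic-site gain) the caller can score that
    site separately via :func:`score_site`.
    """
    extract = donor_window if model.side == "donor" else acceptor_window
    wt, s, e = extract(genome, chrom, strand, site_boundary)
    mut = _mutate_window(wt, s, e, strand, variant)
    score_wt = model.score(wt)
    score_mut = model.score(mut)
    return score_wt, score_mut, score_mut - score_wt


def score_site(
    genome: GenomeSequence, chrom: str, strand: str, boundary: int, model: SpliceStrengthModel
) -> float:
    """Strength of the (reference-sequence) site at ``boundary``."""
    extract = donor_window if model.side == "donor" else acceptor_window
    window, _, _ = extract(genome, chrom, strand, boundary)
    return model.score(window)


def pyrimidine_fraction(genome: GenomeSequence, chrom: str, strand: str, acceptor_boundary: int) -> float:
    """Pyrimidine content of the polypyrimidine tract (intronic +4..+20
    upstream of the acceptor); the companion metric to the 23-mer score."""
    if strand == "+":
        seq = genome.fetch(chrom, acceptor_boundary - 20, acceptor_boundary - 3)
    else:
        seq = revcomp(genome.fetch(chrom, acceptor_boundary + 3, acceptor_boundary + 20))
    return sum(b in "CT" for b in seq) / len(seq)


# ---------------------------------------------------------------------------
# branchpoint / U2 duplex
# ---------------------------------------------------------------------------

U2_MOTIF = "GUGUAGUA"  # U2 snRNA branchpoint-recognition motif, 5'->3'
U2_PERFECT_COMPLEMENT = "TACTACAC"  # intron-sense window pairing every motif base

# stand-in nearest-neighbour stack values (kcal/mol-like); only orderings matter
_STACK_WC_WC = -2.1
_STACK_WC_GU = -1.4
_STACK_GU_GU = -0.8
_MISMATCH_PENALTY = 1.0

_WC = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("T", "G")}


def _pair_type(w: str, m: str) -> str | None:
    if (w, m) in _WC:
        return "wc"
    if (w, m) in _WOBBLE:
        return "gu"
    return None


def u2_binding_energy(window_seq_8nt: str) -> float:
    """Duplex free energy (stand-in units) of an 8-nt branchpoint window
    (BP nucleotide excluded) against the U2 motif GUGUAGUA.

    The window pairs antiparallel with the motif; adjacent paired positions
    contribute a stack energy, unpaired positions a fixed +1.0 penalty.
    Lower (more negative) is more stable.  T and U spellings are equivalent.
    """
    w = window_seq_8nt.upper().replace("U", "T")
    if len(w) != 8:
        raise ValueError(f"U2 window must be 8 nt, got {len(w)}")
    if any(b not in "ACGT" for b in w):
        raise ValueError(f"non-ACGT base in U2 window {w!r}")
    motif_rev = U2_MOTIF[::-1]  # antiparallel: window[i] faces motif[7-i]
    pairs = [_pair_type(w[i], motif_rev[i]) for i in range(8)]
    energy = sum(_MISMATCH_PENALTY for p in pairs if p is None)
    for p1, p2 in zip(pairs, pairs[1:]):
        if p1 is None or p2 is None:
            continue
        if p1 == "wc" and p2 == "wc":
            energy += _STACK_WC_WC
        elif p1 == "gu" and p2 == "gu":
            energy += _STACK_GU_GU
        else:
            energy += _STACK_WC_GU
    return energy


def branchpoint_window(genome: GenomeSequence, chrom: str, strand: str, bp_pos: int) -> tuple[str, list[int]]:
    """8-nt window 5 bp upstream to 3 bp downstream of a branchpoint,
    excluding the BP base itself; returned on the transcript sense together
    with the genomic positions of its bases (in window order)."""
    if strand == "+":
        positions = list(range(bp_pos - 5, bp_pos)) + list(range(bp_pos + 1, bp_pos + 4))
    else:
        positions = list(range(bp_pos + 5, bp_pos, -1)) + list(range(bp_pos - 1, bp_pos - 4, -1))
    seq = "".join(
        genome.fetch(chrom, p, p + 1) if strand == "+" else revcomp(genome.fetch(chrom, p, p + 1))
        for p in positions
    )
    return seq, positions


def u2_delta(
    variant: VariantRecord, genome: GenomeSequence, chrom: str, strand: str, bp_pos: int
) -> tuple[float, float, float]:
    """(dG_wt, dG_mut, ddG) of the U2 duplex at a branchpoint for a variant
    inside the -5..+3 flanking window (the BP base itself is excluded)."""
    wt, positions = branchpoint_window(genome, chrom, strand, bp_pos)
    if variant.pos not in positions:
        raise ValueError(f"variant at {variant.pos} outside the U2 window of BP {bp_pos}")
    i = positions.index(variant.pos)
    alt = variant.alt_allele if strand == "+" else revcomp(variant.alt_allele)
    mut = wt[:i] + alt + wt[i + 1 :]
    g_wt, g_mut = u2_binding_energy(wt), u2_binding_energy(mut)
    return g_wt, g_mut, g_mut - g_wt


@dataclass(frozen=True)
class BranchpointAnnotation:
    """A known or predicted branchpoint adenosine."""

    chrom: str
    pos: int  # genomic, 0-based
    source: str = "known"  # known | predicted


def annotate_branchpoint(
    variant_pos: int,
    bp_list: Sequence[BranchpointAnnotation | int],
    *,
    acceptor_boundary: int,
    strand: str = "+",
    min_dist: int = 15,
    max_dist: int = 60,
) -> tuple[int, int, bool] | None:
    """Assign a variant to its nearest branchpoint.

    Applies only to intronic variants 15-60 bp from the acceptor junction;
    returns ``(bp_pos, relative_position, in_window)`` where the relative
    position is negative upstream of the BP and ``in_window`` marks the
    -5..+3 flank, or ``None`` when out of range or no BP is annotated.
    Equidistant BPs break toward the lower genomic coordinate.
    """
    dist = acceptor_boundary - variant_pos if strand == "+" else variant_pos - acceptor_boundary + 1
    if not min_dist <= dist <= max_dist:
        return None
    positions = sorted(b.pos if isinstance(b, BranchpointAnnotation) else int(b) for b in bp_list)
    if not positions:
        return None
    best = min(positions, key=lambda p: (abs(variant_pos - p), p))
    rel = variant_pos - best if strand == "+" else best - variant_pos
    return best, rel, -5 <= rel <= 3


# ---------------------------------------------------------------------------
# enhancer / silencer hexamers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifSet:
    name: str
    hexamers: frozenset[str]
    role: str  # enhancer | silencer
    source: str = ""

    def __post_init__(self) -> None:
        for h in self.hexamers:
            if len(h) != 6 or any(b not in "ACGT" for b in h):
                raise ValueError(f"motif {h!r} is not an ACGT hexamer")
        if self.role not in ("enhancer", "silencer"):
            raise ValueError(f"role must be enhancer or silencer, got {self.role!r}")


def load_motif_set(source, name: str, role: str) -> MotifSet:
    """Read a one-hexamer-per-line motif list (path, stream, or text)."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    hexamers = frozenset(l.strip().upper().replace("U", "T") for l in text.splitlines() if l.strip())
    return MotifSet(name=name, hexamers=hexamers, role=role, source=str(name))


def flank_11mer(
    genome: GenomeSequence, chrom: str, strand: str, variant: VariantRecord
) -> tuple[str, str]:
    """The +/-5 bp flanking 11-mers with the wild-type and mutant allele, on
    the transcript sense.  Raises when the flank runs off the contig."""
    if variant.kind != "SNV":
        raise ValueError("motif scan applies to SNVs only")
    s, e = variant.pos - 5, variant.pos + 6
    if s < 0 or e > genome.contig_length(chrom):
        raise ValueError(f"11-mer around {variant.pos} truncated by contig end")
    wt_plus = genome.fetch(chrom, s, e)
    if wt_plus[5] != variant.ref_allele:
        raise ValueError(f"reference mismatch at {variant.pos}")
    mut_plus = wt_plus[:5] + variant.alt_allele + wt_plus[6:]
    if strand == "+":
        return wt_plus, mut_plus
    return revcomp(wt_plus), revcomp(mut_plus)


def motif_scan(
    variant: VariantRecord,
    genome: GenomeSequence,
    motif_set: MotifSet,
    *,
    chrom: str,
    strand: str = "+",
) -> tuple[set[str], set[str], bool]:
    """Match all six hexamer frames of the variant's 11-mer flank against a
    motif set, separately for the wild-type and mutant allele.

    Returns ``(wt_matched, mut_matched, sequence_counted_once)``; a sequence
    counts once per set in downstream enrichment no matter how many hexamers
    it matches, which the final flag records.
    """
    wt, mut = flank_11mer(genome, chrom, strand, variant)
    wt_matched = {wt[i : i + 6] for i in range(6)} & motif_set.hexamers
    mut_matched = {mut[i : i + 6] for i in range(6)} & motif_set.hexamers
    return wt_matched, mut_matched, True
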