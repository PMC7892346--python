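"""Gene models, somatic variants, and the coordinate math the pipeline rests on.

All coordinates are kept 0-based, half-open internally; GTF and VCF input is
1-based and converted at the I/O boundary.  Intronic positions are numbered
from the first intron base (+1 immediately after the donor, or +1 immediately
inside the intron on the acceptor side), exonic positions from the last exon
base (-1 at the junction-adjacent base); the ``side`` field of a
:class:`LocationCall` disambiguates the two axes.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "VariantRecord",
    "LocationCall",
    "GenomeSequence",
    "GTFParseError",
    "load_gene_models",
    "load_genome_fasta",
    "select_longest_isoform",
    "classify_variant_location",
    "prefilter_variants",
    "sample_qc",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GTFParseError(ValueError):
    """Raised for malformed GTF records; the message names the offending line."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure (and optional CDS) of one isoform.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    ordered 5'->3' in *transcript* orientation (descending genomic coordinates
    on the minus strand).  ``cds_start``/``cds_end`` bound the genomic CDS
    interval when the isoform is coding.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s1 >= e1 or s2 >= e2:
                raise ValueError(f"{self.transcript_id}: empty exon interval")
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            if s2 - e1 < 4:
                raise ValueError(f"{self.transcript_id}: intron shorter than 4 bp")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not ordered 5'->3' in transcript orientation"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS")
        if self.cds_start is not None:
            if not any(s <= self.cds_start < e for s, e in genomic) or not any(
                s < self.cds_end <= e for s, e in genomic
            ):
                raise ValueError(f"{self.transcript_id}: CDS outside exon union")

    # -- derived geometry ---------------------------------------------------

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted by ascending genomic coordinate."""
        return sorted(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals in transcript orientation."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        g = self.exons_genomic
        return g[0][0], g[-1][1]

    def junctions(self) -> set[tuple[int, int]]:
        """Annotated exon-exon junctions as genomic ``(left_end, right_start)``
        pairs (left exon's half-open end, right exon's start; left < right)."""
        out = set()
        g = self.exons_genomic
        for (s1, e1), (s2, e2) in zip(g, g[1:]):
            out.add((e1, s2))
        return out

    def donor_boundary(self, intron_index: int) -> int:
        """Genomic coordinate of the exon|intron donor boundary of intron
        ``intron_index`` (transcript order), expressed as the first intron base
        for '+' and the last intron base + 1 ... i.e. always the boundary on
        the donor side of the half-open intron interval."""
        s, e = self.introns[intron_index]
        return s if self.strand == "+" else e

    def acceptor_boundary(self, intron_index: int) -> int:
        s, e = self.introns[intron_index]
        return e if self.strand == "+" else s

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos < hi


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV or small deletion with DNA allele counts.

    ``pos`` is 0-based internally (converted from 1-based VCF/MAF at I/O).
    Deletions are located by their 5'-most deleted base.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str  # "SNV" | "deletion"
    sample_id: str
    dna_ref_count: int = 0
    dna_alt_count: int = 0
    caller_count: int = 2
    db_maf: float | None = None
    cosmic_recurrence: int = 0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        if self.kind == "SNV" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ValueError("SNV alleles must be single bases")
        if self.kind not in ("SNV", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if min(self.dna_ref_count, self.dna_alt_count, self.cosmic_recurrence) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LocationCall:
    """Placement of a variant relative to its nearest exon-intron junction."""

    category: str  # splice_site | proximal_intronic | deep_intronic | exonic
    distance_bp: int  # positive into intron, negative into exon
    side: str | None  # donor | acceptor (None only for single-exon transcripts)
    effective_silent: bool = False
    intron_index: int | None = None  # transcript-order index when intronic
    exon_index: int | None = None


class GenomeSequence:
    """Uniform fetch interface over a dict of contig sequences or a pyfaidx
    Fasta handle.  ``fetch`` uses 0-based half-open coordinates and returns
    upper-case sequence on the plus strand."""

    def __init__(self, source) -> None:
        self._source = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0:
            raise ValueError(f"fetch start {start} < 0 on {chrom}")
        seq = self._source[chrom]
        if hasattr(seq, "__getitem__") and not isinstance(seq, str):
            out = str(seq[start:end])
        else:
            out = seq[start:end]
        if len(out) != end - start:
            raise ValueError(f"fetch {chrom}:{start}-{end} truncated by contig end")
        return out.upper()

    def contig_length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def contigs(self) -> list[str]:
        return list(self._source.keys())


def load_genome_fasta(path: str) -> GenomeSequence:
    """Open a FASTA file (via pyfaidx) behind the :class:`GenomeSequence` API."""
    from pyfaidx import Fasta

    return GenomeSequence(Fasta(path, as_raw=True, sequence_always_upper=True))


# ---------------------------------------------------------------------------
# GTF loading
# ---------------------------------------------------------------------------


def load_gene_models(gtf_stream) -> list[TranscriptModel]:
    """Parse exon (and optional CDS) features from a GTF into transcripts.

    Accepts a path, a file object, or GTF text.  Coordinates convert from the
    1-based inclusive GTF frame to the internal 0-based half-open frame.
    Malformed lines raise :class:`GTFParseError` naming the line number.
    """
    if hasattr(gtf_stream, "read"):
        text = gtf_stream.read()
    elif isinstance(gtf_stream, str) and "\t" in gtf_stream:
        text = gtf_stream
    else:
        with open(gtf_stream) as fh:
            text = fh.read()

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise GTFParseError(f"line {lineno}: non-integer coordinates") from None
        if start < 1 or end < start:
            raise GTFParseError(f"line {lineno}: invalid interval {start}-{end}")

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )

    exons: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [None])[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid is None:
                raise GTFParseError(f"{ftype} feature without transcript_id at {feat.seqid}:{feat.start}")
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
            )
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            rec["exons" if ftype == "exon" else "cds"].append(iv)

    models = []
    for tid, rec in exons.items():
        if not rec["exons"]:
            warnings.warn(f"transcript {tid} has CDS but zero exons; rejected")
            continue
        ivs = sorted(rec["exons"])
        if rec["strand"] == "-":
            ivs = ivs[::-1]
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(ivs),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def select_longest_isoform(isoforms: Sequence[TranscriptModel]) -> TranscriptModel:
    """The isoform with the greatest summed exon length; equal lengths break
    toward the lexicographically smallest transcript_id."""
    if not isoforms:
        raise ValueError("select_longest_isoform: empty isoform list")
    genes = {t.gene_id for t in isoforms}
    if len(genes) > 1:
        raise ValueError(f"isoforms from multiple genes: {sorted(genes)}")
    return min(isoforms, key=lambda t: (-t.exon_length, t.transcript_id))


# ---------------------------------------------------------------------------
# Variant location
# ---------------------------------------------------------------------------


def classify_variant_location(
    v: VariantRecord | int,
    t: TranscriptModel,
    *,
    silent: bool = False,
) -> LocationCall:
    """Classify a position as splice-site (1-2 bp), proximal intronic
    (3-20 bp), deep intronic (>20 bp) or exonic, with the signed distance to
    the nearest junction.

    Intronic depth is 1-based from the first intron base on either side;
    exonic offsets are negative, -1 at the junction-adjacent exon base.
    Silent exonic SNVs within 2 bp of a junction are reclassified non-silent
    (``effective_silent=False``).
    """
    pos = v.pos if isinstance(v, VariantRecord) else int(v)
    if not t.contains(pos):
        raise ValueError(f"position {pos} outside transcript {t.transcript_id}")

    plus = t.strand == "+"
    for k, (s, e) in enumerate(t.exons):
        if s <= pos < e:
            # offsets to this exon's transcript-5' (acceptor) and -3' (donor) boundaries
            off5 = pos - s if plus else e - 1 - pos
            off3 = e - 1 - pos if plus else pos - s
            candidates = []
            if k > 0:  # acceptor junction exists upstream
                candidates.append((off5 + 1, "acceptor"))
            if k < len(t.exons) - 1:  # donor junction downstream
                candidates.append((off3 + 1, "donor"))
            if not candidates:
                dist, side = off5 + 1, None
            else:
                dist, side = min(candidates)
            eff = silent and dist > 2
            return LocationCall(
                category="exonic",
                distance_bp=-dist,
                side=side,
                effective_silent=eff,
                exon_index=k,
            )

    for k, intron in enumerate(t.introns):
        s, e = min(intron), max(intron)
        if s <= pos < e:
            if plus:
                d_donor = pos - s + 1
                d_acceptor = e - pos
            else:
                d_donor = e - pos
                d_acceptor = pos - s + 1
            if d_donor <= d_acceptor:
                dist, side = d_donor, "donor"
            else:
                dist, side = d_acceptor, "acceptor"
            if dist <= 2:
                cat = "splice_site"
            elif dist <= 20:
                cat = "proximal_intronic"
            else:
                cat = "deep_intronic"
            return LocationCall(
                category=cat,
                distance_bp=dist,
                side=side,
                effective_silent=False,
                intron_index=k,
            )

    raise AssertionError("unreachable: position inside span but in no exon or intron")


# ---------------------------------------------------------------------------
# Variant and sample QC
# ---------------------------------------------------------------------------


def prefilter_variants(
    variants: Iterable[VariantRecord],
    snp_table: Mapping[tuple[str, int], float | None] | None = None,
    cosmic_table: Mapping[tuple[str, int], int] | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the somatic-variant prefilters.

    Drops variants supported by fewer than two callers; drops common SNPs
    (population MAF > 1%); drops rare/unknown-frequency SNP overlaps unless
    COSMIC records the variant in at least two tumour samples.  Missing
    tables are treated as empty.  Returns ``(kept, dropped_with_reasons)``.
    """
    snp_table = snp_table or {}
    cosmic_table = cosmic_table or {}
    kept, dropped = [], []
    for v in variants:
        if v.caller_count < 2:
            dropped.append((v, "single_caller"))
            continue
        key = (v.chrom, v.pos)
        maf = v.db_maf
        in_snp_table = key in snp_table
        if maf is None and in_snp_table:
            maf = snp_table[key]
        cosmic = max(v.cosmic_recurrence, cosmic_table.get(key, 0))
        if maf is not None and maf > 0.01:
            dropped.append((v, "common_snp"))
            continue
        if (in_snp_table or v.db_maf is not None) and cosmic < 2:
            dropped.append((v, "known_snp"))
            continue
        kept.append(v)
    return kept, dropped


def sample_qc(
    per_sample_junction_stats: Mapping[str, float],
    cancer_type_labels: Mapping[str, str],
    splicing_factor_flags: Iterable[str] = (),
    *,
    z_cutoff: float = 1.96,
) -> list[str]:
    """Cohort-level sample QC.

    Removes samples flagged for pathogenic trans-acting splicing-factor
    mutations, then removes samples whose fraction of novel-junction reads is
    an outlier (per-cancer-type z-score > ``z_cutoff``, population SD).
    Cancer types with fewer than two samples (or zero spread) cannot yield a
    z-score; their samples are retained with a warning.
    """
    flagged = set(splicing_factor_flags)
    by_type: dict[str, list[str]] = {}
    for sample in per_sample_junction_stats:
        if sample in flagged:
            continue
        by_type.setdefault(cancer_type_labels.get(sample, "NA"), []).append(sample)

    kept = []
    for ctype, samples in by_type.items():
        fracs = np.array([per_sample_junction_stats[s] for s in samples], dtype=float)
        if len(samples) < 2 or np.std(fracs) == 0:
            if len(samples) < 2:
                warnings.warn(f"cancer type {ctype!r}: <2 samples, z undefined; samples retained")
            kept.extend(samples)
            continue
        z = (fracs - fracs.mean()) / fracs.std()  # population SD
        kept.extend(s for s, zi in zip(samples, z) if zi <= z_cutoff)
    return sorted(kept)
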