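"""Per-read splicing evidence: data model, TSV I/O, read classification and
RNA allele counting.

A :class:`ReadObservation` is the unit of evidence the pipeline consumes in
place of raw alignments: either the exon-exon junction(s) an RNA read spans,
or the genomic interval of an unspliced read, optionally annotated with the
base the read carries at a variant position.  The evidence TSV defined here
is the contract between the synthetic cohort generator (or any external BAM
extractor) and the statistics downstream.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Iterable, Sequence

from .gene_models import TranscriptModel

__all__ = [
    "ReadObservation",
    "JunctionSupport",
    "AlleleObservation",
    "read_evidence_table",
    "write_evidence_table",
    "classify_read",
    "rna_allele_counts",
    "NORMAL",
    "ABNORMAL",
    "UNINFORMATIVE",
]

NORMAL = "normal"
ABNORMAL = "abnormal"
UNINFORMATIVE = "uninformative"

EVIDENCE_COLUMNS = [
    "sample_id",
    "gene_id",
    "read_id",
    "kind",
    "junctions",
    "span",
    "var_pos",
    "var_base",
    "base_qual",
]


@dataclass(frozen=True)
class AlleleObservation:
    """Base observed by one read at a variant position (0-based)."""

    pos: int
    base: str
    base_quality: int

    def __post_init__(self) -> None:
        if not 0 <= self.base_quality <= 60:
            raise ValueError(f"base quality {self.base_quality} outside [0, 60]")


@dataclass(frozen=True)
class ReadObservation:
    """Splicing evidence carried by a single RNA read.

    ``kind`` is ``"junction"`` (read spans one or more exon-exon junctions,
    given as genomic ``(left_end, right_start)`` pairs, 0-based half-open,
    ordered 5'->3' along the genome) or ``"unspliced_span"`` (contiguous
    genomic interval).
    """

    sample_id: str
    gene_id: str
    read_id: str
    kind: str
    junctions: tuple[tuple[int, int], ...] = ()
    span: tuple[int, int] | None = None
    allele_at: AlleleObservation | None = None

    def __post_init__(self) -> None:
        if self.kind == "junction":
            if not self.junctions:
                raise ValueError("junction read without junctions")
            prev = None
            for left, right in self.junctions:
                if right <= left:
                    raise ValueError(f"junction ({left}, {right}): right end must exceed left end")
                if prev is not None and left < prev:
                    raise ValueError("junctions not ordered 5'->3'")
                prev = right
        elif self.kind == "unspliced_span":
            if self.span is None or self.span[1] - self.span[0] < 1:
                raise ValueError("unspliced span must have length >= 1")
        else:
            raise ValueError(f"unknown read kind {self.kind!r}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def _format_row(obs: ReadObservation) -> list[str]:
    junc = ";".join(f"{l}-{r}" for l, r in obs.junctions) if obs.junctions else "."
    span = f"{obs.span[0]}-{obs.span[1]}" if obs.span else "."
    if obs.allele_at is not None:
        var = [str(obs.allele_at.pos), obs.allele_at.base, str(obs.allele_at.base_quality)]
    else:
        var = [".", ".", "."]
    return [obs.sample_id, obs.gene_id, obs.read_id, obs.kind, junc, span, *var]


def write_evidence_table(observations: Iterable[ReadObservation], path_or_stream=None) -> str | None:
    """Write observations to the evidence TSV.  Returns the text when no
    destination is given.  ``read_evidence_table(write_evidence_table(x))``
    is the identity."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(EVIDENCE_COLUMNS)
    for obs in observations:
        writer.writerow(_format_row(obs))
    text = buf.getvalue()
    if path_or_stream is None:
        return text
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)
    return None


def read_evidence_table(source) -> list[ReadObservation]:
    """Parse the evidence TSV (path, file object, or text)."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and ("\n" in source or "\t" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    lines = text.splitlines()
    if not lines or lines[0].split("\t") != EVIDENCE_COLUMNS:
        raise ValueError("evidence TSV: missing or malformed header")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        f = line.split("\t")
        if len(f) != len(EVIDENCE_COLUMNS):
            raise ValueError(f"evidence TSV line {lineno}: expected {len(EVIDENCE_COLUMNS)} fields")
        kind = f[3]
        if kind not in ("junction", "unspliced_span"):
            raise ValueError(f"evidence TSV line {lineno}: unknown kind {kind!r}")
        junctions: tuple[tuple[int, int], ...] = ()
        if f[4] != ".":
            junctions = tuple(
                (int(a), int(b)) for a, b in (pair.split("-") for pair in f[4].split(";"))
            )
        span = None
        if f[5] != ".":
            a, b = f[5].split("-")
            span = (int(a), int(b))
        allele = None
        if f[6] != ".":
            allele = AlleleObservation(pos=int(f[6]), base=f[7], base_quality=int(f[8]))
        try:
            out.append(
                ReadObservation(
                    sample_id=f[0],
                    gene_id=f[1],
                    read_id=f[2],
                    kind=kind,
                    junctions=junctions,
                    span=span,
                    allele_at=allele,
                )
            )
        except ValueError as exc:
            raise ValueError(f"evidence TSV line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Classification and allele counting
# ---------------------------------------------------------------------------


@dataclass
class JunctionSupport:
    """Per-sample read support at one locus (numerator/denominator of the
    abnormal-splicing ratio)."""

    locus: tuple
    normal_count: int = 0
    abnormal_count: int = 0

    def __post_init__(self) -> None:
        if self.normal_count < 0 or self.abnormal_count < 0:
            raise ValueError("counts must be non-negative")


def classify_read(
    obs: ReadObservation,
    t: TranscriptModel,
    known_junctions: set[tuple[int, int]] | None = None,
    *,
    min_overlap: int = 5,
) -> str:
    """Classify one read as supporting normal or abnormal splicing.

    A junction read is normal iff every junction it spans is annotated.  An
    unspliced read is abnormal (intron-retention evidence) when it covers an
    exon-intron boundary with at least ``min_overlap`` bp on both sides, or
    lies entirely within an intron; an unspliced read fully inside the exon
    union is uninformative and excluded from ratios.
    """
    if known_junctions is None:
        known_junctions = t.junctions()
    if obs.kind == "junction":
        return NORMAL if all(j in known_junctions for j in obs.junctions) else ABNORMAL

    start, end = obs.span
    for intron in t.introns:
        s, e = min(intron), max(intron)
        # covers the boundary at s (exon|intron) or at e (intron|exon)?
        if start <= s - min_overlap and end >= s + min_overlap:
            return ABNORMAL
        if start <= e - min_overlap and end >= e + min_overlap:
            return ABNORMAL
        if start >= s and end <= e:
            return ABNORMAL  # fully intronic: retention evidence for this intron
    return UNINFORMATIVE


def rna_allele_counts(
    obs_at_variant: Sequence[ReadObservation],
    ref_allele: str,
    alt_allele: str,
    min_base_quality: int = 30,
) -> tuple[int, int, int]:
    """Count RNA alleles at a variant position from reads carrying
    ``allele_at`` annotations.

    Bases with quality below ``min_base_quality`` are excluded; remaining
    bases are tallied as ref/alt matches.  The third element counts every
    observation not attributed to either allele (low quality or third
    allele).
    """
    ref = alt = other = 0
    for obs in obs_at_variant:
        a = obs.allele_at
        if a is None:
            continue
        if a.base_quality < min_base_quality:
            other += 1
        elif a.base == ref_allele:
            ref += 1
        elif a.base == alt_allele:
            alt += 1
        else:
            other += 1
    return ref, alt, other
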