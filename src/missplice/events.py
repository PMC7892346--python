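"""Typing of abnormal splicing events from junction geometry.

Six event classes are recognised: full/partial intron retention, full/partial
exon skipping, pseudoexon activation, and combinatorial events (multiple
distinct aberration types at one locus).  Multiple *forms* of the same type
(e.g. partial retention through two different cryptic acceptors) stay one
event with several forms; the exact per-form read-counting rules are a
documented reconstruction (see docs/methods.md), centralised in this module.

Loci are keyed ``("intron", k)`` (transcript-order intron index; retention,
cryptic-site and pseudoexon events) or ``("skip", (left, right))`` (novel
exon-skipping junction between annotated boundaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .evidence import ABNORMAL, NORMAL, ReadObservation, classify_read
from .gene_models import GenomeSequence, TranscriptModel, VariantRecord, revcomp

__all__ = [
    "EventForm",
    "SpliceEventCall",
    "LocusEvidence",
    "collect_gene_evidence",
    "type_event",
    "type_events",
    "locate_cryptic_sites",
    "pseudoexon_bounds",
    "FULL_INTRON_RETENTION",
    "PARTIAL_INTRON_RETENTION",
    "FULL_EXON_SKIPPING",
    "PARTIAL_EXON_SKIPPING",
    "PSEUDOEXON_ACTIVATION",
    "COMBINATORIAL",
]

log = logging.getLogger(__name__)

FULL_INTRON_RETENTION = "full_intron_retention"
PARTIAL_INTRON_RETENTION = "partial_intron_retention"
FULL_EXON_SKIPPING = "full_exon_skipping"
PARTIAL_EXON_SKIPPING = "partial_exon_skipping"
PSEUDOEXON_ACTIVATION = "pseudoexon_activation"
COMBINATORIAL = "combinatorial"

MIN_SEGMENT = 10  # bp; retained segments / pseudoexons shorter than this are artefact-filtered


@dataclass
class EventForm:
    """One concrete splicing aberration (a geometry) with its read support."""

    kind: str
    event_type: str
    count: int
    reads: tuple[ReadObservation, ...] = ()
    cryptic_donor: int | None = None  # genomic boundary coordinate (see module docs)
    cryptic_acceptor: int | None = None
    pseudoexon: tuple[int, int] | None = None
    skipped_exons: tuple[int, ...] = ()
    donor_audit: str | None = None
    acceptor_audit: str | None = None


@dataclass
class SpliceEventCall:
    """A typed abnormal-splicing event at one locus of one sample."""

    gene_id: str
    sample_id: str
    locus: tuple
    event_type: str
    forms: list[EventForm]
    abnormal_count: int
    normal_count: int | None = None
    ratio: float | None = None
    z_normal: float | None = None
    z_cancer: float | None = None
    p_value: float | None = None
    fdr_q: float | None = None
    passed: bool | None = None
    variant: VariantRecord | None = None
    allele_validation: object | None = None

    @property
    def primary_form(self) -> EventForm:
        """Highest-ratio form: with one shared denominator per locus this is
        the highest-count form (first on ties)."""
        return max(self.forms, key=lambda f: f.count)

    @property
    def cryptic_donor(self) -> int | None:
        return self.primary_form.cryptic_donor

    @property
    def cryptic_acceptor(self) -> int | None:
        return self.primary_form.cryptic_acceptor

    @property
    def pseudoexon(self) -> tuple[int, int] | None:
        return self.primary_form.pseudoexon

    def cryptic_positions(self) -> list[int]:
        out = []
        for f in self.forms:
            if f.cryptic_donor is not None:
                out.append(f.cryptic_donor)
            if f.cryptic_acceptor is not None:
                out.append(f.cryptic_acceptor)
        return out


@dataclass
class LocusEvidence:
    """Per-(sample, locus) read support prior to typing."""

    locus: tuple
    normal_count: int = 0
    abnormal_reads: list[ReadObservation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _intron_index_containing(t: TranscriptModel, pos: int) -> int | None:
    for k, iv in enumerate(t.introns):
        lo, hi = min(iv), max(iv)
        if lo < pos < hi:
            return k
    return None


def _exon_index_containing(t: TranscriptModel, pos: int) -> int | None:
    for k, (s, e) in enumerate(t.exons):
        if s < pos < e:
            return k
    return None


def _junction_signature(t: TranscriptModel, junction: tuple[int, int]):
    """Map a novel genomic junction onto an event geometry.

    Returns ``(locus, kind, payload)`` or ``None`` when no rule matches.
    """
    left, right = junction
    exon_ends = {min(iv) if t.strand == "+" else max(iv): k for k, iv in enumerate(t.introns)}
    # exon_ends maps the genomic-left boundary of each intron; build both maps:
    left_bounds = {min(min(iv), max(iv)): k for k, iv in enumerate(t.introns)}
    right_bounds = {max(min(iv), max(iv)): k for k, iv in enumerate(t.introns)}

    left_annot = left in left_bounds  # left coordinate == an exon end (intron start)
    right_annot = right in right_bounds  # right coordinate == an exon start (intron end)
    k_left = _intron_index_containing(t, left)
    k_right = _intron_index_containing(t, right)

    if left_annot and right_annot:
        ki, kj = left_bounds[left], right_bounds[right]
        if ki == kj:
            return None  # annotated junction; not novel
        # skips every exon between intron ki and intron kj
        lo_i, hi_i = sorted((ki, kj))
        genomic = t.exons_genomic
        skipped = tuple(range(lo_i + 1, hi_i + 1))
        # verify skipped indices are internal exons lying between the boundaries
        if all(0 < g < len(genomic) for g in skipped):
            return ("skip", junction), "full_skip", {"skipped_genomic": skipped}
        return None

    if left_annot and k_right is not None:
        k = left_bounds[left]
        if k_right == k:
            # novel right coordinate inside the same intron
            if t.strand == "+":
                return ("intron", k), "cryptic_acceptor", {"site": right}
            return ("intron", k), "cryptic_donor", {"site": right}
        return None
    if right_annot and k_left is not None:
        k = right_bounds[right]
        if k_left == k:
            if t.strand == "+":
                return ("intron", k), "cryptic_donor", {"site": left}
            return ("intron", k), "cryptic_acceptor", {"site": left}
        return None

    # partial exon skipping: one annotated boundary, other inside an exon
    e_left = _exon_index_containing(t, left)
    e_right = _exon_index_containing(t, right)
    if left_annot and e_right is not None:
        k = left_bounds[left]
        site_role = "cryptic_acceptor" if t.strand == "+" else "cryptic_donor"
        return ("intron", k), "partial_skip", {"site": right, "role": site_role}
    if right_annot and e_left is not None:
        k = right_bounds[right]
        site_role = "cryptic_donor" if t.strand == "+" else "cryptic_acceptor"
        return ("intron", k), "partial_skip", {"site": left, "role": site_role}

    if k_left is not None and k_left == k_right:
        # wholly intra-intronic splice: one flank of a pseudoexon candidate is
        # unsupported; keep as a cryptic-pair geometry inside the intron
        return ("intron", k_left), "intra_intron_pair", {"left": left, "right": right}
    return None


def _retention_intron(t: TranscriptModel, span: tuple[int, int], min_overlap: int = 5) -> int | None:
    """Intron whose boundary (or body) an unspliced read covers."""
    start, end = span
    for k, iv in enumerate(t.introns):
        lo, hi = min(iv), max(iv)
        if (start <= lo - min_overlap and end >= lo + min_overlap) or (
            start <= hi - min_overlap and end >= hi + min_overlap
        ):
            return k
        if start >= lo and end <= hi:
            return k
    return None


# ---------------------------------------------------------------------------
# evidence collection
# ---------------------------------------------------------------------------


def collect_gene_evidence(
    observations: Iterable[ReadObservation],
    t: TranscriptModel,
    known_junctions: set[tuple[int, int]] | None = None,
) -> dict[tuple, LocusEvidence]:
    """Assign one sample's reads for one gene to ratio loci.

    Normal junction reads add to the denominator of each intron locus they
    span; abnormal reads are attached to the locus their novel geometry lives
    in.  Skip-locus denominators are the summed annotated-junction support of
    the two flanking introns, filled in here after the scan.
    """
    if known_junctions is None:
        known_junctions = t.junctions()
    annot = {j: k for k, j in ((k, (min(iv), max(iv))) for k, iv in enumerate(t.introns))}

    loci: dict[tuple, LocusEvidence] = {}

    def locus_ev(key: tuple) -> LocusEvidence:
        if key not in loci:
            loci[key] = LocusEvidence(locus=key)
        return loci[key]

    junction_normals = {k: 0 for k in range(len(t.introns))}

    for obs in observations:
        status = classify_read(obs, t, known_junctions)
        if status == NORMAL:
            seen = set()
            for j in obs.junctions:
                k = annot.get(j)
                if k is not None and k not in seen:
                    junction_normals[k] += 1
                    seen.add(k)
        elif status == ABNORMAL:
            if obs.kind == "unspliced_span":
                k = _retention_intron(t, obs.span)
                if k is None:
                    log.debug("retention read %s matches no intron; excluded", obs.read_id)
                    continue
                locus_ev(("intron", k)).abnormal_reads.append(obs)
            else:
                assigned = set()
                for j in obs.junctions:
                    if j in known_junctions:
                        continue
                    sig = _junction_signature(t, j)
                    if sig is None:
                        log.debug("junction %s of read %s matches no rule; excluded", j, obs.read_id)
                        continue
                    key = sig[0]
                    if key not in assigned:
                        locus_ev(key).abnormal_reads.append(obs)
                        assigned.add(key)

    for k, n in junction_normals.items():
        key = ("intron", k)
        if key in loci or n > 0:
            locus_ev(key).normal_count = n

    # skip-locus denominators: inclusion junctions of both flanking introns
    for key, ev in loci.items():
        if key[0] == "skip":
            left, right = key[1]
            flank = [k for k, iv in enumerate(t.introns) if min(iv) == left or max(iv) == right]
            ev.normal_count = sum(junction_normals.get(k, 0) for k in set(flank))

    return loci


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------


def type_event(
    abnormal_reads: Sequence[ReadObservation],
    t: TranscriptModel,
    locus: tuple | None = None,
    *,
    min_segment: int = MIN_SEGMENT,
    min_form_reads: int = 1,
) -> SpliceEventCall | None:
    """Type the abnormal reads of one locus into a :class:`SpliceEventCall`.

    Geometry rules: a novel junction from an annotated boundary into the
    intron is partial intron retention (the novel end is the cryptic site);
    matching cryptic acceptor/donor pairs bound a pseudoexon; annotated-to-
    annotated junctions spanning whole exons are full skipping; junctions
    truncating an exon are partial skipping; boundary-covering unspliced
    reads are full-retention evidence.  Two or more distinct aberration
    *types* at the locus make the event combinatorial, with the constituent
    forms listed.  Order-invariant over the input reads.
    """
    if not abnormal_reads:
        return None
    abnormal_reads = sorted(abnormal_reads, key=lambda o: (o.read_id, o.sample_id))
    sample_ids = {o.sample_id for o in abnormal_reads}
    sample_id = sorted(sample_ids)[0] if len(sample_ids) == 1 else "multiple"
    known = t.junctions()

    groups: dict[tuple, list[ReadObservation]] = {}
    payloads: dict[tuple, dict] = {}
    inferred_locus = locus
    for obs in abnormal_reads:
        if obs.kind == "unspliced_span":
            k = _retention_intron(t, obs.span)
            if k is None:
                continue
            gkey = ("retention", k)
            groups.setdefault(gkey, []).append(obs)
            payloads[gkey] = {"intron": k}
            inferred_locus = inferred_locus or ("intron", k)
            continue
        for j in obs.junctions:
            if j in known:
                continue
            sig = _junction_signature(t, j)
            if sig is None:
                log.debug("read %s junction %s: geometry matches no rule", obs.read_id, j)
                continue
            lkey, kind, payload = sig
            if locus is not None and lkey != locus:
                continue
            inferred_locus = inferred_locus or lkey
            gkey = (kind, j)
            if gkey not in groups or obs not in groups[gkey]:
                groups.setdefault(gkey, []).append(obs)
            payloads[gkey] = payload

    if not groups:
        return None
    if inferred_locus is None:
        inferred_locus = ("intron", -1)

    # pair cryptic donors/acceptors into pseudoexons when transcript order allows
    forms: list[EventForm] = []
    acceptors = {g: p for g, p in payloads.items() if g[0] == "cryptic_acceptor"}
    donors = {g: p for g, p in payloads.items() if g[0] == "cryptic_donor"}
    paired: set[tuple] = set()
    for ga, pa in sorted(acceptors.items()):
        for gd, pd in sorted(donors.items()):
            if gd in paired or ga in paired:
                continue
            a, d = pa["site"], pd["site"]
            in_order = a < d if t.strand == "+" else d < a
            if in_order:
                length = abs(d - a)
                if length < min_segment:
                    log.debug("pseudoexon of %d bp below %d bp floor; excluded", length, min_segment)
                    continue
                reads = sorted(set(groups[ga]) | set(groups[gd]), key=lambda o: o.read_id)
                forms.append(
                    EventForm(
                        kind="pseudoexon",
                        event_type=PSEUDOEXON_ACTIVATION,
                        count=len(reads),
                        reads=tuple(reads),
                        cryptic_donor=d,
                        cryptic_acceptor=a,
                        pseudoexon=(min(a, d), max(a, d)),
                    )
                )
                paired.update((ga, gd))
                break

    for gkey, reads in sorted(groups.items()):
        if gkey in paired:
            continue
        kind = gkey[0]
        payload = payloads[gkey]
        reads = sorted(set(reads), key=lambda o: o.read_id)
        if kind == "retention":
            forms.append(
                EventForm(
                    kind="retention",
                    event_type=FULL_INTRON_RETENTION,
                    count=len(reads),
                    reads=tuple(reads),
                )
            )
        elif kind in ("cryptic_acceptor", "cryptic_donor"):
            k = inferred_locus[1] if inferred_locus[0] == "intron" else None
            site = payload["site"]
            if k is not None and 0 <= k < len(t.introns):
                iv = t.introns[k]
                lo, hi = min(iv), max(iv)
                if kind == "cryptic_acceptor":
                    seg = (hi - site) if t.strand == "+" else (site - lo)
                else:
                    seg = (site - lo) if t.strand == "+" else (hi - site)
                if seg < min_segment:
                    log.debug("retained segment of %d bp below floor; excluded", seg)
                    continue
            forms.append(
                EventForm(
                    kind=kind,
                    event_type=PARTIAL_INTRON_RETENTION,
                    count=len(reads),
                    reads=tuple(reads),
                    cryptic_donor=site if kind == "cryptic_donor" else None,
                    cryptic_acceptor=site if kind == "cryptic_acceptor" else None,
                )
            )
        elif kind == "full_skip":
            forms.append(
                EventForm(
                    kind="full_skip",
                    event_type=FULL_EXON_SKIPPING,
                    count=len(reads),
                    reads=tuple(reads),
                    skipped_exons=payload["skipped_genomic"],
                )
            )
        elif kind == "partial_skip":
            role = payload["role"]
            forms.append(
                EventForm(
                    kind="partial_skip",
                    event_type=PARTIAL_EXON_SKIPPING,
                    count=len(reads),
                    reads=tuple(reads),
                    cryptic_donor=payload["site"] if role == "cryptic_donor" else None,
                    cryptic_acceptor=payload["site"] if role == "cryptic_acceptor" else None,
                )
            )
        elif kind == "intra_intron_pair":
            log.debug("one-sided intra-intron splice at %s flagged, not typed as pseudoexon", gkey[1])
            forms.append(
                EventForm(
                    kind="intra_intron_pair",
                    event_type=PARTIAL_INTRON_RETENTION,
                    count=len(reads),
                    reads=tuple(reads),
                )
            )

    if not forms:
        return None
    # the event type is decided by read-supported forms (>= min_form_reads);
    # sub-threshold forms stay listed but do not make the event combinatorial
    supported = [f for f in forms if f.count >= min_form_reads] or forms
    types = {f.event_type for f in supported}
    event_type = types.pop() if len(types) == 1 else COMBINATORIAL
    return SpliceEventCall(
        gene_id=t.gene_id,
        sample_id=sample_id,
        locus=inferred_locus,
        event_type=event_type,
        forms=forms,
        abnormal_count=len({(r.read_id, r.sample_id) for f in forms for r in f.reads}),
    )


def type_events(
    observations: Iterable[ReadObservation],
    t: TranscriptModel,
    known_junctions: set[tuple[int, int]] | None = None,
    *,
    min_form_reads: int = 1,
) -> list[SpliceEventCall]:
    """Collect one sample's evidence and type every locus with abnormal reads."""
    loci = collect_gene_evidence(observations, t, known_junctions)
    calls = []
    for key, ev in sorted(loci.items(), key=lambda kv: repr(kv[0])):
        if not ev.abnormal_reads:
            continue
        call = type_event(ev.abnormal_reads, t, locus=key, min_form_reads=min_form_reads)
        if call is None:
            continue
        call.normal_count = ev.normal_count
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# cryptic-site audit and pseudoexon bounds
# ---------------------------------------------------------------------------


def _donor_dinucleotide(genome: GenomeSequence, t: TranscriptModel, d: int) -> str:
    if t.strand == "+":
        return genome.fetch(t.chrom, d, d + 2)
    return revcomp(genome.fetch(t.chrom, d - 2, d))


def _acceptor_dinucleotide(genome: GenomeSequence, t: TranscriptModel, a: int) -> str:
    if t.strand == "+":
        return genome.fetch(t.chrom, a - 2, a)
    return revcomp(genome.fetch(t.chrom, a, a + 2))


def _apply_variant(dinuc: str, positions: tuple[int, int], variant: VariantRecord, strand: str) -> str:
    """Substitute the variant base into a dinucleotide fetched from reference.

    ``positions`` are the genomic coordinates of the two dinucleotide bases in
    the order they appear in ``dinuc`` (transcript sense)."""
    if variant is None or variant.kind != "SNV":
        return dinuc
    out = list(dinuc)
    for i, gpos in enumerate(positions):
        if gpos == variant.pos:
            base = variant.alt_allele if strand == "+" else revcomp(variant.alt_allele)
            out[i] = base
    return "".join(out)


def locate_cryptic_sites(
    event: SpliceEventCall,
    genome: GenomeSequence,
    t: TranscriptModel,
    variant: VariantRecord | None = None,
) -> SpliceEventCall:
    """Audit the dinucleotides at the event's cryptic sites.

    A cryptic donor must read GT in the reference (``pre_existing``) or become
    GT through the variant, canonically GC->GT (``created_by_variant``); a
    cryptic acceptor must be preceded by AG.  Violations raise an audit flag
    on the form rather than an exception.
    """
    for form in event.forms:
        if form.cryptic_donor is not None:
            d = form.cryptic_donor
            gpos = (d, d + 1) if t.strand == "+" else (d - 1, d - 2)
            ref = _donor_dinucleotide(genome, t, d)
            mut = _apply_variant(ref, gpos, variant, t.strand)
            if ref == "GT":
                form.donor_audit = "pre_existing"
            elif mut == "GT":
                form.donor_audit = "created_by_variant"
            else:
                form.donor_audit = "non_canonical"
        if form.cryptic_acceptor is not None:
            a = form.cryptic_acceptor
            gpos = (a - 2, a - 1) if t.strand == "+" else (a + 1, a)
            ref = _acceptor_dinucleotide(genome, t, a)
            mut = _apply_variant(ref, gpos, variant, t.strand)
            if ref == "AG":
                form.acceptor_audit = "pre_existing"
            elif mut == "AG":
                form.acceptor_audit = "created_by_variant"
            else:
                form.acceptor_audit = "non_canonical"
    return event


def pseudoexon_bounds(event: SpliceEventCall) -> tuple[tuple[int, int], int]:
    """Genomic interval and length of the event's (primary) pseudoexon.

    The interval covers both exonised ends (half-open); raises when the
    cryptic donor is not downstream of the cryptic acceptor in transcript
    orientation.
    """
    form = event.primary_form
    if form.event_type != PSEUDOEXON_ACTIVATION or form.pseudoexon is None:
        raise ValueError("event is not a pseudoexon activation")
    a, d = form.cryptic_acceptor, form.cryptic_donor
    lo, hi = form.pseudoexon
    if hi <= lo:
        raise ValueError("cryptic donor not downstream of cryptic acceptor")
    return (lo, hi), hi - lo
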