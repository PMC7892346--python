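"""End-to-end orchestration: QC -> ratio detection -> allele validation ->
splice-code scoring -> enrichment -> PTC/NMD -> burden -> prediction.

The pipeline operates on in-memory inputs (a :class:`PipelineInputs`, built
directly from a :class:`~missplice.simulate.SimulatedStudy` or from files via
the CLI); every stage emits a pandas table so runs are easily serialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele import ContingencyResult, confirm_full_intron_retention, cryptic_allele_test
from .detection import (
    CohortCounts,
    DetectionConfig,
    DetectionResult,
    apply_fdr,
    build_background,
    candidate_window,
    event_ratio,
    test_event,
)
from .events import (
    FULL_INTRON_RETENTION,
    SpliceEventCall,
    locate_cryptic_sites,
    type_events,
)
from .evidence import ReadObservation
from .gene_models import (
    GenomeSequence,
    LocationCall,
    TranscriptModel,
    VariantRecord,
    classify_variant_location,
    prefilter_variants,
    sample_qc,
    select_longest_isoform,
)
from .splice_codes import (
    SpliceStrengthModel,
    acceptor_window,
    annotate_branchpoint,
    donor_window,
    motif_scan,
    strength_delta,
    u2_delta,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineInputs",
    "CallRecord",
    "train_strength_models",
    "detect_missplicing",
    "null_locus_scan",
    "calls_to_frame",
]


@dataclass
class PipelineInputs:
    transcripts: dict[str, TranscriptModel]  # gene -> analysis isoform (longest)
    genome: GenomeSequence
    variants: list[VariantRecord]
    evidence: Mapping[tuple[str, str], list[ReadObservation]]
    normal_counts: CohortCounts
    cancer_counts: CohortCounts
    gene_flags: Mapping[str, set[str]] = field(default_factory=dict)
    branchpoints: Mapping[str, list] = field(default_factory=dict)
    sample_types: Mapping[str, str] = field(default_factory=dict)
    novel_junction_fraction: Mapping[str, float] = field(default_factory=dict)
    splicing_factor_flagged: set[str] = field(default_factory=set)

    @classmethod
    def from_study(cls, study) -> "PipelineInputs":
        transcripts = {}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in study.genome.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gene, isoforms in by_gene.items():
            transcripts[gene] = select_longest_isoform(isoforms)
        return cls(
            transcripts=transcripts,
            genome=study.genome.genome,
            variants=list(study.variants),
            evidence=study.evidence,
            normal_counts=study.normal_counts,
            cancer_counts=study.cancer_counts,
            gene_flags=study.gene_flags,
            branchpoints=study.genome.branchpoints,
            sample_types=study.sample_types,
            novel_junction_fraction=study.novel_junction_fraction,
            splicing_factor_flagged=study.splicing_factor_flagged,
        )


@dataclass
class CallRecord:
    """One (variant, event) analysis outcome."""

    variant: VariantRecord
    gene_id: str
    location: LocationCall | None = None
    event: SpliceEventCall | None = None
    detection: DetectionResult | None = None
    validation: ContingencyResult | None = None
    passed: bool = False
    status: str = "pending"  # passed | excluded:<reason> | failed_gates
    confirmation_branch: str | None = None  # allele branch used for full retention


def train_strength_models(
    genome: GenomeSequence, transcripts: Sequence[TranscriptModel]
) -> tuple[SpliceStrengthModel, SpliceStrengthModel]:
    """Fit the default donor/acceptor strength models from the authentic
    junction windows of the supplied gene models."""
    donors, acceptors = [], []
    for t in transcripts:
        for k in range(len(t.introns)):
            donors.append(donor_window(genome, t.chrom, t.strand, t.donor_boundary(k))[0])
            acceptors.append(acceptor_window(genome, t.chrom, t.strand, t.acceptor_boundary(k))[0])
    return (
        SpliceStrengthModel.train("donor", donors),
        SpliceStrengthModel.train("acceptor", acceptors),
    )


def _find_gene(variant: VariantRecord, transcripts: Mapping[str, TranscriptModel]) -> str | None:
    for gene, t in transcripts.items():
        if t.chrom == variant.chrom and t.contains(variant.pos):
            return gene
    return None


def _event_anchor_junctions(event: SpliceEventCall, t: TranscriptModel) -> list[int]:
    if event.locus[0] == "intron":
        k = event.locus[1]
        if 0 <= k < len(t.introns):
            iv = t.introns[k]
            return [min(iv), max(iv)]
        return []
    return list(event.locus[1])


def detect_missplicing(
    inputs: PipelineInputs,
    config: DetectionConfig = DetectionConfig(),
    *,
    run_sample_qc: bool = True,
) -> list[CallRecord]:
    """Run QC, eligibility, the ratio test with run-level FDR, the
    full-retention allele branch, and allele validation over all variants."""
    records: list[CallRecord] = []

    kept_variants, dropped = prefilter_variants(inputs.variants)
    for v, reason in dropped:
        records.append(CallRecord(variant=v, gene_id="", status=f"excluded:{reason}"))

    if run_sample_qc and inputs.novel_junction_fraction:
        kept_samples = set(
            sample_qc(
                inputs.novel_junction_fraction,
                inputs.sample_types,
                inputs.splicing_factor_flagged,
            )
        )
        qc_failed = [v for v in kept_variants if v.sample_id not in kept_samples]
        kept_variants = [v for v in kept_variants if v.sample_id in kept_samples]
        for v in qc_failed:
            records.append(CallRecord(variant=v, gene_id="", status="excluded:sample_qc"))

    # same-sample variant index for the confounder rule
    by_sample_gene: dict[tuple[str, str], list[VariantRecord]] = {}
    gene_of: dict[int, str | None] = {}
    for v in kept_variants:
        gene = _find_gene(v, inputs.transcripts)
        gene_of[id(v)] = gene
        if gene is not None:
            by_sample_gene.setdefault((v.sample_id, gene), []).append(v)

    ratio_pool: list[tuple[CallRecord, DetectionResult]] = []
    exonic_fir_pool: list[tuple[CallRecord, float]] = []

    for v in kept_variants:
        gene = gene_of[id(v)]
        if gene is None:
            records.append(CallRecord(variant=v, gene_id="", status="excluded:outside_gene_models"))
            continue
        t = inputs.transcripts[gene]
        rec = CallRecord(variant=v, gene_id=gene)
        records.append(rec)
        rec.location = classify_variant_location(v, t)

        siblings = [
            (o, classify_variant_location(o, t).category == "exonic")
            for o in by_sample_gene[(v.sample_id, gene)]
        ]
        from .detection import confounder_filter

        ok, reason = confounder_filter(v, siblings, config=config)
        if not ok:
            rec.status = f"excluded:{reason}"
            continue

        reads = inputs.evidence.get((v.sample_id, gene), [])
        events = type_events(reads, t, min_form_reads=config.min_reads)
        for ev in events:
            locate_cryptic_sites(ev, inputs.genome, t, v)
            ev.variant = v

        bp_positions = [
            b.pos if hasattr(b, "pos") else int(b) for b in inputs.branchpoints.get(gene, [])
        ]
        eligible = [
            ev
            for ev in events
            if candidate_window(
                rec.location,
                ev,
                bp_positions,
                variant_pos=v.pos,
                junction_positions=_event_anchor_junctions(ev, t),
                strand=t.strand,
                config=config,
            )
        ]
        if not events:
            rec.status = "excluded:no_abnormal_event"
            continue
        if not eligible:
            rec.event = max(events, key=lambda e: e.abnormal_count)  # kept for the rescue stage
            rec.status = "excluded:distance_window"
            continue
        event = max(eligible, key=lambda e: e.abnormal_count)
        rec.event = event

        if event.locus[0] == "skip":
            locus_global = (gene, "skip", *event.locus[1])
        else:
            locus_global = (gene, *event.locus)
        ratio = event_ratio(event.abnormal_count, event.normal_count or 0, config.min_reads)
        if inputs.normal_counts.has_locus(locus_global):
            bg = build_background(
                locus_global,
                inputs.normal_counts,
                inputs.cancer_counts,
                inputs.gene_flags.get(gene, set()),
                min_normal_reads=config.min_reads,
                min_cohort=config.min_cohort,
            )
            rec.detection = test_event(ratio, bg, config)
        else:
            rec.detection = DetectionResult(ratio=ratio, reason="no_background_locus")

        if event.event_type == FULL_INTRON_RETENTION:
            retention_reads = [r for f in event.forms for r in f.reads]
            if rec.location.category == "exonic":
                confirmed, why, p = confirm_full_intron_retention(
                    v, "exonic", retention_reads, spliced_counts=(0, 0)
                )
                rec.confirmation_branch = "exonic_fisher"
                if p is not None:
                    exonic_fir_pool.append((rec, p))
                else:
                    rec.status = f"excluded:{why}"
            else:
                confirmed, why, _ = confirm_full_intron_retention(
                    v, rec.location.category, retention_reads
                )
                rec.confirmation_branch = "intronic_allele"
                rec.passed = confirmed
                rec.status = "passed" if confirmed else f"failed_gates:{why}"
        else:
            if rec.detection.testable:
                ratio_pool.append((rec, rec.detection))
            else:
                rec.status = f"excluded:{rec.detection.reason}"

    apply_fdr([d for _, d in ratio_pool], config)
    for rec, det in ratio_pool:
        rec.passed = bool(det.passed)
        rec.status = "passed" if rec.passed else "failed_gates"

    if exonic_fir_pool:
        from .detection import bh_fdr

        qs = bh_fdr([p for _, p in exonic_fir_pool])
        for (rec, _), q in zip(exonic_fir_pool, qs):
            rec.passed = bool(q < config.fdr)
            rec.status = "passed" if rec.passed else "failed_gates"

    # allele validation of cryptic-site events
    for rec in records:
        if rec.event is None or not rec.passed:
            continue
        cryptic_reads = [
            r
            for f in rec.event.forms
            if f.cryptic_donor is not None or f.cryptic_acceptor is not None
            for r in f.reads
        ]
        if cryptic_reads:
            rec.validation = cryptic_allele_test(rec.variant, cryptic_reads)
    return records


def calls_to_frame(records: Sequence[CallRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        det = r.detection
        rows.append(
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos + 1,
                "ref": r.variant.ref_allele,
                "alt": r.variant.alt_allele,
                "sample": r.variant.sample_id,
                "gene": r.gene_id,
                "category": r.location.category if r.location else None,
                "distance_bp": r.location.distance_bp if r.location else None,
                "event_type": r.event.event_type if r.event else None,
                "abnormal": r.event.abnormal_count if r.event else None,
                "normal": r.event.normal_count if r.event else None,
                "ratio": det.ratio if det else None,
                "z_normal": det.z_normal if det else None,
                "z_cancer": det.z_cancer if det else None,
                "p_value": det.p_value if det else None,
                "fdr_q": det.fdr_q if det else None,
                "top1_normal": det.top1_normal if det else None,
                "top1_cancer": det.top1_cancer if det else None,
                "passed": r.passed,
                "status": r.status,
                "validation_verdict": r.validation.verdict if r.validation else None,
                "validation_or": r.validation.odds_ratio if r.validation else None,
            }
        )
    return pd.DataFrame(rows)


def null_locus_scan(
    normal_counts: CohortCounts,
    cancer_counts: CohortCounts,
    config: DetectionConfig = DetectionConfig(),
    *,
    query_sample_index: int = 0,
    gene_flags: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Locus-level null diagnostic: test one held-out cancer sample's ratio at
    every locus against backgrounds built from the remaining samples.

    Returns a per-locus table with eligibility, top-1% gate flags and the
    right-tailed P, from which false-positive gate rates are measured.
    """
    query = cancer_counts.sample_ids[query_sample_index]
    rows = []
    for locus in cancer_counts.loci:
        n, a = cancer_counts.sample_counts(query, locus)
        ratio = event_ratio(a, n, config.min_reads)
        flags = set(gene_flags.get(locus[0], set())) if gene_flags else set()
        flags.add(query)
        bg = build_background(
            locus,
            normal_counts,
            cancer_counts,
            flags,
            min_normal_reads=config.min_reads,
            min_cohort=config.min_cohort,
        )
        res = test_event(ratio, bg, config)
        rows.append(
            {
                "locus": "|".join(str(x) for x in locus),
                "eligible": ratio is not None,
                "ratio": ratio,
                "top1_both": bool(res.top1_normal and res.top1_cancer),
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    apply_results = [
        DetectionResult(
            ratio=r.ratio,
            p_value=r.p_value,
            top1_normal=r.top1_both,
            top1_cancer=r.top1_both,
        )
        if r.eligible and r.p_value is not None
        else DetectionResult(ratio=None, reason="ineligible_counts")
        for r in df.itertuples()
    ]
    apply_fdr(apply_results, config)
    df["passed"] = [bool(res.passed) for res in apply_results]
    return df


# ---------------------------------------------------------------------------
# post-detection stages
# ---------------------------------------------------------------------------


def rescue_stage(records: Sequence[CallRecord], config: DetectionConfig = DetectionConfig()) -> list[CallRecord]:
    """Allele-level rescue of variants the ratio criteria excluded.

    Variants excluded for distance from cryptic sites (within 100 bp) or for
    insufficient read counts are reconsidered when >=3 variant-allele
    abnormal reads make up >80% of the abnormal reads.  Rescued records are
    marked ``rescued`` and count as passed.
    """
    from .allele import RescueCandidate, rescue_variants

    candidates: list[tuple[CallRecord, RescueCandidate]] = []
    for rec in records:
        if rec.event is None or rec.passed:
            continue
        distance_excluded = rec.status == "excluded:distance_window"
        count_excluded = (
            rec.detection is not None and rec.detection.reason == "ineligible_counts"
        )
        if not (distance_excluded or count_excluded):
            continue
        reads = [r for f in rec.event.forms for r in f.reads]
        dist = None
        sites = rec.event.cryptic_positions()
        if sites:
            dist = min(abs(rec.variant.pos - s) for s in sites)
        candidates.append(
            (
                rec,
                RescueCandidate(
                    variant=rec.variant,
                    reason_code="distance" if distance_excluded else "coverage",
                    abnormal_reads=reads,
                    distance_to_cryptic=dist,
                ),
            )
        )
    rescued = rescue_variants([c for _, c in candidates])
    rescued_ids = {id(c.variant) for c in rescued}
    out = []
    for rec, cand in candidates:
        if id(cand.variant) in rescued_ids:
            rec.passed = True
            rec.status = "rescued"
            out.append(rec)
    return out


def characterize_calls(
    records: Sequence[CallRecord],
    inputs: PipelineInputs,
    donor_model: SpliceStrengthModel,
    acceptor_model: SpliceStrengthModel,
    enhancers=None,
    silencers=None,
) -> pd.DataFrame:
    """Splice-code alteration metrics for every passed call.

    Scores the variant against whichever code elements it can touch: the
    authentic donor/acceptor windows of the event's intron (losses), any
    activated cryptic site's window (gains), the U2 duplex at an annotated
    branchpoint, and the enhancer/silencer hexamer sets for deep intronic
    variants on pseudoexons or retained segments.
    """
    rows = []
    for rec in records:
        if not rec.passed or rec.event is None:
            continue
        v, t = rec.variant, inputs.transcripts[rec.gene_id]
        row: dict = {
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "sample": v.sample_id,
            "gene": rec.gene_id,
            "category": rec.location.category,
            "event_type": rec.event.event_type,
        }
        k = rec.location.intron_index
        if k is None and rec.event.locus[0] == "intron":
            k = rec.event.locus[1]
        if k is not None and 0 <= k < len(t.introns):
            for side, model, boundary in (
                ("donor", donor_model, t.donor_boundary(k)),
                ("acceptor", acceptor_model, t.acceptor_boundary(k)),
            ):
                try:
                    wt, mut, delta = strength_delta(
                        v, boundary, inputs.genome, model, chrom=t.chrom, strand=t.strand
                    )
                    row[f"authentic_{side}_wt"] = wt
                    row[f"authentic_{side}_mut"] = mut
                    row[f"authentic_{side}_delta"] = delta
                except ValueError:
                    pass
            bps = [b.pos if hasattr(b, "pos") else int(b) for b in inputs.branchpoints.get(rec.gene_id, [])]
            intron_bps = [b for b in bps if min(t.introns[k]) <= b < max(t.introns[k])]
            hit = annotate_branchpoint(
                v.pos,
                intron_bps,
                acceptor_boundary=t.acceptor_boundary(k),
                strand=t.strand,
            )
            if hit is not None:
                bp_pos, rel, in_window = hit
                row["bp_pos"] = bp_pos + 1
                row["bp_relative"] = rel
                if in_window and rel != 0:
                    try:
                        g_wt, g_mut, ddg = u2_delta(v, inputs.genome, t.chrom, t.strand, bp_pos)
                        row["u2_dg_wt"], row["u2_dg_mut"], row["u2_ddg"] = g_wt, g_mut, ddg
                    except ValueError:
                        pass
        for form in rec.event.forms:
            if form.cryptic_donor is not None:
                try:
                    wt, mut, delta = strength_delta(
                        v, form.cryptic_donor, inputs.genome, donor_model, chrom=t.chrom, strand=t.strand
                    )
                    row["cryptic_donor_delta"] = delta
                    row["cryptic_donor_mut"] = mut
                except ValueError:
                    pass
            if form.cryptic_acceptor is not None:
                try:
                    wt, mut, delta = strength_delta(
                        v, form.cryptic_acceptor, inputs.genome, acceptor_model, chrom=t.chrom, strand=t.strand
                    )
                    row["cryptic_acceptor_delta"] = delta
                    row["cryptic_acceptor_mut"] = mut
                except ValueError:
                    pass
        if (
            rec.location.category == "deep_intronic"
            and rec.event.event_type in ("pseudoexon_activation", "partial_intron_retention")
        ):
            for ms, label in ((enhancers, "enhancer"), (silencers, "silencer")):
                if ms is None:
                    continue
                try:
                    wt_m, mut_m, _ = motif_scan(v, inputs.genome, ms, chrom=t.chrom, strand=t.strand)
                    row[f"{label}_wt_match"] = len(wt_m) > 0
                    row[f"{label}_mut_match"] = len(mut_m) > 0
                except ValueError:
                    pass
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_tests(
    records: Sequence[CallRecord],
    inputs: PipelineInputs,
    enhancers,
    silencers,
    *,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> dict[str, object]:
    """Permutation enrichment of motif alterations among called deep intronic
    SNVs against the universe of all deep intronic SNVs.

    Two directions are tested with unique-sequence counting: gain of an
    enhancer on the mutant allele and loss of a silencer (wild-type allele
    match absent from the mutant).
    """
    from .downstream import permutation_enrichment
    from .splice_codes import flank_11mer

    def deep(v: VariantRecord) -> bool:
        gene = _find_gene(v, inputs.transcripts)
        if gene is None or v.kind != "SNV":
            return False
        loc = classify_variant_location(v, inputs.transcripts[gene])
        return loc.category == "deep_intronic"

    universe = [v for v in inputs.variants if deep(v)]
    passed_keys = {id(r.variant) for r in records if r.passed}
    observed = [v for v in universe if id(v) in passed_keys]
    if not observed:
        return {}

    flanks: dict[int, tuple[str, str]] = {}
    for v in universe:
        gene = _find_gene(v, inputs.transcripts)
        t = inputs.transcripts[gene]
        try:
            flanks[id(v)] = flank_11mer(inputs.genome, t.chrom, t.strand, v)
        except ValueError:
            flanks[id(v)] = ("N" * 11, "N" * 11)

    def frames(s: str) -> set[str]:
        return {s[i : i + 6] for i in range(6)}

    def enhancer_gain(v) -> bool:
        wt, mut = flanks[id(v)]
        return bool(frames(mut) & enhancers.hexamers) and not frames(wt) & enhancers.hexamers

    def silencer_loss(v) -> bool:
        wt, mut = flanks[id(v)]
        return bool(frames(wt) & silencers.hexamers) and not frames(mut) & silencers.hexamers

    out = {}
    for name, pred in (("enhancer_gain", enhancer_gain), ("silencer_loss", silencer_loss)):
        out[name] = permutation_enrichment(
            observed,
            universe,
            pred,
            n=n_permutations,
            seed=seed,
            sequence_key=lambda v: flanks[id(v)][1],
        )
    return out


def ptc_nmd_table(records: Sequence[CallRecord], inputs: PipelineInputs) -> pd.DataFrame:
    """PTC presence and NMD class for every passed call."""
    from .downstream import ptc_scan

    rows = []
    for rec in records:
        if not rec.passed or rec.event is None:
            continue
        t = inputs.transcripts[rec.gene_id]
        call = ptc_scan(rec.event, t, inputs.genome)
        rows.append(
            {
                "chrom": rec.variant.chrom,
                "pos": rec.variant.pos + 1,
                "sample": rec.variant.sample_id,
                "gene": rec.gene_id,
                "event_type": rec.event.event_type,
                "form_used": call.form_used,
                "ptc_cds_position": call.ptc_cds_position,
                "nmd_class": call.nmd_class,
            }
        )
    return pd.DataFrame(rows)


def expression_stage(
    ptc_table: pd.DataFrame,
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    gene_flags: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, float | None]:
    """log2 mutant-vs-control expression per PTC call, and a two-sided
    rank-sum P comparing NMD-sensitive calls with the rest."""
    from .downstream import compare_effect_groups, expression_effect

    flags = [(g, s) for g, samples in gene_flags.items() for s in samples]
    rows = []
    for row in ptc_table.itertuples():
        if row.gene not in expression.index or row.sample not in expression.columns:
            continue
        eff = expression_effect(
            row.gene, sample_types.get(row.sample, ""), row.sample, expression, sample_types, flags
        )
        if eff is None:
            continue
        rows.append(
            {
                "gene": row.gene,
                "sample": row.sample,
                "nmd_class": row.nmd_class,
                "log2_ratio": eff[0],
                "n_controls": eff[1],
            }
        )
    df = pd.DataFrame(rows)
    p = None
    if not df.empty:
        sens = df.loc[df.nmd_class == "sensitive", "log2_ratio"]
        rest = df.loc[df.nmd_class != "sensitive", "log2_ratio"]
        if len(sens) >= 3 and len(rest) >= 3:
            p = compare_effect_groups(sens, rest)
    return df, p


def burden_stage(
    records: Sequence[CallRecord],
    gene_flags: Mapping[str, set[str]],
    sample_types: Mapping[str, str],
) -> pd.DataFrame:
    """Gene-level burden: samples with intronic mis-splicing calls versus
    samples with (simulated) truncating lesions."""
    from .downstream import gene_burden_summary

    mis = pd.DataFrame(
        [
            {"gene": r.gene_id, "sample": r.variant.sample_id}
            for r in records
            if r.passed and r.location is not None and r.location.category != "exonic"
        ]
    )
    trunc = pd.DataFrame(
        [{"gene": g, "sample": s} for g, samples in gene_flags.items() for s in samples]
    )
    return gene_burden_summary(mis, trunc)


def prediction_stage(
    records: Sequence[CallRecord],
    inputs: PipelineInputs,
    donor_model: SpliceStrengthModel,
    acceptor_model: SpliceStrengthModel,
    *,
    iterations: int = 100,
    seed: int | None = None,
) -> dict[str, object]:
    """Train the proximal one-class models on passed calls and cross-validate."""
    from .prediction import cross_validate, make_features, train_one_class

    by_class: dict[str, list] = {}
    for rec in records:
        if not rec.passed:
            continue
        t = inputs.transcripts[rec.gene_id]
        try:
            fv = make_features(rec.variant, t, inputs.genome, donor_model, acceptor_model)
        except ValueError:
            continue
        by_class.setdefault(fv.model_class, []).append(fv)
    out = {}
    for mclass, fvs in by_class.items():
        if len(fvs) < 6:
            continue
        model = train_one_class(fvs, model_class=mclass, seed=seed)
        cv = cross_validate(fvs, folds=3, iterations=iterations, seed=seed)
        out[mclass] = {"n": len(fvs), "model": model, "cv": cv}
    return out
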