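"""Allele-specificity validation of splicing calls.

The 2x2 contingency tables here always have rows = (DNA, RNA) — or, for the
exonic full-retention branch, (spliced, unspliced) — and columns =
(reference allele, variant allele).  An odds ratio above 1 on the DNA/RNA
table means the variant allele is overrepresented among the aberrant reads
(variant-specific mis-splicing); below 1 on skipped-exon reads means
reference-allele-specific expression.  Only the sign of the comparison
carries meaning, so zero cells map to the extended values 0 and +inf rather
than being continuity-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .evidence import ReadObservation, rna_allele_counts
from .gene_models import VariantRecord

__all__ = [
    "ContingencyResult",
    "odds_ratio",
    "fisher_exact",
    "cryptic_allele_test",
    "skip_allele_test",
    "confirm_full_intron_retention",
    "rescue_variants",
    "RescueCandidate",
]

VARIANT_SPECIFIC = "variant_specific"
REFERENCE_SPECIFIC = "reference_specific"
INCONCLUSIVE = "inconclusive"


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None  # +inf allowed; None = undefined (0/0)
    fisher_p: float | None
    verdict: str


def odds_ratio(table: Sequence[Sequence[int]]) -> float | None:
    """(a*d)/(b*c) of a 2x2 table with extended-value conventions:
    ``b*c == 0 < a*d`` gives +inf, ``a*d == 0 < b*c`` gives 0, and a table
    where both products vanish has no defined odds ratio (``None``)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    ad, bc = a * d, b * c
    if bc == 0:
        return math.inf if ad > 0 else None
    return ad / bc


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact P by the probability-mass rule.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with the
    customary 1+1e-7 relative tolerance for floating-point ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _verdict_table(
    dna: tuple[int, int], rna: tuple[int, int], direction: str, min_reads: int
) -> ContingencyResult:
    table = (tuple(dna), tuple(rna))
    informative = rna[0] + rna[1]
    or_ = odds_ratio(table)
    if informative < min_reads or or_ is None:
        return ContingencyResult(table=table, odds_ratio=or_, fisher_p=None, verdict=INCONCLUSIVE)
    p = fisher_exact(table)
    if direction == "variant" and or_ > 1:
        verdict = VARIANT_SPECIFIC
    elif direction == "reference" and or_ < 1:
        verdict = REFERENCE_SPECIFIC
    else:
        verdict = INCONCLUSIVE
    return ContingencyResult(table=table, odds_ratio=or_, fisher_p=p, verdict=verdict)


def cryptic_allele_test(
    variant: VariantRecord,
    cryptic_supporting_reads: Sequence[ReadObservation],
    *,
    min_reads: int = 3,
    min_base_quality: int = 30,
) -> ContingencyResult:
    """Variant-specificity of cryptic splice-site activation.

    RNA allele counts come only from reads supporting the cryptic site; the
    DNA row is the tumour DNA allele counts of the variant.  Verifiable with
    >= ``min_reads`` informative RNA reads; verdict ``variant_specific`` iff
    the odds ratio exceeds 1.
    """
    rna_ref, rna_alt, _ = rna_allele_counts(
        cryptic_supporting_reads, variant.ref_allele, variant.alt_allele, min_base_quality
    )
    return _verdict_table(
        (variant.dna_ref_count, variant.dna_alt_count), (rna_ref, rna_alt), "variant", min_reads
    )


def skip_allele_test(
    variant: VariantRecord,
    rna_counts: tuple[int, int],
    *,
    min_reads: int = 3,
) -> ContingencyResult:
    """Reference-allele-specific expression of a skipped exon: the variant
    allele should be underrepresented among RNA reads covering the exon
    (odds ratio < 1)."""
    return _verdict_table(
        (variant.dna_ref_count, variant.dna_alt_count), tuple(rna_counts), "reference", min_reads
    )


def confirm_full_intron_retention(
    variant: VariantRecord,
    category: str,
    retention_reads: Sequence[ReadObservation],
    spliced_counts: tuple[int, int] | None = None,
    *,
    min_reads: int = 3,
    min_alt_fraction: float = 0.8,
    min_base_quality: int = 30,
) -> tuple[bool, str, float | None]:
    """Allele-level confirmation of a full-intron-retention call.

    Intronic variants: confirmed when the odds ratio against DNA exceeds 1,
    the retention reads carry >= ``min_reads`` variant alleles, and the
    variant-allele fraction among them exceeds 80%.  Exonic variants: a
    Fisher exact test on (spliced, unspliced) x (ref, alt); the returned P
    feeds a run-level BH-FDR gate (q < 0.1) applied by the caller.  Returns
    ``(confirmed, reason, fisher_p)``.
    """
    ref, alt, _ = rna_allele_counts(
        retention_reads, variant.ref_allele, variant.alt_allele, min_base_quality
    )
    if category in ("splice_site", "proximal_intronic", "deep_intronic"):
        if alt < min_reads:
            return False, "alt_reads_below_minimum", None
        if alt + ref == 0 or alt / (alt + ref) <= min_alt_fraction:
            return False, "alt_fraction_below_80pct", None
        or_ = odds_ratio(((variant.dna_ref_count, variant.dna_alt_count), (ref, alt)))
        if or_ is None or or_ <= 1:
            return False, "odds_ratio_not_above_1", None
        return True, "allele_confirmed", None
    if category == "exonic":
        if spliced_counts is None:
            raise ValueError("exonic branch requires spliced read allele counts")
        if alt < min_reads:
            return False, "alt_reads_below_minimum", None
        p = fisher_exact((tuple(spliced_counts), (ref, alt)))
        return True, "fisher_pending_fdr", p
    raise ValueError(f"no confirmation branch for category {category!r}")


@dataclass
class RescueCandidate:
    """A variant previously excluded from the ratio analysis, with the
    allele-resolved abnormal reads needed to reconsider it."""

    variant: VariantRecord
    reason_code: str  # why the ratio analysis excluded it
    abnormal_reads: Sequence[ReadObservation]
    distance_to_cryptic: int | None = None


def rescue_variants(
    excluded: Sequence[RescueCandidate],
    *,
    min_reads: int = 3,
    min_alt_fraction: float = 0.8,
    rescue_window: int = 100,
    min_base_quality: int = 30,
) -> list[RescueCandidate]:
    """Allele-level rescue of deep intronic SNVs the ratio criteria excluded.

    Rescued when >= ``min_reads`` abnormal reads carry the variant allele and
    they make up more than 80% of the allele-informative abnormal reads
    (bases below the quality floor are excluded from both counts, matching
    the RNA allele-frequency convention); candidates excluded for distance
    must additionally lie within ``rescue_window`` bp of the cryptic splice
    site.
    """
    rescued = []
    for cand in excluded:
        v = cand.variant
        ref, alt, _ = rna_allele_counts(cand.abnormal_reads, v.ref_allele, v.alt_allele, min_base_quality)
        total = ref + alt
        if alt < min_reads or total == 0 or alt / total <= min_alt_fraction:
            continue
        if cand.reason_code.startswith("distance"):
            if cand.distance_to_cryptic is None or cand.distance_to_cryptic > rescue_window:
                continue
        rescued.append(cand)
    return rescued
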