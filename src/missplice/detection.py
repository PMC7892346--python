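"""The ratio-based statistical test for abnormal splicing.

For every candidate (variant, event) pair the proportion of abnormally
spliced reads among all spliced reads at the locus is compared against two
empirical background distributions — one from a normal-tissue cohort and one
from mutation-free cancer samples, each requiring more than 500 contributing
samples.  A call passes when the observed ratio sits within the top 1% of
both backgrounds and its Benjamini-Hochberg FDR is below 0.1.  Eligibility
and confounder rules restrict which variants are tested at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import SpliceEventCall
from .gene_models import LocationCall, VariantRecord

__all__ = [
    "DetectionConfig",
    "BackgroundDistribution",
    "DetectionResult",
    "CohortCounts",
    "event_ratio",
    "build_background",
    "test_event",
    "bh_fdr",
    "confounder_filter",
    "candidate_window",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds (defaults mirror the published procedure)."""

    min_reads: int = 3  # both spliced-read classes must reach this
    min_cohort: int = 501  # >500 samples per background distribution
    top_pct: float = 0.01
    fdr: float = 0.1
    window_junction: int = 30  # bp flank of authentic junctions
    window_cryptic: int = 30  # bp flank of activated cryptic splice sites
    bp_window: tuple[int, int] = (-5, 3)  # eligible window around a branchpoint
    nearby_bp: int = 50  # "additional variants nearby" exclusion window


@dataclass
class BackgroundDistribution:
    """Per-locus background abnormal-read ratios from the two cohorts."""

    locus: tuple
    normal_ratios: np.ndarray
    cancer_ratios: np.ndarray

    @property
    def n_normal(self) -> int:
        return len(self.normal_ratios)

    @property
    def n_cancer(self) -> int:
        return len(self.cancer_ratios)

    def testable(self, min_cohort: int = 501) -> bool:
        return self.n_normal >= min_cohort and self.n_cancer >= min_cohort

    def stats(self) -> tuple[float, float, float, float]:
        return (
            float(np.mean(self.normal_ratios)),
            float(np.std(self.normal_ratios)),
            float(np.mean(self.cancer_ratios)),
            float(np.std(self.cancer_ratios)),
        )


@dataclass
class DetectionResult:
    ratio: float | None
    z_normal: float | None = None
    z_cancer: float | None = None
    p_value: float | None = None
    top1_normal: bool = False
    top1_cancer: bool = False
    fdr_q: float | None = None
    passed: bool | None = None
    reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.reason is None


def event_ratio(abnormal_count: int, normal_count: int, min_reads: int = 3) -> float | None:
    """Abnormal / (abnormal + normal) read ratio; ``None`` (ineligible) unless
    both read classes reach ``min_reads``."""
    if abnormal_count < 0 or normal_count < 0:
        raise ValueError("counts must be non-negative")
    if abnormal_count < min_reads or normal_count < min_reads:
        return None
    return abnormal_count / (abnormal_count + normal_count)


class CohortCounts:
    """Per-sample normal/abnormal read counts at every locus of a cohort.

    Backed by two integer arrays of shape (n_samples, n_loci); the container
    the cohort generator emits and ``build_background`` consumes.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        loci: Sequence[tuple],
        normal_counts: np.ndarray,
        abnormal_counts: np.ndarray,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.loci = list(loci)
        self._locus_index = {l: i for i, l in enumerate(self.loci)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self.normal_counts = np.asarray(normal_counts)
        self.abnormal_counts = np.asarray(abnormal_counts)
        if self.normal_counts.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("count matrix shape mismatch")

    def locus_column(self, locus: tuple) -> tuple[np.ndarray, np.ndarray]:
        i = self._locus_index[locus]
        return self.normal_counts[:, i], self.abnormal_counts[:, i]

    def sample_counts(self, sample_id: str, locus: tuple) -> tuple[int, int]:
        si, li = self._sample_index[sample_id], self._locus_index[locus]
        return int(self.normal_counts[si, li]), int(self.abnormal_counts[si, li])

    def has_locus(self, locus: tuple) -> bool:
        return locus in self._locus_index


def build_background(
    locus: tuple,
    normal_cohort: CohortCounts,
    cancer_cohort: CohortCounts,
    mutation_flags: Mapping[str, bool] | Iterable[str] | None = None,
    *,
    min_normal_reads: int = 3,
    min_cohort: int = 501,
) -> BackgroundDistribution:
    """Assemble the two background ratio distributions for one locus.

    Cancer samples flagged for non-silent mutations / exonic SV breakpoints
    in the gene are excluded; any sample with fewer than ``min_normal_reads``
    normally spliced reads is excluded from its cohort.  The caller decides
    testability via :meth:`BackgroundDistribution.testable`.
    """
    if mutation_flags is None:
        flagged: set[str] = set()
    elif isinstance(mutation_flags, Mapping):
        flagged = {s for s, f in mutation_flags.items() if f}
    else:
        flagged = set(mutation_flags)

    def cohort_ratios(cohort: CohortCounts, exclude: set[str]) -> np.ndarray:
        n, a = cohort.locus_column(locus)
        mask = n >= min_normal_reads
        if exclude:
            keep = np.array([s not in exclude for s in cohort.sample_ids])
            mask &= keep
        with np.errstate(invalid="ignore"):
            ratios = a[mask] / (a[mask] + n[mask])
        return ratios

    return BackgroundDistribution(
        locus=locus,
        normal_ratios=cohort_ratios(normal_cohort, set()),
        cancer_ratios=cohort_ratios(cancer_cohort, flagged),
    )


def test_event(
    ratio: float | None,
    bg: BackgroundDistribution,
    config: DetectionConfig = DetectionConfig(),
) -> DetectionResult:
    """Z-score the observed ratio against both backgrounds.

    The single reported P is the larger of the two right-tailed normal tail
    probabilities (the conservative reconstruction of the published one-P
    convention); the top-1% flags use the empirical 99th percentile of each
    cohort.
    """
    if ratio is None:
        return DetectionResult(ratio=None, reason="ineligible_counts")
    if not bg.testable(config.min_cohort):
        return DetectionResult(ratio=ratio, reason="cohort_too_small")
    mean_n, sd_n, mean_c, sd_c = bg.stats()
    if sd_n == 0 or sd_c == 0:
        return DetectionResult(ratio=ratio, reason="zero_background_sd")
    z_n = (ratio - mean_n) / sd_n
    z_c = (ratio - mean_c) / sd_c
    p = float(max(stats.norm.sf(z_n), stats.norm.sf(z_c)))
    q_n = float(np.quantile(bg.normal_ratios, 1 - config.top_pct))  # type-7 (linear) quantile
    q_c = float(np.quantile(bg.cancer_ratios, 1 - config.top_pct))
    return DetectionResult(
        ratio=ratio,
        z_normal=float(z_n),
        z_cancer=float(z_c),
        p_value=p,
        top1_normal=bool(ratio > q_n),
        top1_cancer=bool(ratio > q_c),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: Sequence[DetectionResult], config: DetectionConfig = DetectionConfig()) -> None:
    """Fill ``fdr_q`` and ``passed`` across all testable results of a run."""
    testable = [r for r in results if r.testable and r.p_value is not None]
    if testable:
        q = bh_fdr([r.p_value for r in testable])
        for r, qi in zip(testable, q):
            r.fdr_q = float(qi)
            r.passed = bool(r.top1_normal and r.top1_cancer and qi < config.fdr)
    for r in results:
        if r.passed is None:
            r.passed = False


def confounder_filter(
    variant: VariantRecord,
    gene_variants: Sequence[tuple[VariantRecord, bool]],
    sv_exon_breakpoint: bool = False,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[bool, str | None]:
    """Exclude variants whose gene carries confounding lesions.

    ``gene_variants`` are the same-sample variants of the gene as
    ``(variant, is_non_silent)`` pairs, ``is_non_silent`` already reflecting
    the 2-bp silent-reclassification rule.  Fails on any other non-silent
    mutation in the gene, on an exonic SV breakpoint, or on any other variant
    within ``config.nearby_bp`` of the candidate.
    """
    if sv_exon_breakpoint:
        return False, "sv_breakpoint_in_gene"
    for other, non_silent in gene_variants:
        if other.chrom == variant.chrom and other.pos == variant.pos and other.alt_allele == variant.alt_allele:
            continue
        if non_silent:
            return False, "non_silent_in_gene"
        if other.chrom == variant.chrom and abs(other.pos - variant.pos) <= config.nearby_bp:
            return False, "nearby_variant"
    return True, None


def candidate_window(
    location: LocationCall,
    event: SpliceEventCall | None = None,
    bp_positions: Sequence[int] = (),
    *,
    variant_pos: int | None = None,
    junction_positions: Sequence[int] = (),
    strand: str = "+",
    config: DetectionConfig = DetectionConfig(),
) -> bool:
    """Ratio-analysis eligibility of a variant.

    Eligible when within 30 bp of an authentic exon-intron junction or of an
    activated cryptic splice site; deep intronic variants additionally only
    when inside a branchpoint window (5 bp upstream to 3 bp downstream of a
    BP) or a cryptic-site 30 bp flank.  ``bp_positions`` and
    ``junction_positions`` are genomic; ``variant_pos`` is required for the
    cryptic/BP distance checks.
    """
    near_junction = abs(location.distance_bp) <= config.window_junction
    near_cryptic = False
    if event is not None and variant_pos is not None:
        near_cryptic = any(
            abs(variant_pos - site) <= config.window_cryptic for site in event.cryptic_positions()
        )
    if variant_pos is not None and junction_positions:
        near_junction = near_junction or any(
            abs(variant_pos - j) <= config.window_junction for j in junction_positions
        )

    if location.category != "deep_intronic":
        return near_junction or near_cryptic

    if near_cryptic:
        return True
    if variant_pos is not None:
        lo, hi = config.bp_window
        for bp in bp_positions:
            off = variant_pos - bp if strand == "+" else bp - variant_pos
            if lo <= off <= hi:
                return True
    return False
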