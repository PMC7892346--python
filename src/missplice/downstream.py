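"""Downstream characterisation of mis-splicing calls: permutation
enrichment, PTC/NMD classification, expression effects and gene burden.

NMD rule: a premature termination codon is NMD-insensitive when it lies in
the first 250 nt of the (aberrant-transcript) CDS or no more than 55 nt
upstream of the last exon-exon junction — through to the end of the last
exon; everything in between triggers decay.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import COMBINATORIAL, EventForm, SpliceEventCall
from .gene_models import GenomeSequence, TranscriptModel, revcomp

__all__ = [
    "EnrichmentResult",
    "PTCCall",
    "permutation_enrichment",
    "ptc_scan",
    "nmd_classify",
    "aberrant_exons",
    "expression_effect",
    "compare_effect_groups",
    "gene_burden_summary",
    "fisher_exact_rxc",
]

_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    observed_count: int
    n_permutations: int
    null_mean: float
    null_sd: float
    p_value: float
    seed: int | None
    p_is_upper_bound: bool = False
    method: str = "permutation"


def permutation_enrichment(
    observed: Sequence,
    universe: Sequence,
    hit_predicate: Callable[[object], bool],
    n: int = 100_000,
    seed: int | None = None,
    *,
    sequence_key: Callable[[object], str] | None = None,
    exact: bool = False,
) -> EnrichmentResult:
    """Permutation test for enrichment of a property among selected SNVs.

    Draws ``len(observed)`` items from ``universe`` without replacement ``n``
    times and counts predicate hits per draw; P is the proportion of draws
    with a count at least the observed one.  With ``sequence_key`` set (motif
    predicates) identical sequences count once per draw.  ``exact=True``
    enumerates every subset instead of sampling (small universes only).  A
    zero numerator is reported as the upper bound 1/n so that P stays in
    (0, 1].
    """
    observed = list(observed)
    universe = list(universe)
    if len(observed) > len(universe):
        raise ValueError("observed set larger than universe")
    obs_keys = set(observed)
    if not obs_keys <= set(universe):
        raise ValueError("observed set must be a subset of the universe")

    def count_hits(items: Iterable) -> int:
        if sequence_key is None:
            return sum(1 for x in items if hit_predicate(x))
        return len({sequence_key(x) for x in items if hit_predicate(x)})

    observed_count = count_hits(observed)
    k = len(observed)

    if exact:
        total = math.comb(len(universe), k)
        if total > 500_000:
            raise ValueError(f"exact enumeration infeasible: C({len(universe)},{k}) = {total}")
        counts = np.fromiter(
            (count_hits(c) for c in itertools.combinations(universe, k)), dtype=int, count=total
        )
        ge = int((counts >= observed_count).sum())
        return EnrichmentResult(
            observed_count=observed_count,
            n_permutations=total,
            null_mean=float(counts.mean()),
            null_sd=float(counts.std()),
            p_value=ge / total,
            seed=seed,
            method="exact_enumeration",
        )

    rng = np.random.default_rng(seed)
    if sequence_key is None:
        # plain indicator predicate: the hit count of a uniform draw of k
        # items without replacement is exactly hypergeometric, so sample the
        # count law directly instead of materialising each permutation
        n_hits = int(sum(bool(hit_predicate(x)) for x in universe))
        counts = rng.hypergeometric(n_hits, len(universe) - n_hits, k, size=n)
    else:
        # map each universe member to a hit-sequence id (-1 = no hit), then
        # count distinct ids per draw so duplicate sequences count once
        seq_ids: dict[str, int] = {}
        ids = np.empty(len(universe), dtype=np.int64)
        for i, x in enumerate(universe):
            if hit_predicate(x):
                ids[i] = seq_ids.setdefault(sequence_key(x), len(seq_ids))
            else:
                ids[i] = -1
        perms = rng.permuted(np.tile(ids, (n, 1)), axis=1)[:, :k]
        perms.sort(axis=1)
        first = perms[:, :1] >= 0
        distinct = np.concatenate(
            [first, (perms[:, 1:] != perms[:, :-1]) & (perms[:, 1:] >= 0)], axis=1
        )
        counts = distinct.sum(axis=1)

    ge = int((counts >= observed_count).sum())
    return EnrichmentResult(
        observed_count=observed_count,
        n_permutations=n,
        null_mean=float(counts.mean()),
        null_sd=float(counts.std()),
        p_value=(ge / n) if ge else 1.0 / n,
        seed=seed,
        p_is_upper_bound=ge == 0,
    )


# ---------------------------------------------------------------------------
# aberrant transcript reconstruction
# ---------------------------------------------------------------------------


def _genomic_intron(t: TranscriptModel, k: int) -> tuple[int, int]:
    iv = t.introns[k]
    return min(iv), max(iv)


def aberrant_exons(t: TranscriptModel, locus: tuple, form: EventForm) -> list[tuple[int, int]]:
    """Genomic (ascending) exon intervals of the mature mRNA implied by one
    event form; the annotated spliced-out intervals are edited according to
    the form's geometry and the exon set recomputed as their complement."""
    removed = [_genomic_intron(t, k) for k in range(len(t.introns))]
    removed.sort()

    if form.kind == "retention":
        k = locus[1]
        removed.remove(_genomic_intron(t, k))
    elif form.kind in ("cryptic_acceptor", "cryptic_donor"):
        k = locus[1]
        lo, hi = _genomic_intron(t, k)
        removed.remove((lo, hi))
        donor_left = t.strand == "+"  # donor boundary on the genomic-left side?
        if form.kind == "cryptic_acceptor":
            site = form.cryptic_acceptor
            removed.append((lo, site) if donor_left else (site, hi))
        else:
            site = form.cryptic_donor
            removed.append((site, hi) if donor_left else (lo, site))
    elif form.kind == "pseudoexon":
        k = locus[1]
        lo, hi = _genomic_intron(t, k)
        removed.remove((lo, hi))
        pe_lo, pe_hi = form.pseudoexon
        removed.extend([(lo, pe_lo), (pe_hi, hi)])
    elif form.kind == "full_skip":
        ks = form.skipped_exons  # transcript-order exon indices
        flank_introns = {min(ks) - 1, max(ks)}
        bounds = [_genomic_intron(t, k) for k in flank_introns]
        inner = [
            _genomic_intron(t, k) for k in range(min(flank_introns) + 1, max(flank_introns))
        ]
        for iv in bounds + inner:
            removed.remove(iv)
        removed.append((min(b[0] for b in bounds), max(b[1] for b in bounds)))
    elif form.kind == "partial_skip":
        k = locus[1]
        lo, hi = _genomic_intron(t, k)
        removed.remove((lo, hi))
        site = form.cryptic_donor if form.cryptic_donor is not None else form.cryptic_acceptor
        removed.append((lo, site) if site > hi else (site, hi))
    else:
        raise ValueError(f"no reconstruction rule for form kind {form.kind!r}")

    removed.sort()
    g0, g1 = t.span
    exons, cursor = [], g0
    for s, e in removed:
        if s > cursor:
            exons.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < g1:
        exons.append((cursor, g1))
    return exons


def _changed_intervals(t: TranscriptModel, locus: tuple, form: EventForm) -> list[tuple[int, int]]:
    """Genomic intervals whose inclusion in the mRNA the form alters."""
    if form.kind == "full_skip":
        return [tuple(sorted(t.exons[k])) for k in form.skipped_exons]
    k = locus[1]
    lo, hi = _genomic_intron(t, k)
    if form.kind == "retention":
        return [(lo, hi)]
    if form.kind == "pseudoexon":
        return [form.pseudoexon]
    if form.kind in ("cryptic_acceptor", "cryptic_donor"):
        site = form.cryptic_acceptor if form.cryptic_acceptor is not None else form.cryptic_donor
        donor_left = t.strand == "+"
        if form.kind == "cryptic_acceptor":
            return [(site, hi) if donor_left else (lo, site)]
        return [(lo, site) if donor_left else (site, hi)]
    if form.kind == "partial_skip":
        site = form.cryptic_donor if form.cryptic_donor is not None else form.cryptic_acceptor
        if site > hi:
            return [(hi, site)]
        return [(site, lo)]
    return []


@dataclass
class PTCCall:
    """Outcome of scanning an aberrant transcript for a premature stop."""

    form_used: str | None
    ptc_cds_position: int | None  # 1-based nt of the first stop-codon base in the CDS
    nmd_class: str  # sensitive | insensitive | none | excluded_inconsistent
    cds_length_normal: int | None = None
    last_junction_cds_position: int | None = None


def _transcript_offset(exons: Sequence[tuple[int, int]], strand: str, pos: int) -> int | None:
    """Offset of a genomic position in the mRNA built from ``exons``."""
    total = sum(e - s for s, e in exons)
    acc = 0
    for s, e in exons:
        if s <= pos < e:
            plus_off = acc + (pos - s)
            return plus_off if strand == "+" else total - 1 - plus_off
        acc += e - s
    return None


def _mrna_sequence(genome: GenomeSequence, chrom: str, strand: str, exons: Sequence[tuple[int, int]]) -> str:
    seq = "".join(genome.fetch(chrom, s, e) for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


def _scan_form(
    t: TranscriptModel, genome: GenomeSequence, locus: tuple, form: EventForm
) -> PTCCall:
    if t.cds_start is None:
        return PTCCall(form_used=form.kind, ptc_cds_position=None, nmd_class="none")
    cds_iv = (t.cds_start, t.cds_end)
    changed = _changed_intervals(t, locus, form)
    if not any(max(s, cds_iv[0]) < min(e, cds_iv[1]) for s, e in changed):
        return PTCCall(form_used=form.kind, ptc_cds_position=None, nmd_class="none")

    exons = aberrant_exons(t, locus, form)
    start_genomic = t.cds_start if t.strand == "+" else t.cds_end - 1
    stop_first_genomic = t.cds_end - 3 if t.strand == "+" else t.cds_start + 2
    cds_off = _transcript_offset(exons, t.strand, start_genomic)
    if cds_off is None:
        return PTCCall(form_used=form.kind, ptc_cds_position=None, nmd_class="none")
    annotated_stop_off = _transcript_offset(exons, t.strand, stop_first_genomic)

    mrna = _mrna_sequence(genome, t.chrom, t.strand, exons)
    first_stop_off = None
    for off in range(cds_off, len(mrna) - 2, 3):
        if mrna[off : off + 3] in _STOPS:
            first_stop_off = off
            break

    is_ptc = first_stop_off is not None and (
        annotated_stop_off is None or first_stop_off < annotated_stop_off
    )
    if not is_ptc:
        return PTCCall(form_used=form.kind, ptc_cds_position=None, nmd_class="none")

    ptc_pos = first_stop_off - cds_off + 1  # 1-based CDS nt of the stop's first base
    # exon-exon junction positions of the aberrant transcript, in CDS nt
    lengths = [e - s for s, e in (exons if t.strand == "+" else exons[::-1])]
    junction_offs = list(itertools.accumulate(lengths))[:-1]
    last_junction_cds = max((j - cds_off for j in junction_offs), default=None)
    nmd = nmd_classify(ptc_pos, last_junction_cds_position=last_junction_cds)
    return PTCCall(
        form_used=form.kind,
        ptc_cds_position=ptc_pos,
        nmd_class=nmd,
        last_junction_cds_position=last_junction_cds,
    )


def ptc_scan(event: SpliceEventCall, t: TranscriptModel, genome: GenomeSequence) -> PTCCall:
    """Check the aberrant transcript of a passed event for a premature stop.

    For multi-form events of a single type the highest-ratio form is
    analysed; combinatorial events are analysed per constituent form and
    excluded when the forms disagree on the PTC/NMD outcome.  Events not
    touching the coding exons (UTR-only splicing changes) and non-coding
    transcripts return ``nmd_class="none"``.
    """
    if t.cds_start is None:
        return PTCCall(form_used=None, ptc_cds_position=None, nmd_class="none")
    if event.event_type == COMBINATORIAL:
        calls = [_scan_form(t, genome, event.locus, f) for f in event.forms]
        outcomes = {(c.ptc_cds_position is not None, c.nmd_class) for c in calls}
        if len(outcomes) > 1:
            return PTCCall(form_used=None, ptc_cds_position=None, nmd_class="excluded_inconsistent")
        return calls[0]
    return _scan_form(t, genome, event.locus, event.primary_form)


def nmd_classify(
    ptc_cds_position: int,
    *,
    last_junction_cds_position: int | None,
    first_window: int = 250,
    last_junction_window: int = 55,
) -> str:
    """NMD sensitivity of a PTC by the 250 nt / 55 nt rule.

    Insensitive when the PTC lies within the first ``first_window`` nt of
    the CDS, or at/after ``last_junction_window`` nt upstream of the last
    exon-exon junction (both positions in aberrant-transcript CDS
    coordinates); transcripts without any junction cannot be degraded
    through the exon-junction complex and are insensitive.
    """
    if ptc_cds_position < 1:
        raise ValueError("PTC position must be a positive CDS coordinate")
    if last_junction_cds_position is None:
        return "insensitive"
    if ptc_cds_position <= first_window:
        return "insensitive"
    if ptc_cds_position >= last_junction_cds_position - last_junction_window:
        return "insensitive"
    return "sensitive"


# ---------------------------------------------------------------------------
# expression effect and burden summaries
# ---------------------------------------------------------------------------


def expression_effect(
    gene: str,
    cancer_type: str,
    mutant_sample: str,
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    mutation_flags: Iterable[tuple[str, str]] = (),
    *,
    min_wildtype: int = 5,
) -> tuple[float, int] | None:
    """log2 expression of a mutant sample against the wild-type mean.

    Controls are same-cancer-type samples of the gene without non-silent
    mutation / SV / CNA flags; at least ``min_wildtype`` controls are
    required, otherwise the effect is not computed.  Returns
    ``(log2_ratio, n_controls)`` or ``None``.
    """
    flagged = {s for g, s in mutation_flags if g == gene}
    controls = [
        s
        for s in expression.columns
        if sample_types.get(s) == cancer_type and s != mutant_sample and s not in flagged
    ]
    if len(controls) < min_wildtype:
        return None
    control_mean = float(expression.loc[gene, controls].mean())
    mutant = float(expression.loc[gene, mutant_sample])
    if control_mean <= 0 or mutant <= 0:
        return None
    return math.log2(mutant / control_mean), len(controls)


def compare_effect_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U P for a difference between two groups of
    per-gene expression effects."""
    return float(stats.mannwhitneyu(values_a, values_b, alternative="two-sided").pvalue)


def gene_burden_summary(
    missplicing_calls: pd.DataFrame,
    truncating_calls: pd.DataFrame,
    *,
    min_fraction: float = 0.05,
    by_tissue: bool = False,
) -> pd.DataFrame:
    """Per-gene (optionally per-tissue) proportions of mutant samples carried
    by intronic mis-splicing versus truncating mutations.

    Both inputs need columns ``gene``, ``sample`` (and ``tissue`` when
    ``by_tissue``); genes where mis-splicing accounts for more than
    ``min_fraction`` of mutant samples are flagged.
    """
    keys = ["gene", "tissue"] if by_tissue else ["gene"]

    def tally(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=[*keys, name]).set_index(keys)
        return df.groupby(keys)["sample"].nunique().rename(name).to_frame()

    mis = tally(missplicing_calls, "missplicing_samples")
    trunc = tally(truncating_calls, "truncating_samples")
    out = mis.join(trunc, how="outer").astype(float).fillna(0).astype(int)
    out = out[(out["missplicing_samples"] + out["truncating_samples"]) > 0]
    total = out["missplicing_samples"] + out["truncating_samples"]
    out["missplicing_fraction"] = out["missplicing_samples"] / total
    out["above_threshold"] = out["missplicing_fraction"] > min_fraction
    return out.reset_index()


def fisher_exact_rxc(table: Sequence[Sequence[int]]) -> float:
    """Exact P for an r x c contingency table (Freeman-Halton flavour,
    probability-mass rule) by enumerating all tables with the observed
    margins.  Utility for small tables such as the 2 x 3 NMD-class
    comparison; the appropriate sidedness for r x c tables is not uniquely
    defined, so the symmetric probability-mass P is reported.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("table cells must be non-negative")
    row_sums, col_sums = table.sum(axis=1), table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        raise ValueError("all-zero contingency table")

    def log_fact(x: int) -> float:
        return math.lgamma(x + 1)

    const = sum(log_fact(r) for r in row_sums) + sum(log_fact(c) for c in col_sums) - log_fact(n)

    def table_logp(cells: np.ndarray) -> float:
        return const - sum(log_fact(int(c)) for c in cells.flat)

    p_obs = table_logp(table)
    total = 0.0
    r, c = table.shape

    def recurse(row: int, remaining_cols: np.ndarray, cells: list[list[int]]) -> None:
        nonlocal total
        if row == r - 1:
            last = remaining_cols
            if last.min() < 0:
                return
            full = np.array(cells + [list(last)])
            lp = table_logp(full)
            if lp <= p_obs + 1e-9:
                total += math.exp(lp)
            return
        target = row_sums[row]

        def fill(col: int, left: int, current: list[int]) -> None:
            if col == c - 1:
                if 0 <= left <= remaining_cols[col]:
                    recurse(row + 1, remaining_cols - np.array(current + [left]), cells + [current + [left]])
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, current + [v])

        fill(0, int(target), [])

    recurse(0, col_sums.copy(), [])
    return float(min(1.0, total))
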