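"""File-level I/O: loaders and writers binding the pipeline to on-disk
formats (GTF, FASTA, VCF, MAF-like TSV, evidence TSV, count tables, BED).

Locus keys serialise as ``gene|intron|k`` and ``gene|skip|left|right``;
count tables are long-format TSVs (sample, locus, normal, abnormal).
All on-disk coordinates are 1-based (VCF/GTF convention); conversion to the
internal 0-based half-open frame happens here.
"""

from __future__ import annotations

import os
from pathlib import Path
import numpy as np
import pandas as pd

from .detection import CohortCounts
from .evidence import read_evidence_table
from .gene_models import VariantRecord, load_gene_models, load_genome_fasta, select_longest_isoform
from .pipeline import PipelineInputs
from .splice_codes import BranchpointAnnotation, MotifSet, load_motif_set

__all__ = [
    "locus_to_str",
    "str_to_locus",
    "write_counts_tsv",
    "load_counts_tsv",
    "load_variants_tsv",
    "load_variants_vcf",
    "load_branchpoints_tsv",
    "write_study",
    "load_inputs",
    "events_bed",
]


def locus_to_str(locus: tuple) -> str:
    return "|".join(str(x) for x in locus)


def str_to_locus(s: str) -> tuple:
    parts = s.split("|")
    gene, kind = parts[0], parts[1]
    if kind == "intron":
        return (gene, "intron", int(parts[2]))
    if kind == "skip":
        return (gene, "skip", int(parts[2]), int(parts[3]))
    raise ValueError(f"unknown locus string {s!r}")


def write_counts_tsv(counts: CohortCounts, path) -> None:
    n_s, n_l = counts.normal_counts.shape
    df = pd.DataFrame(
        {
            "sample": np.repeat(counts.sample_ids, n_l),
            "locus": [locus_to_str(l) for l in counts.loci] * n_s,
            "normal": counts.normal_counts.ravel(),
            "abnormal": counts.abnormal_counts.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_counts_tsv(path) -> CohortCounts:
    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["sample"]))
    loci = [str_to_locus(s) for s in dict.fromkeys(df["locus"])]
    normal = df["normal"].to_numpy().reshape(len(samples), len(loci))
    abnormal = df["abnormal"].to_numpy().reshape(len(samples), len(loci))
    return CohortCounts(samples, loci, normal, abnormal)


def load_variants_tsv(path) -> list[VariantRecord]:
    """MAF-like TSV: chrom, pos (1-based), ref, alt, sample, t_ref_count,
    t_alt_count, callers."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        kind = "SNV" if len(r.ref) == 1 and len(r.alt) == 1 else "deletion"
        out.append(
            VariantRecord(
                chrom=r.chrom,
                pos=int(r.pos) - 1,
                ref_allele=r.ref,
                alt_allele=r.alt,
                kind=kind,
                sample_id=str(r.sample),
                dna_ref_count=int(r.t_ref_count),
                dna_alt_count=int(r.t_alt_count),
                caller_count=int(r.callers),
            )
        )
    return out


def load_variants_vcf(path) -> list[VariantRecord]:
    """VCF v4.x with SAMPLE/TRC/TAC/CALLERS INFO keys (as the simulator
    writes); read through pysam."""
    import pysam

    out = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            info = rec.info
            alt = rec.alts[0]
            kind = "SNV" if len(rec.ref) == 1 and len(alt) == 1 else "deletion"
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    kind=kind,
                    sample_id=str(info.get("SAMPLE", "NA")),
                    dna_ref_count=int(info.get("TRC", 0)),
                    dna_alt_count=int(info.get("TAC", 0)),
                    caller_count=int(info.get("CALLERS", 2)),
                )
            )
    return out


def load_branchpoints_tsv(path) -> dict[str, list[BranchpointAnnotation]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[BranchpointAnnotation]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_id, []).append(
            BranchpointAnnotation(chrom=r.chrom, pos=int(r.pos) - 1, source=str(r.source))
        )
    return out


def write_study(study, outdir) -> Path:
    """Serialise a simulated study to the file formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genome.fa").write_text(study.genome.to_fasta())
    (out / "genes.gtf").write_text(study.genome.to_gtf())
    (out / "variants.vcf").write_text(study.to_vcf())
    study.variant_table().to_csv(out / "variants.tsv", sep="\t", index=False)
    (out / "evidence.tsv").write_text(study.evidence_tsv())
    write_counts_tsv(study.normal_counts, out / "normal_counts.tsv")
    write_counts_tsv(study.cancer_counts, out / "cancer_counts.tsv")
    (out / "branchpoints.tsv").write_text(study.genome.branchpoint_table())
    (out / "enhancers.txt").write_text("\n".join(sorted(study.genome.enhancers.hexamers)) + "\n")
    (out / "silencers.txt").write_text("\n".join(sorted(study.genome.silencers.hexamers)) + "\n")
    study.expression.to_csv(out / "expression.tsv", sep="\t")
    study.truth_table().to_csv(out / "truth_ledger.tsv", sep="\t", index=False)
    qc = pd.DataFrame(
        {
            "sample": list(study.novel_junction_fraction),
            "novel_junction_fraction": list(study.novel_junction_fraction.values()),
            "cancer_type": [study.sample_types[s] for s in study.novel_junction_fraction],
            "splicing_factor_flag": [
                s in study.splicing_factor_flagged for s in study.novel_junction_fraction
            ],
        }
    )
    qc.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    flags = pd.DataFrame(
        [{"gene": g, "sample": s} for g, ss in study.gene_flags.items() for s in sorted(ss)]
    )
    flags.to_csv(out / "gene_flags.tsv", sep="\t", index=False)
    return out


def load_inputs(indir) -> tuple[PipelineInputs, MotifSet, MotifSet]:
    """Reassemble :class:`PipelineInputs` from a study directory."""
    ind = Path(indir)
    genome = load_genome_fasta(str(ind / "genome.fa"))
    models = load_gene_models(str(ind / "genes.gtf"))
    by_gene: dict[str, list] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    transcripts = {g: select_longest_isoform(ts) for g, ts in by_gene.items()}

    variants = load_variants_tsv(ind / "variants.tsv")
    observations = read_evidence_table(ind / "evidence.tsv")
    evidence: dict[tuple[str, str], list] = {}
    for obs in observations:
        evidence.setdefault((obs.sample_id, obs.gene_id), []).append(obs)

    qc = pd.read_csv(ind / "sample_qc.tsv", sep="\t")
    flags_df = (
        pd.read_csv(ind / "gene_flags.tsv", sep="\t")
        if (ind / "gene_flags.tsv").stat().st_size > 1
        else pd.DataFrame(columns=["gene", "sample"])
    )
    gene_flags: dict[str, set[str]] = {}
    for r in flags_df.itertuples():
        gene_flags.setdefault(r.gene, set()).add(r.sample)

    inputs = PipelineInputs(
        transcripts=transcripts,
        genome=genome,
        variants=variants,
        evidence=evidence,
        normal_counts=load_counts_tsv(ind / "normal_counts.tsv"),
        cancer_counts=load_counts_tsv(ind / "cancer_counts.tsv"),
        gene_flags=gene_flags,
        branchpoints=load_branchpoints_tsv(ind / "branchpoints.tsv"),
        sample_types=dict(zip(qc["sample"], qc["cancer_type"])),
        novel_junction_fraction=dict(zip(qc["sample"], qc["novel_junction_fraction"])),
        splicing_factor_flagged=set(qc.loc[qc["splicing_factor_flag"], "sample"]),
    )
    enhancers = load_motif_set(str(ind / "enhancers.txt"), "enhancers", "enhancer")
    silencers = load_motif_set(str(ind / "silencers.txt"), "silencers", "silencer")
    return inputs, enhancers, silencers


def events_bed(records, transcripts) -> str:
    """BED of pseudoexons and retained segments of passed calls."""
    lines = []
    for rec in records:
        if not rec.passed or rec.event is None:
            continue
        t = transcripts[rec.gene_id]
        for form in rec.event.forms:
            interval = None
            name = None
            if form.pseudoexon is not None:
                interval, name = form.pseudoexon, "pseudoexon"
            elif form.event_type == "partial_intron_retention" and rec.event.locus[0] == "intron":
                k = rec.event.locus[1]
                lo, hi = min(t.introns[k]), max(t.introns[k])
                site = form.cryptic_acceptor if form.cryptic_acceptor is not None else form.cryptic_donor
                if site is None:
                    continue
                donor_left = t.strand == "+"
                if form.cryptic_acceptor is not None:
                    interval = (site, hi) if donor_left else (lo, site)
                else:
                    interval = (lo, site) if donor_left else (site, hi)
                name = "retained_segment"
            elif form.event_type == "full_intron_retention" and rec.event.locus[0] == "intron":
                k = rec.event.locus[1]
                interval = (min(t.introns[k]), max(t.introns[k]))
                name = "retained_intron"
            if interval is not None:
                lines.append(
                    f"{t.chrom}\t{interval[0]}\t{interval[1]}\t{name}|{rec.gene_id}|{rec.variant.sample_id}\t{form.count}\t{t.strand}"
                )
    return "\n".join(lines) + ("\n" if lines else "")
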