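"""Shared fixtures: toy transcripts, a toy genome, and a small simulated
study reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from missplice.gene_models import GenomeSequence, TranscriptModel, VariantRecord
from missplice.pipeline import train_strength_models
from missplice.simulate import MAJOR_CLASSES, SimulationConfig, generate_genome, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plus_transcript() -> TranscriptModel:
    """Three-exon plus-strand transcript: exons 100-200, 300-400, 500-600."""
    return TranscriptModel(
        transcript_id="t_plus",
        gene_id="g_plus",
        chrom="chrT",
        strand="+",
        exons=((100, 200), (300, 400), (500, 600)),
        cds_start=130,
        cds_end=570,
    )


@pytest.fixture(scope="session")
def minus_transcript() -> TranscriptModel:
    """Mirror image of ``plus_transcript`` on the minus strand."""
    return TranscriptModel(
        transcript_id="t_minus",
        gene_id="g_minus",
        chrom="chrT",
        strand="-",
        exons=((500, 600), (300, 400), (100, 200)),
        cds_start=130,
        cds_end=570,
    )


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    rng = np.random.default_rng(12345)
    seq = "".join(rng.choice(list("ACGT"), size=800))
    return GenomeSequence({"chrT": seq})


def make_variant(pos: int, ref="A", alt="G", sample="S1", **kw) -> VariantRecord:
    defaults = dict(
        chrom="chrT", pos=pos, ref_allele=ref, alt_allele=alt, kind="SNV",
        sample_id=sample, dna_ref_count=10, dna_alt_count=10, caller_count=2,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(SimulationConfig(n_genes=12), seed=421)


@pytest.fixture(scope="session")
def strength_models(small_genome):
    return train_strength_models(small_genome.genome, small_genome.transcripts)


@pytest.fixture(scope="session")
def recovery_study():
    """A compact cohort with two mutations per major class."""
    cfg = SimulationConfig(n_genes=20, effect_low=0.25, coverage_floor=30)
    return simulate_study(cfg, {c: 2 for c in MAJOR_CLASSES}, seed=90)
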