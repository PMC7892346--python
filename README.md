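# missplice

Somatic mutations inside introns can silently break a gene: a single base
change at a donor splice site, in the polypyrimidine tract, at the
branchpoint, or deep inside an intron (creating a cryptic splice site or
altering an enhancer/silencer hexamer) can cause intron retention, exon
skipping, or pseudoexon inclusion — often introducing a premature
termination codon that routes the transcript into nonsense-mediated decay.
`missplice` implements an end-to-end pipeline for detecting and
characterising such mutations from paired DNA variant calls and RNA
junction-read evidence, aimed at computational cancer-genomics groups who
want the full statistical machinery without terabyte-scale cohort data:
every stage is exercised against synthetic cohorts with known ground truth.

## The method

For a candidate (variant, splicing event) pair the statistic is the
abnormal-read ratio

```
r = abnormal / (abnormal + normal)        (both read classes >= 3)
```

compared against two per-locus empirical background distributions — one
from a normal-tissue cohort and one from cancer samples without non-silent
lesions in the gene, each requiring more than 500 contributing samples with
>= 3 normally spliced reads. The observed ratio is z-scored against each
cohort, `P = max` of the two right-tailed normal tail probabilities, and a
call passes when `r` exceeds the empirical 99th percentile of **both**
cohorts and its Benjamini–Hochberg FDR is below 0.1. Eligibility is
restricted to variants within 30 bp of an authentic junction or activated
cryptic splice site; deep intronic variants additionally require a
branchpoint window (−5..+3) or cryptic-site flank. Calls are validated by
allele specificity (odds ratio of the DNA vs RNA × ref vs alt 2×2 table;
OR > 1 on cryptic-site reads = variant-specific splicing), full intron
retention is confirmed purely at the allele level, and variants the ratio
criteria excluded can be rescued when ≥3 variant-allele abnormal reads make
up >80% of the informative abnormal reads within 100 bp of a cryptic site.

Downstream, the package quantifies splice-code changes (position log-odds
donor/acceptor strength over the −3..+6 / −20..+3 windows, U2 snRNA duplex
energy over the branchpoint ±(−5..+3) context, enhancer/silencer hexamer
matching of the ±5 bp flank), classifies premature stops by the 250 nt /
55 nt NMD rule, runs permutation enrichment tests, and trains three
one-class SVMs (linear kernel, ν = 0.05) on strength-difference features
(5′MUT−5′WT, 5′MUT−3′WT and the acceptor analogue) to predict mis-splicing
SNVs from sequence alone.

## Worked example

Simulate a 50-gene cohort (600 normal + 600 cancer samples, 10 mutations
per major class) and run the full analysis:

```bash
missplice all --outdir runs/demo --seed 11
```

prints (abridged):

```json
{
  "n_variants": 250,
  "n_passed": 47,
  "event_types": {
    "partial_intron_retention": 19,
    "full_exon_skipping": 9,
    "full_intron_retention": 9,
    "pseudoexon_activation": 9,
    "combinatorial": 1
  },
  "nmd_classes": {"sensitive": 37, "insensitive": 1, "none": 9},
  "expression_group_p": 5.3e-05,
  "burden_genes_above_5pct": 2
}
```

Of the 250 input variants (50 injected + 200 deep-intronic passengers), 47
of the 50 injected mutations pass the ratio and allele gates; their typed
events match the injected mechanisms (retention for donor loss, skipping
for PPT loss, partial retention through the cryptic acceptor for
branchpoint loss, pseudoexons for cryptic-donor gain). 37 calls introduce
an NMD-sensitive premature stop, and those carriers show significantly
lower expression than controls (rank-sum p ≈ 5×10⁻⁵). Per-stage tables
(`calls.tsv`, `splice_codes.tsv`, `ptc_nmd.tsv`, `events.bed`, …) land in
`runs/demo/results/`.

The same stages are available as library functions
(`missplice.pipeline.detect_missplicing`, `rescue_stage`,
`characterize_calls`, `enrichment_tests`, `ptc_nmd_table`,
`prediction_stage`) operating on in-memory objects.

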