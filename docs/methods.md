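# Methods

This note records the model, the numerical conventions, the synthetic
cohorts the tests run on, and the design choices made where the procedure
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frame and gene models

All internal coordinates are 0-based, half-open; GTF and VCF input/output
is 1-based per those standards, converted only at the I/O boundary.
Exons of a `TranscriptModel` are stored 5′→3′ in transcript orientation.
Intronic positions are numbered from the first intron base on either side
(+1 immediately 3′ of the donor; +1 immediately 5′ of the acceptor), exonic
positions from the junction-adjacent base (−1); a `side` field (donor /
acceptor) disambiguates the two axes. Positions 1–2 bp into the intron are
splice-site, 3–20 bp proximal, >20 bp deep intronic; the 2/3 and 20/21
boundaries are exact. When a position is equidistant from both junctions
of an intron the donor side wins (documented tie-break). Deletions are
located by their 5′-most deleted base. Among isoforms of a gene the one
with the greatest summed exon length is analysed; equal lengths break to
the lexicographically smallest transcript id.

## Read evidence

Raw alignments are out of scope: the pipeline consumes per-read evidence
records (junctions spanned, or the span of an unspliced read, plus the
base observed at a variant position with its quality). A junction read is
normal iff every junction it spans is annotated; an unspliced read is
intron-retention evidence when it covers an exon–intron boundary by at
least 5 bp on both sides (or lies wholly inside an intron, assigned to that
intron); unspliced reads inside the exon body are uninformative. RNA
allele counts use bases with quality ≥ 30; lower-quality or third-allele
observations are tallied separately and enter no numerator or denominator.

## Event typing

Loci are introns (retention, cryptic sites, pseudoexons) or novel
annotated-to-annotated junction pairs (skipping). Geometry rules: a novel
junction from an annotated boundary to a position inside the same intron is
partial intron retention, the intra-intron coordinate being the cryptic
site (donor or acceptor depending on which side of the intron it replaces);
a cryptic acceptor and cryptic donor in transcript order bound a pseudoexon
(both flanks must be read-supported; one-sided intra-intron splices are
flagged, not typed as pseudoexons); an annotated pair spanning whole exons
is full skipping; a junction ending inside an exon is partial skipping;
boundary-covering unspliced reads are full-retention evidence. Retained
segments and pseudoexons shorter than 10 bp are treated as alignment
artefacts and dropped.

Multiple forms of the *same* type at one locus (e.g. two cryptic acceptors)
remain one event with several forms — the highest-count form is primary —
whereas two or more distinct aberration types make the event combinatorial.
Because the exact per-event read-counting rules of the original procedure
are not public, the reconstruction here is deliberately centralised: the
locus ratio uses all abnormal reads at the locus over abnormal + annotated
junction reads (for skip loci, the summed inclusion-junction reads of both
flanking introns), and forms below the global 3-read floor do not change
the event type. Cryptic donors must read GT in the reference or become GT
through the variant (canonically GC→GT); cryptic acceptors must be
preceded by AG; violations raise an audit flag rather than an exception.

## Detection statistics

Backgrounds: per locus, one ratio per sample with ≥ 3 normally spliced
reads, separately for the normal cohort and for cancer samples without
non-silent-lesion flags in the gene; both cohorts must exceed 500 samples.
Means and SDs use the population (ddof = 0) estimator. The two z-scores
give two right-tailed normal Ps; the single reported P is the larger
(conservative) — the published procedure shows two distributions but one P,
so this is a documented reconstruction. Top-1% flags use the empirical
99th percentile (NumPy's default linear/type-7 quantile), not a parametric
fit. FDR is Benjamini–Hochberg over all eligible tests of a run; a call
passes iff both top-1% flags are set and q < 0.1. The "additional variants
nearby" confounder window is 50 bp (configurable; the original definition
is not public). Full intron retention bypasses the ratio gates entirely:
intronic variants confirm via OR > 1, ≥ 3 variant-allele retention reads
and > 80% variant-allele fraction; exonic variants via a Fisher exact test
on (spliced, unspliced) × (ref, alt) with a run-level q < 0.1 gate.

The Fisher exact test is two-sided by the probability-mass rule (summing
hypergeometric probabilities not exceeding the observed table's, with the
customary 1 + 1e-7 relative tie tolerance). Odds ratios use extended
values — b·c = 0 < a·d gives +∞, a·d = 0 < b·c gives 0, both zero is
undefined (inconclusive) — because the verdicts only need the comparison
with 1, never a magnitude, so no continuity correction is applied.

Allele-level rescue reconsiders variants excluded for distance (> 30 bp
from a cryptic site, up to 100 bp) or for insufficient counts: ≥ 3
variant-allele abnormal reads making up > 80% of the allele-informative
abnormal reads. The fraction's denominator is quality-filtered
(ref + alt at q ≥ 30), consistent with the RNA allele-frequency convention
above.

## Splice-code models

The default donor/acceptor strength scorer is a per-position probability
model with add-one smoothing, trained on the authentic junction windows of
the supplied gene models (donor: 3 exonic + 6 intronic; acceptor: 20
intronic + 3 exonic), scored as summed log2 odds against a uniform
background. Externally derived tables (e.g. maximum-entropy scores
exported per position) load through the same interface from a TSV of
per-position probabilities, so the scorer is pluggable; note the default
model is positionally independent, which true maximum-entropy models are
not — only score *differences* between alleles are used downstream, where
this matters least. The polypyrimidine-tract question (whether "PPT
strength" is the acceptor 23-mer score or pyrimidine content) is left open
by exposing both: the 23-mer score is the primary metric and
`pyrimidine_fraction` (+4..+20) is the companion.

U2 duplex energies pair the 8-nt branchpoint context (−5..+3, BP base
excluded) antiparallel against GUGUAGUA. The bundled stack table is a
stand-in: Watson–Crick/Watson–Crick stacks −2.1, mixed −1.4, wobble/wobble
−0.8, +1.0 per unpaired position. Only signs and orderings of ΔΔG are
asserted anywhere; the perfect reverse complement is provably the unique
global minimum under this table and every single substitution of it raises
the energy. T and U spellings are equivalent. Branchpoint assignment
applies to intronic variants 15–60 bp from the acceptor; the nearest
annotated BP wins, equidistant BPs breaking to the lower genomic
coordinate.

Motif scanning tests all six hexamer frames of the ±5 bp 11-mer for each
allele; in enrichment counting a sequence counts once per set no matter how
many hexamers match, and identical 11-mers are de-duplicated before
counting.

## Permutation enrichment

P is the proportion of permutations whose hit count reaches the observed
count; a zero numerator is reported as the upper bound 1/n so P stays in
(0, 1]. Draws are without replacement from the SNV universe. For plain
indicator predicates the per-draw hit count of such a draw is exactly
hypergeometric, so the implementation samples that count law directly (a
variance-identical shortcut, not an approximation); the materialised
permutation path is used whenever unique-sequence de-duplication applies.
An exact mode enumerates all subsets for small universes (used by the
worked 4-SNV example, whose P is exactly 1/2).

## PTC and NMD

The aberrant mature mRNA of the highest-ratio form is reconstructed by
editing the spliced-out intervals, translated from the annotated start; the
first in-frame stop upstream of the annotated stop is the PTC, measured in
CDS nucleotides of the aberrant transcript (the PTC exists only there, so
the 250 nt window is measured in that frame). UTR-only events and
non-coding transcripts are not classified; combinatorial events whose forms
disagree on the PTC/NMD outcome are excluded as inconsistent. A PTC is
NMD-insensitive within the first 250 CDS nt or at/after 55 nt upstream of
the last exon–exon junction of the aberrant transcript; transcripts with no
junction cannot assemble an exon-junction complex and are insensitive.
Expression effects use the mean of ≥ 5 wild-type same-cancer-type controls;
classes are compared by a two-sided Mann–Whitney U test.

## One-class prediction models

Three linear-kernel one-class SVMs (ν = 0.05) cover donor intronic
(+3..+6), donor exonic (−2..−1) and acceptor intronic (+3) SNVs, with the
feature pairs (5′MUT−5′WT, 5′MUT−3′WT) and, for the acceptor model,
(3′MUT−3′WT, 3′MUT−5′WT). "Accuracy" of a one-class cross-validation is
defined as the held-out inlier rate (sensitivity) — the only label a
one-class setting provides — reported over folds × iterations, with both
the across-folds and across-iteration-means SDs available (they share the
same mean). Features are divided by their per-feature training RMS,
recorded with the model, and **not** centred: the linear one-class boundary
separates the data from the origin, so mean-centring places the training
cloud exactly on the boundary and collapses the model (training inlier
fraction ≈ 0.4 instead of the ν-bound ≈ 0.95 in our measurements); RMS
scaling leaves the cloud's offset from the origin intact and makes
predictions exactly equivariant under joint feature rescaling. The
comparator model is trained on the same number of random substitutions at
the same positions and cross-validated identically.

Two numerical caveats of the solver are deliberate rather than patched.
First, the origin-separating geometry is what carries the discrimination:
random-substitution feature clouds straddle the origin, for which no
separating offset is stable, and their cross-validated held-out inlier rate
collapses well below 1 − ν — replacing the solver's offset with the exact
conditional optimum (the ν-quantile of the projections) would "repair" both
models into ≈ 95% held-out accuracy and erase the contrast the comparator
exists to measure, so the solver is used with library defaults (only ν
set). Second, on nearly collinear training draws the SMO offset can
under-converge: the weight direction stabilises long before the offset, and
the empirical training inlier fraction can then dip a few points below the
1 − ν bound (we have observed ≈ 0.85 on adversarial draws versus 0.95–0.98
typically); this is reported as-is.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces multi-exon genes (default five exons; internal
junctions codon-aligned so skip events are frame-preserving) with
consensus-bearing donors (MAG|GTRAGT-like position law), acceptors
(pyrimidine-rich tract, fixed AG), and a branchpoint adenosine in a perfect
U2-complementary context 18–40 bp upstream of each acceptor. The middle
introns carry inert cassettes — a decoy pseudoexon (own AG/PPT acceptor
context, a body containing a stop codon in every frame, a planted silencer
hexamer and a one-mismatch enhancer site, and a decoy donor with a weak −1
and a pre-existing GT, plus a second GC-context donor for the GC→GT class)
and a cryptic AG near the branchpoint — so that every mutation class of the
ground-truth taxonomy (donor/acceptor/PPT/BP disruption, cryptic
donor/acceptor/PPT gain, enhancer gain, silencer loss, neutral) is
injectable as a single-base edit with a defined intended event.

Cohort defaults are the study conditions: 600 normal + 600 cancer samples
(satisfying the > 500 minimum), per-locus abnormal-read fraction
Beta(1, 99) (mean 1%), spliced coverage Poisson(mean 40; doubled at
two-junction skip loci), injected ratios Uniform(0.15, 0.6), allele-linkage
fidelity 1.0, DNA depth Poisson(60) at VAF 0.45, 5% of cancer samples
flagged per gene for non-silent lesions, base qualities mostly ≥ 30 (≈ 87%),
and NMD-sensitive carriers' expression multiplied by 0.5. Background
cohorts are emitted as per-sample count tables — a lossless summary for
ratio statistics — while mutation carriers get per-read evidence including
background-level noise reads, so allele-level rules run on realistic input.
Parameter-recovery runs raise the injected-ratio floor to 0.2 and the
event-locus coverage floor to 30 reads (the conditions those checks are
defined at); null-calibration runs use cohorts whose only variants are
neutral deep-intronic controls.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: base-level sequencing error and mapping artefacts
(evidence is junction-level), isoform mixtures and alternative promoters,
mutation signatures, tumour purity and subclonality, expression covariance
between genes, and heavy-tailed or batch-structured backgrounds (a
heavier-tailed Beta can be configured for robustness experiments). The
synthetic enhancer/silencer hexamer sets are random disjoint draws standing
in for published catalogues, which are consumed as plain one-per-line lists
when available.

## Problem sizes and numerical choices in the checks

Null calibration uses 20 replicate 50-gene wild-type cohorts; the
false-gate rate is reported as the mean over replicates (per-replicate
values fluctuate binomially around ~1%). Parameter recovery injects 50
mutations, ten per major class (donor, PPT and BP disruption; cryptic donor
and acceptor gain). Permutation calibration draws 500 of 2000 with a
50% hit rate so the discrete P takes fine-grained values (coarser designs
make a Kolmogorov–Smirnov uniformity check ill-posed regardless of
implementation). One-class models are evaluated at 3 folds × 100
iterations on 150 feature vectors. The Fisher oracle sweep covers all 2×2
tables with margins ≤ 15 in the suite (≤ 12 in the acceptance script).
All randomness flows from explicit seeds; reruns are bit-reproducible.

## Known limitations

Minus-strand genes are fully supported by the coordinate and window
machinery (mirror-image properties are tested) but the generator emits
plus-strand genes only. Per-cancer-type stratified backgrounds are off by
default (the procedure pools cohorts). The exact-vs-sampled permutation
switch is by explicit flag, not automatic. The exact r×c contingency
utility enumerates tables and is only practical for small counts; its
sidedness for r×c tables is reported as the symmetric probability-mass P
since no unique one-sided ordering exists.
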