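# Methods

## The problem

Selenocysteine (Sec), the 21st amino acid, is inserted co-translationally
at dedicated UGA codons. The Sec-specific tRNA (tRNA-Sec, *selC*) is the
central marker of the trait: it is present essentially iff a genome
encodes selenoproteins. General tRNA finders handle it poorly because its
cloverleaf is non-canonical: it is the longest tRNA (90–101 nt), its
acceptor and T stems stack into a 13-bp AT-stem (9/4 in eukaryotes and
archaea, 8/5 in bacteria, vs 7/5 ≙ 12 bp in canonical tRNAs), its D-stem
is long (6 bp; 7 bp in archaea) with a short 4-nt D-loop, and it carries
a long variable arm. `secscan` detects tRNA-Sec genes with
domain-specific covariance models of exactly these architectures.

## Covariance models

A covariance model here is a profile stochastic context-free grammar
derived deterministically from a structurally annotated seed alignment.
The guide tree has pair-match nodes (MATP) for consensus base pairs,
single-strand nodes (MATL/MATR), bifurcations (BIF/BEGL/BEGR) where the
multiloop branches, and ROOT/END. States per node follow the usual
profile-SCFG layout: MP/ML/MR/D plus IL/IR inserts for pair nodes, ML/D
plus IL for left nodes, etc.

**Match columns.** A column is a match column when fewer than 50% of seed
rows are gaps (the common profile-construction rule; the bundled seeds
are gap-free, so every column is a match column and the consensus length
equals the alignment length).

**Emissions.** Match emissions are (counts + pseudocount) normalised;
the default emission pseudocount is Laplace +1. Scores are log₂-odds
bits against a uniform iid null (0.25 per nucleotide; pair null =
product of singlet nulls). Insert states emit at the null distribution
(0 bits). `N` emits at null odds (0 bits) in every context; T and U are
identical.

**Transitions.** Transition probabilities are (counts + pseudocount ×
prior weight) normalised, where the structured prior weights are 1.0 for
continuation targets (match/begin/end states), 0.02 for insert states and
0.03 for delete states — ML/MR of a *pair* node are half-deletions and
share the delete weight. A flat Laplace prior was rejected because with
small, gap-free seeds it makes indel paths so probable that model-sampled
sequences average several indels (breaking the expected 90–101 nt length
band) and makes deletions adjacent to untrained insert states cheaper
than emitting a merely unusual base.

**Intron accommodation.** Eukaryotic tRNA introns interrupt the
anticodon loop one base 3' of the anticodon (between positions 37
and 38). At exactly that insert state the transition scores are floored
(entry ≥ −2 bits, extension ≥ −0.25 bits/base) so that intron-containing
genes remain parseable in one pass; everywhere else insertions remain
expensive. Because the floor applies to scores only, sampling uses the
underlying (uncapped) probabilities.

**Position numbering.** Match columns carry standard-style tRNA position
labels with letter-suffixed inserts. Two anchoring choices matter
downstream: the anticodon occupies labels 34–36 (U33 immediately 5' of
it, G18/G19 in the D-loop), and label 61 is defined as the **last T-loop
column**, i.e. the column immediately 5' of the T-stem's 3' strand. With
a 13-bp AT-stem the discriminator base (position 73) — deliberately not
a model column — is then exactly the 14th residue 3' of the position-61
residue. Placing 61 on the first T-stem 3' column instead would make the
fixed offset 13 and is inconsistent with the 14-residue rule this
package implements.

## Scanning

Scoring is maximum-score (CYK-style) dynamic programming over the state
tables, vectorised in numpy over (start, span) with float32 tables.
Alignment is glocal: global in the model (no local begins/ends or
truncated alignments), local in the genome. Every start position on both
strands is evaluated with span band W = consensus length + 30; per start
only the best span is kept, and every hit at or above the threshold
(default T = 40 bits) is reported. Long contigs are processed in 4-kb
chunks with one window of overlap, which is exact because no parse
exceeds W.

Two bandings keep the scan tractable; both are exact for any parse with
a realistic indel load and only affect parses scoring far below any
threshold: (i) each state's span axis is capped at its subtree's
consensus span + 45 (enough for a 25-nt intron plus slack), and (ii) the
bifurcation split point is restricted to ±25 of the left subtree's
consensus span.

Overlapping same-strand hits (≥1 shared nucleotide) are collapsed,
keeping the highest bit score; ties break by longer interval, then
domain preference (eukaryota, bacteria, archaea), then leftmost start.
The surviving hit's model supplies the domain label. Thresholding happens
before overlap resolution.

## Annotation and filtering

Realized stem pair counts are the MP states in the hit's parse; the fold
label is (A-stem, T-stem) realized pairs: 9/4, 8/5, 7/5, else "other".
The anticodon is the residues aligned to positions 34–36 (undefined if
any is deleted); non-UCA (including undefined) candidates must clear the
stringent threshold (55 bits). The arm-completeness filter requires each
stem to realize at least (consensus pairs − 2), with the V-stem minimum
fixed at 2; these minima are declared defaults, configurable per run.

The discriminator is read **from the genome**, not from the alignment:
the residue aligned to position 61 is located, and the residue 14
positions 3' of it (in hit orientation) is reported — undefined when the
contig ends first. For the rare bacterial 12-bp AT-stem (7/5) variants
this fixed offset knowingly lands one residue 3' of the structural
discriminator; such candidates are flagged (`discriminator_flagged`).
The CCA check reads the three residues immediately 3' of the
discriminator. Intron calls require an insertion of ≥8 nt (default;
eukaryotic tRNA introns are ~14–60 nt) starting one base 3' of the
anticodon; the mature sequence splices it out.

Extra gene copies are classified against the top-scoring candidate:
*identical* = exact sequence match including 100 nt of flanking genomic
context (clamped at contig edges); per consensus pair, *disruptive* =
the pair forms (WC/GU) in exactly one of the two candidates (this
definition is role-symmetric; a deleted partner counts as broken),
*compensatory* = both candidates pair but both partners differ; overall
disrupted ≻ compensatory ≻ equivalent.

## Model training

`filter_training` keeps sequences that score ≥ 0 bits on the bootstrap
model (a structural-plausibility stand-in for an external tRNA
pre-filter) and whose anticodon is UCA. `iterative_align` alternates
aligning all sequences to the current model with rebuilding the model
from the induced alignment, until the alignment is bit-identical between
iterations (convergence) or max_iter is reached; if an iteration lowers
the summed training score the previous model is returned with a warning,
so the returned total is non-decreasing. Folding is maximum base pairing
(Nussinov-style, WC+GU, minimum hairpin loop 3, deterministic 5'-most
tie-break), with a documented adapter point for an external
thermodynamic folder.

## Benchmark harness

Because Sec is not universal, tRNA-Sec admits a genome-level benchmark:
sensitivity = fraction of Sec-positive genomes with ≥1 prediction,
specificity = fraction of Sec-negative genomes with none, plus mean
predictions per genome (N+/N−). Percentages are rounded half-up to one
decimal; an empty class reports NA. The harness consumes a neutral
per-genome prediction TSV so any predictor can be scored. Column
conservation is the modal non-gap residue frequency per column,
partitioned into consensus-paired vs unpaired columns.

## ORF screen

Annotated CDS are extended in frame: 3' through consecutive in-frame TGA
to the first TAA/TAG, 5' to the first upstream non-TGA stop and then
forward to the furthest-upstream start codon (ATG/GTG/TTG, bacterial
table 11); TGA is passed through in both directions. ORFs without
in-frame TGA are dropped; TGA translates as U. Homology evidence is
Smith–Waterman local alignment (Biopython PairwiseAligner, BLOSUM62,
gap open −11 / extend −1, minimum report score 40) with U scored as C;
an ORF whose TGA aligns to Cys in ≥3 distinct subjects is a selenoprotein
candidate.

## Synthetic data

The generator defines the study conditions. The four bundled seeds (one
per domain plus a canonical 7/5 decoy) are deterministic, gap-free
32-row alignments around hand-designed templates with the architectures
above; rows carry two compensatory pair swaps and one loop substitution
each, away from the invariant positions (G18/G19, U33, UCA). This depth
and divergence give sharply-trained models whose error-free samples
score ~90–135 bits, comfortably clear of the 40-bit threshold, while
stems keep covariation signal.

Planted genes are *error-free* samples: emissions drawn from the model
along the consensus path (no indels), every stem pair canonical
(mismatched draws redrawn from the pair distribution restricted to
WC/GU cells), anticodon pinned (UCA by default). `sample_trna` remains
the unconstrained joint-distribution sampler. Genomes are iid background
at configurable GC (default 0.5) with non-overlapping planted cassettes;
the discriminator base (default G) and, for bacteria, a genomic CCA tail
follow the gene. Mutation modes: iid substitutions, compensatory pair
rewrites (both partners changed, pairing kept), and disruptive
single-partner breaks — chosen only among positions that currently pair,
so the planted class is recoverable. Truth BED/TSV record coordinates,
strand, type, mutations, intron and the per-item seed; everything is
byte-deterministic under a fixed seed.

What the generator does **not** emulate: repeats, compositional
heterogeneity, sequencing/assembly error, pseudogene decay gradients,
and real cross-domain sequence divergence (the templates are invented).
Passing the synthetic benchmark therefore demonstrates the pipeline's
internal consistency — recovery of exactly what the model family
describes, rejection of canonical-tRNA decoys and iid background — not
sensitivity on real genomes.

## Problem sizes and numerics

Desk-scale defaults used by the test suite and the acceptance script:
synthetic benchmark = 50 positive + 50 negative genomes of 600 bp
(generator seeds 1–50), unit-test genomes 0.6–12 kb, null-control
12 kb, parser-oracle models ≤4 pairs with sequences ≤7 nt (exhaustive
parse-tree enumeration as the reference), folding oracle ≤12 nt
(exhaustive pairing enumeration), alignment oracle ≤20 aa (plain affine
DP). DP tables are float32; traceback re-evaluates candidate children
and takes the first maximum, making parses deterministic. Model JSON
serialisation round-trips scores bit-exactly.

## Known limitations

- Bit scores are internally consistent but not numerically comparable to
  other covariance-model implementations (different priors, weighting,
  null model; no E-value calibration).
- No local/truncated alignment: genes broken across contig ends are
  missed rather than partially reported.
- The span/bifurcation bands above make deeply indel-laden parses
  (>25 net indels on one side of a bifurcation, or >45 inserted
  residues within one subtree) score as missing; such parses cannot
  reach reporting thresholds anyway.
- The discriminator rule assumes a 13-bp AT-stem; 12-bp variants are
  flagged, mirroring the behaviour it reproduces, not corrected.
- Uniform sequence weighting; heavily redundant training sets will bias
  emissions.
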