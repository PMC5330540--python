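# secscan — selenocysteine tRNA (tRNA-Sec) gene finding

`secscan` finds the selenocysteine tRNA (tRNA-Sec, *selC*) in genomic
DNA. tRNA-Sec drives the recoding of specific UGA stop codons to
selenocysteine, and — uniquely among tRNAs — it is present essentially
only in genomes that encode selenoproteins, which makes it the cleanest
genomic marker of the Sec trait. General-purpose tRNA finders handle it
poorly because its structure is non-canonical: it is the longest tRNA
(90–101 nt), with a 13-bp combined acceptor+T stem (the AT-stem: 9/4
fold in eukaryotes and archaea, 8/5 in bacteria, vs the canonical 7/5 =
12 bp), a long 6–7-bp D-stem with a short D-loop, and a long variable
arm.

The package is aimed at genome annotators and selenoprotein researchers.
It provides:

- three domain-specific **covariance models** (profile stochastic
  context-free grammars) built from structurally annotated seed
  alignments that encode exactly these architectures; scores are
  log₂-odds bits against an iid null, maximised by CYK-style dynamic
  programming;
- a **genome scanner** (both strands, every start position, default
  reporting threshold T = 40 bits) with overlap resolution that keeps
  the best-scoring model per locus and thereby assigns the domain;
- **structural annotation** of each candidate: realized arm pair counts
  and fold label, the anticodon (positions 34–36; non-UCA candidates
  must clear a stringent 55-bit threshold), the discriminator base
  (position 73, read from the genome as the 14th residue 3' of the
  position-61 residue; G73 is required for serylation), a genomic CCA
  tail check, C-loop intron detection, extra-copy classification
  (identical / equivalent / compensatory / disrupted), and cloverleaf
  rendering (text + SVG);
- the **iterative model-building** procedure (filter training sequences
  to UCA anticodons, then align–rebuild until the alignment is stable),
- a **genome-level benchmark harness** (sensitivity = Sec-positive
  genomes with ≥1 prediction; specificity = Sec-negative genomes with
  none) that scores any predictor's output,
- a **TGA-readthrough ORF screen** for novel selenoprotein candidates
  (extend annotated genes through in-frame TGA; select ORFs whose TGA
  aligns to Cys in ≥3 homologues), and
- a **synthetic-data generator** that samples genes from the models,
  plants them in background genomes with canonical-tRNA decoys,
  mutations and introns, and emits truth files — so the whole pipeline
  is testable without downloading anything.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate a 1.5-kb genome with one bacterial tRNA-Sec gene planted on the
reverse strand, then scan it:

```bash
cat > spec.yaml <<EOF
seed: 3
contigs: [1500]
planted:
  - kind: bacteria
    strand: "-"
EOF
secscan simulate --spec spec.yaml --out sim
secscan search sim/genome.fa -o out --plot
```

The log (stderr) shows the filtering stages:

```
INFO secscan: raw hits above threshold: 22
INFO secscan: loci after overlap resolution: 1
INFO secscan.annotate: 1 candidates after anticodon thresholds
INFO secscan.annotate: 1 candidates after arm filter
1 tRNA-Sec candidate(s)
```

`out/secscan.gff3` contains the single candidate:

```
contig1  secscan  tRNA  1141  1231  115.01  -  .  ID=trnasec1;domain_model=bacteria;anticodon=UCA;discriminator=G;g73=true;cca=true;fold=8/5
```

Reading the attributes: the locus at contig1:1141–1231 (reverse strand)
scored 115.01 bits, best explained by the bacterial model; its anticodon
is UCA (complementary to the UGA Sec codon), the discriminator base is a
G (G73, the serylation determinant), the CCA 3' end is genomically
encoded (typical for bacteria), and the fold is 8/5 — a 13-bp AT-stem.
The coordinates match the planted truth record in `sim/truth.bed`
exactly. With `--plot`, each candidate also gets an SVG cloverleaf and a
text diagram (`out/secscan_candidate1.txt`):

```
tRNA-Sec candidate contig1:1141-1231(-)  score=115.0 bits  model=bacteria
Acceptor   5' GGACGAGC
              ||||||||  [8 bp]
           3' CCUGCUCG
...
anticodon (UCA)  fold 8/5  AT-stem 13 bp
discriminator (G) at 1140  CCA tail: yes
```

Other subcommands: `secscan build` (model from a Stockholm seed),
`secscan iterate` (iterative training), `secscan bench` (sensitivity /
specificity tables from label + prediction TSVs), `secscan orfx` (the
TGA-readthrough screen), `secscan plot`.

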