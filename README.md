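# linafunnel

A forward-genetics candidate-gene funnel for bacterial ice nucleation.

Some bacteria catalyze the freezing of supercooled water at temperatures
far above homogeneous nucleation (−38 °C). For the Gram-positive
*Lysinibacillus parviboronicapiens*, ice nucleation activity (INA) rides on
a secreted, non-proteinaceous particle, and the genes behind it can be
found by a three-way squeeze: comparative genomics (genes present only in
the INA-positive clade), transcriptomics (genes expressed under the
INA-inducing condition), and a random-mutagenesis screen (genes hit
recurrently in independent INA-loss mutants). `linafunnel` implements that
inference chain as a tested, reusable pipeline for anyone running a similar
phenotype-to-gene funnel in bacteria, together with a synthetic-data
generator so every step can be validated end to end with planted ground
truth — no sequencing data required.

## What it computes

**Freezing spectra.** From droplet-freezing dilution assays, the cumulative
ice-nucleating-particle concentration per CFU:

    K(Θ) = [ln N₀ − ln N(Θ)] / A

with N₀ droplets per concentration, N(Θ) unfrozen at temperature Θ, and A
CFU per droplet. Replicates are pooled by count summation, dilutions
combined by a droplet-number-weighted mean over the informative range, and
all-frozen points kept as flagged lower bounds. Detection against a water
control (and per-fraction profiling of density gradients) uses a one-sided
exact test at α = 0.05.

**Candidate funnel.** From a Roary-style gene presence/absence matrix, a
count table, and domain-annotated gene models: genes present in all target
genomes and absent everywhere else → of those, genes with TPM > 0 → of
those, core biosynthetic genes under a signature-domain rule (KS domain, or
C+A pair; TE by adjacency; PPTASE/epimerase-dehydratase by proximity within
a 10 kb window), grouped into cluster regions.

**Mutant screen.** Per-mutant VCFs are annotated for coding effect
(bacterial codon table, strand-aware), cleansed of recurrent artifact
substitutions in insertion sequences and short hypothetical genes, and
genes are ranked by the number of distinct complete-loss strains carrying a
candidate-effect variant.

**Synthetic data.** `simulate bundle` emits all of the above formats from a
seeded generator: planted unique clusters among distractors,
negative-binomial expression with planted silent genes, a 5-gene PKS-NRPS
cluster genome (GFF3 + FASTA), UV-mutant VCFs with Poisson(4) background
load and planted causal/artifact variants, and stochastic droplet assays
under the Poisson nucleus-activation model. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Generate the replay bundle (its planted truth mirrors the published study's
stage structure) and run the whole pipeline:

```
linafunnel simulate bundle --config fixtures/in_paper.yaml --seed 1 --out demo/
cat > demo/pipeline.yaml <<EOF
matrix: demo/gene_presence_absence.csv
expression: demo/expression.tsv
gff: demo/genes.gff3
fasta: demo/genome.fasta
vcf_dir: demo/vcf
phenotypes: demo/phenotypes.tsv
assay: demo/assay.csv
target_ids: [VT1065, BAM582]
EOF
linafunnel run-all --config demo/pipeline.yaml --out demo/report.json
```

which prints:

```
linafunnel 0.1.0 report
  funnel unique: 2993
  funnel unique_expressed: 2986
  funnel unique_expressed_bgc_core: 10
  funnel screen_supported: 2
  screen hit VT1065_00008: 5 strains
  screen hit VT1065_00009: 2 strains
  artifacts removed: 6
  INA detectable: UV008, UV009, UV010, VT1065
```

Reading: 2993 genes are unique to the two target genomes; removing the 7
unexpressed ones leaves 2986; 10 of those are core biosynthetic genes; and
exactly 2 of them — the adjacent T1-PKS (`VT1065_00008`) and NRPS
(`VT1065_00009`) — are hit recurrently among the seven complete-loss
mutants (5 and 2 strains respectively), after 6 shared artifact variants in
insertion-sequence genes were removed. The detection calls flag the
wild-type (`VT1065`) and the two reduced-activity mutants (`UV008`,
`UV009`) as INA-positive; the seven complete-loss mutants are negative.
`UV010` is the simulated wild-type sibling strain.

Individual stages are also available as `linafunnel assay spectrum`,
`linafunnel funnel run`, and `linafunnel screen rank`, and the whole
library surface (`linafunnel.assay`, `.funnel`, `.screen`, `.simulate`,
`.io`) can be driven from Python.

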