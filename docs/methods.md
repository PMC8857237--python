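# Methods

This note documents the models, estimators, and design choices behind
`linafunnel`, in the order the pipeline runs them.

## Cumulative freezing spectra from droplet assays

**Model.** A droplet-freezing assay cools arrays of droplets of a dilution
series along a temperature ramp and records cumulative frozen counts. The
cumulative ice-nucleating-particle (INP) concentration per CFU active at or
above temperature Θ is estimated with the classical dilution-series
estimator

    K(Θ) = [ln N₀ − ln N(Θ)] / A

with N₀ droplets per concentration, N(Θ) unfrozen droplets at Θ, and A the
mean CFU per droplet. The estimator assumes ice nuclei are distributed
across droplets as a Poisson process, so the unfrozen fraction at Θ equals
exp(−K(Θ)·A). Frozen counts are cumulative by construction (a frozen droplet
stays frozen), so K is non-decreasing as the temperature falls.

**Protocol defaults.** Six tenfold dilutions from 10⁸ CFU/ml, 20 µl
droplets (so A = 2×10⁶ CFU per droplet at the starting concentration),
30 droplets per concentration, three replicates, a −2 °C … −12 °C ramp in
1 °C steps.

**Censoring.** When every droplet of every informative dilution froze,
ln N(Θ) is undefined. The point is kept as a flagged lower bound by
substituting N(Θ) = 0.5 rather than being dropped: spectra stay plottable
and the flag preserves honesty. Lower bounds legitimately tighten as
droplet numbers grow, so pooling equivalence is exact only at estimated
(uncensored) points.

**Combining dilutions.** Replicates of a dilution are pooled by summing
droplet and frozen counts (droplets are exchangeable across replicates). A
temperature's estimate then combines the informative dilutions
(0 < frozen < pooled N₀) as a droplet-number-weighted mean of their K
values; a `most-dilute` mode instead takes the single most dilute
informative dilution. Because the informative set changes along the ramp
(a dilution saturates and drops out), the combined curve can dip by a
sampling fluctuation where a high-K dilution leaves the set; a final
running maximum restores the monotonicity that each per-dilution curve has
by construction. Per-dilution estimates are never altered.

**Detection calls.** The decision rule behind a "+/−" ice-nucleation call
is a one-sided exact test (Fisher) that the sample's frozen fraction
exceeds the water control's at some temperature, at α = 0.05
(configurable). The same rule profiles density-gradient fractions at one
fixed test temperature against the blank. A single extra frozen droplet
out of 30 is never significant under this rule (p = 0.5), which is the
intended conservatism.

## Pan-genome candidate funnel

**Uniqueness.** A gene cluster is clade-unique when present in *all* target
genomes and absent from *all* non-target genomes; a relaxed mode (present
in ≥1 target) is available behind a flag. Results are reported as the
reference target genome's locus tags, which form the gene-id namespace for
every downstream stage.

**Expression.** Counts are normalized to transcripts per million:
rateᵢ = countᵢ/lengthᵢ, TPMᵢ = 10⁶·rateᵢ/Σrate, which sums to 10⁶ by
construction. The effective length is the annotated CDS length (no
fragment-length correction — read alignment is out of scope). "Expressed"
means TPM strictly above a threshold whose default is 0, i.e. any mapped
read; the threshold is configurable because the boundary between "not
expressed" and "lowly expressed" is a judgement call.

**Biosynthetic-core tagging.** Instead of a full HMM-based cluster
detector, a transparent signature-domain rule stands in, adequate for
presence/absence decisions on annotated domains: a gene is core when it
carries a ketosynthase (KS) domain or a condensation + adenylation (C+A)
pair; thioesterases (TE) are pulled in when an immediate gene-order
neighbour is core; phosphopantetheinyl transferases and
epimerase/dehydratases when within the gap window (default 10 kb) of a core
gene. Dependent classes resolve to a fixed point so chains of support
genes attach. Core genes whose successive gaps are ≤ the window form one
BGC region. The signature table and window are configuration, not code, so
alternative cluster chemistries can be expressed without edits.

**Report.** The funnel emits nested stage sets
(unique ⊇ unique∩expressed ⊇ unique∩expressed∩core ⊇ screen-supported) with
counts and a full parameter echo; nesting is asserted property-style in the
tests for randomized inputs.

## Mutant screen

**Effect annotation.** SNP effects are called at codon level: the
containing CDS is located strand-aware, the affected codon is translated
with the bacterial/archaeal codon table (table 11) before and after the
substitution, giving synonymous / nonsynonymous / nonsense. Indels are
frameshift when the length change is not a multiple of 3, otherwise
in-frame. The unit tests check this codon-level path against an
independent oracle that translates the full mutated CDS and diffs the
proteins, over a thousand random SNPs on both strands.

**Artifact rule.** An identical substitution (same contig, position, ref,
alt) observed in ≥2 strains *and* located in an insertion-sequence or
short-hypothetical gene is treated as a sequencing artifact and removed
from all carriers. The conjunction is deliberate: recurrence alone never
removes a variant (an `or` mode exists for sensitivity analysis), and a
strain-unique variant is never removed under any mode. "Short
hypothetical" means a product containing "hypothetical" with CDS < 300 nt
(threshold configurable; no principled length exists, this one excludes
the spurious mini-ORFs that attract alignment artifacts while keeping real
small genes annotated with a function).

**Recurrence ranking.** Per gene, the number of *distinct* complete-loss
strains carrying at least one candidate-effect variant (nonsynonymous,
nonsense, frameshift, in-frame indel; synonymous and intergenic excluded)
is counted; genes reaching `min_strains` (default 2) are ranked by count,
ties broken lexicographically. Reduced-phenotype strains are excluded by
default — their causal lesions may be regulatory and would dilute the
signal — and can be included with a flag.

## Synthetic-data generator

The generator exists so the full funnel can be exercised with known ground
truth. What it emulates, per input:

- **Pan-genome**: planted clade-unique clusters among four distractor
  classes — core (all genomes), shell (random subsets, never a subset of
  the targets), target-partial (exactly one target), near-unique (targets
  plus exactly one other genome). These distractors are precisely the
  neighbouring presence patterns a buggy uniqueness filter would leak.
- **Expression**: negative-binomial counts (default mean 250, dispersion
  2 — conventional overdispersed RNA-seq behaviour), with the planted
  number of unique genes forced to zero counts and the remaining unique
  genes drawn zero-truncated so the planted expressed set is exact rather
  than approximate.
- **Cluster genome**: one contig carrying the five-gene template (PPTASE,
  EPIM_DH, an intergenic gap, the T1-PKS with KS-AT-DH-KR-ACP, the
  two-module NRPS with C-A-PCP-C-A-PCP, TE), flanking hypothetical genes,
  distant IS elements, and optionally extra distant five-gene KS clusters.
  CDS sequences are random codons without internal stops; locus tags run
  sequentially along the contig.
- **Mutants**: per strain a Poisson(λ = 4) number of background
  candidate-effect variants (80% nonsynonymous SNPs, 20% 1-nt indels,
  placed by rejection sampling); complete-loss strains additionally get
  causal hits split across the PKS and NRPS in the published mix of
  patterns (one or two nonsynonymous SNPs, or a single-nucleotide
  insertion); artifact substitutions are planted identically in ≥2 strains
  inside flagged genes. Background placement for complete-loss strains
  never reuses a gene across strains, so no non-causal gene can reach the
  recurrence threshold by chance in a replay fixture; the Poisson *counts*
  are untouched, only placement is constrained, so load calibration is
  unaffected.
- **Assays**: the Poisson activation model — independent Poisson draws on
  the increments of K(Θ)·A accumulated along the ramp — which is the
  minimal generative model whose void probability exp(−K·A) matches the
  estimator's assumption. The default true spectrum has onset −4 °C,
  K = 10⁻⁷ per CFU at onset, and rises half a decade per degree, reaching
  10⁻³ per CFU at −12 °C, the magnitude range typical of strongly active
  bacterial ice nucleators.

What it does **not** emulate: sequence-level realism (codon usage, GC
skew), multi-contig genomes (readers accept them, the generator emits one
contig), read-level noise (the expression table is counts, not alignments),
variant-caller error models beyond the planted identical artifacts, and
dilution-plating error in A. Passing tests therefore validate the
*inference chain* — filters, estimators, rankings — not robustness to
upstream alignment or calling noise.

**Determinism.** One seeded `numpy` generator drives a bundle end to end;
identical config + seed reproduce byte-identical files (checksum-verified
in the tests). All iteration orders are fixed; no global random state.

## Replay fixture and problem sizes

`fixtures/in_paper.yaml` encodes the published stage structure as data:
2993 unique genes among 19 genomes (1500 core, 800 shell, 120
target-partial, 80 near-unique distractors), exactly 7 unexpressed unique
genes, 10 core biosynthetic genes (the 5-gene template plus one extra
distant cluster), 7 complete-loss mutants split 5/2 across the PKS and
NRPS, 2 reduced mutants, Poisson(4) background, 3 planted artifacts. The
whole bundle generates in ~2 s; the statistical checks use 1000 simulated
strains for mutation-load calibration and 3 × 300-droplet assays for
spectrum recovery, sizes at which the 3-standard-error bands are a few
percent wide.

## Known limitations

- The per-temperature weighted mean across dilutions is not
  variance-optimal; confidence intervals on K are out of scope beyond the
  exact detection test.
- The BGC-core rule only sees annotated domains; genes with missed domain
  annotations are invisible to it, unlike an HMM scan of the sequence.
- Effect annotation handles one variant at a time; compound effects of
  multiple nearby variants in one codon are not composed.
- The exact detection test treats droplets as independent; plate-level
  nucleation artifacts would violate this.
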