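"""Mutant-screen variant annotation, artifact filtering, and recurrence ranking.

After random (UV) mutagenesis, each phenotype-positive mutant carries a
handful of mutations; the causal gene stands out because independent mutants
hit it recurrently.  This module annotates variants for coding effect with
the bacterial codon table, removes putative sequencing artifacts (identical
substitutions shared by several mutants inside insertion sequences or short
hypothetical genes), and ranks genes by the number of distinct
phenotype-positive strains carrying a candidate-effect variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import InputError

__all__ = [
    "VariantCall",
    "GeneModel",
    "MutantRecord",
    "GeneHit",
    "CANDIDATE_EFFECTS",
    "classify_kind",
    "annotate_effect",
    "annotate_all",
    "filter_artifacts",
    "recurrently_hit_genes",
]

#: effect classes that count as potentially function-disrupting
CANDIDATE_EFFECTS = frozenset({"nonsynonymous", "nonsense", "frameshift", "inframe_indel"})

#: the standard bacterial/archaeal translation table
BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]

PHENOTYPES = ("ina_lost", "ina_reduced", "wild_type")

#: genes shorter than this with a hypothetical product are flagged
#: is_short_hypothetical for the artifact rule
SHORT_HYPOTHETICAL_NT = 300


def classify_kind(ref: str, alt: str) -> str:
    """Classify a variant from its allele lengths (snp / insertion / deletion)."""
    if ref == alt:
        raise InputError("ref and alt alleles are identical")
    if len(ref) == len(alt):
        return "snp"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one mutant strain.

    Coordinates are 1-based; insertions/deletions are anchored at the base
    before the inserted/deleted sequence (VCF convention).  ``effect`` and
    ``gene_id`` are filled in by :func:`annotate_effect`.
    """

    strain_id: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str = ""
    effect: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise InputError("ref and alt alleles are identical")
        expected = classify_kind(self.ref_allele, self.alt_allele)
        if self.kind == "":
            object.__setattr__(self, "kind", expected)
        elif self.kind != expected:
            raise InputError(
                f"kind {self.kind!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele} (expected {expected!r})"
            )

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GeneModel:
    """A CDS interval with the flags the artifact rule needs."""

    gene_id: str
    contig: str
    strand: str
    cds_start: int  # 1-based inclusive
    cds_end: int
    product: str = ""
    is_insertion_sequence: bool = False
    is_short_hypothetical: bool = False

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise InputError(f"{self.gene_id}: cds_start > cds_end")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @classmethod
    def with_derived_flags(
        cls,
        gene_id: str,
        contig: str,
        strand: str,
        cds_start: int,
        cds_end: int,
        product: str = "",
        mobile_element: bool = False,
        short_threshold_nt: int = SHORT_HYPOTHETICAL_NT,
    ) -> "GeneModel":
        """Derive the artifact-rule flags from product text and CDS length."""
        length = cds_end - cds_start + 1
        is_is = mobile_element or "insertion sequence" in product.lower() or \
            "transposase" in product.lower()
        is_short_hyp = "hypothetical" in product.lower() and length < short_threshold_nt
        return cls(
            gene_id, contig, strand, cds_start, cds_end, product,
            is_insertion_sequence=is_is, is_short_hypothetical=is_short_hyp,
        )


@dataclass(frozen=True)
class MutantRecord:
    """Phenotype call for one mutant strain."""

    strain_id: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise InputError(
                f"{self.strain_id}: phenotype must be one of {PHENOTYPES}, "
                f"got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class GeneHit:
    """A gene ranked by independent recurrence among phenotype-positive strains."""

    gene_id: str
    n_strains: int
    strains: tuple[str, ...]
    variants: tuple[VariantCall, ...]


def _containing_gene(
    contig: str, pos: int, gene_models: Sequence[GeneModel]
) -> GeneModel | None:
    for g in gene_models:
        if g.contig == contig and g.cds_start <= pos <= g.cds_end:
            return g
    return None


def _translate_codon(codon: str) -> str:
    if codon.upper() in BACTERIAL_TABLE.stop_codons:
        return "*"
    return BACTERIAL_TABLE.forward_table[codon.upper()]


def annotate_effect(
    variant: VariantCall,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> VariantCall:
    """Annotate a variant's coding effect against the gene models.

    SNPs inside a CDS are classified by translating the reference and
    mutated codon (strand-aware, bacterial translation table):
    ``synonymous``, ``nonsynonymous``, or ``nonsense`` (stop gained).
    Indels inside a CDS are ``frameshift`` when the length change is not a
    multiple of 3, else ``inframe_indel``.  Variants outside every CDS are
    ``intergenic``.  Raises if the reference allele disagrees with the
    genome sequence.
    """
    if variant.contig not in genome:
        raise InputError(f"contig {variant.contig!r} absent from genome sequence")
    seq = genome[variant.contig]
    ref = variant.ref_allele
    observed = seq[variant.pos - 1 : variant.pos - 1 + len(ref)]
    if observed.upper() != ref.upper():
        raise InputError(
            f"{variant.strain_id} {variant.contig}:{variant.pos} reference allele "
            f"{ref!r} disagrees with genome sequence {observed!r}"
        )

    gene = _containing_gene(variant.contig, variant.pos, gene_models)
    if gene is None:
        return replace(variant, effect="intergenic", gene_id=None)

    if variant.kind != "snp":
        shift = abs(len(variant.alt_allele) - len(variant.ref_allele))
        effect = "frameshift" if shift % 3 else "inframe_indel"
        return replace(variant, effect=effect, gene_id=gene.gene_id)

    if len(ref) != 1:
        # multi-nucleotide substitution: compare full translations
        cds_ref = seq[gene.cds_start - 1 : gene.cds_end]
        mut_seq = (
            seq[: variant.pos - 1] + variant.alt_allele + seq[variant.pos - 1 + len(ref) :]
        )
        cds_mut = mut_seq[gene.cds_start - 1 : gene.cds_end]
        if gene.strand == "-":
            cds_ref = str(Seq(cds_ref).reverse_complement())
            cds_mut = str(Seq(cds_mut).reverse_complement())
        aa_ref = str(Seq(cds_ref).translate(table=11))
        aa_mut = str(Seq(cds_mut).translate(table=11))
        if aa_ref == aa_mut:
            return replace(variant, effect="synonymous", gene_id=gene.gene_id)
        gained_stop = any(
            b == "*" and a != "*" for a, b in zip(aa_ref, aa_mut)
        )
        effect = "nonsense" if gained_stop else "nonsynonymous"
        return replace(variant, effect=effect, gene_id=gene.gene_id)

    if gene.length % 3 != 0:
        raise InputError(f"{gene.gene_id}: CDS length {gene.length} not divisible by 3")

    if gene.strand == "+":
        offset = variant.pos - gene.cds_start
        codon_start = gene.cds_start + 3 * (offset // 3)
        codon = seq[codon_start - 1 : codon_start + 2]
        within = offset % 3
        mutated = codon[:within] + variant.alt_allele + codon[within + 1 :]
    else:
        offset = gene.cds_end - variant.pos  # position along the coding strand
        codon_start_genomic = gene.cds_end - 3 * (offset // 3) - 2
        codon_fwd = seq[codon_start_genomic - 1 : codon_start_genomic + 2]
        codon = str(Seq(codon_fwd).reverse_complement())
        within = offset % 3
        alt_rc = str(Seq(variant.alt_allele).reverse_complement())
        mutated = codon[:within] + alt_rc + codon[within + 1 :]

    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(mutated)
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return replace(variant, effect=effect, gene_id=gene.gene_id)


def annotate_all(
    variants: Iterable[VariantCall],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantCall]:
    """Annotate every variant (see :func:`annotate_effect`)."""
    return [annotate_effect(v, gene_models, genome) for v in variants]


def filter_artifacts(
    variants: Sequence[VariantCall],
    gene_models: Sequence[GeneModel],
    mode: Literal["and", "or"] = "and",
) -> tuple[list[VariantCall], list[dict]]:
    """Drop putative sequencing artifacts; return kept variants and a removal log.

    A variant is removed iff the identical substitution (contig, position,
    ref, alt) occurs in >= 2 strains AND its containing gene is flagged as an
    insertion sequence or a short hypothetical gene.  ``mode="or"`` (for
    sensitivity analysis) removes on recurrence alone as well.  A variant
    unique to one strain is never removed.
    """
    if mode not in ("and", "or"):
        raise InputError(f"unknown artifact-rule mode {mode!r}")
    strains_by_site: dict[tuple, set[str]] = {}
    for v in variants:
        strains_by_site.setdefault(v.site_key, set()).add(v.strain_id)

    kept: list[VariantCall] = []
    log: list[dict] = []
    for v in variants:
        recurrent = len(strains_by_site[v.site_key]) >= 2
        gene = _containing_gene(v.contig, v.pos, gene_models)
        flagged = gene is not None and (
            gene.is_insertion_sequence or gene.is_short_hypothetical
        )
        remove = recurrent and (flagged if mode == "and" else True)
        if remove:
            log.append(
                {
                    "strain_id": v.strain_id,
                    "contig": v.contig,
                    "pos": v.pos,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "gene_id": gene.gene_id if gene else None,
                    "n_strains": len(strains_by_site[v.site_key]),
                    "reason": "recurrent_in_flagged_gene" if flagged else "recurrent",
                }
            )
        else:
            kept.append(v)
    return kept, log


def recurrently_hit_genes(
    variants: Sequence[VariantCall],
    phenotypes: Sequence[MutantRecord],
    min_strains: int = 2,
    include_reduced: bool = False,
    candidate_effects: frozenset[str] = CANDIDATE_EFFECTS,
) -> list[GeneHit]:
    """Rank genes by independent recurrence among complete-loss mutants.

    Counts, per gene, the DISTINCT strains with phenotype ``ina_lost`` (and
    ``ina_reduced`` when ``include_reduced``) carrying at least one
    candidate-effect variant in that gene; returns genes reaching
    ``min_strains``, sorted by count descending then gene id ascending.
    Variants must be effect-annotated first.
    """
    wanted = {"ina_lost"} | ({"ina_reduced"} if include_reduced else set())
    eligible = {m.strain_id for m in phenotypes if m.phenotype in wanted}

    per_gene: dict[str, dict[str, list[VariantCall]]] = {}
    for v in variants:
        if v.effect is None:
            raise InputError(
                f"variant {v.contig}:{v.pos} in {v.strain_id} is not effect-annotated"
            )
        if v.gene_id is None or v.effect not in candidate_effects:
            continue
        if v.strain_id not in eligible:
            continue
        per_gene.setdefault(v.gene_id, {}).setdefault(v.strain_id, []).append(v)

    hits = [
        GeneHit(
            gene_id=gene,
            n_strains=len(by_strain),
            strains=tuple(sorted(by_strain)),
            variants=tuple(
                v for s in sorted(by_strain) for v in by_strain[s]
            ),
        )
        for gene, by_strain in per_gene.items()
        if len(by_strain) >= min_strains
    ]
    hits.sort(key=lambda h: (-h.n_strains, h.gene_id))
    return hits
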