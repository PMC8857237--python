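"""Variant effect annotation, artifact filtering, recurrence ranking."""

import numpy as np
import pytest
from Bio.Seq import Seq

from linafunnel.errors import InputError
from linafunnel.screen import (
    GeneModel,
    MutantRecord,
    VariantCall,
    annotate_effect,
    classify_kind,
    filter_artifacts,
    recurrently_hit_genes,
)

NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def make_genome(cds, pad=100, rng=None, strand="+"):
    rng = rng or np.random.default_rng(0)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    placed = cds if strand == "+" else str(Seq(cds).reverse_complement())
    genome = {"c1": left + placed + right}
    model = GeneModel("geneA", "c1", strand, pad + 1, pad + len(cds), product="thing")
    return genome, model


def oracle_effect(variant, model, genome):
    """Independent oracle: translate the full mutated CDS and diff proteins."""
    seq = genome[variant.contig]
    mut = seq[: variant.pos - 1] + variant.alt_allele + seq[variant.pos - 1 + len(variant.ref_allele):]
    shift = len(variant.alt_allele) - len(variant.ref_allele)
    if shift != 0:
        return "frameshift" if shift % 3 else "inframe_indel"
    cds_ref = seq[model.cds_start - 1 : model.cds_end]
    cds_mut = mut[model.cds_start - 1 : model.cds_end]
    if model.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_mut = str(Seq(cds_mut).reverse_complement())
    aa_ref = str(Seq(cds_ref).translate(table=11))
    aa_mut = str(Seq(cds_mut).translate(table=11))
    if aa_ref == aa_mut:
        return "synonymous"
    if any(b == "*" and a != "*" for a, b in zip(aa_ref, aa_mut)):
        return "nonsense"
    return "nonsynonymous"


class TestAnnotateEffect:
    # CDS at 101-109 is ATG GCT TAA (Met-Ala-stop)
    def setup_method(self):
        self.genome, self.model = make_genome("ATGGCTTAA")

    def variant(self, pos, ref, alt):
        return VariantCall("S1", "c1", pos, ref, alt)

    def test_synonymous_third_position(self):
        v = annotate_effect(self.variant(106, "T", "A"), [self.model], self.genome)
        assert v.effect == "synonymous"  # GCT and GCA both encode Ala
        assert v.gene_id == "geneA"

    def test_nonsynonymous_first_position(self):
        v = annotate_effect(self.variant(104, "G", "A"), [self.model], self.genome)
        assert v.effect == "nonsynonymous"  # GCT Ala -> ACT Thr

    def test_single_base_insertion_is_frameshift(self):
        v = annotate_effect(self.variant(105, "C", "CA"), [self.model], self.genome)
        assert v.effect == "frameshift"

    def test_three_base_insertion_is_inframe(self):
        v = annotate_effect(self.variant(105, "C", "CGGG"), [self.model], self.genome)
        assert v.effect == "inframe_indel"

    def test_intergenic_outside_cds(self):
        base = self.genome["c1"][10]
        alt = "A" if base != "A" else "G"
        v = annotate_effect(self.variant(11, base, alt), [self.model], self.genome)
        assert v.effect == "intergenic" and v.gene_id is None

    def test_reference_mismatch_rejected(self):
        wrong = "C" if self.genome["c1"][103] != "C" else "G"
        with pytest.raises(InputError, match="disagrees"):
            annotate_effect(self.variant(104, wrong, "T"), [self.model], self.genome)

    def test_unknown_contig_rejected(self):
        with pytest.raises(InputError, match="contig"):
            annotate_effect(
                VariantCall("S1", "cX", 5, "A", "T"), [self.model], self.genome
            )

    def test_matches_full_translation_oracle_on_random_snps(self):
        """Codon-level annotation agrees with whole-protein diffing, 1000 SNPs."""
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 1000:
            n_codons = int(rng.integers(3, 100))  # CDS <= 300 nt
            cds = "ATG" + "".join(rng.choice(NONSTOP, n_codons - 2)) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            genome, model = make_genome(cds, rng=rng, strand=strand)
            for _ in range(10):
                pos = int(rng.integers(model.cds_start, model.cds_end + 1))
                ref = genome["c1"][pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = VariantCall("S1", "c1", pos, ref, alt)
                got = annotate_effect(v, [model], genome).effect
                assert got == oracle_effect(v, model, genome), (cds, strand, pos, ref, alt)
                checked += 1

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and flipping coordinates leaves
        every effect call unchanged."""
        rng = np.random.default_rng(6)
        cds = "ATG" + "".join(rng.choice(NONSTOP, 40)) + "TAA"
        genome, model = make_genome(cds, rng=rng, strand="+")
        length = len(genome["c1"])
        rc_genome = {"c1": str(Seq(genome["c1"]).reverse_complement())}
        rc_model = GeneModel(
            "geneA", "c1", "-", length - model.cds_end + 1, length - model.cds_start + 1,
            product="thing",
        )
        for _ in range(50):
            pos = int(rng.integers(model.cds_start, model.cds_end + 1))
            ref = genome["c1"][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fwd = annotate_effect(
                VariantCall("S1", "c1", pos, ref, alt), [model], genome
            )
            rc = annotate_effect(
                VariantCall(
                    "S1", "c1", length - pos + 1,
                    str(Seq(ref).reverse_complement()),
                    str(Seq(alt).reverse_complement()),
                ),
                [rc_model],
                rc_genome,
            )
            assert fwd.effect == rc.effect


class TestClassifyKind:
    @pytest.mark.parametrize(
        "ref,alt,kind",
        [("A", "T", "snp"), ("A", "AT", "insertion"), ("AT", "A", "deletion")],
    )
    def test_kinds(self, ref, alt, kind):
        assert classify_kind(ref, alt) == kind

    def test_identical_alleles_rejected(self):
        with pytest.raises(InputError):
            classify_kind("A", "A")
        with pytest.raises(InputError):
            VariantCall("S", "c1", 5, "A", "T", kind="insertion")


IS_GENE = GeneModel("isX", "c1", "+", 1000, 2200, product="IS3 family transposase",
                    is_insertion_sequence=True)
OK_GENE = GeneModel("geneB", "c1", "+", 5000, 5899, product="kinase")


def var(strain, pos, ref="A", alt="G"):
    return VariantCall(strain, "c1", pos, ref, alt)


class TestFilterArtifacts:
    models = [IS_GENE, OK_GENE]

    def test_recurrent_in_flagged_gene_removed_everywhere(self):
        vs = [var(s, 1500) for s in ("m1", "m2", "m3")]
        kept, log = filter_artifacts(vs, self.models)
        assert kept == [] and len(log) == 3

    def test_unique_variant_in_flagged_gene_kept(self):
        vs = [var("m1", 1500)]
        kept, log = filter_artifacts(vs, self.models)
        assert kept == vs and log == []

    def test_recurrent_in_unflagged_gene_kept_under_and_rule(self):
        vs = [var("m1", 5100), var("m2", 5100)]
        kept, _ = filter_artifacts(vs, self.models)
        assert kept == vs
        kept_or, _ = filter_artifacts(vs, self.models, mode="or")
        assert kept_or == []

    def test_never_removes_strain_unique_variants(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vs = []
            for s in ("m1", "m2", "m3"):
                for pos in rng.choice(np.arange(900, 6000), size=5, replace=False):
                    vs.append(var(s, int(pos)))
            unique_sites = {
                v.site_key for v in vs
                if sum(1 for w in vs if w.site_key == v.site_key) == 1
            }
            for mode in ("and", "or"):
                kept, _ = filter_artifacts(vs, self.models, mode=mode)
                assert unique_sites <= {v.site_key for v in kept}


def annotated(strain, gene, effect, pos=1):
    return VariantCall(strain, "c1", pos, "A", "G", effect=effect, gene_id=gene)


PHENOS = [MutantRecord(f"L{i}", "ina_lost") for i in range(1, 8)] + [
    MutantRecord("R1", "ina_reduced"),
    MutantRecord("W1", "wild_type"),
]


class TestRecurrence:
    def test_published_split_pattern(self):
        """5 strains hit geneA, 2 hit geneB: ranking is [geneA:5, geneB:2]."""
        vs = [annotated(f"L{i}", "geneA", "nonsynonymous", pos=i) for i in range(1, 6)]
        vs += [annotated("L3", "geneA", "frameshift", pos=99)]  # second hit, same strain
        vs += [annotated(f"L{i}", "geneB", "nonsynonymous", pos=i) for i in (6, 7)]
        hits = recurrently_hit_genes(vs, PHENOS, min_strains=2)
        assert [(h.gene_id, h.n_strains) for h in hits] == [("geneA", 5), ("geneB", 2)]

    def test_empty_input(self):
        assert recurrently_hit_genes([], PHENOS, min_strains=2) == []

    def test_excluded_effects_and_phenotypes(self):
        vs = [
            annotated("L1", "geneC", "synonymous"),
            annotated("L2", "geneC", "intergenic"),
            annotated("R1", "geneC", "nonsynonymous"),
            annotated("W1", "geneC", "nonsynonymous"),
        ]
        assert recurrently_hit_genes(vs, PHENOS, min_strains=1) == []
        with_reduced = recurrently_hit_genes(
            vs, PHENOS, min_strains=1, include_reduced=True
        )
        assert [(h.gene_id, h.n_strains) for h in with_reduced] == [("geneC", 1)]

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(6)]
        effects = ["nonsynonymous", "synonymous", "frameshift", "intergenic"]
        lost = {m.strain_id for m in PHENOS if m.phenotype == "ina_lost"}
        for _ in range(20):
            vs = [
                annotated(
                    str(rng.choice([m.strain_id for m in PHENOS])),
                    str(rng.choice(genes)),
                    str(rng.choice(effects)),
                    pos=int(rng.integers(1, 1000)),
                )
                for _ in range(30)
            ]
            expected = {}
            for g in genes:
                n = len(
                    {
                        v.strain_id
                        for v in vs
                        if v.gene_id == g
                        and v.strain_id in lost
                        and v.effect in ("nonsynonymous", "nonsense", "frameshift",
                                         "inframe_indel")
                    }
                )
                if n >= 2:
                    expected[g] = n
            got = {h.gene_id: h.n_strains for h in recurrently_hit_genes(vs, PHENOS)}
            assert got == expected

    def test_invariant_to_relabeling_and_order(self):
        vs = [annotated(f"L{i}", "geneA", "nonsynonymous", pos=i) for i in (1, 2, 3)]
        base = recurrently_hit_genes(vs, PHENOS)
        relabel = {"L1": "L3", "L2": "L1", "L3": "L2"}
        swapped = [
            VariantCall(relabel[v.strain_id], v.contig, v.pos, v.ref_allele,
                        v.alt_allele, effect=v.effect, gene_id=v.gene_id)
            for v in reversed(vs)
        ]
        again = recurrently_hit_genes(swapped, PHENOS)
        assert [(h.gene_id, h.n_strains) for h in base] == [
            (h.gene_id, h.n_strains) for h in again
        ]

    def test_unannotated_variants_rejected(self):
        with pytest.raises(InputError, match="annotated"):
            recurrently_hit_genes([var("L1", 5)], PHENOS)

    def test_tie_break_is_lexicographic(self):
        vs = [
            annotated("L1", "zeta", "nonsynonymous", pos=1),
            annotated("L2", "zeta", "nonsynonymous", pos=2),
            annotated("L1", "alpha", "nonsynonymous", pos=3),
            annotated("L2", "alpha", "nonsynonymous", pos=4),
        ]
        hits = recurrently_hit_genes(vs, PHENOS)
        assert [h.gene_id for h in hits] == ["alpha", "zeta"]
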