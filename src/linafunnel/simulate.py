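"""Synthetic-data generator for the whole candidate-gene funnel.

Every pipeline input can be generated with known ("planted") ground truth so
the funnel and the mutant screen can be exercised and validated end to end
without any sequencing data:

* a pan-genome presence/absence matrix with clusters planted as clade-unique
  among core, shell, target-partial, and near-unique distractors;
* an RNA-seq count table (negative-binomial, overdispersed) with a chosen
  number of the unique genes forced to zero expression;
* a genome fragment carrying a 5-gene PKS-NRPS biosynthetic cluster
  (phosphopantetheinyl transferase, epimerase/dehydratase, a type I PKS
  with KS-AT-DH-KR-ACP domains, a two-module NRPS with C-A-PCP-C-A-PCP, and
  a thioesterase), flanking hypothetical genes, and distant insertion-
  sequence elements, as GFF3 + FASTA;
* per-mutant variant sets with Poisson background mutation load, planted
  causal hits in the cluster genes, and shared artifact substitutions in
  insertion-sequence genes;
* droplet-freezing assays simulated from a known cumulative INP spectrum
  K(theta) under the Poisson ice-nucleus activation model: the number of
  nuclei active in a droplet at temperature theta is Poisson(K(theta) * A),
  coupled across the ramp by drawing independent Poisson increments, so a
  frozen droplet stays frozen.

All randomness flows through one seeded numpy generator per bundle; an
identical configuration and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assay import DropletSeries
from .errors import InputError, StageError
from .funnel import DomainAnnotation, ExpressionTable, PresenceAbsenceMatrix
from .screen import GeneModel, MutantRecord, VariantCall, annotate_effect

__all__ = [
    "SpectrumParams",
    "AssayProtocol",
    "GeneratorConfig",
    "BgcGenome",
    "FixtureBundle",
    "spectrum_truth",
    "gen_pangenome",
    "gen_expression",
    "gen_bgc_genome",
    "gen_mutants",
    "gen_droplet_assay",
    "gen_funnel_fixture",
]

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SpectrumParams:
    """Parametric cumulative INP spectrum: zero above the onset temperature,
    then log10 K rising linearly as the temperature falls."""

    onset_temp_c: float = -4.0
    k_onset_per_cfu: float = 1e-7
    log10_slope_per_degree: float = 0.5


@dataclass(frozen=True)
class AssayProtocol:
    """Droplet-assay protocol: tenfold dilution series from a starting
    concentration, fixed droplet volume, triplicate 30-droplet arrays over a
    1-degree ramp."""

    n_drops: int = 30
    n_dilutions: int = 6
    n_replicates: int = 3
    start_cfu_per_ml: float = 1e8
    drop_volume_ul: float = 20.0
    temp_start_c: float = -2.0
    temp_stop_c: float = -12.0
    temp_step_c: float = 1.0

    def temperatures(self) -> tuple[float, ...]:
        n = int(round((self.temp_start_c - self.temp_stop_c) / self.temp_step_c)) + 1
        return tuple(self.temp_start_c - i * self.temp_step_c for i in range(n))

    def cfu_per_drop(self, dilution_factor: float) -> float:
        return self.start_cfu_per_ml * (self.drop_volume_ul * 1e-3) / dilution_factor


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    The defaults describe a desk-scale pan-genome of 19 genomes with two
    target genomes, an overdispersed expression model, a mean UV mutation
    load of 4 candidate-effect variants per strain, and the 5-gene PKS-NRPS
    cluster template.  ``fixtures/in_paper.yaml`` overrides the stage sizes
    to replay the published funnel counts.
    """

    seed: int
    # pan-genome
    n_genomes: int = 19
    target_ids: tuple[str, str] = ("VT1065", "BAM582")
    n_core: int = 60
    n_shell: int = 40
    n_unique: int = 80
    n_target_partial: int = 10
    n_near_unique: int = 6
    # expression
    nb_mean: float = 250.0
    nb_dispersion: float = 2.0
    n_zero_expression: int = 3
    # BGC genome
    n_filler_genes: int = 60
    n_short_hypothetical: int = 6
    n_is_elements: int = 3
    n_extra_core_clusters: int = 0
    # mutant screen
    mutation_lambda: float = 4.0
    n_lost: int = 7
    n_reduced: int = 2
    n_wt: int = 1
    causal_split: tuple[int, int] = (5, 2)
    causal_gene_ids: tuple[str, str] | None = None
    n_artifact_variants: int = 3
    # assay
    spectrum: SpectrumParams = field(default_factory=SpectrumParams)
    protocol: AssayProtocol = field(default_factory=AssayProtocol)

    def __post_init__(self) -> None:
        self.target_ids = tuple(self.target_ids)
        self.causal_split = tuple(self.causal_split)
        if len(self.target_ids) != 2 or self.target_ids[0] == self.target_ids[1]:
            raise InputError("target_ids must be 2 distinct genome ids")
        if self.n_genomes < 3:
            raise InputError("need at least 3 genomes (2 targets + 1 other)")
        for name in (
            "n_core", "n_shell", "n_unique", "n_target_partial", "n_near_unique",
            "n_zero_expression", "n_filler_genes", "n_short_hypothetical",
            "n_is_elements", "n_extra_core_clusters", "n_lost", "n_reduced",
            "n_wt", "n_artifact_variants",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.mutation_lambda <= 0:
            raise InputError("mutation_lambda must be > 0")
        if self.n_zero_expression > self.n_unique:
            raise InputError("n_zero_expression exceeds n_unique")
        if self.n_lost > 0 and sum(self.causal_split) != self.n_lost:
            raise InputError(
                f"causal_split {self.causal_split} must sum to n_lost {self.n_lost}"
            )

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "GeneratorConfig":
        """Load a config from YAML, rejecting unknown keys.

        ``seed`` overrides the file's seed (the file may omit it)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise InputError(f"{path}: unknown config keys {unknown}")
        if "spectrum" in raw:
            raw["spectrum"] = _nested(SpectrumParams, raw["spectrum"], path)
        if "protocol" in raw:
            raw["protocol"] = _nested(AssayProtocol, raw["protocol"], path)
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw:
            raise InputError(f"{path}: seed is mandatory (pass one or set it in the file)")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_ids"] = list(self.target_ids)
        d["causal_split"] = list(self.causal_split)
        return d


def _nested(cls, raw: dict, path) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise InputError(f"{path}: unknown {cls.__name__} keys {unknown}")
    return cls(**raw)


def spectrum_truth(
    params: SpectrumParams, temperatures: Sequence[float]
) -> np.ndarray:
    """Evaluate the parametric cumulative spectrum K(theta) on a grid."""
    t = np.asarray(temperatures, dtype=float)
    k = np.where(
        t > params.onset_temp_c,
        0.0,
        params.k_onset_per_cfu
        * 10.0 ** (params.log10_slope_per_degree * (params.onset_temp_c - t)),
    )
    return k


# ---------------------------------------------------------------------------
# pan-genome


class _TagAllocator:
    """Sequential locus-tag allocator for one genome (``PREFIX_00001`` ...)."""

    def __init__(self, prefix: str, start: int = 1) -> None:
        self.prefix = prefix
        self.n = start

    def next(self) -> str:
        tag = f"{self.prefix}_{self.n:05d}"
        self.n += 1
        return tag


def _genome_prefix(genome_id: str) -> str:
    return "".join(ch for ch in genome_id if ch.isalnum()) or "G"


def gen_pangenome(
    config: GeneratorConfig,
    rng: np.random.Generator,
    unique_reference_tags: Sequence[str] | None = None,
    reference_tag_start: int = 1,
) -> tuple[PresenceAbsenceMatrix, dict[str, list[str]], dict]:
    """Generate a presence/absence matrix with planted clade-unique clusters.

    Plants ``n_unique`` clusters present in both targets and nowhere else,
    among distractors: core (all genomes), shell (random genome subsets that
    always include a non-target), target-partial (exactly one target), and
    near-unique (both targets plus exactly one non-target).  Returns the
    matrix, per-genome locus-tag catalogs, and the planted truth
    (reference-genome tags of the unique clusters).
    """

    targets = list(config.target_ids)
    others = [f"LYS{i:02d}" for i in range(1, config.n_genomes - 1)]
    genomes = targets + others
    reference = targets[0]

    allocators = {g: _TagAllocator(_genome_prefix(g)) for g in genomes}
    allocators[reference].n = reference_tag_start
    provided = list(unique_reference_tags or [])
    if len(provided) > config.n_unique:
        raise InputError(
            f"{len(provided)} reserved unique tags exceed n_unique={config.n_unique}"
        )

    rows: list[tuple[str, str, dict[str, str]]] = []  # (cluster, annotation, cells)
    cluster_n = 0

    def new_cluster() -> str:
        nonlocal cluster_n
        cluster_n += 1
        return f"group_{cluster_n:05d}"

    unique_ref_tags: list[str] = []
    for i in range(config.n_unique):
        cells = {}
        if i < len(provided):
            cells[reference] = provided[i]
        else:
            cells[reference] = allocators[reference].next()
        cells[targets[1]] = allocators[targets[1]].next()
        unique_ref_tags.append(cells[reference])
        rows.append((new_cluster(), "clade-unique planted gene", cells))

    for _ in range(config.n_core):
        cells = {g: allocators[g].next() for g in genomes}
        rows.append((new_cluster(), "core gene", cells))

    for _ in range(config.n_shell):
        size = int(rng.integers(1, config.n_genomes))
        members = list(rng.choice(genomes, size=size, replace=False))
        if set(members) <= set(targets):
            members.append(str(rng.choice(others)))
        cells = {g: allocators[g].next() for g in sorted(set(members), key=genomes.index)}
        rows.append((new_cluster(), "shell gene", cells))

    for i in range(config.n_target_partial):
        t = targets[i % 2]
        cells = {t: allocators[t].next()}
        rows.append((new_cluster(), "single-target gene", cells))

    for _ in range(config.n_near_unique):
        extra = str(rng.choice(others))
        cells = {g: allocators[g].next() for g in targets + [extra]}
        rows.append((new_cluster(), "near-unique gene", cells))

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    occupancy = pd.DataFrame(
        [[cells.get(g, "") for g in genomes] for _, _, cells in rows],
        index=pd.Index([cid for cid, _, _ in rows], name="Gene"),
        columns=genomes,
    )
    annotation = pd.Series([ann for _, ann, _ in rows], index=occupancy.index)
    matrix = PresenceAbsenceMatrix(occupancy, annotation)

    catalogs = {
        g: [cells[g] for _, _, cells in rows if g in cells] for g in genomes
    }
    truth = {"unique_reference_tags": sorted(unique_ref_tags)}
    return matrix, catalogs, truth


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    config: GeneratorConfig,
    gene_ids: Sequence[str],
    unique_gene_ids: Sequence[str],
    rng: np.random.Generator,
    protect: set[str] | None = None,
    known_lengths: Mapping[str, int] | None = None,
) -> tuple[ExpressionTable, dict]:
    """Generate a negative-binomial count table with planted zero-expression genes.

    Exactly ``n_zero_expression`` of the unique genes (never one of the
    ``protect`` set) are forced to zero counts; the remaining unique genes
    are drawn from the zero-truncated negative binomial so the planted
    expressed set is exact.  Lengths are uniform on 300-6000 nt unless given
    in ``known_lengths``.
    """
    protect = protect or set()
    unique = sorted(set(unique_gene_ids))
    missing = sorted(set(unique) - set(gene_ids))
    if missing:
        raise InputError(f"unique genes absent from gene_ids: {missing[:5]}")
    if config.n_zero_expression > len(unique):
        raise InputError("n_zero_expression exceeds the number of unique genes")
    eligible = [g for g in unique if g not in protect]
    if config.n_zero_expression > len(eligible):
        raise InputError("not enough unprotected unique genes to force to zero")

    n = len(gene_ids)
    r = config.nb_dispersion
    p = r / (r + config.nb_mean)
    counts = rng.negative_binomial(r, p, size=n).astype(np.int64)
    lengths = rng.integers(300, 6001, size=n)
    if known_lengths:
        for i, g in enumerate(gene_ids):
            if g in known_lengths:
                lengths[i] = known_lengths[g]

    zero_forced = sorted(
        rng.choice(eligible, size=config.n_zero_expression, replace=False).tolist()
    )
    zero_set = set(zero_forced)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in zero_forced:
        counts[idx[g]] = 0
    # unique genes not forced to zero must be expressed: zero-truncated draw
    for g in unique:
        if g in zero_set:
            continue
        while counts[idx[g]] == 0:
            counts[idx[g]] = rng.negative_binomial(r, p)

    table = ExpressionTable.from_counts(list(gene_ids), counts, lengths)
    truth = {"zero_expression_genes": zero_forced}
    return table, truth


# ---------------------------------------------------------------------------
# BGC genome


@dataclass
class BgcGenome:
    """A synthetic genome fragment carrying the PKS-NRPS cluster template."""

    contig: str
    sequence: str
    gene_models: list[GeneModel]
    annotations: list[DomainAnnotation]
    cluster_gene_ids: list[str]  # the 5-gene template, in genomic order
    extra_core_gene_ids: list[str]
    is_gene_ids: list[str]
    pks_gene_id: str
    nrps_gene_id: str

    @property
    def genome(self) -> dict[str, str]:
        return {self.contig: self.sequence}

    @property
    def unique_gene_ids(self) -> list[str]:
        """Genes of the fragment planted as clade-unique (everything but IS)."""
        is_set = set(self.is_gene_ids)
        return [g.gene_id for g in self.gene_models if g.gene_id not in is_set]

    @property
    def cds_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self.gene_models}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A CDS of ``n_codons`` codons: ATG start, no internal stop, TAA stop."""
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_bgc_genome(
    config: GeneratorConfig, rng: np.random.Generator, tag_start: int = 1
) -> BgcGenome:
    """Emit the 5-gene PKS-NRPS cluster template on one contig.

    Genomic order: upstream hypothetical genes; the cluster (PPTASE,
    EPIM_DH, an intergenic gap, T1-PKS [KS,AT,DH,KR,ACP], NRPS
    [C,A,PCP,C,A,PCP], TE); downstream hypothetical genes and further
    filler (some short enough to be flagged short-hypothetical); distant
    insertion-sequence elements; and, when configured, extra distant
    clusters of five KS-carrying genes each.  Locus tags run sequentially
    along the contig in the reference genome's namespace.
    """
    contig = "chr1"
    prefix = _genome_prefix(config.target_ids[0])
    tags = _TagAllocator(prefix, start=tag_start)

    parts: list[str] = []
    pos = 0  # 0-based length so far
    gene_models: list[GeneModel] = []
    annotations: list[DomainAnnotation] = []

    def intergenic(n: int) -> None:
        nonlocal pos
        parts.append("".join(rng.choice(list("ACGT"), size=n)))
        pos += n

    def add_gene(
        n_codons: int,
        product: str,
        domains: Sequence[str],
        strand: str = "+",
        mobile: bool = False,
    ) -> str:
        nonlocal pos
        cds = _random_cds(rng, n_codons)
        start = pos + 1  # 1-based
        parts.append(cds if strand == "+" else _revcomp(cds))
        pos += len(cds)
        gid = tags.next()
        gene_models.append(
            GeneModel.with_derived_flags(
                gid, contig, strand, start, pos, product=product, mobile_element=mobile
            )
        )
        annotations.append(
            DomainAnnotation(gid, tuple(domains), contig, start, pos, strand)
        )
        return gid

    def filler(short: bool = False, strand: str = "+") -> str:
        n_codons = int(rng.integers(40, 96)) if short else int(rng.integers(150, 420))
        return add_gene(n_codons, "hypothetical protein", (), strand=strand)

    intergenic(200)
    n_up, n_down = 5, 5
    n_rest = max(0, config.n_filler_genes - n_up - n_down)
    for i in range(n_up):
        filler(strand="+" if i % 2 else "-")
        intergenic(int(rng.integers(100, 250)))

    # the cluster: support genes, a gap before the PKS, the megasynthases, TE
    pptase = add_gene(250, "4'-phosphopantetheinyl transferase", ("PPTASE",))
    intergenic(120)
    epim = add_gene(300, "NAD-dependent epimerase/dehydratase", ("EPIM_DH",))
    intergenic(400)  # the intergenic region just upstream of the PKS
    pks = add_gene(
        2400, "type I iterative polyketide synthase", ("KS", "AT", "DH", "KR", "ACP")
    )
    intergenic(80)
    nrps = add_gene(
        2100, "non-ribosomal peptide synthetase", ("C", "A", "PCP", "C", "A", "PCP")
    )
    intergenic(80)
    te = add_gene(250, "thioesterase", ("TE",))
    cluster = [pptase, epim, pks, nrps, te]

    for i in range(n_down):
        intergenic(int(rng.integers(100, 250)))
        filler(strand="+" if i % 2 else "-")

    n_short = min(config.n_short_hypothetical, n_rest)
    for i in range(n_rest):
        intergenic(int(rng.integers(120, 400)))
        filler(short=i < n_short, strand="+" if i % 3 else "-")

    is_ids: list[str] = []
    if config.n_is_elements:
        intergenic(15_000)
        for i in range(config.n_is_elements):
            is_ids.append(
                add_gene(400, "IS3 family transposase", (), strand="+", mobile=True)
            )
            intergenic(int(rng.integers(300, 700)))

    extra_core: list[str] = []
    for _ in range(config.n_extra_core_clusters):
        intergenic(15_000)
        for j in range(5):
            extra_core.append(
                add_gene(
                    int(rng.integers(400, 800)),
                    "polyketide synthase, iterative type",
                    ("KS", "AT", "ACP"),
                )
            )
            if j < 4:
                intergenic(200)
    intergenic(300)

    return BgcGenome(
        contig=contig,
        sequence="".join(parts),
        gene_models=gene_models,
        annotations=annotations,
        cluster_gene_ids=cluster,
        extra_core_gene_ids=extra_core,
        is_gene_ids=is_ids,
        pks_gene_id=pks,
        nrps_gene_id=nrps,
    )


# ---------------------------------------------------------------------------
# mutants


def _random_nonsyn_snp(
    gene: GeneModel,
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    strain: str,
    rng: np.random.Generator,
    taken: set[int],
    max_tries: int = 200,
) -> VariantCall:
    """Draw a nonsynonymous SNP inside a CDS by rejection sampling."""
    seq = genome[gene.contig]
    for _ in range(max_tries):
        # skip the start and stop codons
        pos = int(rng.integers(gene.cds_start + 3, gene.cds_end - 2))
        if pos in taken:
            continue
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        cand = VariantCall(strain, gene.contig, pos, ref, alt)
        cand = annotate_effect(cand, gene_models, genome)
        if cand.effect == "nonsynonymous":
            return cand
    raise StageError(f"could not place a nonsynonymous SNP in {gene.gene_id}")


def _random_indel(
    gene: GeneModel,
    genome: Mapping[str, str],
    strain: str,
    rng: np.random.Generator,
    taken: set[int],
) -> VariantCall:
    """A single-nucleotide insertion anchored inside the CDS (frameshift)."""
    seq = genome[gene.contig]
    while True:
        pos = int(rng.integers(gene.cds_start + 3, gene.cds_end - 3))
        if pos not in taken:
            break
    ref = seq[pos - 1]
    alt = ref + str(rng.choice(list("ACGT")))
    return VariantCall(strain, gene.contig, pos, ref, alt)


def gen_mutants(
    config: GeneratorConfig,
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    rng: np.random.Generator,
    causal_gene_ids: tuple[str, str] | None = None,
) -> tuple[dict[str, list[VariantCall]], list[MutantRecord], dict]:
    """Generate per-strain variant sets with planted causal and artifact hits.

    Complete-loss strains receive causal hits split across the two causal
    genes per ``causal_split`` (nonsynonymous SNPs, one strain per causal
    gene a 1-nt insertion when it gets a single hit pattern of that kind);
    every strain receives a Poisson(``mutation_lambda``) number of
    background candidate-effect variants in unflagged filler genes; and
    ``n_artifact_variants`` identical substitutions are planted in flagged
    (insertion-sequence / short-hypothetical) genes across >=2 strains.

    Background placement for complete-loss strains never reuses a gene
    across strains, so no non-causal gene can reach the recurrence
    threshold among them; the Poisson counts themselves are untouched.
    """
    by_id = {g.gene_id: g for g in gene_models}
    causal = causal_gene_ids or config.causal_gene_ids
    if config.n_lost > 0:
        if causal is None:
            raise InputError("causal_gene_ids required when n_lost > 0")
        missing = [g for g in causal if g not in by_id]
        if missing:
            raise InputError(f"causal genes absent from gene_models: {missing}")

    flagged = {
        g.gene_id
        for g in gene_models
        if g.is_insertion_sequence or g.is_short_hypothetical
    }
    causal_set = set(causal or ())
    pool = sorted(
        g.gene_id
        for g in gene_models
        if g.gene_id not in flagged
        and g.gene_id not in causal_set
        and not g.product.startswith(("type I", "non-ribosomal", "polyketide"))
        and g.length >= 150
    )
    if not pool:
        raise InputError("no eligible background genes in gene_models")

    strains: list[tuple[str, str]] = []
    n = 0
    for _ in range(config.n_lost):
        n += 1
        strains.append((f"UV{n:03d}", "ina_lost"))
    for _ in range(config.n_reduced):
        n += 1
        strains.append((f"UV{n:03d}", "ina_reduced"))
    for _ in range(config.n_wt):
        n += 1
        strains.append((f"UV{n:03d}", "wild_type"))

    variants: dict[str, list[VariantCall]] = {s: [] for s, _ in strains}
    taken: dict[str, set[int]] = {s: set() for s, _ in strains}
    truth: dict = {"causal_hits": {}, "background_counts": {}, "artifact_sites": []}

    # causal hits, mirroring the published mix of hit patterns
    if config.n_lost > 0:
        lost = [s for s, ph in strains if ph == "ina_lost"]
        pks_strains = lost[: config.causal_split[0]]
        nrps_strains = lost[config.causal_split[0] :]
        pks_patterns = ["snp", "snp2", "ins", "snp", "snp"]
        for i, s in enumerate(pks_strains):
            gene = by_id[causal[0]]
            pattern = pks_patterns[i % len(pks_patterns)]
            hits: list[VariantCall] = []
            if pattern == "ins":
                hits.append(_random_indel(gene, genome, s, rng, taken[s]))
            else:
                reps = 2 if pattern == "snp2" else 1
                for _ in range(reps):
                    hits.append(
                        _random_nonsyn_snp(gene, genome, gene_models, s, rng, taken[s])
                    )
                    taken[s].add(hits[-1].pos)
            for v in hits:
                taken[s].add(v.pos)
            variants[s].extend(hits)
            truth["causal_hits"][s] = {
                "gene": causal[0],
                "positions": [v.pos for v in hits],
            }
        for s in nrps_strains:
            gene = by_id[causal[1]]
            v = _random_nonsyn_snp(gene, genome, gene_models, s, rng, taken[s])
            taken[s].add(v.pos)
            variants[s].append(v)
            truth["causal_hits"][s] = {"gene": causal[1], "positions": [v.pos]}

    # shared artifact substitutions in flagged genes
    flagged_genes = sorted(flagged)
    if config.n_artifact_variants and not flagged_genes:
        raise InputError("n_artifact_variants > 0 but no flagged genes in gene_models")
    all_strain_ids = [s for s, _ in strains]
    for _ in range(config.n_artifact_variants):
        if len(all_strain_ids) < 2:
            break
        gene = by_id[str(rng.choice(flagged_genes))]
        seq = genome[gene.contig]
        pos = int(rng.integers(gene.cds_start, gene.cds_end + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        size = int(rng.integers(2, min(4, len(all_strain_ids)) + 1))
        carriers = sorted(rng.choice(all_strain_ids, size=size, replace=False).tolist())
        carriers = [s for s in carriers if pos not in taken[s]]
        if len(carriers) < 2:
            continue
        for s in carriers:
            variants[s].append(VariantCall(s, gene.contig, pos, ref, alt))
            taken[s].add(pos)
        truth["artifact_sites"].append(
            {"gene": gene.gene_id, "pos": pos, "ref": ref, "alt": alt,
             "strains": carriers}
        )

    # Poisson background load
    used_by_lost: set[str] = set()
    for s, phenotype in strains:
        k = int(rng.poisson(config.mutation_lambda))
        truth["background_counts"][s] = k
        for _ in range(k):
            if phenotype == "ina_lost":
                avail = [g for g in pool if g not in used_by_lost]
                if not avail:
                    raise StageError(
                        "background gene pool exhausted for complete-loss strains; "
                        "increase n_filler_genes"
                    )
            else:
                avail = pool
            gene = by_id[str(rng.choice(avail))]
            if phenotype == "ina_lost":
                used_by_lost.add(gene.gene_id)
            if rng.random() < 0.8:
                v = _random_nonsyn_snp(gene, genome, gene_models, s, rng, taken[s])
            else:
                v = _random_indel(gene, genome, s, rng, taken[s])
            taken[s].add(v.pos)
            variants[s].append(v)

    for s in variants:
        variants[s].sort(key=lambda v: (v.contig, v.pos, v.alt_allele))
    phenotypes = [MutantRecord(s, ph) for s, ph in strains]
    return variants, phenotypes, truth


# ---------------------------------------------------------------------------
# droplet assays


def gen_droplet_assay(
    config: GeneratorConfig,
    true_spectrum: np.ndarray | Sequence[float] | None,
    rng: np.random.Generator,
    strain_id: str = "VT1065",
) -> tuple[list[DropletSeries], list[DropletSeries]]:
    """Simulate a dilution-series droplet assay from a known spectrum.

    Under the Poisson activation model the number of nuclei active in one
    droplet at temperature theta is Poisson(K(theta) * A); drawing
    independent Poisson counts on the increments of K and accumulating them
    along the ramp couples the draws so a frozen droplet stays frozen.
    Returns the sample series and an all-unfrozen water-control series
    (one per replicate).
    """
    proto = config.protocol
    temps = proto.temperatures()
    if true_spectrum is None:
        k = spectrum_truth(config.spectrum, temps)
    else:
        k = np.asarray(true_spectrum, dtype=float)
    if k.shape != (len(temps),):
        raise InputError(f"true_spectrum must have {len(temps)} values")
    if np.any(k < 0) or np.any(np.diff(k) < -1e-15):
        raise InputError("true_spectrum must be non-negative and non-decreasing")

    increments = np.diff(np.concatenate(([0.0], k)))
    series: list[DropletSeries] = []
    for d in range(proto.n_dilutions):
        dilution = 10.0 ** d
        a = proto.cfu_per_drop(dilution)
        for rep in range(1, proto.n_replicates + 1):
            counts = rng.poisson(
                increments * a, size=(proto.n_drops, len(temps))
            )
            frozen = (np.cumsum(counts, axis=1) >= 1).sum(axis=0)
            series.append(
                DropletSeries(
                    strain_id=strain_id,
                    replicate=rep,
                    dilution_factor=dilution,
                    cfu_per_drop=a,
                    temperatures=temps,
                    n_drops=proto.n_drops,
                    frozen_counts=tuple(int(f) for f in frozen),
                )
            )
    control = [
        DropletSeries(
            strain_id="water",
            replicate=rep,
            dilution_factor=1.0,
            cfu_per_drop=1.0,
            temperatures=temps,
            n_drops=proto.n_drops,
            frozen_counts=(0,) * len(temps),
        )
        for rep in range(1, proto.n_replicates + 1)
    ]
    return series, control


# ---------------------------------------------------------------------------
# the full bundle


@dataclass
class FixtureBundle:
    """Every pipeline input for one synthetic study, with its planted truth."""

    config: GeneratorConfig
    matrix: PresenceAbsenceMatrix
    catalogs: dict[str, list[str]]
    expression: ExpressionTable
    bgc: BgcGenome
    variants: dict[str, list[VariantCall]]
    phenotypes: list[MutantRecord]
    assays: dict[str, list[DropletSeries]]
    control: list[DropletSeries]
    manifest: dict


def gen_funnel_fixture(config: GeneratorConfig) -> FixtureBundle:
    """Generate the complete input bundle for one study configuration.

    One seeded generator drives every step, so the same (config, seed)
    reproduce the bundle exactly.  The planted truth (unique tags, silenced
    genes, core genes, causal genes, artifact sites, spectrum parameters)
    goes into the manifest for testing and provenance.
    """
    rng = np.random.default_rng(config.seed)

    bgc = gen_bgc_genome(config, rng, tag_start=1)
    bgc_unique = bgc.unique_gene_ids
    if config.n_unique < len(bgc_unique):
        raise InputError(
            f"n_unique={config.n_unique} smaller than the {len(bgc_unique)} "
            "clade-unique genes on the cluster contig"
        )
    matrix, catalogs, pg_truth = gen_pangenome(
        config,
        rng,
        unique_reference_tags=bgc_unique,
        reference_tag_start=len(bgc.gene_models) + 1,
    )

    reference = config.target_ids[0]
    expr_gene_ids = sorted(set(catalogs[reference]) | set(bgc.is_gene_ids))
    core_template = set(bgc.cluster_gene_ids) | set(bgc.extra_core_gene_ids)
    expression, expr_truth = gen_expression(
        config,
        expr_gene_ids,
        unique_gene_ids=pg_truth["unique_reference_tags"],
        rng=rng,
        protect=core_template,
        known_lengths=bgc.cds_lengths,
    )

    variants, phenotypes, screen_truth = gen_mutants(
        config,
        bgc.genome,
        bgc.gene_models,
        rng,
        causal_gene_ids=(bgc.pks_gene_id, bgc.nrps_gene_id),
    )

    temps = config.protocol.temperatures()
    k_wt = spectrum_truth(config.spectrum, temps)
    assays: dict[str, list[DropletSeries]] = {}
    wt_series, control = gen_droplet_assay(config, k_wt, rng, strain_id=reference)
    assays[reference] = wt_series
    for rec in phenotypes:
        if rec.phenotype == "ina_lost":
            k = np.zeros_like(k_wt)
        elif rec.phenotype == "ina_reduced":
            k = k_wt * 1e-2
        else:
            k = k_wt
        s, _ = gen_droplet_assay(config, k, rng, strain_id=rec.strain_id)
        assays[rec.strain_id] = s

    manifest = {
        "config": config.to_dict(),
        "planted_truth": {
            **pg_truth,
            **expr_truth,
            "core_gene_ids": sorted(core_template),
            "cluster_gene_ids": list(bgc.cluster_gene_ids),
            "causal_gene_ids": [bgc.pks_gene_id, bgc.nrps_gene_id],
            "is_gene_ids": list(bgc.is_gene_ids),
            **screen_truth,
            "spectrum_k_per_cfu": {
                str(t): float(v) for t, v in zip(temps, k_wt)
            },
        },
        "notes": {
            "mutation_load_model": "Poisson background count per strain (an "
            "assumption; only the mean load is constrained by design)",
            "freezing_model": "Poisson activation of ice nuclei per droplet",
        },
    }
    return FixtureBundle(
        config=config,
        matrix=matrix,
        catalogs=catalogs,
        expression=expression,
        bgc=bgc,
        variants=variants,
        phenotypes=phenotypes,
        assays=assays,
        control=control,
        manifest=manifest,
    )
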