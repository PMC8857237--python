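"""Pan-genome candidate funnel: clade-uniqueness, expression, BGC-core tagging.

The funnel reduces a pan-genome to candidate genes for a clade-specific
phenotype in three nested stages:

1. genes present in every target (phenotype-positive) genome and absent from
   every other genome in the pan-genome matrix;
2. of those, genes expressed under the phenotype-inducing growth condition
   (TPM above a threshold, default any mapped read);
3. of those, genes tagged as core biosynthetic by a signature-domain rule:
   polyketide-synthase ketosynthase (KS) domains and condensation +
   adenylation (C+A) pairs of non-ribosomal peptide synthetases define core
   genes directly; thioesterases (TE) and cluster-support genes
   (phosphopantetheinyl transferases, epimerase/dehydratases) are pulled in
   by adjacency/proximity to a core gene.  Core genes within a gap window
   form biosynthetic gene cluster (BGC) regions.

An optional final stage intersects with genes recurrently hit in a mutant
screen (see :mod:`linafunnel.screen`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "PresenceAbsenceMatrix",
    "ExpressionTable",
    "DomainAnnotation",
    "BgcRegion",
    "CandidateReport",
    "DOMAIN_VOCABULARY",
    "DEFAULT_SIGNATURE",
    "DEFAULT_WINDOW_NT",
    "unique_to_clade",
    "tpm",
    "expressed_genes",
    "call_bgc_core",
    "run_funnel",
]

DOMAIN_VOCABULARY = frozenset(
    {"KS", "AT", "DH", "KR", "ACP", "C", "A", "PCP", "TE", "PPTASE", "EPIM_DH", "OTHER"}
)

#: signature table for the simplified BGC-core rule.  ``primary_any``: a gene
#: with any of these domains is core; ``primary_all``: a gene carrying all
#: domains of any listed group is core; ``adjacent``: core when an immediate
#: gene-order neighbour is core; ``proximal``: core when within the gap
#: window of a core gene.
DEFAULT_SIGNATURE: dict[str, list] = {
    "primary_any": ["KS"],
    "primary_all": [["C", "A"]],
    "adjacent": ["TE"],
    "proximal": ["PPTASE", "EPIM_DH"],
}

DEFAULT_WINDOW_NT = 10_000


class PresenceAbsenceMatrix:
    """Gene clusters x genomes occupancy, cells holding locus tags or absent.

    Mirrors the pan-genome ``gene_presence_absence`` summary produced by
    ortholog clustering: one row per gene cluster, one column per genome,
    each occupied cell carrying that genome's locus tag for the cluster.
    """

    def __init__(
        self,
        occupancy: pd.DataFrame,
        annotation: pd.Series | None = None,
    ) -> None:
        if occupancy.columns.duplicated().any():
            dupes = occupancy.columns[occupancy.columns.duplicated()].tolist()
            raise InputError(f"duplicate genome columns: {dupes}")
        if occupancy.index.duplicated().any():
            dupes = occupancy.index[occupancy.index.duplicated()].tolist()
            raise InputError(f"duplicate gene cluster ids: {dupes}")
        self.occupancy = occupancy.fillna("").astype(str)
        if annotation is None:
            annotation = pd.Series("", index=occupancy.index, dtype=str)
        self.annotation = annotation.reindex(occupancy.index).fillna("").astype(str)

    @property
    def gene_cluster_ids(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.occupancy.columns)

    def present(self) -> pd.DataFrame:
        """Boolean presence mask (non-empty cell = present)."""
        return self.occupancy != ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self.occupancy.equals(other.occupancy) and self.annotation.equals(
            other.annotation
        )


@dataclass
class ExpressionTable:
    """Per-gene raw counts, effective lengths, and TPM for one sample."""

    frame: pd.DataFrame  # columns: gene_id (index), count, length, tpm

    @classmethod
    def from_counts(
        cls, gene_ids: Sequence[str], counts: Sequence[int], lengths: Sequence[float]
    ) -> "ExpressionTable":
        counts = np.asarray(counts)
        lengths = np.asarray(lengths, dtype=float)
        frame = pd.DataFrame(
            {"count": counts, "length": lengths, "tpm": tpm(counts, lengths)},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        if frame.index.duplicated().any():
            raise InputError("duplicate gene ids in expression table")
        return cls(frame)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tpm(self) -> pd.Series:
        return self.frame["tpm"]


@dataclass(frozen=True)
class DomainAnnotation:
    """A gene model with its functional-domain content and coordinates."""

    gene_id: str
    domains: tuple[str, ...]
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if self.start > self.end:
            raise InputError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be + or -")
        unknown = set(self.domains) - DOMAIN_VOCABULARY
        if unknown:
            raise InputError(f"{self.gene_id}: unknown domain labels {sorted(unknown)}")


@dataclass(frozen=True)
class BgcRegion:
    """A maximal run of core biosynthetic genes separated by gaps <= window."""

    contig: str
    start: int
    end: int
    core_gene_ids: tuple[str, ...]


@dataclass
class CandidateReport:
    """Nested funnel stage sets with counts and the full decision record."""

    stage_sets: dict[str, set[str]]
    parameters: dict

    @property
    def stage_counts(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.stage_sets.items()}

    def to_dict(self) -> dict:
        return {
            "stages": {name: sorted(s) for name, s in self.stage_sets.items()},
            "stage_counts": self.stage_counts,
            "parameters": self.parameters,
        }


def unique_to_clade(
    matrix: PresenceAbsenceMatrix,
    target_ids: Sequence[str],
    mode: Literal["all", "any"] = "all",
    reference_id: str | None = None,
) -> set[str]:
    """Genes present only in the target clade's genomes.

    Under ``mode="all"`` (default) a cluster qualifies when present in every
    target genome and absent from every non-target genome; ``mode="any"``
    relaxes presence to at least one target.  Returns the qualifying
    clusters' locus tags in the reference target genome (default: the first
    target id given).
    """
    targets = list(dict.fromkeys(target_ids))
    if not targets:
        raise InputError("target_ids is empty")
    unknown = [t for t in targets if t not in matrix.genome_ids]
    if unknown:
        raise InputError(f"unknown genome ids: {unknown}")
    others = [g for g in matrix.genome_ids if g not in targets]
    if not others:
        raise InputError("target_ids must be a proper subset of the genomes")
    if reference_id is None:
        reference_id = targets[0]
    if reference_id not in targets:
        raise InputError(f"reference_id {reference_id!r} is not a target genome")

    present = matrix.present()
    in_targets = present[targets]
    hit_targets = in_targets.all(axis=1) if mode == "all" else in_targets.any(axis=1)
    if mode not in ("all", "any"):
        raise InputError(f"unknown uniqueness mode {mode!r}")
    clean_elsewhere = ~present[others].any(axis=1)
    clusters = matrix.occupancy.index[hit_targets & clean_elsewhere]

    tags: set[str] = set()
    for cluster in clusters:
        tag = matrix.occupancy.at[cluster, reference_id]
        if tag == "":
            # mode="any" cluster absent from the reference: fall back to the
            # first occupied target column
            for t in targets:
                if matrix.occupancy.at[cluster, t] != "":
                    tag = matrix.occupancy.at[cluster, t]
                    break
        tags.add(tag)
    return tags


def tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million normalization.

    ``rate_i = count_i / length_i``; ``tpm_i = 1e6 * rate_i / sum(rate)``.
    The result sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise InputError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise InputError("gene lengths must be positive")
    if np.any(counts < 0):
        raise InputError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise InputError("all counts are zero: TPM normalization is undefined")
    return 1e6 * rates / total


def expressed_genes(table: ExpressionTable, threshold: float = 0.0) -> set[str]:
    """Genes with TPM strictly above ``threshold`` (default: any mapped read)."""
    return set(table.frame.index[table.frame["tpm"] > threshold])


def _is_primary_core(domains: Iterable[str], signature: Mapping[str, list]) -> bool:
    ds = set(domains)
    if ds & set(signature.get("primary_any", [])):
        return True
    return any(set(group) <= ds for group in signature.get("primary_all", []))


def _gap_nt(a: DomainAnnotation, b: DomainAnnotation) -> int:
    """Nucleotides strictly between two gene intervals (0 if overlapping)."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def call_bgc_core(
    annotations: Sequence[DomainAnnotation],
    window_nt: int = DEFAULT_WINDOW_NT,
    signature: Mapping[str, list] = DEFAULT_SIGNATURE,
) -> tuple[list[BgcRegion], set[str]]:
    """Tag core biosynthetic genes and group them into BGC regions.

    A gene is core iff it carries a primary signature (any ``primary_any``
    domain, or all domains of a ``primary_all`` group), or it carries an
    ``adjacent``-class domain and an immediate neighbour in gene order is
    core, or a ``proximal``-class domain and some core gene lies within
    ``window_nt``.  Dependent classes are resolved to a fixed point so
    chains of support genes attach.  Regions are maximal runs of core genes
    on one contig whose successive gaps are <= ``window_nt``.
    """
    by_contig: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig, []).append(ann)

    core: set[str] = set()
    for contig, genes in by_contig.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        is_core = [_is_primary_core(g.domains, signature) for g in genes]
        adjacent = set(signature.get("adjacent", []))
        proximal = set(signature.get("proximal", []))
        changed = True
        while changed:
            changed = False
            for i, g in enumerate(genes):
                if is_core[i]:
                    continue
                ds = set(g.domains)
                if ds & adjacent:
                    neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(genes)]
                    if any(is_core[j] for j in neighbours):
                        is_core[i] = True
                        changed = True
                        continue
                if ds & proximal:
                    if any(
                        is_core[j] and _gap_nt(g, genes[j]) <= window_nt
                        for j in range(len(genes))
                        if j != i
                    ):
                        is_core[i] = True
                        changed = True
        core.update(g.gene_id for g, c in zip(genes, is_core) if c)

    regions: list[BgcRegion] = []
    for contig in sorted(by_contig):
        genes = by_contig[contig]
        run: list[DomainAnnotation] = []
        for g in genes:
            if g.gene_id not in core:
                continue
            if run and _gap_nt(run[-1], g) > window_nt:
                regions.append(
                    BgcRegion(contig, run[0].start, max(x.end for x in run),
                              tuple(x.gene_id for x in run))
                )
                run = []
            run.append(g)
        if run:
            regions.append(
                BgcRegion(contig, run[0].start, max(x.end for x in run),
                          tuple(x.gene_id for x in run))
            )
    return regions, core


def run_funnel(
    matrix: PresenceAbsenceMatrix,
    expression: ExpressionTable,
    annotations: Sequence[DomainAnnotation],
    target_ids: Sequence[str],
    screen_hits: set[str] | None = None,
    uniqueness_mode: Literal["all", "any"] = "all",
    tpm_threshold: float = 0.0,
    window_nt: int = DEFAULT_WINDOW_NT,
    signature: Mapping[str, list] = DEFAULT_SIGNATURE,
) -> CandidateReport:
    """Run the nested candidate funnel and assemble the report.

    Stage sets: ``unique`` -> ``unique_expressed`` -> ``unique_expressed_bgc_core``
    and, when ``screen_hits`` is given, ``screen_supported``.  Gene ids are
    the reference target genome's locus tags throughout; unique genes missing
    from the expression table indicate a namespace mismatch and raise.
    """
    unique = unique_to_clade(matrix, target_ids, mode=uniqueness_mode)
    known = set(expression.gene_ids)
    unmatched = sorted(unique - known)
    if unmatched:
        preview = ", ".join(unmatched[:10])
        raise InputError(
            f"{len(unmatched)} unique gene ids missing from the expression table "
            f"(namespace mismatch): {preview}"
        )
    expressed = unique & expressed_genes(expression, tpm_threshold)
    regions, core = call_bgc_core(annotations, window_nt=window_nt, signature=signature)
    bgc_stage = expressed & core

    stages: dict[str, set[str]] = {
        "unique": unique,
        "unique_expressed": expressed,
        "unique_expressed_bgc_core": bgc_stage,
    }
    if screen_hits is not None:
        stages["screen_supported"] = bgc_stage & set(screen_hits)

    parameters = {
        "target_ids": list(target_ids),
        "uniqueness_mode": uniqueness_mode,
        "tpm_threshold": tpm_threshold,
        "window_nt": window_nt,
        "signature": {k: list(v) for k, v in signature.items()},
        "screen_hits_provided": screen_hits is not None,
        "n_bgc_regions": len(regions),
    }
    return CandidateReport(stage_sets=stages, parameters=parameters)
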