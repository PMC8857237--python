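"""Readers and writers for every pipeline format, plus the end-to-end run.

Formats handled: droplet-assay CSV, freezing-spectrum CSV, Roary-style
``gene_presence_absence.csv`` (reduced two-meta-column dialect or the full
14-column header), expression TSV, GFF3 gene models with domain attributes,
FASTA, per-strain VCF, phenotype TSV, and the versioned JSON report.
``run_all`` chains the three analysis stages and logs the candidate-count
trail, one line per stage.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .assay import DropletSeries, FreezingSpectrum, ina_detectable, spectrum_from_assay
from .errors import InputError, StageError
from .funnel import (
    DEFAULT_SIGNATURE,
    DEFAULT_WINDOW_NT,
    DomainAnnotation,
    ExpressionTable,
    PresenceAbsenceMatrix,
    run_funnel,
)
from .screen import (
    GeneModel,
    MutantRecord,
    VariantCall,
    annotate_all,
    filter_artifacts,
    recurrently_hit_genes,
)

log = logging.getLogger("linafunnel")

REPORT_SCHEMA_VERSION = "1.0"

#: the full Roary gene_presence_absence.csv meta columns; only Gene and
#: Annotation are used, the rest are accepted and ignored
ROARY_META_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
]


# ---------------------------------------------------------------------------
# assay CSV / spectrum CSV

ASSAY_COLUMNS = [
    "strain", "replicate", "dilution_factor", "cfu_per_drop",
    "temperature_c", "n_drops", "frozen",
]


def write_assay_csv(series: Iterable[DropletSeries], path) -> None:
    rows = []
    for s in series:
        for t, f in zip(s.temperatures, s.frozen_counts):
            rows.append(
                (s.strain_id, s.replicate, s.dilution_factor, s.cfu_per_drop,
                 t, s.n_drops, f)
            )
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, index=False)


def read_assay_csv(path) -> dict[str, list[DropletSeries]]:
    """Read a long-format assay table into per-strain droplet series."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing assay columns {missing}")
    out: dict[str, list[DropletSeries]] = {}
    keys = ["strain", "replicate", "dilution_factor", "cfu_per_drop", "n_drops"]
    for (strain, rep, dil, a, n0), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("temperature_c", ascending=False)
        out.setdefault(str(strain), []).append(
            DropletSeries(
                strain_id=str(strain),
                replicate=int(rep),
                dilution_factor=float(dil),
                cfu_per_drop=float(a),
                temperatures=tuple(grp["temperature_c"]),
                n_drops=int(n0),
                frozen_counts=tuple(int(x) for x in grp["frozen"]),
            )
        )
    if not out:
        raise InputError(f"{path}: empty assay table")
    return out


def write_spectrum_csv(spectra: Iterable[FreezingSpectrum], path) -> None:
    rows = [
        (sp.strain_id, t, k, c, n)
        for sp in spectra
        for t, k, c, n in zip(sp.temperatures, sp.k_per_cfu, sp.censored, sp.n_series_used)
    ]
    pd.DataFrame(
        rows, columns=["strain", "temperature_c", "k_per_cfu", "censored", "n_series_used"]
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> dict[str, FreezingSpectrum]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for strain, grp in df.groupby("strain", sort=True):
        grp = grp.sort_values("temperature_c", ascending=False)
        out[str(strain)] = FreezingSpectrum(
            strain_id=str(strain),
            temperatures=tuple(grp["temperature_c"]),
            k_per_cfu=tuple(grp["k_per_cfu"]),
            censored=tuple(bool(x) for x in grp["censored"]),
            n_series_used=tuple(int(x) for x in grp["n_series_used"]),
        )
    return out


# ---------------------------------------------------------------------------
# presence/absence matrix (Roary dialect)


def read_presence_absence(path) -> PresenceAbsenceMatrix:
    """Read a Roary-style gene_presence_absence.csv.

    Accepts the reduced dialect (``Gene,Annotation,<genome...>``) and the
    full 14-meta-column Roary header (extra meta columns ignored).  Empty
    cells are absences; occupied cells carry the genome's locus tag.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputError(f"{path}: empty file") from None
        if header[: len(ROARY_META_COLUMNS)] == ROARY_META_COLUMNS:
            n_meta = len(ROARY_META_COLUMNS)
            ann_idx = 2
        elif header[:2] == ["Gene", "Annotation"]:
            n_meta = 2
            ann_idx = 1
        else:
            raise InputError(
                f"{path}: unrecognized header (expected Roary dialect), got "
                f"{header[:3]}..."
            )
        genomes = header[n_meta:]
        if not genomes:
            raise InputError(f"{path}: no genome columns")
        dupes = sorted({g for g in genomes if genomes.count(g) > 1})
        if dupes:
            raise InputError(f"{path}: duplicate genome columns {dupes}")
        clusters, annotations, cells = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise InputError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, "
                    f"expected {len(header)})"
                )
            clusters.append(row[0])
            annotations.append(row[ann_idx])
            cells.append(row[n_meta:])
    occupancy = pd.DataFrame(cells, index=pd.Index(clusters, name="Gene"), columns=genomes)
    annotation = pd.Series(annotations, index=occupancy.index)
    return PresenceAbsenceMatrix(occupancy, annotation)


def write_presence_absence(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write the reduced dialect: Gene,Annotation,<one column per genome>."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Gene", "Annotation"] + matrix.genome_ids)
        for cluster in matrix.gene_cluster_ids:
            writer.writerow(
                [cluster, matrix.annotation.at[cluster]]
                + [matrix.occupancy.at[cluster, g] for g in matrix.genome_ids]
            )


# ---------------------------------------------------------------------------
# expression TSV


def write_expression_tsv(table: ExpressionTable, path) -> None:
    table.frame[["count", "length"]].to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "count", "length"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return ExpressionTable.from_counts(
        df["gene_id"].astype(str).tolist(), df["count"].to_numpy(), df["length"].to_numpy()
    )


# ---------------------------------------------------------------------------
# GFF3 gene models + domain annotations


def write_gff3(
    gene_models: Sequence[GeneModel],
    annotations: Sequence[DomainAnnotation],
    path,
) -> None:
    """Write CDS features with product/domain attributes in column 9."""
    domains_by_id = {a.gene_id: a.domains for a in annotations}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            doms = domains_by_id.get(g.gene_id, ())
            if doms:
                attrs.append("domains=" + ",".join(doms))
            if g.is_insertion_sequence:
                attrs.append("mobile_element_type=insertion sequence")
            fh.write(
                "\t".join(
                    [
                        g.contig, "linafunnel", "CDS", str(g.cds_start),
                        str(g.cds_end), ".", g.strand, "0", ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> tuple[list[GeneModel], list[DomainAnnotation]]:
    """Read CDS features into gene models and domain annotations.

    Artifact-rule flags are derived from the ``product`` and
    ``mobile_element_type`` attributes and the CDS length; domain content
    comes from a ``domains=`` attribute (comma-separated labels).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_models: list[GeneModel] = []
    annotations: list[DomainAnnotation] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        mobile = "mobile_element_type" in feat.attributes
        gene_models.append(
            GeneModel.with_derived_flags(
                gid, feat.seqid, feat.strand, feat.start, feat.end,
                product=product, mobile_element=mobile,
            )
        )
        doms = feat.attributes.get("domains", [])
        domain_list = tuple(d for chunk in doms for d in chunk.split(",") if d)
        annotations.append(
            DomainAnnotation(gid, domain_list, feat.seqid, feat.start, feat.end, feat.strand)
        )
    return gene_models, annotations


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    variants: Sequence[VariantCall], contigs: Mapping[str, int], path
) -> None:
    """Write one strain's variants as a sites-only VCF."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.contig, x.pos, x.alt_allele)):
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.filter.add("PASS")
            out.write(rec)


def read_vcf(path, strain_id: str | None = None, pass_only: bool = False) -> list[VariantCall]:
    """Read one VCF into variant calls; kind is classified from allele lengths."""
    strain = strain_id or Path(path).stem
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"{path}: cannot parse VCF ({exc})") from exc
    with vcf:
        for rec in vcf:
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is None:
                continue
            for alt in rec.alts:
                calls.append(
                    VariantCall(strain, rec.contig, rec.pos, rec.ref, str(alt))
                )
    return calls


def read_variants(path, pass_only: bool = False) -> dict[str, list[VariantCall]]:
    """Read per-strain VCFs from a directory (``<strain>.vcf``) or one file."""
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.vcf"))
        if not files:
            raise InputError(f"{path}: no .vcf files found")
        return {f.stem: read_vcf(f, pass_only=pass_only) for f in files}
    return {p.stem: read_vcf(p, pass_only=pass_only)}


def write_phenotypes_tsv(phenotypes: Sequence[MutantRecord], path) -> None:
    pd.DataFrame(
        [(m.strain_id, m.phenotype) for m in phenotypes],
        columns=["strain", "phenotype"],
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> list[MutantRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("strain", "phenotype"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return [MutantRecord(str(r.strain), str(r.phenotype)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# bundle writing (synthetic fixtures)


def write_bundle(bundle, out_dir) -> dict[str, str]:
    """Write a synthetic :class:`~linafunnel.simulate.FixtureBundle` to disk.

    Emits exactly the formats the pipeline consumes plus ``manifest.json``
    with the planted truth.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": str(out / "gene_presence_absence.csv"),
        "expression": str(out / "expression.tsv"),
        "gff": str(out / "genes.gff3"),
        "fasta": str(out / "genome.fasta"),
        "vcf_dir": str(out / "vcf"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "assay": str(out / "assay.csv"),
        "manifest": str(out / "manifest.json"),
    }
    write_presence_absence(bundle.matrix, paths["matrix"])
    write_expression_tsv(bundle.expression, paths["expression"])
    write_gff3(bundle.bgc.gene_models, bundle.bgc.annotations, paths["gff"])
    write_fasta(bundle.bgc.genome, paths["fasta"])
    vcf_dir = Path(paths["vcf_dir"])
    vcf_dir.mkdir(exist_ok=True)
    contigs = {name: len(seq) for name, seq in bundle.bgc.genome.items()}
    for strain in sorted(bundle.variants):
        write_vcf(bundle.variants[strain], contigs, vcf_dir / f"{strain}.vcf")
    write_phenotypes_tsv(bundle.phenotypes, paths["phenotypes"])
    all_series = [s for strain in sorted(bundle.assays) for s in bundle.assays[strain]]
    write_assay_csv(all_series + bundle.control, paths["assay"])
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# pipeline configuration and the end-to-end run


@dataclasses.dataclass
class PipelineConfig:
    """Input paths and every decision parameter for one end-to-end run."""

    matrix: str
    expression: str
    gff: str
    fasta: str
    vcf_dir: str
    phenotypes: str
    target_ids: list[str]
    assay: str | None = None
    control_strain: str = "water"
    uniqueness_mode: str = "all"
    tpm_threshold: float = 0.0
    window_nt: int = DEFAULT_WINDOW_NT
    signature: dict = dataclasses.field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURE.items()}
    )
    artifact_mode: str = "and"
    min_strains: int = 2
    include_reduced: bool = False
    alpha: float = 0.05
    combine: str = "weighted"
    pass_only: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise InputError(f"{path}: unknown config keys {unknown}")
        missing = [
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
            and f.name not in raw
        ]
        if missing:
            raise InputError(f"{path}: missing required config keys {missing}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_all(config: PipelineConfig) -> dict:
    """Execute assay spectra, the candidate funnel, and the mutant screen.

    Returns the versioned report: per-strain spectra and detection calls,
    the funnel stage sets and counts, the ranked recurrently-hit genes, the
    artifact removal log, and the full parameter echo.  Stage failures after
    input validation raise :class:`~linafunnel.errors.StageError` with
    partial results attached.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "parameters": config.to_dict(),
    }

    # stage 1: freezing spectra and detection calls
    if config.assay:
        assays = read_assay_csv(config.assay)
        control = assays.pop(config.control_strain, None)
        spectra = {}
        detection = {}
        for strain in sorted(assays):
            spectra[strain] = spectrum_from_assay(assays[strain], combine=config.combine)
            if control is not None:
                detection[strain] = ina_detectable(
                    assays[strain], control, alpha=config.alpha
                )
        report["spectra"] = {
            strain: {
                "temperature_c": list(sp.temperatures),
                "k_per_cfu": list(sp.k_per_cfu),
                "censored": list(sp.censored),
                "n_series_used": list(sp.n_series_used),
            }
            for strain, sp in spectra.items()
        }
        report["ina_detectable"] = detection
        log.info("assay: %d strains profiled, %d detectable",
                 len(spectra), sum(detection.values()))

    # stage 2: mutant screen (first, so the funnel can take its hits)
    try:
        genome = read_fasta(config.fasta)
        gene_models, annotations = read_gff3(config.gff)
        variants_by_strain = read_variants(config.vcf_dir, pass_only=config.pass_only)
        phenotypes = read_phenotypes_tsv(config.phenotypes)
        all_variants = [
            v for strain in sorted(variants_by_strain)
            for v in variants_by_strain[strain]
        ]
        annotated = annotate_all(all_variants, gene_models, genome)
        kept, removal_log = filter_artifacts(annotated, gene_models, mode=config.artifact_mode)
        hits = recurrently_hit_genes(
            kept, phenotypes,
            min_strains=config.min_strains,
            include_reduced=config.include_reduced,
        )
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        report["failure"] = {"stage": "screen", "error": str(exc)}
        raise StageError(f"mutant screen failed: {exc}") from exc
    log.info(
        "screen: %d variants in %d strains, %d removed as artifacts, %d genes at "
        ">=%d strains",
        len(all_variants), len(variants_by_strain), len(removal_log), len(hits),
        config.min_strains,
    )
    report["screen"] = {
        "ranked_genes": [
            {
                "gene_id": h.gene_id,
                "n_lost_strains": h.n_strains,
                "strains": list(h.strains),
                "variants": [
                    f"{v.strain_id}:{v.contig}:{v.pos}:{v.ref_allele}>{v.alt_allele}"
                    f":{v.effect}"
                    for v in h.variants
                ],
            }
            for h in hits
        ],
        "removal_log": removal_log,
    }

    # stage 3: the funnel, intersected with the screen hits
    matrix = read_presence_absence(config.matrix)
    expression = read_expression_tsv(config.expression)
    funnel_report = run_funnel(
        matrix,
        expression,
        annotations,
        target_ids=config.target_ids,
        screen_hits={h.gene_id for h in hits},
        uniqueness_mode=config.uniqueness_mode,
        tpm_threshold=config.tpm_threshold,
        window_nt=config.window_nt,
        signature=config.signature,
    )
    for stage, count in funnel_report.stage_counts.items():
        log.info("funnel: %s -> %d genes", stage, count)
    report["funnel"] = funnel_report.to_dict()
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_report(report: dict) -> str:
    """A short human-readable account of one run."""
    lines = [f"linafunnel {report.get('tool_version', '?')} report"]
    if "funnel" in report:
        for stage, count in report["funnel"]["stage_counts"].items():
            lines.append(f"  funnel {stage}: {count}")
    if "screen" in report:
        for h in report["screen"]["ranked_genes"]:
            lines.append(
                f"  screen hit {h['gene_id']}: {h['n_lost_strains']} strains"
            )
        lines.append(
            f"  artifacts removed: {len(report['screen']['removal_log'])}"
        )
    if "ina_detectable" in report:
        pos = sorted(s for s, d in report["ina_detectable"].items() if d)
        lines.append(f"  INA detectable: {', '.join(pos) if pos else 'none'}")
    return "\n".join(lines)
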