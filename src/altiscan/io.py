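"""Readers and writers for the standard formats the pipeline consumes.

VCF is parsed with pysam, GFF3 with gffutils (in-memory database), FASTA
with pyfaidx.  All coordinate conversion to the package's internal
0-based half-open convention happens here and nowhere else.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import gffutils
import pysam
from pyfaidx import Fasta

from .datamodel import (
    HAPLOID_CONTIGS,
    CdsFeature,
    GeneSpan,
    GenomeAnnotation,
    Population,
    PopulationCallSet,
    SampleMeta,
    VariantKey,
    VariantRecord,
    classify_variant_type,
)

__all__ = [
    "read_population_vcfs",
    "read_known_vcf",
    "read_genome_annotation",
    "read_sample_manifest",
    "write_variant_table",
    "read_variant_table",
    "VARIANT_TABLE_COLUMNS",
]

PathLike = Union[str, Path]

VARIANT_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "carriers", "known"]


def _split_genotype(
    alleles: Tuple[Optional[int], ...], alt_index: int, chrom: str
) -> Tuple[int, ...]:
    """Project a (possibly multi-allelic) genotype onto one alternate allele.

    Allele index ``alt_index`` maps to 1, everything else (including other
    alternates and missing calls) to 0, so per-alt carrier counts over the
    split records conserve the carriers of the original line.  Diploid
    calls on haploid contigs (MT, W) are collapsed to a single allele.
    """
    coded = tuple(1 if a == alt_index else 0 for a in alleles if a is not None)
    if not coded:
        coded = (0,)
    if chrom in HAPLOID_CONTIGS and len(coded) > 1:
        coded = (1,) if any(coded) else (0,)
    return coded


def read_population_vcfs(
    paths: Sequence[PathLike], meta: Sequence[SampleMeta]
) -> PopulationCallSet:
    """Read one or more (single- or multi-sample) VCFs into a call set.

    Multi-allelic lines are split into one record per alternate allele.
    Carriers are the samples whose genotype contains that alternate.
    Samples named in the VCFs must be declared in ``meta``, all with the
    same population label.
    """
    metas = list(meta)
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    populations = {m.population for m in metas}
    if len(populations) != 1:
        raise ValueError(f"metadata mixes populations: {sorted(p.value for p in populations)}")
    by_id = {m.sample_id: m for m in metas}

    genotypes: Dict[VariantKey, Dict[str, Tuple[int, ...]]] = {}
    for path in paths:
        with pysam.VariantFile(str(path)) as vcf:
            vcf_samples = list(vcf.header.samples)
            unknown = [s for s in vcf_samples if s not in by_id]
            if unknown:
                raise ValueError(f"{path}: samples not in manifest: {unknown}")
            for rec in vcf:
                if rec.alts is None:
                    continue
                for alt_index, alt in enumerate(rec.alts, start=1):
                    if alt is None or set(alt) - set("ACGT"):
                        continue  # symbolic/spanning alleles out of scope
                    try:
                        key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                    except ValueError as exc:
                        raise ValueError(f"{path}: bad record at line {rec.chrom}:{rec.pos}: {exc}")
                    site = genotypes.setdefault(key, {})
                    for s in vcf_samples:
                        alleles = rec.samples[s].get("GT", (None,))
                        gt = _split_genotype(tuple(alleles), alt_index, rec.chrom)
                        if s in site and site[s] != gt and any(site[s]) != any(gt):
                            raise ValueError(
                                f"{path}: conflicting genotypes for {s} at {key.chrom}:{key.pos}"
                            )
                        if s not in site or any(gt):
                            site[s] = gt

    records = {
        key: VariantRecord.from_genotypes(key, gts) for key, gts in genotypes.items()
    }
    return PopulationCallSet(population=metas[0].population, samples=metas, records=records)


def read_known_vcf(path: PathLike) -> Set[VariantKey]:
    """Parse a known-variants (dbSNP-like) VCF into a set of keys."""
    keys: Set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or set(alt) - set("ACGT"):
                    continue
                keys.add(VariantKey(rec.chrom, rec.pos, rec.ref, alt))
    return keys


def read_genome_annotation(
    gff_path: PathLike, fasta_path: Optional[PathLike] = None
) -> GenomeAnnotation:
    """Load gene spans and CDS exons from GFF3; contig lengths come from
    the FASTA index when given, else from ``##sequence-region`` pragmas."""
    contig_lengths: Dict[str, int] = {}
    if fasta_path is not None:
        fa = Fasta(str(fasta_path))
        contig_lengths = {name: len(fa[name]) for name in fa.keys()}
    else:
        with open(gff_path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, name, _start, end = line.split()[:4]
                    contig_lengths[name] = int(end)
                elif not line.startswith("#"):
                    break

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    cds_features: List[CdsFeature] = []
    for f in db.features_of_type("CDS"):
        parents = [p.id for p in db.parents(f, featuretype="mRNA")]
        transcript_id = parents[0] if parents else f.attributes.get("Parent", ["?"])[0]
        gene_ids = [g.id for g in db.parents(f, featuretype="gene")]
        gene_id = gene_ids[0] if gene_ids else transcript_id
        frame = int(f.frame) if f.frame not in (None, ".") else 0
        cds_features.append(
            CdsFeature(
                contig=f.seqid,
                start=f.start - 1,  # GFF3 1-based inclusive -> half-open
                end=f.end,
                strand=f.strand,
                frame=frame,
                gene_id=gene_id,
                transcript_id=transcript_id,
            )
        )
    gene_spans = [
        GeneSpan(contig=g.seqid, start=g.start - 1, end=g.end, gene_id=g.id)
        for g in db.features_of_type("gene")
    ]
    ann = GenomeAnnotation(
        contig_lengths=contig_lengths,
        cds_features=cds_features,
        gene_spans=gene_spans,
    )
    ann.validate_cds_lengths()
    return ann


def read_sample_manifest(path: PathLike) -> List[Tuple[SampleMeta, str]]:
    """Read a TSV manifest with columns sample_id, population, sex, vcf_path."""
    out: List[Tuple[SampleMeta, str]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                (
                    SampleMeta(row["sample_id"], Population(row["population"]), row["sex"]),
                    row["vcf_path"],
                )
            )
    return out


def write_variant_table(records: Iterable[VariantRecord], path: PathLike) -> None:
    """Write records to a tab-delimited table that round-trips through
    :func:`read_variant_table` (genotypes are not serialised)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_TABLE_COLUMNS)
        for rec in sorted(records, key=lambda r: r.key):
            known = "" if rec.known is None else str(rec.known).lower()
            writer.writerow(
                [
                    rec.key.chrom,
                    rec.key.pos,
                    rec.key.ref,
                    rec.key.alt,
                    rec.vtype.value,
                    ",".join(sorted(rec.carriers)),
                    known,
                ]
            )


def read_variant_table(path: PathLike) -> List[VariantRecord]:
    """Read back a table written by :func:`write_variant_table`.

    Carrier genotypes are reconstructed as carrying one alternate allele;
    allele dosage is not stored in the table.
    """
    records: List[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != VARIANT_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {reader.fieldnames}")
        for row in reader:
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            carriers = frozenset(c for c in row["carriers"].split(",") if c)
            ploidy = 1 if key.chrom in HAPLOID_CONTIGS else 2
            genotypes = {c: (1,) * min(1, ploidy) + (0,) * (ploidy - 1) for c in carriers}
            known = None if row["known"] == "" else row["known"] == "true"
            rec = VariantRecord(
                key=key,
                vtype=classify_variant_type(key),
                carriers=carriers,
                genotypes=genotypes,
                known=known,
            )
            if rec.vtype.value != row["vtype"]:
                raise ValueError(f"{path}: vtype column disagrees with alleles at {key}")
            records.append(rec)
    return records
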