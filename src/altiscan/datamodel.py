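"""Canonical in-memory model for variants, samples and genome annotation.

Conventions used throughout the package:

* VCF and GFF3 coordinates are 1-based inclusive on disk; every internal
  interval is 0-based half-open.  Conversion happens only at the I/O
  boundary (:mod:`altiscan.io`).
* Variant identity is the literal tuple ``(chrom, pos, ref, alt)`` with
  ``pos`` the 1-based position of the first reference base.  No
  normalisation (left-alignment, trimming) is applied: call sets are
  compared on the coordinates the caller emitted.
* Genotypes are tuples of allele indices relative to one alternate allele
  (0 = reference, 1 = the record's alternate); diploid tuples have length
  two, haploid calls (MT, W) length one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "Population",
    "Sex",
    "VariantType",
    "SampleMeta",
    "VariantKey",
    "VariantRecord",
    "PopulationCallSet",
    "CdsFeature",
    "GeneSpan",
    "GenomeAnnotation",
    "CoverageParams",
    "classify_variant_type",
    "lander_waterman_coverage",
    "HAPLOID_CONTIGS",
]

#: Contigs carried in a single copy per bird (mitochondrion; W in females,
#: Z in females is likewise hemizygous but handled per-sample at I/O time).
HAPLOID_CONTIGS = frozenset({"MT", "W"})

_VALID_BASES = frozenset("ACGT")


class Population(str, Enum):
    HIGHLAND = "highland"
    LOWLAND = "lowland"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class VariantType(str, Enum):
    SNV = "SNV"
    MNV = "MNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    REPLACEMENT = "replacement"


@dataclass(frozen=True)
class SampleMeta:
    """Identity and study labels for one sequenced individual."""

    sample_id: str
    population: Population
    sex: Sex

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        object.__setattr__(self, "population", Population(self.population))
        object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True, order=True)
class VariantKey:
    """Positional identity of one called variant (one alternate allele)."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def start(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.pos - 1 + len(self.ref)


def classify_variant_type(key: VariantKey) -> VariantType:
    """Assign one of the five caller variant classes to a key.

    SNV: single-base substitution; MNV: equal-length multi-base
    substitution; insertion/deletion: the shorter allele is a prefix of
    the longer; replacement: any other length-changing edit.  The classes
    partition all valid keys.
    """
    ref, alt = key.ref, key.alt
    if len(ref) == len(alt):
        return VariantType.SNV if len(ref) == 1 else VariantType.MNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VariantType.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantType.DELETION
    return VariantType.REPLACEMENT


@dataclass
class VariantRecord:
    """One variant with its per-sample genotype evidence."""

    key: VariantKey
    vtype: VariantType
    carriers: FrozenSet[str]
    genotypes: Dict[str, Tuple[int, ...]]
    known: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.carriers <= set(self.genotypes):
            extra = set(self.carriers) - set(self.genotypes)
            raise ValueError(f"carriers without genotypes: {sorted(extra)}")
        expected = classify_variant_type(self.key)
        if self.vtype != expected:
            raise ValueError(
                f"vtype {self.vtype} inconsistent with key (expected {expected})"
            )

    @classmethod
    def from_genotypes(
        cls,
        key: VariantKey,
        genotypes: Mapping[str, Tuple[int, ...]],
        known: Optional[bool] = None,
    ) -> "VariantRecord":
        carriers = frozenset(s for s, gt in genotypes.items() if any(a == 1 for a in gt))
        return cls(
            key=key,
            vtype=classify_variant_type(key),
            carriers=carriers,
            genotypes=dict(genotypes),
            known=known,
        )


@dataclass
class PopulationCallSet:
    """All variant records observed in one labelled population."""

    population: Population
    samples: List[SampleMeta]
    records: Dict[VariantKey, VariantRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.population = Population(self.population)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in population call set")
        sample_ids = set(ids)
        for rec in self.records.values():
            if not rec.carriers <= sample_ids:
                raise ValueError(
                    f"record {rec.key} has carriers outside population samples"
                )

    def sample_ids(self, sex: Optional[Sex] = None) -> List[str]:
        return [
            s.sample_id
            for s in self.samples
            if sex is None or s.sex == Sex(sex)
        ]

    def keys(self) -> Iterable[VariantKey]:
        return self.records.keys()

    def carrier_count(self, key: VariantKey, sample_ids: Iterable[str]) -> int:
        rec = self.records.get(key)
        if rec is None:
            return 0
        return len(rec.carriers & set(sample_ids))

    def restrict_to_contig(self, contig: str) -> "PopulationCallSet":
        recs = {k: r for k, r in self.records.items() if k.chrom == contig}
        return PopulationCallSet(self.population, list(self.samples), recs)


@dataclass(frozen=True)
class CdsFeature:
    """One CDS exon; coordinates 0-based half-open on the forward strand."""

    contig: str
    start: int
    end: int
    strand: str
    frame: int  # GFF3 phase: bases to skip before the first complete codon
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CDS interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0/1/2, got {self.frame}")


@dataclass(frozen=True)
class GeneSpan:
    contig: str
    start: int  # 0-based half-open
    end: int
    gene_id: str


@dataclass
class GenomeAnnotation:
    """Contig lengths plus gene and CDS features of a reference genome."""

    contig_lengths: Dict[str, int]
    cds_features: List[CdsFeature]
    gene_spans: List[GeneSpan]

    def __post_init__(self) -> None:
        for f in self.cds_features:
            length = self.contig_lengths.get(f.contig)
            if length is not None and f.end > length:
                raise ValueError(
                    f"CDS {f.transcript_id} exceeds contig {f.contig} length"
                )

    def transcript_cds(self, transcript_id: str) -> List[CdsFeature]:
        """CDS exons of one transcript in genomic order."""
        feats = [f for f in self.cds_features if f.transcript_id == transcript_id]
        return sorted(feats, key=lambda f: f.start)

    def validate_cds_lengths(self) -> None:
        """Check that each transcript's CDS totals a whole number of codons."""
        totals: Dict[str, int] = {}
        for f in self.cds_features:
            totals[f.transcript_id] = totals.get(f.transcript_id, 0) + (f.end - f.start)
        bad = {t: n for t, n in totals.items() if n % 3}
        if bad:
            raise ValueError(f"CDS length not divisible by 3 for transcripts: {sorted(bad)}")


@dataclass(frozen=True)
class CoverageParams:
    """Lander-Waterman sequencing design: C = L * N / G."""

    C: float  # fold-coverage
    L: float  # read length (bp)
    N: float  # number of reads
    G: float  # haploid genome length (bp)

    def __post_init__(self) -> None:
        for name in ("C", "L", "N", "G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(self.C, self.L * self.N / self.G, rel_tol=1e-9):
            raise ValueError("C inconsistent with L*N/G")

    @classmethod
    def from_design(cls, L: float, N: float, G: float) -> "CoverageParams":
        return cls(C=lander_waterman_coverage(L, N, G), L=L, N=N, G=G)


def lander_waterman_coverage(L: float, N: float, G: float) -> float:
    """Expected fold-coverage C = L*N/G for read length L, read count N,
    haploid genome length G (all positive)."""
    if L <= 0 or N <= 0 or G <= 0:
        raise ValueError("L, N and G must all be positive")
    return L * N / G
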