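"""Population contrast: differential, common, novel, coding and mtDNA
variant extraction, plus replication-cohort validation.

A variant is *differential* for population A at frequency threshold t
when it is carried by at least one of A's stratum samples, by none of
B's, and its carrier fraction among A's stratum samples is at least
t/100 ("at least" means ties at the threshold are included).  A variant
present in both populations is a common candidate and never differential
at any threshold.  Strata select samples by sex before any fraction is
computed; the carrier-fraction denominator is the number of stratum
samples of the focal population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .datamodel import (
    GenomeAnnotation,
    Population,
    PopulationCallSet,
    Sex,
    VariantKey,
    VariantRecord,
    VariantType,
)

__all__ = [
    "FrequencyThreshold",
    "ContrastResult",
    "CodingConsequence",
    "differential_variants",
    "common_variants",
    "flag_novel",
    "classify_coding",
    "mtdna_classify",
    "validation_percentage",
    "validation_table",
]

STANDARD_THRESHOLDS = (0, 25, 50, 75, 100)


@dataclass(frozen=True)
class FrequencyThreshold:
    """Minimum percent of stratum samples that must carry a variant."""

    percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent <= 100:
            raise ValueError(f"threshold percent must be in [0, 100], got {self.percent}")
        if self.percent not in STANDARD_THRESHOLDS:
            warnings.warn(
                f"threshold {self.percent}% outside the standard set {STANDARD_THRESHOLDS}",
                stacklevel=2,
            )

    @property
    def fraction(self) -> float:
        return self.percent / 100.0


@dataclass
class ContrastResult:
    """Differential and common variants for one stratum and threshold."""

    stratum: str  # "male", "female" or "pooled"
    threshold: FrequencyThreshold
    differential: Dict[Population, Dict[VariantKey, VariantRecord]]
    common: Set[VariantKey]          # present in both populations (any carriage)
    strict_common: Set[VariantKey]   # carried by every stratum sample of both
    below_threshold: Set[VariantKey]  # private but under the carrier fraction
    n_observed: int

    def check_partition(self) -> None:
        """Observed keys are covered exactly once by the four classes."""
        diff_keys = [set(d) for d in self.differential.values()]
        parts = diff_keys + [self.common, self.below_threshold]
        union: Set[VariantKey] = set()
        total = 0
        for part in parts:
            union |= part
            total += len(part)
        if total != len(union) or total != self.n_observed:
            raise AssertionError(
                f"partition violated: {total} classified vs {self.n_observed} observed"
            )


def _stratum_ids(cs: PopulationCallSet, stratum: str) -> List[str]:
    sex = None if stratum == "pooled" else Sex(stratum)
    ids = cs.sample_ids(sex)
    if not ids:
        raise ValueError(f"no {stratum} samples in {cs.population.value} population")
    return ids


def differential_variants(
    a: PopulationCallSet,
    b: PopulationCallSet,
    threshold: FrequencyThreshold,
    stratum: str = "pooled",
) -> ContrastResult:
    """Contrast two call sets within a sex stratum at one threshold."""
    if isinstance(threshold, (int, float)):
        threshold = FrequencyThreshold(threshold)
    ids_a, ids_b = _stratum_ids(a, stratum), _stratum_ids(b, stratum)
    if set(ids_a) & set(ids_b):
        raise ValueError("populations share sample ids")

    observed: Set[VariantKey] = set()
    differential: Dict[Population, Dict[VariantKey, VariantRecord]] = {
        a.population: {},
        b.population: {},
    }
    common: Set[VariantKey] = set()
    below: Set[VariantKey] = set()

    for focal, other, ids_f, ids_o in ((a, b, ids_a, ids_b), (b, a, ids_b, ids_a)):
        for key, rec in focal.records.items():
            n_f = focal.carrier_count(key, ids_f)
            if n_f == 0:
                continue  # not present in this stratum
            observed.add(key)
            if other.carrier_count(key, ids_o) > 0:
                common.add(key)
            elif n_f / len(ids_f) >= threshold.fraction:
                differential[focal.population][key] = rec
            else:
                below.add(key)
    # a key counted from both directions lands in `common` twice -> once;
    # drop from differential/below anything that proved common
    for pop in differential:
        for key in common:
            differential[pop].pop(key, None)
    below -= common

    strict = {
        key
        for key in common
        if a.carrier_count(key, ids_a) == len(ids_a)
        and b.carrier_count(key, ids_b) == len(ids_b)
    }
    result = ContrastResult(
        stratum=stratum,
        threshold=threshold,
        differential=differential,
        common=common,
        strict_common=strict,
        below_threshold=below,
        n_observed=len(observed),
    )
    result.check_partition()
    return result


def common_variants(
    a: PopulationCallSet, b: PopulationCallSet, stratum: str = "pooled"
) -> Tuple[Set[VariantKey], Set[VariantKey]]:
    """Keys present in both populations' stratum samples.

    Returns ``(common_any, common_strict)``: any-carriage in both, and the
    headline subset carried by every stratum sample of both populations
    (the 100%-threshold reading of "all differential variants removed").
    """
    result = differential_variants(a, b, FrequencyThreshold(0), stratum)
    return result.common, result.strict_common


def flag_novel(
    records: Iterable[VariantRecord], known: Set[VariantKey]
) -> List[VariantRecord]:
    """Set each record's ``known`` flag by allele-aware lookup; a record is
    novel when no (chrom, pos, ref, alt) entry matches."""
    out = []
    for rec in records:
        rec.known = rec.key in known
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# coding consequences


@dataclass(frozen=True)
class CodingConsequence:
    key: VariantKey
    gene_id: Optional[str]
    transcript_id: Optional[str]
    region: str  # "coding" | "non-coding"
    effect: Optional[str]  # synonymous | missense | nonsense | other
    aa_change: Optional[Tuple[str, int, str]]  # (ref_aa, codon_index_1based, alt_aa)


class _TranscriptIndex:
    """Per-contig interval trees over CDS exons plus per-transcript maps
    from genomic to CDS coordinates."""

    def __init__(self, ann: GenomeAnnotation):
        self.trees: Dict[str, IntervalTree] = {}
        self.transcripts: Dict[str, List] = {}
        for f in ann.cds_features:
            self.trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
            self.transcripts.setdefault(f.transcript_id, []).append(f)
        for tid in self.transcripts:
            self.transcripts[tid].sort(key=lambda f: f.start)

    def overlapping(self, key: VariantKey):
        tree = self.trees.get(key.chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(key.start, key.end)),
            key=lambda f: (f.transcript_id, f.start),
        )

    def cds_coordinate(self, transcript_id: str, genomic_pos0: int) -> Optional[int]:
        """0-based offset of a genomic position within the spliced CDS,
        in translation order (reversed for minus-strand transcripts)."""
        feats = self.transcripts[transcript_id]
        strand = feats[0].strand
        ordered = feats if strand == "+" else feats[::-1]
        offset = 0
        for f in ordered:
            if f.start <= genomic_pos0 < f.end:
                if strand == "+":
                    return offset + (genomic_pos0 - f.start)
                return offset + (f.end - 1 - genomic_pos0)
            offset += f.end - f.start
        return None

    def cds_sequence(self, transcript_id: str, genome: Fasta) -> str:
        feats = self.transcripts[transcript_id]
        strand = feats[0].strand
        parts = [str(genome[f.contig][f.start : f.end]) for f in feats]
        seq = "".join(parts)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def _substitution_consequence(
    key: VariantKey, tid: str, index: _TranscriptIndex, genome: Fasta
) -> Tuple[Optional[str], Optional[Tuple[str, int, str]]]:
    """Effect of a length-preserving substitution fully inside one
    transcript's CDS; returns (effect, aa_change) or (None, None) when the
    edit does not map contiguously into the spliced CDS."""
    strand = index.transcripts[tid][0].strand
    offsets = []
    for i in range(len(key.ref)):
        off = index.cds_coordinate(tid, key.start + i)
        if off is None:
            return None, None
        offsets.append(off)
    cds = index.cds_sequence(tid, genome)
    alt = key.alt if strand == "+" else str(Seq(key.alt).reverse_complement())
    ref_check = key.ref if strand == "+" else str(Seq(key.ref).reverse_complement())
    # translation-order offsets of successive alt bases
    ordered = offsets if strand == "+" else offsets[::-1]
    if ordered != list(range(ordered[0], ordered[0] + len(key.ref))):
        return None, None  # straddles an intron
    start = ordered[0]
    if cds[start : start + len(alt)] != ref_check:
        raise ValueError(
            f"reference mismatch at {key.chrom}:{key.pos} in transcript {tid}"
        )
    edited = cds[:start] + alt + cds[start + len(alt):]
    first_codon = start // 3
    last_codon = (start + len(alt) - 1) // 3
    ref_aa = str(Seq(cds[first_codon * 3 : (last_codon + 1) * 3]).translate())
    alt_aa = str(Seq(edited[first_codon * 3 : (last_codon + 1) * 3]).translate())
    if ref_aa == alt_aa:
        return "synonymous", None
    changed = [(x, y) for x, y in zip(ref_aa, alt_aa) if x != y]
    if any(y == "*" for _, y in changed):
        effect = "nonsense"  # stop gained
    elif any(x == "*" for x, _ in changed):
        effect = "other"  # stop lost
    else:
        effect = "missense"
    return effect, (ref_aa, first_codon + 1, alt_aa)


def classify_coding(
    records: Iterable[VariantRecord],
    genome: Fasta,
    ann: GenomeAnnotation,
) -> List[CodingConsequence]:
    """Coding/non-coding classification and amino-acid consequences.

    A variant is coding when its reference span intersects any CDS
    interval.  Length-preserving substitutions fully inside one
    transcript's spliced CDS are translated with the standard genetic
    code (minus-strand transcripts via reverse complement); indels and
    boundary-straddling edits get effect "other".  All overlapping
    transcripts are reported (one consequence row each).
    """
    index = _TranscriptIndex(ann)
    out: List[CodingConsequence] = []
    for rec in records:
        feats = index.overlapping(rec.key)
        if not feats:
            out.append(
                CodingConsequence(rec.key, None, None, "non-coding", None, None)
            )
            continue
        seen = set()
        for f in feats:
            if f.transcript_id in seen:
                continue
            seen.add(f.transcript_id)
            if len(rec.key.ref) == len(rec.key.alt):
                effect, aa = _substitution_consequence(rec.key, f.transcript_id, index, genome)
                if effect is None:
                    effect, aa = "other", None
            else:
                effect, aa = "other", None
            out.append(
                CodingConsequence(
                    rec.key, f.gene_id, f.transcript_id, "coding", effect, aa
                )
            )
    return out


def consequence_summary(consequences: Sequence[CodingConsequence]) -> Dict[str, int]:
    """Per-variant rollup: coding/non-coding counts and amino-acid-change
    count (nonsense included, synonymous excluded)."""
    by_key: Dict[VariantKey, List[CodingConsequence]] = {}
    for c in consequences:
        by_key.setdefault(c.key, []).append(c)
    coding = noncoding = aa_changes = 0
    for key, rows in by_key.items():
        if any(r.region == "coding" for r in rows):
            coding += 1
            if any(r.effect in ("missense", "nonsense") for r in rows):
                aa_changes += 1
        else:
            noncoding += 1
    return {"coding": coding, "non_coding": noncoding, "aa_changes": aa_changes}


# ---------------------------------------------------------------------------
# mtDNA table


def mtdna_classify(
    a: PopulationCallSet,
    b: PopulationCallSet,
    known: Set[VariantKey],
    genome: Fasta,
    ann: GenomeAnnotation,
    contig: str = "MT",
) -> pd.DataFrame:
    """Per-(population, sex) classification of mitochondrial variants:
    counts by variant class, novel, coding and amino-acid changes."""
    rows = []
    for cs in (a, b):
        mt = cs.restrict_to_contig(contig)
        for sex in (Sex.MALE, Sex.FEMALE):
            ids = set(cs.sample_ids(sex))
            recs = [r for r in mt.records.values() if r.carriers & ids]
            flag_novel(recs, known)
            cons = classify_coding(recs, genome, ann)
            summary = consequence_summary(cons)
            counts = {vt.value: 0 for vt in VariantType}
            for r in recs:
                counts[r.vtype.value] += 1
            rows.append(
                {
                    "population": cs.population.value,
                    "sex": sex.value,
                    **counts,
                    "total": len(recs),
                    "novel": sum(1 for r in recs if not r.known),
                    "coding": summary["coding"],
                    "aa_changes": summary["aa_changes"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replication validation


def validation_percentage(key: VariantKey, cohort: Sequence[PopulationCallSet]) -> float:
    """Percent of replication samples carrying the variant: 100 * k / n.

    ``cohort`` holds one single-sample call set per replication bird.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty replication cohort")
    k = sum(
        1
        for cs in cohort
        if key in cs.records and cs.records[key].carriers
    )
    return 100.0 * k / n


def validation_table(
    keys: Iterable[VariantKey], cohort: Sequence[PopulationCallSet]
) -> pd.DataFrame:
    rows = [
        {
            "chrom": k.chrom,
            "pos": k.pos,
            "genotype": f"{k.ref}/{k.alt}",
            "validation_pct": validation_percentage(k, cohort),
        }
        for k in sorted(keys)
    ]
    return pd.DataFrame(rows)
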