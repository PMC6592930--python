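"""Genomic variant-density enrichment.

The procedure: (1) per chromosome, a *standard frequency* — variant
count divided by chromosome length in megabases; (2) the chromosome with
the highest standard frequency is selected; (3) its cumulative variant
curve is examined and the region of highest variant density is
extracted, with the genes it contains.

The dense region is found algorithmically (a surrogate for picking the
inflection of the cumulative curve by eye): among fixed-width windows of
``target_fraction`` x chromosome length anchored at 0 and at every
variant position, the one holding the most variants wins; ties go to the
smallest start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import GenomeAnnotation

__all__ = [
    "DensityProfile",
    "DenseRegion",
    "standard_frequency",
    "density_profiles",
    "rank_chromosomes",
    "cumulative_curve",
    "max_density_region",
    "region_genes",
]


def standard_frequency(n_variants: int, length_bp: int) -> float:
    """Variants per megabase: n / (length / 1e6)."""
    if length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    if n_variants < 0:
        raise ValueError("variant count must be non-negative")
    return n_variants / (length_bp / 1e6)


@dataclass
class DensityProfile:
    chrom: str
    n_variants: int
    length_bp: int
    cumulative: pd.DataFrame = field(repr=False, default=None)  # pos, cum_count

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    @property
    def standard_frequency(self) -> float:
        return standard_frequency(self.n_variants, self.length_bp)


def cumulative_curve(positions: Iterable[int], length_bp: int) -> pd.DataFrame:
    """Sorted positions with running counts (duplicates each counted)."""
    pos = np.sort(np.asarray(list(positions), dtype=int))
    if pos.size and (pos[0] < 1 or pos[-1] > length_bp):
        raise ValueError("variant position outside [1, chromosome length]")
    return pd.DataFrame({"pos": pos, "cum_count": np.arange(1, pos.size + 1)})


def density_profiles(
    positions_by_chrom: Mapping[str, Sequence[int]],
    contig_lengths: Mapping[str, int],
) -> Dict[str, DensityProfile]:
    """Build per-chromosome profiles; chromosomes without variants get a
    zero profile.  Lengths come from the annotation, not the data."""
    profiles: Dict[str, DensityProfile] = {}
    for chrom, length in contig_lengths.items():
        pos = list(positions_by_chrom.get(chrom, []))
        profiles[chrom] = DensityProfile(
            chrom=chrom,
            n_variants=len(pos),
            length_bp=length,
            cumulative=cumulative_curve(pos, length),
        )
    return profiles


def rank_chromosomes(
    profiles: Mapping[str, DensityProfile]
) -> Tuple[str, bool]:
    """Chromosome with the maximum standard frequency; ties broken by
    name order and flagged.  Returns (chromosome, tied)."""
    if not profiles:
        raise ValueError("no density profiles")
    best = max(profiles.values(), key=lambda p: (p.standard_frequency, ), default=None)
    top_value = best.standard_frequency
    tied_names = sorted(
        name for name, p in profiles.items() if p.standard_frequency == top_value
    )
    return tied_names[0], len(tied_names) > 1


@dataclass
class DenseRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_in_region: int
    n_variants: int
    fraction_of_variants: float
    fraction_of_length: float
    genes: List[str] = field(default_factory=list)


def max_density_region(
    positions: Sequence[int],
    length_bp: int,
    target_fraction: float = 0.2,
    ann: Optional[GenomeAnnotation] = None,
    chrom: Optional[str] = None,
) -> DenseRegion:
    """Fixed-width window holding the most variants.

    Window width is ``target_fraction * length_bp``; candidate anchors
    are 0 and each variant position (as a window start), clipped to the
    chromosome.  Enlarging the fraction never decreases the count.
    """
    if not positions:
        raise ValueError("need at least one variant position")
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    pos0 = np.sort(np.asarray(positions, dtype=int) - 1)  # to 0-based
    width = max(1, int(round(target_fraction * length_bp)))
    anchors = np.unique(np.concatenate(([0], pos0)))
    anchors = np.minimum(anchors, max(0, length_bp - width))
    starts = np.unique(anchors)
    ends = starts + width
    counts = np.searchsorted(pos0, ends, side="left") - np.searchsorted(
        pos0, starts, side="left"
    )
    best = int(np.argmax(counts))  # argmax takes the first (smallest start) tie
    start, end = int(starts[best]), int(min(ends[best], length_bp))
    region = DenseRegion(
        chrom=chrom or "",
        start=start,
        end=end,
        n_in_region=int(counts[best]),
        n_variants=len(pos0),
        fraction_of_variants=float(counts[best]) / len(pos0),
        fraction_of_length=(end - start) / length_bp,
    )
    if ann is not None and chrom is not None:
        region.genes = region_genes(region, ann)["gene_id"].tolist()
    return region


def region_genes(region: DenseRegion, ann: GenomeAnnotation) -> pd.DataFrame:
    """Genes and transcripts intersecting the region (half-open)."""
    genes = sorted(
        {
            g.gene_id
            for g in ann.gene_spans
            if g.contig == region.chrom and g.start < region.end and region.start < g.end
        }
    )
    tx_by_gene: Dict[str, set] = {}
    for f in ann.cds_features:
        if f.contig == region.chrom and f.start < region.end and region.start < f.end:
            tx_by_gene.setdefault(f.gene_id, set()).add(f.transcript_id)
    rows = [
        {"gene_id": g, "transcripts": ";".join(sorted(tx_by_gene.get(g, [])))}
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "transcripts"])


def profiles_to_frame(profiles: Mapping[str, DensityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": p.chrom, "n_variants": p.n_variants, "length_mb": p.length_mb,
             "standard_frequency": p.standard_frequency}
            for p in profiles.values()
        ]
    )
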