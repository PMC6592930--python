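"""Weir-Cockerham F_ST sweep scan and offline gene-set enrichment.

Per-SNV differentiation is estimated with the full three-level
variance-component estimator for diploid genotype data (r populations,
here r = 2): components a (among populations), b (among individuals
within populations) and c (within individuals, i.e. heterozygosity),
with theta-hat = a / (a + b + c).  Observed heterozygote proportions
enter the estimator directly, so no Hardy-Weinberg assumption is made
within populations.  Negative estimates are reported as computed.

Windows are fixed-width sliding intervals (default 100 kb, 50 kb step,
0-based half-open); sex chromosomes and the mitochondrion are excluded
from the scan.  Window scores are unweighted means of per-site
theta-hat; the top fraction (default 5%) of ranked windows, ties at the
cutoff included, is the sweep candidate set.  Candidate genes are those
whose span intersects a top window; gene-set enrichment is an upper-tail
hypergeometric test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datamodel import (
    GenomeAnnotation,
    PopulationCallSet,
    VariantKey,
    VariantType,
)
from .stats import bh_fdr

__all__ = [
    "FstComponents",
    "FstWindow",
    "EnrichmentResult",
    "wc_fst_site",
    "site_fst_table",
    "make_windows",
    "window_scan",
    "top_fraction",
    "genes_in_windows",
    "geneset_enrichment",
    "fst_scan",
]

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 50_000
DEFAULT_EXCLUDE = ("Z", "W", "MT")


@dataclass(frozen=True)
class FstComponents:
    """Variance components of the per-site estimator."""

    a: float  # among-population
    b: float  # among-individual within-population
    c: float  # within-individual
    theta: float  # a / (a + b + c); nan when undefined
    defined: bool
    n_per_pop: Tuple[int, ...]
    p_hat: Tuple[float, ...]
    h_bar: float


def wc_fst_site(genotypes_by_pop: Sequence[Sequence[Tuple[int, int]]]) -> FstComponents:
    """Per-site variance components from diploid genotypes at a
    bi-allelic site, one genotype list per population.

    Genotypes are (allele, allele) pairs coded 0/1.  Requires at least
    two genotyped diploids in every population.  Returns the components
    and theta-hat; a site monomorphic everywhere has a = b = c = 0 and is
    flagged undefined.
    """
    r = len(genotypes_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    n = np.array([len(g) for g in genotypes_by_pop], dtype=float)
    if np.any(n < 2):
        raise ValueError("need >= 2 genotyped diploid individuals per population")
    p = np.empty(r)
    h = np.empty(r)
    for i, genotypes in enumerate(genotypes_by_pop):
        alleles = np.array([g for g in genotypes], dtype=float)
        if alleles.shape[1] != 2:
            raise ValueError("scan estimator expects diploid genotypes")
        p[i] = alleles.mean()
        h[i] = np.mean(alleles[:, 0] != alleles[:, 1])

    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    defined = denom != 0.0
    theta = a / denom if defined else float("nan")
    return FstComponents(
        a=float(a), b=float(b), c=float(c), theta=float(theta), defined=bool(defined),
        n_per_pop=tuple(int(x) for x in n), p_hat=tuple(float(x) for x in p),
        h_bar=float(h_bar),
    )


def _site_genotypes(
    cs: PopulationCallSet, key: VariantKey, sample_ids: Sequence[str]
) -> Optional[List[Tuple[int, int]]]:
    """Diploid genotypes for every listed sample; samples without a call
    at a site recorded elsewhere are treated as homozygous reference
    (single-sample caller semantics: absence of a line is a 0/0 call)."""
    rec = cs.records.get(key)
    out: List[Tuple[int, int]] = []
    for s in sample_ids:
        if rec is not None and s in rec.genotypes:
            gt = rec.genotypes[s]
            if len(gt) != 2:
                return None  # haploid call: site excluded from the scan
            out.append((gt[0], gt[1]))
        else:
            out.append((0, 0))
    return out


def site_fst_table(
    a: PopulationCallSet,
    b: PopulationCallSet,
    exclude_contigs: Sequence[str] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """Per-SNV theta-hat over the union of both call sets' SNVs on
    included contigs (columns chrom, pos, theta, defined)."""
    ids_a, ids_b = a.sample_ids(), b.sample_ids()
    keys = {
        k for k in set(a.keys()) | set(b.keys())
        if k.chrom not in exclude_contigs
    }
    snv_keys = sorted(
        k for k in keys
        if (a.records.get(k) or b.records[k]).vtype == VariantType.SNV
    )
    rows = []
    for key in snv_keys:
        g_a = _site_genotypes(a, key, ids_a)
        g_b = _site_genotypes(b, key, ids_b)
        if g_a is None or g_b is None:
            continue
        comp = wc_fst_site([g_a, g_b])
        rows.append(
            {"chrom": key.chrom, "pos": key.pos, "theta": comp.theta,
             "defined": comp.defined}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "theta", "defined"])


@dataclass
class FstWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snvs: int = 0
    mean_theta: float = float("nan")
    is_top: bool = False

    @property
    def has_mean(self) -> bool:
        return not math.isnan(self.mean_theta)


def make_windows(
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> List[FstWindow]:
    """Sliding windows [s, min(s + window, L)) for s = 0, step, 2*step, ...
    while s < L, on every included contig; a contig shorter than one
    window yields the single window [0, L)."""
    if step <= 0 or window < step:
        raise ValueError("require window >= step > 0 (gaps would drop SNVs)")
    windows: List[FstWindow] = []
    for contig, length in contig_lengths.items():
        if contig in exclude:
            continue
        if length <= window:
            windows.append(FstWindow(chrom=contig, start=0, end=length))
            continue
        s = 0
        while s < length:
            windows.append(FstWindow(chrom=contig, start=s, end=min(s + window, length)))
            s += step
    return windows


def window_scan(
    sites: pd.DataFrame,
    windows: Sequence[FstWindow],
    min_snvs: int = 1,
) -> List[FstWindow]:
    """Fill each window with the unweighted mean theta-hat of the defined
    SNVs inside it (position pos-1 in [start, end)); windows with fewer
    than ``min_snvs`` defined sites keep mean NaN and are never ranked."""
    usable = sites[sites["defined"]]
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in usable.groupby("chrom"):
        pos0 = grp["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        by_chrom[chrom] = (pos0[order], grp["theta"].to_numpy()[order])
    for w in windows:
        if w.chrom not in by_chrom:
            w.n_snvs, w.mean_theta = 0, float("nan")
            continue
        pos0, theta = by_chrom[w.chrom]
        lo, hi = np.searchsorted(pos0, [w.start, w.end])
        w.n_snvs = int(hi - lo)
        w.mean_theta = float(theta[lo:hi].mean()) if w.n_snvs >= min_snvs else float("nan")
    return list(windows)


def top_fraction(windows: Sequence[FstWindow], fraction: float = 0.05) -> List[FstWindow]:
    """Mark the top ``fraction`` of ranked windows by mean theta-hat.

    count = ceil(fraction * n_ranked); every window whose mean reaches
    the cutoff value is marked (ties included).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ranked = [w for w in windows if w.has_mean]
    if not ranked:
        raise ValueError("no ranked windows")
    count = math.ceil(fraction * len(ranked))
    cutoff = sorted((w.mean_theta for w in ranked), reverse=True)[count - 1]
    for w in windows:
        w.is_top = w.has_mean and w.mean_theta >= cutoff
    return list(windows)


def genes_in_windows(
    windows: Sequence[FstWindow], ann: GenomeAnnotation, top_only: bool = True
) -> pd.DataFrame:
    """Genes whose span intersects any (top) window, deduplicated, with
    the ids of every window they touch."""
    selected = [w for w in windows if w.is_top] if top_only else list(windows)
    hits: Dict[str, List[str]] = {}
    for g in ann.gene_spans:
        for w in selected:
            if g.contig == w.chrom and g.start < w.end and w.start < g.end:
                hits.setdefault(g.gene_id, []).append(f"{w.chrom}:{w.start}-{w.end}")
    rows = [
        {"gene_id": gid, "windows": ";".join(ws)} for gid, ws in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "windows"])


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap: int
    overlap_genes: List[str] = field(default_factory=list)
    p_value: float = 1.0
    p_adjusted: float = 1.0
    significant: bool = False


def geneset_enrichment(
    candidates: Iterable[str],
    universe: Iterable[str],
    genesets: Mapping[str, Set[str]],
    alpha: float = 0.01,
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of candidate genes per term.

    For each term with K genes in the universe of size N and a candidate
    list of size n, p = P(X >= overlap) under X ~ Hypergeom(N, K, n);
    p-values are BH-adjusted across terms and called significant below
    ``alpha`` (default 0.01).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    cand = set(candidates) & universe_set
    if not set(candidates) <= universe_set:
        raise ValueError("candidate genes outside the universe")
    results: List[EnrichmentResult] = []
    for term, genes in sorted(genesets.items()):
        term_genes = set(genes) & universe_set
        overlap = sorted(term_genes & cand)
        k = len(overlap)
        # upper tail P(X >= k); k = 0 gives p = 1 by convention
        p = float(hypergeom.sf(k - 1, len(universe_set), len(term_genes), len(cand)))
        results.append(
            EnrichmentResult(
                term_id=term, term_size=len(term_genes), overlap=k,
                overlap_genes=overlap, p_value=min(1.0, p),
            )
        )
    if results:
        adjusted = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
            r.significant = bool(q < alpha)
    return results


def fst_scan(
    high: PopulationCallSet,
    low: PopulationCallSet,
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
    min_snvs: int = 1,
    fraction: float = 0.05,
) -> Tuple[pd.DataFrame, List[FstWindow]]:
    """End-to-end scan: per-SNV theta-hat, window means, top-fraction
    marking.  Returns the per-site table and the scored windows."""
    sites = site_fst_table(high, low, exclude_contigs=exclude)
    windows = make_windows(contig_lengths, window=window, step=step, exclude=exclude)
    windows = window_scan(sites, windows, min_snvs=min_snvs)
    windows = top_fraction(windows, fraction=fraction)
    return sites, windows


def windows_to_frame(windows: Sequence[FstWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": w.chrom, "start": w.start, "end": w.end,
             "n_snvs": w.n_snvs, "mean_fst": w.mean_theta, "is_top": w.is_top}
            for w in windows
        ]
    )
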