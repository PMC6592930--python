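"""Population structure and phenotype classification.

* Nei's standard genetic distance between two populations from
  per-locus allele frequencies: D = -ln I with
  I = J_xy / sqrt(J_x * J_y), the J's being arithmetic means over loci
  of the allele-frequency cross products.
* UPGMA (average-linkage, cluster-size weighted) agglomeration of a
  distance matrix into a rooted ultrametric tree, emitted as Newick.
* Multiple correspondence analysis of a genotype indicator matrix
  (correspondence analysis of the 0/1 indicator; total inertia
  (K - J) / J for J variables and K categories).
* Correlation-matrix PCA of a quantitative trait table and a linear
  discriminant classifier (pooled covariance, resubstitution by
  default) summarised as a confusion matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import PopulationCallSet, VariantKey, VariantType

__all__ = [
    "NeiDistance",
    "nei_standard_distance",
    "allele_frequency_table",
    "upgma",
    "genotype_indicator_matrix",
    "sample_snv_genotypes",
    "MCAResult",
    "mca",
    "PCAResult",
    "phenotype_pca",
    "ConfusionMatrix",
    "discriminant_classify",
    "choose_n_components",
]


# ---------------------------------------------------------------------------
# Nei distance


@dataclass(frozen=True)
class NeiDistance:
    Jx: float
    Jy: float
    Jxy: float
    I: float  # normalised identity of genes
    D: float  # -ln I; inf when no alleles are shared
    infinite: bool


def nei_standard_distance(
    freq_x: Sequence[Sequence[float]], freq_y: Sequence[Sequence[float]]
) -> NeiDistance:
    """Nei's standard distance from per-locus allele-frequency vectors.

    ``freq_x[l]`` and ``freq_y[l]`` are the allele frequencies of locus l
    in the two populations, same allele order, each summing to 1.
    """
    if len(freq_x) != len(freq_y) or len(freq_x) == 0:
        raise ValueError("need matching non-empty locus lists")
    jx = jy = jxy = 0.0
    for x, y in zip(freq_x, freq_y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("allele vectors differ in length at a locus")
        for name, v in (("x", x), ("y", y)):
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"population {name} frequencies must be a simplex vector")
        jx += float(x @ x)
        jy += float(y @ y)
        jxy += float(x @ y)
    L = len(freq_x)
    jx, jy, jxy = jx / L, jy / L, jxy / L
    identity = jxy / math.sqrt(jx * jy)
    if identity <= 0.0:
        return NeiDistance(jx, jy, jxy, 0.0, float("inf"), True)
    return NeiDistance(jx, jy, jxy, identity, -math.log(identity), False)


def allele_frequency_table(
    a: PopulationCallSet, b: PopulationCallSet, snv_only: bool = True
) -> Tuple[List[List[float]], List[List[float]], List[VariantKey]]:
    """Per-population (ref, alt) frequency vectors from genotype counts.

    Samples without a call at a recorded site count as homozygous
    reference.  Loci monomorphic in both populations carry no
    information and are skipped.
    """
    ids_a, ids_b = a.sample_ids(), b.sample_ids()
    keys = sorted(set(a.keys()) | set(b.keys()))
    fx: List[List[float]] = []
    fy: List[List[float]] = []
    used: List[VariantKey] = []
    for key in keys:
        rec = a.records.get(key) or b.records.get(key)
        if snv_only and rec.vtype != VariantType.SNV:
            continue
        freqs = []
        for cs, ids in ((a, ids_a), (b, ids_b)):
            site = cs.records.get(key)
            total = alt = 0
            for s in ids:
                gt = site.genotypes.get(s, None) if site else None
                if gt is None:
                    gt = (0, 0) if key.chrom not in ("MT", "W") else (0,)
                total += len(gt)
                alt += sum(gt)
            freqs.append([1 - alt / total, alt / total])
        if freqs[0][1] == 0.0 and freqs[1][1] == 0.0:
            continue
        fx.append(freqs[0])
        fy.append(freqs[1])
        used.append(key)
    return fx, fy, used


# ---------------------------------------------------------------------------
# UPGMA


def upgma(distance: pd.DataFrame) -> str:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Returns a rooted ultrametric tree in Newick form; node heights are
    half the join distance and branch lengths subtract child heights.
    Tied merge distances resolve to the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest leaf).
    """
    D = distance.to_numpy(dtype=float)
    labels = list(distance.index)
    if list(distance.columns) != labels:
        raise ValueError("distance matrix index and columns must match")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric, zero-diagonal distance matrix")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    clusters: Dict[int, dict] = {
        i: {"newick": labels[i], "height": 0.0, "size": 1, "label": labels[i]}
        for i in range(len(labels))
    }
    dist: Dict[Tuple[int, int], float] = {
        (i, j): D[i, j] for i in clusters for j in clusters if i < j
    }
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), d = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(clusters[kv[0][0]]["label"], clusters[kv[0][1]]["label"]),
                max(clusters[kv[0][0]]["label"], clusters[kv[0][1]]["label"]),
            ),
        )
        ci, cj = clusters.pop(i), clusters.pop(j)
        if cj["label"] < ci["label"]:
            ci, cj = cj, ci  # smaller cluster label printed first
        height = d / 2.0
        # :g round-trips short values ("1" not "1.0000000000"); fall back
        # to repr precision so depths stay ultrametric to float accuracy
        def fmt(x: float) -> str:
            s = f"{x:.10g}"
            return s if float(s) == x else f"{x:.17g}"

        newick = (
            f"({ci['newick']}:{fmt(height - ci['height'])},"
            f"{cj['newick']}:{fmt(height - cj['height'])})"
        )
        merged = {
            "newick": newick,
            "height": height,
            "size": ci["size"] + cj["size"],
            "label": min(ci["label"], cj["label"]),
        }
        new_dists = {}
        for k in clusters:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            # UPGMA: arithmetic mean over all leaf pairs
            new_dists[k] = (ci["size"] * dik + cj["size"] * djk) / merged["size"]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))
    return root["newick"] + ";"


# ---------------------------------------------------------------------------
# MCA


def sample_snv_genotypes(
    a: PopulationCallSet,
    b: PopulationCallSet,
    n_sites: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Uniform random subset of diploid SNV sites as a samples x sites
    genotype-string table ("0/0", "0/1", "1/1"); the raw material for the
    genotype indicator matrix."""
    rng = rng or np.random.default_rng(0)
    keys = sorted(
        k
        for k in set(a.keys()) | set(b.keys())
        if (a.records.get(k) or b.records.get(k)).vtype == VariantType.SNV
        and k.chrom not in ("MT", "W")
    )
    if len(keys) > n_sites:
        idx = rng.choice(len(keys), size=n_sites, replace=False)
        keys = [keys[i] for i in sorted(idx)]
    samples = a.sample_ids() + b.sample_ids()
    data = {}
    for key in keys:
        col = []
        for cs in (a, b):
            site = cs.records.get(key)
            for s in cs.sample_ids():
                gt = site.genotypes.get(s) if site else None
                if gt is None:
                    gt = (0, 0)
                if len(gt) != 2:
                    gt = (gt[0], gt[0])  # hemizygous shown as homozygous class
                col.append(f"{min(gt)}/{max(gt)}")
        data[f"{key.chrom}:{key.pos}:{key.alt}"] = col
    return pd.DataFrame(data, index=samples)


def genotype_indicator_matrix(
    genotypes: pd.DataFrame,
) -> Tuple[pd.DataFrame, int]:
    """Expand a samples x sites categorical table into a 0/1 indicator
    matrix; constant columns (one category across all samples) are
    dropped with a warning and their variables removed from J."""
    blocks = []
    n_vars = 0
    dropped = 0
    for col in genotypes.columns:
        values = genotypes[col]
        cats = sorted(values.unique())
        if len(cats) < 2:
            dropped += 1
            continue
        n_vars += 1
        for cat in cats:
            blocks.append(pd.Series((values == cat).astype(float), name=f"{col}|{cat}"))
    if dropped:
        warnings.warn(f"dropped {dropped} constant genotype column(s)", stacklevel=2)
    if n_vars < 2:
        raise ValueError("need at least two polymorphic variables for MCA")
    Z = pd.concat(blocks, axis=1)
    return Z, n_vars


@dataclass
class MCAResult:
    coordinates: pd.DataFrame  # samples x axes, principal coordinates
    inertia: np.ndarray  # per-axis principal inertia
    inertia_pct: np.ndarray  # percent of total inertia
    total_inertia: float
    n_variables: int
    n_categories: int


def mca(indicator: pd.DataFrame, n_variables: int, n_components: int = 2) -> MCAResult:
    """Correspondence analysis of a complete-disjunctive indicator matrix.

    Standardised residuals of the correspondence matrix are decomposed
    by SVD; sample principal coordinates scale left singular vectors by
    the singular values.  Per-axis inertia is the squared singular
    value; the total inertia of an indicator matrix with J variables and
    K categories is (K - J) / J.  Deterministic up to axis sign.
    """
    Z = indicator.to_numpy(dtype=float)
    n, K = Z.shape
    if n < 2 or n_variables < 2:
        raise ValueError("need >= 2 samples and >= 2 variables")
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sigma > 1e-12
    sigma = sigma[keep]
    U = U[:, keep]
    coords = (U * sigma) / np.sqrt(r)[:, None]
    inertia = sigma**2
    total = float(inertia.sum())
    k = min(n_components, coords.shape[1])
    return MCAResult(
        coordinates=pd.DataFrame(
            coords[:, :k],
            index=indicator.index,
            columns=[f"axis_{i + 1}" for i in range(k)],
        ),
        inertia=inertia,
        inertia_pct=100.0 * inertia / total,
        total_inertia=total,
        n_variables=n_variables,
        n_categories=K,
    )


# ---------------------------------------------------------------------------
# PCA + discriminant


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    scores: pd.DataFrame  # samples x components
    loadings: np.ndarray
    dropped_traits: List[str] = field(default_factory=list)


def phenotype_pca(table: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of a samples x traits table.

    Traits are standardised (zero-variance traits dropped with a
    warning); eigenvalues of the correlation matrix sum to the number of
    retained traits.  Component scores project the standardised data on
    the eigenvectors.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropped zero-variance trait(s): {dropped}", stacklevel=2)
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Xs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    proportions = eigval / eigval.sum()
    scores = Xs @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        scores=pd.DataFrame(
            scores,
            index=table.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        loadings=eigvec,
        dropped_traits=dropped,
    )


def choose_n_components(pca: PCAResult, cumulative_target: float = 0.92) -> int:
    """Smallest number of leading components reaching the cumulative
    explained-variance target."""
    return int(np.searchsorted(pca.cumulative, cumulative_target - 1e-12) + 1)


@dataclass
class ConfusionMatrix:
    """True-group x assigned-group counts with proportion-correct summaries."""

    counts: pd.DataFrame  # rows: true group, columns: assigned group
    per_group_correct: pd.Series
    overall_correct: float

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ConfusionMatrix":
        counts = counts.astype(int)
        diag = pd.Series(np.diag(counts.to_numpy()), index=counts.index, dtype=float)
        row_totals = counts.sum(axis=1)
        per_group = diag / row_totals
        overall = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
        return cls(counts=counts, per_group_correct=per_group, overall_correct=overall)


def discriminant_classify(
    scores: pd.DataFrame,
    labels: Sequence[str],
    leave_one_out: bool = False,
    ridge: float = 1e-8,
) -> ConfusionMatrix:
    """Linear discriminant with pooled within-group covariance.

    Assignment minimises the Mahalanobis-type discriminant score with
    equal priors; resubstitution by default, optional leave-one-out.  A
    singular pooled covariance is ridge-regularised with a warning.
    """
    X = scores.to_numpy(dtype=float)
    y = np.asarray(labels)
    groups = sorted(set(y))
    if len(groups) != 2:
        raise ValueError("discriminant_classify expects exactly two groups")
    if min((y == g).sum() for g in groups) < 2:
        raise ValueError("need at least two samples per group")

    def fit(X_fit: np.ndarray, y_fit: np.ndarray):
        means = {g: X_fit[y_fit == g].mean(axis=0) for g in groups}
        pooled = np.zeros((X_fit.shape[1], X_fit.shape[1]))
        for g in groups:
            Xg = X_fit[y_fit == g]
            pooled += (Xg - means[g]).T @ (Xg - means[g])
        pooled /= len(y_fit) - len(groups)
        try:
            inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError:
            warnings.warn("singular pooled covariance; ridge-regularised", stacklevel=2)
            inv = np.linalg.inv(pooled + ridge * np.eye(pooled.shape[0]))
        return means, inv

    assigned = []
    if leave_one_out:
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            means, inv = fit(X[mask], y[mask])
            d = {g: (X[i] - means[g]) @ inv @ (X[i] - means[g]) for g in groups}
            assigned.append(min(groups, key=lambda g: d[g]))
    else:
        means, inv = fit(X, y)
        for i in range(len(y)):
            d = {g: (X[i] - means[g]) @ inv @ (X[i] - means[g]) for g in groups}
            assigned.append(min(groups, key=lambda g: d[g]))

    counts = pd.DataFrame(0, index=groups, columns=groups)
    for true, put in zip(y, assigned):
        counts.loc[true, put] += 1
    return ConfusionMatrix.from_counts(counts)
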