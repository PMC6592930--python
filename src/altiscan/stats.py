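"""First-principles statistics for variant-type distribution contrasts.

* Two-sided Fisher exact test on 2x2 tables using the minimum-likelihood
  convention (sum of hypergeometric outcomes no more probable than the
  observed table).
* Per-variant-type Fisher tests between the two populations
  (type-vs-rest construction; a type-vs-type k x 2 chi-square mode is
  also provided since the exact construction used by legacy web tools is
  not recoverable).
* Per-chromosome Pearson chi-square (df = 1, no continuity correction by
  default) stratified by sex and variant type.
* Benjamini-Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .datamodel import PopulationCallSet, Sex, VariantType

__all__ = [
    "fisher_exact_2x2",
    "per_type_distribution_test",
    "per_type_chisq_k2",
    "per_chromosome_chisq",
    "nonsignificant_report",
    "bh_fdr",
]

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Conditional on both margins, the first cell follows a hypergeometric
    distribution; the two-sided p is the total probability of all
    outcomes whose probability does not exceed that of the observed
    table (minimum-likelihood convention).  Outcome probabilities share
    the denominator C(n, col1), so they are compared as exact integer
    numerators — no floating-point ties.
    """
    from math import comb

    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0  # degenerate margin: only one table possible
    w_obs = comb(row1, a) * comb(n - row1, col1 - a)
    total = 0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        w = comb(row1, k) * comb(n - row1, col1 - k)
        if w <= w_obs:
            total += w
    return min(1.0, total / comb(n, col1))


def _type_counts(cs: PopulationCallSet, sex: Optional[Sex] = None) -> Dict[str, int]:
    """Variant counts by class, restricted to records carried by samples
    of the given sex (all samples when None)."""
    ids = set(cs.sample_ids(sex))
    counts = {vt.value: 0 for vt in VariantType}
    for rec in cs.records.values():
        if rec.carriers & ids:
            counts[rec.vtype.value] += 1
    return counts


def per_type_distribution_test(
    high: PopulationCallSet, low: PopulationCallSet
) -> pd.DataFrame:
    """Fisher test per variant class: is class v over- or under-represented
    in one population's variant spectrum?  Each class v is tested on
    [[count(v, high), count(not v, high)], [count(v, low), count(not v, low)]].
    Classes absent from both populations are reported untestable.
    """
    ch, cl = _type_counts(high), _type_counts(low)
    th, tl = sum(ch.values()), sum(cl.values())
    rows = []
    for vt in VariantType:
        v = vt.value
        if ch[v] + cl[v] == 0:
            rows.append(
                {"vtype": v, "count_highland": 0, "count_lowland": 0,
                 "p_value": np.nan, "testable": False}
            )
            continue
        p = fisher_exact_2x2([[ch[v], th - ch[v]], [cl[v], tl - cl[v]]])
        rows.append(
            {"vtype": v, "count_highland": ch[v], "count_lowland": cl[v],
             "p_value": p, "testable": True}
        )
    df = pd.DataFrame(rows)
    df["significant_0.001"] = df["p_value"] < 0.001
    return df


def per_type_chisq_k2(high: PopulationCallSet, low: PopulationCallSet) -> Tuple[float, int, float]:
    """Alternative k x 2 construction: one chi-square over the full
    type-by-population count table.  Returns (statistic, df, p)."""
    ch, cl = _type_counts(high), _type_counts(low)
    table = np.array(
        [[ch[v.value], cl[v.value]] for v in VariantType if ch[v.value] + cl[v.value] > 0]
    )
    stat, df = _pearson_chisq(table)
    return stat, df, float(chi2.sf(stat, df))


def _pearson_chisq(table: np.ndarray) -> Tuple[float, int]:
    total = table.sum()
    if total == 0:
        raise ZeroDivisionError("empty table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ZeroDivisionError("zero expected count")
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def per_chromosome_chisq(
    high: PopulationCallSet,
    low: PopulationCallSet,
    stratify_by_sex: bool = True,
    yates: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson chi-square per (sex, variant type, chromosome).

    Each cell tests whether the focal chromosome's share of type-v
    variants differs between populations:
    [[on-chrom, off-chrom] per population], df = 1.  Cells with a zero
    expected count are flagged untestable.  Yates continuity correction
    is off by default.
    """
    sexes: List[Optional[Sex]] = [Sex.MALE, Sex.FEMALE] if stratify_by_sex else [None]
    rows = []
    for sex in sexes:
        ids_h, ids_l = set(high.sample_ids(sex)), set(low.sample_ids(sex))
        per_chrom: Dict[Tuple[str, str], List[int]] = {}
        totals = {"highland": {vt.value: 0 for vt in VariantType},
                  "lowland": {vt.value: 0 for vt in VariantType}}
        counts: Dict[Tuple[str, str, str], int] = {}
        chroms = set()
        for cs, ids, pop in ((high, ids_h, "highland"), (low, ids_l, "lowland")):
            for rec in cs.records.values():
                if rec.carriers & ids:
                    v = rec.vtype.value
                    counts[(pop, v, rec.key.chrom)] = counts.get((pop, v, rec.key.chrom), 0) + 1
                    totals[pop][v] += 1
                    chroms.add(rec.key.chrom)
        for vt in VariantType:
            v = vt.value
            th, tl = totals["highland"][v], totals["lowland"][v]
            for chrom in sorted(chroms):
                on_h = counts.get(("highland", v, chrom), 0)
                on_l = counts.get(("lowland", v, chrom), 0)
                table = np.array([[on_h, th - on_h], [on_l, tl - on_l]], dtype=float)
                row = {
                    "sex": sex.value if sex else "pooled",
                    "vtype": v,
                    "chrom": chrom,
                    "count_highland": on_h,
                    "count_lowland": on_l,
                }
                try:
                    if yates:
                        total = table.sum()
                        if total == 0:
                            raise ZeroDivisionError
                        expected = np.outer(table.sum(1), table.sum(0)) / total
                        if np.any(expected == 0):
                            raise ZeroDivisionError
                        stat = float(
                            ((np.abs(table - expected) - 0.5).clip(min=0) ** 2 / expected).sum()
                        )
                        df = 1
                    else:
                        stat, df = _pearson_chisq(table)
                    p = float(chi2.sf(stat, df))
                    row.update(
                        {"chi2": stat, "df": df, "p_value": p,
                         "significant": p < alpha, "testable": True}
                    )
                except ZeroDivisionError:
                    row.update(
                        {"chi2": np.nan, "df": 1, "p_value": np.nan,
                         "significant": False, "testable": False}
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def nonsignificant_report(chisq_table: pd.DataFrame) -> pd.DataFrame:
    """Chromosomes without a significant difference, listed per
    (sex, variant type) — the presentation used for sparse reporting."""
    ok = chisq_table[chisq_table["testable"] & ~chisq_table["significant"]]
    rows = []
    for (sex, vtype), grp in ok.groupby(["sex", "vtype"], sort=True):
        rows.append(
            {"sex": sex, "vtype": vtype,
             "nonsignificant_chromosomes": ",".join(sorted(grp["chrom"].tolist()))}
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted[i] = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped
    at 1; monotone non-decreasing in the sorted order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
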