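"""Weir-Cockerham estimator, window scan and gene-set enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from altiscan.datamodel import GeneSpan, GenomeAnnotation
from altiscan.fst import (
    FstWindow,
    geneset_enrichment,
    genes_in_windows,
    make_windows,
    site_fst_table,
    top_fraction,
    wc_fst_site,
    window_scan,
)


def wc_oracle(genotype_lists):
    """Independent transcription of the two-level-sampling variance
    component formulas for diploid data (r populations, allele frequency
    p_i, observed heterozygote proportion h_i, sample size n_i):

        nbar = sum(n_i)/r
        nc   = (r*nbar - sum(n_i^2)/(r*nbar)) / (r-1)
        pbar = sum(n_i p_i)/(r nbar);  hbar = sum(n_i h_i)/(r nbar)
        s2   = sum(n_i (p_i-pbar)^2) / ((r-1) nbar)
        a = nbar/nc * [s2 - 1/(nbar-1) (pbar(1-pbar) - (r-1)/r s2 - hbar/4)]
        b = nbar/(nbar-1) [pbar(1-pbar) - (r-1)/r s2 - (2nbar-1)/(4nbar) hbar]
        c = hbar/2
    """
    r = len(genotype_lists)
    n = [len(g) for g in genotype_lists]
    p = []
    h = []
    for g in genotype_lists:
        alleles = [x for gt in g for x in gt]
        p.append(sum(alleles) / len(alleles))
        h.append(sum(1 for gt in g if gt[0] != gt[1]) / len(g))
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def random_site(rng, n1=None, n2=None):
    n1 = n1 or int(rng.integers(2, 15))
    n2 = n2 or int(rng.integers(2, 15))
    p1, p2 = rng.uniform(0.0, 1.0, size=2)
    pops = []
    for n, p in ((n1, p1), (n2, p2)):
        pops.append([tuple(rng.binomial(1, p, size=2)) for _ in range(n)])
    return pops


class TestWcFstSite:
    def test_fixed_difference_gives_one(self):
        g1 = [(1, 1)] * 10
        g2 = [(0, 0)] * 10
        comp = wc_fst_site([g1, g2])
        assert comp.theta == pytest.approx(1.0)
        assert comp.defined

    def test_monomorphic_everywhere_undefined(self):
        comp = wc_fst_site([[(0, 0)] * 5, [(0, 0)] * 5])
        assert not comp.defined
        assert math.isnan(comp.theta)

    def test_worked_configuration_matches_oracle(self):
        """n1 = n2 = 10, p1 = 0.8, p2 = 0.2, observed het 0.32 in both."""
        def make(p_hom_alt, n_het, n):
            # n_het heterozygotes, p_hom_alt homozygous alt, rest hom ref
            g = [(0, 1)] * n_het + [(1, 1)] * p_hom_alt
            return g + [(0, 0)] * (n - len(g))

        # 10 diploids, allele freq .8 -> 16 alt alleles; het .32 is not
        # integral at n=10, so use the nearest integral design: 3 het + 6
        # hom-alt (p=0.75, h=0.3) vs mirrored; oracle equality matters.
        g1 = make(6, 3, 10)
        g2 = [(1 - a, 1 - b) for a, b in g1]
        comp = wc_fst_site([g1, g2])
        assert comp.theta == pytest.approx(wc_oracle([g1, g2]), abs=1e-12)
        assert comp.p_hat == (0.75, 0.25)

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            pops = random_site(rng)
            comp = wc_fst_site(pops)
            oracle = wc_oracle(pops)
            if comp.defined:
                assert comp.theta == pytest.approx(oracle, abs=1e-10)
                checked += 1
            else:
                assert math.isnan(oracle)
        assert checked > 60

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pops = random_site(rng)
            swapped = [[(1 - a, 1 - b) for a, b in g] for g in pops]
            c1, c2 = wc_fst_site(pops), wc_fst_site(swapped)
            if c1.defined:
                assert c1.theta == pytest.approx(c2.theta, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wc_fst_site([[(0, 1)] * 5])  # one population
        with pytest.raises(ValueError):
            wc_fst_site([[(0, 1)], [(0, 1)] * 5])  # n < 2


class TestMakeWindows:
    def test_truncated_last_window(self):
        windows = make_windows({"1": 250_000})
        starts = [w.start for w in windows]
        assert starts == [0, 50_000, 100_000, 150_000, 200_000]
        assert (windows[-1].start, windows[-1].end) == (200_000, 250_000)

    def test_sex_chromosomes_and_mt_excluded_by_default(self):
        windows = make_windows({"1": 200_000, "Z": 200_000, "W": 100_000, "MT": 16_000})
        assert {w.chrom for w in windows} == {"1"}

    def test_short_contig_single_window(self):
        windows = make_windows({"1": 80_000})
        assert len(windows) == 1
        assert (windows[0].start, windows[0].end) == (0, 80_000)

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"1": 1_000_000}, window=10_000, step=20_000)


class TestWindowScan:
    def test_mean_and_boundary_convention(self):
        sites = pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                # pos is 1-based; a site at pos == start + window belongs
                # to the next window only (half-open internal intervals)
                "pos": [10, 20, 100_001],
                "theta": [0.1, 0.3, 0.9],
                "defined": [True] * 3,
            }
        )
        windows = make_windows({"1": 150_000})
        scanned = window_scan(sites, windows)
        assert scanned[0].mean_theta == pytest.approx(0.2)
        assert scanned[0].n_snvs == 2
        assert scanned[1].n_snvs == 1  # [50k, 150k) holds pos 100001 only

    def test_undefined_sites_skipped_and_empty_flagged(self):
        sites = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [10, 20], "theta": [0.5, np.nan],
             "defined": [True, False]}
        )
        windows = window_scan(sites, make_windows({"1": 60_000, "2": 60_000}))
        assert windows[0].mean_theta == pytest.approx(0.5)
        assert windows[1].n_snvs == 0 and not windows[1].has_mean

    def test_equals_bruteforce_on_shuffled_input(self, callsets):
        high, low = callsets
        sites = site_fst_table(high, low)
        shuffled = sites.sample(frac=1.0, random_state=0).reset_index(drop=True)
        windows = window_scan(shuffled, make_windows({"1": 1_000_000}))
        for w in windows:
            mask = (
                (sites.chrom == w.chrom)
                & (sites.pos - 1 >= w.start)
                & (sites.pos - 1 < w.end)
                & sites.defined
            )
            expected = sites.theta[mask]
            assert w.n_snvs == mask.sum()
            if len(expected):
                assert w.mean_theta == pytest.approx(expected.mean(), rel=1e-12)


class TestTopFraction:
    def test_exact_count_with_distinct_means(self):
        windows = [
            FstWindow("1", i, i + 1, n_snvs=1, mean_theta=i / 100.0) for i in range(100)
        ]
        marked = top_fraction(windows, 0.05)
        assert sum(w.is_top for w in marked) == 5
        assert all(w.mean_theta >= 0.95 for w in marked if w.is_top)

    def test_all_ties_all_marked(self):
        windows = [FstWindow("1", i, i + 1, 1, 0.3) for i in range(10)]
        marked = top_fraction(windows, 0.05)
        assert all(w.is_top for w in marked)

    def test_bad_fraction_rejected(self):
        windows = [FstWindow("1", 0, 1, 1, 0.3)]
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                top_fraction(windows, frac)


class TestGenesInWindows:
    @pytest.fixture
    def ann(self):
        return GenomeAnnotation(
            contig_lengths={"1": 300_000},
            cds_features=[],
            gene_spans=[
                GeneSpan("1", 10_000, 12_000, "inside_top"),
                GeneSpan("1", 210_000, 212_000, "outside_top"),
                GeneSpan("1", 95_000, 105_000, "straddler"),
            ],
        )

    def test_membership_and_straddling(self, ann):
        windows = [
            FstWindow("1", 0, 100_000, 10, 0.9, is_top=True),
            FstWindow("1", 100_000, 200_000, 10, 0.8, is_top=True),
            FstWindow("1", 200_000, 300_000, 10, 0.1, is_top=False),
        ]
        out = genes_in_windows(windows, ann)
        assert set(out.gene_id) == {"inside_top", "straddler"}
        straddler = out.set_index("gene_id").loc["straddler", "windows"]
        assert straddler.count(";") == 1  # listed once, with both window ids


def hypergeom_oracle(N, K, n, k):
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(min(total, Fraction(1)))


class TestGenesetEnrichment:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        genesets = {"T1": set(universe[:5])}
        candidates = universe[:3] + [universe[10]]  # overlap 3 of term size 5
        (res,) = geneset_enrichment(candidates, universe, genesets, alpha=0.05)
        assert res.overlap == 3
        assert res.p_value == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        (res,) = geneset_enrichment(
            universe[5:7], universe, {"T": set(universe[:3])}
        )
        assert res.p_value == 1.0

    def test_candidates_equal_universe_degenerate(self):
        universe = [f"g{i}" for i in range(8)]
        results = geneset_enrichment(
            universe, universe, {"A": set(universe[:4]), "B": set(universe[2:5])}
        )
        for r in results:
            assert r.overlap == r.term_size
            assert r.p_value == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment([], [], {"T": {"g"}})

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            term = set(rng.choice(universe, size=K, replace=False))
            cand = list(rng.choice(universe, size=n, replace=False))
            (res,) = geneset_enrichment(cand, universe, {"T": term}, alpha=0.01)
            assert res.p_value == pytest.approx(
                hypergeom_oracle(N, K, n, res.overlap), abs=1e-12
            )

    def test_bh_adjustment_and_alpha_call(self):
        universe = [f"g{i}" for i in range(40)]
        genesets = {f"T{i}": set(universe[i : i + 10]) for i in range(10)}
        results = geneset_enrichment(universe[:10], universe, genesets, alpha=0.01)
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-15
            assert r.significant == (r.p_adjusted < 0.01)
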