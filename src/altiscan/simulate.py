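"""Self-contained synthetic study generator.

Emulates a two-ecotype resequencing design: a small reference genome
(five autosomes plus Z, W and MT) with annotated protein-coding genes,
two populations of diploid birds diverged under a Balding-Nichols model
(per-population allele frequencies Beta-distributed around an ancestral
frequency with variance theta * p * (1-p)), planted high-differentiation
sweep windows, a known-variants database, per-sample VCFs, a gene-set
annotation table, a 24-trait phenotype table with population mean shifts,
and a five-sample replication cohort.

Defaults mirror the study design the pipeline targets: five samples per
population (highland three males / two females, lowland two males /
three females), mixed-sex phenotype cohort of 16 birds, ~1 variant per
kilobase, background F_ST 0.02 with three planted 100 kb windows at 0.5.

A single global seed governs every stage; each stage derives its own
deterministic substream, so stages re-run independently give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import Population, SampleMeta, Sex, VariantKey

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "sample_metas",
    "simulate_genome",
    "simulate_populations",
    "simulate_phenotypes",
    "simulate_gene_sets",
    "simulate_replication_cohort",
    "simulate_study",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# substream ids for the per-stage rngs
_STAGE_GENOME = 1
_STAGE_POPULATIONS = 2
_STAGE_PHENOTYPES = 3
_STAGE_REPLICATION = 4
_STAGE_GENESETS = 5


@dataclass
class SimConfig:
    """Knobs of the synthetic study (see module docstring for defaults)."""

    seed: int = 0
    n_autosomes: int = 5
    autosome_length: int = 1_000_000
    include_z: bool = True
    include_w: bool = True
    include_mt: bool = True
    z_length: int = 500_000
    w_length: int = 200_000
    mt_length: int = 16_000
    n_samples_per_pop: int = 5
    background_fst: float = 0.02
    n_sweep_windows: int = 3
    sweep_fst: float = 0.5
    sweep_window_size: int = 100_000
    sweep_grid: int = 50_000  # sweep windows start on this grid (scan step)
    snv_density: float = 1e-3  # variants per bp on autosomes/Z
    n_w_variants: int = 10
    n_mt_variants: int = 14
    fraction_known: float = 0.5
    fraction_private: float = 0.30  # sites private to one population
    fraction_private_fixed: float = 0.3  # of private sites: carried by every sample
    vtype_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "SNV": 0.90,
            "MNV": 0.025,
            "insertion": 0.025,
            "deletion": 0.025,
            "replacement": 0.025,
        }
    )
    gene_spacing: int = 20_000
    # phenotypes
    n_traits: int = 24
    n_effect_traits: int = 6
    phenotype_effect: float = 3.0  # standardised mean shift on affected traits
    n_pheno_lowland: int = 10
    n_pheno_highland: int = 6
    # replication
    n_replicates: int = 5
    # gene sets
    n_gene_sets: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_fst < self.sweep_fst <= 1.0):
            raise ValueError("need 0 <= background_fst < sweep_fst <= 1")
        for name in ("snv_density", "fraction_known", "fraction_private"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def contig_lengths(self) -> Dict[str, int]:
        lengths = {str(i + 1): self.autosome_length for i in range(self.n_autosomes)}
        if self.include_z:
            lengths["Z"] = self.z_length
        if self.include_w:
            lengths["W"] = self.w_length
        if self.include_mt:
            lengths["MT"] = self.mt_length
        return lengths

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class SimulatedStudy:
    """Paths and truth for one generated study."""

    config: SimConfig
    fasta: Path
    gff: Path
    highland: List[Tuple[SampleMeta, Path]]
    lowland: List[Tuple[SampleMeta, Path]]
    known_vcf: Path
    truth: pd.DataFrame
    truth_path: Path
    phenotypes: pd.DataFrame
    phenotype_path: Path
    gene_sets_path: Path
    replication: List[Tuple[SampleMeta, Path]]


def sample_metas(cfg: SimConfig) -> Tuple[List[SampleMeta], List[SampleMeta]]:
    """Study samples: highland males first (3M/2F), lowland 2M/3F at n=5;
    other sizes alternate sexes."""
    def build(pop: Population, prefix: str, n: int, n_males: int) -> List[SampleMeta]:
        sexes = [Sex.MALE] * n_males + [Sex.FEMALE] * (n - n_males)
        return [
            SampleMeta(f"{prefix}{i + 1}", pop, sexes[i]) for i in range(n)
        ]

    n = cfg.n_samples_per_pop
    high_males = 3 if n == 5 else (n + 1) // 2
    low_males = 2 if n == 5 else n // 2
    return (
        build(Population.HIGHLAND, "H", n, high_males),
        build(Population.LOWLAND, "L", n, low_males),
    )


# ---------------------------------------------------------------------------
# genome


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _plan_genes(
    cfg: SimConfig, contig: str, length: int, rng: np.random.Generator
) -> List[dict]:
    """Place non-overlapping genes with 1-3 CDS exons along a contig."""
    genes = []
    cursor = 2_000 if length > 50_000 else 200
    idx = 0
    spacing = cfg.gene_spacing if length > 50_000 else max(length // 4, 1_000)
    while True:
        n_exons = int(rng.integers(1, 4))
        n_codons = int(rng.integers(30, 120)) if length > 50_000 else int(rng.integers(40, 90))
        body = rng.choice(len(_NONSTOP_CODONS), size=n_codons)
        coding = "ATG" + "".join(_NONSTOP_CODONS[int(i)] for i in body) + "TAA"
        total = len(coding)
        # nucleotide-level exon cuts (each exon >= 3 nt) exercise non-zero phases
        if n_exons == 1:
            cuts: List[int] = []
        else:
            cuts = sorted(
                int(c) for c in rng.choice(np.arange(3, total - 3), size=n_exons - 1, replace=False)
            )
            if len(set(cuts)) != n_exons - 1 or any(b - a < 3 for a, b in zip([0] + cuts, cuts + [total])):
                cuts = [total * i // n_exons for i in range(1, n_exons)]
        bounds = [0] + cuts + [total]
        exon_lengths = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
        introns = [int(rng.integers(60, 400)) for _ in range(n_exons - 1)]
        span = sum(exon_lengths) + sum(introns)
        if cursor + span + 100 > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        # genomic exon intervals, left to right
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el + (introns[i] if i < len(introns) else 0)
        genes.append(
            {
                "gene_id": f"gene_{contig}_{idx + 1}",
                "transcript_id": f"tx_{contig}_{idx + 1}",
                "contig": contig,
                "strand": strand,
                "coding": coding,
                "exons": exons,
                "start": exons[0][0],
                "end": exons[-1][1],
            }
        )
        idx += 1
        cursor = pos + int(rng.integers(spacing // 2, spacing))
    return genes


def simulate_genome(cfg: SimConfig, outdir: Path) -> Tuple[Path, Path]:
    """Write a random genome FASTA and a GFF3 annotation; returns paths.

    Contigs are uniform-random sequence; exon footprints are overwritten
    with a designed coding sequence (ATG, non-stop codons, terminal stop)
    so every transcript translates cleanly, reverse-complemented into the
    genome for minus-strand genes.  Deterministic under the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(_STAGE_GENOME)
    fasta_path = outdir / "genome.fa"
    gff_path = outdir / "annotation.gff3"

    lengths = cfg.contig_lengths()
    gff_lines = ["##gff-version 3"]
    for contig, length in lengths.items():
        gff_lines.append(f"##sequence-region {contig} 1 {length}")

    with open(fasta_path, "w") as fa:
        for contig, length in lengths.items():
            seq = rng.choice(_BASES, size=length)
            genes = [] if contig == "W" else _plan_genes(cfg, contig, length, rng)
            for gene in genes:
                coding = gene["coding"]
                offset = 0
                exon_iter = gene["exons"] if gene["strand"] == "+" else gene["exons"][::-1]
                for (s, e) in exon_iter:
                    chunk = coding[offset : offset + (e - s)]
                    offset += e - s
                    if gene["strand"] == "-":
                        chunk = _reverse_complement(chunk)
                    seq[s:e] = list(chunk)
                gid, tid = gene["gene_id"], gene["transcript_id"]
                gff_lines.append(
                    f"{contig}\taltisim\tgene\t{gene['start'] + 1}\t{gene['end']}\t.\t"
                    f"{gene['strand']}\t.\tID={gid};Name={gid}"
                )
                gff_lines.append(
                    f"{contig}\taltisim\tmRNA\t{gene['start'] + 1}\t{gene['end']}\t.\t"
                    f"{gene['strand']}\t.\tID={tid};Parent={gid}"
                )
                cum = 0
                for (s, e) in exon_iter:
                    phase = (3 - cum % 3) % 3
                    cum += e - s
                    gff_lines.append(
                        f"{contig}\taltisim\tCDS\t{s + 1}\t{e}\t.\t{gene['strand']}\t"
                        f"{phase}\tID=cds_{tid};Parent={tid}"
                    )
            fa.write(f">{contig}\n")
            text = "".join(seq)
            for i in range(0, length, 60):
                fa.write(text[i : i + 60] + "\n")

    gff_path.write_text("\n".join(gff_lines) + "\n")
    return fasta_path, gff_path


# ---------------------------------------------------------------------------
# populations


def choose_sweep_windows(cfg: SimConfig, rng: np.random.Generator) -> List[Tuple[str, int, int]]:
    """Pick sweep windows aligned to the scan grid, one per autosome."""
    windows: List[Tuple[str, int, int]] = []
    n_slots = (cfg.autosome_length - cfg.sweep_window_size) // cfg.sweep_grid
    for i in range(cfg.n_sweep_windows):
        contig = str((i % cfg.n_autosomes) + 1)
        start = int(rng.integers(1, n_slots)) * cfg.sweep_grid
        windows.append((contig, start, start + cfg.sweep_window_size))
    return windows


def _draw_pop_freqs(
    p: float, theta: float, rng: np.random.Generator
) -> Tuple[float, float]:
    """Balding-Nichols: per-population frequency ~ Beta with mean p and
    variance theta*p*(1-p); theta == 0 collapses to the ancestral p."""
    if theta <= 0.0:
        return p, p
    a = p * (1.0 - theta) / theta
    b = (1.0 - p) * (1.0 - theta) / theta
    return float(rng.beta(a, b)), float(rng.beta(a, b))


def _ploidy(contig: str, sex: Sex) -> int:
    """Copies of a contig carried by one bird (female birds are ZW)."""
    if contig == "MT":
        return 1
    if contig == "W":
        return 1 if sex == Sex.FEMALE else 0
    if contig == "Z":
        return 2 if sex == Sex.MALE else 1
    return 2


def _draw_alleles(
    ref_seq: str, pos0: int, vtype: str, rng: np.random.Generator
) -> Optional[Tuple[str, str]]:
    """Construct (ref, alt) of the requested class at a genome position."""
    def other_base(b: str) -> str:
        choices = [x for x in "ACGT" if x != b]
        return choices[int(rng.integers(3))]

    if vtype == "SNV":
        ref = ref_seq[pos0]
        return ref, other_base(ref)
    if vtype == "MNV":
        ref = ref_seq[pos0 : pos0 + 2]
        alt = other_base(ref[0]) + other_base(ref[1])
        return (ref, alt) if len(ref) == 2 else None
    if vtype == "insertion":
        ref = ref_seq[pos0]
        ins = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(1, 4)))])
        return ref, ref + ins
    if vtype == "deletion":
        n = int(rng.integers(2, 5))
        ref = ref_seq[pos0 : pos0 + n]
        return (ref, ref[0]) if len(ref) == n else None
    if vtype == "replacement":
        ref = ref_seq[pos0 : pos0 + 2]
        if len(ref) != 2:
            return None
        alt = other_base(ref[0]) + "".join(_BASES[rng.integers(0, 4, size=2)])
        return ref, alt
    raise ValueError(f"unknown vtype {vtype}")


def _write_vcf(
    path: Path,
    sample_id: str,
    contig_lengths: Dict[str, int],
    rows: Sequence[Tuple[str, int, str, str, str]],
) -> None:
    """Write a minimal single-sample VCF 4.2 (rows: chrom,pos,ref,alt,gt)."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for chrom, pos, ref, alt, gt in sorted(rows, key=lambda r: (order[r[0]], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def _format_gt(alt_copies: int, ploidy: int) -> str:
    if ploidy == 1:
        return "1" if alt_copies else "0"
    return ["0/0", "0/1", "1/1"][alt_copies]


def simulate_populations(
    cfg: SimConfig, fasta_path: Path, outdir: Path
) -> Tuple[List[Tuple[SampleMeta, Path]], List[Tuple[SampleMeta, Path]], Path, pd.DataFrame]:
    """Simulate both populations' call sets; write per-sample VCFs, the
    known-variants VCF and the truth table.

    Returns ``(highland, lowland, known_vcf_path, truth)`` where the first
    two are lists of ``(SampleMeta, vcf_path)``.  The truth table has one
    row per site that appears in at least one VCF.
    """
    from pyfaidx import Fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(_STAGE_POPULATIONS)
    fa = Fasta(str(fasta_path))
    lengths = cfg.contig_lengths()
    high_meta, low_meta = sample_metas(cfg)
    sweeps = choose_sweep_windows(cfg, rng)

    vtypes = list(cfg.vtype_weights)
    vtype_p = np.array([cfg.vtype_weights[v] for v in vtypes])
    vtype_p = vtype_p / vtype_p.sum()
    mt_types = ["SNV", "insertion", "replacement"]
    mt_p = np.array([0.75, 0.15, 0.10])

    sample_rows: Dict[str, List[Tuple[str, int, str, str, str]]] = {
        m.sample_id: [] for m in high_meta + low_meta
    }
    truth_rows = []
    known_rows: List[Tuple[str, int, str, str]] = []

    for contig, length in lengths.items():
        seq = str(fa[contig])
        if contig == "MT":
            n_sites = cfg.n_mt_variants
        elif contig == "W":
            n_sites = cfg.n_w_variants
        else:
            n_sites = int(round(cfg.snv_density * length))
        if n_sites == 0:
            continue
        # sample sites on an 8 bp grid: uniform along the contig and multi-base
        # reference spans can never overlap
        n_bins = (length - 8) // 8
        n_take = min(n_sites, n_bins)
        kept = [int(b) * 8 for b in np.sort(rng.choice(n_bins, size=n_take, replace=False))]
        contig_sweeps = [(s, e) for (c, s, e) in sweeps if c == contig]

        for pos0 in kept:
            vt_pool, vt_prob = (mt_types, mt_p) if contig == "MT" else (vtypes, vtype_p)
            vtype = vt_pool[int(rng.choice(len(vt_pool), p=vt_prob))]
            alleles = _draw_alleles(seq, pos0, vtype, rng)
            if alleles is None or alleles[0] == alleles[1] or (set(alleles[0] + alleles[1]) - set("ACGT")):
                continue
            ref, alt = alleles
            in_sweep = any(s <= pos0 < e for (s, e) in contig_sweeps)
            u = rng.random()
            if u < cfg.fraction_private / 2:
                category = "private_highland"
            elif u < cfg.fraction_private:
                category = "private_lowland"
            else:
                category = "shared"
            if category == "shared":
                p_anc = float(rng.uniform(0.05, 0.95))
                theta = cfg.sweep_fst if in_sweep else cfg.background_fst
                p_high, p_low = _draw_pop_freqs(p_anc, theta, rng)
            else:
                if rng.random() < cfg.fraction_private_fixed:
                    p_focal = 1.0
                else:
                    p_focal = float(rng.uniform(0.3, 0.9))
                p_high, p_low = (p_focal, 0.0) if category == "private_highland" else (0.0, p_focal)

            known = bool(rng.random() < cfg.fraction_known)
            carriers = {"highland": 0, "lowland": 0}
            per_sample: List[Tuple[SampleMeta, int, int]] = []
            for metas, p_pop, pop in ((high_meta, p_high, "highland"), (low_meta, p_low, "lowland")):
                for m in metas:
                    ploidy = _ploidy(contig, m.sex)
                    if ploidy == 0:
                        continue
                    copies = int(rng.binomial(ploidy, p_pop))
                    if copies:
                        carriers[pop] += 1
                        per_sample.append((m, copies, ploidy))
            if carriers["highland"] + carriers["lowland"] == 0:
                continue  # never called in any sample -> not a site record
            pos = pos0 + 1
            for m, copies, ploidy in per_sample:
                sample_rows[m.sample_id].append(
                    (contig, pos, ref, alt, _format_gt(copies, ploidy))
                )
            if known:
                known_rows.append((contig, pos, ref, alt))
            truth_rows.append(
                {
                    "chrom": contig,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "vtype": vtype,
                    "category": category,
                    "is_sweep": in_sweep,
                    "p_highland": p_high,
                    "p_lowland": p_low,
                    "known": known,
                    "carriers_highland": carriers["highland"],
                    "carriers_lowland": carriers["lowland"],
                }
            )

    # a handful of database entries never called in this study
    for _ in range(50):
        contig = str(int(rng.integers(1, cfg.n_autosomes + 1)))
        pos0 = int(rng.integers(0, lengths[contig] - 1))
        ref = str(fa[contig])[pos0]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        known_rows.append((contig, pos0 + 1, ref, alt))

    highland, lowland = [], []
    for metas, bucket in ((high_meta, highland), (low_meta, lowland)):
        for m in metas:
            path = outdir / f"{m.sample_id}.vcf"
            _write_vcf(path, m.sample_id, lengths, sample_rows[m.sample_id])
            bucket.append((m, path))

    known_path = outdir / "known.vcf"
    order = {c: i for i, c in enumerate(lengths)}
    with open(known_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(set(known_rows), key=lambda r: (order[r[0]], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")

    truth = pd.DataFrame(truth_rows)
    for key in truth.itertuples():
        VariantKey(key.chrom, key.pos, key.ref, key.alt)  # invariant check
    return highland, lowland, known_path, truth


# ---------------------------------------------------------------------------
# phenotypes, gene sets, replication


def simulate_phenotypes(cfg: SimConfig) -> pd.DataFrame:
    """Correlated Gaussian traits for a mixed-sex phenotype cohort.

    Traits share four latent factors (hence realistic correlation
    structure); the highland group mean is shifted by
    ``phenotype_effect`` trait standard deviations on the first
    ``n_effect_traits`` traits.
    """
    rng = cfg.rng(_STAGE_PHENOTYPES)
    n_low, n_high = cfg.n_pheno_lowland, cfg.n_pheno_highland
    n = n_low + n_high
    k = 4
    loadings = rng.uniform(0.2, 0.8, size=(k, cfg.n_traits)) * rng.choice(
        [-1.0, 1.0], size=(k, cfg.n_traits)
    )
    factors = rng.normal(size=(n, k))
    noise = rng.normal(scale=0.5, size=(n, cfg.n_traits))
    data = factors @ loadings + noise
    trait_sd = np.sqrt((loadings**2).sum(axis=0) + 0.25)
    populations = ["lowland"] * n_low + ["highland"] * n_high
    shift = np.zeros(cfg.n_traits)
    shift[: cfg.n_effect_traits] = cfg.phenotype_effect
    for i, pop in enumerate(populations):
        if pop == "highland":
            data[i] += shift * trait_sd
    cols = [f"trait_{j + 1:02d}" for j in range(cfg.n_traits)]
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "sample_id", [f"P{i + 1:02d}" for i in range(n)])
    df.insert(1, "population", populations)
    df.insert(2, "sex", ["male" if i % 2 == 0 else "female" for i in range(n)])
    return df


def simulate_gene_sets(cfg: SimConfig, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Random term -> gene annotation table (columns gene_id, term)."""
    rng = cfg.rng(_STAGE_GENESETS)
    genes = list(gene_ids)
    rows = []
    for t in range(cfg.n_gene_sets):
        size = int(rng.integers(5, min(31, max(6, len(genes)))))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        for gi in members:
            rows.append({"gene_id": genes[int(gi)], "term": f"T{t + 1:03d}"})
    return pd.DataFrame(rows)


def simulate_replication_cohort(
    cfg: SimConfig, truth: pd.DataFrame, outdir: Path
) -> List[Tuple[SampleMeta, Path]]:
    """Draw a fresh highland cohort from the truth-table highland allele
    frequencies and write per-sample VCFs (for replication validation)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng(_STAGE_REPLICATION)
    lengths = cfg.contig_lengths()
    n = cfg.n_replicates
    sexes = [Sex.MALE] * ((n + 1) // 2) + [Sex.FEMALE] * (n // 2)
    metas = [
        SampleMeta(f"R{i + 1}", Population.HIGHLAND, sexes[i]) for i in range(n)
    ]
    rows: Dict[str, List[Tuple[str, int, str, str, str]]] = {m.sample_id: [] for m in metas}
    for site in truth.itertuples():
        p = float(site.p_highland)
        if p <= 0.0:
            continue
        for m in metas:
            ploidy = _ploidy(site.chrom, m.sex)
            if ploidy == 0:
                continue
            copies = int(rng.binomial(ploidy, p))
            if copies:
                rows[m.sample_id].append(
                    (site.chrom, site.pos, site.ref, site.alt, _format_gt(copies, ploidy))
                )
    out = []
    for m in metas:
        path = outdir / f"{m.sample_id}.vcf"
        _write_vcf(path, m.sample_id, lengths, rows[m.sample_id])
        out.append((m, path))
    return out


def simulate_study(cfg: SimConfig, outdir: Path) -> SimulatedStudy:
    """Generate the complete study (genome, populations, phenotypes,
    gene sets, replication cohort) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, gff = simulate_genome(cfg, outdir)
    highland, lowland, known_vcf, truth = simulate_populations(cfg, fasta, outdir / "vcf")
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    phenotypes = simulate_phenotypes(cfg)
    phenotype_path = outdir / "phenotypes.tsv"
    phenotypes.to_csv(phenotype_path, sep="\t", index=False)

    from .io import read_genome_annotation

    ann = read_genome_annotation(gff, fasta)
    gene_sets = simulate_gene_sets(cfg, [g.gene_id for g in ann.gene_spans])
    gene_sets_path = outdir / "gene_sets.tsv"
    gene_sets.to_csv(gene_sets_path, sep="\t", index=False)

    replication = simulate_replication_cohort(cfg, truth, outdir / "replication")

    manifest = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "population": m.population.value,
                "sex": m.sex.value,
                "vcf_path": str(p),
            }
            for m, p in highland + lowland
        ]
    )
    manifest.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    return SimulatedStudy(
        config=cfg,
        fasta=fasta,
        gff=gff,
        highland=highland,
        lowland=lowland,
        known_vcf=known_vcf,
        truth=truth,
        truth_path=truth_path,
        phenotypes=phenotypes,
        phenotype_path=phenotype_path,
        gene_sets_path=gene_sets_path,
        replication=replication,
    )
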