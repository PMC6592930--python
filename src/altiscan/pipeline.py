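"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes: ingest -> population contrast (per sex and
pooled) -> novelty and coding classification -> variant-type
distribution tests -> F_ST sweep scan and gene-set enrichment ->
variant-density enrichment -> mtDNA table -> structure and phenotype
analyses -> replication validation (when a cohort is supplied).  Every
stage logs record counts and writes a fixed-name TSV report; a manifest
records the seed and parameter echo so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .contrast import (
    FrequencyThreshold,
    classify_coding,
    consequence_summary,
    differential_variants,
    flag_novel,
    mtdna_classify,
    validation_table,
)
from .datamodel import Population, PopulationCallSet, SampleMeta
from .density import density_profiles, max_density_region, profiles_to_frame, rank_chromosomes, region_genes
from .fst import fst_scan, geneset_enrichment, genes_in_windows, windows_to_frame
from .io import read_genome_annotation, read_known_vcf, read_population_vcfs, read_sample_manifest
from .simulate import SimConfig, simulate_study
from .stats import nonsignificant_report, per_chromosome_chisq, per_type_distribution_test
from .structure import (
    allele_frequency_table,
    choose_n_components,
    discriminant_classify,
    genotype_indicator_matrix,
    mca,
    nei_standard_distance,
    phenotype_pca,
    sample_snv_genotypes,
    upgma,
)

logger = logging.getLogger("altiscan")

__all__ = ["RunConfig", "run_pipeline", "make_demo"]

REPORT_FILES = [
    "differential.tsv",
    "common.tsv",
    "table6.tsv",
    "table10_mtdna.tsv",
    "tests_table4.tsv",
    "tests_table5.tsv",
    "fst_windows.tsv",
    "top_windows.bed",
    "enrichment.tsv",
    "density_profiles.tsv",
    "dense_regions.bed",
    "mca_coords.tsv",
    "pca_table1.tsv",
    "confusion_table2.tsv",
]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs (paths and thresholds)."""

    sample_manifest: str
    genome_fasta: str
    annotation_gff: str
    output_dir: str
    known_vcf: Optional[str] = None
    gene_sets: Optional[str] = None
    phenotypes: Optional[str] = None
    replication_manifest: Optional[str] = None
    frequency_threshold: float = 100.0
    window: int = 100_000
    step: int = 50_000
    top_fraction: float = 0.05
    min_snvs: int = 1
    alpha: float = 0.01
    target_fraction: float = 0.2
    mca_sites: int = 10_000
    pca_cumulative_target: float = 0.92
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_population(
    manifest: Sequence[Tuple[SampleMeta, str]], population: Population
) -> PopulationCallSet:
    entries = [(m, p) for m, p in manifest if m.population == population]
    if not entries:
        raise ValueError(f"no {population.value} samples in manifest")
    return read_population_vcfs([p for _, p in entries], [m for m, _ in entries])


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all stages; returns a dict of in-memory results and writes
    the report bundle under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    manifest = read_sample_manifest(config.sample_manifest)
    high = _load_population(manifest, Population.HIGHLAND)
    low = _load_population(manifest, Population.LOWLAND)
    logger.info(
        "ingest: %d highland records, %d lowland records",
        len(high.records), len(low.records),
    )

    genome = Fasta(config.genome_fasta)
    ann = read_genome_annotation(config.annotation_gff, config.genome_fasta)
    known = read_known_vcf(config.known_vcf) if config.known_vcf else None

    # --- contrast per stratum ------------------------------------------------
    threshold = FrequencyThreshold(config.frequency_threshold)
    contrast_rows, table6_rows, common_rows = [], [], []
    contrasts = {}
    for stratum in ("male", "female", "pooled"):
        res = differential_variants(high, low, threshold, stratum)
        res.check_partition()  # count conservation, asserted at run time
        contrasts[stratum] = res
        logger.info(
            "contrast[%s]: observed=%d diff_high=%d diff_low=%d common=%d below=%d",
            stratum, res.n_observed,
            len(res.differential[Population.HIGHLAND]),
            len(res.differential[Population.LOWLAND]),
            len(res.common), len(res.below_threshold),
        )
        for pop, recs in res.differential.items():
            for key in sorted(recs):
                contrast_rows.append(
                    {"stratum": stratum, "population": pop.value, "chrom": key.chrom,
                     "pos": key.pos, "ref": key.ref, "alt": key.alt}
                )
        for key in sorted(res.common):
            common_rows.append(
                {"stratum": stratum, "chrom": key.chrom, "pos": key.pos,
                 "ref": key.ref, "alt": key.alt,
                 "strict": key in res.strict_common}
            )
        # Table-6-shaped classification of differential variants
        recs = [
            r
            for pop in res.differential
            for r in res.differential[pop].values()
        ]
        if known is not None:
            flag_novel(recs, known)
        cons = consequence_summary(classify_coding(recs, genome, ann))
        table6_rows.append(
            {
                "stratum": stratum,
                "total_variants": len(recs),
                "novel_variants": sum(1 for r in recs if r.known is False)
                if known is not None else "NA",
                "coding_variants": cons["coding"],
                "non_coding_variants": cons["non_coding"],
                "aa_changes": cons["aa_changes"],
            }
        )
    pd.DataFrame(contrast_rows).to_csv(out / "differential.tsv", sep="\t", index=False)
    pd.DataFrame(common_rows).to_csv(out / "common.tsv", sep="\t", index=False)
    pd.DataFrame(table6_rows).to_csv(out / "table6.tsv", sep="\t", index=False)
    results["contrasts"] = contrasts
    if known is None:
        logger.warning("no known-variants VCF supplied; novelty columns are NA")

    # --- distribution tests --------------------------------------------------
    table4 = per_type_distribution_test(high, low)
    table4.to_csv(out / "tests_table4.tsv", sep="\t", index=False)
    chisq = per_chromosome_chisq(high, low, stratify_by_sex=True)
    nonsig = nonsignificant_report(chisq)
    chisq.to_csv(out / "tests_table5_cells.tsv", sep="\t", index=False)
    nonsig.to_csv(out / "tests_table5.tsv", sep="\t", index=False)
    logger.info("distribution tests: %d type rows, %d chromosome cells", len(table4), len(chisq))
    results["table4"] = table4
    results["table5"] = nonsig

    # --- FST scan + enrichment ----------------------------------------------
    sites, windows = fst_scan(
        high, low, ann.contig_lengths,
        window=config.window, step=config.step,
        min_snvs=config.min_snvs, fraction=config.top_fraction,
    )
    wdf = windows_to_frame(windows)
    wdf.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
    top = wdf[wdf["is_top"]]
    with open(out / "top_windows.bed", "w") as fh:
        for row in top.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.mean_fst:.6g}\n")
    candidates = genes_in_windows(windows, ann)
    logger.info(
        "fst scan: %d SNVs, %d windows, %d top, %d candidate genes",
        len(sites), len(windows), len(top), len(candidates),
    )
    results["fst_sites"], results["fst_windows"] = sites, windows

    enrichment_df = pd.DataFrame(
        columns=["term_id", "term_size", "overlap", "p_value", "p_adjusted", "significant"]
    )
    if config.gene_sets and len(candidates):
        gs = pd.read_csv(config.gene_sets, sep="\t")
        genesets = {
            term: set(grp["gene_id"]) for term, grp in gs.groupby("term")
        }
        universe = [g.gene_id for g in ann.gene_spans]
        enr = geneset_enrichment(
            set(candidates["gene_id"]) & set(universe), universe, genesets,
            alpha=config.alpha,
        )
        enrichment_df = pd.DataFrame(
            [
                {"term_id": e.term_id, "term_size": e.term_size, "overlap": e.overlap,
                 "p_value": e.p_value, "p_adjusted": e.p_adjusted,
                 "significant": e.significant}
                for e in enr
            ]
        )
    enrichment_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    results["enrichment"] = enrichment_df

    # --- density enrichment (on pooled differential variants) ----------------
    pooled = contrasts["pooled"]
    diff_keys = [
        k for pop in pooled.differential for k in pooled.differential[pop]
    ]
    positions_by_chrom: Dict[str, List[int]] = {}
    for k in diff_keys:
        positions_by_chrom.setdefault(k.chrom, []).append(k.pos)
    profiles = density_profiles(positions_by_chrom, ann.contig_lengths)
    profiles_to_frame(profiles).to_csv(out / "density_profiles.tsv", sep="\t", index=False)
    best_chrom, tied = rank_chromosomes(profiles)
    dense_rows = []
    region = None
    if profiles[best_chrom].n_variants:
        region = max_density_region(
            positions_by_chrom[best_chrom],
            ann.contig_lengths[best_chrom],
            target_fraction=config.target_fraction,
            ann=ann,
            chrom=best_chrom,
        )
        region_genes(region, ann).to_csv(out / "dense_region_genes.tsv", sep="\t", index=False)
        dense_rows.append(
            f"{region.chrom}\t{region.start}\t{region.end}\t"
            f"{region.n_in_region}/{region.n_variants}"
        )
    (out / "dense_regions.bed").write_text("\n".join(dense_rows) + ("\n" if dense_rows else ""))
    logger.info("density: max standard frequency on %s%s", best_chrom, " (tie)" if tied else "")
    results["density_profiles"], results["dense_region"] = profiles, region

    # --- mtDNA table ----------------------------------------------------------
    mt_table = mtdna_classify(high, low, known or set(), genome, ann)
    mt_table.to_csv(out / "table10_mtdna.tsv", sep="\t", index=False)
    results["mtdna"] = mt_table

    # --- structure: Nei + UPGMA + MCA ----------------------------------------
    fx, fy, _ = allele_frequency_table(high, low)
    nei = nei_standard_distance(fx, fy)
    dmat = pd.DataFrame(
        [[0.0, nei.D], [nei.D, 0.0]],
        index=["highland", "lowland"], columns=["highland", "lowland"],
    )
    tree = upgma(dmat)
    (out / "upgma.nwk").write_text(tree + "\n")
    rng = np.random.default_rng([config.seed, 77])
    genotypes = sample_snv_genotypes(high, low, n_sites=config.mca_sites, rng=rng)
    indicator, n_vars = genotype_indicator_matrix(genotypes)
    mca_res = mca(indicator, n_vars)
    coords = mca_res.coordinates.copy()
    coords.insert(0, "sample_id", coords.index)
    coords.to_csv(out / "mca_coords.tsv", sep="\t", index=False)
    logger.info(
        "structure: Nei D=%.4f, MCA axes %.1f%%/%.1f%%",
        nei.D, mca_res.inertia_pct[0], mca_res.inertia_pct[1],
    )
    results["nei"], results["upgma"], results["mca"] = nei, tree, mca_res

    # --- phenotypes -----------------------------------------------------------
    results["pca"] = results["confusion"] = None
    if config.phenotypes:
        pheno = pd.read_csv(config.phenotypes, sep="\t")
        traits = pheno.drop(columns=[c for c in ("sample_id", "population", "sex") if c in pheno])
        pca = phenotype_pca(traits)
        k = choose_n_components(pca, config.pca_cumulative_target)
        table1 = pd.DataFrame(
            {
                "component": np.arange(1, len(pca.eigenvalues) + 1),
                "eigenvalue": pca.eigenvalues,
                "proportion": pca.proportions,
                "cumulative": pca.cumulative,
            }
        )
        table1.to_csv(out / "pca_table1.tsv", sep="\t", index=False)
        confusion = discriminant_classify(pca.scores.iloc[:, :k], pheno["population"])
        cm = confusion.counts.copy()
        cm.insert(0, "true_group", cm.index)
        cm.to_csv(out / "confusion_table2.tsv", sep="\t", index=False)
        logger.info(
            "phenotypes: %d components (%.0f%% variance), accuracy %.2f",
            k, 100 * pca.cumulative[k - 1], confusion.overall_correct,
        )
        results["pca"], results["confusion"], results["n_components"] = pca, confusion, k

    # --- validation -----------------------------------------------------------
    results["validation"] = None
    if config.replication_manifest:
        rep_manifest = read_sample_manifest(config.replication_manifest)
        cohort = [read_population_vcfs([p], [m]) for m, p in rep_manifest]
        novel_high = [
            k
            for k, r in contrasts["pooled"].differential[Population.HIGHLAND].items()
            if known is None or not r.known
        ]
        table11 = validation_table(novel_high, cohort)
        table11.to_csv(out / "validation_table11.tsv", sep="\t", index=False)
        logger.info("validation: %d variants against %d replicates", len(table11), len(cohort))
        results["validation"] = table11

    manifest_record = {
        "altiscan_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest_record, indent=2) + "\n")
    return results


def make_demo(seed: int, outdir) -> RunConfig:
    """Generate the default synthetic study on disk and a matching run
    config (written as ``run.yaml``); returns the config."""
    outdir = Path(outdir)
    cfg = SimConfig(seed=seed)
    study = simulate_study(cfg, outdir / "data")
    rep_manifest = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "population": m.population.value,
             "sex": m.sex.value, "vcf_path": str(p)}
            for m, p in study.replication
        ]
    )
    rep_path = outdir / "data" / "replication.tsv"
    rep_manifest.to_csv(rep_path, sep="\t", index=False)
    run = RunConfig(
        sample_manifest=str(outdir / "data" / "samples.tsv"),
        genome_fasta=str(study.fasta),
        annotation_gff=str(study.gff),
        known_vcf=str(study.known_vcf),
        gene_sets=str(study.gene_sets_path),
        phenotypes=str(study.phenotype_path),
        replication_manifest=str(rep_path),
        output_dir=str(outdir / "reports"),
        seed=seed,
    )
    run.to_yaml(outdir / "run.yaml")
    logger.info("demo study written; truth table at %s", study.truth_path)
    return run
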