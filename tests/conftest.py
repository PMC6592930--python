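"""Shared fixtures: one synthetic study per session plus call-set builders."""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Tuple

import pandas as pd
import pytest
from pyfaidx import Fasta

from altiscan.datamodel import (
    Population,
    PopulationCallSet,
    SampleMeta,
    Sex,
    VariantKey,
    VariantRecord,
)
from altiscan.io import read_genome_annotation, read_known_vcf, read_population_vcfs
from altiscan.simulate import SimConfig, SimulatedStudy, simulate_study

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> SimulatedStudy:
    cfg = SimConfig(seed=STUDY_SEED)
    return simulate_study(cfg, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def callsets(study) -> Tuple[PopulationCallSet, PopulationCallSet]:
    high = read_population_vcfs(
        [p for _, p in study.highland], [m for m, _ in study.highland]
    )
    low = read_population_vcfs(
        [p for _, p in study.lowland], [m for m, _ in study.lowland]
    )
    return high, low


@pytest.fixture(scope="session")
def annotation(study):
    return read_genome_annotation(study.gff, study.fasta)


@pytest.fixture(scope="session")
def genome(study) -> Fasta:
    return Fasta(str(study.fasta))


@pytest.fixture(scope="session")
def known_keys(study):
    return read_known_vcf(study.known_vcf)


@pytest.fixture(scope="session")
def truth(study) -> pd.DataFrame:
    return study.truth


@pytest.fixture(scope="session")
def replication_cohort(study):
    return [read_population_vcfs([p], [m]) for m, p in study.replication]


def build_callset(
    population: str,
    sample_sexes: Sequence[str],
    carriers_by_key: Mapping[VariantKey, Iterable[str]],
    prefix: str = "S",
) -> PopulationCallSet:
    """Hand-built call set: samples named <prefix>1.. with given sexes and
    heterozygous carriage of the listed variants."""
    metas = [
        SampleMeta(f"{prefix}{i + 1}", Population(population), Sex(sex))
        for i, sex in enumerate(sample_sexes)
    ]
    ids = {m.sample_id for m in metas}
    records: Dict[VariantKey, VariantRecord] = {}
    for key, carriers in carriers_by_key.items():
        carriers = list(carriers)
        assert set(carriers) <= ids
        ploidy = 1 if key.chrom in ("MT", "W") else 2
        genotypes = {
            s: ((1,) if ploidy == 1 else (0, 1)) for s in carriers
        }
        records[key] = VariantRecord.from_genotypes(key, genotypes)
    return PopulationCallSet(Population(population), metas, records)


def snv(chrom: str, pos: int, ref: str = "A", alt: str = "G") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)
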