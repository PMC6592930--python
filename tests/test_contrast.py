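"""Differential/common extraction, novelty, coding consequences, mtDNA,
and replication validation."""

import pytest
from Bio.Seq import Seq

from altiscan.contrast import (
    FrequencyThreshold,
    classify_coding,
    common_variants,
    consequence_summary,
    differential_variants,
    flag_novel,
    mtdna_classify,
    validation_percentage,
    validation_table,
)
from altiscan.datamodel import Population, VariantKey, VariantRecord

from conftest import build_callset, snv


@pytest.fixture
def pair():
    """5+5 samples; variants covering the headline threshold cases."""
    high_keys = {
        snv("1", 100): ["S1", "S2", "S3"],           # 3/5 highland, absent lowland
        snv("1", 200): ["S1", "S2", "S3", "S4", "S5"],  # 5/5 but also in lowland
        snv("1", 300): ["S1"],                        # 1/5 private
        snv("1", 400): ["S1", "S2", "S3", "S4", "S5"],  # 5/5 private
    }
    low_keys = {
        snv("1", 200): ["T1"],
        snv("1", 500): ["T1", "T2", "T3", "T4", "T5"],  # 5/5 private lowland
    }
    sexes = ["male", "male", "male", "female", "female"]
    high = build_callset("highland", sexes, high_keys, prefix="S")
    low = build_callset("lowland", sexes, low_keys, prefix="T")
    return high, low


class TestDifferentialVariants:
    def test_threshold_arithmetic(self, pair):
        high, low = pair
        res = differential_variants(high, low, FrequencyThreshold(50), "pooled")
        assert snv("1", 100) in res.differential[Population.HIGHLAND]  # 0.60 >= 0.50
        res100 = differential_variants(high, low, FrequencyThreshold(100), "pooled")
        assert snv("1", 100) not in res100.differential[Population.HIGHLAND]
        assert snv("1", 100) in res100.below_threshold

    def test_presence_in_control_disqualifies(self, pair):
        """A variant in 5/5 highland and 1/5 lowland is common, never
        differential at any threshold."""
        high, low = pair
        for t in (0, 25, 50, 75, 100):
            res = differential_variants(high, low, FrequencyThreshold(t), "pooled")
            assert snv("1", 200) not in res.differential[Population.HIGHLAND]
            assert snv("1", 200) in res.common

    def test_tie_at_threshold_included(self, pair):
        high, low = pair
        res = differential_variants(high, low, FrequencyThreshold(100), "pooled")
        assert snv("1", 400) in res.differential[Population.HIGHLAND]
        assert snv("1", 500) in res.differential[Population.LOWLAND]

    def test_stratum_restricts_samples(self, pair):
        high, low = pair
        # S1-S3 are the males: 3/3 male carriage passes t=100 in the male stratum
        res = differential_variants(high, low, FrequencyThreshold(100), "male")
        assert snv("1", 100) in res.differential[Population.HIGHLAND]

    def test_empty_stratum_errors(self):
        high = build_callset("highland", ["male"], {}, prefix="S")
        low = build_callset("lowland", ["male"], {}, prefix="T")
        with pytest.raises(ValueError, match="female"):
            differential_variants(high, low, FrequencyThreshold(0), "female")

    def test_nonstandard_threshold_warns(self):
        with pytest.warns(UserWarning):
            FrequencyThreshold(33)

    def test_monotone_in_threshold_on_study(self, callsets):
        """Raising the threshold never adds a differential variant."""
        high, low = callsets
        previous = None
        for t in (100, 75, 50, 25, 0):
            res = differential_variants(high, low, FrequencyThreshold(t), "pooled")
            keys = set(res.differential[Population.HIGHLAND]) | set(
                res.differential[Population.LOWLAND]
            )
            if previous is not None:
                assert previous <= keys
            previous = keys

    @pytest.mark.parametrize("stratum", ["male", "female", "pooled"])
    def test_partition_conservation_on_study(self, callsets, stratum):
        high, low = callsets
        res = differential_variants(high, low, FrequencyThreshold(50), stratum)
        res.check_partition()  # raises on violation

    def test_fully_carried_private_sites_differential_at_100(self, callsets, truth):
        high, low = callsets
        res = differential_variants(high, low, FrequencyThreshold(100), "pooled")
        n = len(high.samples)
        private_full = truth[
            (truth.category == "private_highland") & (truth.carriers_highland == n)
        ]
        assert len(private_full) > 0
        for row in private_full.itertuples():
            key = VariantKey(row.chrom, row.pos, row.ref, row.alt)
            assert key in res.differential[Population.HIGHLAND]


class TestCommonVariants:
    def test_strict_requires_full_carriage_everywhere(self, pair):
        high, low = pair
        any_c, strict = common_variants(high, low, "pooled")
        assert snv("1", 200) in any_c
        assert snv("1", 200) not in strict  # only 1/5 lowland samples
        assert snv("1", 300) not in any_c   # private to highland

    def test_full_carriage_both_populations_is_strict(self):
        key = snv("2", 10)
        high = build_callset("highland", ["male", "female"], {key: ["S1", "S2"]}, "S")
        low = build_callset("lowland", ["male", "female"], {key: ["T1", "T2"]}, "T")
        any_c, strict = common_variants(high, low, "pooled")
        assert key in strict and key in any_c


class TestFlagNovel:
    def test_allele_aware_matching(self):
        known = {snv("1", 100, "A", "G")}
        recs = [
            VariantRecord.from_genotypes(snv("1", 100, "A", "G"), {"s": (0, 1)}),
            VariantRecord.from_genotypes(snv("1", 100, "A", "T"), {"s": (0, 1)}),
        ]
        flag_novel(recs, known)
        assert recs[0].known is True
        assert recs[1].known is False  # same position, different alt

    def test_empty_known_set_all_novel(self):
        recs = [VariantRecord.from_genotypes(snv("1", 5), {"s": (0, 1)})]
        flag_novel(recs, set())
        assert recs[0].known is False


def _mini_gene(tmp_path, strand="+"):
    """One-exon gene with CDS ATG GAT TAA at positions 101-109 (1-based)."""
    from altiscan.io import read_genome_annotation
    from pyfaidx import Fasta

    cds = "ATGGATTAA"
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    seq = "A" * 100 + cds + "C" * 91
    fasta = tmp_path / "g.fa"
    fasta.write_text(">1\n" + seq + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "\n".join(
            [
                "##gff-version 3",
                "##sequence-region 1 1 200",
                f"1\ttest\tgene\t101\t109\t.\t{strand}\t.\tID=g1",
                f"1\ttest\tmRNA\t101\t109\t.\t{strand}\t.\tID=t1;Parent=g1",
                f"1\ttest\tCDS\t101\t109\t.\t{strand}\t0\tID=c1;Parent=t1",
            ]
        )
        + "\n"
    )
    return Fasta(str(fasta)), read_genome_annotation(gff, fasta)


class TestClassifyCoding:
    def test_missense_on_plus_strand(self, tmp_path):
        """GAT -> GAA at codon 2 third base: Asp2Glu missense."""
        genome, ann = _mini_gene(tmp_path, "+")
        rec = VariantRecord.from_genotypes(VariantKey("1", 106, "T", "A"), {"s": (0, 1)})
        (cons,) = classify_coding([rec], genome, ann)
        assert cons.region == "coding"
        assert cons.effect == "missense"
        assert cons.aa_change == ("D", 2, "E")

    def test_synonymous_excluded_from_aa_changes(self, tmp_path):
        """GAT -> GAC keeps Asp: synonymous, no amino-acid change."""
        genome, ann = _mini_gene(tmp_path, "+")
        rec = VariantRecord.from_genotypes(VariantKey("1", 106, "T", "C"), {"s": (0, 1)})
        (cons,) = classify_coding([rec], genome, ann)
        assert cons.effect == "synonymous"
        assert cons.aa_change is None
        summary = consequence_summary([cons])
        assert summary == {"coding": 1, "non_coding": 0, "aa_changes": 0}

    def test_nonsense_detected(self, tmp_path):
        """GAT -> TAT is missense; ATG -> TAG... use codon2 GAT -> TAA? edit
        middle codon to a stop: GAT (104-106) -> TAA via MNV."""
        genome, ann = _mini_gene(tmp_path, "+")
        rec = VariantRecord.from_genotypes(
            VariantKey("1", 104, "GAT", "TAA"), {"s": (0, 1)}
        )
        (cons,) = classify_coding([rec], genome, ann)
        assert cons.effect == "nonsense"

    def test_noncoding_and_frameshift(self, tmp_path):
        genome, ann = _mini_gene(tmp_path, "+")
        outside = VariantRecord.from_genotypes(VariantKey("1", 50, "A", "G"), {"s": (0, 1)})
        indel = VariantRecord.from_genotypes(VariantKey("1", 105, "A", "AG"), {"s": (0, 1)})
        cons = classify_coding([outside, indel], genome, ann)
        assert cons[0].region == "non-coding"
        assert cons[1].region == "coding" and cons[1].effect == "other"

    def test_reference_mismatch_raises(self, tmp_path):
        genome, ann = _mini_gene(tmp_path, "+")
        rec = VariantRecord.from_genotypes(VariantKey("1", 106, "G", "A"), {"s": (0, 1)})
        with pytest.raises(ValueError, match="mismatch"):
            classify_coding([rec], genome, ann)

    def test_minus_strand_matches_plus_logic(self, tmp_path):
        """The same protein edit called through a minus-strand gene: the
        genomic alt is the reverse complement of the transcript edit."""
        genome, ann = _mini_gene(tmp_path, "-")
        # transcript GAT codon occupies genomic 102-104 on the minus gene
        # (transcript offset 3-5 maps to genomic 106-104); third codon
        # base (transcript T) is genomic position 104 with base A.
        rec = VariantRecord.from_genotypes(VariantKey("1", 104, "A", "T"), {"s": (0, 1)})
        (cons,) = classify_coding([rec], genome, ann)
        assert cons.region == "coding"
        assert cons.effect == "missense"
        assert cons.aa_change == ("D", 2, "E")


class TestMtdnaTable:
    def test_counts_match_raw_vcf_text(self, study, callsets, known_keys, genome, annotation):
        """Row totals agree with an independent recount from the raw VCF
        text: MT lines with a non-reference genotype, unioned over the
        samples of each population x sex cell."""
        high, low = callsets
        table = mtdna_classify(high, low, known_keys, genome, annotation)
        raw: dict = {}
        for metas in (study.highland, study.lowland):
            for m, path in metas:
                sites = set()
                for line in open(path):
                    if line.startswith("#"):
                        continue
                    f = line.split("\t")
                    if f[0] == "MT" and f[9].strip() != "0":
                        sites.add((f[0], f[1], f[3], f[4]))
                raw.setdefault((m.population.value, m.sex.value), set()).update(sites)
        for row in table.itertuples():
            assert row.total == len(raw.get((row.population, row.sex), set()))
            assert row.SNV + row.MNV + row.insertion + row.deletion + row.replacement == row.total

    def test_autosomal_variants_never_included(self, callsets, known_keys, genome, annotation):
        high, low = callsets
        table = mtdna_classify(high, low, known_keys, genome, annotation)
        mt_total = table.total.sum()
        assert mt_total <= len(
            [k for k in set(high.keys()) | set(low.keys()) if k.chrom == "MT"]
        ) * 4  # each site can appear in at most 4 (population, sex) cells


class TestValidation:
    @pytest.mark.parametrize("k,expected", [(0, 0.0), (1, 20.0), (2, 40.0), (3, 60.0), (5, 100.0)])
    def test_carriage_maps_to_20k_percent(self, k, expected):
        key = snv("1", 5928, "C", "A")
        cohort = [
            build_callset(
                "highland", ["male"],
                {key: [f"C{i + 1}1"]} if i < k else {},
                prefix=f"C{i + 1}",
            )
            for i in range(5)
        ]
        assert validation_percentage(key, cohort) == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            validation_percentage(snv("1", 1), [])

    def test_table_shape(self, callsets, replication_cohort, truth):
        keys = [
            VariantKey(r.chrom, r.pos, r.ref, r.alt)
            for r in truth.head(5).itertuples()
        ]
        tab = validation_table(keys, replication_cohort)
        assert list(tab.columns) == ["chrom", "pos", "genotype", "validation_pct"]
        assert len(tab) == 5
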