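# Methods

This note records the models, estimators, conventions and deliberate
design choices behind each stage of the pipeline, and what the
synthetic study does and does not establish about real data.

## Data model and coordinates

VCF and GFF3 are 1-based inclusive on disk; every internal interval is
0-based half-open, converted only at the I/O boundary. Variant identity
is the literal `(chrom, pos, ref, alt)` tuple with no normalisation
(no left-alignment or allele trimming): the workbench-style comparisons
this pipeline mirrors are positional, and normalising would silently
change which calls match across files. Multi-allelic lines are split
into one record per alternate allele; a sample carries the allele its
genotype names, so per-allele carrier counts conserve the original
line's carriers. MT and W are treated as haploid (diploid-coded calls
are collapsed); Z is diploid in males and hemizygous in females.

The five variant classes follow allele lengths: SNV (1 ↔ 1), MNV
(equal length > 1), insertion/deletion (shorter allele a prefix of the
longer), and **replacement** as the catch-all for length-changing
non-prefix edits. Whether "replacement" should additionally require
both alleles longer than one base is genuinely open; the prefix rule
was chosen because it makes the five classes a total partition of valid
keys, which the tests verify by property.

Absence of a record in a single-sample VCF is interpreted as a
homozygous-reference call at sites recorded elsewhere. This is the
correct reading for per-sample caller output, but it conflates "no
variant" with "no coverage"; with real data, sites invisible to a
sample for coverage reasons will deflate its allele frequency.

## Population contrast

"Present in a sample" means at least one alternate allele in the
genotype — detection level, not dosage. For stratum S (male, female or
pooled; the sexed runs mirror how such tables are usually reported, and
whether published thresholds were applied within strata is not
recoverable, so both modes exist) a variant is differential for
population A at threshold t when ≥1 of A's S-samples carries it, none
of B's S-samples does, and the carrier fraction among A's S-samples is
≥ t/100 — ties at the threshold included ("at least"), and the
denominator is the focal population's stratum size only. A variant
present in both populations is *common* and never differential at any
threshold. Two common sets are reported because the published notion is
ambiguous: any-carriage in both populations, and a strict subset
carried by every stratum sample of both (the "100% threshold" reading).
The four classes — differential(A), differential(B), common,
below-threshold — partition the observed sites exactly, and the
pipeline asserts that conservation at run time.

Novelty is allele-aware: a variant is known only if an entry with the
same chromosome, position, reference and alternate exists in the
known-variants VCF.

## Coding consequences

A variant is coding when its reference span intersects any CDS exon
(interval trees over the annotation). For length-preserving
substitutions that map contiguously into one transcript's spliced CDS,
the affected codons are translated before and after the edit with the
standard genetic code, reverse-complementing for minus-strand
transcripts. Effects are assigned from the per-position amino-acid
diff: any position gaining a stop → nonsense, losing a stop → other,
otherwise missense; identical proteins → synonymous. Indels and edits
straddling exon boundaries are "coding/other". Amino-acid-change counts
include nonsense and exclude synonymous. All overlapping transcripts
are reported (one row each); there is no isoform prioritisation. The
test suite checks the classifier against an independent oracle that
rebuilds and translates the *whole* transcript before and after each
edit, on both strands.

## Distribution tests

The two-sided Fisher exact test uses the minimum-likelihood convention
(total probability of hypergeometric outcomes no more probable than the
observed table), computed with exact integer weights sharing the common
denominator C(n, col1) — so tie decisions are never floating-point.
The per-type test is type-vs-rest per population; because the exact
contingency construction used by the legacy web tool is not
recoverable, a k×2 type-by-population chi-square mode is also provided
and the construction is documented rather than guessed. Per-chromosome
tests are Pearson chi-square (df = 1) on [[on-chrom, off-chrom] per
population] for each (sex, variant type, chromosome) cell, without
continuity correction by default (a Yates toggle exists); cells with a
zero expected count are reported untestable rather than dropped.
Benjamini–Hochberg adjustment is the standard step-up with monotonicity
enforcement, input order preserved.

## Weir–Cockerham scan

Per-SNV differentiation uses the full three-level variance-component
estimator for diploid genotype data with r = 2 populations, with
observed heterozygote proportions entering directly (no within-
population Hardy–Weinberg assumption):

    n̄  = Σnᵢ/r          n_c = (r·n̄ − Σnᵢ²/(r·n̄))/(r−1)
    p̄  = Σnᵢpᵢ/(r·n̄)    h̄  = Σnᵢhᵢ/(r·n̄)
    s² = Σnᵢ(pᵢ−p̄)²/((r−1)·n̄)
    a  = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b  = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c  = h̄/2            θ̂ = a/(a+b+c)

Negative θ̂ is retained (an estimator property near zero
differentiation, informative in window means; truncation is exposed as
an option), and a site monomorphic everywhere is flagged undefined and
skipped. Windows are [s, min(s+window, L)) for s = 0, step, 2·step, …
while s < L (default 100 kb / 50 kb); a contig shorter than one window
yields the single window [0, L). Z, W and MT are excluded from the
scan. The window score is the *unweighted mean* of per-site θ̂ (the
ratio-of-sums estimator is offered as an option); windows with fewer
than `min_snvs` (default 1 — no minimum is standard) defined SNVs are
unranked. The top fraction (default 5%, global across chromosomes, not
per-chromosome) marks ceil(f·n) windows with all ties at the cutoff
included. Because windows overlap, each SNV contributes to up to two
windows and the flanking half-overlap windows of a true sweep also
score high; this is reported as-is.

Candidate genes are gene spans intersecting any top window. Enrichment
is the upper-tail hypergeometric P(X ≥ overlap) against a user-supplied
term → gene table, with the annotation's full gene list as the default
universe, BH adjustment across terms and a 0.01 significance level.

## Variant-density enrichment

Per chromosome: standard frequency = variant count / length in Mb
(annotation lengths, never max observed position), and the cumulative
variant curve. The chromosome with the highest standard frequency is
selected (ties broken by name order and flagged). The published
procedure picks the dense region of the cumulative curve by eye; here
it is formalised as the fixed-width window (default 0.2 of the
chromosome, near the published examples' 16–27%) with the maximum
variant count, anchors at zero and at every variant position, smallest
start winning ties. The window set grows with the width, so the
captured count is monotone in the width parameter, and an exhaustive
grid scan can serve as an oracle. This is a declared surrogate for the
visual selection, not a claim about how any published boundary was
chosen.

## Structure and phenotypes

Nei's standard distance works on per-locus allele-frequency vectors
derived from genotype counts (loci monomorphic in both populations are
skipped as uninformative): I = J_xy/√(J_x·J_y) with the J's arithmetic
means over loci of Σ x·y, Σ x², Σ y²; D = −ln I, with an explicit
infinite-distance flag when no alleles are shared. UPGMA is
cluster-size-weighted average linkage; heights are half the join
distance, tied merges resolve to the lexicographically smallest pair of
cluster labels, and the emitted Newick is ultrametric to float
precision.

MCA is plain indicator-matrix correspondence analysis (no Benzécri
correction; a toggle exists): SVD of the standardised residuals of the
correspondence matrix, sample principal coordinates U·Σ scaled by row
masses, per-axis inertia σ²; the total inertia of J variables expanded
into K categories is (K−J)/J, which the tests use as a closed-form
check. Genotype categories constant across all samples are dropped with
a warning. The genotype sample is a seeded uniform random subset of
diploid SNV sites (the published "1,000 per bird" sampling protocol is
under-specified; a uniform site subset is the neutral reading).

Phenotype PCA is eigen-decomposition of the trait correlation matrix
(traits standardised; zero-variance traits dropped with a warning).
The discriminant uses the smallest number of leading components
reaching a cumulative-variance target (default 0.92) and classifies
with a pooled-covariance linear discriminant, equal priors,
resubstitution by default — published confusion tables of this design
are resubstitution tables — with leave-one-out as an option and ridge
regularisation if the pooled covariance is singular.

## Synthetic study

The generator emulates the study design end to end at desk scale: five
1 Mb autosomes plus Z (500 kb), W (200 kb) and MT (16 kb); five birds
per population (highland 3M/2F, lowland 2M/3F); ~1 variant per kb
(≈5,400 called sites), 90% SNV and 2.5% each of the other four
classes; 50% of sites entered in the known-variants VCF; a 16-bird
phenotype cohort (10 lowland, 6 highland) with 24 factor-correlated
traits and a 3σ highland shift on six of them; and a 5-bird highland
replication cohort.

Divergence follows the Balding–Nichols model: per-population
frequencies are Beta-distributed around an ancestral p ~ U(0.05, 0.95)
with variance θ·p(1−p), θ = 0.02 outside and 0.5 inside three planted
100 kb windows aligned to the scan grid — the simplest generative model
whose parameter *is* the target F_ST. Thirty percent of sites are
instead private to one population (frequency 0 in the other; 30% of
those fixed in the focal population) so that differential, common and
validation truths all exist. Genotypes are binomial draws per
individual with sex-appropriate ploidy; sites carried by nobody are not
emitted (a caller sees no such site), so the truth table matches the
VCF site union exactly. Genes are non-overlapping, 1–3 CDS exons on
both strands with nucleotide-level exon cuts (non-zero phases), coding
sequence written as ATG + non-stop codons + stop so transcripts
translate cleanly. One global seed drives per-stage substreams
(`default_rng([seed, stage])`), so stages rerun independently and
reproduce byte-identically.

What the generator does *not* emulate: linkage disequilibrium and
coalescent site correlation, recombination maps, sequencing error and
coverage dropout, genotype uncertainty, multi-allelic sites, and
realistic gene structure (UTRs, isoforms). Passing tests therefore
demonstrate correctness of the algorithms and their statistical
behaviour under the stated generative model, not robustness to
real-data artefacts — in particular, real carrier fractions are
coverage-confounded in a way the model cannot show.

## Problem sizes and numerics

The default study (~5,400 sites, 10 + 5 birds, 100 scan windows) runs
the full pipeline in well under a minute on one core and is the size
used by the test suite and the acceptance script. Estimator unit checks
run against exact-arithmetic or hand-transcribed oracles: Fisher and
hypergeometric p-values to 1e-12, Weir–Cockerham components to 1e-10,
BH to 1e-12. Degenerate inputs have defined behaviour throughout:
degenerate Fisher margins give p = 1, empty F_ST windows are flagged
rather than scored, zero expected chi-square counts are untestable,
monomorphic loci are skipped in Nei distance, and an all-shared-allele
identity of zero raises the infinite-distance flag rather than an
exception.
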