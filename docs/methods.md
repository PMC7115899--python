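# Methods

## The zygosity model

The package's core statistical object is the behaviour of diploid genotype
calls at low read depth. Reads covering a site are assumed independent and,
for a true heterozygote, to sample either allele with probability 1/2. A
true heterozygote covered by *x* reads therefore shows a single allele with
probability `P(x|het) = 1/2^(x−1)` and is then indistinguishable from a
homozygote, while a true homozygote always shows one allele
(`P(x|hom) = 1`). Consequences used throughout:

- detection rate of heterozygotes at depth *x*: `1 − 1/2^(x−1)`
  (0 at 1×, 75% at 3×);
- posterior that an all-identical-read genotype is truly homozygous, for
  prior π: `π / (π + (1−π)/2^(x−1))`. At x = 5 and π = 0.5 this is
  16/17 ≈ 94.1%; the value is sometimes quoted rounded to 95%, but the
  package reports the exact Bayes result;
- expected homozygous-looking fraction among retained genotypes if all were
  truly het, under a depth law D truncated at a minimum depth:
  `E[1/2^(X−1) | X ≥ min_depth]`, computable for an empirical depth
  histogram or any discrete distribution.

Genotypes are called from allele read counts: no reads → missing; at least
`min_allele_reads` (default 1) reads of each allele → het; otherwise the
majority allele homozygous, with exact ties called het. The default of 1
follows from the model itself — any second-allele read reveals
heterozygosity — and makes the calling rule's miscall probability exactly
`1/2^(x−1)` when the per-read error rate is zero.

## Filtering

Site filters (applied in order QUAL → call-rate → MAF → HWE, each with its
removal count reported): QUAL < 20, minor allele frequency < 0.01, exact
Hardy–Weinberg test p < `hwe_alpha`. `hwe_alpha` defaults to 1e-6, common
GWAS practice; no value is dictated by the analysis design, so it is
configurable and logged. The HWE test is the exact conditional test: given
the allele counts, heterozygote counts are enumerated with a numerically
stable two-way recurrence and the two-sided p sums all counts whose
conditional probability does not exceed the observed one.

DP < 2 is implemented as a *genotype-level mask* (set missing before site
statistics), not site removal, because depth-1 genotypes are deliberately
retained for the coverage-stratified zygosity comparison; both behaviours
exist, masking is the default. HWE is tested on the pooled cohort by
default; a per-stratum option exists because pooled HWE is confounded both
by population structure and by sex linkage itself (a fully sex-linked SNP
is a massive HWE outlier — at the default 1e-6 threshold, sites with mild
het excess pass while the association scan, not the HWE filter, is meant to
find sex linkage; users probing very strong sex signals should check the
HWE removal counts).

Sex-specific indels: an indel is reported only if ≤ 30% of its genotypes
are missing, every individual-with-data of one sex carries it (het or
hom-alt; hom-ref counts as absence), and no individual-with-data of the
other sex carries it. Carrier-sex genotype counts are reported as
(hom-alt, het).

## Association

Each SNP is tested with the Cochran–Mantel–Haenszel chi-square over
per-stratum 2×2 sex × allele tables, each called diploid contributing two
alleles:

    χ² = [Σ_k (a_k − E_k)]² / Σ_k V_k,
    E_k = r1_k c1_k / n_k,
    V_k = r1_k r2_k c1_k c2_k / (n_k² (n_k − 1)),

1 df, no continuity correction (matching the standard GWAS implementation
of the allele-based stratified test). Strata with n_k ≤ 1 or degenerate
margins contribute nothing; if all strata are degenerate the site's p is
missing. For a single stratum the statistic equals (n−1)/n times the
Pearson chi-square, an identity the test suite verifies over random tables,
together with an independent cross-check against statsmodels'
stratified-table test. p-values are floored at the smallest positive normal
double and flagged.

Genome-wide significance uses Bonferroni α/m with m defaulting to the
number of SNPs actually tested (an override exists for thresholds computed
on a larger panel). Isolated significant SNPs — fewer than `min_neighbors`
(default 1) other significant SNPs within `window_bp` (default 100 kb) —
are discarded as potentially spurious; surviving SNPs within `max_gap_bp`
(default 1 Mb) of each other merge into regions. The three spatial
parameters are genuine free choices (no principled values exist for them);
the defaults are deliberate, conservative round numbers and all three are
configurable and logged.

## Zygosity analysis and the verdict

"Coverage" for stratification is the genotype's total read depth DP,
equated with the model's identical-read count for homozygous-looking
genotypes (for called heterozygotes the two differ, but those genotypes are
not the ones at risk of miscall). Strata run from depth 1 to `x_max`
(default 21); strata with fewer than `min_stratum_n` (default 5) genotypes
are dropped from the tables, since a handful of observations cannot
distinguish the hypotheses. The per-stratum test is the two-sided exact
binomial (scipy's minimum-likelihood convention; p is exactly 1 when the
observation equals the most probable outcome), with 95% Clopper–Pearson
intervals.

The verdict rule: compute each sex's aggregate homozygous proportion and
the model expectation `E[1/2^(X−1) | X ≥ 1]` under that sex's *observed*
depth histogram. Call XY when the female proportion ≥ `hom_floor`
(default 0.95) and the male proportion is consistent with an
all-heterozygous truth — within `max(3 s.e., 0.02)` of the expectation —
while not itself reaching the floor; ZW for the mirror image; otherwise
undetermined (including when fewer than `min_snps` = 10 sex-associated SNPs
are available). The 0.02 absolute tolerance floor exists because the
expectation is computed for error-free reads, while a per-read error of
order 10⁻³ at ~2.6× shifts aggregate proportions by up to about a
percentage point. A Spearman trend check (male homozygous proportion
falling with depth) is reported as supporting evidence but does not gate
the verdict.

## Annotation

Location categories, in priority order when genes overlap: CDS > splice
site (the two intronic bases at each exon–intron junction) > UTR > intron >
promoter > intergenic; ties between genes break by smallest gene id. The
promoter is anchored at the transcription start site, 2000 bp upstream to
200 bp downstream, strand-aware; anchoring at the TSS (rather than the gene
end) was chosen because the window is meant to capture regulatory sequence.
Exonic positions that are neither CDS nor annotated UTR are assigned to
UTR5/UTR3 by their side relative to the CDS; exons of genes without any CDS
fall back to the intron-level (gene-body) category.

Coding consequences rebuild the reference codon from the spliced CDS
(reverse-complemented for minus-strand genes, honouring the phase of the
first coding segment), substitute the alternative base and translate with
the standard genetic code. Genes whose summed CDS length is not a multiple
of 3 are excluded from codon calls (flagged at GFF parse time). The FASTA
base at the variant position must equal the VCF ref; mismatches raise.

Amino-acid classes: nonpolar {G,A,V,L,I,P,F,M,W,C}, polar {S,T,Y,N,Q},
positively charged {K,R,H}, negatively charged {D,E}. A substitution is
conservative iff both residues share a class. Checked against the 18
published nonconservative substitutions this scheme is meant to reproduce,
16 rows match; the remaining two are internally inconsistent in the source
table itself — Q is printed "nonpolar" in its Q→E row but "polar" in three
other Q rows, and the same S→L substitution is printed with opposite class
directions in two rows — so no single class map can reproduce them, and the
map keeps Q and S polar.

## The synthetic-data generator

The generator emulates the statistical structure of a four-stock,
48-female / 55-male cohort sequenced to ~2.6× per individual:

- **Samples**: sexes fixed at 48/55; strata assigned by largest-remainder
  apportionment of the configured proportions (default four equal stocks).
- **Background SNPs** (default 50,000 across two chromosomes, proportional
  to length): ancestral ref-allele frequency ~ Beta(0.5, 0.5) — a U-shaped,
  frequency-spectrum-like prior; many draws fail the MAF filter, as real
  call sets do. Stratum frequencies are Balding–Nichols resamples
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.02, weak differentiation typical
  of marine stocks; genotypes are drawn in HWE within stratum.
- **Sex-linked SNPs** (default 500 uniform over a 1.2-Mb region): the
  homogametic sex is hom-ref, the heterogametic sex het with probability
  `linkage` (default 1.0, the idealised single-locus system).
- **Observation**: depth ~ Poisson(2.6) per genotype (the design's mean
  coverage; no overdispersion), heterozygote reads equiprobable per allele,
  a symmetric per-read flip with ε = 0.002 (Illumina-scale substitution
  error), genotype called by the package's rule, depth 0 → missing, QUAL
  constant 60 (QUAL generation is out of scope; the constant sits above the
  filter so simulated sites are never QUAL-filtered).
- **Determinism**: everything flows from the config seed; the observation
  seed is derived from it by a fixed multiplicative hash, and outputs are
  byte-identical across runs.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium outside the sex region,
depth overdispersion and mapping artefacts, allele-specific or
strand-specific error, batch effects between stocks, joint variant-calling
artefacts, and partially degenerated sex chromosomes (Y-specific sequence
that fails to map). Recovery of the simulated system is a necessary, not
sufficient, validation.

## Problem sizes and numerics

The test suite exercises the full study design (103 samples, 4 strata,
500 sex-linked + 50,000 background SNPs) for the parameter-recovery check
and scaled-down cohorts (~2–5k SNPs) elsewhere; Monte-Carlo checks use
10⁵–10⁶ replicates with fixed seeds. Binomial tolerances in stochastic
tests are stated as multiples (3–4×) of the exact standard error of the
quantity under test. The HWE recurrence is cached on (het, rare-copies,
n) triples, making the 50k-site scan effectively O(distinct configurations).

## Known limitations

- The heterozygote model ignores base quality; a GATK-style genotype
  likelihood model is explicitly out of scope.
- Pooled HWE filtering can in principle remove extreme sex-linked sites;
  the per-stratum option mitigates but does not remove the issue (sex
  linkage violates HWE in any mixed-sex stratum).
- Multiallelic sites are split into biallelic records with
  other-alt genotypes set missing; indels are taken as left-aligned and
  are not re-normalised.
- The verdict rule is a deliberately simple threshold scheme; cohorts with
  partial sex linkage (`linkage` well below 1) or mis-sexed individuals
  will drift toward "undetermined" rather than being modelled explicitly.
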