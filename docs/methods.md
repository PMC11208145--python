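# Methods

This note documents the models, estimators and numerical choices behind
adnakit, what the synthetic-data generator does and does not emulate, and
the design decisions that were genuinely open.

## Pseudo-haploid data model

All statistics operate on pseudo-haploid calls: at each SNP each
individual contributes a single allele (0 = reference, 1 = alternate,
missing otherwise), the standard representation for low-coverage
ancient-DNA capture data where diploid genotypes cannot be called
reliably. Internally calls are int8 with −1 for missing; EIGENSTRAT
round-trips map {ref, alt, missing} to digits {2, 0, 9} (digits count
reference-allele copies). A heterozygote digit (1) inside a declared
pseudo-haploid dataset is set to missing with a warning rather than
rejected, because merges with diploid reference panels produce them in
practice. Chromosome labels 23/24 normalize to X/Y; coordinates are
1-based.

The individual-retention filter keeps individuals with strictly more than
`min_snps` (default 20,000) covered SNPs.

## Kinship from pairwise mismatch rates

For a pair, PMR = mismatches / overlap over jointly called autosomal SNPs
(X/Y excluded: in an all-male cohort X comparisons are haploid and would
bias the rate). Under HWE with alternate-allele frequency *p*, the per-SNP
mismatch probability is 2p(1−p) for unrelated pairs; two draws from one
diploid genome mismatch only when the genotype is heterozygous and the
draws differ, giving p(1−p). First- and second-degree relatives fall at
3/4 and 7/8 of the unrelated value via the IBD mixture. Normalizing by a
cohort background — the **median** PMR over valid pairs, robust while
relatives are a minority of pairs (≲ 25%, as in cohorts of this kind) —
yields expected values 0.5 / 0.75 / 0.875 / 1.0, and pairs are classified
at the midpoints 0.625 / 0.8125 / 0.90625 (configurable). The documented
failure mode is a cohort dominated by relatives, which drags the median
down and inflates every normalized value.

Pairs with fewer than 5,000 overlapping SNPs are reported but left
unclassified: at overlap n the binomial standard error of PMR ≈ 0.3 is
√(0.21/n), so 5,000 SNPs give ≈ 0.0065 (≈ 0.02 normalized), comfortably
inside the 0.03+ margins between class expectations and bin edges.

## Genetic sexing

Rates are per-site depths relative to autosomes, computed over targeted
SNP counts (not physical chromosome lengths — the panel defines the
denominator). Decision windows, inclusive at both ends: male
0.35 ≤ x ≤ 0.55 and 0.4 ≤ y ≤ 0.7; female x ≥ 0.8 and y ≤ 0.1. The male
window follows published practice for capture data; the female window is
this package's choice (standard practice) since only male confirmation
windows are widely printed; both are configurable. The female y-tolerance
absorbs spurious Y mapping, modelled in the generator at 1% of autosomal
depth by default.

## LSBL selection scan

Per SNP, pairwise F_ST uses Hudson's estimator with sample-size
correction,

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1),

with n counted in called alleles (one per individual for pseudo-haploid
data). Hudson's ratio estimator is chosen for robustness to unequal
sample sizes; a haploid Weir–Cockerham variant sits behind
`estimator="wc"`. Negative per-SNP distances (pure sampling noise when
differentiation is weak) are clipped to 0 before the branch decomposition
— a negative distance has no branch-length interpretation — while the raw
values remain in the output table. The decomposition
x = (d_AB + d_AC − d_BC)/2 (and cyclically) is exact arithmetic, so
x + y + z = (d_AB + d_AC + d_BC)/2 holds to machine precision.

Site filters: autosomes only; individuals with > 97% missingness dropped;
pooled MAF < 0.01 dropped (strict inequalities). LD pruning slides a
200-SNP window by 25 within each chromosome; within a window, any pair
with r² > 0.4 loses its lower-MAF member (ties drop the later position);
sweeps repeat until stable, so pruning is idempotent. Pruning precedes the
scan. r² on pseudo-haploid data is the squared correlation of 0/1 call
vectors over jointly called individuals (composite correlation) — there is
no phase or diploid dosage to do better with.

Outlier tails are empirical: for tail fraction t over n scored SNPs the
threshold is the ⌈nt⌉-th largest branch value; all ties at the threshold
are flagged and smaller tails nest inside larger ones. Tails are computed
per branch, matching per-population candidate lists. Note the arithmetic
consequence: a 0.5% tail of a 10,000-SNP panel holds 50 slots, so a
simulation that plants more signals than slots can at best fill the tail
with planted loci (which the recovery tests check), never exceed it.

## f-statistics

f3(O; A, B) and f4(A, B; C, D) are plain means of per-SNP products over
complete cases. Standard errors use a delete-one block jackknife over
contiguous SNP-count blocks (default 500; the synthetic panels carry no
genetic map, so centimorgan blocks are not used; block size is
configurable). The estimate itself is independent of the partition; the
SE is √((B−1)/B · Σ(θ̂₍ⱼ₎ − θ̄)²) over leave-block-out means. No
heterozygosity correction is applied in f3 by default: outgroup-f3
*rankings* — the intended use — are unaffected by the shared offset, and
a per-SNP correction vector can be supplied.

## HLA analyses

**Frequency shifts.** One 2×2 Fisher exact test per allele (carrier vs
non-carrier counts in each cohort), two-sided by the minimum-likelihood
convention (sum of hypergeometric probabilities ≤ the observed table's).
BH correction is applied across all alleles of all loci in one family by
default — the conservative reading when the family is not stated —
with per-locus families behind a flag. Each typed individual contributes
exactly two alleles per locus; untyped individuals drop out of that
locus's total.

**Non-overlap.** The f\*_adj statistic admits several operationalizations
in the literature; this package's default is explicit and pluggable:
for the haplotype count table of a locus pair, compute conditional
allele distributions at locus 2 given each allele at locus 1; the overlap
of two alleles is Σ_j min(q_j|a, q_j|a′) (1 under identical association,
0 for disjoint support); the directed score is 1 minus the
margin-weighted mean overlap over allele pairs; f\*_adj is the mean of the
two directed scores (orientation-symmetric, relabelling-invariant, 0
under exact independence at large samples, 1 for complete non-overlap).
Any monotone non-overlap statistic can be substituted. The calibration
wrapper is the primary deliverable and is fixed: expand the table to the
haplotype list, permute the allele labels at one locus (both margins
preserved exactly), recompute the statistic for each of 5,000
permutations, and report (observed − null mean)/null SD. A zero null SD
yields an undefined score with a diagnostic rather than ±∞.

## Isotopes

QC: collagen yield strictly > 1% by weight; atomic C:N within
[2.9, 3.6] inclusive; missing fields make a record unevaluable (fails
with its own reason code). Summaries use the sample SD (n−1). The
diet-similarity test uses the mean pairwise Euclidean distance in
(δ13C, δ15N) with equal axis weights by default (both axes carry the
dietary signal; weights configurable), a label-permutation null, and a
one-sided add-one-corrected p value. With k related pairs the null can
tie the observed minimum by chance with probability that shrinks rapidly
in k; single-pair minima therefore do not reach the nominal floor.

## Synthetic-data generator

What it emulates: Beta(0.8, 0.8) ancestral frequencies (a U-shaped SFS
resembling ascertained panels; configurable); HWE founders; fair
Mendelian gene dropping (half-sib structure arises from an explicit
shared parent, never a kinship-coefficient shortcut, so IBD patterns are
exact); MZ twins share one diploid genome before pseudo-haploidization;
per-call independent missingness with an optional per-individual
multiplier; Poisson read totals per chromosome class with 1240K-like
targeted-site counts (autosomes 1,150,000; X 49,000; Y 32,000) — at
0.05–0.1× depth these panel sizes put male X/Y rates many standard errors
inside the decision windows, which is what makes deterministic recovery
tests meaningful; two-cohort HLA draws from a re-weighted haplotype pool;
three-population frequency sets with logit-scale Gaussian drift and an
additive frequency shift at selected loci (clamped inside (0, 1), so a
shift planted near a frequency boundary is genuinely attenuated).

What it does not emulate: sequence reads, post-mortem damage,
contamination, reference bias, or linkage disequilibrium from a
coalescent process (SNPs are independent given the pedigree). Passing
tests therefore validate the estimators and their calibration under the
stated sampling model, not robustness to damage/contamination artefacts
or LD-induced correlation of test statistics on real data.

The packaged fixture is a 64-member all-male cohort containing one
isolated MZ twin pair; a family of four in which a second MZ twin pair
has a half sibling through one parent, who in turn has a half sibling
through their other parent (so the outermost member is unrelated to the
twins — the configuration that reproduces a chained pair pattern without
extra second-degree links); three unrelated full-sib pairs; a
four-member half-sib chain; and 48 singletons. By construction: 11 pairs
of degree ≤ 2, two of them identical, spanning 16 individuals. A full
sibling in place of the twin-adjacent half sibling is impossible here:
any half sibling of a full sibling of twins necessarily shares a parent
with the twins, which would add two more second-degree pairs.

## Problem sizes and reproducibility

Default validation sizes: 100,000 SNPs / 10% missingness for kinship
(pair overlap ≈ 81k SNPs, normalized-PMR SE ≈ 0.005 — an order of
magnitude inside the class margins); 10,000 SNPs / 100 planted loci for
the scan; 5,000 permutations for HLA non-overlap in production and
100–300 in calibration sweeps (the SD-unit scale is already stable there).
Every stochastic component takes an explicit integer seed and is
bit-reproducible under it; derived sub-seeds come from
`numpy.random.SeedSequence` so stages never share a stream.

## Known limitations

* PMR normalization assumes relatives are a minority; it has no
  correction for cohort-wide inbreeding or strong population structure.
* The per-SNP Hudson estimator is noisy at small allele counts; the scan
  relies on empirical tails, not on the absolute F_ST scale.
* The f\*_adj default is one member of a family of non-overlap scores;
  SD-unit calibration makes rankings comparable across choices, but
  absolute score values are not comparable between statistics.
* Block-jackknife SEs assume exchangeable blocks; without a genetic map,
  SNP-count blocks under-account for long-range LD on real data.
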