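# Methods

This note documents the statistical models behind each estimator, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions fixed where the field's tools
disagree.

## Genotype model and QC

Genotypes are diploid biallelic dosages: the count of `allele_b` copies
(0/1/2) with −1 for missing calls.  In PLINK binary input `allele_b` is the
second .bim allele, so codes are format-derived and deterministic; PLINK
text input carries no allele order, so alleles are assigned
lexicographically (a read–write–read cycle is code-exact whenever both
alleles are observed; variants where one allele is absent from the file
cannot preserve orientation, an inherent limitation of the text format).

QC is a fixed single pass: (1) drop samples with call rate ≤ 0.9, (2) drop
variants with call rate ≤ 0.9 over surviving samples, (3) drop variants with
MAF < 0.05 over surviving samples, (4) keep autosomes SSC1–SSC18 only.  Call
rates are strict ("greater than"); the MAF bound keeps exact ties, matching
the dominant `--maf` tool convention.  Sample-first ordering makes the
removal report unambiguous; the report reconciles every removal against the
input dimensions.  The pass is idempotent on realistic missingness patterns
(a pathological pattern could in principle drop a sample's call rate after
variant removal; the bookkeeping would still reconcile).

Panel merging intersects variant ids, flips dosages when the allele pair is
listed in the opposite order, complements alleles for opposite-strand
encodings, and always drops strand-ambiguous A/T and C/G SNPs — without a
reference genome their orientation is undecidable.

## Diversity and inbreeding

Ho is the mean per-individual heterozygous fraction over non-missing calls.
He is the within-group Hardy–Weinberg heterozygosity 2p(1−p), multiplied by
N/(N−1) (N = genotyped group members at the SNP) for small-sample bias, and
averaged over SNPs polymorphic in the full panel.

Fis uses the homozygote-excess (method-of-moments) form
(O(HOM) − E(HOM)) / (N(NM) − E(HOM)) per individual, where E(HOM) sums
1 − 2p(1−p)·N/(N−1) over the individual's non-missing SNPs.  The allele
frequency reference is an explicit parameter:

* `pooled_panel` (default) computes p over all panel samples.  In a
  structured multi-breed panel this makes Fis absorb the Wahlund effect, so
  breeds can show Ho ≥ He together with strongly positive Fis — the behavior
  of published multi-breed diversity tables produced by whole-panel tool
  runs, and the reason this is the default for reproducing them.
* `within_group` computes p within the breed and is the statistically
  conventional estimate; under Hardy–Weinberg simulation its mean converges
  to the simulated inbreeding coefficient (tested at F = 0 and 0.5).

The breed-level CV of Fis uses the population (ddof = 0) standard deviation;
a convention had to be fixed and this one is stable for small breeds.

## Distances, trees, PCA

The allele-sharing distance is 1 − Dst with Dst the mean per-SNP shared
fraction (1, 0.5, 0) over pairwise-complete SNPs — no imputation, because
the statistic is defined on observed alleles.  Breed-average matrices
average cross pairs off-diagonal and distinct within pairs on the diagonal.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration.  Two
conventions are fixed for determinism and valid output: Q ties break on the
lowest active-node index pair, and a negative branch length is clamped to
zero with the deficit moved to its sibling so the pair still sums to their
distance.  On additive matrices the recovered topology is exact (verified
against an independent implementation and against generating trees).
Bootstrap support resamples SNP columns with replacement and reports, for
each internal edge of the point-estimate tree, the fraction of replicate
trees containing that bipartition.

PCA mean-imputes missing dosages per SNP, centers, scales by the empirical
SD, and takes the SVD; it is deliberately plain — the package's inferences
do not depend on a particular PCA scaling.

## Differentiation

The default Fst is the Weir–Cockerham (1984) two-population diploid
estimator: per locus the variance components a (among populations), b
(among individuals within populations) and c (within individuals) are
formed from sample sizes, allele frequencies and observed heterozygote
frequencies; the multi-locus aggregate is Σa / Σ(a+b+c) (ratio of sums),
which is less biased than averaging per-locus ratios.  Loci monomorphic in
the pooled sample are excluded (0/0).  A plain Nei-style (Ht−Hs)/Ht option
exists for scan comparisons.  Under the Balding–Nichols model with equal
drift F in both populations the estimator recovers F within ±0.02 at
200 samples × 5,000 SNPs.  The qualitative bands are lower-inclusive:
[0, 0.05) low, [0.05, 0.15) moderate, [0.15, 0.25) great, ≥ 0.25 high —
printed band edges overlap in common usage, so a convention is fixed.

## LD and historic Ne

r² is the squared Pearson correlation of genotype dosages (composite LD) —
appropriate for unphased array data — over all intra-chromosome pairs
within 1 Mb and a 9,999-SNP index window.  Decay uses the fixed kb ladder
0–1, 1–3, 3–6, 6–9, 9–15, 15–30, 30–40, 40–60, 60–80, 80–100, 100–150,
150–200, 200–250, 250–300, 300–500, 500–800, 800–1000.  The r² = 0.3 extent
is, by default, the linear-interpolation crossing between consecutive
non-empty bin midpoints (0 kb if the first non-empty bin is already below
0.3; censored ">1000" if the curve never crosses).  A `midpoint` dialect
reports the first bin midpoint below threshold instead — published extents
mix both conventions, so the rule is a documented knob.

Historic Ne follows the Sved-lineage relation N(t) = (1/(4c))(1/E[r²_adj] − α)
with t = 1/(2c).  Per distance bin, c is the Haldane-map recombination
fraction of the bin midpoint at a constant map density (default 1 cM/Mb),
r²_adj = r² − 1/(2n) corrects sample size, and α defaults to 1 (drift
without mutation).  All mapping constants are parameters.  Bins whose
adjusted LD would give non-positive Ne are dropped.  Against a forward
Wright–Fisher simulation at Ne = 100 (200 generations, 2,000 SNPs on
100 cM) the recent-generation estimates land within a factor of 2.

## f3 admixture test

f3(X; A, B) averages (x − p_A)(x − p_B) over SNPs with data in all three
groups, subtracting x(1−x)/(2n_X − 1) — the unbiased estimator of the
sampling variance of x — so that an unadmixed target drifting from both
sources has positive expectation and a true intermediate is negative.  The
standard error is a delete-one-block jackknife over consecutive 200-SNP
blocks along the sorted map (trailing block kept if at least half size;
the weighted jackknife form handles the unequal tail exactly).  Z < −2 is
reported as the admixture call.  Under pure three-way drift the false-call
rate measured over 50 replicates is far below the nominal tail.

## Subfamily classification

The farm algorithm has two phases.  *Split:* walk the NJ tree's leaves in
tree order and join consecutive individuals into one subfamily only when
their distance is below mean − 2·SD of all pairwise distances in the farm
(threshold factor and rule are parameters; the permissive ±SD-band reading
of the rule is available behind a flag, since "within two standard
deviations" is ambiguous in common usage).  A non-positive threshold
legitimately yields all singletons.  *Merge:* iteratively merge the pair of
subfamilies with the lowest pairwise Fst among pairs violating the 0.05
floor (undefined Fst — singleton subfamilies — counts as a violation,
ordered by distance), otherwise the closest pair by mean between distance;
ties break on the smallest index pair.  Stop with success when every
pairwise Fst exceeds 0.05 and the CV of between-subfamily mean distances is
below 10% (CV over subfamily-pair means, not over all cross pairs), or with
`success=False` at two subfamilies.  Diagnostics are recomputed from the
final assignment, so the success flag is verifiable after the fact.  On
simulated four-family farms with drifted founder pools the procedure
recovers the planted families (count and membership) in ≥ 90% of seeded
runs.  Real farm subfamily counts additionally depend on pedigrees and
curator judgment, which this algorithm does not model.

## Selection scans

The two-population scan ranks per-locus Weir–Cockerham Fst (descending,
ties by map position) and examines the top N (default 10).  The three-group
LSBL for a focal group is (Fst₁₂ + Fst₁₃ − Fst₂₃)/2 per locus; negative
per-locus Fst inputs are clamped to zero by default so estimator noise
cannot dominate the upper tail (the unclamped identity
LSBL(g1) + LSBL(g2) = Fst₁₂ is exposed and tested).  The empirical
threshold takes the top floor(q·n) values and includes every tie at the
threshold, so the hit count can exceed the floor.  Candidate windows are
1-based closed intervals [max(1, pos − flank), pos + flank] (defaults
100 kb for genes, 1 Mb for QTL-scale features) intersected with a
user-supplied annotation table; the aggregate gene list is deduplicated.
The haplotype diagnostic takes the SNPs in a window around a hit, finds the
largest subset with all pairwise r² above a floor (exact max clique on the
LD graph; window SNP counts are small), and reports each group's modal
multi-locus genotype string and its frequency — fixed, opposite strings at
frequency 1.0 in the two groups indicate a swept haplotype.

## Synthetic data

`simulate_structured` draws ancestral frequencies from Uniform(0.1, 0.9)
(keeping most sites polymorphic after drift), population frequencies from
the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F), and genotypes with
heterozygote probability 2p(1−p)(1−Fis).  `simulate_families` gives each
family an independent strongly drifted founder pool (default F = 0.4) and
produces offspring by Mendelian sampling from random within-family founder
pairs.  `simulate_wright_fisher_ld` runs a discrete-generation forward
simulation of 2·Ne haplotypes with Poisson crossovers under the Haldane
(no-interference) map, positions mapped to bp at 1 cM/Mb.
`simulate_admixed` mixes two deeply split sources α:(1−α) with a small
post-admixture drift.  All generators are deterministic under a fixed seed
and record truth (labels, drift, Fis, Ne, admixture proportions,
monomorphic counts).

What the generators do **not** emulate: real ascertainment bias of array
SNPs, linkage in the structured/family/admixture generators (their SNPs are
exchangeable), realistic pig demography or pedigrees, genotyping error, and
sex chromosomes.  Passing recovery tests therefore demonstrates estimator
correctness under the stated models, not robustness to every artifact of
real array data.

## Problem sizes and numerics

Validation runs use 100–150 samples per population and 2,000–5,000 SNPs for
frequency-based estimators, 2,000 SNPs over 100 cM for the Wright–Fisher Ne
check, and 44-individual farms over 600 SNPs for subfamily recovery — sizes
at which the estimators' sampling noise sits comfortably inside the stated
tolerances while the full suite stays fast.  Degenerate cases are explicit
throughout: pairs with no co-nonmissing SNPs, monomorphic loci, zero
jackknife variance, empty LD bins, singleton breeds and subfamilies all
yield NaN/flags rather than silent numbers, and symmetric matrices are
validated to 1e−12.
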