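# pigpopgen

Population-genetics analyses for SNP-array panels of livestock breeds, built
around the workflow used to audit *in situ* conservation herds: genotype QC,
genetic diversity, individual and breed relatedness, admixture testing,
selection scans, and subfamily partitioning for rotational mating.  A set of
synthetic genotype generators with recorded ground truth lets every estimator
be validated end to end without any external data.

## Who this is for

Researchers and conservation-program managers working with medium-density
diploid SNP genotypes (tens of thousands of markers, hundreds to a thousand
individuals from many breeds or farms) in PLINK text or binary format, who
need the standard battery of population summaries plus the specialized
conservation-farm analyses: subfamily classification and boar coverage.

## What it computes

* **QC** (`apply_qc`): sample call rate > 0.9, variant call rate > 0.9,
  MAF ≥ 0.05, autosomes only (SSC1–SSC18); single pass with a fully
  reconciled removal report.  `merge_panels` combines platforms on shared
  variants with strand/orientation reconciliation.
* **Diversity** (`breed_diversity`): observed/expected heterozygosity and the
  homozygote-excess inbreeding coefficient
  `Fis = (O(HOM) − E(HOM)) / (N(NM) − E(HOM))`, per individual and per breed,
  with an explicit choice of allele-frequency reference (pooled panel vs
  within breed).
* **Relatedness** (`allele_sharing_distance`, `neighbor_joining`,
  `bootstrap_nj`, `pca_coordinates`): allele-sharing distance `1 − Dst`
  (per-SNP score 1 / 0.5 / 0 for identical / half-shared / opposite
  genotypes), breed-average distance matrices, NJ trees with SNP-bootstrap
  support, PCA.
* **Differentiation** (`fst_weir_cockerham`, `pairwise_fst_matrix`,
  `classify_fst`): Weir–Cockerham (1984) two-population Fst with the
  ratio-of-sums aggregate `Σa / Σ(a+b+c)` and the conventional bands
  (low < 0.05 ≤ moderate < 0.15 ≤ great < 0.25 ≤ high).
* **LD and Ne** (`pairwise_r2`, `ld_decay_curve`, `ne_from_ld`): genotype
  dosage r² within 1 Mb, the fixed distance-bin decay ladder with the
  r² = 0.3 extent, and the historic effective population size
  `N(t) = (1/(4c)) (1/E[r²_adj] − α)` at `t = 1/(2c)` generations.
* **Admixture** (`f3_statistic`, `block_jackknife_z`): the three-population
  test `f3(X; A, B) = E[(x − p_A)(x − p_B)]` with small-sample bias
  correction and a 200-SNP block-jackknife Z score; Z < −2 flags admixture.
* **Selection scans** (`fst_scan`, `lsbl_scan`, `candidate_windows`,
  `haplotype_fixation_check`): per-SNP Fst ranking, the locus-specific branch
  length `LSBL(g1) = (Fst₁₂ + Fst₁₃ − Fst₂₃)/2` with empirical top-0.5%
  thresholds, gene/QTL flanking-window retrieval, and haplotype-block
  fixation diagnostics.
* **Subfamilies** (`classify_farm`, `subfamily_report`): NJ-guided maximal
  split (join tree-adjacent individuals closer than mean − 2 SD of all
  pairwise distances), then iterative merging until between-subfamily Fst
  exceeds 0.05 and the CV of between-subfamily distances is under 10%.
* **Simulators** (`simulate_structured`, `simulate_families`,
  `simulate_wright_fisher_ld`, `simulate_admixed`): Balding–Nichols
  multi-population panels with tunable drift and inbreeding, Mendelian
  founder families, forward Wright–Fisher haplotypes with Haldane
  recombination, and two-source admixture — each emitting a `SimTruth`
  ground-truth record.

## Worked example

```python
import pigpopgen as pg

panel, truth = pg.simulate_structured(pg.SimConfig(
    n_pops=2, samples_per_pop=60, n_snps=2000, drift=0.15, fis=0.1, seed=42))
qc_panel, report = pg.apply_qc(panel)
print("QC: variants", report.n_variants_in, "->", report.n_variants_out)
print(pg.breed_diversity(qc_panel, freq_reference="within_group").round(4))
res = pg.fst_weir_cockerham(qc_panel, ("POP1", "POP2"))
print("Fst =", round(res.aggregate, 4), "->", pg.classify_fst(res.aggregate))
```

prints

```
QC: variants 2000 -> 1906
        n      ho      he  fis_mean  fis_cv_percent
breed
POP1   60  0.3136  0.3535    0.1129         29.4285
POP2   60  0.3158  0.3534    0.1066         29.5262
Fst = 0.1478 -> moderate
```

The 94 removed variants drifted below the 5% MAF floor.  Both populations
were simulated with within-population inbreeding F = 0.1 and recover mean
Fis ≈ 0.11; the drift parameter 0.15 is recovered as Fst = 0.148 and falls in
the "moderate" differentiation band.

The same stages are available from the shell (`pigpopgen simulate`, `qc`,
`diversity`, `dist`, `tree`, `fst`, `ld`, `ne`, `f3`, `scan-fst`,
`scan-lsbl`, `subfamily`), and `pigpopgen run-all --config run.txt` executes
a configured pipeline writing tab-separated tables, Newick trees and a
`manifest.json` with input hashes for reproducibility.

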