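# ldmatch

Scale-matched comparison of linkage disequilibrium (LD) between classes of
genomic regions — typically genic versus non-genic — on phased haplotype
panels.

Raw LD comparisons between region classes are confounded: two-locus LD
statistics depend on the minor allele frequencies (MAFs) involved and on
the physical distances between loci, and both differ systematically
between genic and non-genic regions on real genotyping panels. `ldmatch`
removes these scale effects with a matched-pairs design:

1. **Partition.** Overlapping gene annotations are merged; every SNP is
   assigned to a genic region or a run of consecutive non-genic SNPs.
2. **Match.** For each genic reference set `G` of `m ≥ 10` SNPs, all
   sliding windows of `m` consecutive non-genic SNPs are candidate
   controls. Each candidate is compared to the reference on the ECDFs of
   three characteristics — MAFs, pairwise MAF differences `δ`, pairwise
   physical distances PWD — via the area between the ECDF curves (the
   1-Wasserstein distance `A`). Candidates are ranked per characteristic
   and the smallest rank sum `T = rank(A_MAF) + rank(A_δ) + rank(A_PWD)`
   selects the matched control `IG`; a second, non-overlapping window
   matched to `IG` gives the negative control `IG′`. References with
   fewer than 50 candidates are excluded.
3. **Test.** Per region, LD is summarized by the median of all pairwise
   `r² = D²/(p₁(1−p₁)p₂(1−p₂))` and of the MAF-standardized
   `r²ₛ = r²/r²max`, plus the haplotype diversity `H`. Paired
   (reference, control) summaries are compared with two-sided Wilcoxon
   signed-rank tests per chromosome and genome-wide, and reported as mean
   percentage differences `Δ = (LD_G − LD_IG)/LD_G · 100` with standard
   errors.

A founder-mosaic simulator generates phased panels with block-LD
structure, configurable MAF spectrum, distinct per-class SNP densities and
an optionally planted genic LD excess, providing ground truth for
calibration and power analysis of the whole pipeline.

## Worked example

Simulate a genome with a strong planted genic LD excess (the founder
switch rate inside genes is multiplied by γ = 0.25, i.e. 4-fold less
shuffling), then run the comparison:

```bash
ldmatch simulate --seed 7 --gamma 0.25 --out sim
ldmatch compare --vcf sim/panel.vcf --annot sim/genes.bed --out report
```

The run log ends with

```
n_genic_snps: 869
n_nongenic_snps: 4097
n_merged_genic_intervals: 64
n_eligible: 37
n_matched_triples: 37
n_excluded: 27
```

— of 64 merged genic regions, 37 have ≥ 10 SNPs and ≥ 50 candidate
windows and enter the analysis (the rest are listed in
`report/exclusions.tsv` with reasons). The genome-wide rows of
`report/comparisons.tsv` read (abridged):

```
scope   measure    comparison     n_pairs mean_pct_diff se_pct_diff p_value
genome  median_r2  G_vs_IG        37      18.43         3.63        3.1e-05
genome  median_r2  IG_vs_IGprime  37      -1.94         4.24        0.90
genome  median_r2s G_vs_IG        37      21.06         3.86        1.1e-05
genome  H          G_vs_IG        37      -4.39         0.30        1.2e-07
```

Read: genic regions carry ~18% higher median `r²` than their matched
non-genic controls (confirmed by the MAF-standardized `r²ₛ`, +21%), while
the two matched non-genic controls do not differ (p = 0.90) — so the
excess is not an artifact of the selection procedure. Haplotype diversity
is ~4% lower in genic regions, the flip side of their higher LD. Per
chromosome rows give the same comparisons chromosome-wise.

`ldmatch calibrate` runs the simulation harness over a grid of planted
effect sizes and reports rejection rates and mean Δ per γ.

## Library use

```python
from ldmatch import SimConfig, simulate, run_pipeline

ds = simulate(SimConfig(seed=7, genic_ld_multiplier=0.25))
result = run_pipeline(ds.panel, ds.marker_map, ds.genes)
print(result.comparisons.query("scope == 'genome'"))
```

`run_pipeline` accepts any phased panel: `read_phased_vcf` reads phased
VCF (diploid `0|1` or haploid genotypes), `read_haplotype_matrix` reads a
plain 0/1 matrix with a map file, `haplotypes_from_inbred` converts fully
homozygous genotype matrices, and `apply_qc` implements the standard
missingness/MAF filters for raw genotype matrices. Annotations come from
BED or GFF3.

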