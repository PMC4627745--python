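# Methods

## The problem

Whether genic regions of a genome carry more linkage disequilibrium (LD)
than non-genic regions cannot be answered by comparing raw LD summaries:
two-locus LD statistics depend strongly on the minor allele frequencies
(MAFs) of the loci, and on the physical distances between them — and both
the MAF spectrum and the SNP density differ systematically between region
classes on typical genotyping panels. `ldmatch` implements a matched-pairs
design that removes these scale effects before any comparison is made.

## LD measures

For two biallelic loci, oriented so that allele 1 is the minor allele at
each locus, with minor allele frequencies `p1`, `p2` and observed
minor–minor gamete frequency `p12`:

* gametic disequilibrium `D = p12 − p1·p2`;
* squared correlation `r² = D² / (p1(1−p1) p2(1−p2))`, identical to the
  squared Pearson correlation of the 0/1 allele indicators and invariant
  to relabeling either column;
* `r²max`, the largest `r²` attainable at the given frequencies. `D` is
  feasible only inside `[max(−p1p2, −(1−p1)(1−p2)), min(p1(1−p2), (1−p1)p2)]`;
  for minor allele frequencies the maximizing boundary is always
  `pmin(1−pmax)`, giving the closed form
  `r²max = pmin(1−pmax) / ((1−pmin) pmax)`. The closed form is exact (it
  returns exactly 1.0 at `p1 = p2`) and is verified in the tests against a
  brute-force grid maximization over `p12`;
* the MAF-standardized `r²s = r² / r²max ∈ [0, 1]`, which removes most of
  the MAF dependence of `r²`.

Region-level LD is the median (and mean) of all `m(m−1)/2` pairwise `r²`
and `r²s` values within a region. Medians are used because pairwise-`r²`
distributions are strongly skewed; the even-count median is the midpoint of
the two central order statistics.

### Haplotype diversity

For a region of `m` SNPs observed on `N` haplotypes with distinct-haplotype
frequencies `f_i`, diversity is `H = k/(k−1) · (1 − Σ f_i²)`. The
`sample_corrected` default uses `k = N`, the classical finite-sample
(Nei) correction, which guarantees `H ∈ [0, 1]`. The `snp_count` variant
uses `k = m`; it is retained for comparability with analyses that define
the prefactor through the SNP count, but it can exceed 1 (e.g. `m = 2`
with four equally frequent haplotypes gives 1.5) and a warning is emitted
when it does.

## Matching

Every merged genic interval with at least `min_snps = 10` SNPs is a
reference set. Its candidate controls are all sliding windows of the same
SNP count (step 1 SNP by default) over runs of consecutive non-genic SNPs
on the same chromosome (or a configured pooled chromosome group); windows
never span a genic region or a chromosome break, because pairwise physical
distances across such breaks would be incoherent.

Reference and candidate are compared on three characteristics: the MAFs,
the pairwise absolute MAF differences (`δ`), and the pairwise physical
distances (PWD). For each characteristic the area between the two ECDFs
(the 1-Wasserstein distance) is computed. Because reference and candidate
always contain the same number of SNPs, all three samples are equal-size
and the area equals the mean absolute difference of sorted order
statistics; the batch scorer uses this identity, while the public
`ecdf_area` implements the general step-function integral (the two are
tested against each other). Candidates are ranked per characteristic
(smallest area → rank 1; ties take the minimum rank of the tied block) and
the candidate with the smallest rank sum `T` wins. Rank-sum ties are broken
deterministically: smaller MAF area, then smaller `δ` area, then smaller
PWD area, then leftmost genomic position.

The matched control `IG` is the winner for the reference `G`; the negative
control `IG′` is the winner for `IG` after removing every window sharing a
SNP with `IG`. References with fewer than `min_candidates = 50` candidates
at either step are excluded and logged — with a thin candidate pool the
best match cannot be assumed similar. Controls for different references may
overlap; no exclusivity constraint is imposed.

Areas are computed on raw value scales per characteristic; the ranking
makes the three scales commensurable, so no normalization is applied.

## Testing

Each matched pair contributes one paired observation per measure. The
two-sided Wilcoxon signed-rank test runs on the raw paired differences
(reference − control): zeros are dropped, absolute differences receive
average ranks, and the statistic is the positive-rank sum. For `n ≤ 25`
pairs the null distribution is exact — a dynamic program over the `2^n`
equiprobable sign assignments (average ranks are half-integers, so doubling
them gives an integer-supported convolution); beyond that a normal
approximation with tie-corrected variance and continuity correction is
used. The two modes agree to within 0.02 in p at the boundary, and the
large-sample mode holds its nominal 5% size to within [0.043, 0.057] in a
10,000-sample Monte-Carlo check.

The reported effect size is the percentage difference
`Δ = (LD_ref − LD_ctrl)/LD_ref · 100`, averaged over pairs with its
standard error (SD/√n). `Δ` is reporting only — the test never runs on
percentages. Note that per-pair percentage ratios have a small negative
expectation even under exchangeability (dividing by the noisy reference
couples numerator and denominator), so a slightly negative mean `Δ` on null
data is expected and is not a bias of the test. A `pooled` mode
(percentage difference of pooled means) is available as an alternative
summary.

Comparisons run per chromosome and genome-wide (pooling pairs), for both
`G`-vs-`IG` and the `IG`-vs-`IG′` negative control. Each chromosome is
tested at `α = 0.05` without multiplicity correction — the analysis
interprets counts of significant chromosomes; a Bonferroni option exists
but is off by default.

As a scale-effect diagnostic, the coefficient of determination between
per-chromosome mean `Δ` measured with `r²` and with `r²s` is computed
(OLS `R²`); high concordance indicates the matching, not residual MAF
structure, drives the result.

## Synthetic data

The simulator is a founder-mosaic model, not a coalescent: it trades
population-genetic realism for direct, interpretable control of LD decay
with a single parameter, and it is fast enough for thousand-replicate
calibration.

Per chromosome, `K` founder haplotypes carry alleles drawn per SNP with
minor-allele probability `min_maf + (0.5 − min_maf)·Beta(a, b)`. Each
sample haplotype walks along the chromosome copying one founder, redrawing
the founder index between adjacent SNPs with probability
`1 − exp(−c′·d)` (`d` = physical gap). The switch rate is `c′ = γ·c` when
both flanking SNPs are genic and `c` otherwise, so `γ = 1` yields a null
genome in which genic and non-genic SNPs follow the identical LD process,
and `γ < 1` plants a genic LD excess via reduced shuffling — the
recombination-rate mechanism hypothesized for real genomes. Gene intervals
come from an alternating renewal process (exponential gaps, Gamma-shape-4
lengths) hitting the configured genic fraction in expectation; SNP
positions are Poisson with class-specific densities. Columns whose sample
MAF falls below `min_maf` are redrawn at the founder level, so a simulated
dataset passes the default genotype QC unchanged. All randomness derives
from one seed through per-chromosome spawned streams.

### Default study conditions and why

Defaults: 100 haploid haplotypes; 2 chromosomes × 2 Mbp; genic fraction
0.12 with mean gene length 8 kbp; SNP densities 1.6 (genic) and 1.2
(non-genic) per kbp; `K = 8` founders; `c = 5·10⁻⁵`/bp (LD decay length
≈ 20 kbp); `Beta(0.8, 0.8)` MAF spectrum; `min_maf = 0.01`. This yields
roughly 45 eligible genic regions of ≥ 10 SNPs and ~1,700 candidate
windows per reference — comfortably above the 50-candidate rule.

Two aspects of these conditions matter for interpretation. First, the
matched design is only as good as its candidate pool: if the pool is so
small that even the best window retains a systematic distance mismatch,
the comparison inherits a scale bias that the method cannot remove (this
is exactly why references with < 50 candidates are excluded). Real
chromosomes offer tens of thousands of windows; the defaults keep the
desk-scale pool rich relative to the distance-matching problem by keeping
the density contrast moderate (1.33×) and the LD decay length long
relative to within-region distances. Second, the decay length must exceed
typical region spans, as it does on real panels, so that residual
distance mismatch of the matched window translates into a negligible LD
difference. Under these conditions the genome-wide null rejection rate is
close to the nominal 5% — repeated thousand-replicate measurements place
it between 0.04 and 0.08, i.e. a small residual inflation from the
remaining distance mismatch can persist at desk scale — and a 4-fold
genic switch-rate reduction (`γ = 0.25`) is detected essentially always
(see the acceptance suite).

What the simulator does **not** emulate: mutation, selection, demography,
gene conversion, genotyping error, any particular species' empirical decay
curve, and LD structure that differs between region classes for reasons
other than the switch rate. Passing the calibration and power checks
therefore shows that the pipeline is correct and well-calibrated under a
controlled truth — not that any particular real genome has excess genic LD.

## Numerical choices and degenerate inputs

* Allele coding is arbitrary per column; every statistic is invariant to
  relabeling, and MAFs are always recomputed from the final haplotype
  matrix.
* QC filter order is fixed: samples by missingness, then SNPs by
  missingness, then SNPs by MAF — sample removal changes MAFs, so the MAF
  filter must run last. QC is idempotent.
* Gene intervals are 1-based inclusive; BED input is converted on read;
  a SNP exactly on a gene boundary is genic. Overlapping, nested and
  book-ended annotations merge into one genic region.
* Distance-decay profiles drop pairs above the empirical 99% distance
  quantile (linear interpolation) and report binned means (50 equal-width
  bins); smoothing beyond binning is presentation, not inference, and is
  not provided.
* All-zero paired differences give p = 1 with a warning; a zero reference
  value makes that pair's percentage undefined (skipped with a warning);
  fewer than 2 pairs marks a comparison untestable rather than erroring.
* `r²s` is clipped to [0, 1]; an `r² > r²max` discrepancy beyond 1e-9
  raises, since it signals inconsistent inputs rather than rounding.

## Problem sizes used in the checks

The statistical acceptance checks run 1,000 null replicates plus 200
replicates at each planted effect level under the default conditions
(~0.4 s per replicate); `scripts/acceptance.py` reports the same
quantities from 400 null and 150 per-effect replicates. These sizes give
binomial standard errors ≈ 0.007 (suite) and ≈ 0.011 (script) on a 0.05
rejection rate. The `r²`/`r²s` concordance is computed across ten
single-chromosome genomes whose planted effect sizes vary from γ = 1 to
γ = 0.25 — between-chromosome heterogeneity in the true LD excess is
what the concordance diagnostic is about; with homogeneous chromosomes
it would measure only correlated sampling noise.

## Known limitations

* Phasing and imputation are upstream: unphased or missing genotypes at
  ingestion are hard errors by design.
* Autosomal biallelic SNPs only; multiallelic sites and structural
  variants are rejected.
* The exclusion rules (10 SNPs, 50 candidates) are inherited defaults, not
  adaptive; very gene-dense genomes with short intergenic runs will see
  many exclusions, which the exclusion log makes visible.
* With small candidate pools the matched comparison can retain residual
  scale bias (see above); the candidate-count rule mitigates but cannot
  eliminate this, so pool sizes should be inspected when interpreting
  borderline results.
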