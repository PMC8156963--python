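# Methods

This note documents the statistical models, parameter choices and known
limitations of `supmap`. Everything quantitative stated here is computed by
the test suite or the worked example; nothing is quoted from external data.

## Screen scoring

**Plate normalization.** Raw colony sizes are scaled per plate so every
plate median equals the batch median; zeros stay zero and all-zero plates
are excluded. This removes multiplicative plate effects (pinning density,
agar batch). Spatial row/column/edge gradients are *not* modelled: the
synthetic generator does not plant them, and a production deployment that
starts from plate images should apply a dedicated spatial correction first.

**Technical replicates.** Colony sizes are log₂(size + 1) transformed. At
most one outlying technical replicate per cell is removed: replicate j is
dropped when its squared deviation from the mean of the others reaches at
least 90% (`tech_var_fraction`) of the cell's total sum of squares about
the mean, and it is the unique maximum. Ties (in particular any
two-replicate cell, whose shares are equal by symmetry) remove nothing.
This leave-one-out share is one concrete operationalization of "a single
replicate accounting for ≥ 90% of the variation"; the threshold is
configurable.

**Variance floor.** A cell with one replicate (or zero spread) would carry
infinite precision into the posterior combination. Its squared standard
error is floored at the 10th percentile of positive per-cell values
(`variance_floor_quantile`), so no cell can dominate purely through a
degenerate noise estimate.

**Biological replicates.** Replicate 2 is regressed onto replicate 1
(ordinary least squares over shared queries, skipped below 10) to remove
batch effects; its variances scale by slope². The two replicates then
combine as Gaussian posteriors: with between-replicate variance
v = (m₁−m₂)²/2 and precisions pᵢ = 1/(vᵢ+v), the posterior is
N(w₁m₁+w₂m₂, 1/(p₁+p₂)). The estimator v has a single degree of freedom
and is therefore noisy; the z ≥ 4.5 call threshold absorbs the resulting
anti-conservatism. Cells with more than two biological replicates (not
produced by the default designs) combine by iterated pairwise combination
in replicate order — an approximation, noted as such.

**Query filtering.** Queries missing in the reference cross at 34°C, or in
every wild cross, are dropped; queries whose reference-cross fitness
difference between 26°C and 34°C is below 0.2 (`ts_filter_delta`) are
classed temperature-insensitive. Insensitive queries are excluded from
scoring but serve as the *anchor set* for cross-strain normalization.

**Reference normalization.** Wild-cross restrictive fitnesses are shifted
so the anchor-set median matches the reference's, then deviations about the
median are rescaled. The scale is the equal-noise Deming slope — the ratio
of anchor-deviation spreads, signed by their covariance — not the ordinary
regression slope. Both axes carry comparable measurement noise, so OLS
would be attenuated by the anchor noise-to-spread ratio, and that bias is
*extrapolated* across the ~2 log₂-unit gap between the anchor level and the
TS-allele level, systematically inflating every sensitive query's score.
The Deming slope is consistent under the null and inverts affine
distortions exactly (checked by test). Normalization precision scales as
1/√(anchor count): with ~30 anchors the per-strain score offset has sd
≈ 0.07–0.1, with ~60 anchors ≈ 0.05. Calibration experiments therefore run
at 300 queries (~60 anchors), mirroring the anchor-to-noise regime of a
full-size screen, where the anchor set numbers in the hundreds.

**Calling.** score = adjusted wild − reference fitness at 34°C; variances
add (the posteriors are treated as independent); z = score/sd. A pair is
called when score ≥ 0.75 — a 2^0.75 ≈ 1.68-fold growth improvement, a
visually clear difference on plates — and z ≥ 4.5, whose one-sided normal
tail is ≈ 3.4 × 10⁻⁶ and which Bonferroni-survives screens of order 10⁴
tests (0.0359 at 10,554). `n_tests` is computed from the data as retained
queries × wild strains, never hard-coded. A lenient threshold of 0.5
(`lenient_score_threshold`) is exposed for edge-effect analyses.

**Confirmation assay.** For single-colony sporulation assays, the count
statistic is log₂(count34/count26) in the wild cross minus the same ratio
in the reference cross; the area statistic is analogous. Images with < 100
colonies at 26°C are excluded entirely; images with < 30 colonies are
excluded from size determination. A zero count at 34°C is
continuity-corrected to 0.5 and flagged.

## Consistency analyses

Strain trees are UPGMA (average linkage): phenotype distance is 1 − Pearson
correlation of suppression profiles (pairwise-complete, ≥ 3 shared
strains); genotype distance is the symmetric difference of called variant
sets. Trees serialize to Newick and are ultrametric by construction.

The group-consistency statistic for a gene set with N alleles is the mean
Pearson correlation over its N(N−1)/2 allele pairs. The null draws equally
many pairs from the whole matrix B = 1000 times, *matching the number of
same-gene pairs* (same-gene pairs are intrinsically more correlated, so an
unmatched null would be anti-conservative). p = (1 + #{null ≥ observed}) /
(B+1) — one-sided add-one estimator, bounded away from zero — with
Benjamini–Hochberg correction across sets; a set is called consistent when
the mean correlation exceeds 0.25 and the corrected p is below 0.25. The
null does not match the shared-allele overlap structure within a set, which
leaves mild extra variance in the observed statistic relative to the null;
empirically the null rejection rate at p < 0.05 is ≈ 0.058 over 1,000
random groups (test suite). Allele order and pair pools are sorted and each
set draws from an independently keyed RNG stream, so p-values are invariant
to matrix row/column order and to the iteration order of the sets.

Same-gene concordance: for every called (allele, strain) pair whose gene
has another assayed allele, take the maximum score among the sibling
alleles in that strain; the observed mean is compared to B gene-label
permutations (one-sided). Deleterious load compares mean
deleterious-mutation counts between suppressed and other gene/strain pairs
with a two-sided label-permutation p.

## Segregant-pool simulation

Each biological replicate is an independent pool of `pool_size` (default
60,000) haploid genomes. Per chromosome, a haplotype starts from a fair
parental coin flip and switches parent between adjacent sites with the
Haldane probability (1 − e^{−2d})/2, d = distance × rate in Morgans —
crossovers as a Poisson process without interference, which is adequate at
the 10–100 kb scales being mapped. The default rate is 4 × 10⁻⁶ M/bp
(0.4 cM/kb, the yeast genome-wide average). All pool members carry the
reference allele at the TS locus and every SGA selection-marker locus,
implemented exactly by rejection sampling conditioned at those sites.

Selection at the restrictive temperature is one round of weighted
multinomial resampling of the pool (the screen's final pinning is a single
competitive outgrowth): a segregant whose suppressor genotype satisfies the
effect model (`any_sufficient` / `all_required`) carries weight
exp(advantage × `selection_generations`), weight 1 otherwise. The effective
number of selection generations in a real pool is unknown; it is exposed as
a design parameter with default 1 and the deterministic single-locus
expectation w·0.5/(w·0.5+0.5) serves as the oracle in tests. Reads per site
are Binomial(depth, pool frequency) with Poisson-distributed depth; a
`disomy(chrom)` rearrangement doubles the read-sampling rate on that
chromosome. Not emulated: diploid intermediates, gene conversion, crossover
interference, GC/mappability bias in read depth, and linkage between
suppressor and marker loci beyond what the map implies — so passing tests
demonstrate correct inference under the stated generative model, not
robustness to alignment artefacts of real sequencing data.

The default simulated genome is 3 chromosomes × 1 Mb with one marker per
5 kb: large enough to preserve linkage structure around a selected locus,
small enough for a laptop-scale test suite.

## Mendelian cross models

For a cross of the reference strain to a reciprocal-translocation
heterozygote, the two rearranged/normal centromere pairs segregate
independently: of four equally likely gamete combinations, the one lacking
the essential translocated arm is inviable (1/4); the three viable classes
(parental reference, parental translocated, duplication-carrying) are each
1/3 of viable spores. For a cross with a disomic parent, random 2:1
segregation of the three homologs yields one or two copies with equal
probability. Both maps are verified against exhaustive enumeration of
gamete arm-content combinations.

Modifier counting from random-spore viability: with k independent 1:1
modifiers, the expected growing fraction is 1 − 2^{−k} if any one suffices
and 2^{−k} if all are required; the estimate reports the nearest k ≤ 5
under each model and, given a spore count, the set of k whose binomial 95%
interval covers the observation. Observed growing fractions between 0.15
and 0.65 map to k ∈ {1, 2, 3} under both models.

## Frequency-track inference and QTL calling

The latent wild-allele frequency per site is inferred on a uniform grid of
101 levels on [0, 1] (configurable). Emissions are
Binomial(depth, (1−ε)f + ε(1−f)) with per-read mis-assignment rate
ε = 0.002 by default — a round figure for post-filter sequencing plus
alignment error, which also keeps posteriors off the exact 0/1 boundary.
Transitions between adjacent sites are row-normalized Gaussian kernels with
step variance `diffusion_scale` × recombination rate × distance; the walk
couples nearby sites at the scale recombination decorrelates genotypes.
Forward–backward smoothing is exact on the grid — verified to < 10⁻⁶
against brute-force summation over all grid paths on 5-site instances —
and zero-depth sites take the smoothed prior. The posterior mean is
monotone in the alt count at any site (property test).

Replicate tracks combine per site by precision weighting (1/sd²), clipped
to [0, 1]; this approximates joint inference on pooled counts to within
0.02 on simulated pools (test). The delta track is restrictive −
permissive posterior mean with sds in quadrature; positive delta means the
wild allele is beneficial at 34°C. Output writers also emit the opposite
(reference-allele) polarity, since genome-scan figures are conventionally
drawn either way. Sites within 30 kb of the TS allele or a selection marker
are masked — frequency there is pinned by the crossing protocol, not by
suppression — and masking is idempotent.

QTL regions are called by two-threshold hysteresis. Seeds require
|delta| ≥ threshold — 0.12 (`af_stringent`) for the broad/lenient tier,
0.20 (`strict_delta`) for the strict tier — and |delta|/sd ≥ 5
(`sd_stringent`). Seeded regions extend outward while the sign holds,
|delta| ≥ 0.03 (`peak_cutoff`), and either |delta| ≥ 0.8 × the tier seed
threshold (`af_lenient`) or |delta|/sd ≥ 3 (`sd_lenient`). The external
parameters `af_lenient`/`sd_lenient`/`peak_cutoff` are honoured by name but
their extension semantics are this module's own definition, since no
published specification of the envelope exists. Same-sign regions separated
by less than `length_cutoff` (1 kb) merge; regions shorter than 1 kb are
discarded; the strict 0.20 cutoff applies to the smoothed posterior delta.
The caller is verified region-for-region against an independent
brute-force scan on random tracks.

Aneuploidy: per chromosome, the ratio of median site depth to the
genome-wide median; flagged outside [0.65, 1.35] — chosen so that a fully
disomic chromosome (ratio 2) and a half-disomic pool (ratio 1.5) flag while
Poisson depth noise does not — with the flag withheld under 10 sites.

## Candidate prioritization

Within a called region, the candidate window keeps genes whose gene body
overlaps a site with |delta| within 0.03 of the region peak — an absolute
tolerance on the frequency scale, matching how frequency changes are
quoted in percentage points; promoter-only variants are deliberately
outside the window and belong to the validation step. Candidates are ranked
lexicographically on the boolean ladder (co-complex, co-pathway,
co-expressed, co-localized, essential) against the query gene; ties break
by genomic distance to the region peak, then gene id, making the ranking a
total order. Adding an annotation can only improve a gene's rank
(monotonicity test). Known general modifier genes (defaults *MKT1*, *HAP1*)
lying in the region are appended as `manual` candidates regardless of the
frequency-change window. Co-expression accepts either an explicit partner
list or a scored list thresholded at 1.

Gain/loss-of-function for a validated suppressor: deletion of the
suppressor exacerbating the query defect while overexpression suppresses it
implies the wild allele acts by gain of function; deletion itself
suppressing implies loss of function; anything else is inconclusive.

## Problem sizes and test budget

The suite's stochastic experiments run at desk scale: screen calibration
uses 20 screens of 300 queries × 2 wild strains (≈ 11,000 null tests);
power uses 160 planted 1.5-log₂ effects under default noise
(technical sd 0.25, 4 technical / 2 biological replicates); BSA recovery
uses 20 planted and 20 null pools on the 3 × 1 Mb genome at depth 100 with
2 replicates per temperature; permutation calibration uses 1,000 random
gene sets at B = 1000. The full suite completes in a few minutes on one
core.

## Known limitations

- Plate spatial gradients and image-processing artefacts are out of scope.
- The biological-noise estimate v = (m₁−m₂)²/2 has one degree of freedom;
  z-scores are only trustworthy jointly with the score threshold.
- Reference normalization needs an anchor set of order 10² queries;
  screens with few temperature-insensitive queries will show per-strain
  score offsets of ±0.1 or more.
- The permutation null for group consistency matches same-gene pair counts
  but not shared-allele overlap, leaving it very slightly anti-conservative.
- The pool simulator's selection model is single-round; sustained
  exponential competition can be emulated via `selection_generations` but
  clonal interference and de-novo mutation are not modelled.
- Translocation crosses are handled through their Mendelian expectations
  and read-depth signatures; breakpoint detection from split reads is out
  of scope.
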