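# Methods

This document describes the statistical model implemented by `cisqtl`, the
design of the synthetic-data generator, and the numerical choices made.
Nothing here is an empirical claim about real tissue; every number the
package reports is computed from its inputs at run time.

## Association model

For gene *g* and variant *v*, the model is an additive linear regression

> expression(g) = α + β·dosage(v) + Σ γ·covariates + ε

The engine does not fit this regression per pair. Both the normalized
expression matrix and the dosage matrix are residualized once against the
shared covariate design (intercept + cell fractions + expression PCs), and
per-pair statistics come from the correlation *r* of the residual vectors:

- t = r·sqrt(df / (1 − r²)) with **df = n − 2 − #covariates**,
- β = r·sd(expression residual)/sd(dosage residual),
- p = two-sided Student-t tail probability.

By the Frisch–Waugh–Lovell theorem these equal the dosage coefficient's
statistics in the full multiple regression exactly; the test suite checks
agreement with per-pair OLS fits to |Δt| < 1e-8. Residualization is a
single `lstsq` projection per matrix, so a stage-1 scan is two matrix
projections plus one inner product per pair (chunked `einsum`).

Pairs whose dosage (or expression) residual has essentially zero variance
are flagged `monomorphic_residual` and carry no p-value. The zero-variance
tolerance is `1e-12·n` because the least-squares residual of a constant
column is numerical noise (~1e-30), not exact zero.

## Variant and gene QC

Genotyped variants are checked in order: call rate ≥ 95%, exact
Hardy–Weinberg equilibrium p ≥ 1e-5, MAF ≥ 1%. The HWE test is the exact
conditional test on heterozygote counts (log-space via `gammaln`, summing
configurations with probability ≤ the observed one, with a 1+1e-12
relative tolerance on the comparison); fractional dosages are rounded to
hard calls for this test only. Imputed variants are instead checked by
imputation quality (allelic r² ≥ 0.3, skipped when the quality score is
absent) and MAF ≥ 1%. The exclusion log records the *first failing rule*
per variant, and filtering is idempotent. Missing dosages are mean-imputed
per variant after QC.

Genes require a median raw count ≥ 8 across samples. When a gene is
annotated on both X and Y, the X copy is kept.

## Normalization and covariates

Counts become log2-CPM (`log2(count + 0.5) − log2(library_size / 1e6)`),
then a running-median GC correction is subtracted: genes are ordered by GC
fraction and a centered median filter (window ≈ 10% of genes, odd,
edge-replicated) estimates the GC trend, which is mean-centered before
subtraction so the overall expression scale is preserved. This is a
deterministic, dependency-light stand-in for conditional-quantile-style
GC/library normalization; it removes first-order GC trend but not
GC-by-sample interactions.

Expression PCs are computed by SVD of the sample-centered matrix; every
component explaining > 1% of total variance is retained as a covariate
(`pc_max` can cap the count). **Scale caveat:** the >1% rule presumes a
large gene panel. With *k* genes an average gene holds ~1/*k* of the
variance, so for small *k* (say, below a few hundred) pure-noise
components straddle the 1% cutoff, dozens of PCs are retained, and they
can absorb genuine single-gene eQTL signal. The synthetic study
configurations therefore use panels of several hundred genes.

## Risk loci

Published risk variants are screened against the genotype matrix:
`not_in_genotypes`, `low_maf` (< 1%), or `perfect_ld` (r² = 1 with an
earlier *included* risk variant; the first-listed member is kept). Each
included variant contributes a ±100 kb interval; intervals on a chromosome
are transitively merged when they share ≥ 1 bp (1-based inclusive
coordinates, lower flank clamped at 1). Within a region, risk variants
cluster into loci by single-linkage (union-find) at r² ≥ 0.5, and each
locus's LD set is every polymorphic region variant whose maximum r² to a
member risk variant is ≥ 0.5. A region whose risk variants are all
monomorphic yields an empty locus, which is carried through bookkeeping
but contributes no tests. LD r² is the squared Pearson correlation of
dosages (pairwise-complete, requiring ≥ 3 samples and both variants
polymorphic).

## Two-stage testing and error control

**Stage 1** pairs every LD-set variant with each expressed gene whose span
lies within 1.1 Mb of the variant (distance to the nearest span edge,
boundary inclusive); a (gene, variant) pair reachable via several loci is
tested once. Gene-wise significance is hierarchical: within each gene a
Bonferroni correction over that gene's tests, then a Benjamini–Hochberg
pass across genes on the per-gene Bonferroni minima, run separately per
gene class (protein-coding / lncRNA / other); genes with q ≤ 1% are
significant. **Stage 2** pairs each significant gene with *all* QC-passing
variants from TSS − 1.1 Mb to TES + 1.1 Mb and applies one pooled BH pass
across all stage-2 records.

A gene's **peak eQTL variant** is its smallest-p record across both
stages; ties break on larger |t|, then smaller genomic position (stable
mergesort, so the result is deterministic). Each significant gene is
classified per risk locus by the *maximum* r² between the peak variant and
the locus's risk variants: Group 1 (r² ≥ 0.5), Group 2 (0.2 ≤ r² < 0.5),
Group 3 (< 0.2); both lower boundaries are inclusive. A gene paired with
several loci receives one call per locus; unique-gene summaries count it
once in its best (lowest-numbered) group. Summary percentages are rounded
to the reporting precision (`format_pct`: one decimal for locus fractions,
integers for per-class shares).

## Synthetic-data generator

Genotypes: each LD block has a pool of founder haplotypes (default 16)
with per-variant allele indicators; every sample draws two founders per
block, and its dosage is the founders' allele sum. Shared founder
assignments create realistic within-block LD that decays as the founder
pool grows, while variants in different blocks are independent. Founder
allele frequencies are drawn uniformly and redrawn until the realized MAF
clears a floor (bounded retries, then an error). Planted effects use
designed founder patterns: the causal variant is carried by half the
founders (rotated by variant index so two planted variants are never
accidentally identical), and a "high" tag is the same pattern minus one
carrier, giving tag r² ≈ 0.78 at the default pool size. The published risk
list contains the tags (or the causal variant itself for `tag="self"`,
or an unlinked variant one block over for `tag="low"`), plus one variant
deliberately absent from the genotypes to exercise intake screening.

Expression: log-scale means combine a per-gene baseline, a GC-bias term
`gc_bias·(gc − 0.5)`, sample covariates (lymphocyte and epithelial
fractions), a log-normal library-depth factor, and the planted effects,
whose β is expressed in units of σ_ln = sqrt(log1p(dispersion)) — the
log-scale standard deviation implied by the negative-binomial dispersion —
so β is interpretable as "s.d. of log expression per allele". Counts are
drawn Poisson–Gamma (gamma-mixed Poisson ≡ negative binomial). Each
generator stage has its own `default_rng([stage_index, seed])` stream, so
the genotype draw, expression draw, etc. are individually reproducible and
insensitive to reordering.

**Realism limits.** No population structure, relatedness, phasing, or
recombination gradients; LD is block-diagonal with independent blocks. No
trans effects, no batch structure beyond the modeled covariates, no
GC-by-sample interaction, and hard-call genotypes are always in
Hardy–Weinberg equilibrium by construction. Gene spans are uniform and
non-overlapping; gene classes are assigned round-robin. The generator is
built to exercise the pipeline's decision rules, not to mimic a specific
tissue.

## Numerical choices

- BH q-values come from `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`), validated in tests against a brute-force step-up oracle.
- Correlations are computed in chunks via `einsum`; r is clipped to
  [−1, 1] before the t transform, and p-values are floored at the smallest
  positive double to keep downstream `log10`/BH well-defined.
- All sorting that affects results uses stable `mergesort`.
- Seeds are plain integers below 2³¹; replicate seeds derive as
  `(seed·100003 + i) mod (2³¹ − 1)`.

## Limitations

- The GC correction is a running median, not a full conditional-quantile
  fit; residual GC effects may remain when the GC–expression relationship
  varies by sample.
- The >1% PC rule is panel-size dependent (see caveat above); for small
  panels set `pc_max` or expect conservative power.
- Classification relies on sample LD between peak and risk variants;
  with few samples r² estimates are noisy near the 0.2 and 0.5 boundaries.
- Stage-2 "significant variant" flags use a pooled BH threshold across
  target genes and inherit its assumptions under dependence.
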