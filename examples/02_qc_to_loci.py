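"""Walk the pre-association stages one at a time.

Variant QC (call rate, exact HWE, MAF for genotyped variants; allelic r^2
and MAF for imputed ones), expression filtering and normalization,
expression PCs, then risk-variant screening and locus construction.
"""

from cisqtl import (
    PlantedEffect,
    SimConfig,
    assemble_covariates,
    build_loci,
    build_regions,
    compute_expression_pcs,
    filter_genes,
    filter_variants,
    mean_impute,
    normalize_expression,
    screen_risk_variants,
    simulate_dataset,
)
from cisqtl.loci import locus_table

cfg = SimConfig(
    n_samples=400, n_genes=600, n_blocks=3, genome_span_bp=9_000_000,
    planted=(PlantedEffect(gene=0, block=0, snp=0, beta=0.6, tag="high"),),
    seed=7,
)
bundle = simulate_dataset(cfg)

# -- variant QC ---------------------------------------------------------------
geno_qc, exclusions = filter_variants(
    bundle.genotypes, call_rate_min=0.95, hwe_p_min=1e-5, maf_min=0.01,
    allelic_r2_min=0.3)
geno_qc = mean_impute(geno_qc)
print(f"variants: {bundle.genotypes.n_variants} in, {geno_qc.n_variants} pass QC")
if len(exclusions):
    print(exclusions.to_string(index=False))

# -- expression ---------------------------------------------------------------
expr = filter_genes(bundle.expression, median_min=8)
expr = normalize_expression(expr)  # log2-CPM minus a running GC-median
print(f"genes: {bundle.expression.counts.shape[0]} in, "
      f"{expr.counts.shape[0]} expressed (median count >= 8)")

pcs, var_explained = compute_expression_pcs(expr, var_explained_min=0.01)
covset = assemble_covariates(bundle.covariates, pcs, var_explained)
print(f"covariates: {covset.n_covariates} "
      f"({list(bundle.covariates.columns)} + {pcs.shape[1]} expression PCs)")

# -- risk loci ----------------------------------------------------------------
screened = screen_risk_variants(bundle.risk_variants, geno_qc, maf_min=0.01)
print("\nrisk-variant screen:")
print(screened[["rsid", "status", "reason"]].to_string(index=False))

regions = build_regions(screened, flank=100_000)
loci = build_loci(regions, geno_qc, ld_threshold=0.5)
print("\nloci (each risk variant +/- 100 kb, merged; LD set at r^2 >= 0.5):")
print(locus_table(loci).to_string(index=False))
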