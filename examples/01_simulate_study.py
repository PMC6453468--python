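"""Simulate a synthetic eQTL study and look at what it contains.

The generator builds genotypes by copying founder haplotypes per LD block
(so within-block variants are correlated and cross-block variants are not),
plants cis effects on chosen genes, draws negative-binomial read counts
with GC and library-size bias, and publishes a "risk variant" list made of
tag SNPs rather than the causal variants themselves.
"""

from cisqtl import PlantedEffect, SimConfig, simulate_dataset

# One gene (g000) gets a causal variant in block 0. The published risk
# variant is an in-block tag at founder-level r^2 ~ 0.8, not the causal
# variant itself -- the usual GWAS situation.
cfg = SimConfig(
    n_samples=400,
    n_genes=600,
    n_blocks=3,
    genome_span_bp=9_000_000,
    planted=(PlantedEffect(gene=0, block=0, snp=0, beta=0.6, tag="high"),),
    seed=7,
)
bundle = simulate_dataset(cfg)

geno, expr = bundle.genotypes, bundle.expression
print(f"genotypes: {geno.n_samples} samples x {geno.n_variants} variants")
print(f"counts:    {expr.counts.shape[0]} genes x {expr.counts.shape[1]} samples")
print(f"covariates: {list(bundle.covariates.columns)}")
print("\nrisk-variant list (tags, plus one deliberately absent variant):")
print(bundle.risk_variants.to_string(index=False))
print("\nground truth:")
print(" causal pairs:", bundle.truth.causal_pairs)
print(" tag map (risk rsid -> causal variant, LD bin):", bundle.truth.tag_map)
print(" null genes:", len(bundle.truth.null_genes))

# realized LD between the published tag and the hidden causal variant
from cisqtl import ld_r2

tag, causal, _ = bundle.truth.tag_map[0]
r2 = ld_r2(geno.dosages[tag].to_numpy(), geno.dosages[causal].to_numpy())
print(f"\nrealized r^2(tag={tag}, causal={causal}) = {r2:.3f}")
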