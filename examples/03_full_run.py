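"""End-to-end run: simulate a study to files, run the pipeline, inspect
the gene-group calls and a regional association table.

Everything here can also be done from the command line:

    cisqtl simulate --out-dir scratch/study --n-samples 400 --planted 1 --seed 7
    cisqtl run --genotypes scratch/study/genotypes.tsv ... --out-dir scratch/run
    cisqtl regional g000 --config scratch/run/config.yaml --out scratch/g000.tsv
"""

import json
from pathlib import Path

import cisqtl.io as qio
from cisqtl import (
    PlantedEffect,
    RunConfig,
    SimConfig,
    emit_regional_table,
    run_pipeline,
    simulate_dataset,
)

out = Path("scratch/example_run")
out.mkdir(parents=True, exist_ok=True)

# -- write a synthetic study to disk -------------------------------------------
cfg_sim = SimConfig(
    n_samples=400, n_genes=600, n_blocks=3, genome_span_bp=9_000_000,
    planted=(PlantedEffect(gene=0, block=0, snp=0, beta=0.6, tag="high"),),
    seed=7,
)
bundle = simulate_dataset(cfg_sim)
qio.write_dosage_tsv(bundle.genotypes, out / "genotypes.tsv")
qio.write_counts_tsv(bundle.expression, out / "counts.tsv")
qio.write_gene_annotation(bundle.expression.genes, out / "genes.tsv")
qio.write_risk_variants(bundle.risk_variants, out / "risk_variants.tsv")
qio.write_covariates(bundle.covariates, out / "covariates.tsv")

# -- run the two-stage pipeline -------------------------------------------------
cfg = RunConfig(
    genotypes=str(out / "genotypes.tsv"),
    counts=str(out / "counts.tsv"),
    gene_annotation=str(out / "genes.tsv"),
    risk_variants=str(out / "risk_variants.tsv"),
    covariates=str(out / "covariates.tsv"),
    out_dir=str(out / "run"),
)
result = run_pipeline(cfg)

print("summary:")
print(json.dumps(result.summary, indent=1, default=str))

sig = result.gene_significance
print("\nsignificant genes:")
print(sig[sig["significant"]].to_string(index=False))

print("\ngene-group calls (LD of peak eQTL variant to the risk variant):")
print(result.calls.to_string(index=False))

# -- regional association table for the recovered gene --------------------------
gene = result.calls["gene_id"].iloc[0]
table = emit_regional_table(gene, result)
print(f"\nregional table for {gene} (top 5 by -log10 p):")
print(table.sort_values("neglog10_p", ascending=False).head(5)
      .to_string(index=False))
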