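import numpy as np
import pandas as pd
import pytest

from cisqtl.simulate import PlantedEffect, SimConfig, simulate_dataset
from cisqtl.types import ExpressionMatrix, GenotypeMatrix


@pytest.fixture(scope="session")
def planted_bundle():
    """A small study with one planted effect tagged at high LD."""
    cfg = SimConfig(
        n_samples=300, n_genes=120, n_blocks=3, snps_per_block=12,
        genome_span_bp=1_800_000, block_span_bp=120_000,
        planted=(PlantedEffect(gene=0, block=0, snp=0, beta=0.6, tag="high"),),
        seed=11,
    )
    return simulate_dataset(cfg)


def make_genotypes(dosages: np.ndarray, positions=None, chrom="chr1",
                   is_imputed=False, allelic_r2=np.nan) -> GenotypeMatrix:
    """Hand-built genotype matrix (samples x variants)."""
    n, m = dosages.shape
    vids = [f"snp{i}" for i in range(m)]
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    dos = pd.DataFrame(dosages.astype(float),
                       index=pd.Index([f"s{i}" for i in range(n)],
                                      name="sample_id"),
                       columns=pd.Index(vids, name="variant_id"))
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "G",
        "is_imputed": is_imputed, "allelic_r2": allelic_r2,
    }, index=dos.columns)
    return GenotypeMatrix(dosages=dos, variants=variants)


def make_expression(counts: np.ndarray, classes=None, chrom="chr1",
                    tss=None, gc=None) -> ExpressionMatrix:
    g, n = counts.shape
    gids = [f"g{i}" for i in range(g)]
    if tss is None:
        tss = 10_000 * (np.arange(g) + 1)
    if gc is None:
        gc = np.linspace(0.35, 0.65, g)
    if classes is None:
        classes = ["protein_coding"] * g
    genes = pd.DataFrame({
        "gene_class": classes, "chrom": chrom, "tss": tss,
        "tes": np.asarray(tss) + 5_000, "strand": "+", "gc_fraction": gc,
    }, index=pd.Index(gids, name="gene_id"))
    cts = pd.DataFrame(counts, index=genes.index,
                       columns=[f"s{i}" for i in range(n)])
    return ExpressionMatrix(counts=cts, genes=genes)
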