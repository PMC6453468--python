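"""Variant QC, gene filtering, expression normalization, covariates.

Variant filters follow the usual array-genotyping conventions: genotyped
variants must satisfy call rate >= 95%, an exact Hardy-Weinberg test at
p >= 1e-5 and MAF >= 1%; imputed variants must satisfy imputation quality
(allelic r^2 >= 0.3) and MAF >= 1%. Expression is filtered on median raw
count and normalized by a log-CPM transform with a cross-gene smooth GC
correction — a deliberately light-weight stand-in for conditional quantile
normalization that removes the same two biases (GC content and sequencing
depth).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.special import gammaln

from .types import CovariateSet, ExpressionMatrix, GenotypeMatrix, PipelineError

log = logging.getLogger(__name__)


# -- Hardy-Weinberg exact test ----------------------------------------------

def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg equilibrium test (Wigginton-style).

    The p-value is the total probability, under fixed allele counts, of
    every heterozygote configuration whose conditional probability does not
    exceed that of the observed one. Symmetric under allele relabeling.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = n_Aa + 2 * n_aa  # count of the 'a' allele
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:  # cannot happen for consistent counts
        raise ValueError("observed heterozygote count inconsistent with alleles")
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _hwe_from_dosage(dosage: np.ndarray) -> float:
    """HWE p-value from (possibly fractional) dosages, rounded to hard calls."""
    d = dosage[~np.isnan(dosage)]
    if d.size == 0:
        return 1.0
    hard = np.clip(np.rint(d), 0, 2).astype(int)
    counts = np.bincount(hard, minlength=3)
    return hwe_exact_pvalue(int(counts[0]), int(counts[1]), int(counts[2]))


# -- variant filter ----------------------------------------------------------

def filter_variants(geno: GenotypeMatrix, call_rate_min: float = 0.95,
                    hwe_p_min: float = 1e-5, maf_min: float = 0.01,
                    allelic_r2_min: float = 0.3,
                    ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the genotyped-variant and imputed-variant QC rules.

    Genotyped variants are checked, in order: call rate, HWE, MAF.
    Imputed variants: allelic r^2 (skipped when the quality is absent),
    then MAF. The exclusion log records the first failing rule per dropped
    variant. Idempotent: re-filtering a filtered matrix drops nothing.
    """
    maf = geno.maf()
    call = geno.call_rate()
    reasons: dict[str, str] = {}
    for vid, meta in geno.variants.iterrows():
        if meta["is_imputed"]:
            r2 = meta["allelic_r2"]
            if pd.notna(r2) and r2 < allelic_r2_min:
                reasons[vid] = "allelic_r2"
            elif maf[vid] < maf_min:
                reasons[vid] = "maf"
        else:
            if call[vid] < call_rate_min:
                reasons[vid] = "call_rate"
            elif _hwe_from_dosage(geno.dosages[vid].to_numpy()) < hwe_p_min:
                reasons[vid] = "hwe"
            elif maf[vid] < maf_min:
                reasons[vid] = "maf"
    exclusions = pd.DataFrame(
        {"variant_id": list(reasons), "reason": list(reasons.values())}
    )
    keep = [v for v in geno.variants.index if v not in reasons]
    log.info("variant QC: %d in, %d retained, %d excluded",
             geno.n_variants, len(keep), len(reasons))
    return geno.subset_variants(keep), exclusions


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean (post-QC only)."""
    filled = geno.dosages.fillna(geno.dosages.mean(axis=0))
    return GenotypeMatrix(dosages=filled, variants=geno.variants)


# -- gene filter and normalization -------------------------------------------

def resolve_xy_duplicates(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only the chromosome X copy of genes annotated on both X and Y."""
    genes = expr.genes
    if not genes.index.has_duplicates:
        return expr
    keep_mask = np.ones(len(genes), dtype=bool)
    chrom = genes["chrom"].astype(str).str.removeprefix("chr")
    for gid in genes.index[genes.index.duplicated(keep=False)].unique():
        rows = np.flatnonzero(genes.index == gid)
        chroms = set(chrom.iloc[rows])
        if chroms == {"X", "Y"}:
            for r in rows:
                if chrom.iloc[r] != "X":
                    keep_mask[r] = False
        else:
            keep_mask[rows[1:]] = False  # unrelated duplicate: keep first
    return ExpressionMatrix(
        counts=expr.counts.loc[keep_mask], genes=genes.loc[keep_mask]
    )


def filter_genes(expr: ExpressionMatrix, median_min: float = 8,
                 ) -> ExpressionMatrix:
    """Drop insufficiently expressed genes (median raw count < median_min).

    X/Y duplicate resolution is applied first. Raises if nothing survives.
    """
    expr = resolve_xy_duplicates(expr)
    med = expr.counts.median(axis=1)
    keep = med[med >= median_min].index
    if len(keep) == 0:
        raise PipelineError("gene filter removed every gene")
    log.info("gene filter: %d in, %d retained", len(med), len(keep))
    return expr.subset_genes(keep)


def normalize_expression(expr: ExpressionMatrix, gc_correct: bool = True,
                         gc_window: int | None = None) -> ExpressionMatrix:
    """log2-CPM with a cross-gene running-median GC correction.

    Per gene g and sample s: ``log2(count+0.5) - log2(depth_s/1e6)``, then,
    when ``gc_correct``, minus a smooth GC-effect term: the running median
    (window ~10% of genes) of per-gene mean normalized values taken along
    genes ordered by GC fraction, re-centered so the overall mean level is
    untouched. Equivariant under sample and gene permutations.
    """
    counts = expr.counts
    depth = counts.sum(axis=0).astype(float)
    if (depth <= 0).any():
        raise PipelineError("sample(s) with zero total counts")
    norm = np.log2(counts + 0.5) - np.log2(depth / 1e6)
    if gc_correct:
        gc = expr.genes["gc_fraction"]
        missing = gc.index[gc.isna()]
        if len(missing):
            raise PipelineError(
                f"gc_fraction missing for genes: {list(missing[:5])}"
            )
        if gc_window is None:
            gc_window = max(5, (len(gc) // 10) | 1)
        if gc_window % 2 == 0:
            gc_window += 1
        # order by (gc, gene id) — deterministic and permutation-equivariant
        order = np.lexsort((gc.index.to_numpy(), gc.to_numpy()))
        means = norm.mean(axis=1).to_numpy()
        smooth_sorted = median_filter(means[order], size=gc_window,
                                      mode="nearest")
        smooth = np.empty_like(smooth_sorted)
        smooth[order] = smooth_sorted
        smooth -= smooth.mean()
        norm = norm.sub(smooth, axis=0)
    if not np.isfinite(norm.to_numpy()).all():
        raise PipelineError("normalization produced non-finite values")
    return ExpressionMatrix(counts=expr.counts, genes=expr.genes,
                            normalized=norm)


# -- covariates ---------------------------------------------------------------

def compute_expression_pcs(expr: ExpressionMatrix,
                           var_explained_min: float = 0.01,
                           pc_max: int | None = None,
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Sample-space principal components of normalized expression.

    Genes are centered before decomposition; all components whose variance
    fraction exceeds ``var_explained_min`` are returned, with their
    fractions. The number retained is data-dependent by design (the >1%
    rule selects few components on transcriptome-scale matrices but many on
    small ones); ``pc_max`` optionally caps it.
    """
    if expr.normalized is None:
        raise PipelineError("normalize_expression must run before PCs")
    X = expr.normalized.to_numpy().T  # samples x genes
    n = X.shape[0]
    if n < 2:
        raise PipelineError("need at least 2 samples for PCs")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    k = int(np.sum(frac > var_explained_min))
    k = max(k, 1)
    if pc_max is not None:
        k = min(k, pc_max)
    pcs = pd.DataFrame(
        u[:, :k] * s[:k],
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return pcs, pd.Series(frac[:k], index=pcs.columns, name="variance_explained")


def assemble_covariates(cell_fractions: pd.DataFrame, pcs: pd.DataFrame,
                        pc_variance: pd.Series) -> CovariateSet:
    """Cell fractions + expression PCs on the shared sample index."""
    if not cell_fractions.index.equals(pcs.index):
        pcs = pcs.loc[cell_fractions.index]
    table = pd.concat([cell_fractions, pcs], axis=1)
    return CovariateSet(table=table, pc_variance_explained=pc_variance)
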