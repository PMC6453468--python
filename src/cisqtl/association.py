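"""Covariate-adjusted additive-model association and cis-pairing rules.

The engine residualizes both expression and dosage on the shared covariate
design (intercept + cell fractions + expression PCs) and computes, per
gene-variant pair, the correlation of residual rows. By the
Frisch-Waugh-Lovell theorem the resulting t statistic equals the dosage
coefficient's t in the full multiple regression of expression on dosage
plus covariates, with df = n - 2 - n_covariates.

Stage 1 pairs every LD-set variant of a risk locus with all expressed
genes whose span lies within the cis window (1.1 Mb, boundary inclusive)
of the variant; stage 2 pairs a significant gene with every QC-passing
variant from TSS - window to TES + window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import CovariateSet, GenotypeMatrix, PipelineError, RiskLocus

CIS_WINDOW = 1_100_000

RECORD_COLUMNS = ["gene_id", "variant_id", "locus_id", "stage", "beta",
                  "t_stat", "p_value", "n_used", "flag"]


def _design(covariates: pd.DataFrame | CovariateSet | None,
            n_samples: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n_samples, 1))
    table = covariates.table if isinstance(covariates, CovariateSet) else covariates
    X = np.column_stack([np.ones(len(table)), table.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [np.ones(len(table))]
        for name in table.columns:
            cand = np.column_stack(cols + [table[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(table[name].to_numpy(dtype=float))
        raise PipelineError(f"covariate design is rank deficient; collinear "
                            f"column(s): {bad}")
    return X


def residualize(matrix: pd.DataFrame,
                covariates: pd.DataFrame | CovariateSet | None) -> pd.DataFrame:
    """Project each row of a unit x sample matrix off the covariate space.

    An intercept is always prepended, so residual rows have mean zero.
    """
    X = _design(covariates, matrix.shape[1])
    if X.shape[0] != matrix.shape[1]:
        raise PipelineError("covariate rows do not match matrix samples")
    Y = matrix.to_numpy(dtype=float).T  # samples x units
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns)


def associate(expr_resid: pd.DataFrame, geno_resid: pd.DataFrame,
              pairs: pd.DataFrame, n_covariates: int,
              chunk: int = 200_000) -> pd.DataFrame:
    """Per-pair additive-model statistics from residualized matrices.

    ``pairs`` needs columns gene_id, variant_id (and optionally locus_id,
    stage). Returns one record per pair with beta (expression units per alt
    allele), t, two-sided p and df = n - 2 - n_covariates. Pairs whose
    dosage residual has zero variance are flagged ``monomorphic_residual``
    and carry no p-value.
    """
    if not expr_resid.columns.equals(geno_resid.index):
        raise PipelineError("expression and genotype sample order differ")
    n = expr_resid.shape[1]
    df = n - 2 - n_covariates
    if df < 1:
        raise PipelineError(f"non-positive residual df ({df})")

    E = expr_resid.to_numpy(dtype=float)
    G = geno_resid.to_numpy(dtype=float).T  # variants x samples
    e_ss = np.einsum("ij,ij->i", E, E)
    g_ss = np.einsum("ij,ij->i", G, G)
    gi = expr_resid.index.get_indexer(pairs["gene_id"])
    vi = pd.Index(geno_resid.columns).get_indexer(pairs["variant_id"])
    if (gi < 0).any() or (vi < 0).any():
        raise PipelineError("pairs reference unknown gene or variant ids")

    m = len(pairs)
    r = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        num = np.einsum("ij,ij->i", E[gi[lo:hi]], G[vi[lo:hi]])
        r[lo:hi] = num
    denom = np.sqrt(e_ss[gi] * g_ss[vi])
    # residuals of a constant column are numerical noise, not variance
    tol = 1e-12 * n
    zero_var = (g_ss[vi] <= tol) | (e_ss[gi] <= tol)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(zero_var, np.nan, r / np.where(denom > 0, denom, np.nan))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
        beta = (r * np.sqrt(e_ss[gi]) /
                np.where(g_ss[vi] > 0, np.sqrt(g_ss[vi]), np.nan))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(np.maximum(p, np.nextafter(0, 1)), 1.0)
    out = pd.DataFrame({
        "gene_id": pairs["gene_id"].to_numpy(),
        "variant_id": pairs["variant_id"].to_numpy(),
        "locus_id": pairs.get("locus_id", pd.Series([""] * m)).to_numpy(),
        "stage": pairs.get("stage", pd.Series([1] * m)).to_numpy(),
        "beta": beta,
        "t_stat": t,
        "p_value": np.where(zero_var, np.nan, p),
        "n_used": n,
        "flag": np.where(zero_var, "monomorphic_residual", ""),
    })
    return out


def stage1_pairs(loci: list[RiskLocus], genes: pd.DataFrame,
                 variants: pd.DataFrame,
                 cis_window: int = CIS_WINDOW) -> pd.DataFrame:
    """Variant-based pairing: locus LD-set variants x genes within the window.

    Distance runs from the variant to the nearest edge of the gene span
    (0 inside the span), boundary inclusive. A (gene, variant) pair reached
    via several loci is kept once, attributed to the first locus.
    """
    rows: dict[tuple[str, str], str] = {}
    for locus in loci:
        if locus.empty:
            continue
        chrom = locus.region.chrom
        g_sub = genes[genes["chrom"] == chrom]
        if not len(g_sub):
            continue
        tss = g_sub["tss"].to_numpy()
        tes = g_sub["tes"].to_numpy()
        for vid in locus.ld_variant_ids:
            pos = int(variants.loc[vid, "pos"])
            near = (tss - cis_window <= pos) & (pos <= tes + cis_window)
            for gid in g_sub.index[near]:
                rows.setdefault((gid, vid), locus.locus_id)
    out = pd.DataFrame(
        [(g, v, lid, 1) for (g, v), lid in rows.items()],
        columns=["gene_id", "variant_id", "locus_id", "stage"],
    )
    return out


def stage2_pairs(target_genes: pd.DataFrame, geno: GenotypeMatrix,
                 cis_window: int = CIS_WINDOW) -> pd.DataFrame:
    """Gene-based pairing: all variants within TSS-window .. TES+window."""
    rows = []
    variants = geno.variants
    for gid, meta in target_genes.iterrows():
        sel = variants[
            (variants["chrom"] == meta["chrom"])
            & (variants["pos"] >= int(meta["tss"]) - cis_window)
            & (variants["pos"] <= int(meta["tes"]) + cis_window)
        ]
        for vid in sel.index:
            rows.append((gid, vid, "", 2))
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "locus_id",
                                       "stage"])
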