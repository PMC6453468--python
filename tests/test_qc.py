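"""Variant QC, gene filtering, normalization and covariate extraction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cisqtl.qc import (
    compute_expression_pcs,
    filter_genes,
    filter_variants,
    hwe_exact_pvalue,
    mean_impute,
    normalize_expression,
    resolve_xy_duplicates,
)
from cisqtl.types import ExpressionMatrix, PipelineError

from conftest import make_expression, make_genotypes


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact test: sum probabilities of heterozygote
    configurations no more likely than the observed one."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    rare = min(n_a, 2 * n - n_a)

    def prob(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return (math.comb(n, h) * math.comb(n - h, hr) * 2 ** h
                / math.comb(2 * n, rare))

    hets = range(rare % 2, rare + 1, 2)
    p_obs = prob(n_Aa)
    return min(1.0, sum(prob(h) for h in hets if prob(h) <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_matches_enumeration_oracle_small_totals(self):
        for n in range(1, 26):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    got = hwe_exact_pvalue(n_AA, n_Aa, n_aa)
                    want = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-9), (n_AA, n_Aa, n_aa)

    def test_all_heterozygous_is_extreme(self):
        assert hwe_exact_pvalue(0, 100, 0) < 1e-5

    def test_perfect_proportions_give_p_one(self):
        assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_is_p_one(self):
        assert hwe_exact_pvalue(10, 0, 0) == pytest.approx(1.0)

    def test_symmetric_under_allele_relabeling(self):
        for counts in [(5, 10, 30), (1, 7, 2), (0, 3, 12)]:
            assert hwe_exact_pvalue(*counts) == pytest.approx(
                hwe_exact_pvalue(*counts[::-1]))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


class TestFilterVariants:
    def test_clean_common_variant_retained(self):
        d = np.tile([0, 1, 2, 2, 1, 0, 1, 1], (10, 1)).T.reshape(-1, 1)
        d = np.column_stack([np.tile([0., 1, 2, 2, 1, 0, 1, 1], 10)])
        geno = make_genotypes(d)
        kept, excl = filter_variants(geno)
        assert kept.n_variants == 1 and excl.empty

    def test_low_call_rate_dropped(self):
        d = np.tile([0., 1, 2, 1], 25).reshape(-1, 1)
        d[:6, 0] = np.nan  # 94% call rate
        geno = make_genotypes(d)
        kept, excl = filter_variants(geno)
        assert kept.n_variants == 0
        assert excl.iloc[0]["reason"] == "call_rate"

    def test_imputed_low_quality_dropped_as_allelic_r2(self):
        d = np.tile([0., 1, 2, 1, 0], 20).reshape(-1, 1)  # MAF 0.4
        geno = make_genotypes(d, is_imputed=True, allelic_r2=0.29)
        kept, excl = filter_variants(geno)
        assert kept.n_variants == 0
        assert excl.iloc[0]["reason"] == "allelic_r2"

    def test_low_maf_dropped(self):
        d = np.zeros((200, 1))
        d[0, 0] = 1.0  # MAF 0.0025
        geno = make_genotypes(d)
        kept, excl = filter_variants(geno)
        assert excl.iloc[0]["reason"] == "maf"

    def test_hwe_violation_dropped(self):
        d = np.ones((100, 1))  # all heterozygous
        geno = make_genotypes(d)
        kept, excl = filter_variants(geno)
        assert excl.iloc[0]["reason"] == "hwe"

    def test_idempotent(self, planted_bundle):
        once, _ = filter_variants(planted_bundle.genotypes)
        twice, excl2 = filter_variants(once)
        assert excl2.empty
        pd.testing.assert_frame_equal(once.dosages, twice.dosages)

    def test_mean_impute_fills_missing(self):
        d = np.tile([0., 1, 2, 1], 10).reshape(-1, 1)
        d[3, 0] = np.nan
        geno = mean_impute(make_genotypes(d))
        col = geno.dosages.iloc[:, 0]
        assert not col.isna().any()
        assert col.iloc[3] == pytest.approx(np.nanmean(d))


class TestFilterGenes:
    def test_median_below_threshold_dropped_boundary_retained(self):
        counts = np.vstack([np.full(11, 7), np.full(11, 8)])
        expr = make_expression(counts)
        kept = filter_genes(expr, median_min=8)
        assert list(kept.counts.index) == ["g1"]

    def test_xy_duplicate_keeps_x_copy(self):
        counts = pd.DataFrame(np.full((2, 4), 50),
                              index=pd.Index(["gA", "gA"], name="gene_id"),
                              columns=[f"s{i}" for i in range(4)])
        genes = pd.DataFrame({
            "gene_class": "protein_coding", "chrom": ["chrY", "chrX"],
            "tss": [100, 100], "tes": [200, 200], "strand": "+",
            "gc_fraction": 0.5,
        }, index=counts.index)
        expr = ExpressionMatrix(counts=counts, genes=genes)
        resolved = resolve_xy_duplicates(expr)
        assert len(resolved.genes) == 1
        assert resolved.genes.iloc[0]["chrom"] == "chrX"

    def test_all_genes_removed_is_an_error(self):
        expr = make_expression(np.zeros((3, 5), dtype=int))
        with pytest.raises(PipelineError):
            filter_genes(expr, median_min=8)


class TestNormalize:
    def test_depth_offset_is_exactly_one_log2_unit(self):
        counts = np.column_stack([np.full(20, 40), np.full(20, 40)])
        expr = make_expression(counts)
        # double every count in sample 1: same relative expression,
        # double depth
        expr.counts.iloc[:, 1] *= 2
        norm = normalize_expression(expr, gc_correct=False).normalized
        diff = norm.iloc[:, 0] - norm.iloc[:, 1]
        # log2(c+0.5) - log2(2c+0.5) + log2(2) ~ 0 up to the +0.5 offset
        assert np.allclose(diff, diff.iloc[0])
        assert abs(diff.iloc[0]) < 0.02

    def test_equal_depth_preserves_within_gene_ranking(self):
        counts = np.array([[10, 20, 40, 80],
                           [80, 70, 50, 10]])  # equal column sums
        assert len(set(counts.sum(axis=0))) == 1
        norm = normalize_expression(make_expression(counts),
                                    gc_correct=False).normalized
        for g in range(2):
            assert (np.argsort(norm.iloc[g].to_numpy())
                    == np.argsort(counts[g])).all()

    def test_gc_bias_is_reduced_at_least_half(self):
        from cisqtl.simulate import SimConfig, simulate_dataset
        cfg = SimConfig(n_samples=120, n_genes=400, n_blocks=1, seed=21,
                        genome_span_bp=2_000_000, gc_bias=3.0)
        b = simulate_dataset(cfg)
        expr = b.expression
        gc = expr.genes["gc_fraction"].to_numpy()
        depth = expr.counts.sum(axis=0)
        logcpm = np.log2(expr.counts + 0.5) - np.log2(depth / 1e6)
        before = abs(np.corrcoef(logcpm.mean(axis=1), gc)[0, 1])
        norm = normalize_expression(expr, gc_correct=True).normalized
        after = abs(np.corrcoef(norm.mean(axis=1), gc)[0, 1])
        assert after <= 0.5 * before

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(5, 500, size=(30, 12))
        expr = make_expression(counts)
        norm = normalize_expression(expr).normalized
        gp = rng.permutation(30)
        sp = rng.permutation(12)
        shuffled = ExpressionMatrix(counts=expr.counts.iloc[gp, sp],
                                    genes=expr.genes.iloc[gp])
        norm_shuffled = normalize_expression(shuffled).normalized
        pd.testing.assert_frame_equal(norm_shuffled, norm.iloc[gp, sp])

    def test_missing_gc_fraction_names_genes(self):
        expr = make_expression(np.full((4, 6), 20))
        expr.genes.loc["g2", "gc_fraction"] = np.nan
        with pytest.raises(PipelineError, match="g2"):
            normalize_expression(expr)


class TestExpressionPCs:
    def test_rank_one_matrix_yields_single_dominant_pc(self):
        u = np.linspace(-1, 1, 40)
        v = np.linspace(2, 5, 25)
        counts = np.maximum(0, np.outer(v, u * 10 + 20)).astype(int)
        expr = make_expression(counts)
        norm = pd.DataFrame(np.outer(v, u), index=expr.counts.index,
                            columns=expr.counts.columns)
        expr = ExpressionMatrix(counts=expr.counts, genes=expr.genes,
                                normalized=norm)
        pcs, frac = compute_expression_pcs(expr)
        assert pcs.shape[1] == 1
        assert frac.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_small_gene_count_passes_many_pcs(self):
        # with few samples the >1% rule keeps most PCs: the threshold is
        # data-dependent, not a fixed component count
        rng = np.random.default_rng(4)
        n = 100
        counts = rng.integers(10, 100, size=(2000, n))
        expr = make_expression(counts)
        norm = pd.DataFrame(rng.normal(size=(2000, n)),
                            index=expr.counts.index,
                            columns=expr.counts.columns)
        expr = ExpressionMatrix(counts=expr.counts, genes=expr.genes,
                                normalized=norm)
        pcs, frac = compute_expression_pcs(expr, var_explained_min=0.01)
        assert pcs.shape[1] >= 40  # a fixed "13 PCs" would never emerge here
        assert np.allclose(frac.to_numpy(), 1 / (n - 1), atol=5e-3)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_pc_cap(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 100, size=(50, 30))
        expr = normalize_expression(make_expression(counts))
        pcs, _ = compute_expression_pcs(expr, pc_max=3)
        assert pcs.shape[1] == 3

    def test_single_sample_rejected(self):
        expr = make_expression(np.full((5, 1), 20))
        expr = ExpressionMatrix(counts=expr.counts, genes=expr.genes,
                                normalized=np.log2(expr.counts + 0.5))
        with pytest.raises(PipelineError):
            compute_expression_pcs(expr)
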