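"""Residualization, the correlation-based association engine, cis pairing."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cisqtl.association import associate, residualize, stage1_pairs, stage2_pairs
from cisqtl.types import PipelineError, RiskLocus, RiskRegion

from conftest import make_genotypes


def _random_problem(seed, n=120, n_genes=15, n_vars=15, n_cov=4):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    expr = pd.DataFrame(rng.normal(size=(n_genes, n)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=samples)
    geno = pd.DataFrame(rng.binomial(2, 0.3, size=(n, n_vars)).astype(float),
                        index=samples,
                        columns=[f"v{i}" for i in range(n_vars)])
    cov = pd.DataFrame(rng.normal(size=(n, n_cov)), index=samples,
                       columns=[f"c{i}" for i in range(n_cov)])
    return expr, geno, cov


class TestResidualize:
    def test_intercept_only_is_row_centering(self):
        expr, _, _ = _random_problem(0)
        res = residualize(expr, None)
        pd.testing.assert_frame_equal(res, expr.sub(expr.mean(axis=1), axis=0))

    def test_row_equal_to_covariate_vanishes(self):
        expr, _, cov = _random_problem(1)
        expr.iloc[0] = cov["c0"].to_numpy()
        res = residualize(expr, cov)
        assert np.linalg.norm(res.iloc[0]) < 1e-10

    def test_matches_per_row_least_squares_oracle(self):
        expr, _, cov = _random_problem(2)
        res = residualize(expr, cov)
        X = sm.add_constant(cov.to_numpy())
        for g in range(expr.shape[0]):
            fit = sm.OLS(expr.iloc[g].to_numpy(), X).fit()
            assert np.allclose(res.iloc[g].to_numpy(), fit.resid, atol=1e-10)

    def test_rank_deficient_design_names_column(self):
        expr, _, cov = _random_problem(3)
        cov["dup"] = cov["c1"] * 2.0
        with pytest.raises(PipelineError, match="dup"):
            residualize(expr, cov)


class TestAssociate:
    def _records(self, seed, n_cov=4, **kw):
        expr, geno, cov = _random_problem(seed, n_cov=n_cov, **kw)
        pairs = pd.DataFrame(
            [(g, v) for g in expr.index for v in geno.columns],
            columns=["gene_id", "variant_id"])
        er = residualize(expr, cov)
        gr = residualize(geno.T, cov).T
        rec = associate(er, gr, pairs, n_covariates=n_cov)
        return expr, geno, cov, rec

    def test_matches_full_multiple_regression_oracle(self):
        expr, geno, cov, rec = self._records(5)
        X0 = cov.to_numpy()
        for _, row in rec.sample(60, random_state=0).iterrows():
            y = expr.loc[row["gene_id"]].to_numpy()
            x = geno[row["variant_id"]].to_numpy()
            X = sm.add_constant(np.column_stack([x, X0]))
            fit = sm.OLS(y, X).fit()
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert row["t_stat"] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert row["p_value"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_null_p_values_uniform_and_type_one_error(self):
        rng = np.random.default_rng(11)
        n, n_genes, n_vars = 150, 100, 100
        expr = pd.DataFrame(rng.normal(size=(n_genes, n)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n)])
        geno = pd.DataFrame(rng.binomial(2, 0.3, size=(n, n_vars)).astype(float),
                            index=expr.columns,
                            columns=[f"v{i}" for i in range(n_vars)])
        pairs = pd.DataFrame([(g, v) for g in expr.index for v in geno.columns],
                             columns=["gene_id", "variant_id"])
        er = residualize(expr, None)
        gr = residualize(geno.T, None).T
        rec = associate(er, gr, pairs, n_covariates=0)
        p = rec["p_value"].to_numpy()
        assert len(p) == 10_000
        from scipy import stats
        assert stats.kstest(p, "uniform").pvalue > 0.01
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_sample_permutation_invariance(self):
        expr, geno, cov, rec = self._records(6)
        perm = np.random.default_rng(1).permutation(expr.shape[1])
        expr2 = expr.iloc[:, perm]
        geno2 = geno.iloc[perm]
        cov2 = cov.iloc[perm]
        pairs = rec[["gene_id", "variant_id"]]
        rec2 = associate(residualize(expr2, cov2),
                         residualize(geno2.T, cov2).T, pairs, n_covariates=4)
        assert np.allclose(rec["t_stat"], rec2["t_stat"], atol=1e-10)

    def test_monomorphic_residual_flagged_without_p(self):
        expr, geno, cov = _random_problem(7)
        geno["v0"] = 1.0  # constant dosage
        pairs = pd.DataFrame([("g0", "v0")], columns=["gene_id", "variant_id"])
        rec = associate(residualize(expr, cov), residualize(geno.T, cov).T,
                        pairs, n_covariates=4)
        assert rec.iloc[0]["flag"] == "monomorphic_residual"
        assert np.isnan(rec.iloc[0]["p_value"])

    def test_permuted_expression_breaks_planted_signal(self, planted_bundle):
        b = planted_bundle
        gid, vid, _ = b.truth.causal_pairs[0]
        y = np.log2(b.expression.counts.loc[gid].to_numpy() + 0.5)
        x = b.genotypes.dosages[vid].to_numpy()
        expr = pd.DataFrame([y], index=[gid], columns=b.genotypes.sample_ids)
        geno = pd.DataFrame({vid: x}, index=b.genotypes.sample_ids)
        pairs = pd.DataFrame([(gid, vid)], columns=["gene_id", "variant_id"])
        rec = associate(residualize(expr, None), residualize(geno.T, None).T,
                        pairs, n_covariates=0)
        assert rec.iloc[0]["p_value"] < 1e-6
        rng = np.random.default_rng(0)
        expr_perm = expr.iloc[:, rng.permutation(expr.shape[1])]
        expr_perm.columns = expr.columns
        rec_perm = associate(residualize(expr_perm, None),
                             residualize(geno.T, None).T, pairs, n_covariates=0)
        assert rec_perm.iloc[0]["p_value"] > 1e-4


def _pairing_fixture():
    """One locus with two LD variants, genes at boundary distances."""
    n = 10
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=(n, 2)).astype(float)
    geno = make_genotypes(d, positions=[5_000_000, 5_010_000])
    genes = pd.DataFrame({
        "gene_class": "protein_coding", "chrom": "chr1",
        "tss": [5_000_000 + 1_100_000,   # exactly at the window edge
                5_000_000 + 1_200_000,   # beyond it
                4_000_000],
        "tes": [5_000_000 + 1_100_000 + 5000,
                5_000_000 + 1_200_000 + 5000,
                4_000_500],
        "strand": "+", "gc_fraction": 0.5,
    }, index=pd.Index(["edge", "far", "near"], name="gene_id"))
    locus = RiskLocus("L001", RiskRegion("chr1", 4_900_000, 5_110_000,
                                         ("snp0",)),
                      ("snp0",), ("snp0", "snp1"))
    return geno, genes, locus


class TestPairing:
    def test_stage1_boundary_inclusive(self):
        geno, genes, locus = _pairing_fixture()
        pairs = stage1_pairs([locus], genes, geno.variants)
        got = set(zip(pairs["gene_id"], pairs["variant_id"]))
        assert ("edge", "snp0") in got     # TSS exactly 1.1 Mb away
        assert ("far", "snp0") not in got  # 1.2 Mb away
        assert ("near", "snp0") in got

    def test_stage1_deduplicates_within_locus(self):
        geno, genes, locus = _pairing_fixture()
        pairs = stage1_pairs([locus], genes, geno.variants)
        assert not pairs.duplicated(["gene_id", "variant_id"]).any()

    def test_stage2_window_and_chromosome(self):
        geno, genes, _ = _pairing_fixture()
        target = genes.loc[["near"]]
        pairs = stage2_pairs(target, geno)
        # snp0 at 5,000,000 is within TES+1.1Mb = 5,100,500 -> included
        assert ("near", "snp0") in set(zip(pairs["gene_id"], pairs["variant_id"]))
        other = genes.copy()
        other["chrom"] = "chr9"
        assert len(stage2_pairs(other.loc[["near"]], geno)) == 0

    def test_stage2_boundary_exact_and_count(self):
        n = 10
        rng = np.random.default_rng(1)
        tss, tes = 2_000_000, 2_005_000
        inside = [tss - 1_100_000, tss, tes, tes + 1_100_000]
        outside = [tss - 1_100_001, tes + 1_100_001]
        pos = sorted(inside + outside)
        d = rng.integers(0, 3, size=(n, len(pos))).astype(float)
        geno = make_genotypes(d, positions=pos)
        genes = pd.DataFrame({
            "gene_class": "other", "chrom": "chr1", "tss": [tss],
            "tes": [tes], "strand": "+", "gc_fraction": 0.4,
        }, index=pd.Index(["g"], name="gene_id"))
        pairs = stage2_pairs(genes, geno)
        want = {f"snp{pos.index(p)}" for p in inside}
        assert set(pairs["variant_id"]) == want
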