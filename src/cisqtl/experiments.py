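"""Self-contained evaluation experiments for the pipeline.

Each function runs a deterministic-given-seed experiment through the public
API and returns a plain dict of numbers: oracle comparisons for the
association engine, the FDR machinery and region merging, plus synthetic
null-calibration and planted-effect recovery studies. They are shared by
the test suite and the acceptance report script.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .association import associate, residualize
from .loci import build_regions
from .pipeline import InputBundle, run_from_bundle
from .significance import bh_qvalues, gene_wise_significance
from .simulate import (
    block_tag_risk_list,
    null_config,
    recovery_config,
    simulate_dataset,
)
from .types import GENE_CLASSES

log = logging.getLogger(__name__)

_SEED_MOD = 2 ** 31 - 1


def child_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed below 2^31 for replicate ``index``."""
    return (seed * 100_003 + index) % _SEED_MOD


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up with enforced monotonicity."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def fwl_vs_ols(seed: int = 0, n_pairs: int = 1000, n_samples: int = 120,
               n_units: int = 60, n_covariates: int = 4) -> dict:
    """Largest |t| and |beta| gap between the residualize-then-correlate
    engine and a per-pair full multiple regression (statsmodels OLS)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    C = rng.normal(size=(n_samples, n_covariates))
    cov = pd.DataFrame(C, index=[f"s{i}" for i in range(n_samples)],
                       columns=[f"c{j}" for j in range(n_covariates)])
    G = rng.binomial(2, rng.uniform(0.1, 0.5, n_units),
                     size=(n_samples, n_units)).astype(float)
    # covariate leakage into expression so the adjustment is load-bearing
    E = (rng.normal(size=(n_units, n_samples))
         + 0.5 * C[:, 0][None, :] - 0.3 * C[:, 1][None, :])
    expr = pd.DataFrame(E, index=[f"g{i}" for i in range(n_units)],
                        columns=cov.index)
    geno = pd.DataFrame(G, index=cov.index,
                        columns=[f"v{i}" for i in range(n_units)])

    expr_resid = residualize(expr, cov)
    geno_resid = residualize(geno.T, cov).T
    gi = rng.integers(0, n_units, n_pairs)
    vi = rng.integers(0, n_units, n_pairs)
    pairs = pd.DataFrame({"gene_id": expr.index[gi].to_numpy(),
                          "variant_id": geno.columns[vi].to_numpy()})
    got = associate(expr_resid, geno_resid, pairs, n_covariates)

    max_t = max_b = 0.0
    for k in range(n_pairs):
        x = np.column_stack([np.ones(n_samples), G[:, vi[k]], C])
        fit = sm.OLS(E[gi[k]], x).fit()
        max_t = max(max_t, abs(fit.tvalues[1] - got["t_stat"].iat[k]))
        max_b = max(max_b, abs(fit.params[1] - got["beta"].iat[k]))
    return {"max_abs_t_diff": float(max_t), "max_abs_beta_diff": float(max_b),
            "n_pairs": int(n_pairs)}


def bh_vs_oracle(seed: int = 0, n_vectors: int = 1000,
                 n_gene_tables: int = 200) -> dict:
    """Gap between the FDR machinery and brute-force step-up oracles.

    Checks raw BH q-values on random p-vectors (plus monotonicity of q in
    p), and the full gene-centric rule (per-gene Bonferroni of its tests,
    then per-class BH on the minima) on random association tables.
    """
    rng = np.random.default_rng(seed)
    max_q = 0.0
    violations = 0
    for _ in range(n_vectors):
        p = rng.uniform(1e-10, 1.0, size=int(rng.integers(1, 150)))
        q = bh_qvalues(p)
        max_q = max(max_q, float(np.max(np.abs(q - _bh_oracle(p)))))
        order = np.argsort(p, kind="mergesort")
        if np.any(np.diff(q[order]) < -1e-15):
            violations += 1

    max_gene_q = 0.0
    for _ in range(n_gene_tables):
        n_genes = int(rng.integers(2, 30))
        gene_ids = [f"g{i}" for i in range(n_genes)]
        classes = pd.Series(rng.choice(GENE_CLASSES, n_genes), index=gene_ids)
        rows = []
        for gid in gene_ids:
            for j in range(int(rng.integers(1, 8))):
                rows.append((gid, f"v{j}", float(rng.uniform(1e-8, 1.0)), 1.0))
        rec = pd.DataFrame(rows, columns=["gene_id", "variant_id",
                                          "p_value", "t_stat"])
        got = {s.gene_id: s.q_value for s in
               gene_wise_significance(rec, classes)}
        bonf = rec.groupby("gene_id")["p_value"].agg(["size", "min"])
        bonf["b"] = np.minimum(1.0, bonf["size"] * bonf["min"])
        for cls in GENE_CLASSES:
            ids = [g for g in gene_ids if classes[g] == cls]
            if not ids:
                continue
            want = _bh_oracle(bonf.loc[ids, "b"].to_numpy())
            for g, w in zip(ids, want):
                max_gene_q = max(max_gene_q, abs(got[g] - w))
    return {"max_abs_q_diff": max_q, "monotonicity_violations": int(violations),
            "n_vectors": int(n_vectors), "max_abs_gene_q_diff": max_gene_q,
            "n_gene_tables": int(n_gene_tables)}


def null_calibration(seed: int = 0, n_seeds: int = 50, n_samples: int = 400,
                     n_genes: int = 600) -> dict:
    """Per-class gene-wise discovery rate on fully null synthetic studies.

    The bound per class is the nominal 1% plus two Monte-Carlo standard
    errors for the number of genes actually tested in that class.
    """
    tested = {c: 0 for c in GENE_CLASSES}
    hits = {c: 0 for c in GENE_CLASSES}
    for i in range(n_seeds):
        cfg = null_config(child_seed(seed, i), n_samples=n_samples,
                          n_genes=n_genes)
        bundle = simulate_dataset(cfg)
        risk = block_tag_risk_list(bundle.genotypes, cfg)
        res = run_from_bundle(InputBundle(bundle.genotypes, bundle.expression,
                                          bundle.covariates, risk))
        sig = res.gene_significance
        for cls, sub in sig.groupby("gene_class"):
            tested[cls] += len(sub)
            hits[cls] += int(sub["significant"].sum())
    per_class = {}
    for cls in GENE_CLASSES:
        n = tested[cls]
        rate = hits[cls] / n if n else 0.0
        bound = 0.01 + 2 * math.sqrt(0.01 * 0.99 / n) if n else float("inf")
        per_class[cls] = {"n_tested": int(n), "n_discovered": int(hits[cls]),
                          "rate": float(rate), "bound": float(bound)}
    worst = max(s["rate"] - s["bound"] for s in per_class.values())
    return {"per_class": per_class, "worst_rate_minus_bound": float(worst),
            "n_seeds": int(n_seeds)}


def _one_recovery(seed: int, tag: str, beta: float) -> int:
    """Group call at the scenario's tag locus; 0 if the gene misses
    gene-wise significance or has no call at that locus."""
    cfg = recovery_config(seed, tag=tag, beta=beta)
    bundle = simulate_dataset(cfg)
    res = run_from_bundle(InputBundle(bundle.genotypes, bundle.expression,
                                      bundle.covariates,
                                      bundle.risk_variants))
    sig = res.gene_significance
    row = sig[sig["gene_id"] == "g000"]
    if row.empty or not bool(row["significant"].iloc[0]):
        return 0
    want_bin = "high" if tag == "high" else "low"
    rsid = next(r for r, _, b in bundle.truth.tag_map if b == want_bin)
    locus_ids = {lo.locus_id for lo in res.loci if rsid in lo.risk_rsids}
    calls = res.calls
    m = calls[(calls["gene_id"] == "g000")
              & calls["locus_id"].isin(locus_ids)]
    if m.empty:
        return 0
    return int(m["group"].iloc[0])


def recovery_study(seed: int = 0, n_reps: int = 100, beta: float = 0.6) -> dict:
    """Recovery rates for one planted cis effect across replicates.

    A within-block tag (founder-level r^2 ~ 0.8 to the causal variant)
    should yield a significant Group 1 call at its locus; an unlinked tag
    one block away should yield Group 3 at that locus.
    """
    g1 = sum(_one_recovery(child_seed(seed, i), "high", beta) == 1
             for i in range(n_reps))
    g3 = sum(_one_recovery(child_seed(seed, n_reps + i), "low", beta) == 3
             for i in range(n_reps))
    return {"group1_recovery_rate": g1 / n_reps,
            "group3_recovery_rate": g3 / n_reps, "n_reps": int(n_reps)}


def region_merge_vs_oracle(seed: int = 0, n_lists: int = 1000,
                           flank: int = 100_000) -> dict:
    """Region building versus a brute-force inclusive interval merge."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_lists):
        pos = np.unique(rng.integers(flank + 1, 10_000_000,
                                     size=int(rng.integers(1, 20))))
        risk = pd.DataFrame({"rsid": [f"r{i}" for i in range(len(pos))],
                             "chrom": "chrS", "pos": pos})
        got = [(r.start, r.end) for r in build_regions(risk, flank)]
        want: list[tuple[int, int]] = []
        for p in pos:
            s, e = int(p) - flank, int(p) + flank
            if want and s <= want[-1][1]:
                want[-1] = (want[-1][0], max(want[-1][1], e))
            else:
                want.append((s, e))
        if got != want:
            mismatches += 1
    return {"n_mismatches": int(mismatches), "n_lists": int(n_lists)}
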