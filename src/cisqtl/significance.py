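"""Gene-centric FDR, variant-level FDR, peak variants, Group 1/2/3 calls.

Stage 1 uses a hierarchical, gene-centric error control: each gene's tests
are Bonferroni-corrected within the gene, then Benjamini-Hochberg q-values
are computed across genes on the per-gene Bonferroni minima, separately per
gene class (protein_coding / lncRNA / other); genes with q <= 1% are
"gene-wise" significant. Stage 2 applies one pooled BH pass across all
(gene, variant) records of the significant genes. A significant gene is
then classified per risk locus by the LD between the locus's risk
variant(s) and the gene's peak eQTL variant across both stages:
Group 1 (r^2 >= 0.5), Group 2 (0.2 <= r^2 < 0.5), Group 3 (r^2 < 0.2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .loci import ld_r2
from .types import GeneGroupCall, GeneSignificance, GenotypeMatrix, PipelineError, RiskLocus

log = logging.getLogger(__name__)

GENE_Q_MAX = 0.01
GROUP1_MIN_R2 = 0.5
GROUP2_MIN_R2 = 0.2


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_wise_significance(records: pd.DataFrame, gene_classes: pd.Series,
                           q_max: float = GENE_Q_MAX,
                           ) -> list[GeneSignificance]:
    """Per-gene Bonferroni, then per-class BH across genes' minima."""
    rec = records[records["p_value"].notna()]
    if rec.empty:
        return []
    missing = set(rec["gene_id"]) - set(gene_classes.index)
    if missing:
        raise PipelineError(f"gene(s) without class label: {sorted(missing)[:5]}")
    grp = rec.groupby("gene_id")["p_value"]
    stats = pd.DataFrame({"n_tests": grp.size(), "min_p": grp.min()})
    stats["bonferroni_min_p"] = np.minimum(1.0, stats["n_tests"] * stats["min_p"])
    stats["gene_class"] = gene_classes.loc[stats.index]

    out: list[GeneSignificance] = []
    for cls, sub in stats.groupby("gene_class", sort=True):
        q = bh_qvalues(sub["bonferroni_min_p"].to_numpy())
        for (gid, row), qv in zip(sub.iterrows(), q):
            out.append(GeneSignificance(
                gene_id=gid, gene_class=cls, n_tests=int(row["n_tests"]),
                min_p=float(row["min_p"]),
                bonferroni_min_p=float(row["bonferroni_min_p"]),
                q_value=float(qv), significant=bool(qv <= q_max)))
    out.sort(key=lambda s: s.gene_id)
    dropped = records.loc[records["p_value"].isna(), "gene_id"].unique()
    for gid in dropped:
        if gid not in stats.index:
            log.warning("gene %s excluded: no testable stage-1 record", gid)
    return out


def significance_table(sigs: list[GeneSignificance]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in sigs])


def variant_level_fdr(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled BH across all stage-2 records of significant target genes."""
    out = records.copy()
    out["q_value"] = np.nan
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "q_value"] = bh_qvalues(out.loc[ok, "p_value"].to_numpy())
    return out


def find_peak_variant(gene_id: str, records: pd.DataFrame,
                      variant_pos: pd.Series) -> pd.Series:
    """Smallest-p record for a gene across stages 1+2.

    Ties break on larger |t|, then smaller genomic position.
    """
    rec = records[(records["gene_id"] == gene_id) & records["p_value"].notna()]
    if rec.empty:
        raise PipelineError(f"gene {gene_id} has no testable record")
    rec = rec.assign(
        _abs_t=rec["t_stat"].abs(),
        _pos=variant_pos.loc[rec["variant_id"]].to_numpy(),
    )
    rec = rec.sort_values(["p_value", "_abs_t", "_pos"],
                          ascending=[True, False, True], kind="mergesort")
    return rec.iloc[0]


def assign_group(r2: float, group1_min: float = GROUP1_MIN_R2,
                 group2_min: float = GROUP2_MIN_R2) -> int:
    """Group 1 for r^2 >= 0.5, Group 2 for r^2 in [0.2, 0.5), else Group 3;
    both lower boundaries inclusive."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"r^2 out of range: {r2}")
    return 1 if r2 >= group1_min else (2 if r2 >= group2_min else 3)


def classify_gene(locus: RiskLocus, gene_id: str, peak: pd.Series,
                  geno: GenotypeMatrix,
                  group1_min: float = GROUP1_MIN_R2,
                  group2_min: float = GROUP2_MIN_R2) -> GeneGroupCall:
    """Group 1/2/3 by the max r^2 of the peak variant to the locus's risk
    variants (the group-promoting reading for multi-risk-variant loci)."""
    peak_vid = peak["variant_id"]
    peak_dos = geno.dosages[peak_vid].to_numpy()
    if np.ptp(peak_dos[~np.isnan(peak_dos)]) == 0:
        raise PipelineError(f"peak variant {peak_vid} is monomorphic")
    r2 = max(
        ld_r2(geno.dosages[r].to_numpy(), peak_dos) for r in locus.risk_rsids
    )
    group = assign_group(r2, group1_min, group2_min)
    return GeneGroupCall(
        locus_id=locus.locus_id, gene_id=gene_id, peak_variant_id=peak_vid,
        peak_p=float(peak["p_value"]), r2_to_risk=float(r2), group=group)


def calls_table(calls: list[GeneGroupCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def format_pct(numer: int, denom: int, decimals: int = 0) -> float:
    """Percentage rounded to the reporting precision (e.g. 52.0, 41)."""
    if denom == 0:
        return 0.0
    return round(100.0 * numer / denom, decimals if decimals > 0 else None)


def summarize(calls: list[GeneGroupCall], sigs: list[GeneSignificance],
              loci: list[RiskLocus]) -> dict:
    """Headline tallies: per-class gene counts by best group, locus counts.

    A gene significant at several loci is counted once, in the group with
    the highest LD (smallest group number). Locus percentages carry one
    decimal; per-class group percentages are integers.
    """
    sig_class = {s.gene_id: s.gene_class for s in sigs if s.significant}
    best_group: dict[str, int] = {}
    for c in calls:
        if c.gene_id in sig_class:
            best_group[c.gene_id] = min(best_group.get(c.gene_id, 3), c.group)

    per_class: dict[str, dict] = {}
    for cls in sorted({s.gene_class for s in sigs} | {"protein_coding",
                                                      "lncRNA", "other"}):
        genes = [g for g, c in sig_class.items() if c == cls]
        groups = {k: sum(1 for g in genes if best_group.get(g) == k)
                  for k in (1, 2, 3)}
        n = len(genes)
        per_class[cls] = {
            "n_significant_genes": n,
            "group_counts": groups,
            "pct_group1": format_pct(groups[1], n) if n else 0,
        }

    loci_with_sig = set()
    loci_with_group1 = set()
    for c in calls:
        if c.gene_id in sig_class:
            loci_with_sig.add(c.locus_id)
            if c.group == 1:
                loci_with_group1.add(c.locus_id)
    n_loci = len(loci)
    return {
        "n_loci": n_loci,
        "n_loci_with_signal": len(loci_with_sig),
        "pct_loci_with_signal": format_pct(len(loci_with_sig), n_loci, 1),
        "n_loci_with_group1": len(loci_with_group1),
        "pct_loci_with_group1": format_pct(len(loci_with_group1), n_loci, 1),
        "n_significant_genes": len(sig_class),
        "per_class": per_class,
    }
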