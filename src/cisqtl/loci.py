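"""Risk regions and loci from a published risk-variant list.

A risk region is the +/-100 kb physical interval around a risk variant,
with overlapping intervals merged transitively. Within a region, risk
variants are clustered by single-linkage on genotypic r^2 >= 0.5 into risk
loci, and each locus is expanded to the set of all region variants in LD
(r^2 >= 0.5) with at least one of its risk variants. Coordinates are
1-based inclusive; overlap means sharing at least one base.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import EXCLUSION_REASONS, GenotypeMatrix, PipelineError, RiskLocus, RiskRegion

log = logging.getLogger(__name__)

REGION_FLANK = 100_000
LD_THRESHOLD = 0.5


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Genotypic LD: squared Pearson correlation of dosage vectors.

    Invariant to allele flips (d -> 2 - d). Monomorphic input is an error
    (r^2 undefined).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples for r^2")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r^2 undefined for monomorphic dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between columns of a dosage matrix (no missing values)."""
    x = d - d.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (x.T @ x) / d.shape[0] / np.outer(sd, sd)
    return c ** 2


def screen_risk_variants(risk_list: pd.DataFrame, geno: GenotypeMatrix,
                         maf_min: float = 0.01) -> pd.DataFrame:
    """Annotate each risk variant as included or excluded with one reason.

    Reasons, in check order per variant: ``not_in_genotypes``, ``low_maf``,
    ``perfect_ld`` (r^2 = 1 with an earlier *included* risk variant — the
    first-listed member of a perfect-LD pair is kept).
    """
    if len(risk_list) == 0:
        raise ValueError("risk list is empty")
    maf = geno.maf()
    out = risk_list.copy().reset_index(drop=True)
    status, reason = [], []
    kept: list[str] = []
    for _, row in out.iterrows():
        rsid = row["rsid"]
        if rsid not in geno.variants.index:
            status.append("excluded"); reason.append("not_in_genotypes")
            continue
        if maf[rsid] < maf_min:
            status.append("excluded"); reason.append("low_maf")
            continue
        dup = None
        for prev in kept:
            if ld_r2(geno.dosages[rsid].to_numpy(),
                     geno.dosages[prev].to_numpy()) >= 1.0 - 1e-9:
                dup = prev
                break
        if dup is not None:
            status.append("excluded"); reason.append("perfect_ld")
            continue
        kept.append(rsid)
        status.append("included"); reason.append("")
    out["status"] = status
    out["reason"] = reason
    assert set(out.loc[out["status"] == "excluded", "reason"]) <= set(EXCLUSION_REASONS)
    n_exc = (out["status"] == "excluded").sum()
    log.info("risk-variant screen: %d in, %d included, %d excluded",
             len(out), len(out) - n_exc, n_exc)
    return out


def build_regions(risk_list: pd.DataFrame, flank: int = REGION_FLANK,
                  ) -> list[RiskRegion]:
    """Merge +/-flank intervals around included risk variants per chromosome.

    Coordinates are 1-based inclusive; a flank reaching past the chromosome
    start is clamped at 1.
    """
    inc = risk_list
    if "status" in risk_list.columns:
        inc = risk_list[risk_list["status"] == "included"]
    regions: list[RiskRegion] = []
    for chrom, sub in inc.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        cur_start = cur_end = None
        members: list[str] = []
        for _, row in sub.iterrows():
            s, e = max(1, int(row["pos"]) - flank), int(row["pos"]) + flank
            if cur_start is None:
                cur_start, cur_end, members = s, e, [row["rsid"]]
            elif s <= cur_end:  # 1-based inclusive overlap (shared >= 1 bp)
                cur_end = max(cur_end, e)
                members.append(row["rsid"])
            else:
                regions.append(RiskRegion(str(chrom), cur_start, cur_end,
                                          tuple(members)))
                cur_start, cur_end, members = s, e, [row["rsid"]]
        if cur_start is not None:
            regions.append(RiskRegion(str(chrom), cur_start, cur_end,
                                      tuple(members)))
    return regions


def _single_linkage_clusters(r2: np.ndarray, threshold: float) -> list[list[int]]:
    """Union-find single-linkage clustering on r^2 >= threshold."""
    n = r2.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if r2[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def build_loci(regions: list[RiskRegion], geno: GenotypeMatrix,
               ld_threshold: float = LD_THRESHOLD) -> list[RiskLocus]:
    """Cluster risk variants into loci and expand each with its LD set.

    The LD set of a locus is every region variant whose r^2 with *any*
    member risk variant reaches the threshold; member risk variants always
    belong to their own set. A region without polymorphic variants yields a
    single locus flagged ``empty``.
    """
    loci: list[RiskLocus] = []
    counter = 0
    variants = geno.variants
    for region in sorted(regions, key=lambda r: (r.chrom, r.start)):
        in_region = variants[
            (variants["chrom"] == region.chrom)
            & (variants["pos"] >= region.start)
            & (variants["pos"] <= region.end)
        ].index
        dos = geno.dosages[in_region].to_numpy() if len(in_region) else None
        poly = (
            pd.Index([])
            if dos is None
            else in_region[np.ptp(np.nan_to_num(dos), axis=0) > 0]
        )
        risk_present = [r for r in region.member_rsids if r in poly]
        if not risk_present:
            counter += 1
            loci.append(RiskLocus(
                locus_id=f"L{counter:03d}", region=region,
                risk_rsids=region.member_rsids, ld_variant_ids=(), empty=True))
            log.warning("region %s:%d-%d has no polymorphic risk variant",
                        region.chrom, region.start, region.end)
            continue
        poly_dos = geno.dosages[poly].to_numpy()
        r2 = _r2_matrix(poly_dos)
        pos_of = {v: i for i, v in enumerate(poly)}
        risk_idx = [pos_of[r] for r in risk_present]
        sub_r2 = r2[np.ix_(risk_idx, risk_idx)]
        for cluster in _single_linkage_clusters(sub_r2, ld_threshold):
            members = [risk_present[i] for i in cluster]
            member_idx = [pos_of[m] for m in members]
            best = r2[member_idx, :].max(axis=0)
            ld_set = set(poly[best >= ld_threshold]) | set(members)
            ordered = [v for v in in_region if v in ld_set]
            counter += 1
            loci.append(RiskLocus(
                locus_id=f"L{counter:03d}", region=region,
                risk_rsids=tuple(members), ld_variant_ids=tuple(ordered)))
    return loci


def locus_table(loci: list[RiskLocus]) -> pd.DataFrame:
    """Flat locus summary (one row per locus)."""
    rows = []
    for lo in loci:
        rows.append({
            "locus_id": lo.locus_id,
            "chrom": lo.region.chrom,
            "start": lo.region.start,
            "end": lo.region.end,
            "risk_rsids": ",".join(lo.risk_rsids),
            "n_ld_variants": len(lo.ld_variant_ids),
            "empty": lo.empty,
        })
    return pd.DataFrame(rows)
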