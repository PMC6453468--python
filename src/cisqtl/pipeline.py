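"""End-to-end orchestration: QC -> normalization -> covariates -> loci ->
stage-1 scan -> gene-wise significance -> stage-2 scan -> variant FDR ->
peak/classification -> summary.

Every threshold is a named, defaulted :class:`RunConfig` field; a run with
identical config and inputs reproduces identical tables. Per-stage outputs
are persisted as TSV with '#'-prefixed provenance headers when an output
directory is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from . import __version__
from .association import associate, residualize, stage1_pairs, stage2_pairs
from .loci import build_loci, build_regions, locus_table, ld_r2, screen_risk_variants
from .qc import (assemble_covariates, compute_expression_pcs, filter_genes,
                 filter_variants, mean_impute, normalize_expression)
from .significance import (calls_table, classify_gene, find_peak_variant,
                           gene_wise_significance, significance_table,
                           summarize, variant_level_fdr)
from .types import CovariateSet, ExpressionMatrix, GenotypeMatrix, PipelineError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths plus every tunable threshold (defaults = study values)."""

    genotypes: str | None = None          # dosage TSV or .vcf
    counts: str | None = None             # gene x sample TSV
    gene_annotation: str | None = None    # annotation TSV
    risk_variants: str | None = None      # rsid/chrom/pos TSV
    covariates: str | None = None         # sample covariate TSV
    out_dir: str | None = None

    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-5
    maf_min: float = 0.01
    allelic_r2_min: float = 0.3
    gene_median_min: float = 8
    pc_var_min: float = 0.01
    pc_max: int | None = None
    region_flank: int = 100_000
    cis_window: int = 1_100_000
    ld_threshold: float = 0.5
    gene_q_max: float = 0.01
    group1_floor: float = 0.5
    group2_floor: float = 0.2
    stage2_sig_q: float = 0.05
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class InputBundle:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    cell_fractions: pd.DataFrame
    risk_variants: pd.DataFrame


@dataclass
class RunResult:
    config: RunConfig
    loci: list
    locus_table: pd.DataFrame
    stage1: pd.DataFrame
    stage2: pd.DataFrame
    gene_significance: pd.DataFrame
    calls: pd.DataFrame
    summary: dict
    provenance: dict
    genotypes: GenotypeMatrix = None
    exclusions: dict = field(default_factory=dict)


def load_inputs(cfg: RunConfig) -> InputBundle:
    """Read and reconcile the five input files.

    Sample ids are intersected across genotypes, counts and covariates
    (order taken from the genotype file); drops are logged as warnings and
    fewer than 3 shared samples is an error.
    """
    for name in ("genotypes", "counts", "gene_annotation", "risk_variants",
                 "covariates"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise PipelineError(f"input path for {name!r} missing: {p}")
    gpath = str(cfg.genotypes)
    geno = qio.read_vcf(gpath) if gpath.endswith(".vcf") else qio.read_dosage_tsv(gpath)
    counts = qio.read_counts_tsv(cfg.counts)
    genes = qio.read_gene_annotation(cfg.gene_annotation)
    if not counts.index.equals(genes.index):
        genes = genes.loc[counts.index]
    if (genes["tss"] <= 0).any() or (geno.variants["pos"] <= 0).any():
        raise PipelineError("non-positive genomic coordinates in inputs")
    expr = ExpressionMatrix(counts=counts, genes=genes)
    covs = qio.read_covariates(cfg.covariates)
    risk = qio.read_risk_variants(cfg.risk_variants)

    shared = geno.sample_ids.intersection(expr.sample_ids).intersection(covs.index)
    shared = geno.sample_ids[geno.sample_ids.isin(shared)]  # genotype order
    for name, ids in (("genotypes", geno.sample_ids),
                      ("expression", expr.sample_ids),
                      ("covariates", covs.index)):
        dropped = set(ids) - set(shared)
        if dropped:
            log.warning("%d %s sample(s) dropped (absent elsewhere): %s",
                        len(dropped), name, sorted(dropped)[:5])
    if len(shared) < 3:
        raise PipelineError(f"only {len(shared)} shared samples across inputs")
    return InputBundle(
        genotypes=geno.subset_samples(shared),
        expression=expr.subset_samples(shared),
        cell_fractions=covs.loc[shared],
        risk_variants=risk,
    )


def run_from_bundle(bundle: InputBundle, cfg: RunConfig | None = None) -> RunResult:
    """Execute every stage on in-memory inputs."""
    cfg = cfg or RunConfig()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    prov = [f"cisqtl {__version__}", f"config {cfg.digest()}", f"seed {cfg.seed}"]

    # QC
    geno_qc, var_excl = filter_variants(
        bundle.genotypes, cfg.call_rate_min, cfg.hwe_p_min, cfg.maf_min,
        cfg.allelic_r2_min)
    geno_qc = mean_impute(geno_qc)
    expr = filter_genes(bundle.expression, cfg.gene_median_min)
    expr = normalize_expression(expr)

    # covariates
    pcs, pc_var = compute_expression_pcs(expr, cfg.pc_var_min, cfg.pc_max)
    covset = assemble_covariates(bundle.cell_fractions, pcs, pc_var)

    # residualization (shared covariate set for both matrices)
    expr_resid = residualize(expr.normalized, covset)
    geno_resid = residualize(geno_qc.dosages.T, covset).T
    n_cov = covset.n_covariates

    # risk loci
    screened = screen_risk_variants(bundle.risk_variants, geno_qc, cfg.maf_min)
    regions = build_regions(screened, cfg.region_flank)
    loci = build_loci(regions, geno_qc, cfg.ld_threshold)

    # stage 1
    pairs1 = stage1_pairs(loci, expr.genes, geno_qc.variants, cfg.cis_window)
    stage1 = associate(expr_resid, geno_resid, pairs1, n_cov) if len(pairs1) \
        else pd.DataFrame(columns=["gene_id", "variant_id", "locus_id",
                                   "stage", "beta", "t_stat", "p_value",
                                   "n_used", "flag"])
    sigs = gene_wise_significance(stage1, expr.genes["gene_class"],
                                  cfg.gene_q_max)
    sig_genes = [s.gene_id for s in sigs if s.significant]

    # stage 2
    pairs2 = stage2_pairs(expr.genes.loc[sig_genes], geno_qc, cfg.cis_window)
    stage2 = associate(expr_resid, geno_resid, pairs2, n_cov) if len(pairs2) \
        else stage1.iloc[0:0].copy()
    stage2 = variant_level_fdr(stage2)

    # peaks and classification
    both = pd.concat([stage1, stage2], ignore_index=True)
    pos = geno_qc.variants["pos"]
    calls = []
    gene_loci = pairs1.groupby("gene_id")["locus_id"].unique() if len(pairs1) \
        else pd.Series(dtype=object)
    locus_by_id = {lo.locus_id: lo for lo in loci}
    for gid in sig_genes:
        peak = find_peak_variant(gid, both, pos)
        for lid in sorted(gene_loci.get(gid, [])):
            calls.append(classify_gene(locus_by_id[lid], gid, peak, geno_qc,
                                       cfg.group1_floor, cfg.group2_floor))

    summary = summarize(calls, sigs, [lo for lo in loci if not lo.empty])
    summary["counts"] = {
        "variants_in": bundle.genotypes.n_variants,
        "variants_qc": geno_qc.n_variants,
        "genes_in": bundle.expression.counts.shape[0],
        "genes_expressed": expr.counts.shape[0],
        "risk_variants_in": len(bundle.risk_variants),
        "risk_variants_included": int((screened["status"] == "included").sum()),
        "n_loci": len(loci),
        "stage1_tests": int(len(stage1)),
        "stage2_tests": int(len(stage2)),
        "n_expression_pcs": int(pcs.shape[1]),
    }

    result = RunResult(
        config=cfg,
        loci=loci,
        locus_table=locus_table(loci),
        stage1=stage1,
        stage2=stage2,
        gene_significance=significance_table(sigs),
        calls=calls_table(calls),
        summary=summary,
        provenance={"version": __version__, "config_digest": cfg.digest(),
                    "seed": cfg.seed},
        genotypes=geno_qc,
        exclusions={"variants": var_excl, "risk_variants": screened},
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        qio.write_table(var_excl, out / "variant_exclusions.tsv", prov)
        qio.write_table(screened, out / "risk_variant_screen.tsv", prov)
        qio.write_table(result.locus_table, out / "loci.tsv", prov)
        qio.write_table(stage1, out / "stage1_associations.tsv", prov)
        qio.write_table(stage2, out / "stage2_associations.tsv", prov)
        qio.write_table(result.gene_significance,
                        out / "gene_significance.tsv", prov)
        qio.write_table(result.calls, out / "gene_group_calls.tsv", prov)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, default=_jsonable), encoding="utf-8")
        cfg.to_yaml(out / "config.yaml")
    return result


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Load inputs from the configured paths and run every stage."""
    return run_from_bundle(load_inputs(cfg), cfg)


def emit_regional_table(gene_id: str, result: RunResult) -> pd.DataFrame:
    """Per-variant table for a regional association plot of one gene.

    Columns: variant_id, pos, p_value, neglog10_p, r2_to_risk (max over the
    gene's best locus's risk variants), significant (stage-2 q threshold),
    is_risk_variant. Rows are exactly the gene's stage-2 window variants.
    """
    rec = result.stage2[result.stage2["gene_id"] == gene_id]
    if rec.empty:
        raise PipelineError(f"gene {gene_id} absent from stage-2 results")
    calls = result.calls[result.calls["gene_id"] == gene_id]
    if calls.empty:
        raise PipelineError(f"gene {gene_id} has no group call")
    best = calls.sort_values(["group", "locus_id"]).iloc[0]
    locus = next(lo for lo in result.loci if lo.locus_id == best["locus_id"])
    geno = result.genotypes
    rows = []
    for _, row in rec.iterrows():
        vid = row["variant_id"]
        dos = geno.dosages[vid].to_numpy()
        try:
            r2 = max(ld_r2(geno.dosages[r].to_numpy(), dos)
                     for r in locus.risk_rsids)
        except ValueError:
            r2 = np.nan
        p = row["p_value"]
        rows.append({
            "variant_id": vid,
            "pos": int(geno.variants.loc[vid, "pos"]),
            "p_value": p,
            "neglog10_p": -np.log10(p) if pd.notna(p) else np.nan,
            "r2_to_risk": r2,
            "significant": bool(pd.notna(row["q_value"])
                                and row["q_value"] <= result.config.stage2_sig_q),
            "is_risk_variant": vid in locus.risk_rsids,
        })
    return pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
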