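"""Readers and writers for the pipeline's tabular formats.

All tabular outputs are tab-delimited UTF-8 with '#'-prefixed provenance
header lines. Genotypes travel either as a dosage TSV (variants as rows:
metadata columns then one dosage column per sample, NA = missing) or as a
VCF with GT and/or DS FORMAT fields (DS preferred when present).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, ExpressionMatrix, PipelineError

log = logging.getLogger(__name__)

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "is_imputed",
              "allelic_r2"]


def _write_tsv(df: pd.DataFrame, path: Path, provenance: list[str] | None = None,
               index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kw)


# -- genotypes ----------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path,
                     provenance: list[str] | None = None) -> None:
    meta = geno.variants.reset_index()
    meta.columns = _META_COLS
    body = geno.dosages.T.reset_index(drop=True)
    _write_tsv(pd.concat([meta, body], axis=1), Path(path), provenance)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path)
    meta = df[_META_COLS].set_index("variant_id")
    meta["is_imputed"] = meta["is_imputed"].astype(bool)
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    dosages = pd.DataFrame(
        df[sample_cols].to_numpy(dtype=float).T,
        index=pd.Index(sample_cols, name="sample_id"),
        columns=meta.index,
    )
    return GenotypeMatrix(dosages=dosages, variants=meta)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS per sample."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(geno.sample_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Estimated alternate allele dosage">\n')
        for chrom in geno.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for vid, meta in geno.variants.iterrows():
            dos = geno.dosages[vid].to_numpy()
            fields = []
            for d in dos:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gts[int(np.clip(round(d), 0, 2))]}:{d:g}")
            fh.write(f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t"
                     f"{meta['ref']}\t{meta['alt']}\t.\t.\t.\tGT:DS\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path, prefer_ds: bool = True) -> GenotypeMatrix:
    """Load a VCF via cyvcf2; DS used when present, else GT allele sum."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise PipelineError("reading VCF requires cyvcf2") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    used_ds = False
    for var in vcf:
        ds = None
        if prefer_ds:
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            used_ds = True
        else:
            # cyvcf2 gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
            gt = np.asarray(var.gt_types, dtype=float)
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                            default=np.nan)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        cols.append(col)
    if used_ds:
        log.info("VCF %s: DS field used for dosages", path)
    dosages = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=pd.Index(ids, name="variant_id"),
    )
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
         "is_imputed": False, "allelic_r2": np.nan},
        index=dosages.columns,
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


# -- expression ----------------------------------------------------------------

def write_counts_tsv(expr: ExpressionMatrix, path,
                     provenance: list[str] | None = None) -> None:
    df = expr.counts.copy()
    df.index.name = "gene_id"
    _write_tsv(df, Path(path), provenance, index=True)


def read_counts_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """MatrixMarket counts with companion gene/sample id lists."""
    from scipy.io import mmread
    m = mmread(mtx_path).toarray().astype(np.int64)
    genes = [line.strip() for line in open(genes_path, encoding="utf-8")
             if line.strip()]
    samples = [line.strip() for line in open(samples_path, encoding="utf-8")
               if line.strip()]
    return pd.DataFrame(m, index=pd.Index(genes, name="gene_id"),
                        columns=samples)


def write_gene_annotation(genes: pd.DataFrame, path,
                          provenance: list[str] | None = None) -> None:
    df = genes.copy()
    df.index.name = "gene_id"
    _write_tsv(df, Path(path), provenance, index=True)


def read_gene_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    need = {"gene_class", "chrom", "tss", "tes", "gc_fraction"}
    missing = need - set(df.columns)
    if missing:
        raise PipelineError(f"gene annotation missing columns: {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


# -- small tables ---------------------------------------------------------------

def write_risk_variants(risk: pd.DataFrame, path,
                        provenance: list[str] | None = None) -> None:
    _write_tsv(risk, Path(path), provenance)


def read_risk_variants(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"rsid", "chrom", "pos"}
    if not need <= set(df.columns):
        raise PipelineError(f"risk-variant table needs columns {sorted(need)}")
    return df


def write_covariates(cov: pd.DataFrame, path,
                     provenance: list[str] | None = None) -> None:
    df = cov.copy()
    df.index.name = "sample_id"
    _write_tsv(df, Path(path), provenance, index=True)


def read_covariates(path) -> pd.DataFrame:
    return _read_tsv(path, index_col=0)


def write_table(df: pd.DataFrame, path, provenance: list[str] | None = None,
                index: bool = False) -> None:
    _write_tsv(df, Path(path), provenance, index=index)
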