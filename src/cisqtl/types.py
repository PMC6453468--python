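"""Core data containers shared by every stage of the pipeline.

Conventions used throughout:

* genotype dosages are expected alternate-allele counts in [0, 2]
  (fractional after imputation); missing dosages are ``NaN``, never 0;
* genomic coordinates are 1-based and intervals are inclusive at both ends;
* gene classes are one of ``protein_coding``, ``lncRNA``, ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_CLASSES = ("protein_coding", "lncRNA", "other")

#: columns required in a variant metadata table
VARIANT_META_COLUMNS = ("chrom", "pos", "ref", "alt", "is_imputed", "allelic_r2")

#: columns required in a gene metadata table
GENE_META_COLUMNS = ("gene_class", "chrom", "tss", "tes", "strand", "gc_fraction")


class PipelineError(RuntimeError):
    """Raised when a stage receives input it cannot process."""


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix plus per-variant metadata.

    ``dosages``: DataFrame indexed by sample id, columns are variant ids,
    values in [0, 2] with NaN for missing calls.
    ``variants``: DataFrame indexed by variant id with columns
    :data:`VARIANT_META_COLUMNS`; positions strictly increase within a
    chromosome.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_META_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        if not self.dosages.columns.equals(self.variants.index):
            raise ValueError("dosage columns and variant metadata index disagree")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant from non-missing dosages."""
        p = self.dosages.mean(axis=0, skipna=True) / 2.0
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1)

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[:, variant_ids],
            variants=self.variants.loc[variant_ids],
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[sample_ids],
            variants=self.variants,
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with optional normalized values.

    ``counts``: DataFrame indexed by gene id, columns sample ids,
    non-negative integers. ``genes``: metadata indexed by gene id with
    columns :data:`GENE_META_COLUMNS`. ``normalized`` stays ``None`` until
    :func:`cisqtl.qc.normalize_expression` fills it; it then shares the
    (possibly filtered) gene index and sample columns of ``counts``.
    """

    counts: pd.DataFrame
    genes: pd.DataFrame
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GENE_META_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene metadata missing columns: {missing}")
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("count rows and gene metadata index disagree")
        bad = self.genes.loc[self.genes["tss"] > self.genes["tes"]]
        if len(bad):
            raise ValueError(f"tss > tes for genes: {list(bad.index[:5])}")
        unknown = set(self.genes["gene_class"]) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class label(s): {sorted(unknown)}")
        if self.normalized is not None:
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized matrix shape differs from counts")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[gene_ids],
            genes=self.genes.loc[gene_ids],
            normalized=None if self.normalized is None else self.normalized.loc[gene_ids],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[:, sample_ids],
            genes=self.genes,
            normalized=None if self.normalized is None else self.normalized.loc[:, sample_ids],
        )


@dataclass
class CovariateSet:
    """Per-sample covariates used for adjustment.

    ``table`` holds one row per sample: the two histology fractions
    (``lymphocyte_pct``, ``epithelial_pct``) followed by expression
    principal components ``PC1..PCk``. ``pc_variance_explained`` gives the
    per-PC variance fraction (non-increasing).
    """

    table: pd.DataFrame
    pc_variance_explained: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float)
    )

    def __post_init__(self) -> None:
        frac = self.pc_variance_explained.to_numpy()
        if frac.size and np.any(np.diff(frac) > 1e-12):
            raise ValueError("PC variance fractions must be non-increasing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_covariates(self) -> int:
        return self.table.shape[1]


# -- risk loci -------------------------------------------------------------

EXCLUSION_REASONS = ("low_maf", "perfect_ld", "not_in_genotypes")


@dataclass(frozen=True)
class RiskRegion:
    """Merged +/-100 kb physical interval around one or more risk variants."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    member_rsids: tuple[str, ...]


@dataclass
class RiskLocus:
    """A cluster of risk variants (pairwise r^2 >= 0.5) plus its LD set.

    ``ld_variant_ids`` holds every QC-passing variant in the region whose
    r^2 with at least one member risk variant reaches the LD threshold;
    member risk variants are always included.
    """

    locus_id: str
    region: RiskRegion
    risk_rsids: tuple[str, ...]
    ld_variant_ids: tuple[str, ...]
    empty: bool = False  # no polymorphic variant available in the region


@dataclass(frozen=True)
class GeneSignificance:
    """Gene-centric significance from the stage-1 scan."""

    gene_id: str
    gene_class: str
    n_tests: int
    min_p: float
    bonferroni_min_p: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class GeneGroupCall:
    """Per (locus, gene) candidate classification by peak-variant LD."""

    locus_id: str
    gene_id: str
    peak_variant_id: str
    peak_p: float
    r2_to_risk: float
    group: int  # 1: r2 >= 0.5, 2: 0.2 <= r2 < 0.5, 3: r2 < 0.2
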